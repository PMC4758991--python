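"""Static detector physics: crystal, optics and photodetector parameters.

The optical model is deliberately coarse-grained.  A scintillation event at
depth ``Z`` in a crystal of length ``L`` sends a fraction ``f_A(Z)`` of its
light to the entrance surface A and ``f_B(Z) = 1 - f_A(Z)`` to the rear
surface B, with a linear depth dependence controlled by the near-end sharing
fraction ``a``.  Photons arriving at a surface do so in a swarm whose leading
edge is set by geometry and whose tail is an exponential with a dispersion
time constant ``D(s) = n*sqrt(d1^2 + d2^2 s^2)`` for geometric path length
``s``.  The photodetector converts each photon into a bi-exponential single
electron response (SER) pulse and adds Gaussian transit-time jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_CM_PER_NS",
    "FWHM_PER_SIGMA",
    "PAIR_FACTOR",
    "CRT_FACTOR",
    "ScintillatorSpec",
    "OpticalTransportSpec",
    "PhotodetectorSpec",
    "signal_fractions",
    "dispersion_parameter",
    "ser_amplitude",
    "ser_peak_time",
    "ser_peak_amplitude",
    "tabulate_ser",
]

#: Speed of light in vacuum, cm/ns.
SPEED_OF_LIGHT_CM_PER_NS = 29.9792458
#: Conversion from a Gaussian standard deviation to its full width at half max.
FWHM_PER_SIGMA = 2.3548
#: sqrt(2): converts a single-detector width to the width for a detector pair.
PAIR_FACTOR = 1.4142
#: Combined factor taking a per-event time standard deviation to a CRT (fwhm).
CRT_FACTOR = FWHM_PER_SIGMA * PAIR_FACTOR


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class ScintillatorSpec:
    """Intrinsic crystal parameters.

    Parameters
    ----------
    attenuation_length_cm : float
        Exponential attenuation depth of 511 keV annihilation photons (mu).
    refractive_index : float
        Index of refraction n at the emission wavelength.
    length_cm : float
        Full crystal length L; the entrance surface is A (Z=0), the rear
        surface is B (Z=L).
    rise_time_ns, decay_time_ns : float
        Scintillation rise and decay time constants tau_r, tau_d.
    photoelectron_yield : float
        Total photoelectrons N_pe per fully absorbed 511 keV photon, with
        light transport efficiency, fill factor and quantum efficiency
        already folded in.
    """

    attenuation_length_cm: float
    refractive_index: float
    length_cm: float
    rise_time_ns: float
    decay_time_ns: float
    photoelectron_yield: float

    def __post_init__(self) -> None:
        _require(self.attenuation_length_cm > 0, "attenuation_length_cm must be > 0")
        _require(self.refractive_index >= 1, "refractive_index must be >= 1")
        _require(self.length_cm > 0, "length_cm must be > 0")
        _require(self.rise_time_ns >= 0, "rise_time_ns must be >= 0")
        _require(self.decay_time_ns > 0, "decay_time_ns must be > 0")
        _require(
            self.rise_time_ns < self.decay_time_ns,
            "rise_time_ns must be < decay_time_ns",
        )
        _require(self.photoelectron_yield > 0, "photoelectron_yield must be > 0")


@dataclass(frozen=True)
class OpticalTransportSpec:
    """Parameterization of optical photon sharing and time dispersion.

    ``near_end_fraction`` (a) is the fraction of light collected at the near
    end surface for an interaction at that surface; a = 0.5 means no depth
    sensitivity, a = 1 means no light at the far end.  ``dispersion_offset_ns``
    (d1) and ``dispersion_slope_ns_per_cm`` (d2) shape the dispersion
    constant D(s) = n*sqrt(d1^2 + d2^2 s^2).
    """

    near_end_fraction: float = 0.7
    dispersion_offset_ns: float = 0.00873
    dispersion_slope_ns_per_cm: float = 0.0186

    def __post_init__(self) -> None:
        _require(
            0.5 <= self.near_end_fraction <= 1.0,
            "near_end_fraction must be in [0.5, 1.0]",
        )
        _require(self.dispersion_offset_ns >= 0, "dispersion_offset_ns must be >= 0")
        _require(
            self.dispersion_slope_ns_per_cm >= 0,
            "dispersion_slope_ns_per_cm must be >= 0",
        )


@dataclass(frozen=True)
class PhotodetectorSpec:
    """Photodetector transit-time jitter and single-electron-response shape."""

    jitter_fwhm_ns: float
    ser_rise_ns: float = 0.2
    ser_decay_ns: float = 2.0

    def __post_init__(self) -> None:
        _require(self.jitter_fwhm_ns >= 0, "jitter_fwhm_ns must be >= 0")
        _require(self.ser_rise_ns > 0, "ser_rise_ns must be > 0")
        _require(
            self.ser_rise_ns < self.ser_decay_ns,
            "ser_rise_ns must be < ser_decay_ns (degenerate SER shape)",
        )


def signal_fractions(depth_cm, spec: OpticalTransportSpec, length_cm: float):
    """Fractions of the scintillation light reaching surfaces A and B.

    f_A(Z) = a - (2a - 1) Z / L and f_B = 1 - f_A; both lie in [1-a, a] and
    sum to exactly 1.  Accepts scalars or arrays.
    """
    depth = np.asarray(depth_cm, dtype=float)
    if np.any(depth < 0) or np.any(depth > length_cm):
        raise ValueError(f"depth_cm must lie in [0, {length_cm}]")
    a = spec.near_end_fraction
    frac_a = a - (2.0 * a - 1.0) * depth / length_cm
    frac_b = 1.0 - frac_a
    if np.isscalar(depth_cm):
        return float(frac_a), float(frac_b)
    return frac_a, frac_b


def dispersion_parameter(
    path_argument_cm, scint: ScintillatorSpec, opt: OpticalTransportSpec
):
    """Exponential time-dispersion constant for a swarm with geometric path s.

    D(s) = n * sqrt(d1^2 + d2^2 s^2); strictly increasing in s (for d2 > 0)
    and linear in the refractive index.
    """
    s = np.asarray(path_argument_cm, dtype=float)
    if np.any(s < 0):
        raise ValueError("path_argument_cm must be >= 0")
    d1 = opt.dispersion_offset_ns
    d2 = opt.dispersion_slope_ns_per_cm
    disp = scint.refractive_index * np.sqrt(d1 * d1 + d2 * d2 * s * s)
    if np.isscalar(path_argument_cm):
        return float(disp)
    return disp


def ser_amplitude(time_ns, pd: PhotodetectorSpec):
    """Unit-area bi-exponential SER: S(t) = (e^{-t/Sd} - e^{-t/Sr})/(Sd - Sr).

    Zero for t < 0; S(0) = 0; the integral over [0, inf) is exactly 1.
    """
    t = np.asarray(time_ns, dtype=float)
    sr, sd = pd.ser_rise_ns, pd.ser_decay_ns
    with np.errstate(over="ignore"):
        val = (np.exp(-t / sd) - np.exp(-t / sr)) / (sd - sr)
    val = np.where(t < 0, 0.0, val)
    if np.isscalar(time_ns):
        return float(val)
    return val


def ser_peak_time(pd: PhotodetectorSpec) -> float:
    """Time of the SER maximum: t* = Sr*Sd/(Sd-Sr) * ln(Sd/Sr)."""
    sr, sd = pd.ser_rise_ns, pd.ser_decay_ns
    return sr * sd / (sd - sr) * math.log(sd / sr)


def ser_peak_amplitude(pd: PhotodetectorSpec) -> float:
    """Peak value of the unit-area SER; one photoelectron has this amplitude.

    Pulse amplitudes elsewhere in the package are quoted in SER-peak units
    (one photoelectron contributes a pulse of peak 1.0), obtained by dividing
    the unit-area pulse by this value.
    """
    return float(ser_amplitude(ser_peak_time(pd), pd))


def tabulate_ser(
    pd: PhotodetectorSpec, dt_ns: float = 1e-4, relative_cutoff: float = 1e-6
):
    """Tabulate the SER on a uniform grid out to where it falls below cutoff.

    Returns ``(grid, values)`` with values in unit-area form.  The table ends
    at the first grid node past the peak where S(t) < relative_cutoff * peak;
    beyond that point the SER is treated as zero.
    """
    peak = ser_peak_amplitude(pd)
    # the tail decays as exp(-t/Sd)/(Sd-Sr); solve for the cutoff time
    sr, sd = pd.ser_rise_ns, pd.ser_decay_ns
    t_cut = -sd * math.log(relative_cutoff * peak * (sd - sr))
    n = int(math.ceil(t_cut / dt_ns)) + 1
    grid = np.arange(n) * dt_ns
    return grid, ser_amplitude(grid, pd)
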