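"""Annihilation-photon interaction depths and photoelectron counts.

A 511 keV photon entering the crystal at surface A interacts at an
exponentially distributed depth truncated to the crystal length.  The light
reaching each end surface produces an expected photoelectron count, and the
observed counts fluctuate with Gaussian noise of variance equal to the
expectation (the large-count limit of counting statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .physics import ScintillatorSpec, OpticalTransportSpec, signal_fractions

__all__ = [
    "EventRecord",
    "EventBatch",
    "SimulationConfig",
    "RngStreams",
    "sample_interaction_depths",
    "expected_photoelectrons",
    "observed_photoelectrons",
    "generate_events",
]


@dataclass(frozen=True)
class EventRecord:
    """One annihilation-photon interaction."""

    depth_cm: float
    expected_pe_a: float
    expected_pe_b: float
    observed_pe_a: int
    observed_pe_b: int


@dataclass
class EventBatch:
    """Vectorized collection of interaction events (arrays of equal length)."""

    depth_cm: np.ndarray
    expected_pe_a: np.ndarray
    expected_pe_b: np.ndarray
    observed_pe_a: np.ndarray
    observed_pe_b: np.ndarray

    @property
    def n(self) -> int:
        return len(self.depth_cm)

    def record(self, k: int) -> EventRecord:
        return EventRecord(
            float(self.depth_cm[k]),
            float(self.expected_pe_a[k]),
            float(self.expected_pe_b[k]),
            int(self.observed_pe_a[k]),
            int(self.observed_pe_b[k]),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Run-size and reproducibility settings.

    ``fixed_depth_cm`` replaces exponential depth sampling by a delta
    function at the given depth (used for depth-sensitivity studies);
    calibration always samples the full depth distribution.
    """

    n_events: int = 100_000
    seed: int = 12345
    calibration_n_events: Optional[int] = None
    depth_band_count: int = 15
    fixed_depth_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.depth_band_count < 2:
            raise ValueError("depth_band_count must be >= 2")

    @property
    def calibration_events(self) -> int:
        return self.calibration_n_events or self.n_events


_STREAM_NAMES = ("depths", "counts", "photons", "jitter")


@dataclass
class RngStreams:
    """Independent, named random streams derived from one master seed.

    Separate generators for depths, counts, photon emission times and
    photodetector jitter keep each physical noise source reproducible in
    isolation.  ``child(tag)`` derives a further disjoint family (used for
    calibration runs).
    """

    seed: int
    depths: np.random.Generator = field(init=False)
    counts: np.random.Generator = field(init=False)
    photons: np.random.Generator = field(init=False)
    jitter: np.random.Generator = field(init=False)

    def __post_init__(self) -> None:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STREAM_NAMES))
        for name, child in zip(_STREAM_NAMES, children):
            setattr(self, name, np.random.default_rng(child))

    def child(self, tag: int) -> "RngStreams":
        # keyed hash keeps child families disjoint from the parent spawn tree
        derived = np.random.SeedSequence([self.seed, tag]).generate_state(1)[0]
        return RngStreams(seed=int(derived) % 2**31)


def sample_interaction_depths(
    n_events: int, scint: ScintillatorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sample interaction depths Z = -mu ln(R), R uniform on [e^{-L/mu}, 1].

    This is inverse-transform sampling of the exponential attenuation density
    truncated to the crystal, so every depth lies in [0, L].
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    mu = scint.attenuation_length_cm
    lo = np.exp(-scint.length_cm / mu)
    r = rng.uniform(lo, 1.0, size=n_events)
    return -mu * np.log(r)


def expected_photoelectrons(
    depth_cm, scint: ScintillatorSpec, opt: OpticalTransportSpec
):
    """Expected photoelectron counts (N_A, N_B) = N_pe * (f_A(Z), f_B(Z))."""
    frac_a, frac_b = signal_fractions(depth_cm, opt, scint.length_cm)
    n_pe = scint.photoelectron_yield
    return n_pe * np.asarray(frac_a), n_pe * np.asarray(frac_b)


def observed_photoelectrons(n_a, n_b, rng: np.random.Generator):
    """Observed counts m = N + Gaussian(0, variance N), rounded and clamped.

    The Gaussian noise term has variance equal to the expected count.  The
    result is rounded to the nearest integer and clamped at zero so that it
    can index discrete photoelectron generation; a zero expectation gives a
    zero count with no noise.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a < 0) or np.any(n_b < 0):
        raise ValueError("expected counts must be >= 0")
    m_a = n_a + np.sqrt(n_a) * rng.standard_normal(n_a.shape)
    m_b = n_b + np.sqrt(n_b) * rng.standard_normal(n_b.shape)
    m_a = np.clip(np.rint(m_a), 0, None).astype(np.int64)
    m_b = np.clip(np.rint(m_b), 0, None).astype(np.int64)
    return m_a, m_b


def generate_events(
    n_events: int,
    scint: ScintillatorSpec,
    opt: OpticalTransportSpec,
    streams: RngStreams,
    fixed_depth_cm: Optional[float] = None,
) -> EventBatch:
    """Generate a batch of interactions: depths and photoelectron counts."""
    if fixed_depth_cm is None:
        depths = sample_interaction_depths(n_events, scint, streams.depths)
    else:
        if not 0 <= fixed_depth_cm <= scint.length_cm:
            raise ValueError("fixed_depth_cm must lie in [0, L]")
        depths = np.full(n_events, float(fixed_depth_cm))
    n_a, n_b = expected_photoelectrons(depths, scint, opt)
    m_a, m_b = observed_photoelectrons(n_a, n_b, streams.counts)
    return EventBatch(depths, n_a, n_b, m_a, m_b)
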