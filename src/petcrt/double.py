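"""Double-ended readout: DOI estimation, delay/variance calibration, and
corrected, inverse-variance-weighted entrance-time estimators.

With photodetectors on both end surfaces, the ratio of the two signals
estimates the depth of interaction (DOI).  Each detector's trigger time is
corrected for the annihilation-photon transit, the optical leading-edge
delay, and the depth- and level-dependent mean trigger delay (calibrated in
a preliminary run), giving two separate estimates E_A, E_B of the entrance
time.  Combining them — simple average or inverse-variance weighted average
— nearly eliminates depth-dependent timing spread.  Seven CRT summaries are
produced:

  W_DA, W_DB    raw per-detector trigger times
  W_DAB         simple average of the raw trigger times
  W_EA, W_EB    corrected entrance-time estimates
  W_EAB         simple average of E_A and E_B
  W_WAB         inverse-variance weighted average of E_A and E_B

plus W_Z, the fwhm of the DOI estimation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .events import RngStreams, SimulationConfig, generate_events
from .physics import (
    SPEED_OF_LIGHT_CM_PER_NS,
    FWHM_PER_SIGMA,
    OpticalTransportSpec,
    PhotodetectorSpec,
    ScintillatorSpec,
)
from .pulse import TriggerTable, batch_trigger_times, default_cf_table
from .stats import CrtSummary, summarize_trigger_matrix
from .timing import ReadoutMode, build_batch_trains

__all__ = [
    "CalibrationTables",
    "DoubleEndedRun",
    "DoubleEndedResult",
    "estimate_doi",
    "calibrate",
    "correct_entrance_times",
    "combine_estimates",
    "run_double_ended",
]

_CHUNK_PE_BUDGET = 20_000_000


def _fingerprint(
    scint: ScintillatorSpec,
    opt: OpticalTransportSpec,
    pd_spec: PhotodetectorSpec,
    table: TriggerTable,
) -> Dict[str, float]:
    fp = {}
    for prefix, obj in (("scint", scint), ("opt", opt), ("pd", pd_spec)):
        for name, value in vars(obj).items():
            fp[f"{prefix}.{name}"] = float(value)
    fp["trigger.kind"] = table.kind.value
    fp["trigger.levels"] = [float(x) for x in table.levels]
    return fp


@dataclass
class CalibrationTables:
    """Depth-banded mean trigger delays and entrance-time variances.

    ``delay_a[j, n]`` is the mean lag, for events in DOI band j, between the
    earliest-possible-photon arrival at detector A and the level-n trigger;
    ``var_a[j, n]`` is the band variance of the corrected entrance-time
    estimate E_A.  Lookup at an estimated depth interpolates linearly between
    band centers with constant extrapolation beyond the end bands.
    """

    band_centers_cm: np.ndarray
    delay_a: np.ndarray
    delay_b: np.ndarray
    var_a: np.ndarray
    var_b: np.ndarray
    n_calibration_events: int
    fingerprint: Dict = field(default_factory=dict)

    def _interp(self, table: np.ndarray, z: np.ndarray) -> np.ndarray:
        out = np.empty((len(z), table.shape[1]))
        for n in range(table.shape[1]):
            out[:, n] = np.interp(z, self.band_centers_cm, table[:, n])
        return out

    def delays_at(self, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return self._interp(self.delay_a, z), self._interp(self.delay_b, z)

    def variances_at(self, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return self._interp(self.var_a, z), self._interp(self.var_b, z)

    def to_json(self, path) -> None:
        import json

        payload = {
            "band_centers_cm": self.band_centers_cm.tolist(),
            "delay_a": self.delay_a.tolist(),
            "delay_b": self.delay_b.tolist(),
            "var_a": self.var_a.tolist(),
            "var_b": self.var_b.tolist(),
            "n_calibration_events": self.n_calibration_events,
            "fingerprint": self.fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationTables":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            band_centers_cm=np.asarray(payload["band_centers_cm"]),
            delay_a=np.asarray(payload["delay_a"]),
            delay_b=np.asarray(payload["delay_b"]),
            var_a=np.asarray(payload["var_a"]),
            var_b=np.asarray(payload["var_b"]),
            n_calibration_events=int(payload["n_calibration_events"]),
            fingerprint=payload["fingerprint"],
        )


def estimate_doi(m_a, m_b, opt: OpticalTransportSpec, length_cm: float):
    """DOI estimate from the two observed signals (functional inverse of the
    linear light-sharing relation), clamped to the crystal [0, L].

    Z_hat = (L/2) * [1 - ((m_A - m_B)/(m_A + m_B)) / (2a - 1)].
    Works on counts or pulse heights; scalars or arrays.
    """
    a = opt.near_end_fraction
    if a == 0.5:
        raise ValueError("a = 0.5 has no DOI sensitivity; cannot estimate depth")
    m_a = np.asarray(m_a, dtype=float)
    m_b = np.asarray(m_b, dtype=float)
    total = m_a + m_b
    if np.any(total <= 0):
        raise ValueError("DOI estimate undefined for events with no signal")
    ratio = (m_a - m_b) / total
    z = (length_cm / 2.0) * (1.0 - ratio / (2.0 * a - 1.0))
    z = np.clip(z, 0.0, length_cm)
    if z.ndim == 0:
        return float(z)
    return z


def combine_estimates(e_a, e_b, v_a, v_b):
    """Simple and inverse-variance-weighted averages of the two estimates.

    E_AB = (E_A + E_B)/2; E_WAB = (E_A/V_A + E_B/V_B)/(1/V_A + 1/V_B).
    The weighted value always lies between E_A and E_B.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if np.any(v_a <= 0) or np.any(v_b <= 0):
        raise ValueError("variances must be positive (calibration error)")
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    e_ab = 0.5 * (e_a + e_b)
    w_a = 1.0 / v_a
    w_b = 1.0 / v_b
    e_wab = (e_a * w_a + e_b * w_b) / (w_a + w_b)
    if e_ab.ndim == 0:
        return float(e_ab), float(e_wab)
    return e_ab, e_wab


def _geometric_delays(
    z: np.ndarray, scint: ScintillatorSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Earliest-possible-photon arrival times at A and B for depth z."""
    c = SPEED_OF_LIGHT_CM_PER_NS
    n = scint.refractive_index
    return z / c + n * z / c, z / c + n * (scint.length_cm - z) / c


def correct_entrance_times(
    t_a: np.ndarray,
    t_b: np.ndarray,
    doi_estimate: np.ndarray,
    scint: ScintillatorSpec,
    calib: CalibrationTables,
):
    """Entrance-time estimates from raw trigger times and a DOI estimate.

    E_A = T_A - Z/c - nZ/c - delta_A(Z);  E_B = T_B - Z/c - n(L-Z)/c -
    delta_B(Z), with the calibrated delays interpolated at the estimated
    depth.  Inputs may be (n_events, n_levels) matrices.
    """
    z = np.clip(np.asarray(doi_estimate, dtype=float), 0.0, scint.length_cm)
    geom_a, geom_b = _geometric_delays(z, scint)
    d_a, d_b = calib.delays_at(z)
    e_a = t_a - geom_a[:, None] - d_a
    e_b = t_b - geom_b[:, None] - d_b
    return e_a, e_b


@dataclass
class DoubleEndedRun:
    """Configuration bundle for one double-ended CRT calculation.

    ``doi_from_pulse_heights`` switches the DOI estimator input from the
    observed photoelectron counts to the two pulse maxima.
    """

    scint: ScintillatorSpec
    opt: OpticalTransportSpec
    pd: PhotodetectorSpec
    trigger_table: TriggerTable = field(default_factory=default_cf_table)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    doi_from_pulse_heights: bool = False


@dataclass
class DoubleEndedResult:
    """Seven CRT summaries plus the DOI resolution, from one run."""

    w_da: CrtSummary
    w_db: CrtSummary
    w_dab: CrtSummary
    w_ea: CrtSummary
    w_eb: CrtSummary
    w_eab: CrtSummary
    w_wab: CrtSummary
    w_z_fwhm_cm: float
    n_events_used: int
    n_events_excluded: int
    #: mean of the corrected entrance-time estimates at their optimal levels
    #: (consistency diagnostics; both should be ~0 after calibration)
    mean_entrance_a: float = 0.0
    mean_entrance_b: float = 0.0
    #: mean DOI estimation error (cm); ~0 for an unbiased estimator
    mean_doi_error_cm: float = 0.0
    calibration: Optional[CalibrationTables] = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("w_da", "w_db", "w_dab", "w_ea", "w_eb", "w_eab", "w_wab"):
            s: CrtSummary = getattr(self, name)
            rows.append(
                {
                    "estimator": name.upper().replace("W_", "W_"),
                    "crt_ns_fwhm": s.crt_at_optimum_ns,
                    "optimal_level": s.optimal_level,
                    "standard_error_ns": s.standard_error_ns,
                    "n_events": s.n_events_used,
                }
            )
        return pd.DataFrame(rows)


def _chunked(n_events: int, pe_per_event: float):
    per_chunk = max(1, int(_CHUNK_PE_BUDGET / max(pe_per_event, 1.0)))
    left = n_events
    while left > 0:
        take = min(per_chunk, left)
        yield take
        left -= take


def _simulate_triggers(
    n_events: int,
    scint: ScintillatorSpec,
    opt: OpticalTransportSpec,
    pd_spec: PhotodetectorSpec,
    table: TriggerTable,
    streams: RngStreams,
    fixed_depth_cm: Optional[float],
):
    """Generate events and both detectors' trigger times and pulse maxima.

    Events with an empty train on either detector are dropped (both triggers
    would be needed downstream); returns the kept batch columns and a tally
    of exclusions.
    """
    zs, mas, mbs, pas, pbs, tas, tbs = [], [], [], [], [], [], []
    excluded = 0
    for size in _chunked(n_events, scint.photoelectron_yield):
        batch = generate_events(size, scint, opt, streams, fixed_depth_cm)
        trains = build_batch_trains(
            batch, ReadoutMode.DOUBLE, scint, opt, pd_spec, streams
        )
        fa, sa, ca = trains["A"]
        fb, sb, cb = trains["B"]
        keep = (ca > 0) & (cb > 0)
        excluded += int(np.sum(~keep))
        pmax_a, trig_a = batch_trigger_times(fa, sa, ca, pd_spec, table)
        pmax_b, trig_b = batch_trigger_times(fb, sb, cb, pd_spec, table)
        zs.append(batch.depth_cm[keep])
        mas.append(batch.observed_pe_a[keep])
        mbs.append(batch.observed_pe_b[keep])
        pas.append(pmax_a[keep])
        pbs.append(pmax_b[keep])
        tas.append(trig_a[keep])
        tbs.append(trig_b[keep])
    return (
        np.concatenate(zs),
        np.concatenate(mas),
        np.concatenate(mbs),
        np.concatenate(pas),
        np.concatenate(pbs),
        np.vstack(tas),
        np.vstack(tbs),
        excluded,
    )


def calibrate(
    scint: ScintillatorSpec,
    opt: OpticalTransportSpec,
    pd_spec: PhotodetectorSpec,
    trigger_table: TriggerTable,
    sim: SimulationConfig,
) -> CalibrationTables:
    """Two-pass preliminary run building the delay and variance tables.

    Pass 1 bins calibration events by their *true* depth (as a laser scan of
    the crystal would provide) and tabulates the mean trigger delay per band
    and level: delta = mean(T - Z/c - n*path/c).  Pass 2 applies those delays
    (interpolated at the true depth) and tabulates the band variances of the
    corrected entrance-time estimates.  The calibration RNG streams are
    disjoint from the measurement streams.
    """
    n_cal = sim.calibration_events
    n_bands = sim.depth_band_count
    streams = RngStreams(sim.seed).child(tag=0xCA11B)
    length = scint.length_cm
    z, m_a, m_b, _, _, trig_a, trig_b, _ = _simulate_triggers(
        n_cal, scint, opt, pd_spec, trigger_table, streams, fixed_depth_cm=None
    )
    edges = np.linspace(0.0, length, n_bands + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    band = np.clip(np.digitize(z, edges) - 1, 0, n_bands - 1)
    geom_a, geom_b = _geometric_delays(z, scint)
    lag_a = trig_a - geom_a[:, None]
    lag_b = trig_b - geom_b[:, None]
    n_levels = trigger_table.n_levels
    delay_a = np.empty((n_bands, n_levels))
    delay_b = np.empty((n_bands, n_levels))
    # levels a pulse never reaches (possible with leading-edge tables) leave
    # NaN cells; those levels simply have no calibrated estimator downstream
    for j in range(n_bands):
        in_band = band == j
        if not np.any(in_band):
            raise ValueError(
                f"sparse calibration: no events in depth band {j} "
                f"(increase calibration_n_events or reduce depth_band_count)"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            delay_a[j] = np.nanmean(lag_a[in_band], axis=0)
            delay_b[j] = np.nanmean(lag_b[in_band], axis=0)
    # pass 2: variances of the corrected entrance times, delays looked up at
    # the true depth (the calibration knows Z exactly)
    partial = CalibrationTables(
        centers, delay_a, delay_b, np.ones_like(delay_a), np.ones_like(delay_b), n_cal
    )
    e_a, e_b = correct_entrance_times(trig_a, trig_b, z, scint, partial)
    var_a = np.empty((n_bands, n_levels))
    var_b = np.empty((n_bands, n_levels))
    for j in range(n_bands):
        in_band = band == j
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var_a[j] = np.nanvar(e_a[in_band], axis=0, ddof=1)
            var_b[j] = np.nanvar(e_b[in_band], axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        if np.any(var_a <= 0) or np.any(var_b <= 0):
            raise ValueError("calibration produced a non-positive variance band")
    return CalibrationTables(
        band_centers_cm=centers,
        delay_a=delay_a,
        delay_b=delay_b,
        var_a=var_a,
        var_b=var_b,
        n_calibration_events=n_cal,
        fingerprint=_fingerprint(scint, opt, pd_spec, trigger_table),
    )


def run_double_ended(
    run: DoubleEndedRun, calib: Optional[CalibrationTables] = None
) -> DoubleEndedResult:
    """Execute the double-ended Monte Carlo and summarize all estimators.

    If no calibration tables are supplied, a calibration run (same physics,
    disjoint random streams) is performed first.  Supplied tables must have
    been built for the identical physics configuration.
    """
    if calib is None:
        calib = calibrate(run.scint, run.opt, run.pd, run.trigger_table, run.sim)
    else:
        expected = _fingerprint(run.scint, run.opt, run.pd, run.trigger_table)
        if calib.fingerprint and calib.fingerprint != expected:
            raise ValueError(
                "calibration tables were built for a different configuration"
            )
    streams = RngStreams(run.sim.seed)
    z, m_a, m_b, pmax_a, pmax_b, trig_a, trig_b, excluded = _simulate_triggers(
        run.sim.n_events,
        run.scint,
        run.opt,
        run.pd,
        run.trigger_table,
        streams,
        run.sim.fixed_depth_cm,
    )
    if run.doi_from_pulse_heights:
        z_hat = estimate_doi(pmax_a, pmax_b, run.opt, run.scint.length_cm)
    else:
        z_hat = estimate_doi(m_a, m_b, run.opt, run.scint.length_cm)
    e_a, e_b = correct_entrance_times(trig_a, trig_b, z_hat, run.scint, calib)
    v_a, v_b = calib.variances_at(np.asarray(z_hat))
    e_ab, e_wab = combine_estimates(e_a, e_b, v_a, v_b)
    t_ab = 0.5 * (trig_a + trig_b)
    levels = run.trigger_table.levels
    s_ea = summarize_trigger_matrix(levels, e_a, excluded)
    s_eb = summarize_trigger_matrix(levels, e_b, excluded)
    doi_error = np.asarray(z_hat) - z
    result = DoubleEndedResult(
        w_da=summarize_trigger_matrix(levels, trig_a, excluded),
        w_db=summarize_trigger_matrix(levels, trig_b, excluded),
        w_dab=summarize_trigger_matrix(levels, t_ab, excluded),
        w_ea=s_ea,
        w_eb=s_eb,
        w_eab=summarize_trigger_matrix(levels, e_ab, excluded),
        w_wab=summarize_trigger_matrix(levels, e_wab, excluded),
        w_z_fwhm_cm=FWHM_PER_SIGMA * float(np.std(doi_error, ddof=1)),
        n_events_used=len(z),
        n_events_excluded=excluded,
        mean_entrance_a=float(np.nanmean(e_a[:, s_ea.optimal_index])),
        mean_entrance_b=float(np.nanmean(e_b[:, s_eb.optimal_index])),
        mean_doi_error_cm=float(np.mean(doi_error)),
        calibration=calib,
    )
    return result
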