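"""Photoelectron arrival-time trains for the three readout geometries.

Timing origin is the moment the annihilation photon crosses the entrance
surface A.  The photon travels to depth Z at speed c, scintillates with a
rise/decay cascade, and each optical photon reaches a surface no earlier
than the geometric minimum n*s/c for its path s, with an exponential
transport-dispersion tail D(s).  Each photoelectron time is

    T = Z/c + n*s_min/c + Exp(tau_r) + Exp(tau_d) + Exp(D) + Gauss(0, J/2.3548)

In single-ended modes the detector sees two swarms: the direct one and a
delayed one reflected off the opposite (mirrored) surface; both merge into a
single indistinguishable pulse.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Tuple

import numpy as np

from .events import EventBatch, EventRecord, RngStreams
from .physics import (
    FWHM_PER_SIGMA,
    SPEED_OF_LIGHT_CM_PER_NS,
    OpticalTransportSpec,
    PhotodetectorSpec,
    ScintillatorSpec,
    dispersion_parameter,
)

__all__ = [
    "ReadoutMode",
    "PhotoelectronTrain",
    "swarm_geometry",
    "generate_swarm_times",
    "apply_jitter",
    "assemble_event_trains",
    "build_batch_trains",
]


class ReadoutMode(Enum):
    """Which end surfaces carry photodetectors."""

    SINGLE_A = "single_a"
    SINGLE_B = "single_b"
    DOUBLE = "double"


@dataclass
class PhotoelectronTrain:
    """Sorted photoelectron times for one photodetector."""

    detector_label: str
    times_ns: np.ndarray


def swarm_geometry(
    mode: ReadoutMode, depth_cm, scint: ScintillatorSpec
) -> List[Tuple[str, str, np.ndarray, np.ndarray]]:
    """Leading-edge offsets and dispersion path arguments for each swarm.

    Returns a list of ``(detector_label, count_source, offset_ns, path_cm)``
    where ``count_source`` is "A" or "B" naming which photoelectron count
    (light that would reach surface A or B) populates the swarm.

    - SINGLE_A: direct swarm (A-light) offset Z/c + nZ/c, path Z; reflected
      swarm (B-light) offset Z/c + n(2L-Z)/c, path 2L-Z; both on detector A.
    - SINGLE_B: direct swarm (B-light) offset Z/c + n(L-Z)/c, path L-Z;
      reflected swarm (A-light) offset Z/c + n(L+Z)/c, path L+Z; detector B.
    - DOUBLE: A-light on detector A (offset Z/c + nZ/c, path Z) and B-light
      on detector B (offset Z/c + n(L-Z)/c, path L-Z).
    """
    z = np.asarray(depth_cm, dtype=float)
    c = SPEED_OF_LIGHT_CM_PER_NS
    n = scint.refractive_index
    length = scint.length_cm
    base = z / c
    if mode is ReadoutMode.SINGLE_A:
        return [
            ("A", "A", base + n * z / c, z),
            ("A", "B", base + n * (2 * length - z) / c, 2 * length - z),
        ]
    if mode is ReadoutMode.SINGLE_B:
        return [
            ("B", "B", base + n * (length - z) / c, length - z),
            ("B", "A", base + n * (length + z) / c, length + z),
        ]
    if mode is ReadoutMode.DOUBLE:
        return [
            ("A", "A", base + n * z / c, z),
            ("B", "B", base + n * (length - z) / c, length - z),
        ]
    raise ValueError(f"unknown readout mode: {mode!r}")


def generate_swarm_times(
    count: int,
    offset_ns: float,
    scint: ScintillatorSpec,
    dispersion_ns: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Times for one swarm: offset plus rise, decay and dispersion delays.

    Each photoelectron time is offset - tau_r ln U1 - tau_d ln U2 - D ln U3
    with independent uniforms, i.e. the sum of three exponential delays; the
    sample mean converges to offset + tau_r + tau_d + D.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if dispersion_ns < 0 or offset_ns < 0:
        raise ValueError("offset_ns and dispersion_ns must be >= 0")
    t = np.full(count, float(offset_ns))
    if count == 0:
        return t
    if scint.rise_time_ns > 0:
        t += scint.rise_time_ns * rng.standard_exponential(count)
    t += scint.decay_time_ns * rng.standard_exponential(count)
    if dispersion_ns > 0:
        t += dispersion_ns * rng.standard_exponential(count)
    return t


def apply_jitter(
    times: np.ndarray, pd: PhotodetectorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Add Gaussian photodetector transit-time jitter (sigma = J/2.3548)."""
    if pd.jitter_fwhm_ns == 0:
        return times
    sigma = pd.jitter_fwhm_ns / FWHM_PER_SIGMA
    return times + sigma * rng.standard_normal(len(times))


def assemble_event_trains(
    event: EventRecord,
    mode: ReadoutMode,
    scint: ScintillatorSpec,
    opt: OpticalTransportSpec,
    pd: PhotodetectorSpec,
    streams: RngStreams,
) -> Dict[str, PhotoelectronTrain]:
    """Build the sorted photoelectron train(s) for a single event.

    Single-ended modes return one merged train; double-ended returns one per
    detector, keyed by detector label.
    """
    counts = {"A": event.observed_pe_a, "B": event.observed_pe_b}
    pieces: Dict[str, list] = {}
    for det, source, offset, path in swarm_geometry(mode, event.depth_cm, scint):
        disp = dispersion_parameter(float(path), scint, opt)
        t = generate_swarm_times(
            counts[source], float(offset), scint, disp, streams.photons
        )
        pieces.setdefault(det, []).append(t)
    out = {}
    for det, parts in pieces.items():
        merged = np.concatenate(parts)
        merged = apply_jitter(merged, pd, streams.jitter)
        out[det] = PhotoelectronTrain(det, np.sort(merged))
    return out


def _scatter_times(
    offsets: np.ndarray,
    disps: np.ndarray,
    counts: np.ndarray,
    starts: np.ndarray,
    dest: np.ndarray,
    scint: ScintillatorSpec,
    sigma_jitter: float,
    photons: np.random.Generator,
    jitter: np.random.Generator,
) -> None:
    """Fill ``dest`` slots for one swarm group across a batch of events."""
    total = int(counts.sum())
    if total == 0:
        return
    t = np.repeat(offsets, counts)
    if scint.rise_time_ns > 0:
        t += scint.rise_time_ns * photons.standard_exponential(total)
    t += scint.decay_time_ns * photons.standard_exponential(total)
    t += np.repeat(disps, counts) * photons.standard_exponential(total)
    if sigma_jitter > 0:
        t += sigma_jitter * jitter.standard_normal(total)
    # within-group slot index: 0..count_e-1 for each event e
    cum = np.concatenate(([0], np.cumsum(counts)[:-1]))
    intra = np.arange(total) - np.repeat(cum, counts)
    dest[np.repeat(starts, counts) + intra] = t


def build_batch_trains(
    batch: EventBatch,
    mode: ReadoutMode,
    scint: ScintillatorSpec,
    opt: OpticalTransportSpec,
    pd: PhotodetectorSpec,
    streams: RngStreams,
) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Vectorized train assembly for a whole batch of events.

    Returns, per detector label, ``(times_flat, starts, counts)`` where event
    ``e`` owns ``times_flat[starts[e]:starts[e]+counts[e]]`` (unsorted; the
    pulse kernel sorts per event).
    """
    sigma = pd.jitter_fwhm_ns / FWHM_PER_SIGMA if pd.jitter_fwhm_ns > 0 else 0.0
    count_arrays = {"A": batch.observed_pe_a, "B": batch.observed_pe_b}
    swarms = swarm_geometry(mode, batch.depth_cm, scint)
    # group swarms by destination detector
    by_det: Dict[str, list] = {}
    for det, source, offset, path in swarms:
        by_det.setdefault(det, []).append((source, offset, path))
    out = {}
    for det, parts in by_det.items():
        counts_per_part = [count_arrays[src] for src, _, _ in parts]
        total_counts = np.sum(counts_per_part, axis=0)
        starts = np.concatenate(([0], np.cumsum(total_counts)[:-1]))
        dest = np.empty(int(total_counts.sum()))
        part_start = starts.copy()
        for (source, offset, path), cnt in zip(parts, counts_per_part):
            disp = dispersion_parameter(path, scint, opt)
            _scatter_times(
                np.asarray(offset, dtype=float),
                np.asarray(disp, dtype=float),
                np.asarray(cnt, dtype=np.int64),
                part_start,
                dest,
                scint,
                sigma,
                streams.photons,
                streams.jitter,
            )
            part_start = part_start + cnt
        out[det] = (dest, starts.astype(np.int64), total_counts.astype(np.int64))
    return out
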