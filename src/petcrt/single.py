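"""Single-ended readout simulation: one photodetector, opposite face mirrored.

Mode A puts the photodetector on the entrance surface; mode B on the rear
surface.  The detector sees a direct photon swarm plus a delayed swarm
reflected off the mirrored face, merged into one pulse.  The run scans the
trigger table, computes the CRT at every level over N_g events and reports
the optimum (W_SA or W_SB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import RngStreams, SimulationConfig, generate_events
from .physics import OpticalTransportSpec, PhotodetectorSpec, ScintillatorSpec
from .pulse import TriggerTable, batch_trigger_times, default_cf_table
from .stats import CrtSummary, summarize_trigger_matrix
from .timing import ReadoutMode, build_batch_trains

__all__ = ["SingleEndedRun", "run_single_ended"]

# cap on photoelectrons materialized at once; batches are chunked above this
_CHUNK_PE_BUDGET = 20_000_000


@dataclass
class SingleEndedRun:
    """Configuration bundle for one single-ended CRT calculation."""

    mode: ReadoutMode
    scint: ScintillatorSpec
    opt: OpticalTransportSpec
    pd: PhotodetectorSpec
    trigger_table: TriggerTable = field(default_factory=default_cf_table)
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.mode not in (ReadoutMode.SINGLE_A, ReadoutMode.SINGLE_B):
            raise ValueError("SingleEndedRun mode must be SINGLE_A or SINGLE_B")


def _chunk_sizes(n_events: int, pe_per_event: float) -> list[int]:
    per_chunk = max(1, int(_CHUNK_PE_BUDGET / max(pe_per_event, 1.0)))
    sizes = []
    left = n_events
    while left > 0:
        take = min(per_chunk, left)
        sizes.append(take)
        left -= take
    return sizes


def run_single_ended(run: SingleEndedRun) -> CrtSummary:
    """Execute the full single-ended Monte Carlo and summarize the CRT.

    Events whose train is empty (zero observed photoelectrons in total) have
    no defined pulse; they are excluded and tallied in the summary.
    """
    streams = RngStreams(run.sim.seed)
    det = "A" if run.mode is ReadoutMode.SINGLE_A else "B"
    trig_chunks = []
    excluded = 0
    for size in _chunk_sizes(run.sim.n_events, run.scint.photoelectron_yield):
        batch = generate_events(
            size, run.scint, run.opt, streams, run.sim.fixed_depth_cm
        )
        trains = build_batch_trains(
            batch, run.mode, run.scint, run.opt, run.pd, streams
        )
        times_flat, starts, counts = trains[det]
        excluded += int(np.sum(counts == 0))
        _, trig = batch_trigger_times(
            times_flat, starts, counts, run.pd, run.trigger_table
        )
        trig_chunks.append(trig[counts > 0])
    trig_all = np.vstack(trig_chunks)
    if len(trig_all) == 0:
        raise ValueError("all events were excluded; no pulse ever formed")
    return summarize_trigger_matrix(run.trigger_table.levels, trig_all, excluded)
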