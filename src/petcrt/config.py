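"""Run-configuration parsing and validation (YAML or JSON).

A config file has sections ``scintillator``, ``optics``, ``photodetector``,
``trigger`` and ``simulation``; keys mirror the dataclass field names, with
units fixed as cm and ns.  Missing optics values default to the standard
parameterization (a = 0.7, d1 = 0.00873 ns, d2 = 0.0186 ns/cm); a missing
trigger section defaults to the 60-point log-spaced constant-fraction table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .events import SimulationConfig
from .physics import OpticalTransportSpec, PhotodetectorSpec, ScintillatorSpec
from .pulse import TriggerKind, TriggerTable, default_cf_table

__all__ = ["RunConfiguration", "parse_config"]


@dataclass
class RunConfiguration:
    scint: ScintillatorSpec
    opt: OpticalTransportSpec
    pd: PhotodetectorSpec
    trigger_table: TriggerTable
    sim: SimulationConfig
    notices: list = field(default_factory=list)


_SCINT_KEYS = {
    "attenuation_length_cm",
    "refractive_index",
    "length_cm",
    "rise_time_ns",
    "decay_time_ns",
    "photoelectron_yield",
}
_OPT_KEYS = {"near_end_fraction", "dispersion_offset_ns", "dispersion_slope_ns_per_cm"}
_PD_KEYS = {"jitter_fwhm_ns", "ser_rise_ns", "ser_decay_ns"}
_SIM_KEYS = {
    "n_events",
    "seed",
    "calibration_n_events",
    "depth_band_count",
    "fixed_depth_cm",
}


def _take(section: dict, allowed: set, where: str) -> dict:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{where}': {sorted(unknown)}")
    return section


def _build_trigger(section: Optional[dict], notices: list) -> TriggerTable:
    if not section:
        notices.append("trigger: defaulting to 60-point constant-fraction table")
        return default_cf_table()
    kind_name = section.get("kind", "constant_fraction")
    try:
        kind = TriggerKind(kind_name)
    except ValueError:
        raise ValueError(
            f"trigger.kind must be one of "
            f"{[k.value for k in TriggerKind]}, got {kind_name!r}"
        ) from None
    if "levels" in section:
        levels = np.asarray(section["levels"], dtype=float)
    else:
        notices.append("trigger.levels: defaulting to 60-point log-spaced table")
        levels = default_cf_table().levels
    return TriggerTable(kind, levels)


def parse_config(path) -> RunConfiguration:
    """Load and validate a run configuration file.

    Raises ``ValueError`` naming the offending field on any invariant
    violation; records applied defaults in ``notices``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    notices: list = []

    if "scintillator" not in raw:
        raise ValueError("missing required section 'scintillator'")
    scint = ScintillatorSpec(
        **_take(raw["scintillator"], _SCINT_KEYS, "scintillator")
    )

    opt_section = _take(raw.get("optics", {}), _OPT_KEYS, "optics")
    for key, default in (
        ("near_end_fraction", 0.7),
        ("dispersion_offset_ns", 0.00873),
        ("dispersion_slope_ns_per_cm", 0.0186),
    ):
        if key not in opt_section:
            notices.append(f"optics.{key}: defaulting to {default}")
    opt = OpticalTransportSpec(**opt_section)

    if "photodetector" not in raw:
        raise ValueError("missing required section 'photodetector'")
    pd_spec = PhotodetectorSpec(
        **_take(raw["photodetector"], _PD_KEYS, "photodetector")
    )

    table = _build_trigger(raw.get("trigger"), notices)
    sim = SimulationConfig(**_take(raw.get("simulation", {}), _SIM_KEYS, "simulation"))
    if opt.near_end_fraction == 0.5:
        notices.append(
            "optics.near_end_fraction = 0.5: no DOI sensitivity "
            "(single-ended simulation only)"
        )
    return RunConfiguration(scint, opt, pd_spec, table, sim, notices)
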