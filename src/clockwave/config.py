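"""Run configuration shared by the CLI and the pipeline helpers.

Defaults reproduce the analysis parameters used throughout: a 36-frame
moving-average detrending window for PMT traces, 30 frames for imaging,
a 41-frame Savitzky-Golay window (order 2), a 60-min refractory period for
peak acceptance, and 10-min period histogram bins spanning 140-210 min.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import ColonySimConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """Stage parameters for the whole pipeline."""

    # preprocessing
    detrend_window_pmt: int = 36
    detrend_window_imaging: int = 30
    sg_window: int = 41
    sg_polyorder: int = 2
    spike_half_window: int = 2
    spike_k: float = 5.0
    background_window: int = 30
    background_percentile: float = 10.0
    pmt_apply_sg: bool = False
    # oscillation analysis
    min_period_min: float = 60.0
    histogram_bin_min: float = 10.0
    histogram_min_edge_min: float = 140.0
    histogram_max_edge_min: float = 210.0
    # screening
    alpha: float = 0.05
    intensity_drop_frac: float = 0.5
    welch: bool = False
    bh_correct: bool = False
    # simulation
    sim: ColonySimConfig = field(default_factory=ColonySimConfig)
    # run control
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config; omitted keys keep their defaults.

    The ``sim:`` section maps onto :class:`ColonySimConfig`. Unknown keys are
    a hard error (no silent typos).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    sim_data = data.pop("sim", {})
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_known = {f.name for f in dataclasses.fields(ColonySimConfig)}
    sim_unknown = set(sim_data) - sim_known
    if sim_unknown:
        raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
    if "center_xy" in sim_data and sim_data["center_xy"] is not None:
        sim_data["center_xy"] = tuple(sim_data["center_xy"])
    return RunConfig(sim=ColonySimConfig(**sim_data), **data)


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of a configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
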