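"""Pipeline configuration: every tunable in one serialisable object.

Defaults follow the study protocol's printed analysis settings: 1–40 Hz
band-pass, 2-s epochs, ±100 µV rejection, 250 Hz analysis rate, K=7
microstate classes with 100 k-means restarts, theta band 4–7.5 Hz, block
length 6 for the entropy rate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # run
    seed: int = 0
    n_participants: int = 1
    out_dir: str = "mspilot_out"
    # stage toggles
    do_preprocess: bool = True
    do_spectral: bool = True
    do_dynamics: bool = True
    do_stats: bool = True
    # synthetic generator
    n_channels: int = 64
    n_classes: int = 7
    max_similarity: float = 0.7
    mean_dwell_baseline: float = 20.0  # samples
    mean_dwell_trial: float = 12.0  # samples; busier sequences in Trial tasks
    snr_db: float = 20.0
    gfp_uv: float = 10.0
    envelope_freq: float = 10.0
    baseline_duration: float = 30.0
    trial_duration: float = 90.0
    sampling_rate: float = 250.0
    stages: tuple = (("Training", 7), ("PracticeA", 8), ("PracticeB", 7))
    # preprocessing
    band_low: float = 1.0
    band_high: float = 40.0
    epoch_seconds: float = 2.0
    amplitude_uv: float = 100.0
    target_fs: float = 250.0
    # microstate fit
    n_init: int = 100
    max_iter: int = 300
    tol: float = 1e-6
    min_peak_distance_ms: float = 10.0
    # dynamics
    k_max: int = 6
    # spectral
    welch_window_seconds: float = 2.0
    welch_overlap: float = 0.5
    theta_band: tuple = (4.0, 7.5)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple((str(n), int(k)) for n, k in cfg.stages)
        if isinstance(cfg.theta_band, list):
            cfg.theta_band = tuple(cfg.theta_band)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = [list(s) for s in self.stages]
        d["theta_band"] = list(self.theta_band)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
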