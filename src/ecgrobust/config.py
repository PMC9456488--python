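"""Serializable run configuration (YAML) for the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError

EXPERIMENTS = ("clean", "unfiltered", "noise_sweep", "quality_report")


@dataclass
class RunConfig:
    """All pipeline parameters in one serializable object.

    A saved config reproduces a run bit-identically in every
    deterministic stage (everything except wall-clock metadata).
    """

    experiment: str = "noise_sweep"
    seed: int = 0
    synth: dict = field(default_factory=lambda: {
        "n_per_class": 8, "n_leads": 3, "duration_s": 16.0, "fs": 1000.0,
    })
    preprocess: dict = field(default_factory=lambda: {
        "a": 0.0, "b": 1.0, "filter_order": 8, "fc": 0.04,
        "filter_mode": "zero_phase", "t1": 0.30, "t2": 0.35,
        "use_ground_truth_peaks": True,
    })
    noise: dict = field(default_factory=lambda: {
        "types": ["baseline_wander", "muscle_artifact", "electrode_motion"],
        "snr_db": [16.0, 8.0, 2.0, -2.0],
        "seed": 0,
    })
    quality: dict = field(default_factory=lambda: {
        "m": 2, "r": 0.2, "n": 2.0, "r_mode": "sd_relative", "metric": "chebyshev",
    })
    split: dict = field(default_factory=lambda: {
        "g1_per_class": 5, "validation_fraction": 0.2, "test_fraction": 0.8,
    })

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise InvalidArgumentError(f"experiment must be one of {EXPERIMENTS}")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
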