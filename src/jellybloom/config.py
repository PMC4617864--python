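"""Run configuration: one flat key-value file drives the whole pipeline.

A single master seed spawns independent per-stage streams so stages can be
resumed or rerun individually without correlating their randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Config", "stage_seed"]


@dataclass
class Config:
    # synthetic study layout
    n_sites: int = 60
    coast_length_km: float = 500.0
    canyon_positions_km: list = field(
        default_factory=lambda: [30.0, 80.0, 180.0, 420.0]
    )
    env_years: list = field(default_factory=lambda: [2004, 2005, 2006, 2007,
                                                     2008, 2009, 2010])
    sampling_years: list = field(default_factory=lambda: [2007, 2008, 2009, 2010])
    # mesh resolution (km)
    mesh_max_edge: float = 40.0
    mesh_outer_edge: float = 120.0
    mesh_buffer: float = 80.0
    projector_weights: str = "equal_thirds"
    # model
    covariates: list = field(
        default_factory=lambda: [
            "dist_canyon", "sst", "pp", "chl", "u_cur", "v_cur", "month", "year",
        ]
    )
    include_latent: bool = True
    include_iid_effect: bool = True
    standardize: bool = False
    calibration_fraction: float = 0.7
    # bootstrap
    window_days: int = 15
    n_iter: int = 500
    response_draws: bool = True
    # extremes
    months_report: list = field(default_factory=lambda: [5, 6])
    # seeding
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    def validate(self) -> "Config":
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if len(self.env_years) < 2:
            raise ValueError("need at least 2 environmental years")
        if not set(self.sampling_years) <= set(self.env_years):
            raise ValueError("sampling_years must be a subset of env_years")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.window_days % 2 == 0:
            raise ValueError("window_days must be odd")
        return self


_STAGE_TAGS = {
    "sites": 11, "environment": 13, "latent": 17, "counts": 19,
    "split": 23, "fit": 29, "boot_stochastic": 31, "boot_deterministic": 37,
    "extremes": 41, "validate": 43,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent 31-bit stream seed for a named pipeline stage."""
    if stage not in _STAGE_TAGS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGE_TAGS[stage]])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
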