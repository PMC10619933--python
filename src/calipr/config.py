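"""Pipeline configuration: a flat, schema-validated YAML mapping.

Unknown keys are rejected so typos fail loudly; the fully resolved
configuration (defaults included) is serialized into every output's
provenance sidecar together with its hash and the seeds used, so reruns
are bit-reproducible from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .epg import SequenceParams
from .recon import ReconConfig
from .t2fit import FitConfig, T2Grid

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything needed to rerun the pipeline deterministically.

    Defaults mirror the in vivo brain protocol: 56 echoes at 6.0 ms
    spacing, acceleration 23.9, K = 12, lambda = 0.004.
    """

    # sequence
    n_echoes: int = 56
    delta_te_ms: float = 6.0
    t1_ms: float = 1000.0
    # sampling
    grid_shape: tuple[int, int] = (118, 59)
    target_acceleration: float = 23.9
    calib_shape: tuple[int, int] = (12, 12)
    shutter: bool = True
    phase_grid_factor: int = 2
    # reconstruction
    lam: float = 0.004
    lam_step1: "float | None" = None
    K: int = 12
    max_iters: int = 100
    rel_tol: float = 1e-5
    n_virtual_coils: int = 8
    intensity_threshold_fraction: float = 0.1
    # fitting
    t2_grid_n: int = 40
    t2_grid_min_ms: float = 8.0
    t2_grid_max_ms: float = 2000.0
    flip_min_deg: float = 90.0
    flip_max_deg: float = 180.0
    flip_step_deg: float = 1.0
    spatial_weight: float = 0.3
    n_spatial_iters: int = 2
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_acceleration < 1:
            raise ConfigError("target_acceleration must be >= 1")
        if self.lam < 0:
            raise ConfigError("lam must be >= 0")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        # the subspace can never exceed the echo count
        self.K = min(self.K, self.n_echoes)
        self.grid_shape = tuple(self.grid_shape)  # type: ignore[assignment]
        self.calib_shape = tuple(self.calib_shape)  # type: ignore[assignment]

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at the top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as err:
            raise ConfigError(f"{path}: {err}") from err

    # -- derived views --------------------------------------------------
    def sequence(self) -> SequenceParams:
        return SequenceParams(n_echoes=self.n_echoes, delta_te=self.delta_te_ms,
                              t1=self.t1_ms)

    def recon(self) -> ReconConfig:
        return ReconConfig(lam=self.lam, lam_step1=self.lam_step1,
                           K=self.K, max_iters=self.max_iters,
                           rel_tol=self.rel_tol,
                           n_virtual_coils=self.n_virtual_coils,
                           intensity_threshold_fraction=self.intensity_threshold_fraction,
                           calib_shape=self.calib_shape)

    def fit(self) -> FitConfig:
        import numpy as np

        grid = T2Grid.default(self.t2_grid_n, self.t2_grid_min_ms,
                              self.t2_grid_max_ms)
        candidates = np.arange(self.flip_min_deg,
                               self.flip_max_deg + 0.5 * self.flip_step_deg,
                               self.flip_step_deg)
        return FitConfig(grid=grid, seq=self.sequence(),
                         flip_candidates=candidates,
                         spatial_weight=self.spatial_weight,
                         n_spatial_iters=self.n_spatial_iters)

    # -- provenance -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self, **extra) -> dict:
        return {"config": self.to_dict(), "config_hash": self.hash,
                "seed": self.seed, **extra}

    def write_provenance(self, output_path, **extra) -> None:
        """Write the provenance sidecar ``<output>.provenance.json``."""
        side = Path(str(output_path) + ".provenance.json")
        side.write_text(json.dumps(self.provenance(**extra), indent=2,
                                   default=list))
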