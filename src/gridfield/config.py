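"""Run configuration: a serialisable description of one experiment.

Every run is fully reproducible from (config, seed): all randomness flows
from the config's master seed through per-replication derived streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arena import ArenaConfig
from .experiments import (
    direct_pca_experiment,
    module_experiment,
    network_experiment,
    nnpca_experiment,
    ode_experiment,
    spacing_sweep,
)
from .place import PlaceEnsemble

__all__ = ["RunConfig", "run_experiment", "scores_to_frame"]

_MODELS = ("network", "batch_pca", "nnpca", "ode", "theory")


@dataclass
class RunConfig:
    """Declarative description of one experiment run."""

    model: str = "network"  # network | batch_pca | nnpca | ode | theory
    side_length: float = 100.0
    boundary: str = "periodic"
    grid_resolution: int = 64
    cells_per_side: int = 25
    kind: str = "dog"
    sigma1: float = 3.9
    sigma2: float | None = None  # default 2 * sigma1
    preprocessing: str = "raw"
    constrained: bool = True
    steps: int = 3_000_000
    replications: int = 1
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> None:
        errors = []
        if self.model not in _MODELS:
            errors.append(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.side_length <= 0:
            errors.append("side_length must be > 0")
        if self.boundary not in ("periodic", "zero"):
            errors.append("boundary must be 'periodic' or 'zero'")
        if self.grid_resolution < 8:
            errors.append("grid_resolution must be >= 8")
        if self.kind not in ("gaussian", "dog", "disk"):
            errors.append("kind must be gaussian|dog|disk")
        if self.sigma1 <= 0:
            errors.append("sigma1 must be > 0")
        if self.replications < 1:
            errors.append("replications must be >= 1")
        if self.steps < 1:
            errors.append("steps must be >= 1")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @property
    def sigma2_value(self) -> float:
        return self.sigma2 if self.sigma2 is not None else 2.0 * self.sigma1

    def arena(self) -> ArenaConfig:
        return ArenaConfig(self.side_length, self.boundary, self.grid_resolution)

    def ensemble(self) -> PlaceEnsemble:
        return PlaceEnsemble.tiled(
            self.arena(), cells_per_side=self.cells_per_side, kind=self.kind,
            sigma1=self.sigma1, sigma2=self.sigma2_value,
        )

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def scores_to_frame(scores) -> pd.DataFrame:
    """GridScore list -> tidy table (one row per map)."""
    return pd.DataFrame(
        {
            "id": np.arange(len(scores)),
            "gridness60": [s.gridness60 for s in scores],
            "gridness90": [s.gridness90 for s in scores],
            "spacing": [s.spacing for s in scores],
            "orientation": [s.orientation for s in scores],
            "alignment": [s.alignment for s in scores],
        }
    )


def run_experiment(config: RunConfig, out_dir=None) -> pd.DataFrame:
    """Run the configured experiment, write scores TSV + metadata, return scores.

    Writes ``scores.tsv`` (one row per output map) and ``run.yaml`` (the
    config plus package version) under the output directory.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ens = config.ensemble()
    if config.model == "network":
        scores = network_experiment(
            n_runs=config.replications, constrained=config.constrained,
            steps=config.steps, seed=config.seed, ensemble=ens,
        )
    elif config.model == "batch_pca":
        scores = direct_pca_experiment(
            n_runs=config.replications, steps=config.steps, seed=config.seed,
            ensemble=ens,
        )
    elif config.model == "nnpca":
        from .steady_state import fourier_table

        scores, sols = nnpca_experiment(
            n_runs=config.replications, seed=config.seed, arena=config.arena(),
            sigma1=config.sigma1, constrained=config.constrained,
            return_solutions=True,
        )
        for i, sol in enumerate(sols):
            np.savetxt(out / f"map_{i:03d}.txt", sol.projection(), fmt="%.6g")
            np.savetxt(out / f"fourier_{i:03d}.tsv", fourier_table(sol),
                       header="k_x\tk_y\tJ_hat_abs", delimiter="\t", fmt="%.6g")
    elif config.model == "ode":
        scores = ode_experiment(
            n_runs=config.replications, constrained=config.constrained,
            seed=config.seed, ensemble=ens,
        )
    else:
        raise ValueError(f"model {config.model!r} has no tabular experiment")

    frame = scores_to_frame(scores)
    frame.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.6g")
    meta = asdict(config) | {"gridfield_version": __version__}
    (out / "run.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return frame
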