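"""Run configuration: defaults, validation, TOML loading."""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger("zsustain")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the reference analysis: thresholds 1/2/3 per region,
    25 optimisation start points, 1e6 MCMC iterations, up to 4 subtypes,
    10 CV folds, >50% assignment cut-off and 5000 bootstrap replicates.
    Test-scale runs override ``n_mcmc_iter`` and friends.
    """

    z_events: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    n_startpoints: int = 25
    n_mcmc_iter: int = 1_000_000
    max_subtypes: int = 4
    cv_folds: int = 10
    rng_seed: int = 0
    subtype_assignment_cutoff: float = 0.5
    bootstrap_reps: int = 5000
    sigma: float = 1.0
    include_tiv: bool = True
    min_controls_per_stratum: int = 20
    sample_fractions: bool = True
    em_tol: float = 1e-6
    em_max_iter: int = 100
    n_split_tries: int = 3
    parsimony_delta: float = 6.0

    def __post_init__(self) -> None:
        zs = tuple(float(z) for z in self.z_events)
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("z_events must be strictly increasing")
        if zs and zs[-1] >= self.z_max:
            raise ValueError("z_events must lie strictly below z_max")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.subtype_assignment_cutoff < 1.0:
            raise ValueError("subtype_assignment_cutoff must lie in (0, 1)")
        if self.max_subtypes < 1:
            raise ValueError("max_subtypes must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.z_events = zs

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "z_events" in raw:
            raw["z_events"] = tuple(raw["z_events"])
        return cls(**raw)

    def echo(self) -> None:
        """Log the full configuration (including the seed) for provenance."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))
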