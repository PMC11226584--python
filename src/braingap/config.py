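"""Configuration objects for simulation, model fitting, and full runs.

All configs are plain dataclasses that validate on construction and
round-trip losslessly through ``to_dict``/``from_dict`` (and hence YAML),
so a run can be reproduced from its serialized manifest alone.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class SimConfig:
    """Parameters of the synthetic two-cohort world.

    The defaults emulate the study design this package analyses: a
    cognitively-normal training cohort with a wide age range, a target
    cohort aged 67-90, four field centers with site-specific administrative
    censoring (one site two years earlier than the rest), a ~5000-analyte
    protein panel with a small truly-associated subset, and mortality
    hazards that decrease for the lower brain-age-gap tertiles.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_train: int = 300
    n_target: int = 500
    train_age_range: tuple[float, float] = (55.0, 90.0)
    target_age_range: tuple[float, float] = (67.0, 90.0)
    age_ref: float = 72.0
    n_signal_clusters: int = 4
    effect_scale: float = 0.004          # GM-probability units lost per year
    noise_sd: float = 0.05               # voxel noise SD before smoothing
    smooth_fwhm: float = 3.0             # voxels
    bag_sd: float = 2.9                  # SD (years) of the true brain-age gap
    n_proteins: int = 5284
    n_true_proteins: int = 33
    protein_effect_sd: float = 0.12      # analyte SD units per BAG-year
    qc_fail_fraction: float = 407.0 / 5284.0
    hr_lowest: float = 0.4               # hazard ratio, lowest BAG tertile vs highest
    hr_middle: float = 0.6
    baseline_hazard: float = 0.035       # events/year in the highest (reference) tertile
    p_cns_death: float = 0.15
    censor_date_by_site: dict[str, str] = field(
        default_factory=lambda: {
            "Jackson": "2017-12-31",
            "Forsyth": "2019-12-31",
            "Minneapolis": "2019-12-31",
            "Washington": "2019-12-31",
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.train_age_range = tuple(float(a) for a in self.train_age_range)
        self.target_age_range = tuple(float(a) for a in self.target_age_range)
        for name in ("n_train", "n_target", "n_signal_clusters", "n_proteins",
                     "n_true_proteins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_scale == 0:
            raise ValueError("effect_scale must be nonzero")
        if self.n_true_proteins > self.n_proteins:
            raise ValueError("n_true_proteins cannot exceed n_proteins")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1)")
        if not 0 <= self.p_cns_death <= 1:
            raise ValueError("p_cns_death must lie in [0, 1]")
        lo, hi = self.target_age_range
        tlo, thi = self.train_age_range
        if lo < tlo or hi > thi:
            warnings.warn(
                "target_age_range extends outside train_age_range; "
                "age prediction will extrapolate",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class FitConfig:
    """Elastic-net fitting protocol.

    alpha is the L1/L2 mixing parameter (0.5 by default), lambda the overall
    penalty strength, selected by repeated k-fold cross-validation with the
    one-standard-error rule and averaged across repeats.
    """

    alpha: float = 0.5
    n_folds: int = 10
    n_repeats: int = 5
    lambda_grid: Sequence[float] | str = "auto"
    n_lambda: int = 100                  # grid length when lambda_grid == "auto"
    lambda_min_ratio: float = 1e-2       # glmnet's default depth for p > n
    selection_rule: str = "1se"          # "1se" | "min"
    lambda_average: str = "arithmetic"   # "arithmetic" | "log"
    standardize: bool = True
    tol: float = 1e-8                    # duality-gap tolerance, final refit
    cv_tol: float = 1e-3                 # looser tolerance for the CV paths
    max_iter: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.selection_rule not in ("1se", "min"):
            raise ValueError("selection_rule must be '1se' or 'min'")
        if self.lambda_average not in ("arithmetic", "log"):
            raise ValueError("lambda_average must be 'arithmetic' or 'log'")
        if not isinstance(self.lambda_grid, str):
            grid = [float(l) for l in self.lambda_grid]
            if any(l <= 0 for l in grid):
                raise ValueError("lambda_grid values must be positive")
            if any(b >= a for a, b in zip(grid, grid[1:])):
                raise ValueError("lambda_grid must be strictly decreasing")
            self.lambda_grid = grid
        elif self.lambda_grid != "auto":
            raise ValueError("lambda_grid must be 'auto' or a decreasing sequence")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if isinstance(d.get("lambda_grid"), list):
            d["lambda_grid"] = [float(x) for x in d["lambda_grid"]]
        return cls(**d)
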