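"""Synthetic cohort generation under the liability threshold model.

Generates individual-level cohorts with the statistical structure the
downstream analyses assume: a standard-normal latent disease liability
split into a measured polygenic component (PRS), a measured non-genetic
component (a standardized PCE-style score), optional group-level shifts,
and residual noise; a binary outcome from thresholding the liability at
``T = Phi^{-1}(1 - K)`` for target prevalence ``K``; group-varying
participation (retention) bias acting on liability; and structured
quantile grouping driven by a hidden variable ``y ~ N(a1*PRS + a2*PCE, 1)``.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ParameterError",
    "ShapeError",
    "CohortConfig",
    "BiasConfig",
    "StructuredPermutationConfig",
    "generate_base_cohort",
    "apply_participation_bias",
    "assign_quantile_groups",
    "write_cohort",
    "read_cohort",
]


class ParameterError(ValueError):
    """A configuration value is outside its valid domain."""


class ShapeError(ValueError):
    """Configured shapes (group counts, gradient lengths) disagree."""


# Default loadings of the non-genetic covariates on the environmental risk
# score: (mean, sd, correlation with the pce score) for numeric covariates,
# (marginal probability, correlation) for binary ones.  Means and spreads
# follow typical mid-life UK cohort values.
_NUMERIC_COVARIATES: dict[str, tuple[float, float, float]] = {
    "total_chol": (226.7, 35.0, 0.30),   # mg/dl
    "hdl": (55.0, 14.0, -0.30),          # mg/dl
    "sbp": (138.0, 18.0, 0.35),          # mmHg
    "bmi": (27.0, 4.5, 0.30),
    "tdi": (-1.5, 3.0, 0.20),
}
_BINARY_COVARIATES: dict[str, tuple[float, float]] = {
    "smoking": (0.10, 0.25),
    "htn_med": (0.20, 0.35),
    "diabetes": (0.05, 0.30),
}


@dataclass
class CohortConfig:
    """Parameters of the liability-threshold cohort generator.

    The liability of individual *j* in group *g* is

    ``L_j = sqrt(V) * PRS_j + w_env * PCE_j + b_g + eps_j``

    with ``PRS`` and ``PCE`` standardized scores, ``V`` the liability
    variance explained by the polygenic score, ``w_env`` the weight of the
    measured non-genetic score, ``b_g`` a per-group liability shift and
    ``eps`` residual noise scaled so that Var(L) = 1.  Disease occurs when
    ``L`` exceeds ``T = Phi^{-1}(1 - K)``.
    """

    n_groups: int = 21
    group_sizes: int | Sequence[int] = 2000
    prevalence: float = 0.0321
    prs_variance_explained: float = 0.05
    env_weight: float = 0.52
    group_effect_sd: float = 0.0
    group_effects: Sequence[float] | None = None
    age_range: tuple[int, int] = (40, 69)
    covariate_loadings: Mapping[str, float] | None = None
    seed: int = 0

    def resolved_group_sizes(self) -> np.ndarray:
        if np.isscalar(self.group_sizes):
            sizes = np.full(self.n_groups, int(self.group_sizes))
        else:
            sizes = np.asarray(self.group_sizes, dtype=int)
        return sizes

    def residual_variance(self) -> float:
        v = (
            1.0
            - self.prs_variance_explained
            - self.env_weight**2
            - self.group_effect_sd**2
        )
        return v

    def validate(self) -> None:
        K, V = self.prevalence, self.prs_variance_explained
        if not 0.0 < K < 1.0:
            raise ParameterError(f"prevalence K must be in (0, 1), got {K}")
        if not 0.0 <= V < 1.0:
            raise ParameterError(
                f"prs_variance_explained V must be in [0, 1), got {V}"
            )
        if self.group_effect_sd < 0:
            raise ParameterError("group_effect_sd must be >= 0")
        if self.n_groups < 1:
            raise ParameterError("n_groups must be >= 1")
        sizes = self.resolved_group_sizes()
        if len(sizes) != self.n_groups:
            raise ShapeError(
                f"group_sizes has length {len(sizes)} but n_groups={self.n_groups}"
            )
        if (sizes < 2).any():
            raise ParameterError("every group size must be >= 2")
        if self.group_effects is not None and len(self.group_effects) != self.n_groups:
            raise ShapeError(
                f"group_effects has length {len(self.group_effects)} "
                f"but n_groups={self.n_groups}"
            )
        if self.residual_variance() <= 0:
            raise ParameterError(
                "liability variance budget exceeded: "
                "V + env_weight^2 + group_effect_sd^2 must be < 1"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        if d["group_effects"] is not None:
            d["group_effects"] = list(d["group_effects"])
        if not np.isscalar(d["group_sizes"]):
            d["group_sizes"] = [int(s) for s in d["group_sizes"]]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class BiasConfig:
    """Liability- and age-dependent logistic retention (participation bias).

    An individual in group *g* with liability *L* and age *a* is retained
    with probability ``logistic(-(strength * group_gradient_g * L
    + age_coefficient * a + offset))``: ``strength`` is the log-odds of
    non-retention per unit liability, modulated per group by
    ``group_gradient``.  ``strength = 0`` disables selection entirely
    (retention probability 1).
    """

    strength: float = 0.0
    group_gradient: Sequence[float] = field(default_factory=lambda: [1.0])
    age_coefficient: float = 0.0
    offset: float = -2.0
    seed: int = 0

    def validate(self, n_groups: int) -> None:
        if self.strength < 0:
            raise ParameterError("bias strength must be >= 0")
        if len(self.group_gradient) != n_groups:
            raise ShapeError(
                f"group_gradient has length {len(self.group_gradient)} "
                f"but the cohort has {n_groups} groups"
            )


@dataclass
class StructuredPermutationConfig:
    """Quantile grouping on a hidden variable ``y ~ N(a1*PRS + a2*PCE, 1)``."""

    alpha1: float
    alpha2: float
    n_groups: int = 21
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 2:
            raise ParameterError("n_groups must be >= 2")


# ---------------------------------------------------------------------------
# cohort generation

def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_base_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort of ``sum(group_sizes)`` individuals.

    Returns one row per individual with group label, age, sex, standardized
    PRS and PCE scores, correlated non-genetic covariates, the binary
    outcome ``cad`` and the latent liability in the hidden column
    ``_liability`` (kept for testing; stripped on export unless requested).
    Identical configs (including seed) give identical tables.
    """
    config.validate()
    sizes = config.resolved_group_sizes()
    n = int(sizes.sum())
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    group_labels = np.repeat(
        [f"center_{g + 1:02d}" for g in range(config.n_groups)], sizes
    )
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")

    prs = _standardize(rng.standard_normal(n))
    pce = _standardize(rng.standard_normal(n))

    loadings = dict(config.covariate_loadings or {})
    cov_cols: dict[str, np.ndarray] = {}
    for name, (mean, sd, rho) in _NUMERIC_COVARIATES.items():
        rho = loadings.get(name, rho)
        z = rho * pce + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        cov_cols[name] = mean + sd * z
    for name, (p, rho) in _BINARY_COVARIATES.items():
        rho = loadings.get(name, rho)
        z = rho * pce + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        cov_cols[name] = (z > norm.ppf(1 - p)).astype(int)
    # keep clinical measurements positive
    for name in ("total_chol", "hdl", "sbp"):
        cov_cols[name] = np.clip(cov_cols[name], 1.0, None)

    if config.group_effects is not None:
        b = np.asarray(config.group_effects, dtype=float)
    elif config.group_effect_sd > 0:
        b = rng.normal(0.0, config.group_effect_sd, size=config.n_groups)
    else:
        b = np.zeros(config.n_groups)
    b_per_row = np.repeat(b, sizes)

    V = config.prs_variance_explained
    resid_sd = np.sqrt(config.residual_variance())
    liability = (
        np.sqrt(V) * prs
        + config.env_weight * pce
        + b_per_row
        + resid_sd * rng.standard_normal(n)
    )
    threshold = norm.ppf(1.0 - config.prevalence)
    cad = (liability > threshold).astype(int)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "group": group_labels,
            "age": age,
            "sex": sex,
            **cov_cols,
            "prs": prs,
            "pce": pce,
            "cad": cad,
            "_liability": liability,
        }
    )
    return df


def apply_participation_bias(cohort: pd.DataFrame, bias: BiasConfig) -> pd.DataFrame:
    """Thin the cohort by liability- and age-dependent logistic retention.

    Returns the retained subset (with a hidden ``_retention_p`` column).
    ``strength = 0`` returns the input unchanged.  Raises if any group is
    emptied, since downstream group means would be undefined.
    """
    groups = pd.unique(cohort["group"])
    bias.validate(len(groups))
    if bias.strength == 0:
        return cohort.copy()
    if "_liability" not in cohort.columns:
        raise KeyError("cohort lacks the hidden _liability column")

    gradient = dict(zip(groups, np.asarray(bias.group_gradient, dtype=float)))
    grad = cohort["group"].map(gradient).to_numpy(dtype=float)
    eta = (
        bias.offset
        + bias.strength * grad * cohort["_liability"].to_numpy()
        + bias.age_coefficient * cohort["age"].to_numpy()
    )
    p_retain = expit(-eta)
    rng = np.random.default_rng(np.random.SeedSequence(bias.seed))
    keep = rng.random(len(cohort)) < p_retain

    out = cohort.loc[keep].copy()
    out["_retention_p"] = p_retain[keep]
    emptied = [g for g in groups if g not in set(out["group"])]
    if emptied:
        raise ValueError(f"participation bias emptied group(s): {emptied}")
    return out


def assign_quantile_groups(
    cohort: pd.DataFrame, spc: StructuredPermutationConfig
) -> pd.DataFrame:
    """Replace group labels with equal-sized quantiles of a hidden variable.

    Draws ``y_j ~ N(alpha1 * PRS_j + alpha2 * PCE_j, 1)``, ranks ``y``
    ascending (ties broken by row order) and cuts the ranking into
    ``n_groups`` contiguous blocks whose sizes differ by at most one.
    Group labels are integers ``1..n_groups``, ascending in ``y``.
    """
    spc.validate()
    n = len(cohort)
    if spc.n_groups > n:
        raise ValueError(
            f"cannot form {spc.n_groups} groups from {n} rows"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spc.seed))
    mu = spc.alpha1 * cohort["prs"].to_numpy() + spc.alpha2 * cohort["pce"].to_numpy()
    y = mu + rng.standard_normal(n)

    order = np.argsort(y, kind="stable")
    # block sizes equal up to remainder +-1, larger blocks first
    base, rem = divmod(n, spc.n_groups)
    sizes = np.full(spc.n_groups, base)
    sizes[:rem] += 1
    labels_in_order = np.repeat(np.arange(1, spc.n_groups + 1), sizes)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_in_order

    out = cohort.copy()
    out["group"] = labels
    out["_hidden_y"] = y
    return out


# ---------------------------------------------------------------------------
# cohort IO

def write_cohort(cohort: pd.DataFrame, path, keep_latent: bool = False) -> None:
    """Write a cohort to CSV, dropping hidden ``_``-prefixed columns by default."""
    df = cohort
    if not keep_latent:
        df = df[[c for c in df.columns if not c.startswith("_")]]
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
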