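"""Logistic and Mundlak (within-between) GLMs for group-rate prediction.

The standard GLM ``logit(p_j) = b0 + x_j' beta`` is fit at the individual
level and a group's predicted case rate is the mean of its members'
predicted probabilities.  The Mundlak variant augments the design with,
for every covariate, its group-demeaned value (within effect ``beta``)
and its group mean (between effect ``gamma``), relaxing the assumption
that covariates are uncorrelated with group-level unobservables — the
group mean acts as a proxy for unseen group-specific behaviour, which is
what rescues group-rate prediction under Simpson's-paradox structure.

Also here: leave-one-center-out cross-validation (LOCOCV), the Wilson
score interval obtained as a damped fixed point, and AUC with a
placement-value (structural components) variance estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "FitResult",
    "GroupSummary",
    "WilsonInterval",
    "fit_logistic",
    "mundlak_design",
    "fit_mundlak",
    "predict_group_rates",
    "lococv",
    "wilson_interval",
    "auc_with_ci",
    "group_summaries",
]


# ---------------------------------------------------------------------------
# fit results

@dataclass
class FitResult:
    intercept: float
    within_coefficients: dict[str, float]
    between_coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    model: str                               # "glm" | "mundlak"
    covariates: list[str]
    params: pd.Series = field(repr=False, default=None)
    column_map: Optional[dict] = field(repr=False, default=None)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": pd.Series(self.standard_errors)}
        )


@dataclass(frozen=True)
class GroupSummary:
    group_id: object
    n: int
    observed_rate: float
    covariate_means: dict[str, float]


@dataclass(frozen=True)
class WilsonInterval:
    point: float
    lower: float
    upper: float
    z: float
    n: float
    iterations_to_converge: int


def group_summaries(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "cad",
    group_col: str = "group",
) -> list[GroupSummary]:
    out = []
    for g, sub in cohort.groupby(group_col, observed=True):
        out.append(
            GroupSummary(
                g,
                len(sub),
                float(sub[outcome].mean()),
                {c: float(sub[c].mean()) for c in covariates},
            )
        )
    return out


# ---------------------------------------------------------------------------
# logistic fitting (IRLS via statsmodels GLM/Binomial)

def _check_design(X: pd.DataFrame) -> None:
    non_const = [c for c in X.columns if c != "const"]
    degenerate = [c for c in non_const if np.std(X[c].to_numpy(float)) == 0]
    if degenerate:
        raise ValueError(f"zero-variance design column(s): {degenerate}")
    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        # name the offending columns via incremental rank
        collinear = []
        cols: list[str] = []
        for c in X.columns:
            trial = X[cols + [c]].to_numpy(float)
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(c)
            else:
                cols.append(c)
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")


def fit_logistic(
    design_matrix: pd.DataFrame,
    outcomes,
    model: str = "glm",
    covariates: Optional[Sequence[str]] = None,
    column_map: Optional[dict] = None,
) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    ``design_matrix`` columns are used as-is (a ``const`` intercept column
    is added if absent).  Convergence: relative log-likelihood change
    below 1e-10 within 100 iterations; non-convergence is reported in the
    result, perfect separation raises.
    """
    X = design_matrix.copy()
    if "const" not in X.columns:
        X.insert(0, "const", 1.0)
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    _check_design(X)

    glm = sm.GLM(y, X.astype(float), family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = glm.fit(maxiter=100, tol=1e-10)
        except PerfectSeparationError as err:
            raise ValueError(f"perfect separation detected: {err}") from err
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise ValueError(
            "perfect separation detected: fitted probabilities reached 0/1; "
            "maximum-likelihood estimates diverge"
        )
    params = pd.Series(res.params, index=X.columns)

    se = pd.Series(res.bse, index=X.columns)
    n_iter = len(getattr(res, "fit_history", {}).get("deviance", [0, 0])) - 1
    converged = bool(getattr(res, "converged", True))

    if column_map is None:
        within = {c: float(params[c]) for c in X.columns if c != "const"}
        between: dict[str, float] = {}
    else:
        within = {c: float(params[col]) for c, col in column_map["within"].items()}
        between = {c: float(params[col]) for c, col in column_map["between"].items()}
    return FitResult(
        intercept=float(params["const"]),
        within_coefficients=within,
        between_coefficients=between,
        standard_errors={c: float(se[c]) for c in X.columns},
        log_likelihood=float(res.llf),
        n_iterations=max(n_iter, 0),
        converged=converged,
        model=model,
        covariates=list(covariates or [c for c in X.columns if c != "const"]),
        params=params,
        column_map=column_map,
    )


# ---------------------------------------------------------------------------
# Mundlak design and fit

def mundlak_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    group_col: str = "group",
) -> tuple[pd.DataFrame, dict]:
    """Within-between design: per covariate a group-demeaned and a group-mean column.

    Per-group means of every demeaned column are exactly zero by
    construction.  Requires at least two groups (with a single group the
    mean column is collinear with the intercept).
    """
    groups = cohort.groupby(group_col, observed=True)
    if groups.ngroups < 2:
        raise ValueError("Mundlak design needs >= 2 groups")
    sizes = groups.size()
    if (sizes == 1).any():
        warnings.warn(
            f"group(s) of size 1: {list(sizes.index[sizes == 1])}; "
            "their demeaned covariates are zero"
        )
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    column_map = {"within": {}, "between": {}}
    for c in covariates:
        gmean = groups[c].transform("mean")
        X[f"{c}_within"] = cohort[c] - gmean
        X[f"{c}_between"] = gmean
        column_map["within"][c] = f"{c}_within"
        column_map["between"][c] = f"{c}_between"
    return X, column_map


def fit_mundlak(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "cad",
    group_col: str = "group",
) -> FitResult:
    """Fit the within-between logistic model on a grouped cohort."""
    X, cmap = mundlak_design(cohort, covariates, group_col)
    for c in covariates:
        if np.std(X[cmap["within"][c]].to_numpy()) == 0:
            raise ValueError(
                f"covariate {c!r} is constant within every group; "
                "its within column is identically zero"
            )
    return fit_logistic(
        X, cohort[outcome], model="mundlak", covariates=covariates, column_map=cmap
    )


def _predict_probabilities(
    fit: FitResult, cohort: pd.DataFrame, group_col: str = "group"
) -> np.ndarray:
    """Per-row predicted probabilities, rebuilding the design from the cohort.

    For a Mundlak fit the group means are computed from the given cohort's
    own groups — for a new group this uses only its covariates, never its
    outcomes.
    """
    missing = [c for c in fit.covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks covariate column(s): {missing}")
    if fit.model == "mundlak":
        X, _ = mundlak_design(cohort, fit.covariates, group_col)
    else:
        X = cohort[list(fit.covariates)].copy()
        X.insert(0, "const", 1.0)
    eta = X[fit.params.index].to_numpy(float) @ fit.params.to_numpy()
    return expit(eta)


def predict_group_rates(
    fit: FitResult,
    cohort: pd.DataFrame,
    group_col: str = "group",
) -> pd.DataFrame:
    """Group case rates as the mean of members' predicted probabilities."""
    p = _predict_probabilities(fit, cohort, group_col)
    out = (
        pd.DataFrame({group_col: cohort[group_col].to_numpy(), "p": p})
        .groupby(group_col, observed=True)["p"]
        .mean()
        .rename("predicted_rate")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# leave-one-center-out cross-validation

def lococv(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    model: str = "mundlak",
    outcome: str = "cad",
    group_col: str = "group",
) -> tuple[pd.DataFrame, Optional[float]]:
    """Predict each group's case rate from a model trained without that group.

    For a held-out group, a Mundlak model's group-mean columns are built
    from the held-out group's own covariates (its outcomes are never
    used), matching the use case of predicting a new group for which only
    covariate information exists.  Returns the per-group table and the
    Pearson correlation between observed and predicted rates (``None`` if
    any fold failed).
    """
    if model not in ("glm", "mundlak"):
        raise ValueError(f"model must be 'glm' or 'mundlak', got {model!r}")
    groups = list(pd.unique(cohort[group_col]))
    if len(groups) < 3:
        raise ValueError("LOCOCV correlation needs at least 3 groups")

    rows = []
    any_failed = False
    for g in groups:
        train = cohort[cohort[group_col] != g]
        heldout = cohort[cohort[group_col] == g]
        try:
            if model == "mundlak":
                fit = fit_mundlak(train, covariates, outcome, group_col)
            else:
                X = train[list(covariates)].copy()
                X.insert(0, "const", 1.0)
                fit = fit_logistic(X, train[outcome], covariates=covariates)
            if model == "mundlak":
                # single held-out group: demeaned columns are x - own mean,
                # between columns its own covariate means
                x = heldout[list(covariates)]
                eta = np.full(len(heldout), fit.intercept)
                for c in covariates:
                    eta += fit.within_coefficients[c] * (x[c] - x[c].mean()).to_numpy()
                    eta += fit.between_coefficients[c] * x[c].mean()
                pred = float(np.mean(expit(eta)))
            else:
                pred = float(
                    np.mean(_predict_probabilities(fit, heldout, group_col))
                )
            rows.append(
                {
                    group_col: g,
                    "n": len(heldout),
                    "observed_rate": float(heldout[outcome].mean()),
                    "predicted_rate": pred,
                    "failed": False,
                }
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            any_failed = True
            rows.append(
                {
                    group_col: g,
                    "n": len(heldout),
                    "observed_rate": float(heldout[outcome].mean()),
                    "predicted_rate": np.nan,
                    "failed": True,
                    "error": str(err),
                }
            )
    table = pd.DataFrame(rows)
    corr = None
    if not any_failed:
        corr = float(
            stats.pearsonr(table["observed_rate"], table["predicted_rate"])[0]
        )
    return table, corr


# ---------------------------------------------------------------------------
# Wilson score interval by fixed-point iteration

def _wilson_closed_form(p_hat: float, n: float, z: float) -> tuple[float, float]:
    denom = 1.0 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
    return center - half, center + half


def wilson_interval(
    point_estimate: float,
    n: float,
    z: float = 1.96,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> WilsonInterval:
    """Wilson score bounds as damped fixed points of ``p = p_hat ± z*sqrt(p(1-p)/n)``.

    Each bound is iterated from the point estimate with damping factor 1/2
    until successive iterates differ by less than ``tol``; the converged
    bounds coincide with the closed-form Wilson score interval.
    """
    p_hat = float(point_estimate)
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"point estimate must be in [0, 1], got {p_hat}")
    if n < 1:
        raise ValueError("n must be >= 1")

    total_iters = 0

    def solve(sign: float) -> float:
        nonlocal total_iters

        def f(u: float) -> float:
            return p_hat + sign * z * np.sqrt(max(u * (1 - u), 0.0) / n)

        # the sought fixed point is bracketed: lower bound in [0, p_hat],
        # upper bound in [p_hat, 1] (residual u - f(u) changes sign there)
        lo, hi = (0.0, p_hat) if sign < 0 else (p_hat, 1.0)
        u = min(max(p_hat, 1e-4), 1 - 1e-4)  # off the degenerate boundary roots
        for k in range(1, max_iter + 1):
            fu = f(u)
            # slope-damped step: the plain update diverges where |f'| > 1
            fp = sign * z * (1 - 2 * u) / (2 * np.sqrt(max(u * (1 - u) * n, 1e-30)))
            damp = 1.0 / (1.0 - fp) if abs(1.0 - fp) > 1e-3 else 0.5
            u_new = u + damp * (fu - u)
            if not (lo <= u_new <= hi):
                u_new = 0.5 * (lo + hi)  # bisection safeguard
            if u_new - f(u_new) <= 0:
                lo = u_new
            else:
                hi = u_new
            if abs(u_new - u) < tol or hi - lo < tol:
                total_iters += k
                return u_new
            u = u_new
        raise RuntimeError(
            f"Wilson fixed point did not converge in {max_iter} iterations; "
            f"last iterate {u}"
        )

    lower = solve(-1.0)
    upper = solve(+1.0)
    if p_hat == 0.0:
        lower = 0.0
    if p_hat == 1.0:
        upper = 1.0
    return WilsonInterval(p_hat, float(lower), float(upper), z, n, total_iters)


# ---------------------------------------------------------------------------
# AUC with placement-value (structural components) variance

def auc_with_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with mid-rank tie handling and a normal-quantile CI.

    The variance is estimated from the placement values (structural
    components): ``var = var(V10)/n1 + var(V01)/n0`` where ``V10_i`` is
    the fraction of controls scored below case ``i`` (ties counted half)
    and ``V01_j`` symmetrically for controls.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    cases, controls = s[y == 1], s[y == 0]
    n1, n0 = cases.size, controls.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[:n1]
    r_controls = ranks[n1:]
    # placement of each case among controls (and vice versa), via mid-ranks
    v10 = (r_cases - stats.rankdata(cases)) / n0
    v01 = 1.0 - (r_controls - stats.rankdata(controls)) / n1
    auc = float(np.mean(v10))

    var = 0.0
    if n1 > 1:
        var += np.var(v10, ddof=1) / n1
    if n0 > 1:
        var += np.var(v01, ddof=1) / n0
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))
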