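"""End-to-end experiments: structured-permutation study, covariate-subset
model search, and reproducible report assembly.

The structured-permutation experiment is the controlled reproduction of
Simpson's paradox: starting from a liability-threshold cohort, groups are
rebuilt as quantiles of a hidden variable ``y ~ N(a1*PRS + a2*PCE, 1)``
and a standard GLM and a Mundlak GLM (both regressed on PRS only) are
compared by leave-one-group-out prediction of group case rates.  With
``a1`` and ``a2`` of the same sign both models rank groups correctly but
the Mundlak model tracks the rates far better; with opposite signs the
GLM's predictions invert (negative observed-predicted correlation) while
the Mundlak model stays strongly positive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .group_inference import bh_adjust  # noqa: F401  (re-exported convenience)
from .models import (
    auc_with_ci,
    fit_logistic,
    fit_mundlak,
    lococv,
    wilson_interval,
)
from .synthetic import (
    CohortConfig,
    StructuredPermutationConfig,
    assign_quantile_groups,
    generate_base_cohort,
)

__all__ = [
    "ExperimentReport",
    "cohort_hash",
    "run_structured_permutation_experiment",
    "run_participation_bias_demo",
    "regenerate_report",
    "covariate_subset_search",
    "enumerate_subsets",
    "make_report",
]


def cohort_hash(cohort: pd.DataFrame) -> str:
    """Stable content hash of a cohort table (column-order independent)."""
    df = cohort[sorted(cohort.columns)]
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class ExperimentReport:
    """Self-describing experiment output: every number is regenerable from
    the embedded config snapshot."""

    config: dict
    cohort_hash: str
    sections: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(
            {"config": self.config, "cohort_hash": self.cohort_hash,
             "sections": self.sections},
            sort_keys=True, indent=2, default=default,
        )


def run_structured_permutation_experiment(
    cohort_config: CohortConfig,
    alpha1: float,
    alpha2: float,
    n_groups: int = 21,
    covariates: Sequence[str] = ("prs",),
    seed: int = 0,
) -> ExperimentReport:
    """Quantile-group cohort, then LOCOCV group-rate prediction for GLM vs Mundlak.

    The cohort is generated from ``cohort_config`` (its own seed), the
    hidden grouping variable is drawn with ``seed``, and both models are
    regressed on the given covariates (default: PRS only).
    """
    cohort = generate_base_cohort(cohort_config)
    spc = StructuredPermutationConfig(alpha1, alpha2, n_groups, seed)
    grouped = assign_quantile_groups(cohort, spc)

    sections: dict = {}
    covariates = list(covariates)
    h = cohort_hash(grouped)
    corrs = {}
    for model in ("glm", "mundlak"):
        table, corr = lococv(grouped, covariates, model=model)
        corrs[model] = corr
        wilson = [
            wilson_interval(p, n).__dict__
            for p, n in zip(table["predicted_rate"], table["n"])
            if np.isfinite(p)
        ]
        sections[model] = {
            "cohort_hash": h,
            "rates": table.to_dict(orient="records"),
            "lococv_correlation": corr,
            "wilson_intervals": wilson,
        }
    config = {
        "cohort_config": cohort_config.to_dict(),
        "alpha1": alpha1,
        "alpha2": alpha2,
        "n_groups": n_groups,
        "covariates": covariates,
        "seed": seed,
    }
    report = make_report(sections, config)
    report.sections["correlations"] = {**corrs, "cohort_hash": h}
    return report


def regenerate_report(report: ExperimentReport) -> ExperimentReport:
    """Re-run a structured-permutation experiment from its config snapshot."""
    cfg = report.config
    return run_structured_permutation_experiment(
        CohortConfig.from_dict(cfg["cohort_config"]),
        cfg["alpha1"],
        cfg["alpha2"],
        cfg["n_groups"],
        cfg["covariates"],
        cfg["seed"],
    )


def make_report(sections: Mapping[str, Mapping], config: Mapping) -> ExperimentReport:
    """Assemble sections (each carrying a ``cohort_hash``) into one report.

    Sections computed from different cohorts cannot be mixed: a report's
    numbers must share a single provenance.
    """
    hashes = {
        s.get("cohort_hash") for s in sections.values() if "cohort_hash" in s
    }
    if len(hashes) > 1:
        raise ValueError(f"mixed cohort provenance in report sections: {hashes}")
    h = hashes.pop() if hashes else ""
    return ExperimentReport(
        config=dict(config), cohort_hash=h, sections={k: dict(v) for k, v in sections.items()}
    )


# ---------------------------------------------------------------------------
# participation-bias (ascertainment) demonstration

def run_participation_bias_demo(
    n_groups: int = 21,
    n_per_group: int = 10000,
    seed: int = 0,
    bias_strength: float = 1.2,
) -> dict:
    """Reproduce the ascertainment-bias sign reversal on synthetic data.

    Groups receive increasing baseline liability shifts (so case rates rise
    across groups) while liability-dependent retention thins the
    high-liability members of the high-risk groups more strongly — the
    survivors of riskier groups carry lower polygenic scores.  The
    individual-level PRS-outcome correlation stays positive while the
    correlation of group-mean PRS with group case rate turns negative.
    """
    from scipy import stats as _stats

    from .group_inference import simpsons_scan
    from .synthetic import BiasConfig, apply_participation_bias

    cfg = CohortConfig(
        n_groups=n_groups,
        group_sizes=n_per_group,
        group_effects=list(np.linspace(-0.4, 0.4, n_groups)),
        seed=seed,
    )
    cohort = generate_base_cohort(cfg)
    bias = BiasConfig(
        strength=bias_strength,
        group_gradient=list(np.linspace(0.0, 1.0, n_groups)),
        seed=seed + 1,
    )
    biased = apply_participation_bias(cohort, bias)
    individual_r = float(_stats.pearsonr(biased["prs"], biased["cad"])[0])
    means = biased.groupby("group")[["prs", "cad"]].mean()
    group_r = float(_stats.pearsonr(means["prs"], means["cad"])[0])
    scans = simpsons_scan(biased, ["prs", "pce", "cad"])
    flagged = {
        (s.var_a, s.var_b) for s in scans if s.reversal
    }
    return {
        "individual_r": individual_r,
        "group_r": group_r,
        "retained_fraction": len(biased) / len(cohort),
        "prs_outcome_reversal_flagged": ("prs", "cad") in flagged,
        "scans": scans,
        "cohort_hash": cohort_hash(biased),
    }


# ---------------------------------------------------------------------------
# covariate subset search

def enumerate_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^k - 1 non-empty subsets, by size then candidate order."""
    out: list[tuple[str, ...]] = []
    for k in range(1, len(candidates) + 1):
        out.extend(combinations(candidates, k))
    return out


def _fit_and_auc(
    cohort: pd.DataFrame,
    subset: Sequence[str],
    model: str,
    outcome: str,
    group_col: str,
) -> tuple[float, float, float]:
    from .models import _predict_probabilities  # local: private helper reuse

    if model == "mundlak":
        fit = fit_mundlak(cohort, list(subset), outcome, group_col)
    else:
        X = cohort[list(subset)].copy()
        X.insert(0, "const", 1.0)
        fit = fit_logistic(X, cohort[outcome], covariates=list(subset))
    p = _predict_probabilities(fit, cohort, group_col)
    return auc_with_ci(p, cohort[outcome].to_numpy())


def covariate_subset_search(
    cohort: pd.DataFrame,
    candidate_variables: Sequence[str],
    mode: str = "exhaustive",
    model: str = "mundlak",
    outcome: str = "cad",
    group_col: str = "group",
) -> pd.DataFrame:
    """Search covariate subsets ranked by in-sample AUC.

    ``exhaustive`` fits every non-empty subset (2^k - 1 models, k <= 20);
    ``greedy`` follows the forward path — best single variable, then best
    addition — returning one nested model per step.  Individual fit
    failures are recorded per subset and the search continues.
    """
    cands = list(candidate_variables)
    if not cands:
        raise ValueError("candidate list must be non-empty")
    rows = []

    def try_subset(subset: tuple[str, ...], step: Optional[int] = None) -> float:
        try:
            auc, lo, hi = _fit_and_auc(cohort, subset, model, outcome, group_col)
            err = ""
        except (ValueError, np.linalg.LinAlgError) as e:
            auc, lo, hi, err = np.nan, np.nan, np.nan, str(e)
        rows.append(
            {
                "subset": subset,
                "k": len(subset),
                "auc": auc,
                "auc_lower": lo,
                "auc_upper": hi,
                "step": step,
                "error": err,
            }
        )
        return auc

    if mode == "exhaustive":
        if len(cands) > 20:
            raise ValueError("exhaustive mode is bounded at 20 candidates")
        for subset in enumerate_subsets(cands):
            try_subset(subset)
        out = pd.DataFrame(rows).drop(columns="step")
        return out.sort_values("auc", ascending=False, ignore_index=True)

    if mode == "greedy":
        chosen: list[str] = []
        for step in range(1, len(cands) + 1):
            scores = {
                c: try_subset(tuple(chosen + [c]), step)
                for c in cands
                if c not in chosen
            }
            best = max(scores, key=lambda c: (-1 if np.isnan(scores[c]) else scores[c]))
            chosen.append(best)
        df = pd.DataFrame(rows)
        # keep the winning nested chain, one row per path step
        path = [
            df[(df["step"] == k)].sort_values("auc", ascending=False).iloc[0]
            for k in range(1, len(cands) + 1)
        ]
        return pd.DataFrame(path).reset_index(drop=True)

    raise ValueError(f"mode must be 'exhaustive' or 'greedy', got {mode!r}")
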