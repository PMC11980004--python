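"""Risk-model fitting and evaluation.

The discrimination analysis is logistic regression on event-by-end-of-
follow-up, graded by the C-statistic (AUC) with Harrell optimism correction
via bootstrap refitting; nested models are compared with the DeLong test and
continuous net reclassification improvement (NRI).  The association analysis
is Cox proportional hazards (Efron ties, via lifelines) with Schoenfeld
residual checks, plus Kaplan-Meier curves and the log-rank test for groups
split at the Youden-index cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test, proportional_hazard_test
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FittedModel",
    "ModelEval",
    "GLCM_AUTOCORRELATION_CUTOFF",
    "fit_model",
    "auc",
    "bootstrap_corrected_auc",
    "delong_test",
    "youden_cutoff",
    "continuous_nri",
    "categorical_reclassification",
    "cox_models",
    "km_logrank",
    "model_grid",
    "evaluate_model_grid",
]

logger = logging.getLogger(__name__)

#: published development-cohort Youden cutoff on GLCM autocorrelation;
#: cohort-specific — recompute for any new data set
GLCM_AUTOCORRELATION_CUTOFF = 3.93


@dataclass
class FittedModel:
    """Logistic model with standardization baked into prediction."""

    predictors: list[str]
    coef: np.ndarray  # intercept first
    center: np.ndarray
    scale: np.ndarray
    separation_flagged: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        x = df.loc[:, self.predictors].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        eta = self.coef[0] + z @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ModelEval:
    """Apparent and optimism-corrected discrimination of one model."""

    predictors: list[str]
    apparent_auc: float
    corrected_auc: float
    ci: tuple[float, float]
    optimism: float
    risks: np.ndarray
    model: FittedModel


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (x - center) / scale, center, scale


def fit_model(
    df: pd.DataFrame,
    predictors: list[str],
    outcome: str = "event",
    quiet: bool = False,
) -> FittedModel:
    """Maximum-likelihood logistic fit of ``outcome ~ predictors``.

    Predictors are z-scored internally (AUC is unaffected; convergence is
    helped).  Perfect separation or non-convergence triggers a fall back to
    a ridge-penalized fit, flagged on the returned model.
    """
    y = df[outcome].to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 events and 2 non-events")
    x = df.loc[:, predictors].to_numpy(dtype=float)
    z, center, scale = _standardize(x)
    zc = sm.add_constant(z, has_constant="add")
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, zc).fit(disp=0, maxiter=200)
        coef = np.asarray(res.params, dtype=float)
        if not res.mle_retvals.get("converged", False) or np.abs(coef).max() > 30.0:
            raise RuntimeError("separation suspected")
    except Exception:
        if not quiet:
            logger.warning("separation/non-convergence; using penalized logistic fit")
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(z, y)
        coef = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
        flagged = True
    return FittedModel(list(predictors), coef, center, scale, flagged)


def auc(risks: np.ndarray, events: np.ndarray) -> float:
    """Concordance probability (Mann-Whitney form, half credit for ties)."""
    risks = np.asarray(risks, dtype=float)
    events = np.asarray(events).astype(bool)
    n_pos = int(events.sum())
    n_neg = int((~events).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(risks)
    return float((ranks[events].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_corrected_auc(
    df: pd.DataFrame,
    predictors: list[str],
    outcome: str = "event",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ModelEval:
    """Harrell optimism-corrected AUC with a percentile bootstrap CI.

    Each bootstrap resample refits the model; optimism is the mean of
    (AUC on the resample) - (resampled model's AUC on the original data),
    and corrected = apparent - optimism.  The CI takes the 2.5/97.5
    percentiles of the original model's AUC over the resamples, shifted by
    the optimism, then widened if needed to contain the point estimate.
    Resamples missing an outcome class are redrawn.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = df[outcome].to_numpy(dtype=float)
    model = fit_model(df, predictors, outcome)
    risks = model.predict(df)
    apparent = auc(risks, y)

    n = len(df)
    optimisms = np.empty(n_boot)
    orig_model_aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if 2 <= yb.sum() <= n - 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        dfb = df.iloc[idx]
        mb = fit_model(dfb, predictors, outcome, quiet=True)
        auc_boot = auc(mb.predict(dfb), yb)
        auc_orig = auc(mb.predict(df), y)
        optimisms[b] = auc_boot - auc_orig
        orig_model_aucs[b] = auc(risks[idx], yb)
    optimism = float(optimisms.mean())
    corrected = apparent - optimism
    lo, hi = np.percentile(orig_model_aucs, [2.5, 97.5]) - optimism
    ci = (min(float(lo), corrected), max(float(hi), corrected))
    return ModelEval(list(predictors), apparent, corrected, ci, optimism, risks, model)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(risks: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per event) and V01 (per non-event)."""
    pos = risks[events]
    neg = risks[~events]
    m, n = len(pos), len(neg)
    all_r = np.concatenate([pos, neg])
    rank_all = _midrank(all_r)
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    a = float((rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01, a


def delong_test(
    risks_a: np.ndarray, risks_b: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong comparison of two correlated AUCs.

    Returns (AUC_a - AUC_b, two-sided p).  Identical risk orderings give a
    zero-variance difference, reported as p = 1.
    """
    events = np.asarray(events).astype(bool)
    risks_a = np.asarray(risks_a, dtype=float)
    risks_b = np.asarray(risks_b, dtype=float)
    if risks_a.shape != risks_b.shape or risks_a.shape[0] != events.shape[0]:
        raise ValueError("both models must score the same patients")
    v10_a, v01_a, auc_a = _delong_components(risks_a, events)
    v10_b, v01_b, auc_b = _delong_components(risks_b, events)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return diff, 1.0
    z = diff / np.sqrt(var_diff)
    return diff, float(2.0 * stats.norm.sf(abs(z)))


def youden_cutoff(risks: np.ndarray, events: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    High risk is ``risk >= threshold``; candidates are the observed risk
    values; ties take the lowest threshold.  An anti-predictive model
    (max J <= 0) is returned with a warning.
    """
    risks = np.asarray(risks, dtype=float)
    events = np.asarray(events).astype(bool)
    if events.all() or not events.any():
        raise ValueError("both outcome classes must be present")
    candidates = np.unique(risks)
    pos = np.sort(risks[events])
    neg = np.sort(risks[~events])
    sens = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    spec = np.searchsorted(neg, candidates, side="left") / neg.size
    j = sens + spec - 1.0
    # lowest threshold among maximizers; tolerance guards float-order noise
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    if j[best] <= 0:
        logger.warning("anti-predictive risks: best Youden J = %.3f", j[best])
    return float(candidates[best])


def continuous_nri(
    risk_old: np.ndarray,
    risk_new: np.ndarray,
    events: np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float], float]:
    """Continuous (category-free) NRI with percentile-bootstrap CI and p.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
    where up/down is any increase/decrease of predicted risk.  Returns
    (nri, (lo, hi), two-sided p from the bootstrap normal approximation).
    """
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    events = np.asarray(events).astype(bool)

    def _nri(old, new, ev):
        up = new > old
        down = new < old
        ne = ~ev
        if ev.sum() == 0 or ne.sum() == 0:
            return np.nan
        return float(
            (up[ev].mean() - down[ev].mean()) + (down[ne].mean() - up[ne].mean())
        )

    point = _nri(risk_old, risk_new, events)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = events.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        v = _nri(risk_old[idx], risk_new[idx], events[idx])
        if np.isfinite(v):
            boots.append(v)
    boots = np.asarray(boots)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    se = float(boots.std(ddof=1))
    p = 1.0 if se == 0 else float(2.0 * stats.norm.sf(abs(point) / se))
    return point, (float(lo), float(hi)), p


def categorical_reclassification(
    risk_old: np.ndarray,
    risk_new: np.ndarray,
    events: np.ndarray,
    cutoff: float,
) -> pd.DataFrame:
    """Low/high-risk reclassification counts at a fixed cutoff.

    Up-moves are correct for events, down-moves correct for non-events.
    Returns one row per event stratum with counts and percentages.
    """
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    events = np.asarray(events).astype(bool)
    old_high = risk_old >= cutoff
    new_high = risk_new >= cutoff
    up = ~old_high & new_high
    down = old_high & ~new_high
    rows = []
    for label, grp in (("event", events), ("non-event", ~events)):
        n = int(grp.sum())
        n_up, n_down = int(up[grp].sum()), int(down[grp].sum())
        correct, incorrect = (n_up, n_down) if label == "event" else (n_down, n_up)
        rows.append(
            {
                "stratum": label,
                "n": n,
                "up": n_up,
                "down": n_down,
                "unchanged": n - n_up - n_down,
                "correct": correct,
                "incorrect": incorrect,
                "pct_correct": 100.0 * correct / n if n else np.nan,
                "pct_incorrect": 100.0 * incorrect / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cox_models(
    df: pd.DataFrame,
    predictors: list[str],
    duration_col: str = "time_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit with Schoenfeld-residual PH checks.

    Returns a table with one row per predictor: hazard ratio, 95% CI, Wald
    p, and the Schoenfeld proportional-hazards test p.  Requires at least 5
    events.  Non-convergence propagates as a lifelines ConvergenceError.
    """
    if df[event_col].sum() < 5:
        raise ValueError("need at least 5 events for a Cox fit")
    cols = [duration_col, event_col] + list(predictors)
    data = df.loc[:, cols].astype(float)
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ph = proportional_hazard_test(cph, data, time_transform="km")
    summary = cph.summary
    out = pd.DataFrame(
        {
            "predictor": summary.index,
            "hr": summary["exp(coef)"].to_numpy(),
            "hr_ci_low": summary["exp(coef) lower 95%"].to_numpy(),
            "hr_ci_high": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
            "schoenfeld_p": [
                float(np.min(np.atleast_1d(ph.summary.loc[v, "p"])))
                if v in ph.summary.index.get_level_values(0)
                else np.nan
                for v in summary.index
            ],
        }
    ).reset_index(drop=True)
    return out


def km_logrank(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[dict[object, KaplanMeierFitter], float, float]:
    """Kaplan-Meier curves per group and the log-rank test.

    Returns (fitters-by-group-label, chi-square, p).  Every group must be
    nonempty; two groups use the standard two-sample log-rank, more use its
    multivariate generalization.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    fitters: dict[object, KaplanMeierFitter] = {}
    for lab in labels:
        sel = groups == lab
        if not sel.any():
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=str(lab))
        fitters[lab] = kmf
    if len(labels) == 2:
        a, b = (groups == labels[0]), (groups == labels[1])
        res = logrank_test(time[a], time[b], event[a], event[b])
    else:
        res = multivariate_logrank_test(time, groups, event)
    return fitters, float(res.test_statistic), float(res.p_value)


def model_grid(signature_features: list[str]) -> dict[str, list[str]]:
    """The standard model grid: LGE presence/burden and clinical-score
    combinations, each with and without the radiomic signature."""
    grid: dict[str, list[str]] = {
        "radiomics_only": list(signature_features),
        "lge_presence": ["lge_presence"],
        "lge_burden": ["lge_burden"],
        "clinical_lge_presence": ["clinical_score", "lge_presence"],
        "clinical_lge_burden": ["clinical_score", "lge_burden"],
    }
    for base in list(grid):
        if base != "radiomics_only":
            grid[base + "_radiomics"] = grid[base] + list(signature_features)
    return grid


def evaluate_model_grid(
    df: pd.DataFrame,
    signature_features: list[str],
    outcome: str = "event",
    n_boot: int = 1000,
    nri_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, ModelEval]]:
    """Fit and evaluate the whole model grid.

    Returns (per-model AUC table, with-vs-without-radiomics comparison table
    holding DeLong p and continuous NRI, evaluations keyed by model name).
    """
    rng = np.random.default_rng(seed)
    grid = model_grid(signature_features)
    evals: dict[str, ModelEval] = {}
    rows = []
    for name, predictors in grid.items():
        ev = bootstrap_corrected_auc(df, predictors, outcome, n_boot, rng)
        evals[name] = ev
        rows.append(
            {
                "model": name,
                "predictors": "+".join(predictors),
                "apparent_auc": ev.apparent_auc,
                "corrected_auc": ev.corrected_auc,
                "auc_ci_low": ev.ci[0],
                "auc_ci_high": ev.ci[1],
            }
        )
    auc_table = pd.DataFrame(rows)

    y = df[outcome].to_numpy()
    comp_rows = []
    for base in ("lge_presence", "lge_burden", "clinical_lge_presence", "clinical_lge_burden"):
        with_r = base + "_radiomics"
        diff, p_delong = delong_test(evals[with_r].risks, evals[base].risks, y)
        nri, nri_ci, p_nri = continuous_nri(
            evals[base].risks, evals[with_r].risks, y, nri_boot, rng
        )
        comp_rows.append(
            {
                "base_model": base,
                "auc_diff": diff,
                "delong_p": p_delong,
                "nri": nri,
                "nri_ci_low": nri_ci[0],
                "nri_ci_high": nri_ci[1],
                "nri_p": p_nri,
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    return auc_table, comparisons, evals
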