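"""Association and survival statistics for the discovered subtypes.

Feature–subtype association uses one-way ANOVA (parametric) and
Kruskal–Wallis (nonparametric, midrank ties) per feature with
Benjamini–Hochberg correction across all features. Categorical label
associations (molecular subtypes, clinical variables) use the Pearson
chi-squared test, with Yates continuity correction on 2x2 tables by
default. Survival is assessed with Kaplan–Meier curves plus the log-rank
test, and a multivariable Cox proportional-hazards model (Breslow tie
handling, configurable baselines for categorical covariates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "feature_subtype_tests",
    "chisq_test",
    "pearson_corr",
    "km_logrank",
    "cox_ph",
    "TestResult",
    "SurvivalFit",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    q: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class SurvivalFit:
    """Kaplan–Meier step tables per group, log-rank test, and/or a Cox fit."""

    km: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_statistic: float | None = None
    logrank_df: int | None = None
    logrank_p: float | None = None
    cox: pd.DataFrame | None = None  # per-covariate log-HR, HR, CI, Wald p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def feature_subtype_tests(
    F: pd.DataFrame, labels, method_alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature one-way ANOVA and Kruskal–Wallis across subtypes with BH
    correction over all tested features.

    Constant features (no variation anywhere) are skipped with p = 1 by
    convention; features with missing values drop those specimens.
    Returns a DataFrame indexed by feature with columns
    anova_F, anova_p, anova_q, kw_H, kw_p, kw_q.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 members")

    rows = []
    for name in F.columns:
        col = F[name].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        samples = [col[ok & (labels == g)] for g in groups]
        if any(len(s) < 2 for s in samples) or np.all(col[ok] == col[ok][0]):
            rows.append({"feature": name, "anova_F": 0.0, "anova_p": 1.0,
                         "kw_H": 0.0, "kw_p": 1.0})
            continue
        try:
            f_stat, f_p = sps.f_oneway(*samples)
        except Exception:
            f_stat, f_p = 0.0, 1.0
        try:
            h_stat, h_p = sps.kruskal(*samples)
        except ValueError:  # all values identical
            h_stat, h_p = 0.0, 1.0
        if not np.isfinite(f_p):
            f_stat, f_p = 0.0, 1.0
        rows.append(
            {"feature": name, "anova_F": float(f_stat), "anova_p": float(f_p),
             "kw_H": float(h_stat), "kw_p": float(h_p)}
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["anova_q"] = bh_adjust(out["anova_p"].to_numpy())
    out["kw_q"] = bh_adjust(out["kw_p"].to_numpy())
    return out[["anova_F", "anova_p", "anova_q", "kw_H", "kw_p", "kw_q"]]


def chisq_test(table, yates: bool | None = None, name: str = "chisq") -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table.

    Yates continuity correction defaults to on for 2x2 tables and off
    otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    if yates is None:
        yates = t.shape == (2, 2)
    res = sps.chi2_contingency(t, correction=bool(yates))
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
        extra={"expected": res.expected_freq, "yates": bool(yates)},
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def km_logrank(clinical: pd.DataFrame, groups) -> SurvivalFit:
    """Kaplan–Meier estimate per group and the k-sample log-rank test.

    ``clinical`` needs os_time and os_event columns; ``groups`` is a
    per-row group label.
    """
    groups = np.asarray(groups)
    t = clinical["os_time"].to_numpy(dtype=float)
    e = clinical["os_event"].to_numpy(dtype=int)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if e.sum() < 1:
        raise ValueError("need at least 1 event")
    km: dict[str, pd.DataFrame] = {}
    for g in uniq:
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"group {g} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        tab = kmf.event_table.copy()
        tab["survival"] = kmf.survival_function_["KM_estimate"].reindex(tab.index).to_numpy()
        km[str(g)] = tab.reset_index().rename(
            columns={"event_at": "time", "at_risk": "n_at_risk", "observed": "n_events"}
        )[["time", "n_at_risk", "n_events", "censored", "survival"]]
    lr = multivariate_logrank_test(t, groups, e)
    return SurvivalFit(
        km=km,
        logrank_statistic=float(lr.test_statistic),
        logrank_df=int(len(uniq) - 1),
        logrank_p=float(lr.p_value),
    )


def _design_matrix(
    clinical: pd.DataFrame,
    covariates: list[str],
    baselines: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-code categorical covariates against stated baselines; keep
    numeric covariates as-is. Rows with 'unknown' levels are dropped."""
    baselines = baselines or {}
    cols = {}
    keep = pd.Series(True, index=clinical.index)
    for cov in covariates:
        s = clinical[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.astype(float)
            continue
        s = s.astype(str)
        keep &= s != "unknown"
        levels = sorted(s[s != "unknown"].unique())
        base = str(baselines.get(cov, levels[0]))
        if base not in levels:
            logger.warning(
                "baseline %r absent from %r; using %r", base, cov, levels[0]
            )
            base = levels[0]
        for lev in levels:
            if lev != base:
                cols[f"{cov}[{lev}]"] = (s == lev).astype(float)
    X = pd.DataFrame(cols, index=clinical.index)[keep.to_numpy()]
    return X


def cox_ph(
    clinical: pd.DataFrame,
    covariates: list[str],
    baselines: dict[str, str] | None = None,
    ties: str = "breslow",
) -> SurvivalFit:
    """Multivariable Cox proportional-hazards regression.

    Categorical covariates are dummy-coded against the stated baseline
    level; rows with an 'unknown' level are excluded. Partial-likelihood
    maximization uses the chosen tie convention (Breslow by default,
    Efron via ``ties="efron"``). Wald 95% CIs are exp(beta +/- 1.96 se).
    """
    X = _design_matrix(clinical, covariates, baselines)
    sub = clinical.loc[X.index]
    t = sub["os_time"].to_numpy(dtype=float)
    e = sub["os_event"].to_numpy(dtype=int)
    if e.sum() < X.shape[1]:
        raise ValueError(
            f"too few events ({e.sum()}) for {X.shape[1]} parameters"
        )
    model = PHReg(t, X.to_numpy(dtype=float), status=e, ties=ties)
    try:
        fit = model.fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - non-convergence path
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    beta = fit.params
    se = fit.bse
    z = 1.959963984540054
    table = pd.DataFrame(
        {
            "log_hr": beta,
            "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - z * se),
            "hr_ci_high": np.exp(beta + z * se),
            "se": se,
            "wald_p": fit.pvalues,
        },
        index=X.columns,
    )
    return SurvivalFit(cox=table)
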