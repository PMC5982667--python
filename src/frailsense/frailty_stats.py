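"""Group comparisons, effect sizes, and the two-stage feature selection.

Continuous parameters are compared across the three frailty groups with an
ANCOVA-style linear model (covariates configurable, none by default) and
unadjusted pairwise post-hoc contrasts (LSD; Tukey HSD available) for the two
reported comparisons, non-frail vs pre-frail and pre-frail vs frail.
Categorical variables use the Fisher exact test.  Effect sizes are Cohen's d
magnitudes with pooled (n-1 weighted) standard deviation.

Selection is two-stage: the filter keeps parameters with p < 0.05 and
d >= 0.4 on both pre-frail contrasts; the embedded stage keeps, of those, the
parameters whose single-feature decision-tree one-vs-rest AUC (5-fold CV on
the whole dataset) exceeds 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .frailty_clinical import STATUS_FRAIL, STATUS_NON_FRAIL, STATUS_PRE_FRAIL
from .models import roc_auc

FILTER_P_MAX = 0.05
FILTER_D_MIN = 0.4
EMBEDDED_AUC_MIN = 0.7

CONTRAST_NP = (STATUS_NON_FRAIL, STATUS_PRE_FRAIL)
CONTRAST_PF = (STATUS_PRE_FRAIL, STATUS_FRAIL)


def cohens_d(group_a, group_b) -> float:
    """Cohen's d magnitude with pooled (n-1 weighted) standard deviation."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.shape[0], b.shape[0]
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        return float("nan")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))


def compare_groups(values, groups, covariates: pd.DataFrame | None = None,
                   posthoc: str = "lsd") -> dict[tuple[str, str], float]:
    """Pairwise post-hoc p-values for the two reported contrasts.

    Fits ``y ~ C(group) (+ covariates)`` by OLS and tests the pairwise group
    contrasts against the model's residual variance.  ``posthoc='lsd'`` keeps
    the unadjusted p-values; ``'tukey_hsd'`` applies the studentized-range
    adjustment.  Degenerate (zero-variance) input yields NaN p-values.
    """
    y = np.asarray(values, dtype=np.float64)
    g = np.asarray(groups, dtype=object)
    order = [STATUS_NON_FRAIL, STATUS_PRE_FRAIL, STATUS_FRAIL]
    present = [lvl for lvl in order if np.sum(g == lvl) > 0]
    if len(present) < 2 or any(np.sum(g == lvl) < 3 for lvl in present):
        raise ValueError("need >= 2 groups with >= 3 members each")
    if np.var(y) == 0:
        return {CONTRAST_NP: float("nan"), CONTRAST_PF: float("nan")}

    dummies = pd.get_dummies(pd.Categorical(g, categories=present), drop_first=True,
                             dtype=float)
    X = dummies
    if covariates is not None:
        X = pd.concat([dummies.reset_index(drop=True),
                       covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X.to_numpy(dtype=np.float64))
    model = sm.OLS(y, X).fit()

    k = len(present)
    out: dict[tuple[str, str], float] = {}
    for pair in (CONTRAST_NP, CONTRAST_PF):
        lvl_a, lvl_b = pair
        if lvl_a not in present or lvl_b not in present:
            out[pair] = float("nan")
            continue
        contrast = np.zeros(X.shape[1])
        for lvl, sign in ((lvl_a, 1.0), (lvl_b, -1.0)):
            idx = present.index(lvl)
            if idx > 0:            # baseline level is absorbed in the constant
                contrast[idx] = sign
        tt = model.t_test(contrast)
        if posthoc == "lsd":
            out[pair] = float(np.asarray(tt.pvalue).ravel()[0])
        elif posthoc == "tukey_hsd":
            q = abs(float(np.asarray(tt.tvalue).ravel()[0])) * np.sqrt(2.0)
            out[pair] = float(scipy.stats.studentized_range.sf(q, k, model.df_resid))
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
    return out


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("Fisher exact expects a 2x2 table")
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class GroupComparison:
    feature: str
    group_stats: dict = field(default_factory=dict)   # status -> (mean, sd)
    p_np: float = np.nan
    p_pf: float = np.nan
    d_np: float = np.nan
    d_pf: float = np.nan
    selected_filter: bool = False
    auc_mean: float = np.nan
    auc_sd: float = np.nan
    selected_embedded: bool = False


def comparison_table(cohort: pd.DataFrame, feature_names: list[str],
                     covariates: list[str] | None = None,
                     posthoc: str = "lsd",
                     p_max: float = FILTER_P_MAX,
                     d_min: float = FILTER_D_MIN) -> pd.DataFrame:
    """Group means +- SD, contrast p-values, Cohen's d, and the filter star.

    A feature is starred (``selected_filter``) when both the non-frail vs
    pre-frail and pre-frail vs frail contrasts reach p < 0.05 and d >= 0.4.
    """
    cov = cohort[covariates] if covariates else None
    rows = []
    for name in feature_names:
        y = cohort[name].to_numpy(dtype=np.float64)
        g = cohort["status"].to_numpy(dtype=object)
        keep = np.isfinite(y)
        y, gk = y[keep], g[keep]
        ck = cov.loc[keep] if cov is not None else None
        groups = {s: y[gk == s] for s in
                  (STATUS_NON_FRAIL, STATUS_PRE_FRAIL, STATUS_FRAIL)}
        ps = compare_groups(y, gk, ck, posthoc)
        d_np = cohens_d(groups[STATUS_NON_FRAIL], groups[STATUS_PRE_FRAIL])
        d_pf = cohens_d(groups[STATUS_PRE_FRAIL], groups[STATUS_FRAIL])
        row = {"feature": name,
               "p_np": ps[CONTRAST_NP], "p_pf": ps[CONTRAST_PF],
               "d_np": d_np, "d_pf": d_pf}
        for s, vals in groups.items():
            row[f"mean_{s}"] = vals.mean()
            row[f"sd_{s}"] = vals.std(ddof=1)
        row["selected_filter"] = bool(
            row["p_np"] < p_max and row["d_np"] >= d_min
            and row["p_pf"] < p_max and row["d_pf"] >= d_min)
        rows.append(row)
    return pd.DataFrame(rows)


def filter_select(comparisons: pd.DataFrame,
                  p_max: float = FILTER_P_MAX,
                  d_min: float = FILTER_D_MIN) -> list[str]:
    """Features passing the filter thresholds on both contrasts."""
    sel = ((comparisons["p_np"] < p_max) & (comparisons["d_np"] >= d_min)
           & (comparisons["p_pf"] < p_max) & (comparisons["d_pf"] >= d_min))
    return comparisons.loc[sel, "feature"].tolist()


def univariate_auc(x, y_binary, folds: int = 5, seed: int = 0,
                   max_depth: int = 3, min_samples_leaf: int = 5) -> tuple[float, float]:
    """Single-feature decision-tree one-vs-rest AUC, mean +- SD over CV folds.

    A constant feature carries no information and scores 0.5 exactly.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1, 1)
    y = np.asarray(y_binary, dtype=int)
    if np.min(x) == np.max(x):
        return 0.5, 0.0
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in cv.split(x, y):
        clf = DecisionTreeClassifier(max_depth=max_depth,
                                     min_samples_leaf=min_samples_leaf,
                                     random_state=seed)
        clf.fit(x[train], y[train])
        scores = clf.predict_proba(x[test])[:, 1]
        aucs.append(roc_auc(scores, y[test]))
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1))


def embedded_select(cohort: pd.DataFrame, candidates: list[str],
                    auc_min: float = EMBEDDED_AUC_MIN, folds: int = 5,
                    seed: int = 0) -> pd.DataFrame:
    """AUC of each filter-passing feature on the whole dataset; keep > 0.7."""
    y = (cohort["status"] == STATUS_PRE_FRAIL).astype(int).to_numpy()
    rows = []
    for name in candidates:
        mean, sd = univariate_auc(cohort[name].to_numpy(), y, folds=folds, seed=seed)
        rows.append({"feature": name, "auc_mean": mean, "auc_sd": sd,
                     "selected_embedded": mean > auc_min})
    return pd.DataFrame(rows)
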