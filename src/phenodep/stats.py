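"""Correlation and association analyses for the pooled assessment table.

Two complementary views of the feature-depression relationship:

* **Correlation** — per-feature Pearson r against the PHQ-8 total on
  pairwise-complete rows, with Holm step-down adjustment of the p values
  (family-wise error control across the 22 features).
* **Association** — per-feature bivariate linear mixed model
  ``phq8_total ~ standardized feature + (1 | participant)``, fitted on
  multiply-imputed copies of the table (single-level predictive mean
  matching, m = 20) and pooled with Rubin's rules; Benjamini-Hochberg
  adjustment across features.

The intraclass correlation of the outcome (between-participant variance
fraction under a random-intercept-only model) motivates the mixed model:
repeated assessments from one participant are far from independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .features import CANONICAL_FEATURES

__all__ = [
    "AssociationResult",
    "IccResult",
    "holm_adjust",
    "bh_adjust",
    "pearson_with_holm",
    "icc",
    "pmm_impute",
    "rubin_pool",
    "fit_bivariate_lmm_pooled",
    "run_association_analysis",
]


@dataclass
class AssociationResult:
    """One feature's association estimate with adjusted inference."""

    feature: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float
    method: str  # "pearson_holm" | "lmm_bh"


@dataclass
class IccResult:
    """Variance components of a random-intercept-only model."""

    between_variance: float
    within_variance: float
    icc: float


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p values, returned in input order.

    For sorted raw p values p_(1) <= ... <= p_(m):
    ``adj_(i) = max_{j<=i} min(1, (m - j + 1) * p_(j))``.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    ``adj_(i) = min_{j>=i} min(1, m * p_(j) / j)`` over sorted raw values.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, m * p[order] / ranks)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pearson_with_holm(
    samples: pd.DataFrame,
    feature_names=CANONICAL_FEATURES,
    outcome: str = "phq8_total",
) -> list[AssociationResult]:
    """Per-feature Pearson correlation with the outcome on pairwise-complete
    rows, Holm-adjusted across the tested features.

    Constant or all-missing features have an undefined correlation; they
    are reported with NaN estimates (with a warning) and excluded from the
    adjustment family.
    """
    raw: dict[str, tuple[float, float]] = {}
    skipped: list[str] = []
    y_all = samples[outcome].astype(float)
    for feat in feature_names:
        x = samples[feat].astype(float)
        ok = x.notna() & y_all.notna()
        if ok.sum() < 3 or x[ok].nunique() < 2 or y_all[ok].nunique() < 2:
            warnings.warn(f"correlation undefined for feature {feat!r}")
            skipped.append(feat)
            continue
        r, p = sps.pearsonr(x[ok], y_all[ok])
        raw[feat] = (float(r), float(p))
    adj = holm_adjust([raw[f][1] for f in raw]) if raw else np.array([])
    results = [
        AssociationResult(f, raw[f][0], float("nan"), raw[f][1], float(a), "pearson_holm")
        for f, a in zip(raw, adj)
    ]
    results += [
        AssociationResult(f, float("nan"), float("nan"), float("nan"), float("nan"), "pearson_holm")
        for f in skipped
    ]
    return results


def icc(outcome, grouping) -> IccResult:
    """Intraclass correlation from one-way random-effects ANOVA variance
    components (between-group variance truncated at zero).

    Uses the unbalanced-design correction ``n0 = (N - sum n_i^2 / N) / (k-1)``
    for the between-group mean square.
    """
    y = np.asarray(outcome, dtype=float)
    g = pd.Series(grouping).to_numpy()
    ok = np.isfinite(y)
    df = pd.DataFrame({"y": y[ok], "g": g[ok]})
    sizes = df.groupby("g")["y"].size()
    k = len(sizes)
    n_total = int(sizes.sum())
    if k < 2 or (sizes >= 2).sum() < 1:
        raise ValueError("ICC needs >= 2 groups and at least one group with >= 2 observations")
    if (sizes >= 2).sum() == 0 or n_total == k:
        raise ValueError("all groups are singletons; within-group variance undefined")
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - float((sizes**2).sum()) / n_total) / (k - 1)
    var_between = max((ms_between - ms_within) / n0, 0.0)
    var_within = ms_within
    denom = var_between + var_within
    return IccResult(var_between, var_within, var_between / denom if denom > 0 else 0.0)


def pmm_impute(
    table: pd.DataFrame,
    feature_names=CANONICAL_FEATURES,
    *,
    m: int = 20,
    k_donors: int = 5,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Predictive-mean-matching multiple imputation of feature columns.

    For each column with missing cells, an OLS predictive model is fitted on
    the fully observed columns (refitted on a bootstrap resample per
    imputation, approximating parameter uncertainty); each missing cell is
    filled with the observed donor value whose predicted mean is among the
    ``k_donors`` nearest to the target's predicted mean. Imputed values are
    therefore always observed values of the same column.
    """
    rng = np.random.default_rng(seed)
    feats = [f for f in feature_names if f in table.columns]
    missing_cols = [f for f in feats if table[f].isna().any()]
    for f in missing_cols:
        if table[f].isna().all():
            raise ValueError(f"column {f!r} is entirely missing; cannot impute")
    if not missing_cols:
        return [table.copy() for _ in range(m)]

    complete_cols = [f for f in feats if not table[f].isna().any()]
    x_base = table[complete_cols].to_numpy(dtype=float) if complete_cols else np.empty(
        (len(table), 0)
    )
    x_base = np.column_stack([np.ones(len(table)), x_base])

    out = []
    for _ in range(m):
        filled = table.copy()
        for f in missing_cols:
            y = table[f].to_numpy(dtype=float)
            obs = ~np.isnan(y)
            boot = rng.choice(np.flatnonzero(obs), size=int(obs.sum()), replace=True)
            beta, *_ = np.linalg.lstsq(x_base[boot], y[boot], rcond=None)
            pred = x_base @ beta
            donor_pred = pred[obs]
            donor_vals = y[obs]
            for i in np.flatnonzero(~obs):
                d = np.abs(donor_pred - pred[i])
                nearest = np.argpartition(d, min(k_donors, d.size) - 1)[:k_donors]
                filled.iloc[i, filled.columns.get_loc(f)] = donor_vals[
                    rng.choice(nearest)
                ]
        out.append(filled)
    return out


def rubin_pool(estimates, variances) -> tuple[float, float]:
    """Rubin's rules: pooled estimate and total variance across imputations.

    ``total = W + (1 + 1/m) * B`` with W the mean within-imputation variance
    and B the between-imputation variance of the estimates.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    qbar = q.mean()
    w = u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    return float(qbar), float(w + (1.0 + 1.0 / m) * b)


def fit_bivariate_lmm_pooled(
    tables: list[pd.DataFrame],
    feature: str,
    *,
    outcome: str = "phq8_total",
    group_col: str = "participant_id",
) -> AssociationResult:
    """Random-intercept LMM of the outcome on one standardized feature,
    fitted per imputed table and pooled with Rubin's rules.

    The feature is standardized to zero mean and unit SD within each table;
    the Wald p value uses the large-sample normal reference. Raises if more
    than half the imputations fail to fit.
    """
    betas, variances = [], []
    failures = 0
    for tab in tables:
        x = tab[feature].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            failures += 1
            continue
        xs = (x - x.mean()) / sd
        exog = sm.add_constant(xs)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(
                    tab[outcome].to_numpy(dtype=float), exog, groups=tab[group_col]
                ).fit(reml=True)
            betas.append(float(fit.params[1]))
            variances.append(float(fit.bse[1]) ** 2)
        except Exception:
            failures += 1
    if failures > len(tables) / 2 or not betas:
        raise RuntimeError(
            f"mixed model failed for feature {feature!r} in {failures}/{len(tables)} imputations"
        )
    beta, total_var = rubin_pool(betas, variances)
    se = float(np.sqrt(total_var))
    p = float(2.0 * sps.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return AssociationResult(feature, beta, se, p, float("nan"), "lmm_bh")


def run_association_analysis(
    samples: pd.DataFrame,
    feature_names=CANONICAL_FEATURES,
    *,
    outcome: str = "phq8_total",
    group_col: str = "participant_id",
    m_imputations: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Full correlation + mixed-model association table.

    Returns one row per feature: Pearson ``r`` with Holm-adjusted p, pooled
    LMM ``beta`` (standardized) with its SE and BH-adjusted p, plus the
    outcome ICC (repeated as a column for convenience).
    """
    pearson = {res.feature: res for res in pearson_with_holm(samples, feature_names, outcome)}
    tables = pmm_impute(samples, feature_names, m=m_imputations, seed=seed)
    lmm: dict[str, AssociationResult] = {}
    for feat in feature_names:
        try:
            lmm[feat] = fit_bivariate_lmm_pooled(
                tables, feat, outcome=outcome, group_col=group_col
            )
        except RuntimeError:
            lmm[feat] = AssociationResult(
                feat, float("nan"), float("nan"), float("nan"), float("nan"), "lmm_bh"
            )
    valid = [f for f in feature_names if np.isfinite(lmm[f].p_raw)]
    adj = bh_adjust([lmm[f].p_raw for f in valid]) if valid else []
    for f, a in zip(valid, adj):
        lmm[f].p_adjusted = float(a)
    outcome_icc = icc(samples[outcome], samples[group_col]).icc
    return pd.DataFrame(
        {
            "feature": list(feature_names),
            "r": [pearson[f].estimate if f in pearson else np.nan for f in feature_names],
            "p_holm": [pearson[f].p_adjusted if f in pearson else np.nan for f in feature_names],
            "beta": [lmm[f].estimate for f in feature_names],
            "beta_se": [lmm[f].se for f in feature_names],
            "p_bh": [lmm[f].p_adjusted for f in feature_names],
            "icc_outcome": outcome_icc,
        }
    )
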