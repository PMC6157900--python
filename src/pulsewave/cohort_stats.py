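"""Cohort statistics: propensity matching, rank-based repeated measures,
correlation clustering, and two-group comparisons.

The repeated-measures test is a Friedman-type rank statistic that remains
valid for unbalanced designs with missing data: within each subject the
observed conditions are ranked and centred; the vector of per-condition rank
sums is compared against its exact exchangeability covariance through a
pseudo-inverse quadratic form, which is chi-square distributed under the
null.  On complete balanced tables the statistic reduces algebraically to
Friedman's chi-square.  Pairwise follow-up contrasts use a Scheffé-type
family-wise adjustment (each contrast statistic referred to the full
chi-square distribution of the global test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "RepeatedMeasuresTable",
    "MatchResult",
    "propensity_score_match",
    "wittkowski_test",
    "scheffe_pairwise",
    "correlation_cluster",
    "two_group_tests",
]


@dataclass(frozen=True)
class RepeatedMeasuresTable:
    """Subjects x conditions matrix with NaN marking missing entries."""

    values: np.ndarray
    conditions: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("need a 2D table with >= 2 conditions")
        observed = (~np.isnan(v)).sum(axis=1)
        if (observed >= 2).sum() < 3:
            raise ValueError(
                "need >= 3 subjects with at least 2 observed conditions"
            )
        object.__setattr__(self, "values", v)
        if not self.conditions:
            object.__setattr__(
                self, "conditions", tuple(f"C{i}" for i in range(v.shape[1]))
            )
        elif len(self.conditions) != v.shape[1]:
            raise ValueError("condition labels do not match table width")


def _rank_sums_and_cov(table: RepeatedMeasuresTable):
    """Centred within-subject rank sums S and their null covariance."""
    v = table.values
    n_sub, n_cond = v.shape
    S = np.zeros(n_cond)
    cov = np.zeros((n_cond, n_cond))
    used = 0
    for row in v:
        obs = ~np.isnan(row)
        m = int(obs.sum())
        if m < 2:
            continue
        used += 1
        ranks = rankdata(row[obs])
        centred = ranks - (m + 1) / 2.0
        idx = np.flatnonzero(obs)
        S[idx] += centred
        # exchangeable ranks: Var = (m^2-1)/12, Cov = -(m+1)/12
        var = (m * m - 1) / 12.0
        cv = -(m + 1) / 12.0
        for a_i, a in enumerate(idx):
            cov[a, a] += var
            for b in idx[a_i + 1:]:
                cov[a, b] += cv
                cov[b, a] += cv
    if used == 0:
        raise ValueError("no subject has >= 2 observed conditions")
    return S, cov


def wittkowski_test(table: RepeatedMeasuresTable):
    """Global Friedman-type test tolerating missing data.

    Returns ``(statistic, p_value)``; the statistic is the pseudo-inverse
    quadratic form S' Sigma^+ S with chi-square reference on rank(Sigma)
    degrees of freedom.  Equals Friedman's chi-square exactly on complete
    balanced tables.
    """
    S, cov = _rank_sums_and_cov(table)
    if np.allclose(S, 0.0) and np.allclose(cov, 0.0):
        return 0.0, 1.0
    cov_pinv = np.linalg.pinv(cov, rcond=1e-10, hermitian=True)
    stat = float(S @ cov_pinv @ S)
    df = int(np.linalg.matrix_rank(cov, tol=1e-8 * max(1.0, np.abs(cov).max())))
    if df == 0 or stat <= 0:
        return max(stat, 0.0), 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, p


def scheffe_pairwise(table: RepeatedMeasuresTable) -> pd.DataFrame:
    """All pairwise condition contrasts with Scheffé-type adjustment.

    Each contrast chi-square (1 df unadjusted) is additionally referred to
    the global test's chi-square distribution, guaranteeing adjusted p >=
    unadjusted p.
    """
    S, cov = _rank_sums_and_cov(table)
    n_cond = S.size
    df_global = max(
        1, int(np.linalg.matrix_rank(cov, tol=1e-8 * max(1.0, np.abs(cov).max())))
    )
    rows = []
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            c = np.zeros(n_cond)
            c[i], c[j] = 1.0, -1.0
            denom = float(c @ cov @ c)
            if denom <= 0:
                z2 = 0.0
            else:
                z2 = float((c @ S) ** 2 / denom)
            p_raw = float(stats.chi2.sf(z2, 1)) if z2 > 0 else 1.0
            p_adj = float(stats.chi2.sf(z2, df_global)) if z2 > 0 else 1.0
            rows.append({
                "condition_a": table.conditions[i],
                "condition_b": table.conditions[j],
                "statistic": z2,
                "p_unadjusted": p_raw,
                "p_adjusted": max(p_adj, p_raw),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# propensity score matching


@dataclass
class MatchResult:
    pairs: list  # (treated_index, control_index)
    propensity: pd.Series
    balance: pd.DataFrame  # per-covariate test stats before/after
    treated_retained: pd.Index = field(default_factory=lambda: pd.Index([]))
    control_retained: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _balance_row(name, x_t, x_c, categorical):
    if categorical:
        tab = pd.crosstab(
            np.concatenate([np.ones(len(x_t)), np.zeros(len(x_c))]),
            np.concatenate([x_t, x_c]),
        )
        if tab.shape[1] < 2:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(tab, correction=True)
        smd = np.nan
    else:
        stat, p = stats.mannwhitneyu(x_t, x_c, alternative="two-sided",
                                     method="asymptotic")
        sd = np.sqrt((np.var(x_t, ddof=1) + np.var(x_c, ddof=1)) / 2.0)
        smd = (np.mean(x_t) - np.mean(x_c)) / sd if sd > 0 else 0.0
    return {"covariate": name, "statistic": float(stat), "p_value": float(p),
            "smd": float(smd) if smd == smd else np.nan}


def propensity_score_match(
    subjects: pd.DataFrame,
    group_col: str = "group",
    treated_label: str = "HD",
    covariates: tuple = ("age", "male"),
    categorical: tuple = ("male",),
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> MatchResult:
    """Age/gender propensity matching (logistic model, caliper nearest neighbour).

    Greedy 1:1 nearest-neighbour matching on the logit of the propensity
    score without replacement, caliper ``caliper_sd`` SDs of the logit;
    treated order randomised under ``seed``.  Balance diagnostics
    (Wilcoxon rank-sum for continuous, Yates chi-square for categorical)
    are reported before and after matching.
    """
    import statsmodels.api as sm

    df = subjects.reset_index(drop=True)
    y = (df[group_col] == treated_label).astype(float)
    if y.sum() == 0 or y.sum() == len(df):
        raise ValueError("both groups must be non-empty")
    X = sm.add_constant(df[list(covariates)].astype(float))
    try:
        model = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(model.params)):
            raise np.linalg.LinAlgError
        ps = np.asarray(model.predict(X), dtype=float)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(
            "propensity model failed (possible complete separation); "
            "consider exact matching or a wider caliper"
        ) from exc
    eps = 1e-12
    logit = np.log(np.clip(ps, eps, 1 - eps) / np.clip(1 - ps, eps, 1 - eps))
    caliper = caliper_sd * float(np.std(logit, ddof=1))
    treated_idx = list(np.flatnonzero(y.values == 1))
    control_idx = list(np.flatnonzero(y.values == 0))
    rng = np.random.default_rng(seed)
    rng.shuffle(treated_idx)
    available = set(control_idx)
    pairs = []
    for t in treated_idx:
        if not available:
            break
        cands = sorted(available, key=lambda c: abs(logit[c] - logit[t]))
        best = cands[0]
        if abs(logit[best] - logit[t]) <= caliper:
            pairs.append((int(t), int(best)))
            available.discard(best)
    t_ret = pd.Index(sorted(p[0] for p in pairs))
    c_ret = pd.Index(sorted(p[1] for p in pairs))
    rows = []
    for name in covariates:
        cat = name in categorical
        rows.append({**_balance_row(
            name, df.loc[y == 1, name].values, df.loc[y == 0, name].values, cat
        ), "stage": "before"})
        if pairs:
            rows.append({**_balance_row(
                name, df.loc[t_ret, name].values, df.loc[c_ret, name].values, cat
            ), "stage": "after"})
    return MatchResult(
        pairs=pairs,
        propensity=pd.Series(ps, index=df.index, name="propensity"),
        balance=pd.DataFrame(rows),
        treated_retained=t_ret,
        control_retained=c_ret,
    )


# ---------------------------------------------------------------------------
# correlation structure and two-group tests


def correlation_cluster(df: pd.DataFrame, alpha: float = 0.05,
                        method: str = "bh_off"):
    """Spearman correlation matrix, significance mask and average-linkage order.

    Returns ``(R, mask, order)`` where ``mask[i, j]`` is True when the
    pairwise p-value is >= alpha (non-significant); clustering runs on the
    distance 1 - |R| with average linkage.  Constant columns are excluded
    from the analysis and reported via the DataFrame's column order.
    """
    if df.shape[1] < 3:
        raise ValueError("need at least 3 variables")
    keep = [c for c in df.columns if df[c].nunique(dropna=True) > 1]
    dropped = [c for c in df.columns if c not in keep]
    data = df[keep]
    if data.dropna().shape[0] < 5:
        raise ValueError("need >= 5 pairwise-complete observations")
    k = len(keep)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = data.iloc[:, [i, j]].dropna()
            r, p = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    if method == "bh":
        iu = np.triu_indices(k, 1)
        padj = stats.false_discovery_control(P[iu])
        Padj = P.copy()
        Padj[iu] = padj
        Padj.T[iu] = padj
        P = Padj
    mask = P >= alpha
    np.fill_diagonal(mask, False)
    D = 1.0 - np.abs(R)
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    order = [keep[i] for i in leaves_list(Z)]
    Rdf = pd.DataFrame(R, index=keep, columns=keep)
    maskdf = pd.DataFrame(mask, index=keep, columns=keep)
    return Rdf, maskdf, order + dropped


def two_group_tests(a, b, kind: str = "continuous"):
    """Two-group comparison: Wilcoxon rank-sum (normal approximation, mid-rank
    ties) for continuous data; Yates-corrected chi-square for categorical.

    For categorical data pass per-subject category labels (a 2xK table is
    formed internally).  Returns ``(statistic, p_value)``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        stat, p = stats.mannwhitneyu(
            a.astype(float), b.astype(float),
            alternative="two-sided", method="asymptotic",
        )
        return float(stat), float(p)
    if kind == "categorical":
        cats = sorted(set(a.tolist()) | set(b.tolist()))
        tab = np.array([
            [np.sum(a == c) for c in cats],
            [np.sum(b == c) for c in cats],
        ])
        stat, p, _, _ = stats.chi2_contingency(tab, correction=True)
        return float(stat), float(p)
    raise ValueError("kind must be 'continuous' or 'categorical'")
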