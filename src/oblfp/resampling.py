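"""Permutation ANOVA, factorial interaction tests, and classical two-sample tests.

Permutation p-values use the add-one rule ``p = (1 + #{F* >= F}) / (1 + B)``
so p is never 0 and remains valid under exchangeability; exhaustive
enumeration is available for small two-group designs, where the p-value is
the exact fraction of label assignments at least as extreme as the observed
one.  All permutation methods are deterministic given a seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "StatResult",
    "permutation_anova",
    "interaction_anova",
    "chi2_proportions",
    "two_sample_test",
]


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    n_perm: int = 0  # 0 for analytic tests
    seed: int | None = None
    group_sizes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_perm": int(self.n_perm),
            "seed": None if self.seed is None else int(self.seed),
            "group_sizes": [int(v) for v in self.group_sizes],
        }


def _one_way_f(values: np.ndarray, edges: np.ndarray) -> float:
    """One-way ANOVA F for values split at ``edges`` (concatenated groups)."""
    n = values.size
    k = edges.size - 1
    grand = values.mean()
    ssb = 0.0
    for j in range(k):
        g = values[edges[j] : edges[j + 1]]
        ssb += g.size * (g.mean() - grand) ** 2
    sst = ((values - grand) ** 2).sum()
    ssw = sst - ssb
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def _f_many(perm_values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Vectorized one-way F for a [B, N] matrix of permuted values."""
    n = perm_values.shape[1]
    k = edges.size - 1
    grand = perm_values.mean(axis=1)
    ssb = np.zeros(perm_values.shape[0])
    for j in range(k):
        g = perm_values[:, edges[j] : edges[j + 1]]
        ssb += g.shape[1] * (g.mean(axis=1) - grand) ** 2
    sst = ((perm_values - grand[:, None]) ** 2).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f[np.isnan(f)] = 0.0
    return f


def permutation_anova(
    groups,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive: bool = False,
    _chunk: int = 2000,
) -> StatResult:
    """Non-parametric one-way ANOVA by random label shuffles.

    ``exhaustive=True`` (two groups only) enumerates every assignment of
    observations to group labels and reports the exact fraction with
    ``F* >= F_obs``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    values = np.concatenate(groups)
    sizes = np.array([g.size for g in groups])
    edges = np.concatenate([[0], np.cumsum(sizes)])
    if np.ptp(values) == 0:
        return StatResult("perm_anova", 0.0, 1.0, 0, seed, tuple(sizes))
    f_obs = _one_way_f(values, edges)

    if exhaustive:
        if len(groups) != 2:
            raise ValueError("exhaustive enumeration supports exactly 2 groups")
        n, n1 = values.size, sizes[0]
        total = 0
        extreme = 0
        idx = np.arange(n)
        for combo in itertools.combinations(idx, n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            perm = np.concatenate([values[sel], values[~sel]])
            total += 1
            if _one_way_f(perm, edges) >= f_obs - 1e-12:
                extreme += 1
        return StatResult(
            "perm_anova", f_obs, extreme / total, total, None, tuple(sizes)
        )

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_perm:
        b = min(_chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(values, (b, values.size)), axis=1)
        count += int((_f_many(perm, edges) >= f_obs - 1e-12).sum())
        done += b
    p = (1 + count) / (1 + n_perm)
    return StatResult("perm_anova", f_obs, p, n_perm, seed, tuple(sizes))


def _interaction_f(df: pd.DataFrame) -> tuple[float, float]:
    model = ols("value ~ C(genotype) * C(laser)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(genotype):C(laser)"]
    return float(row["F"]), float(row["PR(>F)"])


def interaction_anova(
    values,
    genotype,
    laser,
    n_perm: int = 0,
    seed: int | None = None,
) -> StatResult:
    """Two-way fixed-effects ANOVA interaction term (genotype x laser).

    Analytic by default.  With ``n_perm > 0`` the residuals of the additive
    (main-effects-only) model are shuffled, giving a permutation p for the
    interaction under the additive null.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": np.asarray(genotype, dtype=object),
            "laser": np.asarray(laser, dtype=object),
        }
    )
    cells = df.groupby(["genotype", "laser"]).size()
    if len(cells) < 4:
        raise ValueError("all four genotype x laser cells must be non-empty")
    sizes = tuple(int(v) for v in cells)
    if np.ptp(df["value"].to_numpy()) == 0:
        warnings.warn("all values identical; interaction undefined, p = 1")
        return StatResult("interaction_anova", 0.0, 1.0, 0, seed, sizes)
    f_obs, p_analytic = _interaction_f(df)
    if not np.isfinite(f_obs):
        warnings.warn("degenerate design; interaction F undefined, p = 1")
        return StatResult("interaction_anova", 0.0, 1.0, 0, seed, sizes)
    if n_perm <= 0:
        return StatResult("interaction_anova", f_obs, p_analytic, 0, seed, sizes)

    additive = ols("value ~ C(genotype) + C(laser)", data=df).fit()
    fitted = additive.fittedvalues.to_numpy()
    resid = additive.resid.to_numpy()
    rng = np.random.default_rng(seed)
    count = 0
    perm_df = df.copy()
    for _ in range(n_perm):
        perm_df["value"] = fitted + rng.permutation(resid)
        f_perm, _ = _interaction_f(perm_df)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return StatResult("interaction_anova", f_obs, p, n_perm, seed, sizes)


def chi2_proportions(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> StatResult:
    """Pearson chi-squared comparison of two proportions (df = 1)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        # degenerate margin: proportions identical by construction
        return StatResult("chi2_prop", 0.0, 1.0, 0, None, (n1, n2))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return StatResult("chi2_prop", float(chi2), float(p), 0, None, (n1, n2))


def two_sample_test(a, b, method: str = "ranksum") -> StatResult:
    """Wilcoxon rank-sum (normal approximation, tie-corrected) or paired t."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return StatResult("ranksum", float(res.statistic), float(res.pvalue), 0, None, (a.size, b.size))
    if method == "paired_t":
        if a.size != b.size:
            raise ValueError("paired_t requires equal-length samples")
        if np.allclose(a, b):
            return StatResult("paired_t", 0.0, 1.0, 0, None, (a.size, b.size))
        res = stats.ttest_rel(a, b)
        return StatResult("paired_t", float(res.statistic), float(res.pvalue), 0, None, (a.size, b.size))
    raise ValueError(f"unknown method {method!r}")
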