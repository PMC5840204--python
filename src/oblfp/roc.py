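"""Recentered ROC classification of Δ power, z-test significance, and FDR.

The discriminability of two trial classes (S+/S−, Hit/CR, FA/CR) by a
per-trial score is summarized by the area under the empirical ROC curve
*recentered* to ``[−0.5, 0.5]``: 0 means the score carries no information
about the class, ±0.5 perfect separation in either direction.  The centered
area equals ``P(score_pos > score_neg) + 0.5 P(tie) − 0.5`` and is computed
from midranks, so ties get half credit.

Significance of a single auROC uses a two-sided z-test with the
Hanley–McNeil variance of the (uncentered) area; families of electrodes are
corrected with the Benjamini–Hochberg step-up, reported as the largest
p-value declared significant (pFDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocResult",
    "FdrResult",
    "auroc_centered",
    "auroc_significance",
    "fdr_correct",
    "dprime_normalize",
    "auroc_table",
    "percent_significant",
]

CONTRASTS = {
    "splus_sminus": ("valence", "Splus", "Sminus"),
    "hit_cr": ("outcome", "Hit", "CR"),
    "fa_cr": ("outcome", "FA", "CR"),
}


@dataclass
class RocResult:
    auroc: float  # centered, in [-0.5, 0.5]
    p_value: float
    n_pos: int
    n_neg: int
    curve: np.ndarray = field(repr=False)  # columns (fpr, tpr)
    label_pair: str = ""


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auroc_centered(scores_pos, scores_neg, label_pair: str = "") -> RocResult:
    """Centered auROC with ROC curve points and z-test p-value.

    Antisymmetric under swapping the two classes; invariant under any
    strictly monotone transform of the scores.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    n_pos, n_neg = scores_pos.size, scores_neg.size
    ranks = stats.rankdata(np.concatenate([scores_pos, scores_neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    # center before dividing: U and n_pos*n_neg - U are exact in rank
    # arithmetic, so auroc(A,B) == -auroc(B,A) holds exactly
    centered = (u - n_pos * n_neg / 2.0) / (n_pos * n_neg)
    a = centered + 0.5
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    fpr, tpr, _ = _sk_roc_curve(labels, np.concatenate([scores_pos, scores_neg]))
    result = RocResult(
        auroc=float(centered),
        p_value=np.nan,
        n_pos=int(n_pos),
        n_neg=int(n_neg),
        curve=np.column_stack([fpr, tpr]),
        label_pair=label_pair,
    )
    result.p_value = auroc_significance(result)
    return result


def auroc_significance(result: RocResult) -> float:
    """Two-sided p for auROC != 0 (z-test, Hanley–McNeil standard error)."""
    if result.n_pos < 2 or result.n_neg < 2:
        raise ValueError("z-test needs at least 2 scores per class")
    a = result.auroc + 0.5
    if result.auroc == 0.0:
        return 1.0
    se = _hanley_mcneil_se(a, result.n_pos, result.n_neg)
    if se == 0.0:
        # perfect separation: z diverges
        return 0.0
    z = (a - 0.5) / se
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class FdrResult:
    q: float
    p_fdr: float  # largest p declared significant (0 if none)
    significant: np.ndarray
    m: int


def fdr_correct(p_values, q: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up over one family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresholds
    if not passed.any():
        return FdrResult(q=q, p_fdr=0.0, significant=np.zeros(m, dtype=bool), m=m)
    k = int(np.max(np.nonzero(passed)[0]))
    p_fdr = float(p[order][k])
    return FdrResult(q=q, p_fdr=p_fdr, significant=p <= p_fdr, m=m)


def dprime_normalize(values_by_class: dict) -> dict:
    """Normalize Δ power to d′ by the unweighted mean of per-class SDs.

    Scale-invariant: multiplying every Δ power by a positive constant leaves
    the d′ table unchanged.
    """
    sds = []
    for cls, vals in values_by_class.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"class {cls!r} needs >= 2 values")
        sds.append(vals.std(ddof=1))
    mean_sd = float(np.mean(sds))
    if mean_sd == 0.0:
        raise ValueError("zero pooled standard deviation")
    return {
        cls: np.asarray(vals, dtype=float) / mean_sd
        for cls, vals in values_by_class.items()
    }


def auroc_table(
    delta_df: pd.DataFrame,
    contrast: str = "splus_sminus",
    group_cols=("electrode", "band"),
) -> pd.DataFrame:
    """Centered auROC per group (default: per electrode x band).

    ``delta_df`` is the long-format Δ power table; ``contrast`` picks the
    positive/negative trial classes.  Rows with NaN Δ power (excluded
    trials) are dropped; groups missing a class are skipped with a warning.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; options: {sorted(CONTRASTS)}")
    col, pos_label, neg_label = CONTRASTS[contrast]
    df = delta_df.dropna(subset=["delta_db"])
    rows = []
    for keys, grp in df.groupby(list(group_cols)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        pos = grp.loc[grp[col] == pos_label, "delta_db"].to_numpy()
        neg = grp.loc[grp[col] == neg_label, "delta_db"].to_numpy()
        if pos.size < 2 or neg.size < 2:
            warnings.warn(
                f"group {keys}: fewer than 2 trials in a class for {contrast}; skipped"
            )
            continue
        res = auroc_centered(pos, neg, label_pair=contrast)
        rows.append(
            dict(zip(group_cols, keys))
            | {
                "auroc": res.auroc,
                "p_value": res.p_value,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
                "contrast": contrast,
            }
        )
    return pd.DataFrame(rows)


def percent_significant(
    auroc_df: pd.DataFrame,
    q: float = 0.05,
    family_cols=("band",),
) -> pd.DataFrame:
    """Percent of auROCs significantly different from zero, per FDR family.

    Each family (default: all electrodes of one band) is corrected
    separately; counts are retained for chi-squared comparisons between
    conditions.
    """
    rows = []
    for keys, grp in auroc_df.groupby(list(family_cols)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        fdr = fdr_correct(grp["p_value"].to_numpy(), q=q)
        k = int(fdr.significant.sum())
        n = int(fdr.m)
        rows.append(
            dict(zip(family_cols, keys))
            | {
                "n_significant": k,
                "n_total": n,
                "percent_significant": 100.0 * k / n,
                "p_fdr": fdr.p_fdr,
                "q": q,
            }
        )
    return pd.DataFrame(rows)
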