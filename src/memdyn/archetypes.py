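"""Quintile-stratified archetype analysis of feature–process relationships.

Observations are stratified into quintiles of a process (Cell Speed or
CMD), and each feature's distribution is compared between quintiles 1 vs 3,
3 vs 5 and 1 vs 5 with the two-sided Wilcoxon rank-sum test under a
Bonferroni correction (3 tests × 150 features = 450 comparisons per
process; adjusted P < 0.001 is significant). The pattern of which of the
three comparisons reach significance places each feature in one of seven
archetype categories (the segments of a three-set Venn diagram) or "none":

* all three significant — fully progressive (near-linear over the range)
* 1v5 only — slow but progressive change
* 1v3 & 1v5 — early change then plateau
* 3v5 & 1v5 — plateau then late change
* 1v3 only / 3v5 only — weak local change (hint of non-monotonicity)
* 1v3 & 3v5 (without 1v5) — explicitly non-monotonic

Direction signs (sign of the median difference per pair) are reported
separately, since the archetype shape abstracts over sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QUINTILE_PAIRS",
    "CATEGORY_NAMES",
    "assign_quintiles",
    "wilcoxon_ranksum",
    "archetype_classify",
    "venn_counts",
]

QUINTILE_PAIRS = ((1, 3), (3, 5), (1, 5))

#: category name per (sig 1v3, sig 3v5, sig 1v5) triple
CATEGORY_NAMES = {
    (True, True, True): "all-three",
    (False, False, True): "1v5-only",
    (True, False, True): "plateau-early",  # early change, then flat
    (False, True, True): "plateau-late",  # flat, then late change
    (True, False, False): "1v3-only",
    (False, True, False): "3v5-only",
    (True, True, False): "non-monotone",
    (False, False, False): "none",
}


def assign_quintiles(values: np.ndarray) -> np.ndarray:
    """Rank-based assignment into five equal-count groups (1 = lowest 20%).

    Ties are broken by stable original order so group sizes differ by at
    most one even with duplicated values.
    """
    x = np.asarray(values, float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations for quintiles")
    if np.nanmin(x) == np.nanmax(x):
        raise ValueError("all values identical: quintiles undefined")
    order = np.argsort(x, kind="stable")
    labels = np.empty(len(x), dtype=int)
    labels[order] = np.floor(np.arange(len(x)) * 5 / len(x)).astype(int) + 1
    return labels


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    ``method='auto'`` uses exact enumeration for tie-free samples of at
    most 10 per group and the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class ArchetypeResult:
    """Per-feature testing outcomes for one process stratification."""

    process: str
    per_feature: pd.DataFrame  # p/adjusted-p per pair, signs, triple, category
    family: int
    alpha: float

    @property
    def n_significant(self) -> int:
        """Features with at least one significant pairwise comparison."""
        return int((self.per_feature["category"] != "none").sum())


def archetype_classify(
    table: pd.DataFrame,
    process: str,
    features: list[str] | None = None,
    alpha: float = 0.001,
    family: int | None = None,
    quintiles: np.ndarray | None = None,
) -> ArchetypeResult:
    """Classify each feature's relationship structure to one process.

    ``process`` names the stratifying column (``cell_speed`` or ``cmd``).
    The Bonferroni family defaults to 3 × (number of features), i.e. one
    family of 450 per process for the full 150-feature set; pass ``family``
    explicitly to share a joint family across both processes instead.
    Quintile boundaries are computed on valid observations only, pooled
    across cells.
    """
    if features is None:
        from .ingest import feature_columns

        features = feature_columns(table)
    valid = table["valid"].to_numpy(bool) if "valid" in table else np.ones(len(table), bool)
    t = table[valid]
    if quintiles is None:
        quintiles = assign_quintiles(t[process].to_numpy(float))
    if family is None:
        family = len(QUINTILE_PAIRS) * len(features)

    groups = {q: quintiles == q for q in (1, 3, 5)}
    rows = []
    for feat in features:
        x = t[feat].to_numpy(float)
        rec: dict[str, object] = {"feature": feat}
        triple = []
        for lo, hi in QUINTILE_PAIRS:
            a = x[groups[lo]]
            b = x[groups[hi]]
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            tag = f"{lo}v{hi}"
            if len(a) == 0 or len(b) == 0:
                p = np.nan
            else:
                p = wilcoxon_ranksum(a, b)
            adj = min(1.0, p * family) if np.isfinite(p) else np.nan
            sig = bool(np.isfinite(adj) and adj < alpha)
            rec[f"p_{tag}"] = p
            rec[f"p_adj_{tag}"] = adj
            rec[f"sig_{tag}"] = sig
            rec[f"sign_{tag}"] = int(np.sign(np.median(b) - np.median(a))) if len(a) and len(b) else 0
            triple.append(sig)
        rec["category"] = CATEGORY_NAMES[tuple(triple)]
        rows.append(rec)
    return ArchetypeResult(
        process=process,
        per_feature=pd.DataFrame(rows).set_index("feature"),
        family=family,
        alpha=alpha,
    )


def venn_counts(result: ArchetypeResult) -> dict[str, int]:
    """Feature counts per archetype category, including 'none'."""
    counts = result.per_feature["category"].value_counts().to_dict()
    return {name: int(counts.get(name, 0)) for name in CATEGORY_NAMES.values()}
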