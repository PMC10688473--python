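"""Class-wise feature enrichment statistics.

Binary (or binned) features are tested for enrichment in one variant
class against a background — either all remaining classes or one specific
other class (e.g. GOF against LOF with neutral variants excluded) — with
the two-sided Fisher exact test.  Odds ratios are ad/bc from the 2x2
table; when a zero cell would force 0 or infinity, the Haldane-Anscombe
+0.5 correction is applied and flagged.  Families of p-values are
corrected by the Benjamini-Hochberg step-up procedure at alpha 0.05.
Continuous features are compared with one-sided Welch two-sample t-tests
in a caller-specified direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentRow",
    "fisher_enrichment",
    "bh_adjust",
    "continuous_compare",
    "enrichment_table",
]


@dataclass
class EnrichmentRow:
    feature: str
    cls: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log_odds: float
    p: float
    haldane: bool = False
    or_undefined: bool = False
    p_adjusted: float | None = None
    significant: bool | None = None


def fisher_enrichment(
    binary_feature,
    class_labels,
    target_class: str,
    background: str = "rest",
    other_class: str | None = None,
    feature_name: str = "feature",
) -> EnrichmentRow:
    """Fisher exact enrichment of a binary feature in one class.

    ``background='rest'`` contrasts the target class with all other
    samples; ``background='other_class'`` restricts the contrast to
    ``other_class`` (remaining classes excluded).  The 2x2 table rows are
    (target, background) and columns (feature present, absent).
    """
    feat = np.asarray(binary_feature, dtype=bool)
    labels = np.asarray(class_labels)
    if background == "rest":
        bg_mask = labels != target_class
    elif background == "other_class":
        if other_class is None:
            raise ValueError("other_class required when background='other_class'")
        bg_mask = labels == other_class
    else:
        raise ValueError("background must be 'rest' or 'other_class'")
    tg_mask = labels == target_class

    a = int((feat & tg_mask).sum())
    b = int((~feat & tg_mask).sum())
    c = int((feat & bg_mask).sum())
    d = int((~feat & bg_mask).sum())
    table = ((a, b), (c, d))

    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return EnrichmentRow(
            feature_name, target_class, table, np.nan, np.nan, 1.0,
            or_undefined=True,
        )

    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = False
    if a == 0 or b == 0 or c == 0 or d == 0:
        haldane = True
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentRow(
        feature_name, target_class, table, float(odds), float(np.log(odds)),
        float(p), haldane=haldane,
    )


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags.

    Adjusted p_i = min over j >= rank(i) of m * p_(j) / j, capped at 1;
    rejection when the adjusted value is below ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted < alpha


def continuous_compare(
    values_a, values_b, direction: str = "greater"
) -> tuple[float, float]:
    """One-sided Welch two-sample t-test.

    ``direction='greater'`` tests mean(a) > mean(b).  Returns (t, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least two values per group required")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.statistic), float(res.pvalue)


def enrichment_table(
    binary_features: pd.DataFrame,
    class_labels,
    target_class: str,
    background: str = "rest",
    other_class: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every binary feature column, BH-corrected at ``alpha``."""
    rows = [
        fisher_enrichment(
            binary_features[col], class_labels, target_class,
            background, other_class, feature_name=col,
        )
        for col in binary_features.columns
    ]
    adjusted, reject = bh_adjust([r.p for r in rows], alpha)
    for row, adj, rej in zip(rows, adjusted, reject):
        row.p_adjusted = float(adj)
        row.significant = bool(rej)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "class": [r.cls for r in rows],
            "a": [r.table[0][0] for r in rows],
            "b": [r.table[0][1] for r in rows],
            "c": [r.table[1][0] for r in rows],
            "d": [r.table[1][1] for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "log_odds": [r.log_odds for r in rows],
            "p": [r.p for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "significant": [r.significant for r in rows],
            "haldane": [r.haldane for r in rows],
            "or_undefined": [r.or_undefined for r in rows],
        }
    )
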