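"""End-point trait comparison, seed shape descriptors and derived
allocation statistics.

End-point traits (one value per plant/seed) are compared with a fixed-
effects model with genotype as the only factor, all-pairwise Tukey HSD at
alpha = 0.05 and a compact letter display ('a' assigned to the largest
mean first, letters shared only by groups that do not differ
significantly).  The allocation statistics express fitted organ sizes per
gram of seed (e.g. primary root length per gram) and the efficiency of
cotyledon reserve remobilization (final seedling dry weight over initial
cotyledon dry weight).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "EndpointSummary",
    "endpoint_compare",
    "compact_letter_display",
    "circularity",
    "allocation_per_gram",
    "remobilization_efficiency",
    "round_half_up",
]


@dataclass
class EndpointSummary:
    """Per-line means with Tukey letters and the overall F-test p-value."""

    table: pd.DataFrame   # columns: line, mean, se, letter
    p_value: float
    tukey: pd.DataFrame   # pairwise comparisons (group1, group2, p_adj, ...)

    def letters(self) -> dict:
        return dict(zip(self.table["line"], self.table["letter"]))


def compact_letter_display(groups: Sequence[str], means: Mapping[str, float],
                           significant: set) -> dict:
    """Insert-and-absorb letter assignment.

    ``significant`` holds frozensets {g1, g2} of pairs that differ.  Groups
    sharing a letter are never a significant pair; non-significant pairs
    share at least one letter.  Letters are ordered by descending mean.
    """
    order = sorted(groups, key=lambda g: -means[g])
    columns = [set(order)]
    for pair in sorted(significant, key=lambda p: tuple(sorted(p))):
        g1, g2 = sorted(pair)
        new_cols = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.extend([col - {g1}, col - {g2}])
            else:
                new_cols.append(col)
        # absorb columns contained in another
        columns = [c for c in new_cols
                   if not any(c < other for other in new_cols)]
        seen = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    # letter order follows the best mean within each column
    columns.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in order}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def endpoint_compare(values_by_line: Mapping[str, Sequence[float]],
                     alpha: float = 0.05,
                     pooled: bool = True) -> EndpointSummary:
    """Fixed-effects comparison of line means with Tukey HSD letters.

    With ``pooled`` (the default) standard errors use the pooled residual
    variance, which reproduces the identical-SE pattern of a balanced
    homoscedastic design; otherwise each line's own sample variance is
    used (letters still come from the pooled Tukey procedure).
    """
    lines = list(values_by_line)
    if len(lines) < 2:
        raise ValueError("need >= 2 lines to compare")
    arrays = {l: np.asarray(values_by_line[l], dtype=float) for l in lines}
    for l, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"line {l!r} has < 2 replicates")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"line {l!r} has non-finite values")

    endog = np.concatenate([arrays[l] for l in lines])
    groups = np.concatenate([np.full(arrays[l].size, l, dtype=object)
                             for l in lines])

    # one-way fixed-effects F test
    grand = endog.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2
                     for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(lines) - 1
    df_w = endog.size - len(lines)
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0:
        p_value = 0.0 if ss_between > 0 else 1.0
    else:
        from scipy import stats
        f = (ss_between / df_b) / (ss_within / df_w)
        p_value = float(stats.f.sf(f, df_b, df_w))

    hsd = pairwise_tukeyhsd(endog, groups, alpha=alpha)
    tukey = pd.DataFrame(hsd.summary().data[1:],
                         columns=[str(c) for c in hsd.summary().data[0]])
    significant = {
        frozenset((g1, g2))
        for g1, g2, rej in zip(hsd.groupsunique[hsd._multicomp.pairindices[0]],
                               hsd.groupsunique[hsd._multicomp.pairindices[1]],
                               hsd.reject)
        if rej}

    means = {l: float(arrays[l].mean()) for l in lines}
    mse = ss_within / df_w
    if pooled:
        se = {l: math.sqrt(mse / arrays[l].size) for l in lines}
    else:
        se = {l: float(arrays[l].std(ddof=1) / math.sqrt(arrays[l].size))
              for l in lines}
    letters = compact_letter_display(lines, means, significant)
    table = pd.DataFrame({
        "line": lines,
        "mean": [means[l] for l in lines],
        "se": [se[l] for l in lines],
        "letter": [letters[l] for l in lines],
    })
    return EndpointSummary(table=table, p_value=p_value, tukey=tukey)


def circularity(area: float, perimeter: float) -> float:
    """Shape descriptor 4 pi A / P^2: 1 for a circle, -> 0 when elongated."""
    if not (perimeter > 0 and area > 0):
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter ** 2


def allocation_per_gram(asymptote: float, seed_weight: float) -> float:
    """Fitted organ size (e.g. root length, cm) per gram of seed."""
    if seed_weight <= 0:
        raise ValueError("seed weight must be positive")
    if asymptote < 0:
        raise ValueError("asymptote must be non-negative")
    return asymptote / seed_weight


def remobilization_efficiency(seedling_wf: float,
                              cotyledon_max: float) -> float:
    """Final seedling dry weight over initial cotyledon dry weight."""
    if cotyledon_max <= 0:
        raise ValueError("initial cotyledon dry weight must be positive")
    if seedling_wf <= 0:
        raise ValueError("seedling dry weight must be positive")
    return seedling_wf / cotyledon_max


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties away from zero, matching printed-table rounding."""
    factor = 10.0 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
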