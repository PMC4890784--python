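"""One-way ANOVA with Tukey HSD post-hoc comparisons.

Implements the classical fixed-effects decomposition explicitly (sums of
squares) and Tukey's honestly-significant-difference procedure with the
Tukey-Kramer adjustment for unbalanced groups.  Quantiles of the
studentized-range distribution come from scipy; confidence intervals are
family-wise at 1 - alpha, so an interval excluding zero coincides with an
adjusted p below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

GroupedMeasurements = Mapping[str, Sequence[float]]


def _validate(data: GroupedMeasurements, min_per_group: int = 1) -> dict[str, np.ndarray]:
    if len(data) < 2:
        raise ConfigurationError("need at least 2 groups")
    groups = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < min_per_group:
            raise ConfigurationError(
                f"group {name!r} has {arr.size} values, needs >= {min_per_group}")
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"group {name!r} contains non-finite values")
        groups[name] = arr
    return groups


def one_way_anova(data: GroupedMeasurements) -> tuple[float, float, tuple[int, int]]:
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, p, (df_between, df_within))``.  Identical groups (zero
    between-group variation) give F = 0, p = 1; zero within-group variance
    with non-zero between variance gives F = inf, p = 0.
    """
    groups = _validate(data)
    all_values = np.concatenate(list(groups.values()))
    grand_mean = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand_mean) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    if df_within <= 0:
        raise ConfigurationError("no residual degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else np.inf
    else:
        f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p, (df_between, df_within)


@dataclass
class TukeyResult:
    """All pairwise comparisons with family-wise 95% (1 - alpha) intervals."""

    anova_f: float
    anova_p: float
    df_within: int
    ms_within: float
    alpha: float
    q_critical: float
    pairs: pd.DataFrame          # group1, group2, difference, lower, upper, p_adj
    degenerate: bool = False     # all data identical (MS_within == 0)

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["p_adj"] < self.alpha]


def tukey_hsd(data: GroupedMeasurements, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD over all group pairs (Tukey-Kramer under imbalance).

    Differences are group2 - group1 in sorted group order.  With MS_within
    of exactly zero (all observations identical) the result is flagged
    degenerate: differences are zero with zero-width intervals.
    """
    groups = _validate(data, min_per_group=2)
    f_stat, p_val, (_, df_within) = one_way_anova(data)
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / df_within
    k = len(groups)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_within))

    degenerate = ms_within == 0
    rows = []
    for name1, name2 in combinations(sorted(groups), 2):
        g1, g2 = groups[name1], groups[name2]
        diff = g2.mean() - g1.mean()
        se = np.sqrt(ms_within / 2 * (1 / len(g1) + 1 / len(g2)))
        if degenerate:
            lower = upper = diff
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            half_width = q_crit * se
            lower, upper = diff - half_width, diff + half_width
            q_stat = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_stat, k, df_within))
        rows.append((name1, name2, diff, lower, upper, p_adj))
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "difference",
                                        "lower", "upper", "p_adj"])
    return TukeyResult(anova_f=f_stat, anova_p=p_val, df_within=df_within,
                       ms_within=float(ms_within), alpha=alpha,
                       q_critical=q_crit, pairs=pairs, degenerate=degenerate)


def significance_letters(result: TukeyResult, reference: str | None = None,
                         ) -> dict[str, str]:
    """Compact letter display.

    With ``reference`` set (e.g. the control genotype), groups differing
    significantly from it are lettered "a" and the rest "" — the annotation
    style used for the report tables.  Without a reference, groups are merged
    into letter classes by non-significance (greedy insert-and-absorb).
    """
    names = sorted(set(result.pairs["group1"]) | set(result.pairs["group2"]))
    sig = {}
    for row in result.pairs.itertuples():
        sig[frozenset((row.group1, row.group2))] = row.p_adj < result.alpha
    if reference is not None:
        return {n: ("a" if n != reference and sig.get(frozenset((n, reference)), False)
                    else "") for n in names}
    classes: list[set[str]] = []
    for name in names:
        placed = False
        for cls in classes:
            if all(not sig.get(frozenset((name, other)), False) for other in cls):
                cls.add(name)
                placed = True
        if not placed:
            classes.append({name})
    letters = {n: "" for n in names}
    for i, cls in enumerate(classes):
        for n in sorted(cls):
            letters[n] += chr(ord("a") + i)
    return letters


def familywise_error_rate(n_groups: int, n_per_group: int, n_datasets: int,
                          alpha: float, rng: np.random.Generator) -> float:
    """Monte-Carlo family-wise type-I error of the Tukey procedure under the
    global null (all groups share one normal distribution).

    Vectorised over datasets but uses the identical critical value and test
    statistic as :func:`tukey_hsd` (asserted in the test suite), so this
    measures the implementation, not a reimplementation.
    """
    df_within = n_groups * (n_per_group - 1)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, n_groups, df_within))
    data = rng.standard_normal((n_datasets, n_groups, n_per_group))
    means = data.mean(axis=2)
    ss_within = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
    ms_within = ss_within / df_within
    se = np.sqrt(ms_within / n_per_group)  # balanced: MS/2 * (1/n + 1/n)
    spread = means.max(axis=1) - means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_max = np.where(se > 0, spread / se, 0.0)
    return float(np.mean(q_max > q_crit))
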