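"""Group comparisons: thin wrappers over scipy.stats.

The slice-level metrics (transmission %, mean I/O, IrS_AMP, ...) are
compared between conditions with the field's routine tests: paired/unpaired
two-tailed t-tests, the Wilcoxon matched-pairs signed-rank test, and one-way
ANOVA with Dunnett's post hoc test against control.  Significance is defined
at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError

ALPHA = 0.05

TESTS = ("paired_t", "unpaired_t", "wilcoxon_paired", "anova_dunnett")


@dataclass
class GroupComparison:
    """Result of one group-level test."""

    metric: str
    test: str
    group_labels: tuple[str, ...]
    statistic: float
    p_value: float
    significant: bool
    posthoc_p: dict[str, float] = field(default_factory=dict)


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float] | None = None,
                   groups: Sequence[Sequence[float]] | None = None,
                   test: str = "paired_t", metric: str = "",
                   labels: Sequence[str] | None = None) -> GroupComparison:
    """Run the requested test; two-sample tests take ``values_a``/``values_b``,
    ``anova_dunnett`` takes ``groups`` with the control group first.
    """
    if test not in TESTS:
        raise ParameterError(f"unknown test {test!r}; choose from {TESTS}")

    if test == "anova_dunnett":
        if groups is None:
            groups = [values_a] + ([values_b] if values_b is not None else [])
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if len(arrays) < 3:
            raise ParameterError("anova_dunnett needs at least 3 groups")
        if any(a.size < 2 for a in arrays):
            raise ParameterError("each group needs n >= 2")
        stat, p = sps.f_oneway(*arrays)
        dunnett = sps.dunnett(*arrays[1:], control=arrays[0])
        names = tuple(labels) if labels else tuple(
            f"group{i}" for i in range(len(arrays)))
        posthoc = {names[i + 1]: float(pv)
                   for i, pv in enumerate(dunnett.pvalue)}
        return GroupComparison(metric=metric, test=test, group_labels=names,
                               statistic=float(stat), p_value=float(p),
                               significant=bool(p < ALPHA), posthoc_p=posthoc)

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    names = tuple(labels) if labels else ("a", "b")

    if test in ("paired_t", "wilcoxon_paired"):
        if a.size != b.size:
            raise ParameterError(
                f"paired test needs equal lengths, got {a.size} and {b.size}")
        diff = a - b
        if np.all(diff == 0):
            # identical pairs: no evidence of difference
            return GroupComparison(metric=metric, test=test, group_labels=names,
                                   statistic=0.0, p_value=1.0,
                                   significant=False)
        if test == "paired_t" and np.ptp(diff) == 0:
            raise DegenerateDataError(
                "paired differences have zero variance; t-test undefined")
        if test == "paired_t":
            stat, p = sps.ttest_rel(a, b)
        else:
            stat, p = sps.wilcoxon(a, b)
    else:  # unpaired_t
        stat, p = sps.ttest_ind(a, b)

    return GroupComparison(metric=metric, test=test, group_labels=names,
                           statistic=float(stat), p_value=float(p),
                           significant=bool(p < ALPHA))
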