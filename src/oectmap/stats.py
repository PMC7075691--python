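"""Multi-site aggregation and group comparisons.

Group summaries report mean ± SE (standard error of the mean) of estimated
peak concentrations; comparisons use the classical unpaired two-sided
Student t-test with pooled variance (Welch's correction available by
option), significance at alpha = 0.05, no multiple-testing correction by
default.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FitError, ComparisonError
from .pipeline import ReleaseEstimate

__all__ = [
    "GroupSummary",
    "RegionComparison",
    "summarize_sites",
    "dose_response_fit",
    "compare_groups",
    "lesion_effect_table",
    "lesion_pattern_reproduced",
    "comparisons_frame",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean and standard error (nM)."""

    label: str
    n: int
    mean: float
    se: float
    se_defined: bool = True  # False for n = 1, where SE is reported as 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ComparisonError("group must contain at least one value")
        if self.se < 0:
            raise ComparisonError("se must be >= 0")


@dataclass(frozen=True)
class RegionComparison:
    """Two-group Student t-test result."""

    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = ALPHA


def _summary(label: str, values: np.ndarray) -> GroupSummary:
    n = values.size
    if n == 1:
        return GroupSummary(label, 1, float(values[0]), 0.0, se_defined=False)
    sd = float(np.std(values, ddof=1))
    return GroupSummary(label, int(n), float(values.mean()), sd / math.sqrt(n))


def summarize_sites(
    estimates: Iterable[ReleaseEstimate],
    grouping: str | Callable[[ReleaseEstimate], str] = "site_id",
    include_below_lod: bool = True,
) -> list[GroupSummary]:
    """Mean ± SE of estimated concentration per group.

    ``grouping`` is an attribute/meta key name or a callable mapping an
    estimate to its group label.  Below-detection-limit estimates are
    included by default.
    """
    if callable(grouping):
        key = grouping
    else:
        key = lambda e: str(getattr(e, grouping, None) or e.meta.get(grouping))
    groups: dict[str, list[float]] = defaultdict(list)
    for e in estimates:
        if not include_below_lod and e.below_lod:
            continue
        groups[key(e)].append(e.concentration)
    if not groups:
        raise ComparisonError("no estimates to summarize")
    return [_summary(label, np.asarray(vals)) for label, vals in groups.items()]


def dose_response_fit(
    pulse_counts: Sequence[float], amplitudes: Sequence[float]
) -> tuple[float, float, float]:
    """OLS line of evoked amplitude (nM) on stimulation pulse count.

    Returns ``(slope, intercept, r)`` with Pearson r; requires >= 3 points.
    """
    x = np.asarray(pulse_counts, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise FitError("need >= 3 (pulse count, amplitude) pairs")
    if np.ptp(y) == 0:  # linregress leaves r undefined for a constant response
        return 0.0, float(y[0] - 0.0 * x.mean()), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
    alpha: float = ALPHA,
) -> RegionComparison:
    """Two-sided two-sample Student t-test (pooled variance by default).

    Degrees of freedom are ``n_a + n_b - 2`` for the pooled test; pass
    ``welch=True`` for unequal-variance comparison.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ComparisonError("each group needs at least 2 values for a t-test")
    t, p = sps.ttest_ind(av, bv, equal_var=not welch)
    if math.isnan(t):  # both groups constant and identical
        t, p = 0.0, 1.0
    return RegionComparison(
        group_a=_summary(labels[0], av),
        group_b=_summary(labels[1], bv),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def _cell_values(estimates, region: str, stim: str) -> np.ndarray:
    vals = [
        e.concentration
        for e in estimates
        if e.site_id == region and e.meta.get("stim_site") == stim
    ]
    return np.asarray(vals, dtype=float)


def lesion_effect_table(
    pre: Iterable[ReleaseEstimate],
    post: Iterable[ReleaseEstimate],
    regions: Sequence[str],
    stim_sites: Sequence[str],
    alpha: float = ALPHA,
    bonferroni: bool = False,
) -> dict[tuple[str, str], RegionComparison]:
    """Pre- versus post-lesion comparison for every (region, stim site) cell.

    Comparisons are unpaired (different trials) and uncorrected by default,
    matching per-comparison significance reporting; ``bonferroni=True``
    divides alpha by the number of cells.  Raises if any cell is missing
    from either condition.
    """
    pre = list(pre)
    post = list(post)
    if bonferroni:
        alpha = alpha / (len(regions) * len(stim_sites))
    out: dict[tuple[str, str], RegionComparison] = {}
    for region in regions:
        for stim in stim_sites:
            a = _cell_values(pre, region, stim)
            b = _cell_values(post, region, stim)
            if a.size < 2 or b.size < 2:
                raise ComparisonError(
                    f"missing or underpopulated cell ({region}, {stim}) in pre/post data"
                )
            out[(region, stim)] = compare_groups(
                a, b, labels=(f"{region}/{stim}/pre", f"{region}/{stim}/post"), alpha=alpha
            )
    return out


def lesion_pattern_reproduced(
    table: dict[tuple[str, str], RegionComparison],
    affected: Sequence[tuple[str, str]] = (
        ("nac", "vta"),
        ("nac", "snc"),
        ("cpu_lower", "vta"),
        ("cpu_lower", "snc"),
    ),
    unaffected: Sequence[tuple[str, str]] = (("cpu_upper", "vta"), ("cpu_upper", "snc")),
) -> bool:
    """Whether the qualitative lesion signature holds.

    Affected cells must show a significant *decrease* (post < pre);
    unaffected cells must show no significant decrease.  The contrast is
    directional because the lesion hypothesis is attenuation of release.
    """
    for cell in affected:
        cmp = table[cell]
        if not (cmp.significant and cmp.group_b.mean < cmp.group_a.mean):
            return False
    for cell in unaffected:
        cmp = table[cell]
        if cmp.significant and cmp.group_b.mean < cmp.group_a.mean:
            return False
    return True


def comparisons_frame(
    comparisons: Iterable[RegionComparison] | dict,
) -> pd.DataFrame:
    """Tabulate comparisons (one row per test) for delimited-text export."""
    if isinstance(comparisons, dict):
        comparisons = list(comparisons.values())
    rows = [
        {
            "group_a": c.group_a.label,
            "group_b": c.group_b.label,
            "n_a": c.group_a.n,
            "n_b": c.group_b.n,
            "mean_a": c.group_a.mean,
            "mean_b": c.group_b.mean,
            "se_a": c.group_a.se,
            "se_b": c.group_b.se,
            "t": c.t_statistic,
            "p": c.p_value,
            "significant": c.significant,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)
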