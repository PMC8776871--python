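"""Cohort-level statistics: group summaries, two-group tests, prevalences.

The platelet is the unit of analysis throughout: summaries are mean +/- SEM
over platelets, two-group differences use Student's t (pooled variance by
default, Welch optional) or the Mann-Whitney U test, and phenotype
prevalences are binomial fractions with exact Clopper-Pearson confidence
intervals.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import Group, OrganelleClass, PlateletRecord

__all__ = [
    "METRICS",
    "CohortSummary",
    "PrevalenceResult",
    "summarize",
    "compare",
    "compare_samples",
    "prevalence",
    "prevalence_counts",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

_MITO = OrganelleClass.MITOCHONDRION
_ALPHA = OrganelleClass.ALPHA_GRANULE
_DENSE = OrganelleClass.DENSE_GRANULE

#: metric name -> extractor(PlateletRecord) -> float (NaN = undefined for
#: that platelet, e.g. mean mitochondrial area of a platelet without
#: mitochondria; NaN values are excluded from that metric's summary)
METRICS: dict[str, Callable[[PlateletRecord], float]] = {
    "platelet_area": lambda r: r.platelet_area_1e5nm2,
    "alpha_count": lambda r: float(r.count(_ALPHA)),
    "dense_count": lambda r: float(r.count(_DENSE)),
    "mito_count": lambda r: float(r.count(_MITO)),
    "alpha_avg_area": lambda r: r.avg_area(_ALPHA),
    "dense_avg_area": lambda r: r.avg_area(_DENSE),
    "mito_avg_area": lambda r: r.avg_area(_MITO),
    "alpha_area_fraction": lambda r: r.area_fraction(_ALPHA),
    "dense_area_fraction": lambda r: r.area_fraction(_DENSE),
    "mito_area_fraction": lambda r: r.area_fraction(_MITO),
    "n_abnormal_mito": lambda r: float(r.n_abnormal_mito),
}

_DEFAULT_METRICS = (
    "platelet_area", "alpha_count", "alpha_avg_area",
    "dense_count", "dense_avg_area", "mito_count", "mito_avg_area",
)

_DEFAULT_COMPARISONS = (
    (Group.UNIRRADIATED_WT, Group.AML),
    (Group.UNIRRADIATED_WT, Group.CONTROL_3WK),
    (Group.UNIRRADIATED_WT, Group.PRE_AML),
    (Group.CONTROL_1WK, Group.PRE_AML),
)


def _extractor(metric) -> tuple[str, Callable[[PlateletRecord], float]]:
    if callable(metric):
        return getattr(metric, "__name__", "metric"), metric
    if metric not in METRICS:
        raise KeyError(
            f"unknown metric {metric!r}; known metrics: {sorted(METRICS)}"
        )
    return metric, METRICS[metric]


def _group_values(
    records: Iterable[PlateletRecord], metric
) -> dict[Group, np.ndarray]:
    _, fn = _extractor(metric)
    out: dict[Group, list[float]] = {}
    for r in records:
        v = fn(r)
        if not math.isnan(v):
            out.setdefault(r.group, []).append(v)
    return {g: np.asarray(v, dtype=float) for g, v in out.items()}


def summarize(
    records: Iterable[PlateletRecord],
    metric,
    groups: Sequence[Group] | None = None,
) -> pd.DataFrame:
    """Per-group n, mean and SEM of one metric over platelets.

    Groups with no defined value are omitted with a warning (never reported
    as NaN); single-platelet groups report SEM 0 with ``degenerate_n`` set.
    """
    name, _ = _extractor(metric)
    values = _group_values(records, metric)
    groups = list(groups) if groups is not None else list(values)
    rows = []
    for g in groups:
        v = values.get(Group(g), np.empty(0))
        if v.size == 0:
            logger.warning("metric %s: group %s has no values; omitted", name, g)
            continue
        sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append(dict(
            group=Group(g).value, metric=name, n=int(v.size),
            mean=float(v.mean()), sem=sem, degenerate_n=v.size < 2,
        ))
    return pd.DataFrame(rows, columns=["group", "metric", "n", "mean", "sem",
                                       "degenerate_n"])


def compare_samples(
    a: np.ndarray,
    b: np.ndarray,
    test: str = "student_t",
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample test on raw values.

    ``student_t`` uses pooled variance unless ``welch``; ``mann_whitney``
    uses SciPy's automatic choice of the exact distribution (small samples
    without ties) or the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if test == "student_t":
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            return 0.0, 1.0
        res = sps.ttest_ind(a, b, equal_var=not welch)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def compare(
    records: Iterable[PlateletRecord],
    group_a: Group | str,
    group_b: Group | str,
    metric,
    test: str = "student_t",
    welch: bool = False,
) -> tuple[float, float]:
    """(statistic, two-sided p-value) comparing one metric between groups."""
    values = _group_values(records, metric)
    ga, gb = Group(group_a), Group(group_b)
    for g in (ga, gb):
        if g not in values or values[g].size == 0:
            raise ValueError(f"group {g.value} has no values for this metric")
    return compare_samples(values[ga], values[gb], test=test, welch=welch)


@dataclass
class PrevalenceResult:
    """A binomial fraction with its exact 95% (or 1-alpha) CI."""

    count: int
    n: int
    fraction: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def prevalence_counts(count: int, n: int, alpha: float = 0.05) -> PrevalenceResult:
    """Clopper-Pearson exact binomial interval for ``count`` successes of ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, {n}], got {count}")
    lo = 0.0 if count == 0 else float(sps.beta.ppf(alpha / 2, count, n - count + 1))
    hi = 1.0 if count == n else float(sps.beta.ppf(1 - alpha / 2, count + 1, n - count))
    return PrevalenceResult(count=count, n=n, fraction=count / n,
                            ci_low=lo, ci_high=hi, alpha=alpha)


def prevalence(
    records: Iterable[PlateletRecord],
    predicate: Callable[[PlateletRecord], bool],
    alpha: float = 0.05,
) -> PrevalenceResult:
    """Fraction of platelets satisfying a predicate, with exact binomial CI."""
    records = list(records)
    count = sum(1 for r in records if predicate(r))
    return prevalence_counts(count, len(records), alpha=alpha)


@dataclass
class CohortSummary:
    """Per-group summaries, two-group tests and phenotype prevalences."""

    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    prevalences: pd.DataFrame


def cohort_summary(
    records: Sequence[PlateletRecord],
    metrics: Sequence[str] = _DEFAULT_METRICS,
    comparisons: Sequence[tuple[Group, Group]] = _DEFAULT_COMPARISONS,
    tests: Sequence[str] = ("student_t", "mann_whitney"),
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> CohortSummary:
    """The full cohort bookkeeping table set.

    Prevalences reported: abnormal-mitochondrion platelets per group, ghost
    platelets in the AML group, tubule-structure platelets in the WT group.
    ``bh_adjust`` adds a Benjamini-Hochberg adjusted p-value column (off by
    default, matching the per-comparison reporting convention).
    """
    records = list(records)
    present = {r.group for r in records}
    summaries = pd.concat(
        [summarize(records, m) for m in metrics], ignore_index=True
    )

    comp_rows = []
    for m in metrics:
        values = _group_values(records, m)
        for ga, gb in comparisons:
            if ga not in values or gb not in values:
                continue
            for test in tests:
                stat, p = compare_samples(values[ga], values[gb], test=test)
                comp_rows.append(dict(
                    metric=m, group_a=ga.value, group_b=gb.value,
                    test=test, statistic=stat, p_value=p,
                ))
    comps = pd.DataFrame(comp_rows, columns=["metric", "group_a", "group_b",
                                             "test", "statistic", "p_value"])
    if bh_adjust and len(comps):
        from statsmodels.stats.multitest import multipletests
        comps["p_adj_bh"] = multipletests(comps["p_value"], method="fdr_bh")[1]

    prev_rows = []

    def add_prev(name, group, pred):
        if Group(group) not in present:
            return
        res = prevalence([r for r in records if r.group == Group(group)],
                         pred, alpha=alpha)
        prev_rows.append(dict(
            phenotype=name, group=Group(group).value, count=res.count,
            n=res.n, fraction=res.fraction,
            ci_low=res.ci_low, ci_high=res.ci_high,
        ))

    for g in (Group.UNIRRADIATED_WT, Group.CONTROL_1WK, Group.CONTROL_3WK,
              Group.PRE_AML, Group.AML):
        add_prev("abnormal_mito", g, lambda r: r.n_abnormal_mito > 0)
    add_prev("ghost", Group.AML, lambda r: r.is_ghost)
    add_prev("tubule_structure", Group.UNIRRADIATED_WT, lambda r: r.has_ts)

    prevs = pd.DataFrame(prev_rows, columns=["phenotype", "group", "count",
                                             "n", "fraction", "ci_low",
                                             "ci_high"])
    return CohortSummary(summaries=summaries, comparisons=comps,
                         prevalences=prevs)
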