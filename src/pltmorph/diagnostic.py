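"""Screening design for a rare platelet phenotype.

A phenotype present in a fraction ``p`` of a subject's platelets is
detected by imaging ``n`` independently sampled cells with probability

    P(detect) = 1 - (1 - p)**n,

so with the observed pre-leukemic prevalence p = 17/72 (23.6%), sampling
12 cells already gives a ~96% chance of catching at least one abnormal
cell.  Conversely, when the phenotype is never seen among ``N`` cells from
healthy subjects, the exact one-sided binomial (Clopper-Pearson) upper
bound on the per-cell false-positive rate at level ``alpha`` is

    1 - alpha**(1/N),

about 2.8% for N = 106 at alpha = 0.05 (the familiar rule of three, 3/N,
is the large-N approximation).  Cells are assumed sampled independently
from a well-mixed platelet population.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

from .stats import PrevalenceResult, prevalence_counts

__all__ = [
    "DetectionDesign",
    "detection_probability",
    "min_sample_size",
    "fp_upper_bound",
    "rule_of_three",
    "screening_report",
]


def detection_probability(p: float, n: int) -> float:
    """Probability of >= 1 positive among n cells at per-cell prevalence p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence p must be in [0, 1], got {p}")
    if n < 1 or int(n) != n:
        raise ValueError(f"n must be a positive integer, got {n}")
    return 1.0 - (1.0 - p) ** int(n)


def min_sample_size(p: float, target: float) -> int:
    """Smallest n with detection_probability(p, n) >= target.

    Closed form ceil(log(1-target)/log(1-p)), then verified by direct
    evaluation at n and n-1 to guard against floating-point edge cases.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"need 0 < p < 1 for a finite design, got p={p}")
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    n = max(1, math.ceil(math.log1p(-target) / math.log1p(-p)))
    while detection_probability(p, n) < target:
        n += 1
    while n > 1 and detection_probability(p, n - 1) >= target:
        n -= 1
    return n


def fp_upper_bound(n_negatives: int, alpha: float = 0.05) -> float:
    """Exact upper bound on the per-cell false-positive rate with 0 events.

    One-sided Clopper-Pearson at level alpha for 0 positives among
    ``n_negatives`` cells: 1 - alpha**(1/N), the largest rate q with
    (1-q)**N >= alpha.
    """
    if n_negatives < 1 or int(n_negatives) != n_negatives:
        raise ValueError(f"n_negatives must be a positive integer, got {n_negatives}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return 1.0 - alpha ** (1.0 / int(n_negatives))


def rule_of_three(n_negatives: int) -> float:
    """Large-N approximation 3/N to the zero-event 95% upper bound."""
    if n_negatives < 1:
        raise ValueError("n_negatives must be >= 1")
    return 3.0 / n_negatives


@dataclass
class DetectionDesign:
    """A screening design built from observed cohort counts.

    ``p`` is the per-cell phenotype prevalence (point estimate k/n_pre),
    ``n_test`` the number of cells imaged per subject, ``n_negatives`` the
    phenotype-free cells observed across non-malignant subjects.
    """

    p: float
    p_ci_low: float
    p_ci_high: float
    k: int
    n_pre: int
    n_test: int
    detection_probability: float
    detection_at_ci_low: float
    target: float
    min_n_for_target: int | None
    n_negatives: int
    alpha: float
    fp_upper_bound: float
    fp_rule_of_three: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def screening_report(
    k: int,
    n_pre: int,
    n_negatives: int,
    n_test: int = 12,
    alpha: float = 0.05,
    target: float = 0.95,
) -> DetectionDesign:
    """Full screening design from cohort counts.

    ``k`` phenotype-positive cells among ``n_pre`` pre-leukemic cells give
    the prevalence estimate and its exact CI; detection probability is
    evaluated at ``n_test`` cells (and, conservatively, at the CI's lower
    prevalence bound); the zero-event bound comes from ``n_negatives``.
    """
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    ci: PrevalenceResult = prevalence_counts(k, n_pre, alpha=alpha)
    p = ci.fraction
    if p == 0.0:
        import warnings
        warnings.warn(
            "zero observed prevalence: detection probability is 0 at any n",
            stacklevel=2,
        )
    det = detection_probability(p, n_test)
    det_lo = detection_probability(ci.ci_low, n_test)
    min_n = min_sample_size(p, target) if 0.0 < p < 1.0 else None
    return DetectionDesign(
        p=p, p_ci_low=ci.ci_low, p_ci_high=ci.ci_high,
        k=int(k), n_pre=int(n_pre), n_test=int(n_test),
        detection_probability=det, detection_at_ci_low=det_lo,
        target=target, min_n_for_target=min_n,
        n_negatives=int(n_negatives), alpha=alpha,
        fp_upper_bound=fp_upper_bound(n_negatives, alpha),
        fp_rule_of_three=rule_of_three(n_negatives),
    )
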