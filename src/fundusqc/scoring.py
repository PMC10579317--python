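"""Image Quality Comprehensive Score (IQCS), grading, and threshold search.

The IQCS is ``1 - sum_i w_i p_i`` where ``p_i`` is the probability that the
image is "poor" in the i-th quality aspect and the weights sum to one
(equal weights by default: k = 6 aspects for posterior images, k = 3 for
peripheral). Scores live in [0, 1]; higher is better. A threshold pair
(lower, upper) partitions scores into ineligible / eligible / excellent,
and the pair is chosen by an exhaustive grid search maximising three-class
accuracy over lower in {0.05..0.90}, upper in {0.10..0.95}, step 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assessment import AspectProbabilities
from .synthetic import ValidationError, aspects_for

GRADES = ("ineligible", "eligible", "excellent")

# grid bounds expressed in integer ticks of 0.05
_LOWER_TICKS = range(1, 19)   # 0.05 .. 0.90
_UPPER_TICKS = range(2, 20)   # 0.10 .. 0.95


@dataclass(frozen=True)
class IQCSWeights:
    """Nonnegative aspect weights summing to one."""

    w: tuple[float, ...]

    def __post_init__(self):
        arr = np.asarray(self.w, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("weights must be a non-empty vector")
        if (arr < 0).any():
            raise ValidationError("weights must be nonnegative")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {arr.sum()!r}")
        object.__setattr__(self, "w", tuple(float(x) for x in arr))

    @property
    def k(self) -> int:
        return len(self.w)

    @classmethod
    def equal(cls, k: int) -> "IQCSWeights":
        if k <= 0:
            raise ValidationError("k must be positive")
        return cls(tuple([1.0 / k] * k))

    @classmethod
    def for_location(cls, location: str) -> "IQCSWeights":
        return cls.equal(len(aspects_for(location)))


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper IQCS cutoffs: score < lower is ineligible, score >= upper
    is excellent, in between eligible. Boundary scores classify upward."""

    lower: float = 0.2
    upper: float = 0.8

    def __post_init__(self):
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValidationError(
                f"need 0 <= lower < upper <= 1, got ({self.lower}, {self.upper})"
            )


@dataclass
class IQCSResult:
    score: float
    location: str
    grade: str | None = None


@dataclass
class GridSearchResult:
    best: ThresholdPair
    best_accuracy: float
    accuracy_surface: dict[tuple[float, float], float] = field(repr=False,
                                                               default_factory=dict)


def compute_iqcs(probs: AspectProbabilities,
                 weights: IQCSWeights | None = None) -> IQCSResult:
    """Score = 1 - sum(w_i p_i); equal weights by default."""
    p = probs.p_vector
    if weights is None:
        weights = IQCSWeights.equal(len(p))
    if weights.k != len(p):
        raise ValidationError(
            f"{weights.k} weights for {len(p)} aspects"
        )
    score = 1.0 - float(np.dot(weights.w, p))
    # snap float dust at the analytic bounds (e.g. six exact 1/6 weights)
    if abs(score) < 1e-12:
        score = 0.0
    elif abs(score - 1.0) < 1e-12:
        score = 1.0
    return IQCSResult(score=score, location=probs.location)


def classify_grade(score: float, t: ThresholdPair) -> str:
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"score {score} outside [0, 1]")
    if score < t.lower:
        return "ineligible"
    if score < t.upper:
        return "eligible"
    return "excellent"


def grid_search_thresholds(scores, grades) -> GridSearchResult:
    """Exhaustive accuracy-maximising search over the 0.05 threshold grid.

    Ties break to the lexicographically smallest (lower, upper) pair. The
    grid values are generated from integer ticks so every run sees the
    identical float lattice.
    """
    scores = np.asarray(scores, dtype=float)
    grades = np.asarray(grades)
    if scores.size == 0:
        raise ValidationError("empty inputs")
    if scores.shape != grades.shape:
        raise ValidationError("scores and grades must have equal length")
    unknown = set(np.unique(grades)) - set(GRADES)
    if unknown:
        raise ValidationError(f"unknown grades {sorted(unknown)}")
    if ((scores < 0) | (scores > 1)).any():
        raise ValidationError("scores must lie in [0, 1]")

    n = scores.size
    is_inel = grades == "ineligible"
    is_elig = grades == "eligible"
    is_exc = grades == "excellent"

    surface: dict[tuple[float, float], float] = {}
    best_pair: ThresholdPair | None = None
    best_acc = -1.0
    for i in _LOWER_TICKS:
        lower = i / 20.0
        below_lower = scores < lower
        for j in _UPPER_TICKS:
            if j <= i:
                continue
            upper = j / 20.0
            at_least_upper = scores >= upper
            correct = (
                (below_lower & is_inel).sum()
                + (~below_lower & ~at_least_upper & is_elig).sum()
                + (at_least_upper & is_exc).sum()
            )
            acc = correct / n
            surface[(lower, upper)] = acc
            if acc > best_acc:  # strict: earlier (smaller) pairs win ties
                best_acc = acc
                best_pair = ThresholdPair(lower, upper)
    assert best_pair is not None
    return GridSearchResult(best=best_pair, best_accuracy=float(best_acc),
                            accuracy_surface=surface)
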