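"""Threshold selection and evidence intervals from a bounded curve.

Given a calibration curve with one-sided bootstrap bounds, the pathogenic
threshold for a strength with LR+ cutoff ``x`` is the smallest observed
score ``tau`` such that the *lower* bound of lr+(s) is at least ``x`` for
every observed score ``s >= tau`` (a suffix condition); the benign
threshold is the largest score such that the *upper* bound is at most
``1/x`` for every score below it (a prefix condition).  Requiring the whole
tail rather than a single crossing makes the selection robust to local dips
in the bound curve, and using bounds instead of point estimates makes it
deliberately stringent.

The two threshold sets carve the score line into up to nine half-open
intervals: four benign strengths, an indeterminate middle, and four
pathogenic strengths.  Pathogenic intervals are closed on the left
(``[tau, next)``), benign intervals closed on the right (``(prev, tau]``),
and the indeterminate region is open on both sides.  Scores are assigned to
exactly one interval; missing scores are indeterminate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .calibration import CalibrationCurve, ScoreSet
from .evidence import BENIGN, PATHOGENIC, STRENGTHS, EvidenceConfig

__all__ = [
    "INDETERMINATE",
    "ThresholdSet",
    "EvidenceIntervals",
    "select_threshold",
    "build_threshold_sets",
    "build_intervals",
    "assign_strength",
]

logger = logging.getLogger(__name__)

INDETERMINATE = "indeterminate"

#: The nine interval labels in score order (benign very strong first).
INTERVAL_LABELS: tuple[str, ...] = tuple(
    f"benign_{s}" for s in reversed(STRENGTHS)
) + (INDETERMINATE,) + tuple(f"pathogenic_{s}" for s in STRENGTHS)


@dataclass(frozen=True)
class ThresholdSet:
    """Score thresholds per strength for one direction.

    ``thresholds[strength]`` is the score threshold on the normalized
    (higher-is-pathogenic) scale, or ``None`` when the strength was not
    met.  If a strength is not met no stronger strength is met either.
    ``native_thresholds`` carries the same values mapped back to the
    predictor's native scale when a score set was supplied.
    """

    direction: str
    thresholds: Mapping[str, float | None]
    lr_cutoffs: Mapping[str, float]
    native_thresholds: Mapping[str, float | None] | None = None

    def met(self, strength: str) -> bool:
        return self.thresholds.get(strength) is not None

    @property
    def met_strengths(self) -> tuple[str, ...]:
        return tuple(s for s in STRENGTHS if self.met(s))

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "thresholds": dict(self.thresholds),
            "lr_cutoffs": dict(self.lr_cutoffs),
            "native_thresholds": (
                dict(self.native_thresholds) if self.native_thresholds else None
            ),
        }


def select_threshold(
    curve: CalibrationCurve, lr_cutoff: float, direction: str
) -> float | None:
    """Bound-based threshold for one strength cutoff, or None if not met.

    Pathogenic: minimal observed score ``tau`` with the lower LR+ bound at
    or above ``lr_cutoff`` for *all* observed scores ``>= tau``.  Benign:
    maximal observed score with the upper LR+ bound at or below
    ``1 / lr_cutoff`` for all scores ``<= tau``.  Candidate thresholds are
    the curve's observed scores; between them the bound is undefined.
    """
    if len(curve) == 0:
        raise ValueError("empty calibration curve")
    if lr_cutoff <= 0:
        raise ValueError("lr_cutoff must be positive")
    if direction == PATHOGENIC:
        bound = curve.bound_lr("pathogenic")
        suffix_min = np.minimum.accumulate(bound[::-1])[::-1]
        ok = suffix_min >= lr_cutoff
        if not ok.any():
            return None
        return float(curve.scores[int(np.argmax(ok))])
    if direction == BENIGN:
        bound = curve.bound_lr("benign")
        prefix_max = np.maximum.accumulate(bound)
        ok = prefix_max <= 1.0 / lr_cutoff
        if not ok.any():
            return None
        idx = len(ok) - 1 - int(np.argmax(ok[::-1]))
        return float(curve.scores[idx])
    raise ValueError(f"unknown direction {direction!r}")


def build_threshold_sets(
    curve: CalibrationCurve,
    config: EvidenceConfig,
    score_set: ScoreSet | None = None,
) -> tuple[ThresholdSet, ThresholdSet]:
    """Select all eight thresholds and enforce the nesting invariants.

    Pathogenic thresholds must be non-decreasing with strength and benign
    thresholds non-increasing; a strength that is not met censors all
    stronger strengths in its direction.  Violations (possible only with
    ragged bounds) are repaired by clipping toward the weaker threshold,
    with a warning.
    """
    sets: list[ThresholdSet] = []
    for direction in (PATHOGENIC, BENIGN):
        taus: dict[str, float | None] = {}
        cutoffs: dict[str, float] = {}
        for strength in STRENGTHS:
            cutoff = config.pathogenic_lr[strength]
            cutoffs[strength] = (
                cutoff if direction == PATHOGENIC else 1.0 / cutoff
            )
            taus[strength] = select_threshold(curve, cutoff, direction)
        prev: float | None = None
        blocked = False
        for strength in STRENGTHS:
            tau = taus[strength]
            if blocked and tau is not None:
                logger.warning(
                    "%s %s threshold found although a weaker strength was "
                    "unmet; censoring",
                    direction,
                    strength,
                )
                taus[strength] = None
                continue
            if tau is None:
                blocked = True
                continue
            if prev is not None:
                bad = tau < prev if direction == PATHOGENIC else tau > prev
                if bad:
                    logger.warning(
                        "%s %s threshold %.6g out of order with weaker "
                        "threshold %.6g; clipping",
                        direction,
                        strength,
                        tau,
                        prev,
                    )
                    taus[strength] = prev
                    tau = prev
            prev = tau
        native = None
        if score_set is not None:
            native = {
                s: (None if t is None else score_set.to_native(t))
                for s, t in taus.items()
            }
        sets.append(
            ThresholdSet(
                direction=direction,
                thresholds=taus,
                lr_cutoffs=cutoffs,
                native_thresholds=native,
            )
        )
    return sets[0], sets[1]


@dataclass(frozen=True)
class EvidenceIntervals:
    """Partition of the score line into evidence-strength intervals.

    Only met strengths appear in ``pathogenic``/``benign``; the union of
    the resulting intervals plus the indeterminate middle covers the whole
    line.  Assignment convention: a score earns the strongest pathogenic
    strength whose threshold it reaches (``score >= tau``, left-closed) or
    the strongest benign strength whose threshold caps it
    (``score <= tau``, right-closed); otherwise it is indeterminate.
    """

    pathogenic: Mapping[str, float]
    benign: Mapping[str, float]

    def __post_init__(self) -> None:
        p = [self.pathogenic[s] for s in STRENGTHS if s in self.pathogenic]
        if any(b < a for a, b in zip(p, p[1:])):
            raise ValueError("pathogenic thresholds must be non-decreasing")
        b = [self.benign[s] for s in STRENGTHS if s in self.benign]
        if any(y > x for x, y in zip(b, b[1:])):
            raise ValueError("benign thresholds must be non-increasing")
        if self.pathogenic and self.benign:
            if self.benign[min(self.benign, key=_strength_rank)] >= self.pathogenic[
                min(self.pathogenic, key=_strength_rank)
            ]:
                raise ValueError(
                    "benign supporting threshold must lie below the "
                    "pathogenic supporting threshold"
                )

    def assign(self, score: float | None) -> str:
        if score is None or (isinstance(score, float) and math.isnan(score)):
            return INDETERMINATE
        for strength in reversed(STRENGTHS):
            tau = self.pathogenic.get(strength)
            if tau is not None and score >= tau:
                return f"pathogenic_{strength}"
        for strength in reversed(STRENGTHS):
            tau = self.benign.get(strength)
            if tau is not None and score <= tau:
                return f"benign_{strength}"
        return INDETERMINATE

    def assign_many(self, scores) -> np.ndarray:
        """Vectorized assignment; NaN maps to indeterminate."""
        arr = np.asarray(scores, dtype=float)
        out = np.full(arr.shape, INDETERMINATE, dtype=object)
        assigned = np.isnan(arr)
        for strength in reversed(STRENGTHS):
            tau = self.pathogenic.get(strength)
            if tau is not None:
                mask = ~assigned & (arr >= tau)
                out[mask] = f"pathogenic_{strength}"
                assigned |= mask
        for strength in reversed(STRENGTHS):
            tau = self.benign.get(strength)
            if tau is not None:
                mask = ~assigned & (arr <= tau)
                out[mask] = f"benign_{strength}"
                assigned |= mask
        return out

    def bounds(self) -> list[tuple[str, float, float]]:
        """Interval bounds per label as (label, low, high) in score order.

        Pathogenic intervals are ``[low, high)``; benign intervals are
        ``(low, high]``; the indeterminate interval is open on both sides.
        Labels for unmet strengths are omitted.
        """
        out: list[tuple[str, float, float]] = []
        ben = [(s, self.benign[s]) for s in STRENGTHS if s in self.benign]
        prev = -math.inf
        for strength, tau in reversed(ben):  # strongest first
            out.append((f"benign_{strength}", prev, tau))
            prev = tau
        pat = [(s, self.pathogenic[s]) for s in STRENGTHS if s in self.pathogenic]
        indeterminate_hi = pat[0][1] if pat else math.inf
        out.append((INDETERMINATE, prev, indeterminate_hi))
        for i, (strength, tau) in enumerate(pat):
            hi = pat[i + 1][1] if i + 1 < len(pat) else math.inf
            out.append((f"pathogenic_{strength}", tau, hi))
        return out

    def to_dict(self) -> dict:
        return {"pathogenic": dict(self.pathogenic), "benign": dict(self.benign)}


def _strength_rank(strength: str) -> int:
    return STRENGTHS.index(strength)


def build_intervals(
    pathogenic: ThresholdSet, benign: ThresholdSet
) -> EvidenceIntervals:
    """Assemble the interval partition from the two threshold sets."""
    if pathogenic.direction != PATHOGENIC or benign.direction != BENIGN:
        raise ValueError("threshold sets passed in the wrong order")
    return EvidenceIntervals(
        pathogenic={
            s: t for s, t in pathogenic.thresholds.items() if t is not None
        },
        benign={s: t for s, t in benign.thresholds.items() if t is not None},
    )


def assign_strength(score: float | None, intervals: EvidenceIntervals) -> str:
    """Map one score (or None/NaN for missing) to its interval label."""
    return intervals.assign(score)
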