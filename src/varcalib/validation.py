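"""Independent-set validation of evidence intervals.

Once thresholds are selected on a calibration set, two audits are run on
data the selection never saw:

* **Interval likelihood ratios.**  For each evidence interval ``[a, b)``
  the global likelihood ratio restricted to the interval is the ratio of
  the fraction of pathogenic variants falling inside to the fraction of
  benign variants inside.  A pathogenic interval passes when this ratio
  meets or exceeds its strength's LR+ cutoff; a benign interval passes
  when the ratio is at or below the reciprocal cutoff.

* **Population fractions.**  The fraction of a large unlabeled population
  set landing in each interval (missing scores count as indeterminate)
  gauges how often each evidence strength would be invoked in practice —
  pathogenic intervals swallowing a large share of a population set signal
  overprediction.

Also provided: assessment of a fixed (e.g. developer-recommended) score
threshold against the calibrated curve, and a joint rank-space local LR+
estimator for simple multi-tool consensus queries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .calibration import (
    CalibrationCurve,
    CalibrationSettings,
    benign_weight,
    _clean,
)
from .evidence import (
    BENIGN,
    PATHOGENIC,
    STRENGTHS,
    EvidenceConfig,
    lr_from_posterior,
)
from .thresholds import INDETERMINATE, INTERVAL_LABELS, EvidenceIntervals

__all__ = [
    "interval_lr",
    "population_fractions",
    "ValidationReport",
    "validate_intervals",
    "FixedThresholdAssessment",
    "assess_fixed_threshold",
    "consensus_lr",
]


def _in_interval(scores: np.ndarray, lo: float, hi: float, lo_closed: bool, hi_closed: bool):
    above = scores >= lo if lo_closed else scores > lo
    below = scores <= hi if hi_closed else scores < hi
    return above & below


def interval_lr(
    interval: tuple[float, float],
    pathogenic_scores,
    benign_scores,
    lo_closed: bool = True,
    hi_closed: bool = False,
) -> float:
    """Global likelihood ratio restricted to a score interval.

    Ratio of the pathogenic class rate inside the interval to the benign
    class rate inside.  Returns ``inf`` when only pathogenic variants fall
    inside and NaN when the interval is empty of both classes.  Computed
    unweighted (raw class rates), as appropriate for a held-out test set.
    """
    lo, hi = interval
    P = _clean(pathogenic_scores)
    B = _clean(benign_scores)
    if P.size == 0 or B.size == 0:
        raise ValueError("both labeled classes must be non-empty")
    tp = _in_interval(P, lo, hi, lo_closed, hi_closed).mean()
    fp = _in_interval(B, lo, hi, lo_closed, hi_closed).mean()
    if fp == 0.0:
        return math.nan if tp == 0.0 else math.inf
    return float(tp / fp)


def population_fractions(
    intervals: EvidenceIntervals, population_scores
) -> dict[str, float]:
    """Fraction of a population score set falling into each of the 9 bins.

    Missing scores (NaN) contribute to the indeterminate bin.  All nine
    labels are always present; intervals for unmet strengths receive 0.
    The fractions sum to 1.
    """
    arr = np.asarray(population_scores, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("population set must be non-empty")
    labels = intervals.assign_many(arr)
    out = {label: 0.0 for label in INTERVAL_LABELS}
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    for label, count in zip(uniq, counts):
        out[label] = count / arr.size
    return out


@dataclass
class ValidationReport:
    """Per-interval audit results, one row per interval label."""

    frame: pd.DataFrame

    @classmethod
    def build(
        cls,
        intervals: EvidenceIntervals,
        config: EvidenceConfig,
        pathogenic_scores,
        benign_scores,
        population_scores=None,
    ) -> "ValidationReport":
        P = _clean(pathogenic_scores)
        B = _clean(benign_scores)
        pop = (
            np.asarray(population_scores, dtype=float).ravel()
            if population_scores is not None
            else None
        )
        fractions = (
            population_fractions(intervals, pop) if pop is not None else None
        )
        rows = []
        for label, lo, hi in intervals.bounds():
            direction = (
                PATHOGENIC
                if label.startswith("pathogenic")
                else BENIGN if label.startswith("benign") else None
            )
            lo_closed = direction == PATHOGENIC and math.isfinite(lo)
            hi_closed = direction == BENIGN and math.isfinite(hi)
            mask_p = _in_interval(P, lo, hi, lo_closed, hi_closed)
            mask_b = _in_interval(B, lo, hi, lo_closed, hi_closed)
            lr = interval_lr((lo, hi), P, B, lo_closed, hi_closed)
            cutoff = math.nan
            passed: bool | None = None
            if direction is not None:
                strength = label.split("_", 1)[1]
                base = config.pathogenic_lr[strength]
                if direction == PATHOGENIC:
                    cutoff = base
                    passed = bool(lr >= cutoff)
                else:
                    cutoff = 1.0 / base
                    passed = bool(lr <= cutoff)
            rows.append(
                {
                    "label": label,
                    "low": lo,
                    "high": hi,
                    "n_pathogenic": int(mask_p.sum()),
                    "n_benign": int(mask_b.sum()),
                    "interval_lr": lr,
                    "lr_cutoff": cutoff,
                    "passed": passed,
                    "population_fraction": (
                        fractions[label] if fractions is not None else math.nan
                    ),
                }
            )
        frame = pd.DataFrame(rows)
        if fractions is not None:
            # bounds() omits unmet strengths, which hold no population mass;
            # account for them so the fractions column sums to 1.
            missing = set(INTERVAL_LABELS) - set(frame["label"])
            for label in missing:
                assert fractions[label] == 0.0
        return cls(frame)

    def to_json(self, path=None) -> str:
        payload = self.frame.replace({math.inf: "inf", -math.inf: "-inf"}).to_dict(
            orient="records"
        )
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ValidationReport":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("["):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        frame = pd.DataFrame(payload)
        with pd.option_context("future.no_silent_downcasting", True):
            frame = frame.replace(
                {"inf": math.inf, "-inf": -math.inf}
            ).infer_objects(copy=False)
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def validate_intervals(
    intervals: EvidenceIntervals,
    config: EvidenceConfig,
    pathogenic_scores,
    benign_scores,
    population_scores=None,
) -> ValidationReport:
    """Audit intervals on an independent labeled set (and population set)."""
    return ValidationReport.build(
        intervals, config, pathogenic_scores, benign_scores, population_scores
    )


@dataclass(frozen=True)
class FixedThresholdAssessment:
    """Local LR+ at a fixed score threshold, with CI and achieved strength."""

    threshold: float
    lr: float
    lr_ci: tuple[float, float]
    strength: str | None
    population_fraction: float | None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "lr": self.lr,
            "lr_ci": list(self.lr_ci),
            "strength": self.strength,
            "population_fraction": self.population_fraction,
        }


def assess_fixed_threshold(
    curve: CalibrationCurve,
    threshold: float,
    direction: str,
    config: EvidenceConfig,
    population_scores=None,
) -> FixedThresholdAssessment:
    """Grade a fixed (e.g. developer-recommended) threshold on the curve.

    The local LR+ and its bootstrap interval are read off the curve at the
    observed score nearest the threshold; the achieved strength is decided
    on the LR+ *point estimate* against the config cutoffs, and the
    population fraction counts scores at or beyond the threshold
    (inclusive) in the given direction.  The curve's two stored one-sided
    bounds form the reported interval, so for a 95% two-sided interval
    compute the bounds at ``one_sided_alpha = 0.025``.
    """
    if direction not in (PATHOGENIC, BENIGN):
        raise ValueError(f"unknown direction {direction!r}")
    if not curve.scores.min() <= threshold <= curve.scores.max():
        raise ValueError(
            f"threshold {threshold!r} outside the observed score range "
            f"[{curve.scores.min()!r}, {curve.scores.max()!r}]"
        )
    idx = int(np.argmin(np.abs(curve.scores - threshold)))
    lr = float(curve.lr_plus[idx])
    lo = float(curve.bound_lr("pathogenic")[idx])
    hi = float(curve.bound_lr("benign")[idx])
    strength: str | None = None
    for s in STRENGTHS:  # keep the strongest satisfied cutoff
        cutoff = config.pathogenic_lr[s]
        ok = lr >= cutoff if direction == PATHOGENIC else lr <= 1.0 / cutoff
        if ok:
            strength = s
    pop_fraction = None
    if population_scores is not None:
        pop = np.asarray(population_scores, dtype=float).ravel()
        scored = pop[np.isfinite(pop)]
        beyond = scored >= threshold if direction == PATHOGENIC else scored <= threshold
        pop_fraction = float(beyond.sum() / pop.size)
    return FixedThresholdAssessment(
        threshold=float(threshold),
        lr=lr,
        lr_ci=(lo, hi),
        strength=strength,
        population_fraction=pop_fraction,
    )


def consensus_lr(
    score_matrix,
    labels,
    query: Sequence[float],
    settings: CalibrationSettings | None = None,
    prior: float = 0.0441,
    weight: float | None = None,
) -> float:
    """Joint local LR+ of a 2- or 3-tool score vector.

    ``score_matrix`` has one row per variant with complete scores from all
    component tools and ``labels`` marks each row pathogenic (True) or
    benign (False).  Scores are mapped to per-tool ranks (removing scale
    differences), and an axis-aligned hypercube around the query's rank
    vector is expanded until it holds at least ``min_labeled_in_window``
    labeled variants; the weighted posterior of the cube converts to a
    local LR+ exactly as in the univariate estimator.
    """
    settings = settings or CalibrationSettings()
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2 or not 2 <= X.shape[1] <= 3:
        raise ValueError("score_matrix must be (n_variants, 2 or 3)")
    if not np.isfinite(X).all():
        raise ValueError("consensus estimation requires complete scores")
    y = np.asarray(labels, dtype=bool)
    n, d = X.shape
    if n < settings.min_labeled_in_window:
        raise ValueError(
            f"insufficient joint data: {n} complete-score variants < "
            f"min_labeled_in_window ({settings.min_labeled_in_window})"
        )
    q = np.asarray(query, dtype=float)
    if q.shape != (d,):
        raise ValueError("query dimension does not match the score matrix")
    ranks = np.column_stack([rankdata(X[:, j]) / n for j in range(d)])
    q_rank = np.array(
        [np.searchsorted(np.sort(X[:, j]), q[j]) / n for j in range(d)]
    )
    cheb = np.abs(ranks - q_rank).max(axis=1)
    k = min(settings.min_labeled_in_window, n)
    radius = np.partition(cheb, k - 1)[k - 1]
    inside = cheb <= radius + 1e-12
    n_path = int((inside & y).sum())
    n_ben = int((inside & ~y).sum())
    if weight is None:
        weight = settings.weight
    if weight is None:
        weight = benign_weight(int(y.sum()), int((~y).sum()), prior)
    posterior = n_path / (n_path + weight * n_ben)
    return float(lr_from_posterior(posterior, prior))
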