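"""Local posterior-probability / local LR+ curve estimation.

A computational predictor emits a continuous score ``s`` per variant.  To
grade such scores as ACMG/AMP evidence we estimate the *local* positive
likelihood ratio ``lr+(s)`` — the density ratio of pathogenic to benign
score distributions at ``s`` — and, equivalently at a fixed prior, the
local posterior probability of pathogenicity (the local positive predictive
value).

The estimator is a sliding window over sorted unique scores.  At each score
``s`` the half-width ``eps`` is chosen adaptively as the smallest value such
that the window ``[s - eps, s + eps]`` contains at least a minimum number of
labeled (pathogenic + benign) variants and at least a minimum fraction of an
unlabeled population reference set; the requirements are proportionally
scaled down where the window runs past the ends of the observed score range.
Within the window the benign count is multiplied by a weight ``w`` that
re-calibrates the labeled sample's class balance to the configured prior, so
the weighted posterior ``P / (P + w * B)`` is anchored to the prior rather
than to the (pathogenic-enriched) composition of curated databases.

One-sided confidence bounds on the curve are obtained by bootstrap:
labeled variants are resampled with replacement within each class, window
positions and widths are held fixed, and the empirical quantile of the
weighted posterior is taken in the conservative direction for each side
(lower for pathogenic evidence, upper for benign evidence).  Threshold
selection downstream uses these bounds, never the point estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import DEFAULT_PRIOR, lr_from_posterior, prior_odds

__all__ = [
    "HIGHER_IS_PATHOGENIC",
    "LOWER_IS_PATHOGENIC",
    "PATHOGENIC_LABELS",
    "BENIGN_LABELS",
    "ScoreSet",
    "normalize_orientation",
    "CalibrationSettings",
    "CalibrationCurve",
    "benign_weight",
    "window_halfwidth",
    "window_halfwidths",
    "local_posterior_curve",
    "bootstrap_bounds",
    "bootstrap_bound",
    "calibrate",
]

logger = logging.getLogger(__name__)

HIGHER_IS_PATHOGENIC = "higher-is-pathogenic"
LOWER_IS_PATHOGENIC = "lower-is-pathogenic"

#: Clinical labels collapsed into the two calibration classes.
PATHOGENIC_LABELS = frozenset({"P", "LP", "pathogenic", "likely_pathogenic"})
BENIGN_LABELS = frozenset({"B", "LB", "benign", "likely_benign"})


@dataclass
class ScoreSet:
    """Per-variant scores of one predictor, with declared orientation.

    ``scores`` is a Series indexed by variant key; missing scores are NaN.
    After :func:`normalize_orientation` higher always means more pathogenic,
    and ``flipped`` records whether the native scale was negated so that
    thresholds can be reported back on the native scale.
    """

    tool_name: str
    orientation: str
    scores: pd.Series
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER_IS_PATHOGENIC, LOWER_IS_PATHOGENIC):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.scores.index.has_duplicates:
            raise ValueError("each variant key may appear at most once")
        finite = self.scores.dropna()
        if not np.isfinite(finite.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite or missing (NaN)")

    def to_native(self, value):
        """Map a value on the normalized scale back to the native scale."""
        return -value if self.flipped else value


def normalize_orientation(score_set: ScoreSet) -> ScoreSet:
    """Return a score set on the higher-is-pathogenic scale.

    Lower-is-pathogenic scores are negated — an order-reversing monotone
    transform — so the rest of the pipeline can assume that larger scores
    mean stronger evidence of pathogenicity.  The flip is recorded for
    reporting thresholds on the native scale.
    """
    if score_set.orientation == HIGHER_IS_PATHOGENIC:
        return score_set
    return ScoreSet(
        tool_name=score_set.tool_name,
        orientation=HIGHER_IS_PATHOGENIC,
        scores=-score_set.scores,
        flipped=not score_set.flipped,
    )


@dataclass(frozen=True)
class CalibrationSettings:
    """Tuning knobs of the sliding-window estimator and its bootstrap.

    min_labeled_in_window
        Minimum pathogenic + benign variants per window (default 100).
    min_unlabeled_fraction
        Minimum fraction of the unlabeled population set per window
        (default 0.03).
    n_bootstrap
        Bootstrap replicates for the confidence bounds (default 10,000;
        tests and examples use far fewer).
    one_sided_alpha
        Tail probability of each one-sided bound (default 0.05, i.e. a 95%
        one-sided bound).
    weight
        Benign weight w; ``None`` (default) derives it from the class
        counts and the prior via :func:`benign_weight`.
    edge_scaling_rule
        ``"proportional"`` scales the window requirements by the fraction
        of the window inside the observed score range; ``"none"`` keeps
        them fixed.
    """

    min_labeled_in_window: int = 100
    min_unlabeled_fraction: float = 0.03
    n_bootstrap: int = 10_000
    one_sided_alpha: float = 0.05
    weight: float | None = None
    random_seed: int = 0
    edge_scaling_rule: str = "proportional"

    def __post_init__(self) -> None:
        if self.min_labeled_in_window < 1:
            raise ValueError("min_labeled_in_window must be >= 1")
        if not 0.0 <= self.min_unlabeled_fraction <= 1.0:
            raise ValueError("min_unlabeled_fraction must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.one_sided_alpha < 0.5:
            raise ValueError("one_sided_alpha must be in (0, 0.5)")
        if self.weight is not None and self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.edge_scaling_rule not in ("proportional", "none"):
            raise ValueError(f"unknown edge_scaling_rule {self.edge_scaling_rule!r}")


@dataclass
class CalibrationCurve:
    """Local posterior / local LR+ estimates over the unique labeled scores.

    Bounds are on the posterior scale: ``bound_pathogenic`` is the lower
    (conservative toward pathogenicity claims) one-sided bound and
    ``bound_benign`` the upper one.  Pure-pathogenic windows yield posterior
    1 and an ``inf`` LR+ sentinel, never NaN.
    """

    scores: np.ndarray
    epsilon: np.ndarray
    pathogenic_count: np.ndarray
    benign_count: np.ndarray
    weight: float
    prior: float
    posterior: np.ndarray
    lr_plus: np.ndarray
    bound_pathogenic: np.ndarray | None = None
    bound_benign: np.ndarray | None = None

    def __len__(self) -> int:
        return self.scores.size

    def bound_lr(self, side: str) -> np.ndarray:
        """Conservative one-sided bound converted to the LR+ scale."""
        bound = self.bound_pathogenic if side == "pathogenic" else self.bound_benign
        if bound is None:
            raise ValueError(f"{side} bound has not been computed")
        return lr_from_posterior(bound, self.prior)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "score": self.scores,
            "epsilon": self.epsilon,
            "n_pathogenic": self.pathogenic_count,
            "n_benign": self.benign_count,
            "posterior": self.posterior,
            "lr_plus": self.lr_plus,
        }
        if self.bound_pathogenic is not None:
            data["bound_pathogenic"] = self.bound_pathogenic
        if self.bound_benign is not None:
            data["bound_benign"] = self.bound_benign
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, weight: float, prior: float
    ) -> "CalibrationCurve":
        return cls(
            scores=frame["score"].to_numpy(float),
            epsilon=frame["epsilon"].to_numpy(float),
            pathogenic_count=frame["n_pathogenic"].to_numpy(float),
            benign_count=frame["n_benign"].to_numpy(float),
            weight=weight,
            prior=prior,
            posterior=frame["posterior"].to_numpy(float),
            lr_plus=frame["lr_plus"].to_numpy(float),
            bound_pathogenic=(
                frame["bound_pathogenic"].to_numpy(float)
                if "bound_pathogenic" in frame
                else None
            ),
            bound_benign=(
                frame["bound_benign"].to_numpy(float)
                if "bound_benign" in frame
                else None
            ),
        )


def benign_weight(n_path_total: int, n_benign_total: int, prior: float) -> float:
    """Weight applied to benign counts to match the configured prior.

    ``w = (n_path / n_benign) / prior_odds``.  A window whose composition
    matches the full data set then has weighted posterior exactly equal to
    the prior.  The counts are taken over variants with available scores,
    so w varies slightly per tool when scores are missing for some
    variants.
    """
    if n_path_total <= 0 or n_benign_total <= 0:
        raise ValueError("both class counts must be positive")
    return (n_path_total / n_benign_total) / prior_odds(prior)


def _interval_counts(sorted_arr: np.ndarray, lo, hi):
    """Count points of a sorted array inside closed intervals [lo, hi].

    Bounds are widened by a few ulps so points sitting exactly on a window
    edge are counted despite floating-point rounding: ``s + eps`` can land
    up to ~2 ulp below a point whose computed distance to ``s`` is exactly
    ``eps``.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    pad = 4.0 * np.spacing(np.maximum(np.abs(lo), np.abs(hi)))
    return np.searchsorted(sorted_arr, hi + pad, side="right") - np.searchsorted(
        sorted_arr, lo - pad, side="left"
    )


def window_halfwidths(
    points,
    labeled_scores,
    unlabeled_scores,
    settings: CalibrationSettings,
) -> np.ndarray:
    """Adaptive window half-width eps at each evaluation point (vectorized).

    eps is the smallest distance-to-a-data-point d such that
    ``[s - d, s + d]`` holds at least ``min_labeled_in_window`` labeled
    scores and at least ``min_unlabeled_fraction`` of the unlabeled scores,
    with both requirements scaled by the fraction of the window inside the
    observed score range under the proportional edge rule.  Restricting
    candidate widths to observed point distances makes the estimate
    identical to an exhaustive scan while allowing a bisection search.
    """
    s = np.atleast_1d(np.asarray(points, dtype=float))
    L = np.sort(np.asarray(labeled_scores, dtype=float))
    U = np.sort(np.asarray(unlabeled_scores, dtype=float))
    if L.size == 0 or U.size == 0:
        raise ValueError("labeled and unlabeled score arrays must be non-empty")
    lo_r = min(L[0], U[0])
    hi_r = max(L[-1], U[-1])
    req_l = float(settings.min_labeled_in_window)
    req_u = settings.min_unlabeled_fraction * U.size
    proportional = settings.edge_scaling_rule == "proportional"

    def coverage(eps: np.ndarray) -> np.ndarray:
        if not proportional:
            return np.ones_like(eps)
        with np.errstate(divide="ignore", invalid="ignore"):
            overlap = np.minimum(s + eps, hi_r) - np.maximum(s - eps, lo_r)
            cov = np.where(eps > 0, np.clip(overlap, 0.0, None) / (2.0 * eps), 1.0)
        return np.clip(cov, 0.0, 1.0)

    def satisfied(eps: np.ndarray) -> np.ndarray:
        cl = _interval_counts(L, s - eps, s + eps)
        cu = _interval_counts(U, s - eps, s + eps)
        cov = coverage(eps)
        return (cl >= req_l * cov - 1e-9) & (cu >= req_u * cov - 1e-9)

    eps_max = np.maximum(np.maximum(s - lo_r, hi_r - s), hi_r - lo_r)
    eps_max = np.maximum(eps_max, 1.0e-12)
    bad = ~satisfied(eps_max)
    if bad.any():
        i = int(np.argmax(bad))
        e = eps_max[i]
        cl = int(_interval_counts(L, s[i] - e, s[i] + e))
        cu = int(_interval_counts(U, s[i] - e, s[i] + e))
        cov = float(coverage(np.asarray([e]))[0])
        failing = []
        if cl < req_l * cov - 1e-9:
            failing.append(
                f"min_labeled_in_window ({cl} < {req_l * cov:.3g} labeled)"
            )
        if cu < req_u * cov - 1e-9:
            failing.append(
                f"min_unlabeled_fraction ({cu} < {req_u * cov:.3g} unlabeled)"
            )
        raise ValueError(
            f"window requirements unsatisfiable at score {s[i]!r} even over "
            f"the full range: {'; '.join(failing)}"
        )

    ok0 = satisfied(np.zeros_like(s))
    eps_lo = np.zeros_like(s)
    eps_hi = eps_max.copy()
    for _ in range(64):
        mid = 0.5 * (eps_lo + eps_hi)
        ok = satisfied(mid)
        eps_hi = np.where(ok, mid, eps_hi)
        eps_lo = np.where(ok, eps_lo, mid)

    # Snap to the smallest candidate point-distance beyond the bracket.
    cand = np.full_like(s, np.inf)
    for arr in (L, U):
        hi_edge = np.nextafter(s + eps_lo, np.inf)
        idx = np.searchsorted(arr, hi_edge, side="right")
        valid = idx < arr.size
        d_r = np.where(valid, arr[np.minimum(idx, arr.size - 1)] - s, np.inf)
        cand = np.minimum(cand, np.where(valid, d_r, np.inf))
        lo_edge = np.nextafter(s - eps_lo, -np.inf)
        idx2 = np.searchsorted(arr, lo_edge, side="left") - 1
        valid2 = idx2 >= 0
        d_l = np.where(valid2, s - arr[np.maximum(idx2, 0)], np.inf)
        cand = np.minimum(cand, np.where(valid2, d_l, np.inf))
    eps = np.where(ok0, 0.0, np.where(np.isfinite(cand), cand, eps_hi))
    # Pathological float collisions aside, cand >= the true minimum, so the
    # snapped width still satisfies the (monotone) requirements.
    return eps


def window_halfwidth(
    s: float,
    labeled_scores,
    unlabeled_scores,
    settings: CalibrationSettings,
) -> float:
    """Adaptive half-width at a single score (scalar convenience wrapper)."""
    return float(window_halfwidths([s], labeled_scores, unlabeled_scores, settings)[0])


def _clean(scores) -> np.ndarray:
    arr = np.asarray(scores, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def local_posterior_curve(
    pathogenic_scores,
    benign_scores,
    unlabeled_scores,
    settings: CalibrationSettings | None = None,
    prior: float = DEFAULT_PRIOR,
    weight: float | None = None,
) -> CalibrationCurve:
    """Point-estimate curve of the local posterior and local LR+.

    Evaluated at every unique labeled score.  The posterior point estimate
    at score ``s`` is ``P_w / (P_w + w * B_w)`` with pathogenic/benign
    window counts ``P_w``/``B_w`` over ``[s - eps, s + eps]``; the LR+
    estimate follows through Bayes' rule at the given prior.  Missing
    scores must be removed upstream (NaNs are dropped here).
    """
    settings = settings or CalibrationSettings()
    P = np.sort(_clean(pathogenic_scores))
    B = np.sort(_clean(benign_scores))
    U = _clean(unlabeled_scores)
    labeled = np.concatenate([P, B])
    if labeled.size < settings.min_labeled_in_window:
        raise ValueError(
            f"need at least {settings.min_labeled_in_window} labeled scored "
            f"variants, got {labeled.size}"
        )
    scores = np.unique(labeled)
    eps = window_halfwidths(scores, labeled, U, settings)
    lo = scores - eps
    hi = scores + eps
    cp = _interval_counts(P, lo, hi).astype(float)
    cb = _interval_counts(B, lo, hi).astype(float)
    if weight is None:
        weight = settings.weight
    if weight is None:
        weight = benign_weight(P.size, B.size, prior)
    denom = cp + weight * cb
    if np.any(denom <= 0):
        raise RuntimeError("empty window after edge scaling")  # pragma: no cover
    posterior = cp / denom
    lr = lr_from_posterior(posterior, prior)
    return CalibrationCurve(
        scores=scores,
        epsilon=eps,
        pathogenic_count=cp,
        benign_count=cb,
        weight=float(weight),
        prior=float(prior),
        posterior=posterior,
        lr_plus=np.asarray(lr, dtype=float),
    )


def bootstrap_bounds(
    curve: CalibrationCurve,
    pathogenic_scores,
    benign_scores,
    settings: CalibrationSettings,
    sides: Sequence[str] = ("pathogenic", "benign"),
    rng: np.random.Generator | None = None,
) -> CalibrationCurve:
    """Fill one-sided bootstrap confidence bounds on an estimated curve.

    Labeled variants are resampled with replacement within each class
    (stratified, keeping class sizes and the weight fixed); the windows
    ``[s - eps, s + eps]`` are held at their original positions.  Per score
    the empirical ``alpha`` quantile of the weighted posterior is taken for
    the pathogenic side and the ``1 - alpha`` quantile for the benign side.
    Bounds are clipped to the conservative side of the point estimate.
    Deterministic given the settings seed.
    """
    if rng is None:
        rng = np.random.default_rng(settings.random_seed)
    P = np.sort(_clean(pathogenic_scores))
    B = np.sort(_clean(benign_scores))
    lo = curve.scores - curve.epsilon
    hi = curve.scores + curve.epsilon
    n_boot = settings.n_bootstrap
    m = curve.scores.size
    post = np.empty((n_boot, m), dtype=np.float32)
    for i in range(n_boot):
        ps = np.sort(P[rng.integers(0, P.size, P.size)])
        bs = np.sort(B[rng.integers(0, B.size, B.size)])
        cp = _interval_counts(ps, lo, hi).astype(float)
        cb = _interval_counts(bs, lo, hi).astype(float)
        denom = cp + curve.weight * cb
        with np.errstate(invalid="ignore"):
            post[i] = np.where(denom > 0, cp / np.where(denom > 0, denom, 1.0), np.nan)
    quantile = np.nanquantile if np.isnan(post).any() else np.quantile
    out = curve
    if "pathogenic" in sides:
        lower = quantile(post, settings.one_sided_alpha, axis=0)
        out = replace(out, bound_pathogenic=np.minimum(lower, curve.posterior))
    if "benign" in sides:
        upper = quantile(post, 1.0 - settings.one_sided_alpha, axis=0)
        out = replace(out, bound_benign=np.maximum(upper, curve.posterior))
    return out


def bootstrap_bound(
    curve: CalibrationCurve,
    pathogenic_scores,
    benign_scores,
    settings: CalibrationSettings,
    side: str,
) -> CalibrationCurve:
    """One-sided bound for a single side; see :func:`bootstrap_bounds`."""
    if side not in ("pathogenic", "benign"):
        raise ValueError(f"side must be 'pathogenic' or 'benign', got {side!r}")
    return bootstrap_bounds(curve, pathogenic_scores, benign_scores, settings, (side,))


def split_labeled_scores(
    score_set: ScoreSet, labels: Mapping[str, str] | pd.Series
) -> tuple[np.ndarray, np.ndarray, int]:
    """Join labels onto a score set and split into class score arrays.

    Returns (pathogenic scores, benign scores, number of labeled variants
    without a score).  Labels may use raw clinical codes (P/LP/B/LB) or the
    collapsed class names.
    """
    labels = pd.Series(labels)
    path_keys = labels.index[labels.isin(PATHOGENIC_LABELS)]
    ben_keys = labels.index[labels.isin(BENIGN_LABELS)]
    path = score_set.scores.reindex(path_keys)
    ben = score_set.scores.reindex(ben_keys)
    n_missing = int(path.isna().sum() + ben.isna().sum())
    return (
        path.dropna().to_numpy(float),
        ben.dropna().to_numpy(float),
        n_missing,
    )


def calibrate(
    score_set: ScoreSet,
    labels: Mapping[str, str] | pd.Series,
    unlabeled_scores,
    settings: CalibrationSettings | None = None,
    prior: float = DEFAULT_PRIOR,
) -> CalibrationCurve:
    """End-to-end calibration of one predictor.

    Normalizes orientation, joins labels, estimates the local posterior
    curve, and fills both one-sided bootstrap bounds.
    """
    settings = settings or CalibrationSettings()
    ss = normalize_orientation(score_set)
    path, ben, n_missing = split_labeled_scores(ss, labels)
    if n_missing:
        logger.info(
            "%s: %d labeled variants lack scores and are excluded from the curve",
            ss.tool_name,
            n_missing,
        )
    unl = np.asarray(unlabeled_scores, dtype=float).ravel()
    if ss.flipped:
        unl = -unl
    unl = unl[np.isfinite(unl)]
    curve = local_posterior_curve(path, ben, unl, settings, prior)
    return bootstrap_bounds(curve, path, ben, settings)


def run_manifest(
    score_set: ScoreSet,
    curve: CalibrationCurve,
    settings: CalibrationSettings,
    n_unlabeled: int,
) -> dict:
    """JSON-serializable record of a calibration run."""
    return {
        "tool": score_set.tool_name,
        "orientation": score_set.orientation,
        "flipped": score_set.flipped,
        "prior": curve.prior,
        "weight": curve.weight,
        "n_scores": int(len(curve)),
        "n_unlabeled": int(n_unlabeled),
        "settings": {
            "min_labeled_in_window": settings.min_labeled_in_window,
            "min_unlabeled_fraction": settings.min_unlabeled_fraction,
            "n_bootstrap": settings.n_bootstrap,
            "one_sided_alpha": settings.one_sided_alpha,
            "weight": settings.weight,
            "random_seed": settings.random_seed,
            "edge_scaling_rule": settings.edge_scaling_rule,
        },
    }
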