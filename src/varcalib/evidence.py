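"""Odds/posterior algebra of the Bayesian ACMG/AMP evidence framework.

The ACMG/AMP guidelines grade evidence for or against variant pathogenicity
in four strengths: supporting, moderate, strong, and very strong.  In the
Bayesian formulation of the guidelines each strength corresponds to a
positive likelihood ratio (LR+) that rises exponentially: a single very
strong line of evidence carries LR+ = c, and each step down halves the
exponent, so strong is c**(1/2), moderate c**(1/4), and supporting c**(1/8).
Benign evidence of a given strength carries the exact reciprocal likelihood
ratio.  Combining independent lines of evidence multiplies their likelihood
ratios, which in exponential form means adding exponents.

This module implements that algebra:

* prior/posterior odds conversions (`prior_odds`, `posterior_from_lr`,
  `lr_from_posterior`);
* evidence combination (`EvidenceCombination`, `combined_lr`);
* the per-strength cutoff table (`strength_cutoff_table` ->
  `EvidenceConfig`), i.e. the LR+ and posterior-probability cutoffs that a
  computational predictor must reach for each PP3/BP4 strength;
* a grid solver for the scaling constant c given a set of classification
  rule constraints (`solve_c`);
* the points-based equivalents (supporting = 1 point, doubling per
  strength; benign negative) used by the points implementation of the
  guidelines (`points_value`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PATHOGENIC",
    "BENIGN",
    "STRENGTHS",
    "STRENGTH_EXPONENT",
    "DEFAULT_PRIOR",
    "DEFAULT_C",
    "prior_odds",
    "posterior_from_lr",
    "lr_from_posterior",
    "EvidenceCombination",
    "combined_lr",
    "EvidenceConfig",
    "strength_cutoff_table",
    "RuleConstraint",
    "default_rule_constraints",
    "solve_c",
    "points_value",
    "pp3_pm1_within_cap",
]

PATHOGENIC = "pathogenic"
BENIGN = "benign"

#: Evidence strengths ordered weakest to strongest.
STRENGTHS: tuple[str, ...] = ("supporting", "moderate", "strong", "very_strong")

#: Exponent of the scaling constant c contributed by one line of evidence.
STRENGTH_EXPONENT: Mapping[str, float] = {
    "supporting": 1.0 / 8.0,
    "moderate": 1.0 / 4.0,
    "strong": 1.0 / 2.0,
    "very_strong": 1.0,
}

_POINTS: Mapping[str, int] = {
    "supporting": 1,
    "moderate": 2,
    "strong": 4,
    "very_strong": 8,
}

#: Default prior probability that a rare missense variant in a broad
#: population reference set is pathogenic, and the matching scaling constant.
DEFAULT_PRIOR = 0.0441
DEFAULT_C = 1124.0


def _check_prior(prior: float) -> float:
    prior = float(prior)
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior probability must be in (0, 1), got {prior!r}")
    return prior


def _check_direction(direction: str) -> str:
    if direction not in (PATHOGENIC, BENIGN):
        raise ValueError(f"direction must be {PATHOGENIC!r} or {BENIGN!r}, got {direction!r}")
    return direction


def prior_odds(prior_probability: float) -> float:
    """Convert a prior probability of pathogenicity to prior odds p/(1-p)."""
    p = _check_prior(prior_probability)
    return p / (1.0 - p)


def posterior_from_lr(lr, prior: float):
    """Posterior probability of pathogenicity given a likelihood ratio.

    Implements Bayes' rule on the odds scale:
    ``posterior = lr * p / ((lr - 1) * p + 1)``.  Accepts scalars or arrays;
    an infinite likelihood ratio maps to posterior 1.  Strictly increasing
    in both ``lr`` and ``prior``.
    """
    p = _check_prior(prior)
    lr_arr = np.asarray(lr, dtype=float)
    if np.any(lr_arr < 0):
        raise ValueError("likelihood ratio must be non-negative")
    with np.errstate(invalid="ignore"):
        post = np.where(
            np.isinf(lr_arr), 1.0, lr_arr * p / ((lr_arr - 1.0) * p + 1.0)
        )
    if np.isscalar(lr) or np.ndim(lr) == 0:
        return float(post)
    return post


def lr_from_posterior(posterior, prior: float):
    """Inverse of :func:`posterior_from_lr`: posterior odds / prior odds.

    Posterior 1 maps to ``inf``.  Round-trips with :func:`posterior_from_lr`
    to high relative precision.
    """
    p = _check_prior(prior)
    post = np.asarray(posterior, dtype=float)
    if np.any((post < 0) | (post > 1)):
        raise ValueError("posterior must be in [0, 1]")
    po = p / (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.where(post >= 1.0, np.inf, post / (1.0 - post) / po)
    if np.isscalar(posterior) or np.ndim(posterior) == 0:
        return float(lr)
    return lr


@dataclass(frozen=True)
class EvidenceCombination:
    """Counts of applied evidence lines of each strength, with a direction.

    ``n_vs``, ``n_st``, ``n_mo``, ``n_su`` are the numbers of very strong,
    strong, moderate, and supporting lines.  For the benign direction the
    combined likelihood ratio is the reciprocal of the pathogenic one.
    """

    n_vs: int = 0
    n_st: int = 0
    n_mo: int = 0
    n_su: int = 0
    direction: str = PATHOGENIC

    def __post_init__(self) -> None:
        for name in ("n_vs", "n_st", "n_mo", "n_su"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        _check_direction(self.direction)

    @property
    def exponent(self) -> float:
        """Exponent of c contributed by all lines: n_vs + n_st/2 + n_mo/4 + n_su/8."""
        return self.n_vs + self.n_st / 2.0 + self.n_mo / 4.0 + self.n_su / 8.0


def combined_lr(combination: EvidenceCombination, c: float) -> float:
    """Combined likelihood ratio of an evidence combination.

    ``c ** exponent`` for pathogenic evidence and its reciprocal for benign
    evidence.  Multiplicative: concatenating two combinations multiplies
    their likelihood ratios.
    """
    c = float(c)
    if c <= 1.0:
        raise ValueError(f"scaling constant c must be > 1, got {c!r}")
    lr = c ** combination.exponent
    if combination.direction == BENIGN:
        return 1.0 / lr
    return lr


@dataclass(frozen=True)
class EvidenceConfig:
    """Per-strength likelihood-ratio and posterior cutoffs for PP3/BP4.

    ``pathogenic_lr[strength]`` is the minimum local LR+ a score must
    sustain to count as that strength of pathogenic evidence;
    ``benign_lr[strength]`` is its exact reciprocal (the *maximum* LR+ for
    benign evidence).  Posterior cutoffs are expressed as the probability of
    pathogenicity for the pathogenic direction and the probability of
    benignity (1 - pathogenic posterior) for the benign direction.
    """

    prior_probability: float
    scaling_constant_c: float
    strengths: tuple[str, ...] = STRENGTHS
    pathogenic_lr: Mapping[str, float] = field(default_factory=dict)
    pathogenic_posterior: Mapping[str, float] = field(default_factory=dict)
    benign_lr: Mapping[str, float] = field(default_factory=dict)
    benign_posterior: Mapping[str, float] = field(default_factory=dict)

    @property
    def prior_odds(self) -> float:
        return prior_odds(self.prior_probability)

    def lr_cutoff(self, strength: str, direction: str) -> float:
        _check_direction(direction)
        table = self.pathogenic_lr if direction == PATHOGENIC else self.benign_lr
        return table[strength]

    def to_dict(self) -> dict:
        return {
            "prior": self.prior_probability,
            "c": self.scaling_constant_c,
            "strengths": list(self.strengths),
            "pathogenic_lr": dict(self.pathogenic_lr),
            "pathogenic_posterior": dict(self.pathogenic_posterior),
            "benign_lr": dict(self.benign_lr),
            "benign_posterior": dict(self.benign_posterior),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvidenceConfig":
        with open(path) as fh:
            d = json.load(fh)
        return strength_cutoff_table(d["prior"], d["c"])


def strength_cutoff_table(prior: float, c: float) -> EvidenceConfig:
    """Build the full cutoff table for a given prior and scaling constant.

    For each strength the pathogenic LR+ cutoff is ``c ** exponent`` and the
    benign cutoff is its reciprocal; posterior cutoffs follow from Bayes'
    rule at the given prior, with benign posteriors reported as probability
    of benignity.
    """
    p = _check_prior(prior)
    c = float(c)
    if c <= 1.0:
        raise ValueError("scaling constant c must be > 1")
    path_lr: dict[str, float] = {}
    path_post: dict[str, float] = {}
    ben_lr: dict[str, float] = {}
    ben_post: dict[str, float] = {}
    for strength in STRENGTHS:
        lr = c ** STRENGTH_EXPONENT[strength]
        path_lr[strength] = lr
        path_post[strength] = posterior_from_lr(lr, p)
        ben_lr[strength] = 1.0 / lr
        ben_post[strength] = 1.0 - posterior_from_lr(1.0 / lr, p)
    return EvidenceConfig(
        prior_probability=p,
        scaling_constant_c=c,
        pathogenic_lr=path_lr,
        pathogenic_posterior=path_post,
        benign_lr=ben_lr,
        benign_posterior=ben_post,
    )


@dataclass(frozen=True)
class RuleConstraint:
    """A classification rule the evidence model must satisfy.

    The posterior reached by ``combination`` at the candidate scaling
    constant must be at least ``posterior_floor`` (if set) and at most
    ``posterior_ceiling`` (if set).
    """

    combination: EvidenceCombination
    posterior_floor: float | None = None
    posterior_ceiling: float | None = None

    def __post_init__(self) -> None:
        for bound in (self.posterior_floor, self.posterior_ceiling):
            if bound is not None and not 0.0 < bound < 1.0:
                raise ValueError("posterior floor/ceiling must be in (0, 1)")
        if self.posterior_floor is None and self.posterior_ceiling is None:
            raise ValueError("constraint needs a floor or a ceiling")

    def satisfied(self, prior: float, c: float, tol: float = 1e-12) -> bool:
        post = posterior_from_lr(combined_lr(self.combination, c), prior)
        if self.posterior_floor is not None and post < self.posterior_floor - tol:
            return False
        if self.posterior_ceiling is not None and post > self.posterior_ceiling + tol:
            return False
        return True


def default_rule_constraints(
    pathogenic_floor: float = 0.99, likely_pathogenic_floor: float = 0.9
) -> list[RuleConstraint]:
    """Reconstruction of the standard ACMG/AMP combining rules as constraints.

    Each pathogenic combining rule must reach a posterior of at least 0.99
    and each likely-pathogenic rule at least 0.9.  The guidelines publish
    the combining rules but not the exact constraint list used to fix c, so
    this default is a reconstruction from the standard rule tables; the
    shipped cutoff table does not depend on it (c is a configuration
    constant).
    """
    EC = EvidenceCombination
    pathogenic = [
        EC(n_vs=1, n_st=1),
        EC(n_vs=1, n_mo=2),
        EC(n_vs=1, n_mo=1, n_su=1),
        EC(n_vs=1, n_su=2),
        EC(n_st=1, n_mo=3),
        EC(n_st=1, n_mo=2, n_su=2),
        EC(n_st=1, n_mo=1, n_su=4),
    ]
    likely = [
        EC(n_vs=1, n_mo=1),
        EC(n_st=1, n_mo=1),
        EC(n_st=1, n_su=2),
        EC(n_mo=3),
        EC(n_mo=2, n_su=2),
        EC(n_mo=1, n_su=4),
        # Two strong lines are graded pathogenic by the combining tables but
        # are a known discordance of the exponential model, which places
        # them at the likely-pathogenic posterior; constrain them there.
        EC(n_st=2),
    ]
    constraints = [
        RuleConstraint(comb, posterior_floor=pathogenic_floor) for comb in pathogenic
    ]
    constraints += [
        RuleConstraint(comb, posterior_floor=likely_pathogenic_floor) for comb in likely
    ]
    return constraints


def solve_c(
    prior: float,
    constraints: Sequence[RuleConstraint] | None = None,
    search_grid: Iterable[float] | None = None,
) -> float | None:
    """Smallest grid value of c satisfying every rule constraint.

    Returns ``None`` when no grid value is feasible.  The default grid is
    the integers 2..10000.
    """
    p = _check_prior(prior)
    if constraints is None:
        constraints = default_rule_constraints()
    if not constraints:
        raise ValueError("constraint list must be non-empty")
    if search_grid is None:
        search_grid = np.arange(2.0, 10001.0)
    for c in search_grid:
        if all(con.satisfied(p, float(c)) for con in constraints):
            return float(c)
    return None


def points_value(strength: str, direction: str) -> int:
    """Points-scale equivalent of one evidence line (log2 of the LR+ weight).

    Supporting/moderate/strong/very strong map to 1/2/4/8 points, signed
    negative for benign evidence.
    """
    _check_direction(direction)
    if strength not in _POINTS:
        raise ValueError(f"unknown strength {strength!r}")
    pts = _POINTS[strength]
    return -pts if direction == BENIGN else pts


def pp3_pm1_within_cap(pp3_strength: str | None, pm1_points: int, cap: int = 4) -> bool:
    """Check the recommended cap on combined PP3 + PM1 evidence.

    Computational (PP3) and hot-spot/domain (PM1) evidence partially share
    underlying signal; the recommended policy limits their combined weight
    to strong (4 points).
    """
    pp3 = 0 if pp3_strength is None else points_value(pp3_strength, PATHOGENIC)
    return pp3 + pm1_points <= cap
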