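"""Synthetic score and record generators with known ground truth.

Real calibration inputs are per-variant predictor scores for a curated
labeled set and a large unlabeled population set.  The generators here
emulate that structure with parametric class-conditional score
distributions, so every downstream estimate can be checked against the
analytic truth: the local LR+ is the exact density ratio of the two
components, thresholds for any LR+ cutoff have closed-form (root-findable)
values, and the unlabeled set's pathogenic mixing proportion is a known
constant.

The default model uses Beta-distributed classes on [0, 1], mimicking the
bounded, posterior-style outputs of many pathogenicity predictors, with a
class imbalance resembling a curated archive (pathogenic-enriched labeled
sample; ~4% pathogenic mass in the unlabeled population) and a small
missing-score rate.  Equal-variance Gaussian classes are available for
closed-form checks (their log density ratio is linear in the score).

Record-level fixtures for the filter engine are built rule-by-rule: each
record violates exactly one named filter rule (or none), so the expected
survivor set is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calibration import HIGHER_IS_PATHOGENIC, ScoreSet
from .filtering import variant_keys

__all__ = [
    "DistSpec",
    "ScoreModel",
    "TruthBundle",
    "SimulatedScores",
    "simulate_scores",
    "analytic_lr",
    "analytic_threshold",
    "make_record_fixture",
    "FIXTURE_RULES",
]


@dataclass(frozen=True)
class DistSpec:
    """A 1-D score distribution: 'normal' (loc, scale) or 'beta' (a, b)."""

    family: str
    params: tuple[float, ...]

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(*self.params)
        if self.family == "beta":
            return stats.beta(*self.params)
        raise ValueError(f"unknown distribution family {self.family!r}")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    def pdf(self, x) -> np.ndarray:
        return self._frozen().pdf(x)

    def support(self) -> tuple[float, float]:
        return self._frozen().support()


@dataclass(frozen=True)
class ScoreModel:
    """Generative model for one predictor's scores.

    ``alpha`` is the pathogenic mixing proportion of the unlabeled set.
    Defaults emulate a curated-archive labeled sample (≈4k pathogenic vs
    ≈8k benign scored variants), a much larger population sample with ≈4.4%
    pathogenic mass, and a 5% missing-score rate.
    """

    pathogenic: DistSpec = DistSpec("beta", (7.0, 2.0))
    benign: DistSpec = DistSpec("beta", (2.0, 7.0))
    n_pathogenic: int = 4000
    n_benign: int = 7834
    n_unlabeled: int = 100_000
    alpha: float = 0.0441
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if min(self.n_pathogenic, self.n_benign, self.n_unlabeled) < 0:
            raise ValueError("sample sizes must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthBundle:
    """Analytic ground truth attached to a simulated data set."""

    model: ScoreModel
    alpha: float

    def lr(self, s) -> np.ndarray:
        return analytic_lr(self.model, s)

    def threshold(self, lr_cutoff: float) -> float:
        return analytic_threshold(self.model, lr_cutoff)


@dataclass(frozen=True)
class SimulatedScores:
    """Labeled and unlabeled synthetic score tables plus the truth bundle.

    ``labeled`` has columns (variant_key, label, score); ``unlabeled`` has
    (variant_key, score).  Missing scores are NaN.
    """

    labeled: pd.DataFrame
    unlabeled: pd.DataFrame
    truth: TruthBundle

    def score_set(self, tool_name: str = "synthetic") -> ScoreSet:
        return ScoreSet(
            tool_name=tool_name,
            orientation=HIGHER_IS_PATHOGENIC,
            scores=pd.Series(
                self.labeled["score"].to_numpy(),
                index=self.labeled["variant_key"],
            ),
        )

    @property
    def pathogenic_scores(self) -> np.ndarray:
        mask = self.labeled["label"] == "P"
        return self.labeled.loc[mask, "score"].dropna().to_numpy(float)

    @property
    def benign_scores(self) -> np.ndarray:
        mask = self.labeled["label"] == "B"
        return self.labeled.loc[mask, "score"].dropna().to_numpy(float)

    @property
    def unlabeled_scores(self) -> np.ndarray:
        return self.unlabeled["score"].dropna().to_numpy(float)


def simulate_scores(model: ScoreModel) -> SimulatedScores:
    """Draw one synthetic data set; byte-identical for identical seeds."""
    rng = np.random.default_rng(model.seed)
    path = model.pathogenic.rvs(model.n_pathogenic, rng)
    ben = model.benign.rvs(model.n_benign, rng)
    n_path_unl = rng.binomial(model.n_unlabeled, model.alpha)
    unl = np.concatenate(
        [
            model.pathogenic.rvs(n_path_unl, rng),
            model.benign.rvs(model.n_unlabeled - n_path_unl, rng),
        ]
    )
    rng.shuffle(unl)

    def hide(arr: np.ndarray) -> np.ndarray:
        if model.missing_rate == 0.0 or arr.size == 0:
            return arr
        out = arr.astype(float).copy()
        out[rng.random(arr.size) < model.missing_rate] = np.nan
        return out

    labeled = pd.DataFrame(
        {
            "variant_key": [
                f"v{i:07d}" for i in range(model.n_pathogenic + model.n_benign)
            ],
            "label": ["P"] * model.n_pathogenic + ["B"] * model.n_benign,
            "score": hide(np.concatenate([path, ben])),
        }
    )
    unlabeled = pd.DataFrame(
        {
            "variant_key": [f"u{i:07d}" for i in range(model.n_unlabeled)],
            "score": hide(unl),
        }
    )
    return SimulatedScores(
        labeled=labeled,
        unlabeled=unlabeled,
        truth=TruthBundle(model=model, alpha=model.alpha),
    )


def analytic_lr(model: ScoreModel, s) -> np.ndarray:
    """Exact local LR+ of the model: pathogenic density over benign density."""
    x = np.asarray(s, dtype=float)
    num = model.pathogenic.pdf(x)
    den = model.benign.pdf(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        out = np.where((den == 0) & (num == 0), np.nan, out)
    if np.ndim(s) == 0:
        return float(out)
    return out


def _lr_grid(model: ScoreModel, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
    lo_p, hi_p = model.pathogenic.support()
    lo_b, hi_b = model.benign.support()
    lo = max(lo_p, lo_b)
    hi = min(hi_p, hi_b)
    if not np.isfinite(lo):
        lo = min(model.pathogenic._frozen().ppf(1e-6), model.benign._frozen().ppf(1e-6))
    if not np.isfinite(hi):
        hi = max(
            model.pathogenic._frozen().ppf(1 - 1e-6),
            model.benign._frozen().ppf(1 - 1e-6),
        )
    pad = 1e-9 * max(1.0, abs(hi - lo))
    grid = np.linspace(lo + pad, hi - pad, n)
    return grid, analytic_lr(model, grid)


def analytic_threshold(model: ScoreModel, lr_cutoff: float) -> float:
    """Score at which the analytic LR+ equals the cutoff.

    Requires a monotone likelihood ratio (checked on a dense grid); models
    without it (e.g. unequal-variance Gaussians crossing twice) are
    rejected.
    """
    if lr_cutoff <= 0:
        raise ValueError("lr_cutoff must be positive")
    grid, lr = _lr_grid(model)
    finite = np.isfinite(lr)
    g, v = grid[finite], lr[finite]
    if np.any(np.diff(v) < -1e-9 * np.maximum(v[:-1], 1e-12)):
        raise ValueError("model does not have a monotone likelihood ratio")
    logv = np.log(np.clip(v, 1e-300, None))
    target = np.log(lr_cutoff)
    if target <= logv[0] or target >= logv[-1]:
        raise ValueError(
            f"cutoff {lr_cutoff} outside the attainable LR+ range "
            f"[{v[0]:.3g}, {v[-1]:.3g}]"
        )
    idx = int(np.searchsorted(logv, target))
    bracket = (g[max(idx - 1, 0)], g[min(idx, g.size - 1)])
    return float(
        optimize.brentq(
            lambda s: np.log(analytic_lr(model, s)) - target, bracket[0], bracket[1]
        )
    )


def _set_af(rec: dict) -> None:
    rec["af_exomes"] = 0.02


def _set_af_fallback(rec: dict) -> None:
    rec["af_exomes"] = np.nan
    rec["af_genomes"] = 0.005


FIXTURE_RULES: Mapping[str, Callable[[dict], None]] = {
    "clean": lambda rec: None,
    "af": _set_af,
    "af_genomes_fallback_ok": _set_af_fallback,  # survives: fallback AF is rare
    "not_missense": lambda rec: rec.update(consequence="synonymous"),
    "no_pathogenic_gene": lambda rec: rec.update(gene="GENE_NO_PATH"),
    "vus": lambda rec: rec.update(label="VUS"),
    "conflicting": lambda rec: rec.update(label="conflicting"),
    "zero_star": lambda rec: rec.update(stars=0),
    "training": lambda rec: rec.update(_training=True),
    "non_pass": lambda rec: rec.update(filter="RF"),
    "low_gq": lambda rec: rec.update(gq=15.0),
    "low_depth_rare": lambda rec: rec.update(ac=2, dp=25.0),
    "depth_ok_common": lambda rec: rec.update(ac=3, dp=25.0),  # survives
    "segdup": lambda rec: rec.update(segdup=True),
    "lowcomplexity": lambda rec: rec.update(lowcomplexity=True),
    "decoy": lambda rec: rec.update(decoy=True),
    "archive_overlap": lambda rec: rec.update(_archive=True),
}

#: Rules whose records survive despite the mutation (edge-case probes).
_SURVIVING_RULES = frozenset({"clean", "af_genomes_fallback_ok", "depth_ok_common"})


def make_record_fixture(
    spec: Mapping[str, int], seed: int = 0
) -> tuple[pd.DataFrame, set[str], frozenset[str], frozenset[str]]:
    """Variant records violating exactly one named rule each.

    ``spec`` maps rule names (see ``FIXTURE_RULES``) to record counts.
    Returns (records, expected surviving variant keys, training keys,
    archive-overlap keys).  Expected survivors assume a filter mode that
    applies every violated rule; records flagged with rules the chosen
    filter does not implement will survive it too.
    """
    unknown = set(spec) - set(FIXTURE_RULES)
    if unknown:
        raise ValueError(f"unknown fixture rules: {sorted(unknown)}")
    if any(n < 0 for n in spec.values()):
        raise ValueError("rule counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    expected: set[str] = set()
    training: set[str] = set()
    archive: set[str] = set()
    i = 0
    for rule, count in spec.items():
        for _ in range(count):
            i += 1
            pos = int(rng.integers(1_000, 9_000_000))
            rec = {
                "chrom": str(rng.integers(1, 23)),
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "gene": f"GENE{rng.integers(1, 40):03d}",
                "consequence": "missense",
                "label": "P" if i % 2 else "B",
                "stars": 2,
                "af_exomes": 0.001,
                "af_genomes": 0.001,
                "filter": "PASS",
                "gq": 50.0,
                "dp": 40.0,
                "ac": 5,
                "segdup": False,
                "lowcomplexity": False,
                "decoy": False,
                "_training": False,
                "_archive": False,
                "rule": rule,
            }
            FIXTURE_RULES[rule](rec)
            key = f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}"
            if rec.pop("_training"):
                training.add(key)
            if rec.pop("_archive"):
                archive.add(key)
            if rule in _SURVIVING_RULES:
                expected.add(key)
            rows.append(rec)
    records = pd.DataFrame(rows)
    if len(records) and variant_keys(records).duplicated().any():  # pragma: no cover
        return make_record_fixture(spec, seed + 1)
    # every gene used by fixture records harbors a pathogenic variant,
    # except the dedicated no_pathogenic_gene symbol
    return records, expected, frozenset(training), frozenset(archive)


def fixture_filter_config(
    records: pd.DataFrame,
    training_keys: frozenset[str],
    archive_keys: frozenset[str],
) -> "FilterConfig":
    """Filter config matching a record fixture's conventions."""
    from .filtering import FilterConfig

    genes = frozenset(records["gene"]) - {"GENE_NO_PATH"}
    return FilterConfig(
        pathogenic_genes=genes,
        training_keys=training_keys,
        archive_keys=archive_keys,
    )
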