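"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive explicit loops and share no code with the
package's vectorized estimators.
"""

from __future__ import annotations

import math

import numpy as np


def _in_window(x, s, eps):
    """Closed-window membership with edge points included up to float noise.

    Two points at the same decimal distance on opposite sides of ``s`` can
    differ by an ulp in float; window counting treats both as edge points.
    """
    pad = 4.0 * np.spacing(max(abs(s - eps), abs(s + eps), 1e-300))
    return abs(x - s) <= eps + pad


def brute_window_halfwidth(s, labeled, unlabeled, min_labeled, min_frac,
                           edge_scaling=True):
    """Exhaustive scan over candidate half-widths (distances to data points)."""
    labeled = np.asarray(labeled, float)
    unlabeled = np.asarray(unlabeled, float)
    lo_r = min(labeled.min(), unlabeled.min())
    hi_r = max(labeled.max(), unlabeled.max())
    pts = np.concatenate([labeled, unlabeled])
    candidates = sorted(set(abs(x - s) for x in pts) | {0.0})
    req_u = min_frac * unlabeled.size
    for eps in candidates:
        if edge_scaling and eps > 0:
            overlap = min(s + eps, hi_r) - max(s - eps, lo_r)
            cov = min(max(overlap, 0.0) / (2 * eps), 1.0)
        else:
            cov = 1.0
        cl = sum(1 for x in labeled if _in_window(x, s, eps))
        cu = sum(1 for x in unlabeled if _in_window(x, s, eps))
        if cl >= min_labeled * cov - 1e-9 and cu >= req_u * cov - 1e-9:
            return eps
    return None


def brute_curve(path, ben, unl, min_labeled, min_frac, weight,
                edge_scaling=True):
    """Loop-based local posterior curve: (scores, eps, n_path, n_ben, post)."""
    path = np.asarray(path, float)
    ben = np.asarray(ben, float)
    labeled = np.concatenate([path, ben])
    scores = np.unique(labeled)
    eps_list, cp_list, cb_list, post_list = [], [], [], []
    for s in scores:
        eps = brute_window_halfwidth(s, labeled, unl, min_labeled, min_frac,
                                     edge_scaling)
        assert eps is not None
        cp = sum(1 for x in path if _in_window(x, s, eps))
        cb = sum(1 for x in ben if _in_window(x, s, eps))
        eps_list.append(eps)
        cp_list.append(cp)
        cb_list.append(cb)
        post_list.append(cp / (cp + weight * cb))
    return (scores, np.array(eps_list), np.array(cp_list), np.array(cb_list),
            np.array(post_list))


def brute_select_threshold(scores, bound_lr, lr_cutoff, direction):
    """Quantifier-literal threshold selection by checking every suffix/prefix."""
    n = len(scores)
    if direction == "pathogenic":
        for i in range(n):
            if all(bound_lr[j] >= lr_cutoff for j in range(i, n)):
                return scores[i]
        return None
    for i in reversed(range(n)):
        if all(bound_lr[j] <= 1.0 / lr_cutoff for j in range(0, i + 1)):
            return scores[i]
    return None


def brute_filter_labeled(records, pathogenic_genes, training_keys,
                         archive_keys=frozenset(), af_max=0.01):
    """Record-by-record labeled-set filter."""
    kept = []
    for rec in records.to_dict(orient="records"):
        if rec.get("consequence", "missense") != "missense":
            continue
        af = rec.get("af_exomes")
        if af is None or (isinstance(af, float) and math.isnan(af)):
            af = rec.get("af_genomes")
        if af is None or (isinstance(af, float) and math.isnan(af)):
            af = 0.0
        if af >= af_max:
            continue
        if rec["gene"] not in pathogenic_genes:
            continue
        if rec["label"] not in {"P", "LP", "B", "LB"}:
            continue
        if rec.get("stars", 1) <= 0:
            continue
        key = f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}"
        if key in training_keys or key in archive_keys:
            continue
        kept.append(key)
    return kept


def brute_filter_population(records, pathogenic_genes, training_keys,
                            archive_keys=frozenset(), af_max=0.01):
    """Record-by-record population-set filter."""
    kept = []
    seen = set()
    for rec in records.to_dict(orient="records"):
        af = rec.get("af_exomes")
        if af is None or (isinstance(af, float) and math.isnan(af)):
            af = rec.get("af_genomes")
        if af is None or (isinstance(af, float) and math.isnan(af)):
            af = 0.0
        if af >= af_max:
            continue
        if rec["filter"] != "PASS":
            continue
        if rec["gq"] <= 20:
            continue
        if rec["ac"] < 3:
            if rec["dp"] < 30:
                continue
        elif rec["dp"] < 10:
            continue
        if rec["gene"] not in pathogenic_genes:
            continue
        if rec.get("consequence", "missense") != "missense":
            continue
        key = f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}"
        if key in seen:
            continue
        seen.add(key)
        if rec.get("segdup") or rec.get("lowcomplexity") or rec.get("decoy"):
            continue
        if key in training_keys or key in archive_keys:
            continue
        kept.append(key)
    return kept
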