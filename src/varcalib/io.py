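"""Readers and writers for the delimited-table dialects used throughout.

Score tables are TSV with columns ``variant_key`` and ``score`` (blank
scores allowed); label tables pair ``variant_key`` with a clinical label
(P/LP/B/LB plus VUS/conflicting/none in record tables); variant record
tables carry the filter-engine columns.  VCF input is supported for
record tables through cyvcf2 when available.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "read_score_table",
    "write_score_table",
    "read_label_table",
    "read_record_table",
    "read_vcf_records",
    "write_json",
]


def read_score_table(path) -> pd.Series:
    """Score table -> float Series indexed by variant key (NaN = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str})
    if not {"variant_key", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns variant_key, score")
    series = pd.Series(
        df["score"].astype(float).to_numpy(), index=df["variant_key"]
    )
    if series.index.has_duplicates:
        raise ValueError(f"{path}: duplicate variant keys")
    return series


def write_score_table(scores: pd.Series, path) -> None:
    pd.DataFrame(
        {"variant_key": scores.index, "score": scores.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_label_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_key", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns variant_key, label")
    return pd.Series(df["label"].to_numpy(), index=df["variant_key"])


def read_record_table(path) -> pd.DataFrame:
    """Variant records from TSV (or VCF via :func:`read_vcf_records`)."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf_records(path)
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_vcf_records(path) -> pd.DataFrame:
    """Minimal VCF -> record table conversion (INFO fields become columns).

    Pulls the fields the filter engine understands from INFO when present:
    GENE, CSQ-style consequence, AF/AF_genomes, AC, GQ_MEDIAN, DP_MEDIAN,
    CLNSIG-style label, and review stars.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    rows = []
    for var in VCF(str(path)):
        info = dict(var.INFO)
        for alt in var.ALT:
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": alt,
                    "gene": info.get("GENE", info.get("GENEINFO", "")),
                    "consequence": info.get("CSQ", "missense"),
                    "label": info.get("CLNSIG", "none"),
                    "stars": info.get("STARS", 1),
                    "af_exomes": info.get("AF", np.nan),
                    "af_genomes": info.get("AF_genomes", np.nan),
                    "filter": var.FILTER or "PASS",
                    "gq": info.get("GQ_MEDIAN", np.nan),
                    "dp": info.get("DP_MEDIAN", np.nan),
                    "ac": info.get("AC", 0),
                }
            )
    return pd.DataFrame(rows)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
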