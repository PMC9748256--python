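"""Dataset-construction filter engine for variant records.

Calibration and validation sets are assembled from curated archives
(labeled sets) and population sequencing resources (population sets) by a
fixed sequence of filters.  This module applies those rules to tabular
variant records and emits a per-step "waterfall" of surviving counts so a
dataset build is auditable.

Labeled-set rules: keep rare missense variants (allele frequency below a
cap, preferring exome AF with genome AF as fallback) from genes that harbor
at least one pathogenic variant; drop variants of uncertain significance,
zero-star review status, and conflicting classifications; drop variants
present in any predictor's training set (for meta-predictors including
their constituent tools' training sets).

Population-set rules: keep rare variants passing the caller's filters,
with median genotype quality above 20 and an allele-count-conditional
depth requirement (median depth >= 30 when the allele count is below 3,
>= 10 otherwise); restrict to missense variants in genes with a pathogenic
variant; merge exome and genome call sets by variant key; drop variants in
segmental-duplication, low-complexity, and decoy regions (BED exclusion);
drop training-set members and variants overlapping the labeled archive.

Coordinates follow VCF convention (1-based, closed) for records and BED
convention (0-based, half-open) for exclusion regions; any overlap
excludes the record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "FilterConfig",
    "variant_keys",
    "effective_af",
    "read_bed",
    "region_overlap_mask",
    "merge_population_tables",
    "filter_labeled_set",
    "filter_population_set",
]

#: Clinical labels retained in labeled calibration/validation sets.
KEPT_LABELS = frozenset({"P", "LP", "B", "LB"})


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the dataset filters.

    ``pathogenic_genes`` is the set of gene symbols with at least one
    pathogenic variant of any type; when ``None`` it is derived from the
    records' own P/LP labels.  ``training_keys`` are variant keys found in
    any predictor's training data (constituent tools' keys concatenated
    in); ``archive_keys`` are labeled-archive keys removed from population
    sets (and from later labeled releases to keep test sets independent).
    ``training_exclusion_last`` defers training-set removal to the end of
    the pipeline, the ordering used for follow-up labeled releases.
    """

    af_max: float = 0.01
    require_missense: bool = True
    pathogenic_genes: frozenset[str] | None = None
    training_keys: frozenset[str] = frozenset()
    archive_keys: frozenset[str] = frozenset()
    min_gq: float = 20.0
    depth_low_ac: int = 30
    depth_high_ac: int = 10
    ac_switch: int = 3
    training_exclusion_last: bool = False
    missing_field_policy: str = "drop"  # records missing a required field

    @classmethod
    def from_json(cls, path) -> "FilterConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("pathogenic_genes", "training_keys", "archive_keys"):
            if d.get(key) is not None:
                d[key] = frozenset(d[key])
        return cls(**d)


def variant_keys(records: pd.DataFrame) -> pd.Series:
    """Canonical 'chrom:pos:ref:alt' key per record."""
    return (
        records["chrom"].astype(str)
        + ":"
        + records["pos"].astype(int).astype(str)
        + ":"
        + records["ref"].astype(str)
        + ":"
        + records["alt"].astype(str)
    )


def effective_af(records: pd.DataFrame) -> pd.Series:
    """Exomes-first allele frequency with genomes fallback.

    A variant absent from both resources has no frequency evidence against
    rarity and is treated as rare (AF 0).
    """
    af = records.get("af_exomes")
    if af is None:
        af = pd.Series(np.nan, index=records.index)
    af = af.astype(float)
    if "af_genomes" in records:
        af = af.fillna(records["af_genomes"].astype(float))
    return af.fillna(0.0)


def read_bed(path) -> dict[str, IntervalTree]:
    """Load a BED file (0-based, half-open) into per-chromosome trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {line_no}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"malformed BED interval on line {line_no}: {start}-{end}"
                )
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def region_overlap_mask(
    records: pd.DataFrame, trees: Mapping[str, IntervalTree]
) -> pd.Series:
    """True where a record overlaps any excluded region.

    A record at 1-based position ``pos`` with reference allele of length L
    occupies the 0-based half-open interval ``[pos - 1, pos - 1 + L)``.
    """
    out = np.zeros(len(records), dtype=bool)
    chroms = records["chrom"].astype(str).to_numpy()
    pos = records["pos"].astype(int).to_numpy()
    ref_len = records["ref"].astype(str).str.len().to_numpy()
    for i in range(len(records)):
        tree = trees.get(chroms[i])
        if tree is not None and tree.overlaps(pos[i] - 1, pos[i] - 1 + ref_len[i]):
            out[i] = True
    return pd.Series(out, index=records.index)


def merge_population_tables(
    exomes: pd.DataFrame, genomes: pd.DataFrame
) -> pd.DataFrame:
    """Union of exome and genome call sets, deduplicated by variant key."""
    merged = pd.concat([exomes, genomes], ignore_index=True)
    return merged.loc[~variant_keys(merged).duplicated()].reset_index(drop=True)


def _require(records: pd.DataFrame, columns: list[str], config: FilterConfig):
    """Apply the missing-field policy; returns records with usable rows."""
    present = [c for c in columns if c in records.columns]
    missing_cols = set(columns) - set(present)
    if missing_cols:
        raise KeyError(f"records lack required columns: {sorted(missing_cols)}")
    usable = records[present].notna().all(axis=1)
    if not usable.all():
        if config.missing_field_policy == "error":
            raise ValueError("records with missing required fields")
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d records with missing required fields", (~usable).sum()
        )
    return records.loc[usable]


def _pathogenic_genes(records: pd.DataFrame, config: FilterConfig):
    if config.pathogenic_genes is not None:
        return config.pathogenic_genes
    if "label" not in records.columns:
        raise KeyError(
            "pathogenic_genes not configured and records carry no labels to "
            "derive them from"
        )
    mask = records["label"].isin({"P", "LP"})
    return frozenset(records.loc[mask, "gene"].astype(str))


def filter_labeled_set(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Labeled-set filter pipeline with a per-step waterfall of counts."""
    config = config or FilterConfig()
    waterfall: list[tuple[str, int]] = [("input", len(records))]
    if len(records) == 0:
        steps = ["missense", "allele_frequency", "gene_has_pathogenic",
                 "label_quality"]
        if config.training_keys:
            steps.append("training_exclusion")
        if config.archive_keys:
            steps.append("archive_overlap")
        waterfall += [(s, 0) for s in steps]
        return records.copy(), waterfall

    df = _require(records, ["chrom", "pos", "ref", "alt", "gene", "label"], config)
    genes = _pathogenic_genes(df, config)

    if config.require_missense and "consequence" in df.columns:
        df = df.loc[df["consequence"].astype(str) == "missense"]
    waterfall.append(("missense", len(df)))

    df = df.loc[effective_af(df) < config.af_max]
    waterfall.append(("allele_frequency", len(df)))

    df = df.loc[df["gene"].astype(str).isin(genes)]
    waterfall.append(("gene_has_pathogenic", len(df)))

    keep = df["label"].isin(KEPT_LABELS)
    if "stars" in df.columns:
        keep &= df["stars"].astype(float) > 0
    df = df.loc[keep]
    waterfall.append(("label_quality", len(df)))

    steps = []
    if config.training_keys:
        steps.append(("training_exclusion", config.training_keys))
    if config.archive_keys:
        steps.append(("archive_overlap", config.archive_keys))
    if config.training_exclusion_last:
        steps.reverse()
    for name, keys in steps:
        df = df.loc[~variant_keys(df).isin(keys)]
        waterfall.append((name, len(df)))
    return df.reset_index(drop=True), waterfall


def filter_population_set(
    records: pd.DataFrame,
    config: FilterConfig | None = None,
    exclude_regions: Mapping[str, IntervalTree] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Population-set filter pipeline with a per-step waterfall of counts.

    ``exclude_regions`` holds the merged segmental-duplication /
    low-complexity / decoy intervals; when absent, boolean flag columns
    (``segdup``, ``lowcomplexity``, ``decoy``) are honored instead if
    present.
    """
    config = config or FilterConfig()
    waterfall: list[tuple[str, int]] = [("input", len(records))]
    if len(records) == 0:
        for s in ("allele_frequency", "pass_filter", "genotype_quality",
                  "depth", "missense_in_pathogenic_gene", "deduplicate",
                  "region_exclusion", "training_exclusion", "archive_overlap"):
            waterfall.append((s, 0))
        return records.copy(), waterfall

    df = _require(
        records,
        ["chrom", "pos", "ref", "alt", "gene", "filter", "gq", "dp", "ac"],
        config,
    )
    genes = (
        config.pathogenic_genes
        if config.pathogenic_genes is not None
        else _pathogenic_genes(records, config)
    )

    df = df.loc[effective_af(df) < config.af_max]
    waterfall.append(("allele_frequency", len(df)))

    df = df.loc[df["filter"].astype(str) == "PASS"]
    waterfall.append(("pass_filter", len(df)))

    df = df.loc[df["gq"].astype(float) > config.min_gq]
    waterfall.append(("genotype_quality", len(df)))

    ac = df["ac"].astype(int)
    dp = df["dp"].astype(float)
    depth_ok = np.where(
        ac < config.ac_switch, dp >= config.depth_low_ac, dp >= config.depth_high_ac
    )
    df = df.loc[depth_ok]
    waterfall.append(("depth", len(df)))

    keep = df["gene"].astype(str).isin(genes)
    if config.require_missense and "consequence" in df.columns:
        keep &= df["consequence"].astype(str) == "missense"
    df = df.loc[keep]
    waterfall.append(("missense_in_pathogenic_gene", len(df)))

    df = df.loc[~variant_keys(df).duplicated()]
    waterfall.append(("deduplicate", len(df)))

    if exclude_regions is not None:
        df = df.loc[~region_overlap_mask(df, exclude_regions)]
    else:
        for col in ("segdup", "lowcomplexity", "decoy"):
            if col in df.columns:
                flag = df[col].where(df[col].notna(), False).astype(bool)
                df = df.loc[~flag]
    waterfall.append(("region_exclusion", len(df)))

    if config.training_keys:
        df = df.loc[~variant_keys(df).isin(config.training_keys)]
    waterfall.append(("training_exclusion", len(df)))

    if config.archive_keys:
        df = df.loc[~variant_keys(df).isin(config.archive_keys)]
    waterfall.append(("archive_overlap", len(df)))

    return df.reset_index(drop=True), waterfall
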