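"""Relative-abundance normalization and rank aggregation.

Gene-level tables are normalized per sample (optionally length-corrected) and
summed up to phylum/genus/species tables — a partition, so per-sample mass is
conserved, with ``unclassified`` kept as an explicit row — or to KO tables,
where a gene carrying k KOs contributes its full abundance to each of them
(many-to-many, columns need not sum to 1). Presence for richness and
shared/exclusive bookkeeping means abundance strictly above a configurable
floor that defaults to 0.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AbundanceTable,
    AnnotationMap,
    TAXON_RANKS,
    site_sample_ids,
    validate_metadata,
)
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def normalize_relative(
    counts: AbundanceTable, gene_lengths: Optional[pd.Series] = None
) -> AbundanceTable:
    """Column-normalize to relative abundances, optionally dividing by feature length (bp).

    All-zero columns stay all-zero and are reported through the module logger.
    """
    data = counts.data.astype(float)
    if gene_lengths is not None:
        lengths = pd.Series(gene_lengths).reindex(data.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()
            raise ValidationError(f"gene lengths missing for features: {missing[:5]}")
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0].tolist()
            raise ValidationError(f"non-positive gene lengths: {bad[:5]}")
        data = data.div(lengths, axis=0)
    sums = data.sum(axis=0)
    zero_cols = sums[sums == 0].index.tolist()
    if zero_cols:
        logger.warning("all-zero sample columns left unnormalized: %s", zero_cols)
    nonzero = sums != 0
    data.loc[:, nonzero] = data.loc[:, nonzero].div(sums[nonzero], axis=1)
    return AbundanceTable(data, level=counts.level, normalized=True)


def aggregate_rank(
    table: AbundanceTable, annotation: AnnotationMap, rank: str
) -> AbundanceTable:
    """Sum a gene-level table to one taxonomic rank or to KO space."""
    if table.level != "gene":
        raise ValidationError(f"aggregation expects a gene-level table, got {table.level!r}")
    if rank not in TAXON_RANKS + ("KO",):
        raise ValidationError(f"unknown rank {rank!r}")
    unknown = table.data.index.difference(annotation.taxonomy.index)
    if len(unknown):
        raise ValidationError(f"genes missing from annotation: {unknown.tolist()[:10]}")

    if rank in TAXON_RANKS:
        labels = annotation.taxonomy.loc[table.data.index, rank]
        out = table.data.groupby(labels.to_numpy()).sum()
        out.index.name = rank
    else:
        pairs = [
            (gene, ko)
            for gene in table.data.index
            for ko in annotation.kos_of(gene)
        ]
        if not pairs:
            raise ValidationError("no gene carries a KO assignment")
        link = pd.DataFrame(pairs, columns=["gene", "ko"])
        out = (
            table.data.loc[link["gene"]]
            .set_axis(link["ko"].to_numpy(), axis=0)
            .groupby(level=0)
            .sum()
        )
        out.index.name = "KO"
    # KO columns legitimately do not sum to 1 (multi-mapping duplicates mass)
    return AbundanceTable(out.sort_index(), level=rank, normalized=False)


def gene_richness(table: AbundanceTable, sample: str, min_abundance: float = 0.0) -> int:
    """Number of features detected (abundance > floor) in one sample."""
    if sample not in table.data.columns:
        raise ValidationError(f"unknown sample {sample!r}")
    return int((table.data[sample] > min_abundance).sum())


def richness_by_sample(table: AbundanceTable, min_abundance: float = 0.0) -> pd.Series:
    return (table.data > min_abundance).sum(axis=0)


def shared_exclusive_taxa(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    min_abundance: float = 0.0,
) -> tuple[set, set, set]:
    """Partition taxa present anywhere into (shared, mucosa-only, feces-only).

    A taxon is present in a site if its abundance exceeds the floor in at
    least one sample of that site.
    """
    validate_metadata(metadata)
    present = {}
    for site in ("mucosa", "feces"):
        cols = [s for s in site_sample_ids(metadata, site) if s in table.data.columns]
        if not cols:
            raise ValidationError(f"no {site} samples in the table")
        present[site] = set(table.data.index[(table.data[cols] > min_abundance).any(axis=1)])
    shared = present["mucosa"] & present["feces"]
    return shared, present["mucosa"] - shared, present["feces"] - shared


def top_n_taxa(
    table: AbundanceTable, metadata: pd.DataFrame, site: str, n: int
) -> list[str]:
    """Taxa sorted by mean abundance over the site's samples; ties break lexicographically."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    cols = [s for s in site_sample_ids(metadata, site) if s in table.data.columns]
    if not cols:
        raise ValidationError(f"no {site} samples in the table")
    means = table.data[cols].mean(axis=1)
    if n > len(means):
        logger.info("requested top %d of %d taxa; returning all", n, len(means))
        n = len(means)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:n]


def site_mean_abundance(
    table: AbundanceTable, metadata: pd.DataFrame, features: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-feature mean abundance in each site (columns mucosa, feces)."""
    out = {}
    for site in ("mucosa", "feces"):
        cols = [s for s in site_sample_ids(metadata, site) if s in table.data.columns]
        out[site] = table.data[cols].mean(axis=1)
    frame = pd.DataFrame(out)
    if features is not None:
        missing = [f for f in features if f not in frame.index]
        if missing:
            raise ValidationError(f"features absent from table: {missing[:5]}")
        frame = frame.loc[list(features)]
    return frame
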