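"""Core in-memory containers.

Abundance matrices are features x samples pandas DataFrames wrapped in
:class:`AbundanceTable`, which carries the aggregation level and a
``normalized`` flag. Sample metadata is a plain DataFrame indexed by
sample id and validated by :func:`validate_metadata`. Taxonomic and
functional annotation live in :class:`AnnotationMap`; pathway membership
is a mapping pathway id -> tuple of KO ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

SITES = ("mucosa", "feces")
TAXON_RANKS = ("phylum", "genus", "species")
RANKS = TAXON_RANKS + ("KO",)
LEVELS = ("gene",) + RANKS
UNCLASSIFIED = "unclassified"

METADATA_COLUMNS = ("subject_id", "site", "age", "gender", "bmi", "polyp_group")

NORMALIZATION_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Non-negative features x samples matrix at one aggregation level."""

    data: pd.DataFrame
    level: str = "gene"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if not self.data.columns.is_unique:
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance table must be numeric")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("abundance values must be finite and non-negative")
        if self.normalized:
            sums = values.sum(axis=0)
            bad = ~(np.isclose(sums, 1.0, atol=NORMALIZATION_TOL) | (sums == 0.0))
            if np.any(bad):
                offenders = self.data.columns[bad].tolist()
                raise ValidationError(
                    f"table flagged normalized but columns do not sum to 1: {offenders[:5]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return AbundanceTable(self.data[list(sample_ids)], level=self.level,
                              normalized=self.normalized)


def validate_metadata(metadata: pd.DataFrame, require_paired: bool = False) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample id).

    Checks column presence, (subject, site) uniqueness, positive age/BMI and
    known site labels. With ``require_paired`` every subject must contribute
    exactly one mucosa and one feces sample.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if not metadata.index.is_unique:
        raise ValidationError("duplicate sample ids in metadata")
    bad_site = sorted(set(metadata["site"]) - set(SITES))
    if bad_site:
        raise ValidationError(f"unknown site labels: {bad_site}")
    if metadata.duplicated(subset=["subject_id", "site"]).any():
        raise ValidationError("(subject_id, site) pairs must be unique")
    if (metadata["age"] <= 0).any() or (metadata["bmi"] <= 0).any():
        raise ValidationError("age and bmi must be positive")
    if require_paired:
        counts = metadata.groupby("subject_id")["site"].agg(lambda s: tuple(sorted(s)))
        unpaired = counts[counts != ("feces", "mucosa")]
        if len(unpaired):
            raise ValidationError(
                f"subjects without exactly one sample per site: {unpaired.index.tolist()[:5]}"
            )
    return metadata


def paired_sample_ids(metadata: pd.DataFrame) -> tuple[list[str], list[str], list[str]]:
    """Return (subjects, mucosa sample ids, feces sample ids) aligned by subject."""
    validate_metadata(metadata, require_paired=True)
    subjects = sorted(metadata["subject_id"].unique())
    by_key = {(row.subject_id, row.site): idx for idx, row in metadata.iterrows()}
    mucosa = [by_key[(s, "mucosa")] for s in subjects]
    feces = [by_key[(s, "feces")] for s in subjects]
    return subjects, mucosa, feces


def site_sample_ids(metadata: pd.DataFrame, site: str) -> list[str]:
    if site not in SITES:
        raise ValidationError(f"unknown site {site!r}")
    return metadata.index[metadata["site"] == site].tolist()


@dataclass
class AnnotationMap:
    """Gene-level annotation: taxonomy lineage plus KO assignments.

    ``taxonomy`` is indexed by gene id with columns phylum/genus/species;
    ``gene_kos`` maps gene id -> tuple of KO ids (possibly empty). The literal
    label ``unclassified`` is allowed at any rank and exempt from the
    nesting-consistency check.
    """

    taxonomy: pd.DataFrame
    gene_kos: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TAXON_RANKS if c not in self.taxonomy.columns]
        if missing:
            raise ValidationError(f"annotation missing ranks: {missing}")
        if not self.taxonomy.index.is_unique:
            raise ValidationError("duplicate gene ids in annotation")
        for child, parent in (("species", "genus"), ("genus", "phylum")):
            sub = self.taxonomy[self.taxonomy[child] != UNCLASSIFIED]
            n_parents = sub.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"inconsistent taxonomy: {child} mapping to multiple {parent}s: "
                    f"{bad.index.tolist()[:5]}"
                )
        extra = set(self.gene_kos) - set(self.taxonomy.index)
        if extra:
            raise ValidationError(f"KO assignments for unknown genes: {sorted(extra)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return self.taxonomy.index.tolist()

    def kos_of(self, gene: str) -> tuple[str, ...]:
        return tuple(self.gene_kos.get(gene, ()))

    def all_kos(self) -> list[str]:
        out: set[str] = set()
        for kos in self.gene_kos.values():
            out.update(kos)
        return sorted(out)


PathwayMap = dict  # pathway_id -> tuple of KO ids


def validate_pathway_map(pathway_map: Mapping[str, tuple[str, ...]]) -> None:
    for pid, kos in pathway_map.items():
        if len(kos) == 0:
            raise ValidationError(f"pathway {pid!r} holds no KOs")
        if len(set(kos)) != len(kos):
            raise ValidationError(f"pathway {pid!r} lists duplicate KOs")
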