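"""TSV readers/writers and the artifact manifest.

All tabular artifacts are UTF-8 TSV: abundance matrices (first column =
feature id, header = sample ids), sample metadata, gene annotation
(gene/phylum/genus/species/ko_list with semicolon-delimited KOs), the
two-column pathway map (pathway_id, ko_id) and differential-result tables.
Relative abundances are written with 10 significant digits so write->read
round trips are exact to ~1e-12. Readers validate rather than coerce: ragged
rows, duplicate ids, non-numeric or negative cells raise ParseError naming
the offender.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceTable, AnnotationMap
from .differential import DifferentialResult, results_frame
from .exceptions import ParseError
from .reporter import ReporterResult
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def write_abundance_tsv(table: AbundanceTable, path) -> None:
    frame = table.data.copy()
    frame.index.name = frame.index.name or "feature"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_abundance_tsv(path, level: str = "gene", normalized: bool = False) -> AbundanceTable:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed TSV ({exc})") from exc
    if frame.shape[0] == 0:
        raise ParseError(f"{path}: no features")
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no samples")
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups[:5]}")
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()][:1]
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {bad.tolist()}"
            )
    neg = frame < 0
    if neg.any().any():
        row = frame.index[neg.any(axis=1)][0]
        col = frame.columns[neg.loc[row].to_numpy()][0]
        raise ParseError(f"{path}: negative abundance at row {row!r}, column {col!r}")
    if frame.isna().any().any():
        row = frame.index[frame.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    return AbundanceTable(frame, level=level, normalized=normalized)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    from .containers import validate_metadata

    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_metadata(frame)


# ---------------------------------------------------------------------------
# annotation and pathway maps
# ---------------------------------------------------------------------------

def write_annotation_tsv(annotation: AnnotationMap, path) -> None:
    frame = annotation.taxonomy.copy()
    frame["ko_list"] = [";".join(annotation.kos_of(g)) for g in frame.index]
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def write_pathway_tsv(pathway_map, path) -> None:
    rows = [(pid, ko) for pid in sorted(pathway_map) for ko in pathway_map[pid]]
    pd.DataFrame(rows, columns=["pathway_id", "ko_id"]).to_csv(path, sep="\t", index=False)


def read_maps(annotation_path, pathway_path) -> tuple[AnnotationMap, dict]:
    """Read the annotation and pathway TSVs; dangling pathway KOs are kept with a warning."""
    apath = Path(annotation_path)
    frame = pd.read_csv(apath, sep="\t", index_col="gene", dtype=str, keep_default_na=False)
    required = ("phylum", "genus", "species", "ko_list")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{apath}: missing columns {missing}")
    gene_kos = {
        gene: tuple(k for k in str(kos).split(";") if k)
        for gene, kos in frame["ko_list"].items()
    }
    annotation = AnnotationMap(taxonomy=frame[["phylum", "genus", "species"]],
                               gene_kos=gene_kos)

    ppath = Path(pathway_path)
    pw = pd.read_csv(ppath, sep="\t", dtype=str)
    if list(pw.columns[:2]) != ["pathway_id", "ko_id"]:
        raise ParseError(f"{ppath}: expected columns pathway_id, ko_id")
    if pw.isna().any().any() or (pw["ko_id"] == "").any():
        line = int(pw.index[pw.isna().any(axis=1) | (pw["ko_id"] == "")][0]) + 2
        raise ParseError(f"{ppath}: malformed row at line {line}")
    n_before = len(pw)
    pw = pw.drop_duplicates()
    if len(pw) < n_before:
        logger.info("pathway map: deduplicated %d repeated rows", n_before - len(pw))
    known = set()
    for kos in gene_kos.values():
        known.update(kos)
    dangling = sorted(set(pw["ko_id"]) - known)
    if dangling:
        logger.warning("pathway map lists %d KOs absent from the annotation (kept): %s",
                       len(dangling), dangling[:5])
    pathway_map = {pid: tuple(sorted(group["ko_id"]))
                   for pid, group in pw.groupby("pathway_id")}
    return annotation, pathway_map


# ---------------------------------------------------------------------------
# results, ground truth, manifest
# ---------------------------------------------------------------------------

def write_differential_tsv(results: Sequence[DifferentialResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_reporter_tsv(results: Sequence[ReporterResult], path) -> None:
    pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in results],
            "k": [r.k for r in results],
            "raw_score": [r.raw_score for r in results],
            "corrected_score": [r.corrected_score for r in results],
            "label": [r.label for r in results],
            "low_confidence": [r.low_confidence for r in results],
        }
    ).set_index("pathway").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: Sequence[Path], out_path, extra: Optional[dict] = None) -> dict:
    """JSON manifest of artifacts with checksums; returns the manifest dict."""
    out_path = Path(out_path)
    manifest = {
        "artifacts": {
            str(Path(p).relative_to(out_path.parent)): sha256_of(p) for p in paths
        }
    }
    if extra:
        manifest.update(extra)
    out_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
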