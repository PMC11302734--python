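"""End-to-end pipeline: profile -> diversity -> differential -> enrichment -> phenotypes.

``run_pipeline`` consumes gene-level inputs (counts or relative abundances,
annotation, pathway map, metadata), writes every stage's TSV artifacts under
the output directory and finishes with a checksummed JSON manifest, so a rerun
under the same configuration and seed is byte-reproducible. Any stage failure
aborts with the failing stage named and no manifest written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as gio
from .containers import RANKS, TAXON_RANKS
from .differential import differential_screen, group_mean_correlation, leave_one_out_screen
from .diversity import bray_curtis, pcoa
from .exceptions import ConfigurationError, PipelineError
from .phenotypes import SCHEMES, subgroup_screen, polyp_risk_contrast
from .profiling import aggregate_rank, normalize_relative, richness_by_sample, shared_exclusive_taxa
from .reporter import enrich

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    annotation_path: str
    pathway_path: str
    outdir: str
    method: str = "wilcoxon"
    alpha: float = 0.05
    reporter_draws: int = 1000
    seed: int = 0
    pcoa_rank: str = "genus"
    phenotype_site: str = "mucosa"
    phenotype_schemes: tuple[str, ...] = ("age", "gender", "bmi", "polyp_risk")
    already_normalized: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.reporter_draws < 100:
            raise ConfigurationError("reporter_draws must be >= 100")
        if self.pcoa_rank not in TAXON_RANKS:
            raise ConfigurationError(f"pcoa_rank must be one of {TAXON_RANKS}")
        unknown = [s for s in self.phenotype_schemes if s not in SCHEMES]
        if unknown:
            raise ConfigurationError(f"unknown phenotype schemes: {unknown}")
        for name in ("counts_path", "metadata_path", "annotation_path", "pathway_path"):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise ConfigurationError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: expected a mapping")
        if "phenotype_schemes" in payload:
            payload["phenotype_schemes"] = tuple(payload["phenotype_schemes"])
        return cls(**payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the artifact manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    def load():
        metadata = gio.read_metadata_tsv(config.metadata_path)
        counts = gio.read_abundance_tsv(
            config.counts_path, level="gene", normalized=config.already_normalized
        )
        annotation, pathway_map = gio.read_maps(config.annotation_path, config.pathway_path)
        return metadata, counts, annotation, pathway_map

    metadata, counts, annotation, pathway_map = run_stage("load", load)

    def profile():
        genes = counts if config.already_normalized else normalize_relative(counts)
        tables = {"gene": genes}
        for rank in RANKS:
            tables[rank] = aggregate_rank(genes, annotation, rank)
            gio.write_abundance_tsv(tables[rank], emit(outdir / f"abundance_{rank}.tsv"))
        richness = richness_by_sample(genes)
        richness.rename("gene_richness").to_csv(emit(outdir / "gene_richness.tsv"), sep="\t")
        shared, excl_m, excl_f = shared_exclusive_taxa(tables["genus"], metadata)
        (outdir / "shared_exclusive_genera.tsv").write_text(
            "set\tgenus\n"
            + "".join(f"shared\t{g}\n" for g in sorted(shared))
            + "".join(f"exclusive_mucosa\t{g}\n" for g in sorted(excl_m))
            + "".join(f"exclusive_feces\t{g}\n" for g in sorted(excl_f))
        )
        emit(outdir / "shared_exclusive_genera.tsv")
        return tables

    tables = run_stage("profile", profile)

    def diversity():
        dist = bray_curtis(tables[config.pcoa_rank])
        dist.to_dataframe().to_csv(
            emit(outdir / f"braycurtis_{config.pcoa_rank}.tsv"),
            sep="\t", float_format=gio.FLOAT_FORMAT,
        )
        ord_res = pcoa(dist, n_axes=min(2, len(dist.sample_ids) - 1))
        ord_res.coordinates.to_csv(
            emit(outdir / f"pcoa_{config.pcoa_rank}.tsv"),
            sep="\t", float_format=gio.FLOAT_FORMAT,
        )
        with open(emit(outdir / f"pcoa_{config.pcoa_rank}_eigenvalues.tsv"), "w") as fh:
            fh.write("axis\teigenvalue\n")
            for i, ev in enumerate(ord_res.eigenvalues):
                fh.write(f"{i + 1}\t{ev:.10g}\n")

    run_stage("diversity", diversity)

    def differential():
        per_rank = {}
        for rank in RANKS:
            res = differential_screen(tables[rank], metadata,
                                      method=config.method, alpha=config.alpha)
            gio.write_differential_tsv(res, emit(outdir / f"differential_site_{rank}.tsv"))
            per_rank[rank] = res
        shared, _, _ = shared_exclusive_taxa(tables["genus"], metadata)
        if len(shared) >= 4:
            loo = leave_one_out_screen(tables["genus"], metadata, sorted(shared))
            loo.to_csv(emit(outdir / "leave_one_out_genus.tsv"),
                       sep="\t", float_format=gio.FLOAT_FORMAT)
        return per_rank

    diff_per_rank = run_stage("differential", differential)

    def enrichment():
        reporter = enrich(diff_per_rank["KO"], pathway_map,
                          n_draws=config.reporter_draws, seed=config.seed)
        gio.write_reporter_tsv(reporter, emit(outdir / "reporter_site.tsv"))

    run_stage("enrichment", enrichment)

    def phenotypes():
        for scheme_name in config.phenotype_schemes:
            scheme = SCHEMES[scheme_name]()
            for rank in RANKS:
                if scheme_name == "polyp_risk":
                    res = polyp_risk_contrast(tables[rank], metadata, alpha=config.alpha,
                                              site_filter=config.phenotype_site)
                else:
                    res = subgroup_screen(tables[rank], metadata, scheme,
                                          site_filter=config.phenotype_site,
                                          alpha=config.alpha)
                gio.write_differential_tsv(
                    res, emit(outdir / f"differential_{scheme_name}_{rank}.tsv")
                )
                if rank == "KO":
                    reporter = enrich(res, pathway_map,
                                      n_draws=config.reporter_draws, seed=config.seed)
                    gio.write_reporter_tsv(
                        reporter, emit(outdir / f"reporter_{scheme_name}.tsv")
                    )

    run_stage("phenotypes", phenotypes)

    manifest = gio.write_manifest(
        artifacts, outdir / "manifest.json",
        extra={"seed": config.seed, "method": config.method, "alpha": config.alpha},
    )
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest
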