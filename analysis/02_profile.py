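"""Aggregate the gene table to phylum/genus/species/KO and profile the taxa.

Reads results/data/, writes per-rank abundance tables, per-sample richness and
the shared/exclusive genus partition under results/profile/, and prints the
top-10 genera per site plus the sharing summary.
"""

import argparse
from pathlib import Path

from gutpair import io as gio
from gutpair.containers import RANKS
from gutpair.profiling import (
    aggregate_rank,
    richness_by_sample,
    shared_exclusive_taxa,
    top_n_taxa,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.outdir / "data"
    out = args.outdir / "profile"
    out.mkdir(parents=True, exist_ok=True)
    table = gio.read_abundance_tsv(data / "abundance_gene.tsv", level="gene", normalized=True)
    metadata = gio.read_metadata_tsv(data / "metadata.tsv")
    annotation, _ = gio.read_maps(data / "annotation.tsv", data / "pathways.tsv")
    truth = gio.read_ground_truth(data / "ground_truth.json")

    tables = {}
    for rank in RANKS:
        tables[rank] = aggregate_rank(table, annotation, rank)
        gio.write_abundance_tsv(tables[rank], out / f"abundance_{rank}.tsv")
    richness_by_sample(table).rename("gene_richness").to_csv(
        out / "gene_richness.tsv", sep="\t"
    )

    shared, excl_m, excl_f = shared_exclusive_taxa(tables["genus"], metadata)
    print(f"genera: {len(shared)} shared, {len(excl_m)} mucosa-only, {len(excl_f)} feces-only")
    print(f"planted mucosa-only genera recovered exactly: "
          f"{excl_m == set(truth.exclusive_mucosa)}")
    for site in ("mucosa", "feces"):
        top = top_n_taxa(tables["genus"], metadata, site, 10)
        print(f"top-10 genera in {site}: {', '.join(top)}")
    print(f"wrote per-rank tables to {out}")


if __name__ == "__main__":
    main()
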