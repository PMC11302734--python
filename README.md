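# gutpair

Paired mucosa-versus-feces shotgun-metagenome comparison, built as a tested,
reusable pipeline: gene-catalog abundance profiling, taxonomic and KEGG
Orthology (KO) aggregation, Bray-Curtis/PCoA ordination, paired
differential-abundance screening, phenotype-stratified contrasts, and
reporter-score KO-pathway enrichment — exercised end-to-end on a synthetic
paired-cohort generator with planted ground truth.

## Who this is for

Microbiome researchers comparing gut sampling sites (mucosal biopsies vs
stool) within the same subjects, where feces is a convenient but imperfect
proxy for the mucosal community. The pipeline consumes gene-level abundance
tables (genes x samples TSV, as produced by aligning reads to a gene catalog),
gene-to-taxonomy and gene-to-KO annotation, and a pathway-to-KO map. Because
the interesting statistical structure — a two-orders-of-magnitude gene-richness
gap between sites, ~50% genus overlap, one genus dominating the mucosa — is
hard to obtain at desk scale, the package ships a generator that emulates it
with known planted effects, so every stage is testable without external data.

## The statistics at the core

* **Relative abundance & aggregation.** Per-sample column normalization
  (optionally length-corrected); taxonomic ranks are a partition so
  per-sample mass is conserved (with `unclassified` as an explicit row), while
  a gene with k KOs contributes its full abundance to each KO.
* **Beta diversity.** Bray-Curtis d(u,v) = Σ|u−v| / Σ(u+v) and classical PCoA:
  eigendecomposition of −½·J·D²·J, coordinates scaled by √λ for positive
  eigenvalues, deterministic axis orientation.
* **Paired differential abundance.** Wilcoxon signed-rank on within-subject
  differences (zero differences dropped). For n ≤ 25 retained pairs the
  two-sided p comes from the exact sign-flip null computed by dynamic
  programming over rank sums — identical to enumerating all 2ⁿ sign
  assignments, ties included; larger n uses the tie-corrected normal
  approximation. Paired t and (for between-subject phenotype groups)
  Mann-Whitney rank-sum tests are available. No multiple-testing correction by
  default (raw p < 0.05), Benjamini-Hochberg by flag.
* **Cross-site correlation & leverage.** Squared Pearson correlation of
  per-genus site means over shared genera, with a leave-one-genus-out screen
  ranking each genus by Δr² = r²(without) − r²(all) — the top genus is the
  dominant site discriminator.
* **Reporter scores.** Each KO's two-sided p becomes a signed z =
  ±Φ⁻¹(1 − p/2) (positive = group A); a pathway of k scored KOs gets
  Z = Σz/√k, standardized against the empirical distribution of random
  k-subsets of all scored KOs; labels `++`/`+`/`0`/`-`/`--` at the strict
  ±1.96 and ±2.3 cutoffs (1.96 being the two-sided 97.5% normal quantile).

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (20 subjects, paired mucosa/feces samples, 8000 genes over
60 genera):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_profile.py
python analysis/03_diversity.py
python analysis/04_site_differential.py
python analysis/05_enrichment.py
python analysis/06_phenotypes.py
```

Selected output (seed 0):

```
mean gene richness: mucosa 69, feces 6042 (ratio 87.4x)
genera: 30 shared, 3 mucosa-only, 27 feces-only
planted mucosa-only genera recovered exactly: True
variance explained by PCo1/PCo2: 85.5%, 8.3%
mean Bray-Curtis distance: within-site 0.188, between-site 0.801
genus: 57/60 differential at p<0.05 (4 higher in mucosa, 53 in feces)
planted site-differential genera detected: 6/6
cross-site mean correlation over 30 shared genera: R^2 = 0.02626
most discriminating genus (leave-one-out): g01; R^2 without it = 0.90364
  pw01: corrected +10.91 ++ (k=10, enriched in mucosa)
```

Reading this: the feces samples carry ~87x more detected genes than mucosa;
half the genera are shared; the ordination separates the sites (between-site
distances are far larger than within-site); most differential features are
higher in feces; the planted dominant mucosa genus g01 destroys the cross-site
mean correlation (R² jumps from 0.026 to 0.904 when it is excluded, making it
the top leave-one-out discriminator); and the KO pathway planted on g01 is the
top mucosa-enriched pathway (`++`).

The same stages are exposed as a CLI (`gutpair simulate/profile/diversity/
diff/enrich/pheno/run`) for user-supplied TSVs; `gutpair run --config cfg.yaml`
executes everything and writes a checksummed artifact manifest, so reruns under
one seed are byte-identical.

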