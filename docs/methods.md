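# Methods

This note documents the models, conventions and numerical choices behind
`gutpair`, and what the synthetic cohort does and does not emulate.

## Synthetic paired-cohort generator

**Cohort.** Default 20 subjects, each contributing one mucosal and one fecal
sample. Exactly `round(gender_ratio * n)` subjects are male (default 12/20);
ages are integer years uniform on [44, 68]; BMI uniform on [19.7, 27.0] kg/m²
to one decimal; polyp-risk groups have fixed sizes (3 low / 12 moderate /
5 high). These defaults reproduce the phenotype strata the stratified screens
are designed around.

**Community skeleton (deterministic).** Genes are assigned to genera with
Zipf (1/rank) sizes — dominant gut genera contribute many more catalog genes
than rare ones — genera nest in phyla round-robin, and each genus's species
split its genes as one dominant species (~70%) plus evenly sized minor
species. Because the skeleton depends only on the counts, planted effects can
be addressed by stable ids (`g01`, `s021`, ...). A configurable fraction of
genes (default 4%) is relabeled `unclassified` at the species rank so the
aggregation path for unassigned mass is always exercised.

**Abundance model.** The abundance of gene g in the sample of subject s is

    x[g, sample] = u_g · exp(N(μ, σ_subject)) · exp(N(0, σ_sample)) · 2^(planted log2 effects) · mask

with one subject-level draw shared by the subject's two samples
(σ_subject = 1.0), an independent per-sample draw (σ_sample = 0.5), and a
persistent per-gene community-abundance factor u_g ~ LogNormal(0, 1.5) shared
by all samples. Columns are renormalized to relative abundances, so all
planted effects act on the compositional scale — enriching one taxon
necessarily depletes the rest (closure).

**Detection (occupancy) model.** Each gene×sample cell is masked by an
independent Bernoulli draw whose probability is abundance-weighted:
p_g = min(1, (c·u_g)^γ), with γ = 2.5 and c calibrated by bisection so that
mean(p) equals the configured occupancy exactly. Expected per-sample richness
is therefore `n_genes × occupancy` (and its variance is at most binomial),
while detection concentrates on the community's abundant core — a shallow
profile of a real community detects abundant organisms first, not a uniform
random subset of genes. Defaults: mucosa occupancy 0.01, feces 0.81 over 8000
genes, i.e. ~80 vs ~6500 detected genes, an ~80-fold richness gap emulating
the two-orders-of-magnitude gap between mucosal biopsies and stool. With a
uniform mask (γ = 1, u degenerate) mucosal genus shares become thin random
subsamples and between-subject screens lose essentially all power; the
abundance-weighted mask is the package's own design choice to keep the
low-richness site statistically usable, as real data are.

**Structural site exclusivity.** Occupancy alone cannot make a genus
site-exclusive against 20 samples, so the generator zeroes a configurable
number of genera per site structurally (default 3 mucosa-only, 27 feces-only,
leaving 30/60 genera shared — about half, as observed for paired gut sites).
Exclusive genera are chosen deterministically among genera carrying no planted
effect: the largest free genera for mucosa (they must remain observable at
occupancy 0.01), the smallest for feces.

**Planted truth.** Site effects multiply a feature's genes by 2^log2fc in the
enriched site; phenotype effects do the same for subjects in the enriched
group (both sites, since they are subject-level), and the polyp-risk effect is
a monotone gradient across groups 1→2→3. Defaults: the largest genus `g01` is
32-fold mucosa-enriched — it comes to dominate the mucosal composition, which
(i) makes it the high-leverage outlier of the cross-site mean correlation and
(ii) pushes, through closure, most other features to "higher in feces",
matching the asymmetry such paired designs show; five mid-sized genera are
4-fold feces-enriched; one genus each is 4-fold gender- and age-associated,
one species 4-fold BMI-associated, and one species carries the polyp gradient
reaching 16-fold between the extreme groups (a 3-vs-5 rank-sum contrast has
minimum attainable two-sided p = 2/C(8,3) ≈ 0.036, so anything short of
complete separation is undetectable by construction). One KO pathway's KOs are
carried exclusively by the abundant core genes of `g01`, planting a known
mucosa-enriched pathway. A dominant mucosa genus compositionally cancels other
mucosa-enrichments of ordinary size; planting several strong mucosa-enriched
genera simultaneously is therefore deliberately avoided.

`GroundTruth` records every planted effect (feature, level, variable, enriched
group, log2fc) plus, per rank, the *lineage-untouched* null features: a
species inside an enriched genus, the host genus of an enriched species, and
every KO riding on affected genes are all excluded from the null sets, since
planted gene-level effects propagate through the annotation.

**Null configuration.** `null_community_config()` is the effect-free,
site-symmetric-occupancy variant used for calibration work. Site symmetry
matters: with the default asymmetric occupancies the paired difference of a
feature's relative abundance is mean-zero but not sign-symmetric, and the
signed-rank test is not calibrated against such nulls — an inherent property
of presence/absence asymmetry, not an implementation artifact. Under equal
occupancy the two sites are exchangeable given the subject, the difference
distribution is sign-symmetric, and the measured type-I rate at α = 0.05 is
~0.046.

**Determinism.** All draws derive from one seed through `SeedSequence` stream
splitting (cohort=1, annotation=2, baselines=3, sample noise=4, masks=5,
gene factors=6); identical config+seed gives byte-identical outputs.

## Profiling conventions

Presence means abundance strictly above a configurable floor (default 0).
Taxonomic aggregation conserves per-sample mass to ~1e-15 including the
`unclassified` row; KO aggregation deliberately duplicates mass (many-to-many
annotation), so KO columns are not renormalized. Gene-length correction is
optional and off by default (whether catalog profiling length-normalizes is
dataset-specific). Top-N taxa sort by site mean with lexicographic
tie-breaking.

## Ordination

Bray-Curtis comes from `scipy.spatial.distance` with the convention
d = 0 between two all-zero profiles. PCoA is implemented directly
(double-centering + symmetric eigendecomposition) because the package fixes a
deterministic sign convention (each axis's largest-|loading| entry positive)
and a negative-eigenvalue policy: negatives are reported, excluded from
coordinates and from the variance-explained denominator; a Lingoes correction
is available by flag but off by default. scikit-bio's implementation serves as
an independent cross-check in the tests, not as the implementation.

## Differential testing

The Wilcoxon signed-rank test is implemented in the package: the exact
two-sided p for n ≤ 25 retained pairs is computed by dynamic programming over
the distribution of the positive-rank sum on doubled (hence integral,
tie-averaged) ranks — exactly the 2ⁿ sign-flip enumeration, but in
O(n · Σranks) — because exactness under ties is a tested contract that
library exact modes refuse. Above n = 25 the normal approximation uses the
tie-robust variance Σr²/4, no continuity correction. Zero differences are
dropped and counted; all-zero features are skipped, not tested; p-values are
clamped to ≥1e-300. Direction is reported from the group means. The paired t
and Mann-Whitney tests delegate to scipy. No multiplicity correction by
default (raw p < 0.05 is the pipeline's significance convention);
Benjamini-Hochberg via statsmodels by flag.

Group A is always the first-named group (mucosa for site screens; the scheme's
first label for phenotype screens), and every downstream sign convention
(direction, reporter z, reporter score) inherits it.

## Reporter enrichment

z = sign(direction)·Φ⁻¹(1 − p/2) with p clamped to [1e-10, 1−1e-10]; a result
with no direction (exactly equal means) contributes z = 0 with a warning,
which preserves the sign-antisymmetry of the whole chain under label swaps.
Pathway aggregation is Σz/√k; background correction standardizes against
n_draws = 1000 seeded random k-subsets (drawn without replacement, by index,
so a global sign flip of the population negates the background mean exactly
and antisymmetry holds to machine precision). Backgrounds are cached per
distinct k; the per-k RNG is derived from (seed, k), so a pathway's corrected
score does not depend on which other pathways are present. Degenerate
backgrounds (constant z population) raise; a pathway covering every scored KO
is its own background and scores 0 by definition; single-KO pathways are
scored but flagged low-confidence.

## Phenotype stratification

Age groups LOW [44, 53] / HIGH [54, 68] years and BMI groups DOWN [19.7, 23] /
UP [23.5, 27] kg/m² follow the printed closed intervals; values in the BMI gap
(23, 23.5) are excluded with a warning rather than snapped. Gender and polyp
group pass through. Between-subject contrasts use the two-sided rank-sum test
(the groups contain disjoint subjects, so paired tests do not apply); the
polyp contrast compares only Groups 1 and 3 and logs a small-sample warning at
n ≤ 5 per group. Phenotype screens default to mucosa samples, with feces
available by flag.

## What passing tests do and do not show

The generator emulates compositional structure, a richness gap, site-exclusive
taxa, subject pairing and multiplicative effects. It does not emulate
sequencing error, read-count (integer sampling) noise, correlated taxa
(effects are planted independently), overdispersion beyond log-normal, batch
effects or real taxonomies. Power and calibration measured on it therefore
demonstrate that the machinery is correct and well-calibrated under its stated
model, not that the same power holds on any particular real dataset.

## Problem sizes

Tests and the acceptance script run the study-scale cohort (20 subjects, 8000
genes) for structure/power checks — 100 simulated cohorts for the sensitivity
measurement — a 1000-gene site-symmetric null for type-I calibration (10
cohorts), and a 500-KO / 1000-pathway synthetic null for reporter calibration.
These sizes put Monte-Carlo noise well inside the asserted tolerance bands
while keeping a full run to tens of seconds.
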