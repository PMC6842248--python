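# Methods

This note documents the models, conventions and deliberate choices behind
`mycoscreen`, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Co-expression screen

**Model.** Genes are nodes; an undirected edge connects two genes whose
expression profiles across cultivation conditions have Spearman rank
correlation strictly greater than the cutoff (default 0.5). Ties receive
average (fractional) ranks, the standard Spearman convention. Correlations
are signed: anti-correlated genes never form edges, since the screen's
notion of co-expression is concordant regulation. The multi-query screen
intersects the neighbour sets of the query genes and removes the queries
themselves from the result.

**Numerical route.** Rows are rank-transformed once, centred and
normalised, so all pairwise correlations reduce to a matrix product. In
screen mode only query-versus-all correlations are computed, because only
query neighbourhoods are consumed; the resulting graph is therefore
incomplete away from the queries, which the network object documents.

**Degenerate inputs.** Constant expression rows make Spearman undefined and
are rejected, as are matrices with missing values (rejection at load time
was chosen over pairwise deletion for reproducibility) and matrices with
fewer than 5 conditions, where the rank correlation is too unstable to
threshold.

## GO over-representation

The test is the one-sided hypergeometric over-representation tail
P(X ≥ k), equivalent to a one-sided Fisher exact test — the de facto
standard of GO tools. The family for Benjamini–Hochberg adjustment is the
set of terms with at least one candidate hit, which fixes the family size
deterministically; the universe is the set of annotated genes in the
annotation table. Annotations are flat gene→term sets: no ontology
propagation, so parent terms receive no implicit counts. The survival
function is evaluated in log space and is stable at genome scale.

BH is the step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j clipped at 1, returned in
input order. It never falls below the raw p and never exceeds 1; it is not
claimed to be idempotent on already-adjusted values. Reported terms are
those with q ≤ the threshold (default 0.05). Note the sign of the rule:
enrichment reports terms at or *below* the FDR threshold; descriptions of
such pipelines occasionally say "above" the threshold, which can only be a
typo for the complementary filter and is read as such here.

## Culture morphometry

**Conventions.** Foreground structures are 8-connected, so thin diagonal
hyphae stay joined. All hull-based descriptors use the convex hull of pixel
*corners* (each pixel contributes its four corners): a 1-pixel-wide line
then has minimum Feret diameter 1 px rather than 0, so the aspect ratio
never divides by zero. Area is pixel count × (pixel size)²; solidity is
area over hull area; Feret max is the hull diameter and Feret min the
smallest edge-flush caliper width (for convex polygons the minimum width is
attained flush with an edge); aspect ratio is Feret max / Feret min — the
maximum over the minimum caliper diameter, not a fitted-ellipse axis ratio. Inputs are assumed pre-thresholded binary images; no hole filling or
smoothing is applied.

**Classification.** Pellets are structures with area ≥ 500 µm², dispersed
mycelium occupies [95, 500) µm², and smaller debris is excluded from both
the pellet-area fraction (pellet area over pellet+dispersed area) and the
MN summaries. The pellet inequality is inclusive: a structure of exactly
500 µm² is a pellet. The boundaries are parameters of the pipeline
configuration, defaulting to these values. MN is reported per pellet in summaries, matching how the statistic
is used to describe pelleted morphologies; an empty image yields NaN
fractions and statistics, never 0.

**Why MN ≤ 1 holds exactly.** Pixel area never exceeds corner-hull area,
and the isodiametric inequality bounds any convex set's area by
π·diameter²/4; together these give MN ≤ Feret_min/Feret_max ≤ 1 for every
structure measured under these conventions. The test suite asserts the
(0, 1] range with no rasterisation allowance.

**Rasterisation accuracy.** The corner hull slightly overstates a smooth
shape's convex footprint (diagonal corners protrude by up to half a pixel
diagonal), a ~1/R penalty in pixel radius R. For a 100-µm disc rendered at
0.5 µm/px the pipeline measures MN ≈ 0.978 rather than 1 (Feret and aspect
ratio inflate by ~0.7% each, solidity deflates by ~0.9%); at 0.25 µm/px the
value is ≈ 0.989. This is a property of the measurement convention — the
same polygon convention ImageJ-style tools use — not of the renderer, whose
pixel counts are exact (see below).

## Synthetic data generators

All generators take explicit integer seeds, use `numpy.random.default_rng`
and no global state, and are bit-reproducible for identical arguments.

**Expression compendium.** Module members are linear (hence monotone)
copies of a shared standard-normal latent condition profile plus
independent Gaussian noise; background genes are independent noise. The
latent loading is chosen from the target within-module Spearman correlation
via the bivariate-normal identity ρ_Pearson = 2·sin(π·ρ_Spearman/6), so the
pairwise Spearman concentrates near the target; with zero noise members are
exact copies (ρ = 1). The default screen scenario plants one 50-gene
"nexus" module containing the six query genes, the three Arf-regulator
genes and filler members, over 1000 background genes and 155 conditions —
matching the compendium scale the screen is meant for — with a target
within-module correlation of 0.9 and noise SD 0.3. The generator idealises
a real microarray compendium: no probe-level artifacts, normalisation
residue, batch structure, or between-module correlation. Passing recovery
tests therefore demonstrates correctness of the screen's logic and its
behaviour at realistic size and correlation levels, not robustness to
microarray-specific noise.

**Annotations.** Module members carry their module's planted GO terms plus
`terms_per_gene` draws from a pool of generic background terms; background
genes carry draws only. With an empty pool, genes without planted terms
have nothing to carry and are omitted — the annotation universe is the set
of annotated genes. Because module genes also draw generic terms, a generic
term can occasionally be genuinely over-represented in a planted module;
enrichment tests assert that planted terms are reported, not that generic
terms never are.

**Culture images.** Images are generated directly as binary masks (the
quantification operates on thresholded structures, so simulated
illumination would add nothing): pellets as ellipses with optional
sinusoidal boundary roughness at constant target area, dispersed fragments
as oriented rectangles with areas in the dispersed window. A radial-scale
bisection followed by depth-ordered trimming/annexation of boundary pixels
makes each object's pixel count match its requested area exactly (the only
residual is the sub-pixel rounding of the target itself, well inside the
renderer's stated 3% tolerance). Objects must lie fully inside the image
and never touch, enforced with a one-pixel dilation margin.

**Fermentation tables.** A dose-response spec maps each strain × dose to
model means for protein (mg), dry weight (g), citric and oxaloacetic acid
(g/l) and depleted glucose (g/l); replicates are the mean times a unit-mean
lognormal multiplier with coefficient of variation `noise_cv` (default
0.1, a typical shake-flask replicate spread; multiplicative noise keeps
titres nonnegative). The default model encodes the qualitative
dose-response pattern of the conditional-expression strains: a dose-independent progenitor (MA70.15), a *secG* strain
with citric acid absent at 0–0.2 µg/ml doxycycline (represented as a
measured 0, not missing) and oxaloacetate accumulation at low dose, and
essential-gene strains lacking the 0 µg/ml condition with strong protein
suppression at 0.2 µg/ml. Magnitudes are order-of-scale choices for a
20-ml shake-flask run, not reconstructions of unpublished measurements;
four replicates per cell reflect duplicate experiments of duplicate
cultures. Doses default to {0, 0.2, 2, 20} µg/ml.

## Fermentation statistics

Protein is normalised to fungal dry weight (mg/g biomass) and each acid to
depleted glucose (g/g); a zero denominator yields NaN with a warning, never
0. Comparisons against the control use two-sided two-sample Student's
*t*-tests with pooled variance — pooled rather than Welch because that is
the named procedure being mirrored; this is a known limitation when group
variances differ. Zero pooled variance with equal means gives p = 1 by
convention. No multiple-testing correction is applied across the strain ×
dose × variable cells (each is a single planned contrast, as in the
original analysis); the report logs how many tests were run so readers can
judge the multiplicity. Tests operate on normalised values.

Trend fits are ordinary least-squares polynomials over strain × dose means
(means, not medians), degree 2 for protein-vs-citrate and degree 1 for
protein-vs-oxaloacetate, with R² = 1 − SS_res/SS_tot and R² ≡ 0 for
constant responses; the nesting guarantee R²(deg 2) ≥ R²(deg 1) holds for
every dataset. The numeric R² values printed by the analysis scripts
describe the synthetic effect model, not any published measurement.

## Pipeline

A single YAML-loadable configuration drives all stages; unknown keys are
rejected. Defaults are the study conditions: Spearman cutoff 0.5,
enrichment FDR threshold 0.05, dispersed/pellet boundaries 95/500 µm²,
t-test alpha 0.05, doses {0, 0.2, 2, 20} µg/ml. Every stage writes a
manifest (config, SHA-256 of the config, package version) so reruns are
byte-identical. CLI exit codes: 0 success, 1 configuration error, 2 data
error; unreadable images are skipped with a per-file error and reported in
a nonzero exit summary.

## Problem sizes

The default test and analysis scale — 1050 genes × 155 conditions for the
screen, ~1.4-megapixel images with a dozen objects, four replicates per
fermentation cell, 10 generator seeds for recovery sweeps and 200 draws
for the enrichment null — was chosen so a full run completes in well under
a minute per stage on one CPU while keeping the Monte-Carlo assertions
(recovery ≥ 95%, contamination ≤ 1%, null reporting ≤ 7%) statistically
meaningful.

## Known limitations

- The co-expression generator cannot say anything about how the screen
  behaves on compendia with correlated background structure (shared batch
  effects can inflate neighbourhoods); the contamination bound holds only
  under independent background genes.
- GO enrichment ignores the ontology graph; results are per flat term.
- Morphology operates on binary images; thresholding of raw micrographs is
  upstream and out of scope, and the pixel calibration (µm/px) must be
  supplied explicitly.
- The pooled-variance t-test is anticonservative under variance
  heterogeneity; Welch's test would be the defensive default in new work.
- MN of near-circular objects is biased low by the corner-hull convention
  at coarse pixel sizes (see "Rasterisation accuracy").
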