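# Methods

This note documents the statistical procedures implemented in `seqbind`,
the generative model used to exercise them, the parameter choices that
matter, and the known limitations of both.

## The scientific problem

Methyl-CpG-binding proteins such as MeCP2 bind chromatin genome-wide, and
their ChIP-seq coverage correlates with several sequence and epigenome
tracks at once: GC%, CpG%, methylated-CpG density (mCpG%), and nucleosome
occupancy. Because these covariates are strongly correlated with each
other along the genome, a marginal correlation between binding and any one
of them is uninterpretable: binding may track CpG% only because CpG%
tracks GC%. The package implements the confound-controlled toolchain for
this situation — background normalization, binned track construction,
partial correlations and Gaussian graphical models, sequence-based
prediction, and annotation-aggregated differential expression — and a
synthetic-data generator with planted ground truth against which every
stage is validated.

## Genome tracks

The genome is tiled with fixed-width windows (150 bp for track analyses,
roughly the ChIP/MNase fragment size; 200 bp for the prediction grid);
the trailing partial window of each chromosome is dropped. All
coordinates are 0-based half-open internally; BED is native, cytosine
reports convert from 1-based on read.

Per window we record the base-composition features f_GC (fraction of G/C
bases) and f_CpG (fraction of within-window dinucleotide start positions
holding CpG, denominator W−1; dinucleotides spanning a window boundary
are ignored, an approximation bounded by 1/(W−1)). Windows containing any
non-ACGT base are undefined and excluded from all statistics. Fragment
coverage extends read starts 3′ to the experimentally determined fragment
length (200 bp for ChIP/Input, 146 bp for mononucleosomal MNase) and
records mean per-base coverage per window; point sampling at the window
centre is available as `stat="center"` for the bivariate analyses.

Anomalous regions are masked by two rules: windows with occupancy above
100, and runs of ten or more consecutive 1 kb bins with mean mappability
below 50%; both padded by ±10 kb.

## SES normalization

Signal extraction scaling separates ChIP signal from non-specific
background. Bins are ordered by increasing ChIP count (ties broken by
Input, then position) and the cumulative fraction curves f_ChIP and
f_Input along the ordering are compared; the percentile p* of maximal
|f_ChIP − f_Input| marks the separation between background-dominated and
signal-carrying bins.

Two scalar summaries come out of the separation and must not be
conflated:

* **share ratio** = f_Input(p*)/f_ChIP(p*). This is invariant to
  rescaling either channel; it measures what fraction of the ChIP channel
  is signal rather than background.
* **υ (scaling factor)** — the background Input/ChIP *rate* ratio, i.e.
  the factor that rescales the ChIP background to match Input so that the
  pseudocounted enrichment E(i) = υ·(n_ChIP(i)+ε)/(n_Input(i)+ε), with
  ε = 0.1 throughout, is ≈1 in background bins. Being a rate ratio, no
  per-channel-normalized curve can estimate it; it must come from raw
  sums.

Estimating υ by summing the same ChIP counts that defined the ordering is
strongly biased: the low end of a ChIP ordering preferentially contains
bins whose ChIP count fluctuated downward (we measured up to +80% bias at
10 fragments/bin). The package therefore re-selects the background set as
the m = ⌈0.25·p*·n⌉ bins with the smallest *combined* count
n_ChIP + n_Input and takes υ = ΣInput/ΣChIP over that set. Conditional on
the combined count and the latent background rate λ of a bin, the ChIP
count is Binomial(n_ChIP+n_Input, 1/(1+υ)) — independent of λ — so any
selection based on the combined count leaves the channel ratio unbiased.
The shrink factor 0.25 keeps weakly separated signal bins out of the
background set. On simulated data this recovers υ within ~1% on pure
background and within 5% with 30% of the genome enriched, across
υ ∈ [1, 8]. Two caveats: the argument requires both channels on the raw
count scale (after rescaling a channel the estimate is equivariant only
in the deep-coverage limit), and a degenerate all-zero ChIP background
raises an error rather than returning a value.

## Binned methylation

The per-site methylation level is l(x) = n_m(x)/n_tot(x); the binned
level is the coverage-weighted average l(i) = Σn_m/Σn_tot over the sites
of the bin, which down-weights poorly covered sites and has no larger
variance than the unweighted site mean. Methylation density is
f_mCpG(i) = l(i)·f_CpG(i): bins without CpG are *defined* as zero, bins
with CpG but no coverage stay undefined and are excluded from all
correlations. CpH (CHG+CHH) calls are pooled into a single CH context
and treated identically. Calls on the two strands of a CpG are distinct
records pooled by position into the containing bin.

## Association statistics

Partial correlations are computed two ways — the first-order recursion
formula for a single control, and the correlation of least-squares
residuals for any number of controls — and the two paths are checked
against each other (10⁻¹⁰ agreement). Note that a partial correlation
removes only the *linear* dependence on the controls; conclusions about
conditional independence require the construction (or an argument) that
the conditional mean is linear in the controls — see the generator notes
below.

The conditional enrichment map groups windows by (f_GC, f_CpG) at fixed
resolutions and averages a mean-normalized signal per cell; cells with
fewer than 50 windows are masked (a count threshold stands in for a
density-based mask: the CpG-rich, GC-poor corner of the plane is
undersampled and carries no reliable mean). Peak-versus-flank contrasts
merge peaks, take flanks of the peak's own width on both sides (clipped
at chromosome ends and neighbouring peaks), and report per-peak and
aggregate folds plus a two-sided Wilcoxon rank-sum p-value. The track
autocorrelation is pooled across chromosomes with pairwise-complete
products; its half width at half maximum is linearly interpolated and
reported in bp (flagged as a lower bound when no crossing occurs within
the lag range). Cross-correlation scans signed bin offsets of two tracks.

## Gaussian graphical model

Edge weights are full partial correlations from the inverse of the
pairwise correlation matrix, w_ij = −J_ij/√(J_ii·J_jj), J = R⁻¹, computed
on complete-case bins (any bin undefined in any track, or masked, is
dropped). Tracks enter on their raw scale; edge weights are invariant to
affine rescaling of any input. A condition number above 10⁸ raises an
error naming the most collinear pair rather than silently regularizing.
For two tracks the edge equals the marginal Pearson correlation; for
three it equals the first-order partial correlation (both identities are
tested). The same qualitative graph is recovered at 150 bp and at 10×
coarser bins on the linear construction, because aggregation preserves a
linear conditional mean.

## Random-Forest binding prediction

A 100-tree CART Random-Forest regressor (scikit-learn) is trained on
10,000 windows sampled uniformly without replacement from unmasked 200 bp
windows, predicting window-averaged fold enrichment from
reverse-complement-collapsed k-mer frequencies. Mononucleotides reduce to
the single feature GC% (frequencies sum to one; strand symmetry ties A to
T and C to G), so mono+di = 11 features and mono+di+tri = 43. Tree depth
is restricted to 3–8; results are insensitive across this range (AUC
spread < 0.3 points on synthetic data). The regressor classifies windows
by thresholding its prediction; a window counts as truly bound when it
overlaps a peak interval by ≥ 50 bp. ROC is evaluated on all eligible
windows outside the training sample; the operating point is fixed where
false positive and false negative rates are equal (EER), with accuracy
1 − FPR there. Two feature-importance readouts are reported: the standard
mean impurity decrease, and a depth-based score in which every split on a
feature contributes 1 − depth/tree-depth (splits near the root weigh
more; unused features score zero; normalized to sum to one). The
depth-based score spreads mass more evenly across correlated features
than the impurity score does — both are reported, and on GC-driven
synthetic data both rank GC% first.

The regression target is the SES enrichment smoothed with a 9-bin
(1.8 kb) rolling mean, standing in for the window-averaged fold
enrichment a peak caller reports; without smoothing, per-window Poisson
noise lets correlated dinucleotide features absorb spurious splits.

## Differential expression aggregated by annotation

Genes with geometric-mean FPKM (√(WT·KO)) strictly above 1 are kept.
Because fold-change dispersion depends on expression, genes are split
into 20 equal-count bins of log₂ geometric-mean FPKM (ties broken by gene
id for determinism); per-bin means and variances of log₂(WT/KO) are
fitted with quadratics in the bin centres, and each gene is standardized:
Z_g = (lfc_g − μ̂(e_g))/σ̂(e_g), with the fits clamped to the fitted
range. Terms with ≥ 10 qualifying genes are scored by their aggregated
fold change (mean member lfc) and tested with a two-sided one-sample
t-test of member Z-scores against zero — the Z construction makes this
the natural test; a term whose members all have Z = 0 is reported with
p = 1 and a degeneracy flag. Benjamini–Hochberg runs across all tested
terms. On simulated nulls the chain's mean fraction of q < 0.05 terms is
≈ 0.001 (≤ the nominal 0.05); a planted 50-gene term at −1 log₂-fold with
noise sd 0.5 is detected (q < 0.05) and ranked first essentially always.

The rank-based conditional slope test rank-transforms the response and
both covariates, regresses response ranks on both covariate ranks, and
reports the two-sided t-test on the second covariate's coefficient,
plus a quintile×quintile table of mean response. Its null p-values are
uniform (KS-checked) when the response depends only on the first
covariate.

## Signal alignment

Alignment matrices hold a mean-normalized track at bin-resolution offsets
in ±1 to ±4 kb windows around anchors, one row per anchor, minus-strand
rows reversed, rows sorted by an anchor score (ties broken by coordinate).
Display matrices are pixelated to ≤ 200×200 by block averaging that
ignores undefined cells (weighting pixels by their defined-cell counts
reproduces the source mean exactly; blanked cells stay blank rather than
being zeroed). Quartile median profiles split rows into four equal-count
groups in score order (remainders to the lower quartiles) and take
column-wise nan-medians.

## The synthetic-data generator

Every generator is a pure function of (configuration, seed); each output
stream has its own RNG (`seed + fixed offset`), so files are
independently reproducible and byte-identical across reruns.

**Genome.** Per-window GC targets follow a stationary AR(1) on the logit
scale (mean 0.42, sd 0.07, autocorrelation length 1 kb — mouse-like bulk
composition with megabase-free isochore-like variation), clamped to
[0.2, 0.8]. Bases are drawn independently at the local target; extra CpG
dinucleotides are implanted at rate (g/2)²·(exp(κ(g−ḡ))−1) with κ = 4, so
CpG density is coupled to GC beyond the product effect; κ = 0 gives
exactly independent placement (tested against the product law).

**ChIP/Input/MNase.** ChIP and Input share a lognormal (σ = 0.5)
background rate λ_i around 10 fragments per bin; Input ~ Poisson(λ_i),
ChIP ~ Poisson((λ_i+e_i)/υ_true) with υ_true = 4.41 by default.
Enrichment e_i is positive only in peak bins and is a *linear function of
the realized window GC%*: e_i = d·(fold + β·(f_GC,i − ḡ)). Fragments are
emitted as bin-aligned intervals so that channel counts are exactly
conserved (read-level realism is a non-goal). MNase is Poisson with rate
∝ exp(γ·(f_GC−ḡ)), γ = 3 calibrated to r(MNase, GC%) ≈ 0.6. Two peak
placements are first-class study conditions:

* `gc` (default): peaks are the top-10% runs of 3 kb-smoothed window GC%,
  with fold = 8 — strongly separated, sequence-predictable binding. Used
  by the Random-Forest experiment and the end-to-end dataset.
* `random` with peak_fraction = 1 and fold = 5, β = 10 — the
  **conditional-independence construction**: enrichment everywhere,
  linear in realized GC%. Because λ and the Poisson noise are independent
  of CpG% given GC%, and the conditional mean is exactly linear in GC%,
  the partial correlation r(ChIP, CpG% | GC%) is zero by construction
  while the marginal r(ChIP, CpG%) ≈ 0.4. The "construction value" of
  r(ChIP, GC% | CpG%) is computed analytically from the realized rates:
  conditional on the covariates Var(ChIP) = Var(rate) + mean(rate) and
  Cov(ChIP, X) = Cov(rate, X). Linearity is essential: with
  GC-thresholded peaks the conditional mean is sigmoidal in GC% and a
  linear partial correlation would *not* vanish — which is why the two
  modes exist.

**Methylation.** Every genomic CpG is emitted on both strands with
coverage ~ Poisson(10) and methylated counts Binomial at the regional
level: 70% background, 10% in promoter-proximal CpG islands (placed at
half the gene TSSs), 90% in distal islands, islands capped at 4% of the
genome so the pooled level stays ≈ 69–70%; CH sites sit at 2%.
Zero-coverage sites are emitted and exercise undefined-bin handling.

**Expression.** Per-gene log₂(WT/KO) = a·(promoter binding, z-scored) +
length_effect·(log₁₀L − mean) + planted term shift + ε, with
Var(ε) = 0.25·(1 + ((x−3)/4)²) depending on log₂ expression x ~ N(3, 2) —
a smooth quadratic heteroskedasticity the dispersion fit can recover.
FPKM pairs are reconstructed as gm·2^(±lfc/2) so the filter and binning
operate exactly as on real tables. Default effects are zero (a null
experiment); the planted-term and regression analyses switch them on
explicitly. Annotation terms draw 10–60 random genes; a planted term gets
a dedicated 50-gene set.

**What the generator does not emulate.** Read-level sequences and errors,
alignment and duplication artifacts, fragment-length variability,
isochore/repeat structure, strand-asymmetric methylation, bisulfite
conversion failure, annotation hierarchies, and correlated gene-gene
expression noise. Passing tests therefore demonstrate correctness of the
estimators under the stated stochastic model and calibrated behaviour of
the inference chain — not performance on real sequencing data.

## Problem sizes

The validation suite simulates 10⁵ windows (two 7.5 Mb chromosomes) for
the scaling-factor grid and the confounding dissection, 4×10⁴ 200 bp
windows for the prediction experiment, 200 null + 100 planted expression
datasets of 3,000 genes and 50 terms for the false-discovery calibration,
and smaller genomes (≈ 0.6–3 Mb) for per-module checks; these sizes give
sampling errors well inside the asserted tolerances.

## Numerical choices and degenerate inputs

Ties in the SES ordering break by Input then bin index; the first maximal
gap wins. Identical ChIP and Input tracks define υ = 1. ε = 0 with empty
Input bins, constant regression targets, collinear GGM tracks, fitted
variances ≤ 10⁻¹⁰, and anchors outside the genome all raise explicit
errors rather than producing values. Quadratic fits use `numpy.polyfit`;
matrix inversion is unregularized by design (see GGM). BH adjustment goes
through `statsmodels` and is oracle-checked against the step-up
definition.
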