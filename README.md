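# seqbind

Confound-aware analysis of the sequence determinants of genome-wide
protein–DNA binding, built around the kind of question raised by
methyl-CpG-binding proteins such as MeCP2: ChIP-seq coverage correlates
with GC%, CpG%, methylated-CpG density and nucleosome occupancy *at the
same time*, because those tracks are strongly correlated with each other
along the genome. Which associations are direct? `seqbind` implements the
toolchain for answering that on binned genome tracks, plus a
synthetic-data generator with planted ground truth that validates every
stage end-to-end. It is written for computational genomicists who want
the individual estimators as library functions and for readers who want
to re-run the whole analysis chain.

The pieces:

* **SES normalization** — ChIP/Input bins ordered by ChIP coverage; the
  maximal gap between the cumulative-fraction curves separates
  background from signal, and the background Input/ChIP rate ratio υ
  puts the pseudocounted enrichment E = υ·(ChIP+ε)/(Input+ε) on a scale
  where background ≈ 1. The background set is re-selected by combined
  ChIP+Input count, which provably removes the selection bias of
  ordering by a noisy channel (binomial splitting of Poisson counts).
* **Binned methylation** — coverage-weighted level l(i) = Σn_m/Σn_tot
  per window and the densities mCpG% = l·CpG%, mCpH%.
* **Association dissection** — Pearson and partial correlations (dual
  formula/residual paths), conditional mean maps over the (GC%, CpG%)
  plane, peak-vs-flank contrasts with rank-sum tests, autocorrelation
  HWHM, cross-correlation.
* **Gaussian graphical models** — full partial correlations
  w_ij = −J_ij/√(J_ii J_jj) from the inverse correlation matrix of any
  set of tracks.
* **Random-Forest prediction** — binding predicted from
  reverse-complement-collapsed k-mer frequencies (GC% + 10 dinucleotide
  classes = 11 features), ROC against peak calls with a 50 bp overlap
  rule, equal-error-rate accuracy, depth- and impurity-based feature
  importances.
* **Annotation-aggregated differential expression** — FPKM filtering,
  empirical expression-dependent dispersion (quadratic mean/variance
  fits), per-gene Z-scores, per-term t-tests with BH correction, and a
  rank-based conditional slope test.
* **Signal alignment** — anchor-centred heat-map matrices pixelated to
  200×200 and quartile median profiles.

See `docs/methods.md` for the statistical details and the generative
model.

## Worked example

The numbered scripts under `analysis/` run the study chain on a simulated
3 Mb genome (two chromosomes, 150 bp windows, planted scaling factor
υ = 4.41, 10% of the genome in GC-driven peaks, 70% background CpG
methylation). Bulky intermediates go to `scratch/`, summary tables to
`results/`.

```bash
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/04_confounding.py
```

prints, in order:

```
genome: 2 x 1.5 Mb, 20000 bins of 150 bp
planted upsilon_true = 4.41, peak bins = 1999 (10.0% of genome)
CpG sites (both strands): 324642; genes: 3000; GO terms: 50

SES scaling factor upsilon = 4.408 (separation at percentile 0.90, gap 0.427)
masked 1157 / 20000 bins; median enrichment 1.123

marginal r(ChIP, CpG%) = 0.407 over 100000 windows
partial r(ChIP, CpG% | GC%) = +0.0054  (conditional independence holds by construction)
partial r(ChIP, GC% | CpG%) = 0.254 (construction value 0.256)
ChIP autocorrelation HWHM = 89 bp; ChIP x MNase cross-correlation peaks at 0 bp (r = 0.312)
```

Reading this: the scaling factor recovers the planted 4.41 to 0.1%, and
masked-region handling plus the pseudocount leave the background
enrichment at ≈ 1. The confounding dissection is the core result — the
binding track correlates marginally with CpG% (r = 0.41), but the partial
correlation controlling GC% collapses to ≈ 0 exactly as planted (the
generator makes enrichment a function of GC% alone), while the direct
GC% association survives conditioning and matches the construction's
analytic value. The remaining scripts fit the methylation tracks
(genome-wide CpG level 69.1%; mCpG% 1.4-fold higher in peaks than
flanks), the six-track graphical model, the Random-Forest predictor
(mono-feature AUC 92%, stable to 0.1 AUC points across tree depths 3–8,
GC% the top-ranked feature under both importance measures), the
annotation-level expression analysis (a planted −1 log₂-fold 50-gene
term ranks first at q = 3×10⁻¹⁵), and the anchor-aligned profiles.

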