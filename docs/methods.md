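# Methods

This note documents the statistical models behind `axoprop`, the defaults
and why they were chosen, what the synthetic data do and do not emulate, and
the package's known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Differential expression model

Counts K_gj for gene g in sample j are modeled as negative binomial with
mean μ_gj = s_j · e^{o_gj} · q_{g,group(j)} and dispersion α_g
(Var = μ + α μ²). The design is the four-group factor
species × vertebra; each named contrast compares two groups.

**Size factors.** Median-of-ratios: s_j = median over genes with no zero
count of K_gj / (geometric mean of the gene's counts across samples). The
factors are defined only up to a common rescaling, which the GLM absorbs
into q. A `pseudo_reference` flag switches to a positive-count-only
reference for sparse toy matrices.

**Gene-length offsets.** For interspecies contrasts, o_gj =
ln(L_{g,species(j)} / √(L_{g,mouse} · L_{g,jerboa})). Geometric-mean
centering makes the two species' offsets equal and opposite per gene, so
the offset removes annotation-length asymmetry without shifting net
expression. The offset (rather than count-prescaling) formulation keeps
counts integral and the NB likelihood exact; this is an interpretation
choice, since length normalization schemes differ in whether they rescale
counts or offset the model. One-to-zero orthologs lack one species' length
and are excluded from interspecies contrasts but retained intra-species.

**Dispersion.** Gene-wise estimates maximize the Cox–Reid adjusted profile
likelihood (APL): the NB log likelihood with group means profiled out,
minus ½·Σ_groups ln(Σ_j μ/(1+αμ)). The CR term corrects the downward bias
of the plain profile MLE when group means are estimated from few
replicates. Maximization is a 61-point log-grid search (10⁻⁸ to 30) with
3-point parabolic refinement, vectorized across genes; estimates are
floored at 10⁻⁸.

`run_de` additionally shrinks gene-wise estimates toward a fitted trend
α(μ) = a₁ + a₀/μ (trimmed least squares on gene-wise estimates vs. inverse
base mean) by maximizing APL minus a normal penalty on ln α. The prior
width is estimated empirically: the robust (MAD) spread of gene-wise
log-dispersions about the trend, minus the expected sampling variance of a
log-dispersion MLE (trigamma((m−p)/2) for m samples, p groups), floored at
variance 0.05. Genes whose gene-wise estimate lies more than twice the
observed spread *above* the trend keep it: over-dispersion outliers are
never moderated toward significance. Rationale, measured on this package's
own simulations (20 datasets × 2000 genes, 4 vs 4 replicates, α = 0.05
nominal): raw gene-wise dispersions give mean realized false-discovery
proportion ≈ 0.12 because dispersion-estimation noise inflates Wald
statistics; with shrinkage the mean FDP is ≈ 0.05, and with oracle
dispersions ≈ 0.044 — i.e., the calibration loss is dispersion noise, and
shrinkage restores it. `estimate_dispersions` exposes the shrinkage as a
flag (off by default at the function level) so the raw estimator remains
available and testable.

**Wald test.** lfc = log₂(q_num/q_den) from per-group Fisher-scoring fits;
se from the observed information Σ μ/(1+αμ) of the two group log-means;
two-sided p from the normal reference (the conventional form of this test);
BH adjustment across tested genes. Expression filter: count ≥ 10 in ≥ 2
samples of the contrast; filtered genes and all-zero rows carry missing
statistics. Groups with all-zero counts are fit with half a pseudo-count to
report a finite, wide-error estimate.

Exact invariances that hold (and are tested): size-factor *ratios* scale
exactly with per-sample count scaling; log-fold changes are exactly
invariant under common rescaling of the size factors; doubling one gene's
jerboa length while doubling its jerboa counts leaves its interspecies lfc
unchanged. Scaling one sample's counts, by contrast, genuinely re-weights
the per-group score equations of a count GLM, so estimates move slightly
(tested to be < 0.05 in log₂, median < 0.005) — no count-model
implementation can make that an exact identity.

## Disproportionality classification

The regression of TV6 LFC on TV1 LFC is ordinary least squares over the
both-significant set only, fitted in a single pass (no outlier-exclusion
refit — which set the original workflow used is not documented, so the
simpler convention is implemented and stated). The prediction interval is
the standard OLS interval for a new observation with Student-t critical
value at n−2 df; boundary-exact points count as inside. Sign consistency
compares the interspecies TV6 LFC sign with the intra-jerboa LFC sign for
all of D = A ∪ B; a zero LFC with significant padj is excluded with a
warning. α = 0.05 is one global constant across stages; the PI level
defaults to 0.95.

Collation matches gene symbols case-insensitively with no alias
resolution; external lists are consumed as inputs. The bundled curated
table covers 20 candidate genes with four external limb-proportion dataset
tags (SHR, JH, MY, TP) and a mouse tail-phenotype flag; a gene is
highlighted if it has a phenotype or ≥ 3 dataset tags.

## Enrichment and overlap

Term enrichment is the hypergeometric upper tail P(X ≥ k) against a
user-supplied universe (the expressed-gene universe is the intended
choice), BH-adjusted across terms; terms with K < 3 or K > N/2 are skipped
by default as uninformative extremes (configurable). Overlap tests are
one-sided ("greater") Fisher exact tests, the convention of gene-list
overlap packages, with a two-sided flag; the universe size is a required
parameter because the appropriate universe (expressed genes vs. all
orthologs) is analysis-specific. Sample odds ratios use a 0.5 continuity
correction on zero cells. Synthetic term collections are generated in the
tests; real ontology content is out of scope because it is database-version
dependent.

## Morphometrics

**Length measurement.** A 1D intensity profile along the tail axis is
thresholded at half range; maximal supra-threshold runs (gaps ≥ 2 px
separate, shorter gaps merge) are the ossified diaphyses, labeled TV1…TVn
cranial→caudal. For each element, the local minimum m and maximum M are
taken over the element plus flanking gaps, and the element's boundaries are
the linearly interpolated crossings of (m+M)/2 on the leading and trailing
edges; length = crossing distance × voxel × resize µm (27 µm at the default
9 µm voxel, resize 3). The "midpoint between first intensity minimum and
maximum" landmark of manual cursor-based measurement is interpreted as this
half-height crossing — the only reading that yields a well-defined
sub-pixel landmark on both edges; the m/M window is per-element rather than
per-edge. A centered 3-px moving average can be enabled before
thresholding for noisy profiles; it is off by default since the manual
procedure involves no filtering. Growth plates and epiphyses are excluded
by construction (only mineralized bone rises above threshold).

**Proportions and dynamics.** Lengths are normalized per animal to the
naso-anal distance; the tail:body ratio sums vertebral lengths (plus gaps
when provided). The weekly change matrix takes per-timepoint animal means
first, then differences consecutive timepoints (a per-week rate form is a
flag; whether published heatmaps show differences or rates is ambiguous,
so the difference form is the default). The peak vertebra is the argmax of
summed change over a window, ties broken toward the smaller index and
flagged. Averaging order throughout histomorphometry is sections →
specimen → group. The calcein rate is distance/(hours/24), so the standard
48-h chase halves the distance. Welch's t uses the Satterthwaite df and is
delegated to scipy, cross-checked in the tests against the closed form and
a quadrature tail integral. Sex labels are carried but not stratified by
default.

## Synthetic data: what it emulates

The generators reproduce the study design: 4 replicates per each of
mouse/jerboa × TV1/TV6; NB counts with species-specific transcript lengths
(mouse lengths log-normal around 2 kb, jerboa/mouse log-ratio sd 0.3, 2%
one-to-zero); per-sample size factors uniform on [0.7, 1.3]; and a single
per-gene ground truth from which all three contrasts derive
(mouseTV1 = baseline, mouseTV6 = baseline + Δvert,
jerboaTV1 = baseline + lfc_TV1, jerboaTV6 = baseline + Δvert + lfc_TV6,
so intra-jerboa lfc ≡ Δvert + lfc_TV6 − lfc_TV1). Class fractions default
to 55% equivalent / 10% TV6-only / 2.5% PI-outlier / 32.5% null, chosen
once to mirror the observed proportions of the real analysis (roughly
one-third of orthologs both-significant, ~6% of pairs outside the PI,
TV6-only genes several-fold more numerous than outliers). The paired-LFC
line is calibrated at slope 0.883 with residual sd 0.25 and x ~ N(0, 1.5²);
the slope and replicate count are the only constants taken from the
measured biology — every other default (baseline log₂ mean 7 ± 1.5,
dispersion 0.05, TV6-only effect ±N(2, 0.3²), outlier offset
±N(1.5, 0.25²), one-to-zero rate, size-factor range) is a declared
synthetic choice. The magnitude distribution of true fold changes is not
something desk-scale information constrains; the defaults are declared,
not inferred.

Tail phantoms render each ossified diaphysis as a high plateau with 1-px
half-height edge ramps, so the half-height rule has an exact analytic
answer (an element of k pixels measures exactly k pixels); unossified
elements and inter-vertebral gaps are background, and Gaussian intensity
noise is additive. Growth series allocate a monotone body-growth
trajectory (tail:body 0.5 at birth in both species, flat through the first
week, rising to 1.0 in mouse and 1.5 in jerboa by P42) across vertebrae
with a crescendo-decrescendo pulse centered at 6.2 (peak at TV6, plateau
TV5–TV8); animal noise is a time-constant multiplicative factor so series
remain monotone. Growth-plate tables draw zone and cell heights from
normal laws, EdU labels Bernoulli per cell, and calcein distances as
2 × daily rate + noise.

What the synthetic data do *not* emulate: mean-dependent dispersion trends,
GC/mappability biases, batch effects, correlated genes, 2D/3D image
content, sequencing-level artifacts (generation starts at gene counts), or
real ontology annotations. Passing tests therefore demonstrate the
*statistical* correctness of the pipeline under its stated model, not
robustness to every artifact of real libraries.

All generators are pure functions of their configuration including the
seed; a master seed fans out to per-stage streams via `spawn_seeds`
(SeedSequence-derived, kept below 2³¹).

## Problem sizes and numerical choices

Simulation-based checks use 2000 genes × 16 samples (single datasets) and
20 replicates for the FDR experiment; interval-coverage experiments use
5000 training and 5000 held-out points — sizes at which the Monte-Carlo
error of each checked quantity is several times smaller than its tolerance,
while the full suite runs in about a minute. Newton fits clip steps at ±5
on the log scale and stop at 10⁻¹² step size; dispersion grids span
[10⁻⁸, 30]; degenerate inputs (flat profiles, zero-variance groups,
all-zero genes, empty universes, Sxx = 0) raise informative errors rather
than propagate NaNs.

## Known limitations

* No empirical-Bayes LFC shrinkage: reported LFCs are MLEs. Downstream
  classification uses padj and sign only, which shrinkage would not change,
  but LFC magnitudes for low-count genes are noisier than shrunken ones.
* FDR control is demonstrated under the simulator's homogeneous-dispersion
  conditions; with strongly gene-heterogeneous dispersions the trend prior
  widens and calibration degrades toward the gene-wise estimator's.
* No independent filtering, Cook's-distance outlier handling, or
  multi-factor designs beyond the three named contrasts.
* The PI-outlier rule inherits OLS assumptions; heavy contamination of the
  both-significant set inflates s_e and widens the interval, lowering
  outlier recall (the default study conditions keep contamination ≈ 6%).
* Gene-name collation is exact-match only; no alias or ID mapping.
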