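# axoprop

Cross-species transcriptomics and vertebral morphometrics for studying how
skeletal proportion evolves — specifically, which genes are associated with
the disproportionate elongation of mid-tail vertebrae in the lesser Egyptian
jerboa (*Jaculus jaculus*) relative to the laboratory mouse.

The package is aimed at researchers running intersectional bulk RNA-seq
comparisons between homologous skeletal elements of two species, plus the
morphometric measurements that motivate them (µCT vertebral lengths,
growth-plate histomorphometry). Every pipeline input can also be simulated
with planted ground truth, so the statistical behavior of the whole analysis
(FDR control, interval coverage, candidate recovery) is testable.

## The analysis

Tail vertebra 6 (TV6) elongates disproportionately faster in jerboa than in
mouse, while TV1 grows similarly in both species. Genes driving that
disproportion should be *disproportionately differentially expressed* in
jerboa TV6. With log₂ fold changes (LFC) from three negative-binomial Wald
contrasts —

* x = interspecies TV1 (jerboa vs mouse),
* y = interspecies TV6 (jerboa vs mouse),
* intra = intra-jerboa (TV6 vs TV1),

all at Benjamini–Hochberg padj < α = 0.05 — the classification is:

* **A** — significant in y but not in x (TV6-only genes);
* **B** — significant in both, with y outside the 95% prediction interval
  of the OLS regression ŷ = a + b·x fitted over the both-significant set,
  using the textbook interval for a new observation,
  t₍ₙ₋₂₎ · s_e · √(1 + 1/n + (x₀ − x̄)²/Sxx);
* **candidates** — genes in D = A ∪ B that are also significant in the
  intra-jerboa contrast with sign(intra LFC) = sign(y LFC).

Because orthologous transcripts have different annotated lengths in the two
genomes, interspecies contrasts add a per-gene offset
ln(L_species / √(L_mouse·L_jerboa)) to the GLM log-mean, testing expression
net of annotation-length asymmetry. Candidates are then checked for
enrichment (hypergeometric) and for overlap with external limb-proportion
gene lists (one-sided Fisher exact, BH across lists).

The morphometrics module measures vertebral diaphysis lengths from 1D µCT
intensity profiles (half-height edge crossings with sub-pixel interpolation,
pixel = voxel × resize µm), normalizes lengths to the naso-anal distance,
builds weekly growth-change matrices, and computes calcein growth rates,
EdU proliferative indices and Welch's t tests.

## Worked example

Run the default simulated study (2000 genes; 4 replicates per each of
mouse/jerboa × TV1/TV6; negative-binomial counts at dispersion 0.05; 55%
of genes equivalently DE along a planted line of slope 0.883, 10% TV6-only,
2.5% prediction-interval outliers):

```sh
axoprop run --seed 1 --outdir demo
```

which logs

```
stage disproportionality: |A|=291 |pairs|=649 |B|=31 |candidates|=229
```

and writes `demo/report.md`:

```
- genes × samples: 2000 × 16
- TV6-only (A): 291
- both-significant pairs: 649
- outside 95% prediction interval (B): 31
- union D = A ∪ B: 322
- sign-consistent candidates: 229

Fitted line: slope=0.909, intercept=-0.004, R²=0.905, n=649
```

Reading: 649 genes were DE between species in both vertebrae and their TV6
LFCs track their TV1 LFCs along a line of slope ≈ 0.9 (near the planted
0.883; the mild excess comes from the planted outliers sitting in the fitted
cloud). 31 of them fall outside the 95% prediction interval; together with
the 291 TV6-only genes they give 322 disproportionate genes, of which 229
also change in the same direction within the jerboa (TV6 vs TV1). Against
the planted truth (234 ground-truth candidates) this run attains precision
0.94 and recall 0.92. Full outputs: per-contrast DE tables, the pair table,
`fit.json`, the category/candidate tables, `manifest.json` and a scatter of
y vs x with the prediction-interval band (`lfc_scatter.png`).

Other entry points: `axoprop simulate|de|intersect|enrich|overlap|measure|
growth|stats` (see `--help` for each), e.g.

```sh
axoprop measure --profile vertebra.csv --voxel 9 --resize 3
```

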