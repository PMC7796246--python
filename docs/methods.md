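# Methods

## Synthetic TMA cores

A core is a disc of `core_diameter_px` pixels (default 900 px at
0.5 µm/px ≈ a 0.45 mm core).  Tumour nests are smooth random blobs —
perturbed circles with low-order cosine modulation of the radius — sized so
that the requested intratumoural cell population fits at the minimum centre
separation; nest area never exceeds 55% of the core, otherwise generation
fails with an explicit placement error naming the parameter to relax.

Cells are placed by dart throwing with a minimum centre separation of
3 nucleus radii (1.5 nucleus diameters, ≈ 9 µm at the defaults), a
physically plausible epithelial packing.  Tumour cells are placed inside
nests with a half-radius interior margin, so that a detected centroid (the
detector is accurate to ~1–2 px) can never fall outside the nest polygon;
this keeps the point-in-nest test used by the naive gating order sharp.
Immune cells (macrophages, T-cells) are split between nest interior and
stroma by `intratumoural_immune_fraction`; remaining stromal cells go
outside nests.  Lineage counts follow the configured fractions with
rounding; coordinates are 0-based pixel indices, x right / y down.

**PD-L1 assignment.**  Among tumour cells, exactly
`round(tps_true/100 × n_tumour)` cells are PD-L1⁺ (quota sampling), so the
true TPS is recoverable to within the quota rounding `100/(2 n_tumour)`; a
Bernoulli mode (`pdl1_bernoulli`) is available when sampling noise in the
truth itself is wanted.  Macrophages and T-cells are PD-L1⁺ with their own
Bernoulli probabilities — these are the confounders that make gating order
matter.

**Rendering.**  DAPI is a Gaussian blob per nucleus (σ = 0.55 r); CK, CD68
and CD8 are cytoplasmic discs of radius 2 r on their lineages; PD-L1 is a
membrane annulus (1.15 r – 1.9 r) with randomised angular coverage drawn
uniformly from 25–100% on positive cells, emulating partial or complete
membrane staining.  Per-cell amplitudes vary ~±10%.  Background, i.i.d.
Gaussian noise and an optional channel-crosstalk mixing matrix are then
applied and intensities clipped at zero.  Real scanners' intensity scales
are arbitrary and instrument-specific, so the simulated scale
(signal ≈ 1, background 0.05, noise sd 0.05) is a free choice, documented
here once; the phenotype thresholds below are calibrated to it the same way
an assay's thresholds are agreed against its own staining batch.

**Serial sections.**  The chromogenic slide of a core is an emulated
*adjacent* section: every cell's centroid is jittered isotropically
(sd `section_jitter_px`, default 2 px) and cells drop out independently
with `section_dropout_prob` (default 0.05).  Labels are preserved on
survivors.  This reproduces the fact that paired modalities never observe
exactly the same cells.

**H-DAB rendering.**  Haematoxylin optical density is deposited at every
nucleus; DAB OD (default level 0.3) as a filled cytoplasmic disc on
marker-positive cells — the DAB reaction product is diffuse, so membrane
markers also fill the cell footprint in brightfield.  RGB is the
Beer–Lambert transform through the standard unit-norm H/DAB stain vectors,
quantised to 8 bits.

## Segmentation

Detection mirrors classical watershed cell detection: Gaussian smoothing
(σ = 1.5 px), a global threshold (Otsu by default, fixed value optional),
Euclidean distance transform, h-maxima seeds (h = 2 px) and watershed,
then a minimum-area filter (10 px²).  Two numerical choices matter:

- seed fragments closer than ~4 px are fused (the seed mask is dilated by
  2 px before labelling); image noise can crack one plateau maximum of the
  distance map into fragments a pixel apart, which would over-split nuclei;
- a blank or constant image returns zero detections rather than an error.

Whole-cell regions grow each nucleus outward by `cell_expansion_um`
(default 5 µm) with nearest-nucleus assignment of contested pixels, so
regions are disjoint and each nucleus is a subset of its cell.  Per-cell
mean intensities are measured in both compartments.

**Colour deconvolution.**  RGB → OD (−log₁₀ transmittance) → per-pixel
least squares onto the two stain vectors, weighted by I² per colour channel
(8-bit quantisation noise has OD standard deviation ∝ 1/I, so weights are
inverse variances).  This keeps the round-trip error of render → deconvolve
below 0.02 OD over the whole [0,1]² OD range, which unweighted projection
does not quite achieve near saturation.  Negative projections clip to zero.

## Phenotyping

Rules are `(label, channel, compartment, threshold, comparator)` with ≥ as
the default comparator, so a value exactly at threshold counts positive
(deterministic boundary behaviour).  The cascade applies lineage rules in
order, first match wins, fall-through to `other`; a CD8⁺CD68⁺
double-positive is resolved by cascade position, which is why order is part
of the configuration.  The optimised default order is **CD8 → CD68 → CK**,
with PD-L1 evaluated only within the CK⁺ tumour class.

Default thresholds on the synthetic intensity scale: 0.2 (whole-cell) for
CD8/CD68/CK, 0.10 for PD-L1 — chosen midway between the negative
(background + neighbour bleed-through) and positive (worst-case 25% annulus
coverage) intensity distributions of the simulated assay.  `auto_threshold`
offers Otsu (plateau-midpoint variant: for well-separated modes the
between-class variance is flat across the gap, and we return the plateau
centre rather than its first bin) and a two-component Gaussian-mixture
midpoint; it is a helper, never applied silently.

**Naive ordering.**  `naive_pdl1_first` evaluates PD-L1 on every cell
before lineage assignment; a cell enters the numerator if PD-L1⁺ and inside
the tumour region (truth nest polygons by default for sharpness; a binary
mask is also accepted).  The denominator is kept identical to the cascade's
CK⁺ class so the comparison isolates the numerator inflation — by
construction the naive numerator is a superset of the cascade numerator,
hence naive TPS ≥ cascade TPS always, strictly whenever at least one
PD-L1⁺ intratumoural immune cell was segmented.

## Scoring

TPS = 100 · n(CK⁺ PD-L1⁺)/n(CK⁺).  Cores with no CK⁺ cells are flagged
`non-evaluable`, never scored 0.  Clinical bins: [0,1) → `<1%`,
[1,50) → `1–49%`, [50,100] → `≥50%`; a score of exactly 50 is high
expression, following standard TPS practice (the inclusive-50 convention is
the one genuinely open choice here and is fixed prominently).

**DAB path.**  Cells are detected on the deconvolved haematoxylin channel;
a positive tumour cell is one in the tumour compartment whose mean DAB OD
is ≥ 0.15.  The per-cell DAB OD is summarised over the *nuclear* footprint:
the simulated chromogen disc fully covers its own nucleus (so a cell
rendered at OD 0.3 measures 0.3 exactly) while barely touching neighbours'
nuclei, keeping bleed-through well under threshold; whole-cell DAB OD is
also measured and exposed.  The tumour compartment comes from the nest-mask
(the stand-in for a classifier trained on pathologist annotations — a
deliberate simplification, since the mask cannot exclude intratumoural
immune cells any more than a tumour/stroma classifier can).  This is why
the DAB path genuinely overcalls near the `<1%` boundary when PD-L1⁺
macrophages infiltrate nests, mirroring practice.

## Concordance

R² is the squared Pearson correlation (for paired same-scale scores this
coincides with the least-squares fit statistic).  Spearman ρ uses mid-ranks
for ties.  Categorical concordance reports the 3×3 crosstab, concordant
percent (1 decimal, round-half-even), and the discordance split into
overcalls by either side.  Non-evaluable cores are excluded pairwise with a
logged count.  A `manual_flags` pass-through carries per-core review notes
(for cores whose ground truth is hard to discern); no computable definition
exists for that class, so it is metadata only.

The packaged modality-concordance cohort draws each core's immune make-up
(immune fractions, intratumoural split, immune PD-L1 rates) from ranges, so
cores differ the way TMA cores do.  Its categorical concordance runs lower
than a pathologist-curated cohort would show, for a structural reason: at a
few hundred tumour cells per core the `<1%` bin spans only one or two
cells, so a single PD-L1⁺ intratumoural macrophage tips the chromogenic
path over the boundary.  The informative outputs are the direction of the
disagreement — overcalls come overwhelmingly from the DAB side — and the
near-unity score-scale correlation.

## Experiment problem sizes

The packaged experiments use: 50 cores × 500 cells (parameter recovery,
true TPS drawn uniformly from 2–95%), 20 cores × 300 cells at true TPS 45%
with 80% PD-L1⁺ macrophages (order effect), 45 cores × 300 cells spread
evenly over the three categories (modality concordance), and 40 ROIs of
60–200 cells (serial-section correlation).  These sizes give stable
statistics in a few minutes on one CPU; all are parameters of the
experiment functions.

## What the simulation does not model

No autofluorescence, photobleaching, tissue-thickness or focus variation;
no spectral unmixing residuals beyond the linear crosstalk matrix; nuclei
are circular with a fixed radius; no necrosis/fold artefacts and no manual
QC step; single cores only, no whole-slide dearraying.  Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis chain — segmentation, gating order, scoring arithmetic, agreement
statistics — under controlled conditions, not the calibration of any
specific scanner or staining chemistry.
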