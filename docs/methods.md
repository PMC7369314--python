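# Methods

This note documents the models, procedures, parameter choices, and known
limitations of the `dgquant` pipeline: automated fluorescence cell counting,
section-series stereology, co-expression phenotyping, trajectory summaries,
and the synthetic-data generators the tests are built on.

## Cell counting (`dgquant.counting`)

### Procedure

Input is an 8-bit micrograph (0 = black, 255 = white) and a boolean ROI
mask of the freehand-traced region. The chain is:

1. **Grayscale conversion** — RGB collapses with ITU-R BT.601 luminance
   weights (0.299, 0.587, 0.114); grayscale passes through unchanged.
2. **Background estimation** — grayscale morphological opening (erosion
   then dilation) with a disk of radius `disk_radius_px` (default 10 px,
   matched to the average soma). Opening removes every bright structure
   strictly smaller than the disk, so the cells vanish while illumination
   gradients and super-cellular structures remain. The output is pixelwise
   ≤ the input.
3. **Iterated subtraction with saturating contrast** — each of
   `n_subtractions` passes (default 4) subtracts the *original* background
   image from the current image, clips at zero, and applies a saturating
   linear stretch over the ROI: values map by `255 · v / (0.72 · max)` and
   clip at 255.
4. **Binarization and size filtering** — Otsu's threshold over the
   *positive* ROI pixels, connected-component labeling (8-connectivity),
   and removal of components with pixel area outside
   `[size_min_px, size_max_px]` (defaults [31, 943] = 10%–300% of the
   nominal cell area π·10² ≈ 314 px) or with centroid outside the ROI.

### Why the contrast stretch saturates

The stretch operator was the one genuinely open design point. A plain
min–max rescale is unstable under iteration: writing one pass as
`v → a·(v − b)` with gain `a` and local background level `b`, min–max gives
`a` barely above 1, the map's fixed point sits above the data range, and
every pixel value — including the flanks of genuine cells — decays a step
per pass. Empirically spot areas shrink by ~30 px per pass and drop below
the minimum size bound by the fifth pass, collapsing counts exactly in the
regime where the pass count should not matter.

With saturation at `0.72 × max`, cell cores clip to 255 and stay there: a
saturated plateau survives the next subtraction whenever
`(255 − b)/0.72 ≥ 255`, i.e. for background levels up to ~71 of 255, while
everything dimmer — noise residue, shading leftovers, large structures the
opening preserved and the subtraction removed — decays geometrically. This
is also what 8-bit saturating arithmetic does implicitly in image-processing
environments where such pipelines are usually prototyped. The result is the
behavior the method depends on: counts essentially identical at 3, 4, and 5
passes on clean fields, and r > 0.99 between 4- and 5-pass counts across a
heterogeneous batch.

The anchor 0.72 satisfies the plateau-stability bound for the default
imaging condition (background 40 + gradient up to 30) with margin against
sensor noise; pushing it above ~0.8 erodes plateaus on the bright side of
the gradient, pushing it below ~0.7 slows the decay of noise residue enough
that sparse images accumulate false components at 3 passes.

### Why Otsu runs on positive pixels only

After clipped subtraction most background pixels are exactly zero. Zero
carries no information about the cell/residue boundary, but it dominates
the histogram; full-ROI Otsu then maximizes between-class variance by
splitting {zero} from {everything else}, placing the threshold inside the
noise residue. On sparse images this admits ~100-px noise clusters as false
cells. Restricting the histogram to positive pixels restores the intended
bimodal problem (residue vs cells). Degenerate inputs are handled
explicitly: an ROI that is constant (or all zero) yields zero components,
not an error; an already-binary image thresholds between zero and its
single positive value.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `disk_radius_px` | 10 | opening structuring element; match to soma radius |
| `n_subtractions` | 4 | subtraction passes; 3–5 give equivalent counts |
| `threshold_method` | otsu | or `fixed` with an explicit level |
| `size_min_px`, `size_max_px` | 31, 943 | 10%–300% of nominal cell area |
| `connectivity` | 8 | component connectivity |
| `SATURATION_FRAC` | 0.72 | contrast-stretch saturation anchor |

The counter assumes cells are *brighter* than their local background and
*smaller* than the structuring element. Cells larger than the disk partly
survive the opening, depress their own contrast after subtraction, and are
undercounted — the disk radius must track the cell size.

## Stereology (`dgquant.stereology`)

Totals: summed per-section counts × sampling interval (default 10).
Volumes: Cavalieri's principle, summed traced areas (mm²) × effective
spacing = thickness (30 µm) × interval = 300 µm = 0.3 mm. Density:
total / volume, cells/mm³; the identity `density × volume = total` holds to
float rounding by construction. Units are fixed (areas mm², thickness µm,
bregma mm) and converted in a single helper to avoid factor-of-10³ slips.

Dorsal/ventral assignment: dorsal = bregma ∈ (−4.52, −1.80], ventral =
[−6.80, −4.52]. The two published ranges share the −4.52 endpoint; the
shared boundary goes to ventral (the ventral range being the closed one),
making the classification a true partition — property-tested over the full
range. Counts from one hemisphere are reported per counted volume, not
doubled.

Image-derived counts (e.g. Sox2 from 20× fields) are per-ROI-area
quantities; section-series counts are per-mm³. The two are kept distinct
and never mixed.

## Phenotyping (`dgquant.phenotyping`)

The co-expression estimator samples 50 labeled cells per animal uniformly
without replacement (seeded); the percentage is `100·k/n`. When fewer than
50 labeled cells exist, all are used and the record carries an
`under_target` flag rather than being silently accepted or dropped. The
estimator is unbiased with SD `100·√(p(1−p)/50)` (≈ 6.9 points at p = 0.6),
verified by simulation.

DCX morphology staging is symbolic — it classifies descriptors (process
class, reaches molecular layer, branches in molecular layer), not pixels,
because the underlying assessment is visual; automated neurite tracing is
out of scope. Type C iff a dendrite branches within the molecular layer;
else type B iff processes are medium/apical or reach the molecular layer;
else type A. The classifier is total over the finite descriptor space
(exhaustively tested) and the descriptor invariant (branching implies
reaching) is enforced at construction.

Proestrus rules: estradiol ≥ 50 pg/ml (inclusive, "or higher"); lavage
nucleated-cell fraction ≥ 0.70. Whether exactly 70% qualifies is not
specified in the source convention; inclusive was chosen and is documented
here and in the docstring.

## Trajectory summaries (`dgquant.trajectory`)

Group tables report n, mean, and SEM (sample SD, n−1, over √n) per
sex × region × time; single-animal groups report a mean with SEM absent
(NaN), never zero. Attrition is the signed percent change of the group mean
between two time points. Cohen's *d* uses the (n−1)-weighted pooled SD;
partial η² is provided as the primitive `SS_eff/(SS_eff+SS_err)` only —
reconstructing any particular ANOVA's denominators requires raw data the
pipeline does not presume. Repeated-measures ANOVA and post hoc machinery
are intentionally not reimplemented; the tidy long-format CSV is the
interface to external stats software. Proestrous animals are flagged, not
excluded.

## Synthetic data (`dgquant.synth`)

### Micrographs

Cells render as truncated Gaussian spots (σ = radius/2, cut at 3σ) —
smoother than hard disks and closer to slightly defocused somata — at
default radius 10 px with ±10% uniform jitter, peak 200 over background 40,
on a horizontal linear gradient of amplitude 30, with Gaussian sensor noise
(SD 8) and two artifact classes that straddle the size filter: "small"
(< 10% of nominal cell area, rendered at cell intensity) and "large"
(> 300%, rendered as a dim plateau — large structures survive the opening
and are removed by subtraction, small ones fall to the size filter). Cell
centers are placed by seeded rejection sampling with pairwise separation
≥ 40 px (4× radius); unsatisfiable requests raise an explicit placement
error rather than degrading silently. The ROI is a rectangle inset 25 px
from the frame — more than the disk diameter — because a freehand trace
never hugs the image border and the opening is boundary-distorted there.
Pixels are the only length unit; no physical pixel size is assumed.

Radius jitter is 10% rather than larger: at ±15% the smallest cells on the
bright side of the gradient stabilize at plateau areas just under the 31-px
size minimum and drop out at 4–5 passes; ±10% keeps every cell above the
filter while preserving visible size heterogeneity.

What the generator does **not** emulate: point-spread blur and chromatic
channels, clustered or touching somata, intensity variation between cells
beyond radius jitter, tissue autofluorescence texture, or non-linear
shading. Passing counts on these images therefore demonstrate correctness
of the algorithmic chain under its stated assumptions (bright, separated,
sub-disk cells), not performance on arbitrary real tissue.

### Section series

Cells are placed by a uniform 3-D Poisson process through the *full* stack:
the total is one Poisson draw on density × stack volume, and per-section
counts are a multinomial split proportional to slab volumes. Systematic
1-in-k sampling starts at a seeded random offset. Because counts come from
slab membership of actually-placed cells — not independent per-section
Poisson draws — exhaustive sampling (interval 1) returns counts summing to
the true total *exactly*, and the interval-k estimator is unbiased over
random offsets (verified by Monte Carlo at 500 stacks, bias < 2%).

### Cohorts

Per-animal densities are log-normal around group-truth means (CV 0.25):
densities are positive and right-skewed, and log-normal noise cannot
produce negative animals at small n. Co-label counts are binomial over the
50-cell sample at the group-truth probability; DCX stage mixtures are
multinomial over the DCX-positive subsample. Female hormone state follows
the study design: lavage cytology at the acute time points (10% proestrous
rate), serum estradiol (log-normal, mean 14.41 pg/ml, CV 0.30 — below the
50 pg/ml cutoff with overwhelming probability) in the week groups; male
testosterone log-normal with mean 1.07 ng/ml. The default group size is 4,
mirroring a 22-per-sex cohort split over five time points.

The default calibration table is **illustrative**: round numbers encoding
the qualitative structure of the study system (male dorsal BrdU trajectory
9 000 → 10 000 → 20 000 → 10 000 → 8 000 cells/mm³, i.e. a 1-week peak at
exactly twice the 2-week value so designed attrition is −50%; females flat
at 7 000; NeuN probability 0.12/0.70/0.90 in males vs 0.12/0.30/0.90 in
females at 1/2/3 weeks; Sox2 co-label decay 0.95 → 0.05; male-leading Ki67
and dorsal Sox2 densities, female ventral > dorsal Sox2 gradient). They
are generator truths to be recovered, not measured group means.

## Problem sizes and tolerances

Test and analysis scale was chosen for tight statistical checks at
interactive runtimes: 24–50 micrographs per counting batch, 500 simulated
stacks for stereology bias (< 2% tolerance ≈ 3 SE), 10⁴ replicates for
estimator calibration (0.5-point tolerance on percentages, 0.03 on Cohen's
*d*), and cohorts of 30–100 per group for recovery tests at 3-SEM
tolerance. All randomness flows through explicit integer seeds;
regenerating any figure or table is exact.

## Known limitations

- The counter's accuracy claims hold for separated cells (≥ 4× radius);
  touching somata merge into single components and there is no watershed
  split.
- Otsu assumes some foreground exists; a field with zero true cells yields
  zero counts only because nothing passes the size filter, and extremely
  dense fields (foreground majority) would bias the threshold.
- The size-filter bounds are pixel counts; they must be rescaled for other
  magnifications.
- Partial η² values from any specific repeated-measures design cannot be
  reproduced from group summaries alone; only the primitive is provided.
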