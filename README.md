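# dgquant

Quantification pipeline for adult hippocampal neurogenesis studies: automated
fluorescence cell counting, Cavalieri stereology, co-expression phenotyping,
and sex × time trajectory summaries — with a ground-truthed synthetic-data
generator so every stage is testable end to end without microscope data.

## The scientific problem

Studies of adult neurogenesis in the dentate gyrus (DG) birth-date dividing
progenitors with BrdU and follow the labeled cohort across maturation time
points (2 h, 24 h, 1, 2, 3 weeks), comparing sexes and hippocampal regions
(dorsal vs ventral). The measurement chain behind such a study is:

1. **Cell counting.** Immunoreactive (-ir) cells appear as bright
   quasi-circular blobs in 8-bit fluorescence micrographs. The counter
   estimates the background by grayscale morphological opening with a disk
   structuring element matched to the cell radius (10 px) — opening removes
   every bright structure the disk cannot fit inside, i.e. the cells — then
   repeatedly subtracts that background from the image with a saturating
   contrast stretch between passes (default 4, useful range 3–5), binarizes
   with Otsu's threshold inside the user-traced ROI, and discards connected
   components outside plausible cell-size bounds.
2. **Stereology.** Cells are counted on every 10th 30-µm section; the region
   total is the summed count × 10, the region volume follows Cavalieri's
   principle (summed traced areas × 300 µm effective spacing), and density
   is their ratio in cells/mm³. Sections are assigned to dorsal
   (bregma −1.80 to −4.52 mm) or ventral (−4.52 to −6.80 mm) DG.
3. **Phenotyping.** Marker co-expression (NeuN, DCX, Sox2 on BrdU⁺ cells) is
   estimated from a random 50-cell sample per animal: `pct = 100·k/50`, and
   double-label densities as `density × pct/100`. DCX⁺ cells are staged
   A/B/C by dendritic morphology; proestrus is classified by serum estradiol
   ≥ 50 pg/ml or ≥ 70% nucleated epithelial cells in vaginal lavage.
4. **Trajectories.** Per-animal endpoints aggregate to mean ± SEM per
   sex × region × time, 1w→2w attrition (`100·(m₂−m₁)/m₁`), and effect sizes
   (Cohen's *d* with pooled SD, partial η²). Omnibus ANOVA is deliberately
   out of scope — the tidy tables feed any stats package.

The synthetic-data module generates micrographs with known cell positions,
section stacks with known cell totals (uniform 3-D placement, so exhaustive
sampling conserves the total exactly), and cohorts with known group-level
truths (male 1-week density peak with ~50% attrition, flat females, faster
male NeuN maturation, both sexes ~90% NeuN⁺ at 3 weeks).

## Worked example

```python
from dgquant.synth import ImageSpec, generate_micrograph
from dgquant.counting import CountParams, count_cells

image, roi, truth = generate_micrograph(ImageSpec(n_cells=20, seed=7))
res = count_cells(image, roi, CountParams(n_subtractions=4))
print(truth.n_cells, res.n_cells, res.roi_area_px, res.cell_area_px)
# 20 20 213444 2090
```

The counter found exactly the 20 cells the generator placed; the ROI trace
covers 213 444 px and the detected somata 2090 px. The same chain at study
scale (`python analysis/02_count_cells.py`, 24 images spanning 7–57 true
cells with gradients, noise, and artifacts) prints:

```
self-consistency r (4x vs 5x passes): 0.9995
agreement with ground truth (4x):     1.0000
worst absolute count error at 4x:     0 cells
```

and the cohort chain (`python analysis/04_cohort_trajectories.py`) recovers
the designed trajectory structure:

```
1w -> 2w attrition (% change in group mean):
   sex  region  attrition_1w_to_2w_pct
  male  dorsal              -48.189850
  male ventral              -49.099964
female  dorsal                2.725131
female ventral               -1.678102

%NeuN+ of BrdU-ir cells at 3 weeks:
  male   dorsal: 90.9 +/- 0.7 (n=30)
  female dorsal: 89.3 +/- 0.6 (n=30)
```

The analysis drivers under `analysis/` (01 simulate images, 02 count,
03 stereology recovery, 04 cohort trajectories) write their tables under
`results/`. A thin CLI is also available: `dgquant count --image a.tif
--roi a.roi.png --out counts.csv`, `dgquant stereology`, `dgquant
trajectory`, `dgquant simulate-image`.

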