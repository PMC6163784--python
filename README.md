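# stainquant

Quantitative image analysis for multi-donor cell-culture differentiation
studies, plus the nonparametric statistics that compare their outcomes.

Mesenchymal progenitor (stromal) cell characterisation relies on trilineage
differentiation assays read out by histological dyes — Oil Red O for lipid
(adipogenic), Alcian blue for cartilage glycosaminoglycan (chondrogenic),
von Kossa for mineralised matrix (osteogenic) — together with phase-contrast
confluency, LIVE/DEAD viability staining and manual histology scoring.
`stainquant` turns these images into per-sample numbers reproducibly:

* **Illumination correction** from brightfield/darkfield references:
  `corrected = (original − darkfield) / (brightfield − darkfield)`.
* **Color deconvolution** in optical density. Per pixel,
  `OD = −log10(I) = Σ_s c_s·v_s` (Beer–Lambert), so dye concentrations
  `c` come from a 3×3 linear solve. Stain vectors are polar-parametrised
  unit vectors in the nonnegative OD octant; two-dye kernels are completed
  by a cross-product residual. A deterministic coordinate-descent estimator
  refines kernel angles on an image collage (replacing interactive tuning)
  and writes a static QC report.
* **Segmentation**: a local-adaptive cell mask (threshold
  `1.1·μ − 0.3·σ` over a 30/60-px window on the negated luminance at 512-px
  working width), a global-Otsu pellet mask with disk-4 closing and
  largest-component selection, and a `mean + 0.07` confluency mask.
* **Assay metrics**: masked dye-mass ratios (Oil Red O : hematoxylin,
  Alcian blue : nuclear fast red), pellet and cell areas, inverted mean
  brightness for von Kossa, confluency percent, dead-cell spot counts, and
  0–10 histology score totals.
* **Statistics**: Friedman tests over donor-blocked conditions with paired
  Wilcoxon signed-rank post-hocs (exact where feasible, with brute-force
  enumeration oracles in the tests), efficiency-corrected qPCR expression
  ratios `E_t^ΔCt_t / E_ref^ΔCt_ref`, within-donor fold-change
  normalisation, and generation times `t·ln2 / ln(n1/n0)`.
* **Synthetic data**: forward renderers (stained scenes under a vignette,
  LIVE/DEAD spot fields) and a lognormal random-effects cohort simulator,
  all seeded and with exact ground truth, so the entire pipeline is testable
  without any raw images.

## Worked example

```python
import numpy as np
from stainquant import (preset_kernel, adipogenic_metrics,
                        AdaptiveThresholdParams, count_dead_cells,
                        simulate_cohort, CohortSpec, wilcoxon_signed_rank)
from stainquant.synthetic import (adipogenic_scene, render_livedead_image,
                                  render_stained_image)

# render an adipogenic culture: cells carrying 0.8 OD Oil Red O + 0.2 OD
# hematoxylin, under a 30% vignette, and quantify it with its own calibration
kernel = preset_kernel("oilredo_hematoxylin")
scene = adipogenic_scene(kernel, lipid_od=0.8, nuclei_od=0.2,
                         vignette_strength=0.3, seed=42)
rendered = render_stained_image(scene, kernel)
m = adipogenic_metrics(rendered.image, rendered.calibration, kernel,
                       AdaptiveThresholdParams(region_size=30, work_width=256))
print(f"cell area fraction : {m.area_fraction:.3f}")
print(f"Oil Red O : hematoxylin ratio = {m.dye_ratio:.3f}")

# count dead cells in a LIVE/DEAD field with 25 planted red spots
field = render_livedead_image(n_live=30, n_dead=25, seed=7)
print("dead cells counted:", count_dead_cells(field.red).dead_count)

# a 7-donor cohort with a true 2x condition effect at 20% noise CV
cohort = simulate_cohort(CohortSpec(conditions=("control", "TNFa-high"),
                                    condition_effects={"TNFa-high": 2.0},
                                    days=(1,), noise_cv=0.2, seed=3))
wide = cohort.pivot_table(index="donor", columns="condition", values="value")
res = wilcoxon_signed_rank(wide["TNFa-high"], wide["control"])
print(f"Wilcoxon W = {res.statistic:.0f}, p = {res.pvalue:.4f} (n = {res.n})")
```

Output:

```
cell area fraction : 0.766
Oil Red O : hematoxylin ratio = 4.000
dead cells counted: 25
Wilcoxon W = 0, p = 0.0156 (n = 7)
```

The dye ratio recovers the generating 0.8/0.2 mixture exactly; the cell-area
fraction includes the mask's window-wide neighbourhood around each cell (the
local-adaptive rule restricts analysis to generous cell regions — see
`docs/methods.md`). The Wilcoxon p = 2/2⁷ is the smallest attainable
two-sided value at n = 7, as expected when all seven donors move the same
way under a 2× effect.

A `stainquant` command-line driver wraps the same functions for batch runs
(`adipo`, `chondro`, `osteo`, `confluency`, `livedead`, `score`,
`kernel-estimate`, `stats`, `simulate`); each run writes a tidy results CSV
and a JSON manifest capturing version, parameters and skipped files.

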