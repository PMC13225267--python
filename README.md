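# mtasym

Shape- and volume-asymmetry analysis of the mesial temporal structures
(hippocampus and amygdala) for case-control neuroimaging studies — e.g.
asking whether people with cognitive impairment and co-morbid epilepsy show
a locally smaller left hippocampal head than their matched peers.

Conventional volumetry compresses each structure into one number and misses
localized change. `mtasym` instead builds a *mirrored correspondence-point
shape model*: right-hemisphere segmentations are reflected across the
sagittal plane, all shapes are rigidly aligned (no scaling — size asymmetry
is signal), and M corresponded points (512 hippocampus / 256 amygdala) are
placed on every surface by projecting a shared mean-shape template along
its outward normals. The per-point **directional left-to-right asymmetry**

```
a_i(k) = (x_i,left(k) − x_i,right-flipped(k)) · n(k)       [mm]
```

is positive where the left surface lies outside the mirrored right surface
(left locally larger). Group differences in a_i(k) are tested point-wise
with covariate-adjusted linear models (age, sex, total intracranial volume,
and CDR-global where both groups are impaired), and all M × 6 = 3072
(hippocampus) or 1536 (amygdala) p-values of the six group comparisons are
pooled into a single Benjamini–Hochberg FDR correction (q < 0.05,
two-sided). The scalar volume-asymmetry index (L − R)/(L + R) is tested
alongside. Control cohorts are selected by exact 1:k optimal
propensity-score matching (minimum total |logit-propensity| distance,
without replacement).

Because clinical MRI cohorts of this kind cannot be redistributed, the
package ships a synthetic-cohort generator that produces paired left/right
segmentations with known ground truth: a small normative left<right offset,
group-specific localized deformations (hippocampal head/body/tail, lateral/
medial amygdala), smooth measurement noise, and realistic covariates. Every
stage of the pipeline is validated against that ground truth.

## Worked example

Inject a 2 mm inward deformation of the *left hippocampal head* in the
nonAD_Epi group only (30 participants per group, 0.5 mm surface noise),
run the full pipeline, and ask where the significant points land:

```python
import numpy as np
from mtasym.synthetic import CohortConfig, EffectSpec, generate_cohort
from mtasym.pipeline import analyze_structure

effect = EffectSpec("hippocampus", "head", "left", amplitude=2.0,
                    spatial_sigma=4.0, affected_groups=frozenset({"nonAD_Epi"}))
cfg = CohortConfig(
    n_per_group={g: 30 for g in ("AD_Epi", "nonAD_Epi", "AD_NoEpi",
                                 "nonAD_NoEpi", "HC")},
    structures=("hippocampus",), seed=42, effects=(effect,))
covariates, masks = generate_cohort(cfg)
model, table, results = analyze_structure(covariates, masks,
                                          "hippocampus", n_points=512)
print("pooled family size:", len(results))
sig = results[results["significant"]]
print("significant (comparison, point) results:", len(sig))
print(sig.groupby(["comparison", "sign"]).size())
print("mean HC volume-asymmetry index: %.4f"
      % table.volume_asym[covariates["group"] == "HC"].mean())
```

prints

```
pooled family size: 3072
significant (comparison, point) results: 47
comparison                sign
AD_Epi_vs_HC              left_larger      2
nonAD_Epi_vs_HC           left_larger      1
                          left_smaller    24
nonAD_Epi_vs_nonAD_NoEpi  left_smaller    19
nonAD_NoEpi_vs_HC         left_larger      1
dtype: int64
mean HC volume-asymmetry index: -0.0189
```

The 3072 tests are the 512 points × six comparisons entering one BH
family. The signal lands where it was injected: 43 of 47 significant
results belong to the two comparisons involving the affected nonAD_Epi
group and carry the `left_smaller` label (the left head was pushed
inward); the four stray points are the false discoveries a q < 0.05 family
is expected to admit. The HC volume-asymmetry index is slightly negative
because the generator gives everyone a 0.1 mm smaller left surface, the
normative hemispheric asymmetry.

A command-line interface wraps the same pipeline:

```
mtasym simulate --seed 1 --n-per-group 10 --out cohort/     # NIfTI + CSV
mtasym run-all --input-dir cohort/ --points 256 --out run/  # full analysis
mtasym qc run/                                              # QC flags
```

`run-all` writes groomed fields, the template and per-subject point sets
(CSV + legacy-ASCII VTK for rendering), asymmetry tables, point-wise
results with q-values and sign labels, volume tests, match tables, a QC
log, and a run manifest. Runs are byte-reproducible from config + seed.

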