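# gliaquant

Quantification of oligodendroglial lineage cells, duplex RNAscope smFISH
expression and myelin morphometry in multi-channel fluorescence microscopy
stacks — together with a synthetic scene generator that produces images
with known ground truth, so that every stage of the analysis can be scored
exactly.

## Who this is for

Labs quantifying oligodendrocyte precursor cells (OPCs) and
oligodendrocytes in confocal z-stacks of brain tissue: counting
reporter-positive (e.g. *Sox10*-GFP) cells, classifying them by
immunomarkers (NG2, PDGFRa, CC1), calling per-nucleus mRNA expression from
RNAscope puncta (e.g. *C1ql1* / *Cspg4* duplex assays), and measuring
myelination (MBP/CNP band thickness and integrated density). The package
reimplements this whole measurement chain as tested, scriptable Python.

## The measurement chain

1. **Projection** — the first *N* z-planes (default 15, step 0.68 μm) are
   reduced per pixel (max by default).
2. **Nucleus segmentation** — Gaussian smoothing → Otsu threshold →
   distance-transform watershed, followed by an exact projected-area
   filter (μm²) and label compaction. The segmenter sits behind a simple
   contract so a learned model can be swapped in.
3. **Reporter colocalization** — the reporter channel is thresholded
   (manual value or Otsu) and a nucleus is reporter-positive when at least
   half of its area overlaps the mask. These are the oligolineage cells.
4. **Marker classification** — each nucleus is dilated by 1 μm and scored
   with the background-corrected mean intensity

   `meanIntCor = meanInt − bg`

   where `bg` is the mean of the darkest 1 % of the projection; a strict
   `meanIntCor > threshold` yields the marker call.
5. **smFISH** — scale-normalized Laplacian-of-Gaussian blob detection at
   diffraction scale (σ = 0.35 μm); each punctum's area is its half-peak
   support; surfaces accumulate per nucleus and a nucleus is positive for
   a probe when its total puncta surface exceeds **1.5 μm²** (strict).
6. **Morphometry** — fiber-band thickness as the per-column full width at
   half maximum (median over columns), and rolling-ball-corrected raw
   integrated density per ROI area.
7. **Statistics** — per-scene/animal densities
   (`n / (ROI area × depth) × 10⁹` cells/mm³), mean ± SEM, percent
   reduction `100 × (1 − mean_ablated / mean_control)`, pooled
   percentages, and the unpaired Welch *t*-test.

The synthetic generator renders every signal the chain assumes (nuclear
ellipsoids at tissue densities with hard-core spacing, reporter somata,
membrane-ring and somatic markers, Poisson-count RNA puncta, fiber bands)
under a Gaussian PSF and Poisson–Gaussian noise, and returns the exact
per-cell ground truth alongside the stack.

## Worked example

Generate three control and three ablated scenes at measured oligolineage
densities (41.2 vs 13.9 × 10⁴ cells/mm³), quantify GFP⁺ density per scene
through the image pipeline only, and compare the groups:

```python
import pandas as pd
from gliaquant.studies import density_scene_spec
from gliaquant.synthetic_data import place_cells, render_stack
from gliaquant.pipeline import analyze_scene
from gliaquant.stats_reporting import build_report

rows = []
for group, density in (("control", 41.2e4), ("ablated", 13.9e4)):
    for i in range(3):
        spec = density_scene_spec(density, seed=100 + (0 if group == "control" else 50) + i)
        truth = place_cells(spec)
        stack = render_stack(truth, spec, channels=["hoechst", "gfp"])
        res = analyze_scene(stack)
        rows.append({"group": group, "unit": f"{group}_{i}",
                     "measure": "gfp_density_per_mm3", "region": "cc_center",
                     "value": res.gfp_density().density_per_mm3})
summary, text = build_report(pd.DataFrame(rows))
print(text)
```

Output:

```
Group comparison report
Data are represented as mean +/- SEM per unit (animal/scene).
Unpaired t test with Welch's correction; no multiple-testing correction applied.

gfp_density_per_mm3 [cc_center]: control 4.31e+05 +/- 3.2e+04 (n=3) vs ablated 1.36e+05 +/- 7.8e+03 (n=3); +68% reduction; t=9.059, df=2.24, p=0.008253
```

The pipeline estimates a 68 % reduction against a true generated reduction
of 66 % (1 − 13.9/41.2), with the Welch test resolving the group
difference at n = 3 scenes per group.

The same chain is available from the shell:

```sh
gliaquant simulate --config config.yaml --seed 3 --out scene/
gliaquant segment  --config config.yaml --in scene/ --out seg/
gliaquant classify --config config.yaml --stack scene/ --out cls/
gliaquant smfish   --config config.yaml --stack scene/ --out fish/
gliaquant morpho   --config config.yaml --stack scene/ --out morph/
gliaquant report   --in samples.csv --out report/
```

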