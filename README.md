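# perfusemri

Quantitative MRI analysis for machine-perfused ex vivo livers.

Machine perfusion keeps an explanted organ viable by circulating oxygenated
blood through it, and MRI of the perfused organ gives a non-invasive,
quantitative window on its vasculature, microstructure and flow.  This
package implements the image-analysis side of that workflow:

- **Vessel segmentation** of T2-weighted volumes by seeded region growing,
  with per-plane masks merged by union.
- **Skeleton-graph extraction**: a 26-neighbourhood chamfer distance
  transform (3-4-5 weights), distance-ordered topology-preserving thinning,
  line tracing into a spatial graph, polyline smoothing (10 iterations,
  smoothing 0.5, attach-to-data 0.25) and per-point radii from the chamfer
  map.
- **Vascular morphometrics**: total length and volume, branching/terminal
  node counts, coordination numbers, segment lengths, radii and tortuosity
  (curved length / chord length).
- **ADC mapping** from multi-b diffusion-weighted imaging via the
  monoexponential model `S = S0 · exp(−D·b)` (b = 90, 500, 1500,
  2000 s/mm², three orthogonal directions averaged), with background
  subtraction and vessel masking for parenchymal statistics.
- **DCE-MRI flow analysis**: voxel-wise time-to-peak (TTP) maps, ROI
  enhancement curves with repeat envelopes, bolus-front tracking along a
  centerline, and volumetric flow `Q = ¼·π·d²·v` from vessel diameter `d`
  and front velocity `v`.
- **Histopathology scoring**: a 0–3 rubric per feature (neutrophil
  infiltration, hepatocyte necrosis, sinusoidal congestion, sinusoidal
  oedema) summed to a 0–12 composite, with group summaries and a two-sample
  comparison.

Because no external image data is needed, every stage is validated by
**parameter recovery on synthetic phantoms**: bifurcating vascular trees
with known centerlines, radii and tortuosity are rasterized into volumes,
diffusion and contrast dynamics are simulated on them, and the pipeline's
estimates are compared against the known ground truth.

## Worked example

Generate a depth-4 vascular phantom, rasterize it at 0.66 mm voxels, and
recover its network by skeletonization:

```python
import perfusemri as pm
from perfusemri.morphometrics import network_summary

spec = pm.PhantomSpec(seed=1)          # depth-4 tree, root radius 5 mm
truth = pm.generate_vessel_tree(spec)
mask = pm.rasterize_tree(truth, spec)
graph = pm.mask_to_graph(mask)          # chamfer -> thin -> trace -> radii

s, t = network_summary(graph), network_summary(truth)
print(f"segments: {graph.n_segments}  branching: {s.n_branching_nodes}  terminal: {s.n_terminal_nodes}")
print(f"terminal fraction: {s.terminal_fraction:.4f} (truth {t.terminal_fraction:.4f})")
print(f"median radius: {s.median_radius_mm:.2f} mm (truth {t.median_radius_mm:.2f} mm)")
print(f"median tortuosity: {s.median_tortuosity:.3f} (truth {t.median_tortuosity:.3f})")
```

prints

```
segments: 15  branching: 7  terminal: 9
terminal fraction: 0.5625 (truth 0.5625)
median radius: 2.53 mm (truth 2.50 mm)
median tortuosity: 1.041 (truth 1.051)
```

The recovered topology is exact — 15 segments, every internal node a
bifurcation (coordination 3), 9 of 16 nodes terminal — and the median
radius and tortuosity land within ~1% and ~0.01 of the generator's ground
truth.

The full configuration-driven pipeline (phantom → segmentation → graph →
morphometrics, plus ADC, DCE and histology stages) runs from the command
line:

```bash
perfusemri run --config run.yaml --seed 1 --out run/
perfusemri morphometrics run/traced_graph.json
perfusemri histology summarize run/histology_scores.csv
```

Every run directory contains the resolved configuration and a log, and
identical configurations reproduce identical outputs.

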