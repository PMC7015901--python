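# seedmorph

Quantitative cell morphometry and proximal–distal polarity profiling for
curved plant cell layers, built around the analyses used to characterise
seed-coat endothelium polarity in *Arabidopsis*.

## The scientific problem

The innermost cell layer of the inner seed-coat integument (the
endothelium, ii1) and its sub-epidermal derivative (ii1') are curved,
one-cell-wide chains running from the chalaza (proximal) to the
micropyle (distal).  Cell size, shape and growth orientation change
systematically along this axis, and mutations in seed-coat regulators
shift those gradients — enlarging cells, flipping the direction of cell
expansion in an axis sub-domain, or tearing holes in a layer.  Testing
such claims needs per-cell shape statistics, a common axis coordinate
across specimens, and position-wise group comparisons.  `seedmorph`
implements that tool chain for segmented cell outlines (polygon tables
or integer label masks) and ships a synthetic curved-tissue generator
with analytic ground truth so the whole pipeline is testable without
imaging data.

## The statistics at the core

For each cell polygon with area *A*, perimeter *P* and periclinal
length *L* (caliper extent along the local layer tangent):

* **roundness** = 4πA / P² (isoperimetric circularity, 1 for a circle;
  an ellipse-axis-ratio variant is available behind a switch);
* **growth polarity** GP = ½(P/L − 2).  Modelling the cell as a
  rectangle with periclinal side *L* and anticlinal side *a*, GP = a/L
  exactly: GP < 1 means growth along the layer (periclinal), GP > 1
  growth across it (anticlinal).

Cells are ordered along the layer by chaining touching polygons,
parametrised by normalised arc length *s* ∈ [0, 1] of the centroid
polyline, and labelled chalazal / curving zone / micropylar by two
axis fractions (default 1/3, 2/3).  Per-cell measurements become step
functions of *s*, sampled at N equally spaced positions (N = 67 for
within-genotype region profiles, N = 201 for genotype comparisons).
At every position the two groups are compared with a two-tailed
pooled-variance Student's t-test, tiered at P < 0.05, P < 0.001 and
P < 0.00001, and maximal contiguous significant runs are reported.
Gaps in a layer are scored as the ratio of total inter-cell clearance
to layer length, optionally restricted to one region.

## Worked example

Generate the default two-group cohort (33 wild-type-like vs 20
mutant-like specimens, one endothelium-like layer of 60 cells each;
the mutant carries 1.3× larger cells and an anticlinal micropylar
sub-domain at s = 0.75–0.95), then profile growth polarity:

```python
import numpy as np
from seedmorph import (trace_layer, measure_layer, resample_records,
                       compare_profiles)
from seedmorph.synthetic import default_cohort_spec, synthesize_cohort

cohort = synthesize_cohort(default_cohort_spec(seed=0, with_effect=True))
mats = {}
for group in ("wt", "mutant"):
    rows = []
    for sp in cohort.group(group):
        cells, gt = sp.layers["endothelium"]
        trace = trace_layer(cells, start_hint=gt.start_point)
        rows.append(resample_records(measure_layer(trace),
                                     "growth_polarity", 201))
    mats[group] = np.array(rows)
res = compare_profiles(mats["wt"], mats["mutant"], group_a="wt",
                       group_b="mutant", measurement="growth_polarity")
for tier, runs in res.runs.items():
    for (_, _, s0, s1) in runs:
        print(f"{tier}: s = {s0:.3f} .. {s1:.3f}")
mid = res.positions >= 0.8
print(f"mean GP at s>0.8: wt {np.nanmean(res.mean_a[mid]):.2f}, "
      f"mutant {np.nanmean(res.mean_b[mid]):.2f}")
```

prints

```
p05: s = 0.465 .. 0.465
p05: s = 0.750 .. 0.755
p05: s = 0.765 .. 0.940
p001: s = 0.770 .. 0.940
p00001: s = 0.770 .. 0.940
mean GP at s>0.8: wt 0.55, mutant 1.13
```

The strongest tier (P < 0.00001) flags essentially exactly the
injected sub-domain, where the mutant's mean GP has crossed 1 (growth
flipped from periclinal to anticlinal); the isolated single-position
P < 0.05 hit at s = 0.465 is the expected false-positive rate at work.

The same analyses run from the shell: `seedmorph simulate | ingest |
measure | trace | gaps | profile | compare | run` (see `--help`).

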