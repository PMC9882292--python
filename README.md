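# vesselprox

Spatial statistics for cell-to-blood-vessel coupling in 2D fluorescence
microscopy of developing bone (and similar tissues).

During endochondral ossification, osteoblast precursors invade the primary
ossification center alongside blood vessels and sit strikingly close to
them.  When a genetic perturbation increases the measured cell-to-vessel
distance, three very different mechanisms could be responsible: weaker
cell–vessel **attraction**, a change in **cell number**, or a change in
**vessel morphology** (the distance any random position has to a vessel
depends entirely on the vessel map).  `vesselprox` implements the distance
measurements and the Monte-Carlo null models that dissect these factors, plus
the surrounding morphometry, on segmented inputs — binary vessel masks, cell
centroid tables, ROI polygons — none of which require raw images.

## The core quantities

For a vessel mask *V* (pixel size *s* μm) and cells at continuous positions
*c₁ … cₙ* inside an ROI Ω:

- **Distance field** `D(p) = min_{v∈V} ‖p − v‖` — exact Euclidean distance
  from each pixel centre to the nearest vessel pixel centre, in μm.
- **Per-cell distances** `dᵢ = min_{v∈V} ‖cᵢ − v‖`, measured from the
  continuous coordinate (not snapped to the grid); summarized as mean ± SD,
  histogram, and ECDF.
- **Three null models** for the distance distribution:
  1. *reposition*: the observed cells redistributed uniformly over
     extravascular ROI pixel centres of the same map (destroys attraction);
  2. *matched number*: a common cell count placed uniformly on each map
     (destroys attraction and number differences);
  3. *all pixels*: the exact distance distribution of every extravascular
     ROI pixel — the n → ∞ limit of uniform placement and a pure property
     of vessel morphology.
- **Comparison statistic**: the Kolmogorov–Smirnov distance
  `D = sup_x |F_obs(x) − F_null(x)|` against the null's pooled ECDF, with an
  add-one Monte-Carlo p-value `p = (1 + #{D_b ≥ D_obs})/(n_mc + 1)`.
- **Attraction model**: observed distances are modelled as the mixture
  `p(d) ∝ (1−α)·g(d) + α·g(d)·e^(−d/λ)/Z`, where `g` is the map's pixel
  distance density; `fit_attraction` recovers the mixture weight α and
  length scale λ by maximum likelihood.
- **Morphometry**: vessel area fraction, exposed-edge perimeter-to-area
  ratio, looping-vessel counts within a band (default 50 μm) of a junction
  polyline split into core/annulus sub-regions, and skeleton-based tube
  count / mean tube length normalized to ROI area.
- **Axial profiles**: area-normalized, background-subtracted mean channel
  intensity in bins (20–30 μm) along the rudiment's central axis.

A synthetic-scene generator (`vesselprox.synthetic`) produces tubular vessel
networks, cells with known attraction (α, λ), junction lines and intensity
channels, so every stage is testable with known ground truth.

## Worked example

```python
from vesselprox import *
from vesselprox.synthetic import SyntheticConfig

wt = generate_scene(SyntheticConfig(shape=(200, 300), n_tubes=8, tube_steps=40,
                                    n_cells=500, seed=1))
ko = generate_scene(SyntheticConfig(shape=(200, 300), n_tubes=2, tube_steps=40,
                                    tube_radius=8.0, n_cells=500, seed=2))

f_wt = compute_distance_field(wt.mask, wt.roi)
f_ko = compute_distance_field(ko.mask, ko.roi)
d_wt = cell_distances(wt.cells, f_wt)
d_ko = cell_distances(ko.cells, f_ko)
s_wt, s_ko = summarize(d_wt), summarize(d_ko)
print(f"mean±SD distance: {s_wt.mean:.1f}±{s_wt.sd:.1f} μm (dense) "
      f"vs {s_ko.mean:.1f}±{s_ko.sd:.1f} μm (sparse)")

table = attribute_shift(d_wt, d_ko, wt.mask, ko.mask, wt.roi, ko.roi,
                        n_reps=200, n_mc=199, seed=0)
print(table[["test", "statistic", "p_value"]].round(3).to_string(index=False))
print("verdict:", table.attrs["verdict"])
```

prints

```
mean±SD distance: 16.9±11.4 μm (dense) vs 47.4±31.6 μm (sparse)
          test  statistic  p_value
observed_shift      0.500    0.005
  attraction_A      0.039    0.420
  attraction_B      0.029    0.730
        number      0.481      NaN
    morphology      0.482      NaN
verdict: vascular morphology
```

Read: the two conditions differ massively (between-condition KS 0.50,
p = 0.005), yet within each map the cells are indistinguishable from uniform
repositioning (attraction p = 0.42 / 0.73) and cell counts match — the shift
is carried entirely by the vessel maps themselves (population KS between the
two all-pixel distributions 0.48).  The companion morphometry confirms it:
`vessel_morphometry` reports area fraction 0.219 vs 0.076 for these maps.

## Command line

Every analysis is also a `vesselprox` subcommand operating on files
(TIFF/PNG masks, `x_um,y_um` CSVs, `{"polygon_um": ...}` JSON ROIs):

```bash
vesselprox simulate --out scene/ --seed 1
vesselprox proximity --mask scene/mask.tif --cells scene/cells.csv \
    --roi scene/roi.json --pixel-size 1.0 --out prox.csv
vesselprox nulls --model reposition --mask scene/mask.tif \
    --cells scene/cells.csv --roi scene/roi.json --seed 1 --out null.json
vesselprox morpho --mask scene/mask.tif --roi scene/roi.json --out morpho.csv
vesselprox looping --mask scene/mask.tif --junction scene/junction.csv \
    --band 50 --out looping.csv
vesselprox run --config study.yaml      # full multi-sample study
```

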