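# morphoheart

Morphometric staging, statistical shape analysis and 3D+t atlas construction
for triangle meshes of the forming mammalian heart tube.

During early development (~E7.75–E8.5 in the mouse) the cardiac crescent — a
thin, bilateral sheet of differentiated myocardium — folds and closes
dorsally into the primitive heart tube and starts looping. Specimens at a
nominally identical age vary strongly in shape, which makes staging by eye
unreliable and frustrates any attempt to average or compare geometries.
`morphoheart` implements the quantitative toolchain for this problem:

- **Morphometric staging.** The ratio *d1/d2* — the length of the
  myocardium–second-heart-field border over the length of the
  myocardium–juxta-cardiac-field border, both measured along the outline of
  the tissue midsurface — grows monotonically as the crescent closes into a
  tube and serves as a continuous developmental clock. Candidate staging
  parameters (*d1/d2*, height/width *h/w*, dorsal gap *l*, …) are compared
  by 1-D *k*-means clustering quality, scored with the average silhouette
  coefficient s̄ = mean of *s(i)* = (*b−a*)/max(*a,b*).
- **Mean shapes and local variability.** Landmark-driven surface maps
  (thin-plate-spline warp + closest-point projection) put every specimen of
  a stage group in vertex-to-point correspondence with a reference; after
  rigid alignment the mean shape of the group (MSG) is the per-vertex mean,
  and the per-vertex variability is √λ_max of the 3×3 covariance of each
  vertex's corresponding points.
- **Medoids.** The representative shape of a group (RSG) is the member with
  the smallest accumulated morphological distance
  q_i = Σ_{j≠i} D(S_i, S_j), where D is the mean distance over
  corresponding vertices after size normalisation.
- **Left–right asymmetry.** The insertion direction **v** of each inflow
  tract is the principal axis of its vertex region; its polar angles are
  *θ* (transverse plane, right side *x*-flipped so mirror-symmetric pairs
  score θ_l − θ_r = 0) and *φ* (angle to the cranio-caudal axis, −90°
  offset). A mirror-fit of one body side onto the other quantifies
  whole-tissue asymmetry.
- **3D+t atlas.** Stage keyframes are re-expressed on one shared mesh
  connectivity, rigidly aligned, linearly interpolated (30 frames per
  interval by default: 11 keyframes → 311 frames) and smoothed per-vertex
  over time with a Savitzky–Golay filter.
- **Synthetic embryos.** A parametric crescent→tube generator produces
  landmarked midsurfaces and closed thin shells with exactly known staging
  measurements, planted left–right insertion-angle asymmetry and
  controllable bulge-like shape noise, so every stage of the pipeline is
  testable without any imaging data.

## Worked example

```python
from morphoheart import SynthParams, generate_sequence, compute_measurements
from morphoheart.staging import select_parameter
import pandas as pd

specimens = generate_sequence(11, None, SynthParams(seed=7, noise_sigma=2.0))
table = pd.DataFrame([compute_measurements(sp).to_dict() for sp in specimens])
print(table[["specimen", "d1_d2", "h_w", "gap"]].round(3).to_string(index=False))
name, k, scores = select_parameter(table[["d1_d2", "h_w", "gap"]],
                                   k_range=range(2, 7), seed=7)
print(f"best staging parameter: {name} at k={k} groups "
      f"(s_bar={scores.loc[k, name]:.3f})")
```

prints

```
               specimen  d1_d2   h_w   gap
 synthetic-t0.000-seed7   1.00 0.482 130.0
 synthetic-t0.100-seed8   1.14 0.588 117.8
 synthetic-t0.200-seed9   1.28 0.680 105.6
synthetic-t0.300-seed10   1.42 0.770  93.4
synthetic-t0.400-seed11   1.56 0.860  81.2
synthetic-t0.500-seed12   1.70 0.950  69.0
synthetic-t0.600-seed13   1.84 1.040  56.8
synthetic-t0.700-seed14   1.98 1.130  44.6
synthetic-t0.800-seed15   2.12 1.220  32.4
synthetic-t0.900-seed16   2.26 1.310  20.2
synthetic-t1.000-seed17   2.40 1.400   8.0
best staging parameter: gap at k=2 groups (s_bar=0.557)
```

The measured *d1/d2* climbs from 1.0 (flat crescent) to 2.4 (looping tube)
and the dorsal gap closes from 130 µm to 8 µm — the measurements recover the
generator's planted truths to well under 1% despite 2 µm vertex noise. (On
this noiseless-trend toy family several parameters cluster almost equally
well; with realistic inter-specimen scatter the ratio parameters win, as the
recovery tests under `tests/` show.)

The same pipeline is scriptable from the shell:

```bash
morphoheart synth --n 11 --seed 7 --out specimens/
morphoheart stage --meshes specimens/ --out staging.csv
morphoheart select-param --table staging.csv --kmax 6
morphoheart angles --meshes specimens/ --out angles.csv
morphoheart atlas --keyframes specimens/ --n-between 30 --out atlas/
```

or end to end with `morphoheart run --config pipeline.json`.

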