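# vlstitch

Reconstruction of **virtual large slides** (VLS) from whole-slide-image
fragments, with micron-calibrated tumor-bed measurement and **Residual
Cancer Burden** (RCB) scoring.

## The problem

After neoadjuvant therapy, the residual tumor bed of a breast-cancer
specimen is usually larger than a single glass slide: the largest
cross-section is cut into several pieces, each scanned as its own
whole-slide image. To measure the bed — its longest diameter, the
perpendicular width, the fraction of the bed occupied by residual
carcinoma and the in-situ share of that carcinoma — the pathologist must
mentally (or physically) re-assemble the pieces. `vlstitch` does this
digitally and losslessly: each fragment carries a recorded rigid pose
(mirror, rotation, translation), stitching is arranged on 64-fold
downsampled thumbnails with tissue matting so fragments do not occlude
each other, and the full-resolution reconstruction is rendered
tile-by-tile into a Deflate-compressed tiled pyramidal TIFF that any
generic WSI reader can open.

Measurements feed the RCB index

```
d_prim = sqrt(d1 * d2)
f_inv  = (pct_ca / 100) * (1 - pct_cis / 100)
RCB    = 1.4 * (f_inv * d_prim)^0.17  +  [4 * (1 - 0.75^LN) * d_met]^0.17
```

with `d1, d2` the bed diameters (mm), `pct_ca` the percent of the bed
that is residual carcinoma, `pct_cis` the in-situ share of that
carcinoma, `LN` the number of positive lymph nodes and `d_met` the
largest nodal metastasis diameter (mm). The score bands into grades
0 (= pathologic complete response), I (≤ 1.36), II (≤ 3.28) and III,
and the longest diameter gives the ypT size stage (T1 ≤ 20 mm,
T2 20–50 mm, T3 > 50 mm).

The package also ships a synthetic-fixture generator (sections with
closed-form ellipse ground truth, cut into 2–8 perturbed fragments) and
the reliability statistics used to evaluate multi-reader panels:
ICC(2,1), Fleiss' kappa and the paired t-test.

## Worked example

Generate a synthetic sectioned specimen, reconstruct it, measure it and
score it:

```bash
vls synth --n-fragments 4 --seed 7 --out demo/
vls render --layout demo/truth_layout.json --out demo/vls.tiff
vls measure --layout demo/truth_layout.json --annotations demo/truth.geojson
```

The measure step prints

```json
{
  "length_mm": 30.0,
  "width_mm": 20.0,
  "pct_ca": 30.0,
  "pct_cis": 10.000000000000004
}
```

i.e. a 30 × 20 mm tumor bed, 30 % of which is residual carcinoma, with
10 % of that carcinoma in situ — matching the generator's analytic
ground truth. Feeding these into the calculator together with the
fixture's nodal data (2 positive nodes, largest metastasis 5 mm):

```bash
vls rcb --d1 30 --d2 20 --pct-ca 30 --pct-cis 10 --nodes 2 --dmet 5
```

```json
{
  "score": 3.376112227738062,
  "grade": "III",
  "t_stage": "T2",
  "primary_term": 1.9302018692576333,
  "nodal_term": 1.4459103584804287,
  "d_prim_mm": 24.49489742783178,
  "f_inv": 0.27,
  "size_mode": "geometric_mean"
}
```

The primary term comes from a 24.5 mm geometric-mean bed size at 27 %
invasive cellularity; the nodal term from the two positive nodes. A
score of 3.38 falls just above the 3.28 band edge: grade III (extensive
residual disease), while the 30 mm longest diameter stages as ypT2.

Rater panels are analyzed from CSV (first column = case id, remaining
columns = raters):

```bash
vls reliability --table ratings.csv --kind continuous   # -> ICC(2,1)
vls reliability --table grades.csv --kind categorical   # -> Fleiss' kappa
```

## Layout

- `vlstitch.fragment_io` — fragment reading (TIFF/PNG + mpp), region
  access, thumbnails, lossless pyramidal TIFF writer
- `vlstitch.matting` — binary tissue/background alpha masks
- `vlstitch.layout` — poses, affine matrices, canvas bounds, layout JSON
- `vlstitch.renderer` — painter's-rule compositing, preview and full render
- `vlstitch.measure` — rulers, polygon areas, bed diameters, percentages
  (GeoJSON annotations)
- `vlstitch.rcb` — RCB index, grade bands, ypT stage
- `vlstitch.synth` — synthetic sections, cut plans, simulated rater panels
- `vlstitch.reliability` — ICC(2,1), Fleiss' kappa, paired t-test
- `vlstitch.cli` — the `vls` command

See `docs/methods.md` for the models, conventions and numerical choices.
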