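# facesym

Coordinate-system-free quantification of 3D facial asymmetry from landmark
coordinates exported from 3D-CT simulation software.

For each measurement landmark the **asymmetry index** is the
root-sum-of-squares of differences between distances measured from fixed
cranial reference landmarks:

- **bilateral** landmarks (orbitale, condylion, gonion, first molars): for
  each midline reference (sella, nasion, MidZ — the midpoint of the two
  frontozygomatic suture points), distance-to-left minus distance-to-right;
- **midline** landmarks (ANS, incisor contact points, B point, menton):
  distance differences from the Z-point pair and the porion pair.

A perfectly symmetric configuration scores 0; right deviation is encoded
negative, left positive. Because only inter-landmark distances enter the
formula, the index is invariant to rigid motion of the whole landmark set —
no reference coordinate frame is required. Patient left/right comes purely
from the `L`/`R` side labels, never from axis directions.

The package also ships:

- packaged normative reference ranges (per-landmark mean/SD of |index| from
  a 25-subject normal group) with a configurable `mean + z·SD` symmetry
  threshold (default z = 1.96) and the menton-deviation cohort screen
  (< 4 mm perpendicular distance to the N–S–MidZ plane);
- pre/post-surgical comparison reports and a polygonal (radar) chart with
  the normative band (first profile red, second blue; deterministic SVG);
- Dahlberg method error `SE = √(Σd²/2n)` and a paired t test for
  double-measurement reliability;
- a synthetic landmark generator: a bilaterally symmetric skull template
  with controllable per-landmark displacements, rigid pose, and seeded
  Gaussian placement noise.

## File formats

Landmark CSV (UTF-8, mm; side `L`/`R` for bilateral, `M` or empty for
midline; names case-insensitive, long forms like "Gonion" accepted; `MidZ`
is always derived, never an input):

```csv
name,side,x,y,z
S,M,0.0,0.0,0.0
N,M,0.0,75.0,35.0
Z,L,45.0,60.0,25.0
Z,R,-45.0,60.0,25.0
Po,L,60.0,-10.0,-10.0
Po,R,-60.0,-10.0,-10.0
Me,M,0.0,70.0,-100.0
```

The six reference landmarks (S, N, Z pair, Po pair) are mandatory;
measurement landmarks are individually optional. A JSON dialect
(`{subject, timepoint, landmarks: [{name, side, x, y, z}]}`) is equivalent.

## CLI

```sh
facesym compute landmarks.csv                  # asymmetry profile (CSV/JSON)
facesym screen landmarks.csv                   # menton < 4 mm inclusion screen
facesym classify landmarks.csv [--z 1.96] [--normative override.csv]
facesym compare pre.csv post.csv --chart chart.svg --json-out report.json
facesym chart pre.csv post.csv --out chart.svg # polygonal chart (.svg/.png)
facesym reliability m1.csv m2.csv [--absolute] # Dahlberg SE + paired t
facesym simulate spec.json --out sim.csv       # synthetic landmark file
```

Inputs may be landmark files or previously computed profile files (detected
by header). Logs go to stderr, data to stdout/files. Exit codes: 0 success,
1 validation/analysis error, 2 usage error.

Simulation spec example:

```json
{
  "displacements": [{"name": "Me", "dx": 6}, {"name": "Go", "side": "L", "dz": -3}],
  "rotation_deg": [10, 0, -5],
  "translation_mm": [1, 2, 3],
  "noise_sd_mm": 0.5,
  "seed": 7
}
```

Normative override CSV: `landmark,mean_abs,sd_abs` rows plus an optional
`# z=<float>` comment line.

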