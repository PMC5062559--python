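# tensionmap

Image-analysis pipeline for **ratiometric molecular tension sensors** — the
FRET-based probes that report piconewton-scale forces across individual
adhesion receptors (e.g. integrins) in live cells.

A tension-sensor module is a donor–elastic linker–acceptor cassette inserted
into a receptor. Tensile force stretches the linker, separating the
fluorophores and lowering FRET efficiency. For a single-chain sensor the
per-pixel FRET *ratio* (acceptor emission / donor emission under donor
excitation) is therefore a force readout once calibrated. `tensionmap`
implements the full chain from raw camera frames to calibrated force maps,
plus the companion analyses typically run alongside them in migrating-cell
studies:

- **Calibration** — quartic efficiency-vs-force curve for a 0–6 pN sensor
  module, two-point linear ratio-vs-efficiency map from reference constructs,
  and a numeric inverse giving force from ratio with saturation handling.
- **Image preparation** — dark-current subtraction, flat-field correction,
  robust background estimation by half-Gaussian histogram fitting.
- **FRET force maps** — smoothed per-pixel ratio maps with a signal-validity
  rule, photobleach correction by AIC-selected exponential fits, whole-cell
  force summaries.
- **Segmentation & protrusions** — threshold / active-contour masks, edge
  bands, protrusion events as space–time connected mask gains, cell QC.
- **Axial localization** — variance-based z-centering of TIRF z-stacks,
  chromatic calibration from beads, relative receptor-vs-actin height.
- **Actin flow** — kymographs with feature-slope and structure-tensor
  retrograde-flow estimators that cross-check each other.
- **Morphodynamics** — constant-number edge windowing (bands × boundary
  positions), edge-velocity series, band-wise force–motion cross-correlation
  with permutation significance.
- **Stain statistics** — pixelwise stain-vs-tension correlations and
  nonparametric group comparisons (Mann–Whitney, Kruskal–Wallis + Dunn).
- **Synthetic scenes** — forward-model generators that plant known forces,
  flows, protrusions, axial offsets and stain correlations, used throughout
  the test suite as ground truth.

All data in this repository is synthetic. The packaged calibration tables
reproduce the qualitative shape of a 0–6 pN sensor module (efficiency falling
from 0.30 to 0.05 with a high-FRET plateau at low force), not any
instrument's measured values. The generator defaults define the study
conditions used by the tests and the acceptance script.

## Worked example

Command line (`tensionmap --help` lists all stages):

```bash
$ tensionmap calibrate --out model.json
model written to model.json; ratio domain [0.865, 1.430], round-trip max error 0.046 pN

$ tensionmap simulate --out scene --seed 1 --frames 6 --force-pn 3.0
scene written to scene

$ tensionmap run --out run --scene scene
run complete: run
cell_id,frame_policy,mean_ratio,mean_efficiency,mean_force_pN,n_pixels
cell,first,1.1309679068378864,0.1676258790086699,3.016794334489524,5029
```

The planted uniform 3.0 pN force comes back as 3.017 pN over 5029 valid
in-cell pixels, through dark/flat correction, background estimation, ratio
mapping, segmentation, photobleach correction and calibration.

The same primitives from Python:

```python
import numpy as np
from tensionmap import calibration as cal, synth, zstack, flow

model = cal.default_calibration_model()
model.zero_force_ratio            # 1.430  (ratio of a relaxed sensor)
float(model.ratio_for_force(3.0)) # 1.133
float(model.inverse.force(1.1))   # 3.288 pN

# relative axial position: channel 1 planted 45 nm below channel 2
sc = synth.make_zstack_scene(-45.0, step=25.0, seed=2)
zstack.relative_z(sc.channels["ch1"], sc.channels["ch2"], step_nm=25.0).delta_z_nm
# 45.4 nm  (sign: first channel minus second)

# retrograde actin flow planted at -100 nm/s, measured two ways
p = synth.SceneParams(n_frames=30, frame_interval_s=1.0, seed=3, shading=False)
scene = synth.make_cell_scene(p, model)
line = np.array([[30, 64], [98, 64]])
k = flow.extract_kymograph(scene.channels["actin"].astype(float), line,
                           width=3, pixel_size_nm=160.0, frame_interval_s=1.0)
flow.measure_feature_velocity(k, flow.auto_feature_endpoints(k)).velocity_nm_s
# -99.7 nm/s
flow.gradient_flow_speed(k).velocity_nm_s
# -97.7 nm/s
```

## Reproduction

`scripts/acceptance.py` exercises every major analysis on seeded synthetic
data and writes the principal quantities (calibration round-trip error,
background bias, force recovery at planted levels, axial RMSE, flow errors,
windowing coupling, statistics checks, stain correlations) as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Every random draw derives from `--seed`; the same seed reproduces the same
file byte for byte. The property-based contracts themselves live in
`tests/test_acceptance.py` and run as part of `pytest`.

## Documentation

`docs/methods.md` describes the models, parameter defaults with units, the
synthetic generators' realism and limits, and the numerical design choices.
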