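# Methods

This document describes the models implemented by `tensionmap`, the
parameter defaults (with units), the synthetic generators used as ground
truth, and the reasoning behind the numerical design choices. Numbers quoted
here are either definitions/defaults or quantities computed by the test
suite and `scripts/acceptance.py` in this repository.

## 1. Force calibration (`tensionmap.calibration`)

**Model.** Three fitted pieces:

1. `E(f)` — a quartic polynomial in force, least-squares fitted to tabulated
   (force pN, FRET efficiency) calibration points. Requires ≥ 5 points
   spanning ≥ 3 pN; fits are flagged non-monotone if the derivative changes
   sign on the calibrated domain.
2. `E(R)` — an ordinary-least-squares line between the FRET ratio `R` and
   efficiency, fitted on reference constructs of known efficiency. The
   packaged synthetic references are (R = 2.0, E = 0.55) and
   (R = 1.0, E = 0.11), giving slope 0.44 and intercept −0.33 exactly; the
   linearity assumption is conventional for this efficiency interval of the
   mTFP1/mVenus pair (Förster distance 6.0 nm).
3. `f(R)` — the numeric inverse: at 1000 points along the calibration curve,
   `curve(f) = line(R)` is solved by bracketed Brent root finding and a
   quartic is fitted to the (R, f) pairs. Neither `E(f)` nor the chain has a
   closed-form inverse, hence the sampled-root construction.

Forces are clamped to `[0, f_max]` (default domain 0–6 pN); ratios outside
the calibrated ratio domain (default [0.865, 1.430]) clamp to the endpoint
force and are flagged *saturated*. Inconsistent curve/line pairs — lines
mapping the curve's efficiencies to non-positive ratios, or > 1% root
failures — raise `CalibrationError`.

**Accuracy.** With the packaged tables the full round trip
`f → R → f` has a maximum error of 0.046 pN over a 1000-point grid
(contract: ≤ 0.1 pN).

## 2. Synthetic scenes (`tensionmap.synth`)

The generators are the ground truth for every test. Forward model for a
FRET time-lapse (`make_cell_scene`):

- geometry: a disk cell (radius 40 px default) on a 128×128 px frame at
  160 nm/px, 5 s frame interval (1 s conventional for actin-flow movies);
- per-pixel planted force field (scalar, array, named regions, or a smooth
  random field), converted to the true ratio through the same calibration
  chain the analysis inverts;
- donor level 1500 counts, FRET channel = donor × true ratio; acceptor
  photodamage as `exp(−k_b · t)` on the FRET channel only
  (`bleach_rate` 0.01 /frame default), donor constant;
- actin channel: band-limited speckle texture advected rigidly at the
  planted flow velocity (−100 nm/s default, retrograde negative), sampled
  from a static canvas by interpolation so the velocity is exact;
- camera: signal × shading (smooth ±15% vignetting) passed through Poisson
  shot noise, plus dark level 100 counts and Gaussian read noise
  (σ = 3 counts). Noise is applied in the physical order — shot noise on
  the shaded optical signal, then offset and read noise — so that shading
  also scales the shot-noise variance as it does on a real camera.

Protrusions are planted as exact-volume voxel sets: strips grown layer by
layer from the cell edge, scheduled over given frames, so detection
thresholds can be tested as exact step functions. Z-stack scenes defocus a
texture (or beads) with a blur σ growing linearly with distance from focus
(σ(dz) = hypot(1 px, 0.006 px/nm · dz)), which makes the in-plane variance
peak at focus. Stain scenes mix the standardized inverted true ratio with
noise orthogonalized against it, so the realized in-mask Pearson
correlation equals the requested ρ exactly before camera noise.

**Realism and limits.** The generator reproduces the *statistical* structure
the analyses rely on (shot + read noise, shading, bleaching, rigid flow,
defocus-driven variance, exact planted correlations) but not optics at the
PSF level: no diffraction model, no depth-dependent TIRF excitation decay,
rigid rather than deforming flow fields, circular cells rather than real
morphologies. Conclusions about algorithm correctness transfer; absolute
noise floors on real data will differ.

## 3. Image preparation (`tensionmap.prep`)

Processing order: dark subtraction → flat-field division → background
estimation/subtraction. Dark current is an additive camera offset and must
leave before the multiplicative shading correction; background (cellular
debris, medium fluorescence) is an optical signal that shares the shading
field, so it is estimated after flattening.

Background is estimated by fitting a Gaussian to the *left shoulder* of the
intensity histogram: bins at or below the histogram mode are dominated by
background even when bright foreground covers half the image, so fitting
only those bins makes the estimator robust to contamination. Bin width
follows Freedman–Diaconis on sub-median pixels; the fit falls back to
half-normal-corrected sub-median statistics if it fails to converge.
Measured bias (acceptance script, 100 seeds, σ = 3): 0.085 counts clean,
0.033 counts with 50% bright-foreground contamination (contracts: < σ/10
and < σ/4).

## 4. Ratio, bleaching, force (`tensionmap.fret`)

Both channels are pre-filtered with a renormalized 3×3 Gaussian (σ = 1 px).
A pixel is valid only if both smoothed, background-subtracted channels
exceed `k·σ_bg` (k = 3): this suppresses division-of-noise artifacts and
defines the map's validity mask, which propagates unchanged into force maps.

Photobleaching is fitted on the whole-cell mean-ratio series with a single
or double exponential, selected by small-sample corrected AIC; frames are
divided by the fitted decay normalized to 1 at frame 0, so the first frame
is never altered, and the default whole-cell summary uses only frame 0 —
force quantification therefore cannot depend on the correction. Planted
rates are recovered with ~0.2% mean relative error at the default noise
level (contract: 10%).

End-to-end, planted region forces {0, 1.5, 3, 6} pN come back as
{0.12, 1.50, 3.00, 5.88} pN (20 seeds, acceptance script, seed 1;
contract ± 0.3 pN). The 0 pN and 6 pN levels show small inward biases
because forces clamp to the calibrated domain, which rectifies noise at the
boundaries.

## 5. Segmentation and protrusions (`tensionmap.segment`)

Masks come from `μ_bg + 3σ_bg` thresholding (or morphological Chan–Vese
seeded by it), refined by radius-1 closure, removal of objects < 50 px, and
hole filling; the largest 8-connected component is kept. Edge bands are the
mask minus its disk erosion (depth 10 px default). Protrusion events are
26-connected (t, y, x) components of frame-to-frame mask gains, kept when
space–time volume ≥ 1000 voxels and duration ≥ 3 frames (5 for
morphodynamic selection); on planted events detection is an exact step
function in both thresholds. Cell QC applies track length ≥ 10 consecutive
frames, no border or neighbor contact, protrusive activity (≥ 5 gaining
frames, > 1000 px total gain) and in-protrusion SNR ≥ 5.

## 6. Axial localization (`tensionmap.zstack`)

Per-plane sharpness metric: normalized variance `var/mean²` (scale-invariant;
`var/mean` available). A Gaussian plus constant offset is fitted to the
variance-vs-z profile; profiles whose maximum sits at the scan edge raise an
error rather than extrapolate. Chromatic aberration is calibrated from bead
stacks — per-bead two-channel center fits, median-combined after 3-MAD
outlier rejection — and subtracted from two-channel comparisons. Relative
offsets (`channel 1 − channel 2 − chromatic`) cancel cell-to-cell variation
in absolute height; negative values place channel 1 closer to the
coverslip. Measured: RMSE 0.83 nm on offsets drawn U(−100, 100) nm at 25 nm
plane spacing (contract ≤ 15 nm); planted 25 nm chromatic offset recovered
as 24.8 nm (contract ± 5 nm).

## 7. Actin flow (`tensionmap.flow`)

Kymographs are built by bilinear sampling along a polyline, averaging over
`width` parallel normal offsets. Two estimators:

- **feature slope** — velocity from two endpoints on a stripe. Endpoints may
  be supplied (annotation) or detected automatically: a coarse
  consecutive-column cross-correlation picks a frame gap over which stripes
  move a resolvable distance, then the cross-correlation averaged over all
  column pairs that far apart, with parabolic sub-pixel refinement, gives
  the slope. The automated detector replaces manual clicking so results are
  reproducible; it assumes a dominant coherent motion in the sampled region.
- **structure tensor** — the eigenvector of the smaller eigenvalue of the
  region-averaged spatiotemporal structure tensor gives the stripe
  orientation; the eigenvalue contrast (coherence) flags near-isotropic
  texture as low confidence (threshold 0.2).

Sign convention: `direction_sign = −1` (default) makes features moving
toward larger line coordinate — inward, when the line is drawn from the
edge into the cell — report negative, i.e. retrograde. On planted speeds
10–250 nm/s both estimators land within 10% of truth and of each other
(mean relative errors 3.1% and 4.7% in the acceptance run).

## 8. Morphodynamic windowing (`tensionmap.windows`)

**Grid.** The frame-0 boundary (longest marching-squares contour) is divided
into `n_pos = round(perimeter / window_px)` equal-arclength positions
(window_px = 5 px default ⇒ 0.8 µm windows); that count is held fixed for
all frames (*constant-number propagation*). Bands stack inward at window_px
depth (`n_bands` = 6): band b is exactly the set of in-mask pixels with
Euclidean distance to the edge in ((b−1)·5, b·5]. Positions re-anchor per
frame by normalized arclength from a reference point tracked to the nearest
boundary point of the next frame; each pixel takes the position of its
nearest boundary point. The constant-count contract is a *slot* contract:
every band exposes the same `n_pos` windows at every frame, and band 1
occupies all of them; deep-band slots can be empty in a given frame when
rasterized geometry leaves no pixel in that (band, position) cell — window
signals report such slots as NaN, never 0.

**Edge velocity.** For each frame-t boundary point, the signed distance
transform of frame t+1 minus that of frame t is sampled (both with the
half-pixel correction aligning pixel-center distances to the 0.5-contour
boundary); per-position means convert px/frame to nm/s. Positive =
protrusion; static masks give exactly zero.

**Coupling statistics.** Band-wise temporal cross-correlation: each window's
Pearson correlation with the (broadcast) comparison series at lags
−5…+5 frames, averaged over windows per band; significance of the peak
|mean r| by circularly shifting each window's series independently
(1000 permutations, seeded; p = (1 + exceedances)/(1 + permutations)).
Spatial localization: per band, time-averaged window force correlated
across positions with the time-averaged protrusive-sector indicator,
position-permutation significance; the peak band converts to a distance
from the edge as (b − 0.5)·window_px·pixel_size (band 3 ⇒ 2.0 µm at
defaults). Per-event force-vs-velocity association uses Pearson r with a
Fisher-z 95% CI and a least-squares line.

## 9. Stain and group statistics (`tensionmap.stainstats`)

Stain correlations use stringent pixel selection: in-mask, ratio-valid, and
above `μ_bg + 4σ_bg` in both donor and FRET channels (≥ 100 pixels).
Pearson correlation is computed against the *negated* ratio — Pearson is
affine-invariant, so negation implements "inverted ratio" exactly, and only
the sign convention matters (tension lowers the ratio). Planted ρ = −0.3
over 10 557 eligible pixels is recovered as −0.300.

Group comparisons are nonparametric: two-sided Mann–Whitney U for two
groups (verified against an exhaustive pair-counting oracle, including
ties), Kruskal–Wallis for more, followed by Dunn's rank-based pairwise test
with tie correction `Σ(t³ − t)/(12(N − 1))` and Bonferroni adjustment.
Dunn's test is implemented in-package because no installed dependency
provides it; the z and tie formulas are asserted against hand-computed
examples in the tests. Measured Kruskal–Wallis type-I error at nominal
0.05: 0.044 over 2000 null simulations (contract [0.03, 0.07]).

## 10. Pipeline and provenance (`tensionmap.pipeline`, `tensionmap.cli`)

`RunConfig` captures every stage parameter and every seed; the SHA-256 hash
of the serialized config is written into the run manifest, and reruns with
the same config are byte-identical in tabular outputs. Stage outputs:
calibration model JSON, per-frame background table, mask/ratio/force
OME-TIFFs (float32, NaN = invalid), bleach fit JSON, whole-cell summary
CSV, optional windowing products, an inverted-heat-map PNG (low ratio =
high force = hot, fixed color limits), and `manifest.json`. Each stage is
independently runnable from the `tensionmap` CLI.

## Open design choices

Where a published description leaves the implementation open, the choice
and its rationale:

- **Regression direction for `E(R)`** — efficiency is regressed on ratio
  (not ratio on efficiency): the line is consumed as `E = a·R + b` by the
  inverse construction, and with two reference points both directions
  interpolate identically.
- **Automatic kymograph endpoints** — an interactive annotation step would
  make the contracted accuracy untestable; the averaged cross-correlation
  detector is deterministic and validated against planted truth.
- **`var/mean²` as the default sharpness metric** — exactly invariant to
  global intensity rescaling, so bleaching between stacks does not shift
  the fitted center; `var/mean` is provided for comparison.
- **Window slot semantics** — "constant window count" is implemented as a
  fixed number of per-band slots rather than forcing every slot nonempty,
  which would require resampling pixels across band boundaries and break
  the exact band tiling.
- **First-frame force policy** — reporting frame 0 after a correction that
  is normalized to 1 at frame 0 makes the headline force numbers provably
  independent of the bleach model choice.
- **Physical noise ordering in the generator** — shot noise is applied to
  the shaded signal (then offset and read noise added), matching camera
  physics; the alternative (shading applied after noise) would make
  flat-field correction also "correct" shot noise, which real optics does
  not allow.

## Limitations

- All validation is against the package's own forward models; the
  generators share some machinery (e.g. the calibration chain) with the
  analyses, so calibration-table errors would cancel rather than surface.
  The numeric *inverse* is still independently exercised by planting in
  force units and recovering through rendered images.
- No PSF/diffraction model; spatial resolution effects beyond the 3×3
  pre-filter are untested.
- Flow fields are rigid; converging or shearing flow will bias the single
  slope estimators in ways the synthetic tests do not measure.
- The active-contour segmentation is validated only on high-contrast
  synthetic cells.
- Permutation p-values are lower-bounded by 1/(n_permutations + 1).
- Clamping to the calibrated force domain biases means near 0 and 6 pN
  (rectified noise), visible as the ±0.12 pN edge biases in the acceptance
  run.
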