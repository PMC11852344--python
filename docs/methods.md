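# Methods

## Scope and model

The package quantifies postoperative haemodynamics from time-resolved
three-directional phase-contrast MR velocity data ("4D-flow") in the left
ventricular outflow tract (LVOT) and ascending aorta, for a three-arm
feasibility design (isolated septal myectomy, myectomy + anterior
mitral-valve leaflet extension, healthy controls; three subjects per arm).
Because no patient data are distributable, the study conditions are
reproduced by a synthetic generator whose outputs carry exact analytic
ground truth; every measurement operation is validated against those closed
forms, and group-level claims are validated by recovering the published
group means through the complete pipeline.

### Flow phantom

Each vascular segment is modelled as a straight rigid tube (axis along z)
with a quasi-steady power-law profile

    v_z(r, t) = vmax(t) · (1 − (r/R)ⁿ),  r ≤ R,  n ≥ 1,

zero velocity outside the lumen.  The profile *shape* is frozen while the
amplitude follows a raised-sine systolic waveform (peak at frame 5 of 24,
flow-free diastole).  Closed forms used as oracles:

| quantity | closed form |
|---|---|
| wall shear stress | τ = μ n vmax / R |
| mean KE density | ½ ρ vmax² g(n), g(n) = 1 − 4/(n+2) + 1/(n+1) |
| bulk velocity | v̄ = vmax n/(n+2) |
| stroke volume | Σ_t πR² v̄(t) Δt |

A full Womersley (oscillatory, Bessel-function) solution is deliberately out
of scope: quasi-steady amplitude modulation keeps every per-frame quantity
in closed form, which is what makes the phantom a usable oracle.  The
price is that the phantom has no flow-profile phase lag or near-wall
oscillatory layer — conclusions about those phenomena cannot be drawn from
these tests.

### Calibration to the published group columns

The exponent n decouples peak velocity (vmax) from mean KE (g(n)), so a
single tube can match a (vpeak, KE) pair — solved by inverting the
monotone g — or a (WSS, KE) pair — solved by bisection on
h(n) = g(n)/n², which is strictly decreasing on [1, 20].  Infeasible pairs
raise a named error; the healthy-control aortic column (WSS 0.47 Pa with
KE 345.4) admits no solution at the 12.5 mm patient radius and is therefore
generated with a 14 mm radius (28 mm diameter — normal adult ascending
aorta).  LVOT radii follow the reported group LVOT diameters
(18.8 / 15.9 / 19.6 mm).  Stroke-volume targets are met by scaling the
waveform amplitude at fixed parabolic profile.

Per-subject targets are **moment-matched** draws: standardized normal scores
rescaled so the 3-subject sample mean and SD equal the published column
exactly.  The cohort's true group mean therefore equals the table value by
construction, and group-mean recovery tests measure pipeline error, not
3-subject sampling luck (with raw i.i.d. draws the sample-mean scatter alone
reaches 8–17 % for the high-SD columns, swamping any measurement signal at
n = 3).  Jointly infeasible draw sets are redrawn as a whole, at most 10
times.

### Acquisition emulation

Defaults mirror a clinical protocol: 2.4 × 2.4 mm in-plane, 2.5 mm slices,
24 frames over a 1000 ms cycle (41.7 ms temporal resolution), venc 2.0 m/s.
Corruptions are applied in the order **noise → offset → wrap**:

* Gaussian velocity noise, independent per component, SD = noise_frac × venc
  (cohort default noise_frac 0.02) — the standard phase-contrast noise model;
* a 2nd-order spatial polynomial background offset per component, constant
  in time (per-subject coefficients: constant ±0.03 m/s, linear ±0.01,
  quadratic ±0.005 in normalized coordinates);
* venc wrap-around: values mapped into [−venc, venc) modulo 2 venc.

Truth records are computed before corruption and are independent of the
noise seed.  Features of real data the generator does **not** emulate:
curved/branching geometry, wall motion, partial-volume magnitude decay at
the wall, spatially correlated noise, and k-space undersampling artefacts.
Passing tests therefore demonstrate correctness of the measurement chain on
resolvable cylindrical geometry, not clinical-grade accuracy on patient
anatomy.

## Measurement pipeline

**Static tissue** — voxels whose temporal speed SD *and* mean are below
0.05 × venc.  In static tissue the phase-contrast signal is offset + noise,
so both statistics are small; flowing blood fails the SD criterion.

**Offset correction** — least-squares fit of the 2nd-order polynomial basis
to static-voxel velocities, per frame and component; coefficients are
averaged over frames (offsets are temporally stable) and subtracted
everywhere.  Rank-deficient static geometry falls back to a constant fit
with a warning.  Injected polynomial offsets are recovered to 10⁻⁶ m/s
noise-free.

**Anti-aliasing** — temporal-only unwrapping: scanning frames in order, any
frame-to-frame jump exceeding venc is reduced by the multiple of 2 venc that
minimizes it (ties at exactly venc untouched).  Idempotent; no spatial
unwrapping.  A voxel aliased in *every* frame by the same multiple is
undetectable by construction; with the phantom's flow-free diastole this
case does not arise.

**PC-MRA and segmentation** — pcmra = time-mean of magnitude × speed;
threshold at a fraction of the maximum (default 0.5), keep the largest
26-connected component.  Supplied masks always take precedence: the
threshold stand-in replaces manual segmentation only when no masks exist.
At half-maximum the threshold tracks the *velocity* iso-contour, so it
recovers the lumen of blunt (plug-like) jets (Dice ≥ 0.9 at n = 20) but
under-segments low-n profiles — a documented limitation of
threshold segmentation, not of the metric code, and the reason cohort runs
use the generator's true masks.

**Wall surface** — marching cubes at level 0.5 of the binary mask smoothed
with a 1-voxel Gaussian (placing the surface at the 50 %-occupancy boundary
and giving stable gradient normals); per-vertex area weights are one third
of adjacent triangle areas; normals oriented inward by the occupancy
gradient.  Open tube ends produce artificial caps: cap faces are dropped,
and wall-shear evaluation additionally stays 6 mm clear of the cut ends,
where smoothing pinches the lateral wall inward.

**Peak systole** — argmax of mean lumen speed over frames < ⌈n_frames/2⌉,
earliest frame on ties.  "First half" is defined by frame index because the
reconstruction grids the cycle uniformly.

**Wall shear stress** — per surface point, velocity is trilinearly sampled
at distances (1.2, 1.8, …, 4.8) mm along the inward normal (half-voxel steps
from 0.5 to 2 voxels), projected onto the tangent plane, and each tangential
component is fitted by least squares with a quadratic **with free
intercept**; τ = μ × fitted wall gradient, summarised as the area-weighted
mean magnitude.  The intercept is the load-bearing numerical choice: pinning
the fit to v = 0 at the reconstructed wall makes the gradient first-order
sensitive to sub-voxel wall mislocation (≈ 0.9 %/0.01 mm here), and measured
biases then swing from −14 % to +27 % purely with the digitization phase of
the vessel radius against the 2.4 mm grid.  With the intercept, the no-slip
condition remains true of the flow but is not imposed on uncertain geometry,
and all tested radii/profiles agree with the closed form within ±4 %
(noise-free) at clinical resolution.  Points whose samples exit the volume
are skipped; > 20 % skipped aborts with a coverage error.

**Peak velocity** — the single maximum voxel speed in the mask at the
peak-systolic frame, deliberately without percentile robustification; with
noise_frac 0.02 this statistic carries a positive extreme-value bias of
≈ +5–7 % at the cohort lumen sizes, which is accepted and visible in the
recovery numbers.

**KE density** — mask-mean of ½ ρ |v|² at the peak-systolic frame, reported
numerically in J/m³.  The clinical tables print "mJ/m³", which is
dimensionally inconsistent with ½ ρ v² at the printed magnitudes but
numerically consistent with mJ/L ≡ J/m³; the package computes in J/m³ and
reports the numbers on the printed scale without resolving the label.
Voxel-centre discretization at 4–5 voxels per radius contributes a ±4–9 %
geometry-dependent bias, the dominant error for the LVOT segments.

**Transvalvular flow** — the valve aperture is a disc (origin, unit normal,
radius) per frame; v·n̂ is resampled by trilinear interpolation on an
in-plane grid at half the smallest voxel dimension, summed to Q(t), and the
positive/negative parts integrated over the beat.  Velocities outside the
lumen contribute their near-zero values (no lumen masking at the valve).
Quadrature error is < 1 % on smooth profiles.

**Bernoulli gradients** — ΔP = 4 v² mmHg on the per-frame LVOT peak-speed
series; dp_max is the systolic maximum and dp_mean the systolic time-average
of instantaneous 4 v²; systole is defined as first-half frames whose mean LV
speed exceeds 25 % of the peak frame's.  **Strain** — contour-length
definition (min L(t) − L(0))/L(0) × 100; the generator supplies a contour
series shortening with the systolic waveform so the drawn strain target is
realised exactly.

**Group statistics** — sample mean, sample SD (n − 1), Student-t CI on the
mean; percent differences of group means against the isolated-myectomy
reference.  The published CIs are mutually inconsistent with any single
(mean, SD, n) rule and the published percent differences do not reproduce
from the rounded table means (e.g. (0.59 − 0.73)/0.73 = −19.2 % vs a printed
−21.2 %), so the standard definitions are used and those printed derived
values are not targeted.  No hypothesis tests, matching the descriptive
design.

## Physical constants and defaults

| parameter | default | note |
|---|---|---|
| μ (blood viscosity) | 3.2 × 10⁻³ Pa·s | standard literature value; not stated in the study |
| ρ (blood density) | 1060 kg/m³ | standard literature value |
| venc | 2.0 m/s | must exceed the largest calibrated vmax (1.88 m/s) |
| static_sd_frac | 0.05 | static-tissue speed threshold as a venc fraction |
| pcmra_threshold_frac | 0.5 | threshold-segmentation fraction of the PC-MRA maximum |
| wss_sample_distances | 1.2–4.8 mm | half-voxel steps, 0.5–2 voxels |
| ci_level | 0.95 | group confidence intervals |

## Problem sizes

Phantom grids are ~21 × 21 × 20 voxels × 24 frames per tube segment (sized
to hold the tube with a 9 mm velocity-free margin and ≥ 2 voxels of axial
padding); cohorts are 3 subjects per arm with up to four segments each.
One full cohort analysis runs in seconds on one CPU, and the complete
acceptance recomputation (8 cohorts, 24 tubes) in under a minute.

## Known limitations

* Straight, static, circular geometry only; WSS accuracy on curved or
  moving walls is untested by construction.
* The max-voxel peak-velocity statistic is noise-biased upward (documented
  above); robustified alternatives are intentionally not used because the
  study reports a peak.
* Threshold segmentation is profile-shape dependent; it is a stand-in for
  manual segmentation, not a replica of it.
* The n = 3 arms make small group differences (e.g. the ~+11 % LVOT KE
  contrast) fragile: measurement biases of a few percent can flip their
  sign, which is visible in the cohort report and mirrors the study's own
  caution about its sample size.
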