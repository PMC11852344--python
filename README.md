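# flow4d

Quantitative haemodynamics from 4D-flow cardiac MR velocity fields, built
around a feasibility question from hypertrophic-cardiomyopathy (HCM)
surgery: after septal myectomy, does adding an anterior mitral-valve leaflet
extension (AMVLE) move left-ventricular-outflow-tract (LVOT) and aortic
haemodynamics closer to healthy values?  The package implements the full
measurement chain for that study — and, because the patient scans are not
public, a synthetic pulsatile tube-flow generator whose cohorts are
calibrated so their true group means equal the published group tables,
giving every metric an exact analytic oracle.

## What it computes

Given a time-resolved three-component velocity field v(x, t) (24 cardiac
frames, 2.4 × 2.4 × 2.5 mm voxels in the emulated acquisition):

* **Preprocessing** — static-tissue detection from temporal speed
  statistics; background phase-offset removal by a 2nd-order spatial
  polynomial fitted to static voxels; velocity anti-aliasing by temporal
  phase unwrapping at the venc; PC-MRA construction
  (magnitude × |v|, time-averaged).
* **Timing** — peak systole = the frame with the highest mean LV speed in
  the first half of the cycle.
* **Wall shear stress** τ = μ ∂v_t/∂n at the vessel wall, from velocities
  sampled along inward surface normals and a quadratic profile fit;
  area-weighted mean over the wall surface (Pa).
* **Kinetic-energy density** KE = mean(½ ρ |v|²) over a segment mask,
  reported on the clinical tables' mJ/m³ scale (numerically J/m³).
* **LVOT peak velocity** = max voxel speed in the LVOT mask (m/s).
* **Transvalvular flow** through a tracked valve plane: Q(t) = ∮ v·n̂ dA,
  forward/backward volumes per beat (ml).
* **Simplified Bernoulli gradients** ΔP = 4 v² (mmHg) and contour-length
  **longitudinal strain** (%).

The phantom is a rigid tube with a power-law profile
v_z(r, t) = vmax(t)·(1 − (r/R)ⁿ), for which WSS = μ n vmax/R,
KE = ½ ρ vmax² g(n) with g(n) = 1 − 4/(n+2) + 1/(n+1), and
SV = Σ πR² vmax(t) n/(n+2) Δt are exact — the exponent n decouples peak
velocity from kinetic energy so each published (vpeak, KE) or (WSS, KE)
column pair is matched by one tube.

## Worked example

```python
from flow4d import AnalysisConfig, compute_wss
from flow4d.phantom import default_waveform, make_tube_phantom, tube_spec
from flow4d.segmentation import extract_wall_surface, find_peak_systole

cfg = AnalysisConfig()                       # mu = 0.0032 Pa·s, rho = 1060 kg/m³
spec = tube_spec(10.0, 1.0 * default_waveform(), profile_exponent=2.0)
field, mag, masks, truth = make_tube_phantom(spec, cfg)

frame = find_peak_systole(field, masks.lv)   # -> 5 (waveform peak)
surface = extract_wall_surface(masks.aorta, field.spacing,
                               drop_caps_axis=2, cap_margin_mm=6.0)
wss = compute_wss(field, frame, surface, cfg)
print(f"{wss.summary:.3f} Pa vs analytic {truth.wss_true:.3f} Pa")
```

prints

```
0.608 Pa vs analytic 0.640 Pa
```

i.e. the pipeline recovers the parabolic-flow wall shear stress
2 μ vmax / R within 5 % at clinical resolution.

The cohort-level analysis is driven by the numbered scripts:

```bash
python analysis/01_simulate_cohorts.py    # 3 subjects × 3 groups + truth table
python analysis/02_run_pipeline.py        # full pipeline per subject
python analysis/03_cohort_report.py       # group means ± SD / CI / % differences
```

On the default seed the measured group contrast of myectomy + AMVLE against
isolated myectomy is −17.9 % aortic WSS, −4.5 % LVOT peak velocity and
−25.1 % aortic KE (healthy controls: −33.1 %, −20.2 %, −26.3 %), i.e. the
treated-with-AMVLE group sits between the isolated-myectomy and healthy
groups on every aortic metric, matching the study's qualitative finding.
Tables land in `results/`.

A `flow4d` console script exposes each stage
(`simulate / preprocess / segment / analyze / valveflow / report`) for
running the same chain on stored HDF5/NIfTI datasets.

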