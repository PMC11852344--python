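"""Synthetic pulsatile tube-flow phantoms with closed-form ground truth.

The phantom is a straight rigid tube (axis along z) carrying an axial
power-law velocity profile

    v_z(r, t) = vmax(t) · (1 − (r/R)ⁿ),   r ≤ R,

zero outside — a quasi-steady pulsatile flow whose profile shape is fixed
while the amplitude follows a per-frame waveform.  For this family every
quantity the pipeline measures has an exact closed form:

* wall shear stress     τ = μ · n · vmax / R
* cross-section mean kinetic-energy density
                        KE = ½ ρ vmax² g(n),  g(n) = 1 − 4/(n+2) + 1/(n+1)
* mean (bulk) velocity  v̄ = vmax · n/(n+2)
* stroke volume         SV = Σ_t πR² v̄(t) Δt

so generated datasets double as test oracles for the measurement code.
The exponent n decouples peak velocity from kinetic energy, which is what
lets one tube match a published (vpeak, KE) or (WSS, KE) pair at once.

The generator emulates a clinical 4D-flow acquisition: 2.4 × 2.4 mm in-plane
resolution, 2.5 mm slices, 24 cardiac frames, and — when enabled — Gaussian
velocity noise, low-order polynomial background phase offsets, and venc
wrap-around aliasing, applied in that order.  Truth records are computed
before corruption and are independent of the noise seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from ._basis import quadratic_basis
from .config import AnalysisConfig
from .errors import DomainError, InfeasibleTargetError, ResolutionError, ValidationError
from .fields import MagnitudeSeries, SegmentMaskSet, VelocityField4D
from .targets import GROUP_RADII_MM, STUDY_GROUPS
from .valve_flow import ValvePlaneTrack

#: Exponent search interval for calibration.
N_MIN, N_MAX = 1.0, 20.0

#: Magnitude-image levels (arbitrary units): blood pool vs. surrounding tissue.
MAG_LUMEN, MAG_BACKGROUND = 100.0, 10.0


# ---------------------------------------------------------------------------
# Closed-form oracles

def profile_shape_factor(n: float) -> float:
    """g(n) = 1 − 4/(n+2) + 1/(n+1): cross-section average of (1 − (r/R)ⁿ)².

    Monotone increasing on n ≥ 1, from 1/6 at n = 1 toward 1 (plug flow).
    """
    if not n > 0:
        raise DomainError("profile exponent must be > 0")
    return 1.0 - 4.0 / (n + 2.0) + 1.0 / (n + 1.0)


def poiseuille_wall_shear(vmax: float, radius: float, mu: float, n: float = 2.0) -> float:
    """Exact wall shear stress (Pa) of v(r) = vmax·(1 − (r/R)ⁿ).

    Parameters are SI: vmax m/s, radius m, mu Pa·s.  τ = μ·n·vmax/R.
    """
    if not (vmax > 0 and radius > 0 and mu > 0 and n > 0):
        raise DomainError("poiseuille_wall_shear requires strictly positive inputs")
    return mu * n * vmax / radius


def powerlaw_mean_ke_density(vmax: float, rho: float, n: float = 2.0) -> float:
    """Cross-section-averaged kinetic-energy density (J/m³): ½·ρ·vmax²·g(n)."""
    if not (vmax > 0 and rho > 0 and n > 0):
        raise DomainError("powerlaw_mean_ke_density requires strictly positive inputs")
    return 0.5 * rho * vmax * vmax * profile_shape_factor(n)


def mean_velocity_factor(n: float) -> float:
    """v̄/vmax = n/(n+2) for the power-law profile."""
    return n / (n + 2.0)


# ---------------------------------------------------------------------------
# Calibration (inverse problems)

def calibrate_segment(
    target_wss: float,
    target_ke: float,
    radius: float,
    config: AnalysisConfig,
) -> tuple[float, float]:
    """Invert the WSS and KE closed forms jointly: find (vmax, n).

    Solves  μ·n·vmax/R = target_wss  and  ½ρ vmax² g(n) = target_ke  for
    n ∈ [1, 20] by deterministic root bracketing on h(n) = g(n)/n², which is
    strictly decreasing.  radius is in metres; targets in Pa and J/m³.

    Raises
    ------
    InfeasibleTargetError
        If no exponent in [1, 20] satisfies both targets; the message names
        the violated bound.
    """
    if not (target_wss > 0 and target_ke > 0 and radius > 0):
        raise DomainError("calibration targets and radius must be > 0")
    k = target_wss * radius / config.mu          # = n · vmax
    h_star = 2.0 * target_ke / (config.rho * k * k)   # = g(n)/n²

    def h(n: float) -> float:
        return profile_shape_factor(n) / (n * n)

    if h_star > h(N_MIN):
        raise InfeasibleTargetError(
            f"targets require g(n)/n² = {h_star:.4g} > {h(N_MIN):.4g} at n = {N_MIN}: "
            "KE too high for this WSS/radius (exponent would fall below 1)"
        )
    if h_star < h(N_MAX):
        raise InfeasibleTargetError(
            f"targets require g(n)/n² = {h_star:.4g} < {h(N_MAX):.4g} at n = {N_MAX}: "
            "KE too low for this WSS/radius (exponent would exceed 20)"
        )
    n = brentq(lambda x: h(x) - h_star, N_MIN, N_MAX, xtol=1e-12, rtol=1e-12)
    vmax = k / n
    return vmax, n


def calibrate_velocity_ke(
    target_vpeak: float, target_ke: float, config: AnalysisConfig
) -> tuple[float, float]:
    """Find (vmax, n) matching a peak-velocity / KE-density pair.

    The peak voxel velocity of the profile is vmax itself, so only the
    exponent is free:  g(n) = 2·KE/(ρ·vpeak²).
    """
    if not (target_vpeak > 0 and target_ke > 0):
        raise DomainError("calibration targets must be > 0")
    g_star = 2.0 * target_ke / (config.rho * target_vpeak * target_vpeak)
    g_lo, g_hi = profile_shape_factor(N_MIN), profile_shape_factor(N_MAX)
    if g_star < g_lo:
        raise InfeasibleTargetError(
            f"targets require g(n) = {g_star:.4g} < g(1) = {g_lo:.4g}: "
            "KE too low for this peak velocity"
        )
    if g_star > g_hi:
        raise InfeasibleTargetError(
            f"targets require g(n) = {g_star:.4g} > g(20) = {g_hi:.4g}: "
            "KE too high for this peak velocity"
        )
    n = brentq(
        lambda x: profile_shape_factor(x) - g_star, N_MIN, N_MAX, xtol=1e-12, rtol=1e-12
    )
    return target_vpeak, n


def calibrate_stroke_volume(
    target_sv_ml: float,
    radius: float,
    waveform_shape: np.ndarray,
    frame_duration_ms: float,
    n: float = 2.0,
) -> float:
    """Peak amplitude (m/s) whose waveform realises a stroke-volume target.

    SV = Σ_t πR²·vmax·s(t)·n/(n+2)·Δt with s the unit-peak waveform shape;
    scaling the amplitude scales the systolic waveform area linearly.
    radius in metres, target in ml.
    """
    if not (target_sv_ml > 0 and radius > 0):
        raise DomainError("stroke-volume target and radius must be > 0")
    area_m2 = math.pi * radius * radius
    shape_sum = float(np.sum(waveform_shape))
    if shape_sum <= 0:
        raise DomainError("waveform shape must have positive area")
    dt_s = frame_duration_ms / 1000.0
    sv_per_unit_vmax_ml = area_m2 * mean_velocity_factor(n) * shape_sum * dt_s * 1e6
    return target_sv_ml / sv_per_unit_vmax_ml


# ---------------------------------------------------------------------------
# Waveform

def default_waveform(
    n_frames: int = 24, peak_frame: int = 5, systole_end: int = 11
) -> np.ndarray:
    """Unit-peak systolic waveform: a raised-sine pulse in early systole.

    Frames 0 … systole_end−1 carry sin²(π·f/(systole_end−1)) — zero at the
    cycle start, peaking at ``peak_frame`` — and diastole is flow-free.
    """
    if not 0 < peak_frame < systole_end <= n_frames:
        raise ValidationError("need 0 < peak_frame < systole_end <= n_frames")
    s = np.zeros(n_frames)
    f = np.arange(systole_end)
    s[:systole_end] = np.sin(np.pi * f / (systole_end - 1)) ** 2
    # place the peak exactly at peak_frame by shifting the pulse if needed
    native_peak = (systole_end - 1) // 2
    if native_peak != peak_frame:
        s = np.roll(s, peak_frame - native_peak)
    return s


# ---------------------------------------------------------------------------
# Phantom specification and truth

@dataclass
class PhantomSpec:
    """Full description of one synthetic tube acquisition.

    Lengths in mm, velocities in m/s, times in ms.  ``vmax_waveform`` holds
    the per-frame centreline peak velocity.  ``offset_coeffs`` (3, 10) are
    per-component coefficients on the 2nd-order polynomial basis
    (1, x, y, z, x², y², z², xy, xz, yz) in [-1, 1]-normalized coordinates,
    constant in time.
    """

    radius: float
    length: float
    profile_exponent: float
    vmax_waveform: np.ndarray
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.4, 2.4, 2.5)
    rr_interval: float = 1000.0
    venc: float = 2.0
    noise_frac: float = 0.0
    offset_coeffs: Optional[np.ndarray] = None
    alias: bool = False
    systole_frames: Optional[tuple[int, ...]] = None
    seed: int = 0
    static_gap: float = 5.0  # mm of buffer between lumen and static-tissue label

    def __post_init__(self) -> None:
        self.vmax_waveform = np.asarray(self.vmax_waveform, dtype=float)
        if self.vmax_waveform.ndim != 1 or self.vmax_waveform.size < 2:
            raise ValidationError("vmax_waveform must be a per-frame 1-D array")
        if np.any(self.vmax_waveform < 0):
            raise ValidationError("vmax_waveform must be non-negative")
        if not (self.radius > 0 and self.length > 0 and self.profile_exponent >= 1):
            raise ValidationError("radius, length > 0 and profile_exponent >= 1 required")
        if self.noise_frac < 0:
            raise ValidationError("noise_frac must be >= 0")
        if self.radius < 3.0 * max(self.spacing):
            raise ResolutionError(
                f"tube radius {self.radius} mm under-resolved: need >= 3 voxels "
                f"across the radius at spacing {self.spacing} mm"
            )
        if self.systole_frames is None:
            self.systole_frames = tuple(np.nonzero(self.vmax_waveform > 0)[0])
        if self.offset_coeffs is not None:
            self.offset_coeffs = np.asarray(self.offset_coeffs, dtype=float)
            if self.offset_coeffs.shape != (3, 10):
                raise ValidationError("offset_coeffs must have shape (3, 10)")

    @property
    def n_frames(self) -> int:
        return self.vmax_waveform.size

    @property
    def frame_duration(self) -> float:
        return self.rr_interval / self.n_frames


def tube_spec(
    radius: float,
    vmax_waveform: np.ndarray,
    *,
    profile_exponent: float = 2.0,
    length: float = 40.0,
    margin: float = 9.0,
    spacing: tuple[float, float, float] = (2.4, 2.4, 2.5),
    **kwargs,
) -> PhantomSpec:
    """Build a :class:`PhantomSpec` with a grid sized to hold the tube.

    The grid leaves ``margin`` mm of velocity-free surround in-plane and at
    least two voxels of padding beyond the tube ends, so lumen masks never
    touch the volume border.
    """
    dx, dy, dz = spacing
    nx = 2 * (int(math.ceil((radius + margin) / dx)) + 1) + 1
    ny = 2 * (int(math.ceil((radius + margin) / dy)) + 1) + 1
    nz = int(math.ceil(length / dz)) + 4
    return PhantomSpec(
        radius=radius,
        length=length,
        profile_exponent=profile_exponent,
        vmax_waveform=np.asarray(vmax_waveform, dtype=float),
        shape=(nx, ny, nz),
        spacing=spacing,
        **kwargs,
    )


@dataclass
class PhantomTruth:
    """Analytic ground truth of one phantom, computed before any corruption."""

    wss_per_frame: np.ndarray          # Pa
    ke_density_per_frame: np.ndarray   # J/m³
    peak_velocity_true: float          # m/s
    stroke_volume_true: float          # ml/beat
    peak_systole_frame_true: int
    vmax: float
    profile_exponent: float
    radius_mm: float

    @property
    def wss_true(self) -> float:
        """Wall shear stress at peak systole (Pa)."""
        return float(self.wss_per_frame[self.peak_systole_frame_true])

    @property
    def ke_density_true(self) -> float:
        """KE density at peak systole (J/m³)."""
        return float(self.ke_density_per_frame[self.peak_systole_frame_true])


def phantom_truth(spec: PhantomSpec, config: AnalysisConfig) -> PhantomTruth:
    """Closed-form truth record for ``spec`` (independent of noise/corruption)."""
    r_m = spec.radius / 1000.0
    n = spec.profile_exponent
    w = spec.vmax_waveform
    wss = np.where(w > 0, config.mu * n * w / r_m, 0.0)
    ke = 0.5 * config.rho * w * w * profile_shape_factor(n)
    area_m2 = math.pi * r_m * r_m
    sv_ml = float(
        np.sum(area_m2 * w * mean_velocity_factor(n) * (spec.frame_duration / 1000.0))
        * 1e6
    )
    return PhantomTruth(
        wss_per_frame=wss,
        ke_density_per_frame=ke,
        peak_velocity_true=float(w.max()),
        stroke_volume_true=sv_ml,
        peak_systole_frame_true=int(np.argmax(w)),
        vmax=float(w.max()),
        profile_exponent=n,
        radius_mm=spec.radius,
    )


# ---------------------------------------------------------------------------
# Generation

def _tube_geometry(spec: PhantomSpec):
    """Radial map (mm, in-plane), lumen mask and tube z-slice range."""
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    cx, cy = nx // 2, ny // 2          # tube axis passes through voxel centres
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    r2d = np.hypot(x[:, None], y[None, :])
    nz_tube = int(round(spec.length / dz))
    z0 = (nz - nz_tube) // 2
    z0 = max(z0, 1)
    z1 = min(z0 + nz_tube, nz - 1)
    if z1 <= z0:
        raise ResolutionError("grid too short in z for the requested tube length")
    return r2d, z0, z1


def make_tube_phantom(
    spec: PhantomSpec,
    config: Optional[AnalysisConfig] = None,
    *,
    lumen_labels: Sequence[str] = ("aorta",),
) -> tuple[VelocityField4D, MagnitudeSeries, SegmentMaskSet, PhantomTruth]:
    """Generate one synthetic 4D-flow acquisition of a pulsatile tube.

    The uncorrupted voxel velocities equal the analytic profile evaluated at
    voxel centres exactly.  Corruptions are applied in the order
    noise → polynomial offset → venc wrapping, each only when enabled, and the
    truth record is computed from the closed forms before any corruption.
    Output is reproducible for a fixed ``spec.seed``.

    ``lumen_labels`` names the analysis masks (``"aorta"``, ``"lvot"``) to
    which the lumen is assigned; the LV mask is always the lumen (it is the
    moving-blood compartment used for peak-systole detection).
    """
    config = config or AnalysisConfig()
    truth = phantom_truth(spec, config)
    r2d, z0, z1 = _tube_geometry(spec)
    nx, ny, nz = spec.shape
    nt = spec.n_frames

    profile2d = np.clip(1.0 - (r2d / spec.radius) ** spec.profile_exponent, 0.0, None)
    profile2d[r2d >= spec.radius] = 0.0
    lumen2d = r2d < spec.radius

    lumen = np.zeros(spec.shape, dtype=bool)
    lumen[:, :, z0:z1] = lumen2d[:, :, None]

    data = np.zeros((nx, ny, nz, nt, 3))
    data[:, :, z0:z1, :, 2] = (
        profile2d[:, :, None, None] * spec.vmax_waveform[None, None, None, :]
    )

    rng = np.random.default_rng(spec.seed)
    if spec.noise_frac > 0:
        data += rng.normal(0.0, spec.noise_frac * spec.venc, size=data.shape)
    if spec.offset_coeffs is not None and np.any(spec.offset_coeffs):
        basis = quadratic_basis(spec.shape)           # (nx, ny, nz, 10)
        offset = basis @ spec.offset_coeffs.T          # (nx, ny, nz, 3)
        data += offset[:, :, :, None, :]
    if spec.alias:
        data = wrap_velocity(data, spec.venc)

    field = VelocityField4D(
        data=data,
        spacing=np.asarray(spec.spacing, dtype=float),
        frame_duration=spec.frame_duration,
        venc=spec.venc,
        rr_interval=spec.rr_interval,
    )

    mag = np.full((nx, ny, nz, nt), MAG_BACKGROUND)
    mag[lumen] = MAG_LUMEN
    magnitude = MagnitudeSeries(data=mag)

    static = np.zeros(spec.shape, dtype=bool)
    static[:, :, :] = (r2d >= spec.radius + spec.static_gap)[:, :, None]
    mask_kwargs: dict = {"lv": lumen, "static_tissue": static}
    for label in lumen_labels:
        if label in ("aorta", "lvot"):
            mask_kwargs[label] = lumen
    masks = SegmentMaskSet(**mask_kwargs)

    return field, magnitude, masks, truth


def wrap_velocity(data: np.ndarray, venc: float) -> np.ndarray:
    """Apply venc wrap-around: values map into [−venc, venc) modulo 2·venc."""
    return np.mod(data + venc, 2.0 * venc) - venc


def inlet_valve_track(spec: PhantomSpec, aperture_margin: float = 2.0) -> ValvePlaneTrack:
    """A static valve plane at the tube inlet, covering the whole lumen.

    The plane sits one slice inside the tube with its normal along +z; the
    aperture radius exceeds the lumen radius by ``aperture_margin`` mm (the
    surrounding voxels carry near-zero velocity and contribute nothing).
    """
    _, z0, _ = _tube_geometry(spec)
    nx, ny, _ = spec.shape
    dx, dy, dz = spec.spacing
    origin = np.array([(nx // 2) * dx, (ny // 2) * dy, (z0 + 1) * dz])
    nt = spec.n_frames
    return ValvePlaneTrack(
        origins=np.tile(origin, (nt, 1)),
        normals=np.tile(np.array([0.0, 0.0, 1.0]), (nt, 1)),
        radii=np.full(nt, spec.radius + aperture_margin),
    )


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class PhantomBundle:
    """One generated tube segment plus its spec and analytic truth."""

    field: VelocityField4D
    magnitude: MagnitudeSeries
    masks: SegmentMaskSet
    truth: PhantomTruth
    spec: PhantomSpec


@dataclass
class CohortSubject:
    """One synthetic subject: independent tube segments plus drawn targets."""

    subject_id: str
    group: str
    segments: dict[str, PhantomBundle]
    true_targets: dict[str, float]
    contour_lengths: Optional[np.ndarray] = None  # mm, per frame (LVOT strain input)


_MAX_RESAMPLE = 10


def draw_matched_targets(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    *,
    positive: bool = True,
) -> np.ndarray:
    """Per-subject target values whose sample moments equal (mean, sd) exactly.

    Normal scores are drawn, standardized (sample mean 0, sample SD 1 with
    the n−1 denominator) and rescaled, so the cohort's true group mean and SD
    reproduce the published column exactly while subjects still vary
    stochastically.  Draws are rejected (and redrawn) while any value is
    non-positive when ``positive``.
    """
    if n == 1 or sd == 0:
        return np.full(n, mean)
    for _ in range(1000):
        z = rng.normal(size=n)
        zsd = z.std(ddof=1)
        if zsd < 1e-12:
            continue
        x = mean + sd * (z - z.mean()) / zsd
        if not positive or np.all(x > 0):
            return x
    raise InfeasibleTargetError(
        f"could not draw {n} positive moment-matched values from N({mean}, {sd})"
    )


def make_cohort(
    group: str,
    n_subjects: int,
    config: Optional[AnalysisConfig] = None,
    *,
    segments: Sequence[str] = ("aorta", "lvot", "av", "mv"),
    noise_frac: float = 0.02,
    offsets: bool = True,
    alias: bool = True,
    seed: Optional[int] = None,
    targets: Optional[dict] = None,
    radii: Optional[dict] = None,
    peak_frame: int = 5,
    n_frames: int = 24,
) -> list[CohortSubject]:
    """Generate a calibrated cohort of synthetic subjects for one study group.

    Per-subject targets are drawn from the group mean/SD as moment-matched
    normal deviates (:func:`draw_matched_targets`), so the cohort's true
    group mean and SD equal the published column exactly while subjects
    still vary.  Each target set is inverted to tube parameters with the
    closed-form calibrators and realised as independent tube segments:

    * ``"aorta"`` — jointly calibrated to the (WSS, aortic KE) pair;
    * ``"lvot"``  — jointly calibrated to the (peak velocity, LVOT KE) pair;
    * ``"av"``/``"mv"`` — systolic waveform area scaled so the stroke volume
      matches the forward-flow target (parabolic profile).

    A jointly infeasible draw set is redrawn up to 10 times before failing
    with a diagnostic.  Fixed ``seed`` reproduces the cohort bit-identically.
    """
    config = config or AnalysisConfig()
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    group_targets = dict(targets if targets is not None else STUDY_GROUPS[group])
    group_radii = dict(radii if radii is not None else GROUP_RADII_MM[group])
    group_targets.pop("_radii", None)
    seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(n_subjects + 1)
    draw_rng = np.random.default_rng(children[0])
    subject_rngs = [np.random.default_rng(c) for c in children[1:]]

    def _joint_draws(keys, calib_fn, label):
        """Cohort-level target vectors accepted only if every subject calibrates."""
        last_err: Exception | None = None
        for _ in range(_MAX_RESAMPLE):
            vecs = [
                draw_matched_targets(draw_rng, *group_targets[k], n_subjects)
                for k in keys
            ]
            try:
                params = [calib_fn(*(v[i] for v in vecs)) for i in range(n_subjects)]
            except InfeasibleTargetError as err:
                last_err = err
                continue
            return vecs, params
        raise InfeasibleTargetError(
            f"{group}/{label}: targets stayed infeasible after "
            f"{_MAX_RESAMPLE} cohort redraws; last error: {last_err}"
        )

    shape_wave = default_waveform(n_frames=n_frames, peak_frame=peak_frame)
    drawn: dict[str, np.ndarray] = {}
    tube_params: dict[str, list[tuple[float, float]]] = {}

    if "aorta" in segments:
        r_m = group_radii["aorta"] / 1000.0
        (drawn["wss_aorta"], drawn["ke_aorta"]), tube_params["aorta"] = _joint_draws(
            ("wss_aorta", "ke_aorta"),
            lambda w, k: calibrate_segment(w, k, r_m, config),
            "aorta",
        )
    if "lvot" in segments:
        (drawn["vpeak_lvot"], drawn["ke_lvot"]), tube_params["lvot"] = _joint_draws(
            ("vpeak_lvot", "ke_lvot"),
            lambda v, k: calibrate_velocity_ke(v, k, config),
            "lvot",
        )
    for valve in ("av", "mv"):
        if valve not in segments:
            continue
        key = f"{valve}_forward"
        sv = draw_matched_targets(draw_rng, *group_targets[key], n_subjects)
        drawn[key] = sv
        r_m = group_radii[valve] / 1000.0
        tube_params[valve] = [
            (
                calibrate_stroke_volume(
                    sv[i], r_m, shape_wave, 1000.0 / n_frames, n=2.0
                ),
                2.0,
            )
            for i in range(n_subjects)
        ]
    if "strain_lvot" in group_targets:
        drawn["strain_lvot"] = draw_matched_targets(
            draw_rng, *group_targets["strain_lvot"], n_subjects, positive=False
        )

    subjects = []
    for i, rng in enumerate(subject_rngs):

        def _spec_kwargs():
            kw: dict = {
                "noise_frac": noise_frac,
                "alias": alias,
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
            if offsets:
                coeffs = np.zeros((3, 10))
                coeffs[:, 0] = rng.uniform(-0.03, 0.03, size=3)      # constant, m/s
                coeffs[:, 1:4] = rng.uniform(-0.01, 0.01, size=(3, 3))   # linear
                coeffs[:, 4:] = rng.uniform(-0.005, 0.005, size=(3, 6))  # quadratic
                kw["offset_coeffs"] = coeffs
            return kw

        bundles: dict[str, PhantomBundle] = {}
        for name in segments:
            if name not in tube_params:
                continue
            vmax, n_exp = tube_params[name][i]
            spec = tube_spec(
                group_radii[name], vmax * shape_wave, profile_exponent=n_exp,
                **_spec_kwargs(),
            )
            labels = (name,) if name in ("aorta", "lvot") else ()
            bundles[name] = PhantomBundle(
                *make_tube_phantom(spec, config, lumen_labels=labels), spec
            )

        contour = None
        if "strain_lvot" in drawn:
            # LVOT contour length shortens with the systolic waveform; its
            # minimum realises the drawn strain exactly.
            l0 = 50.0
            contour = l0 * (1.0 + (drawn["strain_lvot"][i] / 100.0) * shape_wave)

        subjects.append(
            CohortSubject(
                subject_id=f"{group}_{i:02d}",
                group=group,
                segments=bundles,
                true_targets={k: float(v[i]) for k, v in drawn.items()},
                contour_lengths=contour,
            )
        )
    return subjects
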