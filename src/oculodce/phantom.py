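"""Digital eye phantom: synthetic DCE datasets with known ground truth.

The phantom emulates an orbital DCE-MRI study in image space: a spherical
eye (vitreous, long T1) containing a wall-attached lesion (spherical-cap
geometry, pigmentation-dependent T1), surrounded by textured orbital tissue
that gives the head registration something to lock onto.  Enhancement is
generated by running the analysis chain in reverse - Tofts kinetics to
concentration, concentration to R1, R1 to SPGR signal with the local
achieved flip angle B1 * alpha - then frames are resampled through a rigid
motion trace (head motion globally, eye motion inside the globe) and Rician
noise is added.  Every stage is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .core_io import (
    AcquisitionParams,
    B1Map,
    DynamicSeries,
    FlipAngleSeries,
    Mask,
    RigidTransform,
    VolumeImage,
)
from .kinetics import AIF, population_aif, tofts_forward
from .relaxometry import spgr_signal

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "MotionTrace",
    "SimulatedStudy",
    "build_phantom",
    "simulate_motion_trace",
    "simulate_dce",
    "simulate_study",
]


@dataclass
class PhantomSpec:
    """Full ground-truth description of a synthetic eye DCE study.

    Geometry defaults follow a typical adult globe (11 mm radius) with a
    medium-large wall-attached lesion (7.8 mm prominence, 14.5 mm basal
    diameter); kinetic and relaxometric defaults sit at the cohort-typical
    values (Ktrans 0.46 1/min, ve 0.22, lesion T1 1122 ms, lesion-median
    B1+ 0.91).
    """

    shape: tuple[int, int, int] = (64, 53, 21)
    spacing: tuple[float, float, float] = (1.25, 1.5, 1.5)
    eye_center_mm: tuple[float, float, float] | None = None
    eye_radius_mm: float = 11.0
    lesion_prominence_mm: float = 7.8
    lesion_basal_diameter_mm: float = 14.5
    lesion_t1_ms: float = 1122.0
    two_lobe: bool = False
    lobe_t1_ms: tuple[float, float] = (494.0, 1464.0)
    lobe_ktrans_per_min: tuple[float, float] | None = None
    lobe_ve: tuple[float, float] | None = None
    vitreous_t1_ms: float = 4000.0
    orbit_t1_ms: float = 1000.0
    lesion_ktrans_per_min: float = 0.46
    lesion_ve: float = 0.22
    lesion_heterogeneity: float = 0.0  # lognormal sigma of intra-lesion Ktrans field
    zone_params: list | None = None  # list of {"ktrans","ve","t1"} dicts
    b1_lesion_median: float = 0.91
    b1_gradient: tuple[float, float] = (-0.04, 0.03)
    detachment: bool = False
    # motion
    n_dynamics: int = 125
    interval_s: float = 2.0
    bat_index: int = 5
    drift_amplitude_mm: float = 0.0
    blink_shift_mm: float = 0.0
    n_blinks: int = 2
    gaze_rotation_deg: float = 0.0
    n_gaze_events: int = 2
    head_drift_amplitude_mm: float = 0.0
    head_rotation_deg: float = 0.0
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 20.0
    ref_index: int | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_ve <= 0 or self.lesion_ve > 1:
            raise ValueError("lesion ve must lie in (0, 1]")
        if self.lesion_ktrans_per_min < 0:
            raise ValueError("lesion Ktrans must be non-negative")
        if self.lesion_t1_ms <= 0 or self.vitreous_t1_ms <= 0:
            raise ValueError("T1 values must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def resolved_eye_center(self) -> np.ndarray:
        if self.eye_center_mm is not None:
            return np.asarray(self.eye_center_mm, dtype=float)
        return (np.asarray(self.shape, dtype=float) - 1) / 2.0 * np.asarray(self.spacing)

    def resolved_ref_index(self) -> int:
        if self.ref_index is not None:
            return int(self.ref_index)
        return 49 if self.n_dynamics >= 50 else self.n_dynamics // 2


@dataclass
class PhantomTruth:
    """Ground-truth maps and masks on the phantom grid."""

    grid: VolumeImage
    t1_ms: VolumeImage
    m0: VolumeImage
    ktrans_per_min: VolumeImage
    ve: VolumeImage
    eye_mask: Mask
    lesion_mask: Mask
    b1: B1Map
    lobe_masks: tuple[np.ndarray, np.ndarray] | None = None
    zone_masks: list | None = None


@dataclass
class MotionTrace:
    """Per-dynamic rigid eye and head transforms; identity at the reference."""

    eye: list[RigidTransform]
    head: list[RigidTransform]
    ref_index: int

    def __post_init__(self) -> None:
        if len(self.eye) != len(self.head):
            raise ValueError("one eye and one head transform per dynamic")
        for name, tf in (("eye", self.eye[self.ref_index]), ("head", self.head[self.ref_index])):
            if not tf.is_identity(1e-6, 1e-6):
                raise ValueError(f"{name} transform at the reference dynamic must be identity")

    def __len__(self) -> int:
        return len(self.eye)

    def composed(self, i: int) -> RigidTransform:
        """Total transform seen by eye voxels at dynamic i (head after eye)."""
        return self.head[i].compose(self.eye[i])

    def max_translation_mm(self) -> float:
        return max(
            float(np.linalg.norm(self.composed(i).apply(self.eye[i].center_mm)[0] - self.eye[i].center_mm))
            for i in range(len(self))
        )


@dataclass
class SimulatedStudy:
    """Everything a pipeline run needs, plus the truth that generated it."""

    dynamic: DynamicSeries
    fa_series: FlipAngleSeries
    b1: B1Map
    truth: PhantomTruth
    trace: MotionTrace
    aif: AIF
    acq: AcquisitionParams
    spec: PhantomSpec
    noise_sigma_abs: float = 0.0
    clean_dynamic: DynamicSeries | None = None


# ---------------------------------------------------------------------------
# Geometry


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*ax, indexing="ij")


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize the geometry and truth maps described by a spec."""
    grid = VolumeImage(np.zeros(spec.shape), spec.spacing)
    X, Y, Z = _world_grids(spec)
    c = spec.resolved_eye_center()
    fov = spec.fov_mm
    if np.any(c - spec.eye_radius_mm < -fov * 0.5) or np.any(c + spec.eye_radius_mm > fov * 1.5):
        raise ValueError("eye lies (mostly) outside the field of view")

    r_eye = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
    eye = r_eye <= spec.eye_radius_mm
    if not eye.any():
        raise ValueError("eye mask is empty: geometry outside the FOV")

    # Wall-attached spherical-cap lesion along +x: its sphere has radius
    # r_l = (a^2 + p^2) / (2 p) for basal radius a and prominence p, centred
    # so the cap protrudes p mm into the globe.
    p = spec.lesion_prominence_mm
    a = spec.lesion_basal_diameter_mm / 2.0
    if p <= 0 or a <= 0:
        raise ValueError("lesion prominence and basal diameter must be positive")
    r_l = (a**2 + p**2) / (2 * p)
    d = spec.eye_radius_mm + r_l - p
    lc = c + np.array([d, 0.0, 0.0])
    r_les = np.sqrt((X - lc[0]) ** 2 + (Y - lc[1]) ** 2 + (Z - lc[2]) ** 2)
    lesion = eye & (r_les <= r_l)
    if not lesion.any():
        raise ValueError("lesion mask is empty: degenerate geometry")

    rng = np.random.default_rng(spec.seed)

    t1 = np.full(spec.shape, spec.orbit_t1_ms, dtype=float)
    t1[eye] = spec.vitreous_t1_ms
    kt = np.zeros(spec.shape)
    ve = np.full(spec.shape, 0.999)  # irrelevant where ktrans = 0

    lobes = None
    zones = None
    if spec.zone_params:
        # partition lesion voxels into contiguous index-ordered chunks
        idx = np.argwhere(lesion)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx = idx[order]
        chunks = np.array_split(idx, len(spec.zone_params))
        zones = []
        for chunk, params in zip(chunks, spec.zone_params):
            zm = np.zeros(spec.shape, dtype=bool)
            zm[tuple(chunk.T)] = True
            t1[zm] = params["t1"]
            kt[zm] = params["ktrans"]
            ve[zm] = params["ve"]
            zones.append(zm)
    elif spec.two_lobe:
        lobe_a = lesion & (Y < lc[1])
        lobe_b = lesion & ~lobe_a
        t1[lobe_a] = spec.lobe_t1_ms[0]
        t1[lobe_b] = spec.lobe_t1_ms[1]
        kt_pair = spec.lobe_ktrans_per_min or (spec.lesion_ktrans_per_min,) * 2
        ve_pair = spec.lobe_ve or (spec.lesion_ve,) * 2
        kt[lobe_a], kt[lobe_b] = kt_pair
        ve[lobe_a], ve[lobe_b] = ve_pair
        lobes = (lobe_a, lobe_b)
    else:
        t1[lesion] = spec.lesion_t1_ms
        kt[lesion] = spec.lesion_ktrans_per_min
        ve[lesion] = spec.lesion_ve

    if spec.lesion_heterogeneity > 0:
        # smooth lognormal modulation: uveal melanomas show intra-lesion
        # Ktrans spreads comparable to their median
        hfield = gaussian_filter(rng.standard_normal(spec.shape), sigma=1.5)
        hfield /= max(hfield.std(), 1e-9)
        kt[lesion] = kt[lesion] * np.exp(spec.lesion_heterogeneity * hfield[lesion])

    if spec.detachment:
        dc = c + np.array([0.55 * spec.eye_radius_mm, 0.6 * spec.eye_radius_mm, 0.0])
        det = eye & ~lesion & (
            np.sqrt((X - dc[0]) ** 2 + (Y - dc[1]) ** 2 + (Z - dc[2]) ** 2) <= 0.35 * spec.eye_radius_mm
        )
        t1[det] = 3000.0

    # Intra-ocular anatomy: a lens anteriorly (opposite the lesion) and a
    # small papilla-like spot on an oblique wall direction.  Besides realism
    # these break the rotational near-symmetry of the globe, without which
    # rotation about the lesion axis would be unobservable to registration.
    lens_c = c - np.array([0.65 * spec.eye_radius_mm, 0.0, 0.0])
    lens_ax = np.array([0.35, 0.45, 0.45]) * spec.eye_radius_mm
    lens = (
        ((X - lens_c[0]) / lens_ax[0]) ** 2
        + ((Y - lens_c[1]) / lens_ax[1]) ** 2
        + ((Z - lens_c[2]) / lens_ax[2]) ** 2
    ) <= 1.0
    lens &= eye & ~lesion
    t1[lens] = 1100.0
    u = np.array([-0.45, 0.75, 0.5])
    u /= np.linalg.norm(u)
    pap_c = c + 0.85 * spec.eye_radius_mm * u
    papilla = eye & ~lesion & (
        np.sqrt((X - pap_c[0]) ** 2 + (Y - pap_c[1]) ** 2 + (Z - pap_c[2]) ** 2) <= 2.5
    )
    t1[papilla] = 900.0

    # Equilibrium signal: textured orbit so full-FOV registration has
    # features, a bright scleral rim, dimmer vitreous.
    texture = gaussian_filter(rng.standard_normal(spec.shape), sigma=2.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    m0 = 700.0 * (1.0 + 0.4 * texture)
    rim = (r_eye > spec.eye_radius_mm) & (r_eye <= spec.eye_radius_mm + 2.0)
    m0[rim] = 1200.0
    m0[eye] = 900.0
    m0[lens] = 600.0
    m0[papilla] = 800.0
    m0[lesion] = 1000.0

    # Smooth B1+ field: mild in-plane gradients rescaled so the lesion
    # median hits the target.
    gx, gy = spec.b1_gradient
    b1 = 1.0 + gx * (X - c[0]) / (fov[0] / 2) + gy * (Y - c[1]) / (fov[1] / 2)
    b1 *= spec.b1_lesion_median / np.median(b1[lesion])

    return PhantomTruth(
        grid=grid,
        t1_ms=grid.with_values(t1),
        m0=grid.with_values(m0),
        ktrans_per_min=grid.with_values(kt),
        ve=grid.with_values(ve),
        eye_mask=Mask(grid.with_values(eye.astype(np.uint8)), "eye"),
        lesion_mask=Mask(grid.with_values(lesion.astype(np.uint8)), "lesion"),
        b1=B1Map(grid.with_values(b1)),
        lobe_masks=lobes,
        zone_masks=zones,
    )


# ---------------------------------------------------------------------------
# Motion


def _smooth_drift(rng: np.random.Generator, nt: int, amplitude: float, ndim: int = 3) -> np.ndarray:
    """Slow sinusoidal drift per axis, peak vector norm == amplitude."""
    if amplitude <= 0:
        return np.zeros((nt, ndim))
    t = np.linspace(0, 1, nt)
    out = np.zeros((nt, ndim))
    for axis in range(ndim):
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        out[:, axis] = np.sin(2 * np.pi * freq * t + phase)
    norms = np.linalg.norm(out, axis=1)
    return out * (amplitude / max(norms.max(), 1e-9))


def simulate_motion_trace(spec: PhantomSpec, seed: int | None = None) -> MotionTrace:
    """Draw a per-dynamic rigid motion trace.

    Eye motion combines a slow gaze drift, brief blink-like translation
    spikes and step changes of gaze angle; head motion is a slow drift.
    All components are re-expressed relative to the reference dynamic (so
    the trace is identity there) and clipped to the spec's amplitude caps.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nt = spec.n_dynamics
    ref = spec.resolved_ref_index()
    c_eye = spec.resolved_eye_center()
    c_head = (np.asarray(spec.shape, dtype=float) - 1) / 2.0 * np.asarray(spec.spacing)

    t_eye = _smooth_drift(rng, nt, spec.drift_amplitude_mm)
    if spec.blink_shift_mm > 0 and spec.n_blinks > 0:
        frames = rng.choice(
            [i for i in range(1, nt - 1) if abs(i - ref) > 2],
            size=min(spec.n_blinks, nt - 4),
            replace=False,
        )
        for f in frames:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            for df in range(rng.integers(1, 3)):
                if f + df < nt:
                    t_eye[f + df] += spec.blink_shift_mm * direction

    r_eye = np.zeros((nt, 3))
    if spec.gaze_rotation_deg > 0 and spec.n_gaze_events > 0:
        starts = np.sort(
            rng.choice(
                [i for i in range(1, nt) if abs(i - ref) > 2],
                size=min(spec.n_gaze_events, nt - 4),
                replace=False,
            )
        )
        for s in starts:
            rv = rng.standard_normal(3)
            rv /= np.linalg.norm(rv)
            rv *= rng.uniform(0.4, 1.0) * spec.gaze_rotation_deg
            r_eye[s:] = rv  # gaze holds until the next event overwrites it

    t_head = _smooth_drift(rng, nt, spec.head_drift_amplitude_mm)
    r_head = np.zeros((nt, 3))
    if spec.head_rotation_deg > 0:
        r_head = _smooth_drift(rng, nt, spec.head_rotation_deg)

    # identity at the reference dynamic, then clip to the amplitude caps
    for arr, cap in (
        (t_eye, spec.max_translation_mm),
        (r_eye, spec.max_rotation_deg),
        (t_head, spec.max_translation_mm),
        (r_head, spec.max_rotation_deg),
    ):
        arr -= arr[ref]
        norms = np.linalg.norm(arr, axis=1)
        over = norms > cap
        if np.any(over):
            arr[over] *= (cap / norms[over])[:, None]

    def _tf(tr, rv, center):
        return RigidTransform(
            translation_mm=tr,
            center_mm=center,
            matrix=Rotation.from_rotvec(rv, degrees=True).as_matrix(),
        )

    eye_tfs = [_tf(t_eye[i], r_eye[i], c_eye) for i in range(nt)]
    head_tfs = [_tf(t_head[i], r_head[i], c_head) for i in range(nt)]
    return MotionTrace(eye_tfs, head_tfs, ref)


# ---------------------------------------------------------------------------
# Forward simulation


def _apply_motion(
    frame: np.ndarray,
    grid: VolumeImage,
    head: RigidTransform,
    eye: RigidTransform,
    eye_center: np.ndarray,
    eye_radius: float,
    margin_mm: float = 4.0,
) -> np.ndarray:
    """Resample one frame through the rigid trace (linear interpolation).

    The head transform acts globally; the eye transform acts only inside the
    (head-moved) globe, i.e. the eye is rigid within a static orbit - a
    deliberate simplification of real ocular motion.
    """
    if head.is_identity(1e-9, 1e-9) and eye.is_identity(1e-9, 1e-9):
        return frame
    shape = frame.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = grid.index_to_world(idx)
    src = head.inverse().apply(world)
    in_eye = np.linalg.norm(src - eye_center, axis=1) <= eye_radius + margin_mm
    if not eye.is_identity(1e-9, 1e-9):
        src[in_eye] = eye.inverse().apply(src[in_eye])
    src_idx = grid.world_to_index(src)
    out = map_coordinates(frame, src_idx.T, order=1, mode="nearest")
    return out.reshape(shape)


def simulate_dce(
    truth: PhantomTruth,
    acq: AcquisitionParams,
    aif: AIF,
    trace: MotionTrace | None,
    spec: PhantomSpec,
    return_clean: bool = False,
) -> tuple[DynamicSeries, FlipAngleSeries, B1Map, float, DynamicSeries | None]:
    """Generate the dynamic series and flip-angle series for a phantom.

    Per lesion voxel the tissue concentration follows the Tofts forward
    model; R1(t) = 1/T1_0 + r1 C(t); the SPGR signal uses the local achieved
    angle B1 * alpha.  Frames are then resampled through the motion trace and
    Rician noise of scale noise_sigma * (mean baseline lesion signal) is
    added.  Returns the absolute noise sigma for SNR bookkeeping.
    """
    nt = spec.n_dynamics
    times = np.arange(nt) * spec.interval_s
    if aif.times.size != nt or not np.allclose(aif.times, times):
        raise ValueError("AIF must be sampled on the dynamic time grid")

    t1_0 = truth.t1_ms.values
    m0 = truth.m0.values
    b1 = truth.b1.as_fraction()
    alpha_eff = b1 * acq.flip_angle_dce_deg

    base = spgr_signal(m0, t1_0, alpha_eff, acq.tr_dce_ms)
    signal = np.repeat(base[..., None], nt, axis=-1)

    enh = truth.ktrans_per_min.values > 0
    if enh.any():
        kt_v = truth.ktrans_per_min.values[enh]
        ve_v = truth.ve.values[enh]
        conc = tofts_forward(kt_v, ve_v, aif, times, spec.bat_index)  # (nvox, nt)
        r1_t = 1000.0 / t1_0[enh][:, None] + acq.relaxivity_r1 * conc  # 1/s
        t1_t = 1000.0 / r1_t
        signal[enh, :] = spgr_signal(
            m0[enh][:, None], t1_t, alpha_eff[enh][:, None], acq.tr_dce_ms
        )

    clean_frames = None
    grid = truth.grid
    if trace is not None:
        c_eye = spec.resolved_eye_center()
        moved = np.empty_like(signal)
        for i in range(nt):
            moved[..., i] = _apply_motion(
                signal[..., i], grid, trace.head[i], trace.eye[i], c_eye, spec.eye_radius_mm
            )
        if return_clean:
            clean_frames = signal
        signal = moved
    elif return_clean:
        clean_frames = signal.copy()

    sigma_abs = 0.0
    lesion = truth.lesion_mask.as_bool()
    if spec.noise_sigma > 0:
        sigma_abs = float(spec.noise_sigma * base[lesion].mean())
        rng = np.random.default_rng(spec.seed + 1)
        signal = _rician(signal, sigma_abs, rng)

    dynamic = DynamicSeries.from_array(signal, grid, times=times, interval=spec.interval_s)
    clean = (
        DynamicSeries.from_array(clean_frames, grid, times=times, interval=spec.interval_s)
        if clean_frames is not None
        else None
    )

    angles = np.array([2.0, 5.0, 9.0, 15.0])
    fa_stack = spgr_signal(
        m0[None, ...], t1_0[None, ...], b1[None, ...] * angles[:, None, None, None], acq.tr_vfa_ms
    )
    if spec.noise_sigma > 0:
        rng_fa = np.random.default_rng(spec.seed + 2)
        fa_stack = _rician(fa_stack, sigma_abs, rng_fa)
    fa_series = FlipAngleSeries(
        [grid.with_values(fa_stack[i]) for i in range(len(angles))], angles, acq.tr_vfa_ms
    )
    return dynamic, fa_series, truth.b1, sigma_abs, clean


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-image noise: |signal + n1 + i n2| with n1, n2 ~ N(0, sigma)."""
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_study(
    spec: PhantomSpec,
    acq: AcquisitionParams | None = None,
    aif: AIF | None = None,
    with_motion: bool = True,
    return_clean: bool = False,
) -> SimulatedStudy:
    """One-call convenience: phantom + trace + forward simulation."""
    acq = acq or AcquisitionParams()
    times = np.arange(spec.n_dynamics) * spec.interval_s
    if aif is None:
        # the Tofts forward model applies the bat_index shift itself,
        # so the generator consumes the unshifted population curve
        aif = population_aif(times, delay_s=0.0)
    truth = build_phantom(spec)
    has_motion = with_motion and (
        spec.drift_amplitude_mm > 0
        or spec.blink_shift_mm > 0
        or spec.gaze_rotation_deg > 0
        or spec.head_drift_amplitude_mm > 0
        or spec.head_rotation_deg > 0
    )
    trace = simulate_motion_trace(spec) if has_motion else _identity_trace(spec)
    dynamic, fa_series, b1, sigma_abs, clean = simulate_dce(
        truth, acq, aif, trace if has_motion else None, spec, return_clean=return_clean
    )
    return SimulatedStudy(
        dynamic=dynamic,
        fa_series=fa_series,
        b1=b1,
        truth=truth,
        trace=trace,
        aif=aif,
        acq=acq,
        spec=spec,
        noise_sigma_abs=sigma_abs,
        clean_dynamic=clean,
    )


def _identity_trace(spec: PhantomSpec) -> MotionTrace:
    ref = spec.resolved_ref_index()
    c_eye = spec.resolved_eye_center()
    c_head = (np.asarray(spec.shape, dtype=float) - 1) / 2.0 * np.asarray(spec.spacing)
    nt = spec.n_dynamics
    return MotionTrace(
        [RigidTransform.identity(c_eye) for _ in range(nt)],
        [RigidTransform.identity(c_head) for _ in range(nt)],
        ref,
    )
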