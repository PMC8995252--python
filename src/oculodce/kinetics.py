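"""Signal-to-concentration conversion, population AIF, bolus-arrival-time
search, voxel-wise standard Tofts fitting and lesion summaries.

The tracer-kinetic core is the standard Tofts model

    C(t) = Ktrans * integral_0^t Cp(tau) exp(-(Ktrans/ve) (t - tau)) dtau

with Ktrans the transfer constant (1/min), ve the extravascular extracellular
volume fraction and Cp the plasma concentration (arterial input function).
The convolution is evaluated with the exact recursion for a piecewise-linear
Cp, not a Riemann sum, so the forward model is accurate even at a 2 s
dynamic interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .core_io import AcquisitionParams, DynamicSeries, Mask
from .relaxometry import T1Map, spgr_signal

__all__ = [
    "AIF",
    "ConcentrationSeries",
    "PKMap",
    "population_aif",
    "aif_from_table",
    "tofts_forward",
    "signal_to_concentration",
    "relative_enhancement",
    "peak_concentration",
    "estimate_bat",
    "fit_tofts",
    "summarize_lesion",
]

#: Published population AIF parameters (mixed-Gaussian plus
#: exponential/sigmoid form; times in minutes, concentrations in mmol/L).
PARKER_AIF_PARAMS = {
    "A1": 0.809,
    "A2": 0.330,
    "T1": 0.17046,
    "T2": 0.365,
    "sigma1": 0.0563,
    "sigma2": 0.132,
    "alpha": 1.050,
    "beta": 0.1685,
    "s": 38.078,
    "tau": 0.483,
}


@dataclass
class AIF:
    """Plasma contrast concentration on the dynamic time grid (mmol/L)."""

    times: np.ndarray  # seconds since bolus arrival at t = delay_s
    cp: np.ndarray
    delay_s: float = 0.0
    kind: str = "population"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape:
            raise ValueError("times and cp must have equal length")
        if np.any(self.cp < -1e-12):
            raise ValueError("AIF concentrations must be non-negative")
        if np.any(self.cp[self.times < self.delay_s] > 1e-12):
            raise ValueError("AIF must be zero before its delay")


@dataclass
class ConcentrationSeries:
    """Per-voxel gadolinium concentration over time (mmol/L).

    ``conc`` has shape grid + (nt,), NaN outside the analysed region and at
    non-invertible voxel-timepoints; negative values from noise are kept.
    """

    conc: np.ndarray
    times: np.ndarray
    baseline_frames: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=int)
        if self.conc.shape[-1] != self.times.size:
            raise ValueError("concentration and time axes disagree")
        if self.valid is None:
            self.valid = np.isfinite(self.conc)


@dataclass
class PKMap:
    """Voxel-wise standard-Tofts parameters on the dynamic grid."""

    ktrans_per_min: np.ndarray
    ve: np.ndarray
    rss: np.ndarray
    fit_ok: np.ndarray
    bat_index: int

    @property
    def kep_per_min(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.ktrans_per_min / self.ve


# ---------------------------------------------------------------------------
# AIF


def _parker_cp(t_min: np.ndarray, p: dict) -> np.ndarray:
    g = np.zeros_like(t_min)
    for A, T, s in ((p["A1"], p["T1"], p["sigma1"]), (p["A2"], p["T2"], p["sigma2"])):
        g += A / (s * np.sqrt(2 * np.pi)) * np.exp(-((t_min - T) ** 2) / (2 * s**2))
    washout = p["alpha"] * np.exp(-p["beta"] * t_min) / (1 + np.exp(-p["s"] * (t_min - p["tau"])))
    return g + washout


def population_aif(
    times_s,
    params: dict | None = None,
    delay_s: float = 0.0,
) -> AIF:
    """Parametric population AIF sampled on the dynamic time grid.

    Uses the published mixed-Gaussian + exponential/sigmoid population model
    (parameters in :data:`PARKER_AIF_PARAMS`, overridable); the curve is
    shifted so the bolus arrives at ``delay_s`` seconds and is exactly zero
    before it.
    """
    times_s = np.asarray(times_s, dtype=float)
    if times_s.ndim != 1 or np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be a strictly ascending 1D grid")
    p = dict(PARKER_AIF_PARAMS)
    if params:
        p.update(params)
    t_min = (times_s - delay_s) / 60.0
    cp = np.where(t_min >= 0, _parker_cp(np.maximum(t_min, 0.0), p), 0.0)
    cp = np.maximum(cp, 0.0)
    cp[times_s < delay_s] = 0.0
    return AIF(times_s, cp, delay_s=delay_s, kind="population")


def aif_from_table(path: str | Path, times_s, delay_s: float = 0.0) -> AIF:
    """Load a tabulated AIF (two columns: time s, Cp mmol/L) and resample it
    onto the dynamic grid by linear interpolation."""
    table = np.loadtxt(path, delimiter=None)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("AIF table must have two columns: time_s, cp")
    t, cp = table[:, 0], table[:, 1]
    if np.any(cp < 0):
        raise ValueError("tabulated AIF contains negative concentrations")
    times_s = np.asarray(times_s, dtype=float)
    out = np.interp(times_s, t + delay_s, cp, left=0.0, right=float(cp[-1]))
    out[times_s < delay_s] = 0.0
    return AIF(times_s, out, delay_s=delay_s, kind="file")


# ---------------------------------------------------------------------------
# Tofts forward model


def tofts_forward(ktrans_per_min, ve, aif: AIF, times_s=None, bat_index: int = 0):
    """Standard Tofts tissue concentration for a piecewise-linear AIF.

    ``ktrans_per_min`` and ``ve`` broadcast, so a whole parameter grid can be
    evaluated in one call; the result has shape ``broadcast + (nt,)``.
    ``bat_index`` shifts the AIF so the bolus arrives at that dynamic frame:
    the tissue curve is identically zero before it.
    """
    ktrans = np.asarray(ktrans_per_min, dtype=float)
    ve_arr = np.asarray(ve, dtype=float)
    if np.any(ktrans < 0):
        raise ValueError("Ktrans must be non-negative")
    if np.any(ve_arr <= 0) or np.any(ve_arr > 1):
        if np.any((ve_arr == 0) & (ktrans > 0)):
            raise ValueError("ve = 0 with positive Ktrans is unphysical")
        raise ValueError("ve must lie in (0, 1]")
    times_s = aif.times if times_s is None else np.asarray(times_s, dtype=float)
    nt = times_s.size
    if aif.cp.size != nt:
        raise ValueError("AIF must be sampled on the dynamic time grid")

    # Shift the AIF by bat_index frames: cp_shift[i] = cp[i - bat]
    bat_index = int(bat_index)
    if bat_index < 0 or bat_index >= nt:
        raise ValueError("bat_index outside the scan")
    cp = np.zeros(nt)
    cp[bat_index:] = aif.cp[: nt - bat_index]

    kt, ve_b = np.broadcast_arrays(ktrans, ve_arr)
    shape = kt.shape
    kep = kt / ve_b  # 1/min
    t_min = times_s / 60.0
    dts = np.diff(t_min)

    uniform = np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12)
    if uniform and shape == ():
        # uniform grid, scalar parameters: the recursion collapses to a
        # discrete convolution of the per-interval integrals with E^k,
        # which is what the voxel-wise fitter hammers on
        dt = float(dts[0])
        kep_f = float(kep)
        E = np.exp(-kep_f * dt)
        m = np.diff(cp) / dt
        if kep_f * dt < 1e-8:
            seg = 0.5 * (cp[:-1] + cp[1:]) * dt
        else:
            inv = 1.0 / kep_f
            seg = cp[:-1] * (1.0 - E) * inv + m * (dt * inv - (1.0 - E) * inv * inv)
        kernel = E ** np.arange(nt - 1)
        acc = np.convolve(seg, kernel)[: nt - 1]
        out = np.zeros(nt)
        out[1:] = float(kt) * acc
        return out

    out = np.zeros(shape + (nt,))
    acc = np.zeros(shape)  # running integral value
    for i in range(1, nt):
        dt = t_min[i] - t_min[i - 1]
        E = np.exp(-kep * dt)
        m = (cp[i] - cp[i - 1]) / dt
        with np.errstate(divide="ignore", invalid="ignore"):
            small = kep * dt < 1e-8
            inv = np.where(small, np.inf, 1.0 / np.where(kep == 0, np.inf, kep))
            # exact integral of (cp[i-1] + m u) e^{-kep (dt-u)} over u in [0, dt]
            seg = cp[i - 1] * (1.0 - E) * inv + m * (dt * inv - (1.0 - E) * inv * inv)
        seg = np.where(small, 0.5 * (cp[i - 1] + cp[i]) * dt, seg)
        acc = acc * E + seg
        out[..., i] = kt * acc
    return out


# ---------------------------------------------------------------------------
# Signal <-> concentration


def signal_to_concentration(
    series: DynamicSeries,
    t1map: T1Map,
    acq: AcquisitionParams,
    baseline_frames,
    flip_angle_eff_deg: float | None = None,
    region: Mask | None = None,
) -> ConcentrationSeries:
    """Convert DCE signal to gadolinium concentration via full SPGR inversion.

    Per voxel, S0 is the mean over the baseline frames; the implied M0 from
    (S0, T1_0) then lets each dynamic signal be inverted for E1(t), hence
    R1(t) = 1/T1(t), and

        C(t) = (R1(t) - R1_0) / r1      [mmol/L, r1 in L/(mmol s)].

    Signals beyond the SPGR saturation branch are non-invertible; those
    voxel-timepoints are flagged NaN.  Negative concentrations from noise are
    retained.
    """
    data = series.stack().astype(float)
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size < 1:
        raise ValueError("need at least one baseline frame")
    if baseline_frames.max() >= series.n_frames or baseline_frames.min() < 0:
        raise ValueError("baseline frame index outside the series")

    alpha = float(flip_angle_eff_deg if flip_angle_eff_deg is not None else acq.flip_angle_dce_deg)
    a = np.deg2rad(alpha)
    tr = acq.tr_dce_ms

    t1_0 = np.asarray(t1map.t1_ms.values, dtype=float)
    sel = t1map.fit_ok.copy()
    if region is not None:
        sel &= region.as_bool()

    s0 = data[..., baseline_frames].mean(axis=-1)
    sel &= s0 > 0

    e1_0 = np.exp(-tr / t1_0)
    unit = np.sin(a) * (1 - e1_0) / (1 - e1_0 * np.cos(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / unit
        ms = m0 * np.sin(a)
        # invert S = M0 sin a (1-E1)/(1-E1 cos a)  ->  E1
        e1_t = (ms[..., None] - data) / (ms[..., None] - data * np.cos(a))
    valid = sel[..., None] & (e1_t > 0) & (e1_t < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_t = -np.log(np.where(valid, e1_t, 0.5)) / tr * 1000.0  # 1/s
        r1_0 = 1000.0 / t1_0
        conc = (r1_t - r1_0[..., None]) / acq.relaxivity_r1
    conc = np.where(valid, conc, np.nan)
    return ConcentrationSeries(conc, series.times, baseline_frames, valid)


def relative_enhancement(series: DynamicSeries, baseline_frames) -> np.ndarray:
    """Percent signal change from baseline: 100 (S(t) - S0) / S0.

    Voxels with S0 = 0 are NaN.  This is the T1-dependent time-intensity
    curve readout; it is biased across pigmentation and provided for
    comparison against true concentration curves.
    """
    data = series.stack().astype(float)
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    s0 = data[..., baseline_frames].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        re = 100.0 * (data - s0[..., None]) / s0[..., None]
    re[s0 <= 0] = np.nan
    return re


def peak_concentration(cs: ConcentrationSeries, q: float = 95.0) -> np.ndarray:
    """Per-voxel peak concentration: the 95th percentile over time.

    Uses the linear-interpolation percentile definition; robust against a
    single motion spike, unlike the maximum.
    """
    if cs.times.size < 20:
        raise ValueError("need at least 20 timepoints for a stable percentile")
    with np.errstate(invalid="ignore"):
        return np.nanpercentile(cs.conc, q, axis=-1)


# ---------------------------------------------------------------------------
# Fitting


def _grid_models(
    aif: AIF,
    times_s: np.ndarray,
    bat_index: int,
    grid_kt: np.ndarray,
    grid_ve: np.ndarray,
):
    """Model curves on the coarse start grid, shared by every voxel."""
    kt_g, ve_g = np.meshgrid(grid_kt, grid_ve, indexing="ij")
    return kt_g, ve_g, tofts_forward(kt_g, ve_g, aif, times_s, bat_index)


def _fit_curve(
    curve: np.ndarray,
    aif: AIF,
    times_s: np.ndarray,
    bat_index: int,
    grid_kt: np.ndarray,
    grid_ve: np.ndarray,
    n_starts: int = 2,
    grid_models=None,
) -> tuple[float, float, float, bool]:
    """NLLS fit of one concentration curve; multi-start from a coarse grid."""
    finite = np.isfinite(curve)
    if finite.sum() < 10:
        return np.nan, np.nan, np.nan, False
    y = curve[finite]

    if grid_models is None:
        grid_models = _grid_models(aif, times_s, bat_index, grid_kt, grid_ve)
    kt_g, ve_g, model_full = grid_models
    model = model_full[..., finite]
    rss = ((model - y) ** 2).sum(axis=-1)
    order = np.argsort(rss, axis=None)[:n_starts]

    def resid(p):
        return tofts_forward(p[0], p[1], aif, times_s, bat_index)[finite] - y

    best = None
    for flat in order:
        i, j = np.unravel_index(flat, rss.shape)
        x0 = np.array([kt_g[i, j], ve_g[i, j]])
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=([0.0, 1e-3], [5.0, 1.0]),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=500,
            )
        except Exception:
            continue
        cost = 2 * sol.cost
        if best is None or cost < best[2] - 1e-15:
            best = (sol.x[0], sol.x[1], cost, sol.success)
    if best is None:
        return np.nan, np.nan, np.nan, False
    kt, ve, cost, success = best
    ok = bool(success) and not (ve <= 1e-3 + 1e-9) and kt < 5.0 - 1e-9
    if kt <= 1e-6:
        ok = False  # no measurable uptake: ve is unidentifiable
    return float(kt), float(ve), float(cost), ok


_DEFAULT_GRID_KT = np.geomspace(0.02, 3.0, 4)
_DEFAULT_GRID_VE = np.array([0.05, 0.15, 0.35, 0.8])


def estimate_bat(
    median_curve,
    aif: AIF,
    times_s,
    n_candidates: int = 25,
    window: int = 40,
) -> tuple[int, np.ndarray]:
    """Grid search for the bolus arrival time on the median lesion curve.

    Fits (Ktrans, ve) on the first ``window`` timepoints for each of
    ``n_candidates`` consecutive integer frame shifts and returns the
    candidate with the lowest residual sum of squares (ties: earliest),
    together with the per-candidate RSS.
    """
    curve = np.asarray(median_curve, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if curve.size < window:
        raise ValueError(f"curve shorter than the {window}-point fit window")
    if not np.any(np.nan_to_num(curve) > 0):
        raise ValueError("flat zero curve: no enhancement to locate")
    head = curve[:window]
    t_head = times_s[:window]
    aif_head = AIF(t_head, aif.cp[:window], delay_s=aif.delay_s, kind=aif.kind)
    rss = np.full(n_candidates, np.inf)
    for b in range(min(n_candidates, window - 1)):
        _, _, cost, ok = _fit_curve(
            head, aif_head, t_head, b, _DEFAULT_GRID_KT, _DEFAULT_GRID_VE
        )
        if np.isfinite(cost):
            rss[b] = cost
    if not np.any(np.isfinite(rss)):
        raise ValueError("no BAT candidate produced a finite fit")
    return int(np.argmin(rss)), rss


def fit_tofts(
    cs: ConcentrationSeries,
    aif: AIF,
    bat_index: int,
    lesion: Mask,
    grid_kt: np.ndarray = _DEFAULT_GRID_KT,
    grid_ve: np.ndarray = _DEFAULT_GRID_VE,
) -> PKMap:
    """Voxel-wise standard-Tofts NLLS over the full dynamic curve.

    Bounds: Ktrans in [0, 5] 1/min, ve in (0, 1].  Each voxel starts from
    the best cells of a coarse log-spaced grid; non-converged or bound-pinned
    voxels are flagged.  Deterministic: no randomness anywhere in the fit.
    """
    sel = lesion.as_bool()
    if cs.conc.shape[:-1] != sel.shape:
        raise ValueError("concentration grid and lesion mask disagree")
    shape = sel.shape
    kt = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    ok = np.zeros(shape, dtype=bool)
    times_s = cs.times
    models = _grid_models(aif, times_s, bat_index, grid_kt, grid_ve)
    for idx in np.argwhere(sel):
        i, j, k = idx
        curve = cs.conc[i, j, k, :]
        kt_v, ve_v, cost, ok_v = _fit_curve(
            curve, aif, times_s, bat_index, grid_kt, grid_ve, grid_models=models
        )
        kt[i, j, k] = kt_v
        ve[i, j, k] = ve_v
        rss[i, j, k] = cost
        ok[i, j, k] = ok_v
    return PKMap(kt, ve, rss, ok, int(bat_index))


def summarize_lesion(values: np.ndarray, lesion: Mask, fit_ok: np.ndarray | None = None) -> dict:
    """Median / 25th / 75th percentile summary over fit-ok lesion voxels.

    Percentiles use the linear-interpolation definition.  Raises when no
    voxel is usable rather than returning a silent NaN row.
    """
    sel = lesion.as_bool()
    usable = sel if fit_ok is None else (sel & np.asarray(fit_ok, dtype=bool))
    vals = np.asarray(values, dtype=float)[usable]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no fit-ok lesion voxels to summarize")
    p25, med, p75 = np.percentile(vals, [25, 50, 75])
    return {
        "median": float(med),
        "p25": float(p25),
        "p75": float(p75),
        "iqr": float(p75 - p25),
        "n_total": int(sel.sum()),
        "n_ok": int(vals.size),
    }
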