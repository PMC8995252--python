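"""B1+-corrected variable-flip-angle T1 mapping.

The forward model is the spoiled gradient-echo (SPGR) steady state

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),   E1 = exp(-TR / T1).

T1 and M0 are estimated from signals at several flip angles by the classic
linearisation: plotting S/sin(a) against S/tan(a) gives a line with slope E1
and intercept M0 (1 - E1).  Transmit-field inhomogeneity scales the achieved
flip angle, so nominal angles are corrected by the relative B1+ before the
fit; the default correction uses a single scalar factor, the median B1+ over
the lesion, which is how small ocular lesions are handled in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import B1Map, FlipAngleSeries, Mask, VolumeImage

__all__ = [
    "T1Map",
    "spgr_signal",
    "correct_flip_angles",
    "fit_vfa_t1",
    "masked_median_filter",
]

_NEIGHBORHOOD_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
]


@dataclass
class T1Map:
    """Per-voxel baseline T1 (ms) with equilibrium signal and fit flags.

    Voxels where the linearised fit produced a slope outside (0, 1) are
    flagged ``fit_ok = False`` and carry NaN instead of a clamped value.
    """

    t1_ms: VolumeImage
    m0: VolumeImage
    fit_ok: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fit_ok is None:
            self.fit_ok = np.isfinite(self.t1_ms.values)
        self.fit_ok = np.asarray(self.fit_ok, dtype=bool)
        ok_vals = self.t1_ms.values[self.fit_ok]
        if ok_vals.size and (np.any(~np.isfinite(ok_vals)) or np.any(ok_vals <= 0)):
            raise ValueError("fit-ok voxels must carry finite positive T1")

    def with_t1(self, t1_ms: np.ndarray, fit_ok: np.ndarray | None = None) -> "T1Map":
        return T1Map(
            self.t1_ms.with_values(t1_ms),
            self.m0,
            self.fit_ok if fit_ok is None else fit_ok,
        )


def spgr_signal(m0, t1_ms, flip_deg, tr_ms):
    """Steady-state SPGR signal; broadcasts over voxel arrays.

    Parameters are the equilibrium signal, T1 in ms, flip angle in degrees
    and TR in ms.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("T1 must be positive")
    flip_deg = np.asarray(flip_deg, dtype=float)
    if np.any(flip_deg < 0) or np.any(flip_deg > 90):
        raise ValueError("flip angle must lie in [0, 90] degrees")
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("TR must be positive")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / t1_ms)
    return np.asarray(m0) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def correct_flip_angles(
    nominal_deg,
    b1: B1Map,
    lesion: Mask,
    mode: str = "lesion-median",
):
    """Scale nominal flip angles by the achieved B1+.

    ``lesion-median`` (default) applies one scalar factor, the median B1+
    fraction over the lesion; ``voxelwise`` returns per-voxel effective
    angles of shape (n_angles, nx, ny, nz).
    """
    nominal = np.asarray(nominal_deg, dtype=float)
    frac = b1.as_fraction()
    sel = lesion.as_bool()
    if not sel.any():
        raise ValueError("lesion mask is empty; cannot derive a B1+ factor")
    if frac.shape != sel.shape:
        raise ValueError("B1 map and lesion mask must share one grid")
    if mode == "lesion-median":
        factor = float(np.median(frac[sel]))
        return nominal * factor
    if mode == "voxelwise":
        return nominal[:, None, None, None] * frac[None, ...]
    raise ValueError(f"unknown correction mode {mode!r}")


def fit_vfa_t1(
    fa_series: FlipAngleSeries,
    effective_angles_deg=None,
    mask: Mask | None = None,
) -> T1Map:
    """Estimate T1 and M0 from a variable-flip-angle SPGR series.

    Per voxel, an ordinary least-squares line through (S/tan a, S/sin a)
    yields slope E1 and intercept M0 (1 - E1); T1 = -TR / ln(E1).  Voxels
    with slope outside (0, 1), all-zero signal, or a degenerate design are
    flagged instead of raising.
    """
    signals = fa_series.stack().astype(float)  # (n_angles, nx, ny, nz)
    if effective_angles_deg is None:
        effective_angles_deg = fa_series.nominal_flip_angles_deg
    angles = np.asarray(effective_angles_deg, dtype=float)
    if angles.ndim == 1:
        angles = angles[:, None, None, None]
    elif angles.shape != signals.shape:
        raise ValueError("per-voxel angles must match the signal array shape")
    a = np.deg2rad(angles)

    with np.errstate(divide="ignore", invalid="ignore"):
        y = signals / np.sin(a)
        x = signals / np.tan(a)

    sel = np.ones(signals.shape[1:], dtype=bool) if mask is None else mask.as_bool()

    n = signals.shape[0]
    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n

    ok = (
        sel
        & np.isfinite(slope)
        & np.isfinite(intercept)
        & (slope > 0.0)
        & (slope < 1.0)
        & (np.abs(denom) > 0)
        & np.all(np.isfinite(y), axis=0)
        # a signal that does not vary with the flip angle carries no T1
        # information even when the linearised slope lands in (0, 1)
        & (signals.std(axis=0) > 0)
    )
    t1 = np.full(slope.shape, np.nan)
    m0 = np.full(slope.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1[ok] = -fa_series.tr_ms / np.log(slope[ok])
        m0[ok] = intercept[ok] / (1.0 - slope[ok])

    grid = fa_series.grid
    return T1Map(grid.with_values(t1), grid.with_values(m0), ok)


def masked_median_filter(t1map: T1Map, lesion: Mask) -> T1Map:
    """3D median filter over the 26-connected neighbourhood, lesion-masked.

    Each lesion voxel is replaced by the median of itself and those of its
    26 neighbours that also lie inside the lesion (and fitted OK); voxels
    outside the lesion never contribute and are never altered.  This removes
    isolated outliers without dragging in the long-T1 vitreous next door.
    """
    sel = lesion.as_bool()
    if sel.shape != t1map.t1_ms.shape:
        raise ValueError("T1 map and lesion mask must share one grid")
    vals = np.asarray(t1map.t1_ms.values, dtype=float)
    inmask = np.where(sel & t1map.fit_ok, vals, np.nan)

    stacks = np.full((len(_NEIGHBORHOOD_26),) + vals.shape, np.nan)
    for i, (dx, dy, dz) in enumerate(_NEIGHBORHOOD_26):
        src = inmask[
            max(0, -dx) : inmask.shape[0] - max(0, dx),
            max(0, -dy) : inmask.shape[1] - max(0, dy),
            max(0, -dz) : inmask.shape[2] - max(0, dz),
        ]
        stacks[
            i,
            max(0, dx) : inmask.shape[0] - max(0, -dx),
            max(0, dy) : inmask.shape[1] - max(0, -dy),
            max(0, dz) : inmask.shape[2] - max(0, -dz),
        ] = src

    lesion_cols = stacks[:, sel]
    n_valid = np.isfinite(lesion_cols).sum(axis=0)
    filtered = np.full(lesion_cols.shape[1], np.nan)
    has = n_valid > 0
    if has.any():
        filtered[has] = np.nanmedian(lesion_cols[:, has], axis=0)

    out = vals.copy()
    fin = np.isfinite(filtered)
    lesion_idx = np.argwhere(sel)
    out[tuple(lesion_idx[fin].T)] = filtered[fin]
    ok = t1map.fit_ok.copy()
    ok[tuple(lesion_idx[fin].T)] = True
    ok[tuple(lesion_idx[~fin].T)] = False
    out[~ok] = np.nan
    return T1Map(t1map.t1_ms.with_values(out), t1map.m0, ok)
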