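"""Voxelwise T1 relaxometry: spoiled gradient-echo (VFA) and inversion
recovery signal models and their least-squares fits.

VFA model (SPGR steady state, TE << T2*)::

    S(alpha) = S0 * sin(f*alpha) * (1 - E1) / (1 - E1 * cos(f*alpha)),
    E1 = exp(-TR / T1)

where ``alpha`` is the prescribed flip angle and ``f`` the flip-angle
correction factor from B1 mapping (f = 1 for the uncorrected fit).

IR model (magnitude, inversion flip ``alpha_inv``, predelay TD)::

    S(TI) = S0 * | cos(alpha_inv) * (1 - exp(-TD/T1)) * exp(-TI/T1)
                  + 1 - exp(-TI/T1) |

Both fits run as batched Levenberg-Marquardt over all foreground voxels
(see :mod:`bst1map.fitting`) with deterministic, data-derived starting
values: the VFA fit initializes from the classic linearized regression of
``S/sin(f*alpha)`` on ``S/tan(f*alpha)`` (DESPOT1), the IR fit from the
signal-null heuristic ``T1 ~ TI_null / ln 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CorrectionFactorMap, IRSeries, T1Map, VFASeries
from .fitting import lm_fit

__all__ = [
    "FitOptions",
    "spgr_signal",
    "ir_signal",
    "fit_vfa",
    "fit_ir",
]


@dataclass
class FitOptions:
    """Optimizer settings for the voxelwise fits.

    ``t1_bounds_ms`` brackets every tissue of interest by default;
    ``min_signal`` skips voxels whose strongest sample is at or below the
    floor (background); ``init_strategy`` is ``"linearized"`` (data-driven,
    default) or ``"fixed"`` (T1 = 1000 ms, S0 from the data maximum).
    ``fit_inv_flip`` frees the inversion flip angle in the IR fit instead
    of fixing it at the protocol value.
    """

    t1_bounds_ms: tuple[float, float] = (1.0, 10000.0)
    max_iter: int = 60
    tol: float = 1e-12
    init_strategy: str = "linearized"
    min_signal: float = 0.0
    fit_inv_flip: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.t1_bounds_ms
        if not (0 < lo < hi):
            raise ValueError("t1_bounds_ms must satisfy 0 < low < high")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init_strategy not in ("linearized", "fixed"):
            raise ValueError("init_strategy must be 'linearized' or 'fixed'")


def spgr_signal(t1_ms, s0, alpha_deg, f=1.0, tr_ms=7.9):
    """Spoiled gradient-echo steady-state signal (pure function, broadcasts)."""
    t1 = np.asarray(t1_ms, dtype=float)
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float) * np.asarray(f, dtype=float))
    e1 = np.exp(-tr_ms / t1)
    return np.asarray(s0, dtype=float) * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def ir_signal(t1_ms, s0, ti_ms, td_ms=2500.0, inv_flip_deg=180.0):
    """Magnitude inversion-recovery signal with finite predelay TD."""
    t1 = np.asarray(t1_ms, dtype=float)
    ti = np.asarray(ti_ms, dtype=float)
    ca = np.cos(np.deg2rad(inv_flip_deg))
    e_td = np.exp(-td_ms / t1)
    e_ti = np.exp(-ti / t1)
    return np.asarray(s0, dtype=float) * np.abs(ca * (1 - e_td) * e_ti + 1 - e_ti)


# ---------------------------------------------------------------------------
# VFA fit


def _despot1_init(signals: np.ndarray, alpha: np.ndarray, f: np.ndarray, tr_ms: float,
                  t1_bounds: tuple[float, float]) -> np.ndarray:
    """Linearized DESPOT1 start: regress S/sin(fa) on S/tan(fa) per voxel."""
    a = alpha[None, :] * f[:, None]  # (N, K) effective angles, rad
    y = signals / np.sin(a)
    x = signals / np.tan(a)
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    sxy = np.sum((x - xm) * (y - ym), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = (ym[:, 0] - slope * xm[:, 0])
        t1 = -tr_ms / np.log(slope)
        s0 = intercept / (1 - slope)
    bad = ~np.isfinite(t1) | (slope <= 0) | (slope >= 1) | ~np.isfinite(s0) | (s0 <= 0)
    t1 = np.where(bad, 1000.0, t1)
    s0 = np.where(bad, signals.max(axis=1) / np.maximum(np.sin(a).max(axis=1), 1e-6), s0)
    t1 = np.clip(t1, t1_bounds[0], t1_bounds[1])
    return np.column_stack([t1, s0])


def fit_vfa(
    series: VFASeries,
    f_map: CorrectionFactorMap | None = None,
    options: FitOptions | None = None,
) -> T1Map:
    """Fit the SPGR model per voxel in (T1, S0).

    ``f_map`` supplies the per-voxel flip-angle correction; omit it (or
    pass a uniform-1 map) for the uncorrected fit.  The returned map is
    tagged ``"VFA_B1"`` when any correction factor differs from 1, else
    ``"VFA"``.  Voxels that are background (signal floor), carry an
    invalid correction factor, or fail to converge are invalid (NaN).
    """
    options = options or FitOptions()
    if len(series.flip_angles_deg) < 3:
        raise ValueError("VFA fit needs at least 3 flip angles")
    shape = series.shape
    signals = series.stack().reshape(len(series.flip_angles_deg), -1).T  # (N, K)
    signals = np.abs(signals)
    alpha = np.deg2rad(np.array(series.flip_angles_deg))

    if f_map is None:
        f_flat = np.ones(signals.shape[0])
        f_valid = np.ones(signals.shape[0], dtype=bool)
        corrected = False
    else:
        if f_map.shape != shape:
            raise ValueError("f_map grid differs from the series grid")
        f_flat = f_map.f.reshape(-1)
        f_valid = f_map.valid_mask.reshape(-1)
        f_flat = np.where(f_valid, f_flat, 1.0)
        corrected = bool(np.any(np.abs(f_flat[f_valid] - 1.0) > 1e-12))

    fit_mask = (signals.max(axis=1) > options.min_signal) & f_valid & \
        np.all(np.isfinite(signals), axis=1) & (signals.max(axis=1) > 0)

    t1 = np.full(signals.shape[0], np.nan)
    s0 = np.full(signals.shape[0], np.nan)
    rss = np.full(signals.shape[0], np.nan)
    valid = np.zeros(signals.shape[0], dtype=bool)

    if fit_mask.any():
        sig = signals[fit_mask]
        f_sel = f_flat[fit_mask]
        tr = series.tr_ms

        if options.init_strategy == "linearized":
            p0 = _despot1_init(sig, alpha, f_sel, tr, options.t1_bounds_ms)
        else:
            p0 = np.column_stack([
                np.full(sig.shape[0], 1000.0),
                sig.max(axis=1) / np.maximum(np.sin(alpha).max(), 1e-6),
            ])

        a_eff = alpha[None, :] * f_sel[:, None]
        sin_a_all, cos_a_all = np.sin(a_eff), np.cos(a_eff)

        def model_jac(p, idx, need_jac=True):
            sin_a = sin_a_all if idx is None else sin_a_all[idx]
            cos_a = cos_a_all if idx is None else cos_a_all[idx]
            t1_, s0_ = p[:, 0:1], p[:, 1:2]
            e1 = np.exp(-tr / t1_)
            denom = 1 - e1 * cos_a
            frac = (1 - e1) / denom
            pred = s0_ * sin_a * frac
            if not need_jac:
                return pred, None
            # dS/dE1 = s0 * sin * (cos - 1) / denom^2 ; dE1/dT1 = e1*tr/t1^2
            ds_de1 = s0_ * sin_a * (cos_a - 1) / denom**2
            dt1 = ds_de1 * e1 * tr / t1_**2
            ds0 = sin_a * frac
            return pred, np.stack([dt1, ds0], axis=-1)

        lo = np.array([options.t1_bounds_ms[0], 1e-12])
        hi = np.array([options.t1_bounds_ms[1], np.inf])
        p, cost, conv = lm_fit(
            model_jac, p0, sig, (lo, hi),
            max_iter=options.max_iter, tol=options.tol,
        )
        ok = conv & (p[:, 0] > options.t1_bounds_ms[0]) & \
            (p[:, 0] < options.t1_bounds_ms[1]) & (p[:, 1] > 0)
        idx = np.flatnonzero(fit_mask)
        t1[idx[ok]] = p[ok, 0]
        s0[idx[ok]] = p[ok, 1]
        rss[idx[ok]] = cost[ok]
        valid[idx[ok]] = True

    return T1Map(
        t1_ms=t1.reshape(shape),
        s0=s0.reshape(shape),
        rss=rss.reshape(shape),
        method="VFA_B1" if corrected else "VFA",
        valid_mask=valid.reshape(shape),
        voxel_size_mm=series.volumes[0].voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# IR fit


def fit_ir(series: IRSeries, options: FitOptions | None = None) -> T1Map:
    """Fit the magnitude IR model per voxel.

    Default: two parameters (T1, S0) with the inversion flip fixed at the
    protocol value; set ``options.fit_inv_flip`` to additionally free the
    inversion flip angle.  The magnitude model is fitted directly -- no
    polarity restoration is attempted.
    """
    options = options or FitOptions()
    if len(series.ti_ms) < 4:
        raise ValueError("IR fit needs at least 4 inversion times")
    shape = series.shape
    ti = np.array(series.ti_ms)
    td = series.td_ms
    signals = np.abs(series.stack().reshape(len(ti), -1).T)  # (N, K)

    fit_mask = (signals.max(axis=1) > options.min_signal) & \
        np.all(np.isfinite(signals), axis=1) & (signals.max(axis=1) > 0)

    t1 = np.full(signals.shape[0], np.nan)
    s0 = np.full(signals.shape[0], np.nan)
    rss = np.full(signals.shape[0], np.nan)
    valid = np.zeros(signals.shape[0], dtype=bool)

    if fit_mask.any():
        sig = signals[fit_mask]
        # null heuristic: the TI with the weakest signal sits near T1*ln2
        ti_null = ti[np.argmin(sig, axis=1)]
        t1_init = np.clip(ti_null / np.log(2.0), *options.t1_bounds_ms)
        s0_init = sig[:, -1]  # longest TI ~ fully recovered
        s0_init = np.maximum(s0_init, 1e-12)
        if options.init_strategy == "fixed":
            t1_init = np.full_like(t1_init, 1000.0)

        ca0 = np.cos(np.deg2rad(series.inv_flip_deg))

        if options.fit_inv_flip:
            p0 = np.column_stack([t1_init, s0_init,
                                  np.full_like(t1_init, series.inv_flip_deg)])
            lo = np.array([options.t1_bounds_ms[0], 1e-12, 90.0])
            hi = np.array([options.t1_bounds_ms[1], np.inf, 180.0])
        else:
            p0 = np.column_stack([t1_init, s0_init])
            lo = np.array([options.t1_bounds_ms[0], 1e-12])
            hi = np.array([options.t1_bounds_ms[1], np.inf])

        def model_jac(p, idx, need_jac=True):
            t1_, s0_ = p[:, 0:1], p[:, 1:2]
            ca = np.cos(np.deg2rad(p[:, 2:3])) if options.fit_inv_flip else ca0
            e_td = np.exp(-td / t1_)
            e_ti = np.exp(-ti[None, :] / t1_)
            inner = ca * (1 - e_td) * e_ti + 1 - e_ti
            pred = s0_ * np.abs(inner)
            if not need_jac:
                return pred, None
            sgn = np.where(inner >= 0, 1.0, -1.0)
            # d inner / dT1 via d/dT1 exp(-x/T1) = exp(-x/T1) * x / T1^2
            de_td = e_td * td / t1_**2
            de_ti = e_ti * ti[None, :] / t1_**2
            dinner_dt1 = ca * (-de_td * e_ti + (1 - e_td) * de_ti) - de_ti
            dt1 = s0_ * sgn * dinner_dt1
            ds0 = np.abs(inner)
            if options.fit_inv_flip:
                dca = -np.sin(np.deg2rad(p[:, 2:3])) * np.pi / 180.0
                dflip = s0_ * sgn * (1 - e_td) * e_ti * dca
                jac = np.stack([dt1, ds0, dflip], axis=-1)
            else:
                jac = np.stack([dt1, ds0], axis=-1)
            return pred, jac

        p, cost, conv = lm_fit(
            model_jac, p0, sig, (lo, hi),
            max_iter=options.max_iter, tol=options.tol,
        )
        ok = conv & (p[:, 0] > options.t1_bounds_ms[0]) & \
            (p[:, 0] < options.t1_bounds_ms[1]) & (p[:, 1] > 0)
        idx = np.flatnonzero(fit_mask)
        t1[idx[ok]] = p[ok, 0]
        s0[idx[ok]] = p[ok, 1]
        rss[idx[ok]] = cost[ok]
        valid[idx[ok]] = True

    return T1Map(
        t1_ms=t1.reshape(shape),
        s0=s0.reshape(shape),
        rss=rss.reshape(shape),
        method="IR",
        valid_mask=valid.reshape(shape),
        voxel_size_mm=series.volumes[0].voxel_size_mm,
    )
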