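"""Vectorized Levenberg-Marquardt for voxelwise model fitting.

Relaxometry maps require the same small nonlinear least-squares problem
solved independently at every voxel (2-3 parameters, 10-12 data points).
Calling a generic scalar optimizer per voxel is orders of magnitude slower
than batching, so this module implements the standard damped Gauss-Newton
(Levenberg-Marquardt) update across all voxels at once with analytic
Jacobians, simple box bounds by projection, and monotone cost acceptance:
a step is taken only where it lowers the residual sum of squares, so the
final residual never exceeds the initialization's.  Voxels leave the
active set as they converge.  Everything is plain numpy and deterministic.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["lm_fit"]

_LAM_MAX = 1e10


def lm_fit(
    model_jac: Callable,
    p0: np.ndarray,
    data: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    max_iter: int = 60,
    tol: float = 1e-10,
    lam0: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimize ``sum((model(p) - data)**2)`` independently per row.

    Parameters
    ----------
    model_jac
        ``model_jac(p, idx, need_jac)`` evaluates the model for the rows
        selected by the index array ``idx`` (``None`` means all rows) at
        parameters ``p`` of shape ``(M, P)``; returns ``(pred, jac)`` of
        shapes ``(M, K)`` and ``(M, K, P)`` (``jac`` may be ``None`` when
        ``need_jac`` is False).
    p0
        Initial parameters, shape ``(N, P)``.
    data
        Observations, shape ``(N, K)``.
    bounds
        ``(lo, hi)`` arrays broadcastable to ``(P,)``; parameters are kept
        inside by projection after each accepted step.
    tol
        Relative cost-decrease threshold: a voxel is converged once an
        accepted step improves its cost by less than this fraction, or no
        acceptable step remains (damping saturated / step negligible).

    Returns
    -------
    p, rss, converged
        Parameters ``(N, P)``, per-voxel residual sum of squares ``(N,)``
        and a boolean convergence flag ``(N,)``.
    """
    lo = np.broadcast_to(np.asarray(bounds[0], dtype=float), p0.shape[1:])
    hi = np.broadcast_to(np.asarray(bounds[1], dtype=float), p0.shape[1:])
    p = np.clip(np.asarray(p0, dtype=float), lo, hi)
    n, n_par = p.shape
    eye = np.eye(n_par)

    pred0 = model_jac(p, None, False)[0]
    cost = np.sum((pred0 - data) ** 2, axis=1)
    lam = np.full(n, lam0)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)

    for _ in range(max_iter):
        if active.size == 0:
            break
        pa = p[active]
        pred, jac = model_jac(pa, active, True)
        resid = pred - data[active]
        # normal equations per voxel: (J^T J + lam * diag(J^T J)) dp = -J^T r
        jtj = np.einsum("nkp,nkq->npq", jac, jac)
        jtr = np.einsum("nkp,nk->np", jac, resid)
        diag = jtj * eye
        diag = np.where(diag > 1e-300, diag, 1e-300 * eye)
        a = jtj + lam[active, None, None] * diag
        try:
            dp = -np.linalg.solve(a, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            dp = -np.linalg.solve(a + 1e-12 * eye, jtr[..., None])[..., 0]
        p_trial = np.clip(pa + dp, lo, hi)
        pred_t = model_jac(p_trial, active, False)[0]
        cost_t = np.sum((pred_t - data[active]) ** 2, axis=1)

        cost_a = cost[active]
        better = cost_t < cost_a
        rel_gain = (cost_a - cost_t) / np.maximum(cost_a, 1e-300)
        step_rel = np.max(np.abs(p_trial - pa) / np.maximum(np.abs(pa), 1e-300),
                          axis=1)

        upd = active[better]
        p[upd] = p_trial[better]
        cost[upd] = cost_t[better]
        lam[upd] = np.maximum(lam[upd] / 3.0, 1e-12)
        rej = active[~better]
        lam[rej] = np.minimum(lam[rej] * 10.0, _LAM_MAX)

        done = np.zeros(active.size, dtype=bool)
        done |= better & (rel_gain < tol)
        done |= ~better & ((lam[active] >= _LAM_MAX) | (step_rel < 1e-12))
        converged[active[done]] = True
        active = active[~done]

    return p, cost, converged
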