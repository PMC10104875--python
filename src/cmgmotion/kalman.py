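"""Linear-Gaussian state-space smoothing of 1-D trajectories.

The state is a local linear trend (position, velocity) evolving as

    [x, v]_{k+1} = [[1, dt], [0, 1]] [x, v]_k + w_k,   w_k ~ N(0, Q)
    y_k          = x_k + e_k,                           e_k ~ N(0, R)

Process covariance Q, observation variance R and the initial state are
fitted to each trace by expectation-maximization (Shumway & Stoffer),
then the Rauch-Tung-Striebel smoother produces the denoised positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["smooth_positions", "KalmanSmoothResult"]


@dataclass
class KalmanSmoothResult:
    smoothed: np.ndarray  # smoothed positions, same length as input
    converged: bool  # False -> input returned unchanged
    n_iter: int
    log_likelihood: float


def _filter_smooth(y, F, H, Q, R, mu0, P0):
    # H is the row [1, 0]: only the position is observed; R is scalar.
    n, dim = y.size, 2
    h = np.asarray(H).ravel()
    r = float(np.asarray(R).ravel()[0])
    xp = np.zeros((n, dim))
    Pp = np.zeros((n, dim, dim))
    xf = np.zeros((n, dim))
    Pf = np.zeros((n, dim, dim))
    ll = 0.0
    for k in range(n):
        if k == 0:
            xp[0], Pp[0] = mu0, P0
        else:
            xp[k] = F @ xf[k - 1]
            Pp[k] = F @ Pf[k - 1] @ F.T + Q
        S = max(float(h @ Pp[k] @ h) + r, 1e-12)
        K = (Pp[k] @ h) / S
        innov = y[k] - float(h @ xp[k])
        xf[k] = xp[k] + K * innov
        Pf[k] = Pp[k] - np.outer(K, h @ Pp[k])
        ll += -0.5 * (np.log(2 * np.pi * S) + innov**2 / S)
    # RTS smoother
    xs = np.zeros_like(xf)
    Ps = np.zeros_like(Pf)
    xs[-1], Ps[-1] = xf[-1], Pf[-1]
    G = np.zeros((n, 2, 2))
    for k in range(n - 2, -1, -1):
        G[k] = Pf[k] @ F.T @ np.linalg.inv(Pp[k + 1])
        xs[k] = xf[k] + G[k] @ (xs[k + 1] - xp[k + 1])
        Ps[k] = Pf[k] + G[k] @ (Ps[k + 1] - Pp[k + 1]) @ G[k].T
    # lag-one smoothed cross-covariances P_{k,k-1}
    Pcc = np.zeros((n, 2, 2))
    for k in range(1, n):
        Pcc[k] = Ps[k] @ G[k - 1].T
    return xs, Ps, Pcc, ll


def smooth_positions(
    positions: np.ndarray,
    frame_interval: float = 1.0,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> KalmanSmoothResult:
    """EM-fitted Kalman smoothing of a position series.

    Returns the input unchanged (``converged=False``) when EM cannot make
    numerical progress, e.g. on degenerate or very short series.
    """
    y = np.asarray(positions, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D series of at least 3 positions")
    n = y.size
    dt = float(frame_interval)
    F = np.array([[1.0, dt], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])

    # Moment-based initialization from first differences.
    dy = np.diff(y)
    var_d = max(float(np.var(dy)), 1e-8)
    R = var_d / 2.0
    Q = np.diag([var_d / 10.0, max(var_d / (10.0 * dt * dt), 1e-10)])
    mu0 = np.array([y[0], dy[0] / dt if n > 1 else 0.0])
    P0 = np.diag([var_d, var_d / (dt * dt)])

    ll_prev = -np.inf
    xs = None
    n_iter = 0
    try:
        for n_iter in range(1, max_iter + 1):
            xs, Ps, Pcc, ll = _filter_smooth(y, F, H, Q, np.array([[R]]), mu0, P0)
            # E-step sufficient statistics
            Exx = Ps + np.einsum("ki,kj->kij", xs, xs)
            A = Exx[:-1].sum(axis=0)
            B = (Pcc[1:] + np.einsum("ki,kj->kij", xs[1:], xs[:-1])).sum(axis=0)
            C = Exx[1:].sum(axis=0)
            # M-step with F fixed: Q from residual second moments
            Qn = (C - B @ F.T - F @ B.T + F @ A @ F.T) / (n - 1)
            Qn = (Qn + Qn.T) / 2.0
            Qn += 1e-10 * np.eye(2)
            Rn = float(np.mean((y - xs[:, 0]) ** 2 + Ps[:, 0, 0]))
            mu0, P0 = xs[0], Ps[0] + 1e-10 * np.eye(2)
            Q, R = Qn, max(Rn, 1e-10)
            if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
                break
            ll_prev = ll
    except np.linalg.LinAlgError:
        return KalmanSmoothResult(y.copy(), converged=False, n_iter=n_iter, log_likelihood=np.nan)
    if xs is None or not np.all(np.isfinite(xs)):
        return KalmanSmoothResult(y.copy(), converged=False, n_iter=n_iter, log_likelihood=np.nan)
    return KalmanSmoothResult(xs[:, 0], converged=True, n_iter=n_iter, log_likelihood=float(ll))
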