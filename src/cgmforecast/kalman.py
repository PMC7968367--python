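"""Kalman filtering and Rauch–Tung–Striebel smoothing for CGM correction.

CGM traces carry sensor error: white measurement noise, isolated spikes,
pressure-induced sensor attenuation (PISA) episodes and transmission gaps.
A linear-Gaussian state-space model

    x_{k+1} = Φ x_k + B u_k + w_k,      w_k ~ N(0, Q)
    y_k     = H x_k + v_k,              v_k ~ N(0, R)

is filtered forward (time update + measure update, skipping the measure
update at missing slots) and smoothed backward with the RTS fixed-interval
recursion, yielding a posterior glucose mean and variance at every grid
index — including gaps, where the variance inflates to reflect the missing
data.  The smoother must be run per data file (training and test files
separately) so no information leaks across the train/test boundary.

The default CGM model is a two-state local linear trend: state
``[glucose (mg/dl), rate of change (mg/dl per index)]`` with
``Φ = [[1, 1], [0, 1]]``, ``H = [1, 0]`` and a white-noise-jerk process
covariance ``Q = q·[[1/3, 1/2], [1/2, 1]]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import PatientSeries


@dataclass
class StateSpaceModel:
    """Time-invariant linear-Gaussian state-space model (scalar measurement)."""

    phi: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: float
    x0: np.ndarray
    P0: np.ndarray
    B: np.ndarray | None = None  # input matrix; default zero (no exogenous input)

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        d = self.phi.shape[0]
        if self.phi.shape != (d, d):
            raise ValueError("phi must be square")
        self.H = np.asarray(self.H, dtype=float).reshape(1, d)
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.Q.shape != (d, d):
            raise ValueError("Q dimension mismatch")
        if not np.allclose(self.Q, self.Q.T):
            raise ValueError("Q must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Q) < -1e-10):
            raise ValueError("Q must be positive semidefinite")
        self.R = float(self.R)
        if self.R <= 0:
            raise ValueError("R must be positive")
        self.x0 = np.asarray(self.x0, dtype=float).reshape(d)
        self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
        if self.P0.shape != (d, d):
            raise ValueError("P0 dimension mismatch")
        if np.any(np.linalg.eigvalsh((self.P0 + self.P0.T) / 2) < -1e-10):
            raise ValueError("P0 must be positive semidefinite")

    @property
    def dim(self) -> int:
        return self.phi.shape[0]


@dataclass
class FilterResult:
    """Forward-pass quantities per index: priori/posteriori means and covariances."""

    x_prior: np.ndarray  # (N, d)
    P_prior: np.ndarray  # (N, d, d)
    x_post: np.ndarray
    P_post: np.ndarray
    gain: np.ndarray  # (N, d); zero where no measurement
    observed: np.ndarray  # (N,) bool

    @property
    def n(self) -> int:
        return len(self.observed)


@dataclass
class SmoothedSeries:
    """Backward-pass output: full-series posterior per index."""

    mean: np.ndarray  # (N,) glucose component, mg/dl
    variance: np.ndarray  # (N,) glucose component, (mg/dl)^2
    state_mean: np.ndarray  # (N, d)
    state_cov: np.ndarray  # (N, d, d)
    filtered: FilterResult
    smoother_gain: np.ndarray = field(default=None)  # type: ignore[assignment]


def kalman_filter(
    y: np.ndarray, model: StateSpaceModel, u: np.ndarray | None = None
) -> FilterResult:
    """Forward Kalman filter over a measurement series with NaN gaps.

    Time update: ``x̄_k = Φ x̂_{k-1} + B u_{k-1}``, ``P̄_k = Φ P̂_{k-1} Φᵀ + Q``
    (at ``k = 0`` the priori is the initial prior ``x0, P0``).  Measure
    update at observed indices: ``K = P̄ Hᵀ (H P̄ Hᵀ + R)⁻¹``,
    ``x̂ = x̄ + K (y - H x̄)``, ``P̂ = (I - K H) P̄``.  At missing indices the
    measure update is skipped, so posteriori equals priori.
    """
    y = np.asarray(y, dtype=float)
    if np.any(np.isinf(y)):
        raise ValueError("non-finite (infinite) measurement encountered")
    observed = np.isfinite(y)
    if not observed.any():
        raise ValueError("kalman_filter requires at least one observed measurement")
    N, d = len(y), model.dim
    phi, H, Q, R = model.phi, model.H, model.Q, model.R
    I = np.eye(d)
    res = FilterResult(
        x_prior=np.zeros((N, d)),
        P_prior=np.zeros((N, d, d)),
        x_post=np.zeros((N, d)),
        P_post=np.zeros((N, d, d)),
        gain=np.zeros((N, d)),
        observed=observed,
    )
    x, P = model.x0.copy(), model.P0.copy()
    for k in range(N):
        if k > 0:
            x = phi @ x
            if model.B is not None and u is not None:
                x = x + model.B @ np.atleast_1d(u[k - 1])
            P = phi @ P @ phi.T + Q
        res.x_prior[k], res.P_prior[k] = x, P
        if observed[k]:
            S = (H @ P @ H.T).item() + R
            K = (P @ H.T / S).ravel()
            x = x + K * (y[k] - (H @ x).item())
            P = (I - np.outer(K, H)) @ P
            res.gain[k] = K
        res.x_post[k], res.P_post[k] = x, P
    return res


def rts_smooth(filt: FilterResult, model: StateSpaceModel) -> SmoothedSeries:
    """Rauch–Tung–Striebel backward pass over a complete forward filter run.

    ``C_k = P̂_k Φᵀ P̄⁻¹_{k+1}``; ``x̂ˢ_k = x̂_k + C_k (x̂ˢ_{k+1} - x̄_{k+1})``;
    ``P̂ˢ_k = P̂_k + C_k (P̂ˢ_{k+1} - P̄_{k+1}) C_kᵀ``; anchored at
    ``x̂ˢ_N = x̂_N``.
    """
    N, d = filt.n, model.dim
    xs = filt.x_post.copy()
    Ps = filt.P_post.copy()
    gains = np.zeros((N, d, d))
    for k in range(N - 2, -1, -1):
        P_prior_next = filt.P_prior[k + 1]
        try:
            C = np.linalg.solve(P_prior_next.T, (filt.P_post[k] @ model.phi.T).T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular priori covariance at index {k + 1}; cannot smooth"
            ) from exc
        xs[k] = filt.x_post[k] + C @ (xs[k + 1] - filt.x_prior[k + 1])
        Ps[k] = filt.P_post[k] + C @ (Ps[k + 1] - P_prior_next) @ C.T
        gains[k] = C
    return SmoothedSeries(
        mean=xs[:, 0],
        variance=Ps[:, 0, 0],
        state_mean=xs,
        state_cov=Ps,
        filtered=filt,
        smoother_gain=gains,
    )


def default_cgm_model(
    first_obs: float, q: float = 10.0, r: float = 25.0, p0: tuple[float, float] = (1e4, 1e2)
) -> StateSpaceModel:
    """Local-linear-trend CGM model with a diffuse start at the first observation.

    ``q`` scales the white-noise-jerk process covariance ((mg/dl)² per
    index³-ish units); ``r`` is the measurement-noise variance, default 25
    (mg/dl)² i.e. a 5 mg/dl sensor noise sd.
    """
    return StateSpaceModel(
        phi=np.array([[1.0, 1.0], [0.0, 1.0]]),
        H=np.array([1.0, 0.0]),
        Q=q * np.array([[1.0 / 3.0, 0.5], [0.5, 1.0]]),
        R=r,
        x0=np.array([first_obs, 0.0]),
        P0=np.diag(p0),
    )


def smooth_cgm(
    series: PatientSeries,
    q: float = 10.0,
    r: float = 25.0,
    p0: tuple[float, float] = (1e4, 1e2),
) -> SmoothedSeries:
    """Kalman-smooth a patient's CGM channel over its full grid.

    Gaps receive interpolated means with inflated variance.  Call this
    separately on a patient's training and test files; smoothing across the
    boundary would leak test information into the training channel.
    """
    y = series.cgm
    if np.isfinite(y).sum() < 2:
        raise ValueError("smooth_cgm requires at least 2 observed CGM values")
    first = float(y[np.isfinite(y)][0])
    model = default_cgm_model(first, q=q, r=r, p0=p0)
    return rts_smooth(kalman_filter(y, model), model)


def batch_wls_smoother(y: np.ndarray, model: StateSpaceModel) -> np.ndarray:
    """Batch weighted-least-squares solution of the same state-space problem.

    Stacks the prior, all dynamics constraints and all measurements into one
    dense generalized least-squares system and solves it directly.  This is
    the independent oracle for the RTS smoother: for an invertible Q the
    posterior mode of the joint Gaussian equals the smoothed means.  Intended
    for small instances only (dense ``(N·d)²`` normal equations).
    """
    y = np.asarray(y, dtype=float)
    N, d = len(y), model.dim
    A_T_W_A = np.zeros((N * d, N * d))
    A_T_W_b = np.zeros(N * d)

    def block(i: int) -> slice:
        return slice(i * d, (i + 1) * d)

    P0_inv = np.linalg.inv(model.P0)
    A_T_W_A[block(0), block(0)] += P0_inv
    A_T_W_b[block(0)] += P0_inv @ model.x0
    Q_inv = np.linalg.inv(model.Q)
    phi = model.phi
    for k in range(N - 1):
        # residual x_{k+1} - phi x_k ~ N(0, Q)
        A_T_W_A[block(k), block(k)] += phi.T @ Q_inv @ phi
        A_T_W_A[block(k), block(k + 1)] += -phi.T @ Q_inv
        A_T_W_A[block(k + 1), block(k)] += -Q_inv @ phi
        A_T_W_A[block(k + 1), block(k + 1)] += Q_inv
    H = model.H
    for k in range(N):
        if np.isfinite(y[k]):
            A_T_W_A[block(k), block(k)] += (H.T @ H) / model.R
            A_T_W_b[block(k)] += (H.ravel() * y[k]) / model.R
    return np.linalg.solve(A_T_W_A, A_T_W_b).reshape(N, d)
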