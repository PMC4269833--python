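"""Least-squares estimation of (ell, alpha, beta) and the chirality index.

The model velocities are linear in ``alpha`` and ``beta`` for fixed
hydrodynamic length ``ell``, and the boundary contribution is independent of
both.  The fit therefore profiles: an outer one-dimensional search over
``ell`` with, at each candidate, the exact closed-form linear least-squares
solution for ``alpha`` (from the axial profile) and ``beta`` (from the
chiral profile).  Endpoint samples are imposed as Dirichlet boundary
conditions and excluded from the residual.

Standard errors come from the Hessian of half the residual sum of squares
at the optimum, computed by central finite differences:
``cov = s^2 H^{-1}`` with ``s^2 = rss / (n_obs - 3)``.  The error on
``c = beta/alpha`` follows by first-order propagation including the
alpha–beta covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .model import (
    AxialProfile,
    ModelParams,
    SolverConfig,
    forward_model,
    with_boundary_conditions,
)

__all__ = ["FitResult", "fit_parameters", "fit_uncertainties"]

#: z-score for "error of the mean with 99% confidence" summaries.
Z_99 = 2.576


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    stderr_ell: float
    stderr_alpha: float
    stderr_beta: float
    stderr_c: float
    rss: float
    n_obs: int
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("residual sum of squares cannot be negative")

    def to_dict(self) -> dict:
        return {
            "ell_um": self.params.ell,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "c": self.params.c,
            "stderr_ell_um": self.stderr_ell,
            "stderr_alpha": self.stderr_alpha,
            "stderr_beta": self.stderr_beta,
            "stderr_c": self.stderr_c,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "message": self.message,
        }


def _check_grids(I: AxialProfile, vx_obs: AxialProfile, vy_obs: AxialProfile) -> None:
    if not (np.allclose(I.x, vx_obs.x) and np.allclose(I.x, vy_obs.x)):
        raise ValueError("intensity and velocity profiles must share one grid")


def _basis(I: AxialProfile, ell: float, cfg: SolverConfig):
    """Unit-coefficient responses and boundary-only solutions at fixed ell.

    vx_model = alpha * ux + hx and vy_model = beta * uy + hy, where ux, uy
    are the responses to unit alpha/beta with zero boundary values and
    hx, hy carry the boundary conditions alone.
    """
    zero_bc = SolverConfig(cfg.n_nodes, cfg.interp)
    unit = ModelParams(ell=ell, alpha=1.0, beta=1.0)
    ux, uy = forward_model(I, unit, zero_bc)
    null = ModelParams(ell=ell, alpha=0.0, beta=0.0)
    bc_only = SolverConfig(cfg.n_nodes, cfg.interp, cfg.bc_vx, cfg.bc_vy)
    hx, hy = forward_model(I, null, bc_only)
    return ux.values, uy.values, hx.values, hy.values


def _profiled_rss(
    I: AxialProfile,
    vx: np.ndarray,
    vy: np.ndarray,
    ell: float,
    cfg: SolverConfig,
    interior: slice,
) -> tuple[float, float, float]:
    """(rss, alpha_hat, beta_hat) at fixed ell, interior points only."""
    ux, uy, hx, hy = _basis(I, ell, cfg)
    rx = (vx - hx)[interior]
    ry = (vy - hy)[interior]
    bx = ux[interior]
    by = uy[interior]
    sxx = float(bx @ bx)
    syy = float(by @ by)
    alpha = float(rx @ bx) / sxx if sxx > 0 else 0.0
    beta = float(ry @ by) / syy if syy > 0 else 0.0
    rss = float(np.sum((rx - alpha * bx) ** 2) + np.sum((ry - beta * by) ** 2))
    return rss, alpha, beta


def _rss_at(
    theta: np.ndarray,
    I: AxialProfile,
    vx: np.ndarray,
    vy: np.ndarray,
    cfg: SolverConfig,
    interior: slice,
) -> float:
    """RSS as a free function of (ell, alpha, beta), for the Hessian."""
    ell, alpha, beta = theta
    ux, uy, hx, hy = _basis(I, ell, cfg)
    rx = (vx - hx - alpha * ux)[interior]
    ry = (vy - hy - beta * uy)[interior]
    return float(rx @ rx + ry @ ry)


def fit_parameters(
    I: AxialProfile,
    vx_obs: AxialProfile,
    vy_obs: AxialProfile,
    cfg: SolverConfig | None = None,
    init: ModelParams | None = None,
) -> FitResult:
    """Fit (ell, alpha, beta) to measured velocity profiles.

    Boundary conditions are taken from the endpoint values of the observed
    profiles; the endpoints are excluded from the residual.  ``init``, if
    given, seeds the bracket of the hydrodynamic-length search; otherwise
    the search covers [grid spacing, 10 x domain length] with a coarse
    log-spaced scan followed by bounded refinement.
    """
    cfg = cfg or SolverConfig()
    _check_grids(I, vx_obs, vy_obs)
    I.require_intensity()
    cfg = with_boundary_conditions(cfg, vx_obs, vy_obs)
    vx = vx_obs.values
    vy = vy_obs.values
    interior = slice(1, -1)
    n_obs = (I.n - 2) * 2

    if np.allclose(vx, 0) and np.allclose(vy, 0):
        params = ModelParams(ell=(I.extent[1] - I.extent[0]) / 3, alpha=0.0, beta=0.0)
        return FitResult(
            params, math.nan, math.nan, math.nan, math.nan,
            rss=0.0, n_obs=n_obs, converged=False,
            message="all-zero velocities: alpha=beta=0, ell unidentifiable",
        )

    length = I.extent[1] - I.extent[0]
    lo = max(length / (cfg.n_nodes - 1), 1e-3 * length)
    hi = 10.0 * length
    if init is not None:
        scan = np.array([init.ell])
    else:
        scan = np.geomspace(lo, hi, 25)
    best_ell = scan[int(np.argmin([
        _profiled_rss(I, vx, vy, e, cfg, interior)[0] for e in scan
    ]))]
    bracket_lo = max(lo, best_ell / 4)
    bracket_hi = min(hi, best_ell * 4)
    opt = minimize_scalar(
        lambda e: _profiled_rss(I, vx, vy, e, cfg, interior)[0],
        bounds=(bracket_lo, bracket_hi),
        method="bounded",
        options={"xatol": 1e-10 * length},
    )
    ell = float(opt.x)
    rss, alpha, beta = _profiled_rss(I, vx, vy, ell, cfg, interior)
    converged = bool(opt.success)

    theta = np.array([ell, alpha, beta])
    hess = _half_rss_hessian(theta, I, vx, vy, cfg, interior)
    stderr, cov = fit_uncertainties(rss, hess, n_obs, return_cov=True)
    stderr_c = _propagate_c_error(alpha, beta, cov)

    params = ModelParams(ell=ell, alpha=alpha, beta=beta)
    return FitResult(
        params,
        stderr_ell=stderr[0],
        stderr_alpha=stderr[1],
        stderr_beta=stderr[2],
        stderr_c=stderr_c,
        rss=rss,
        n_obs=n_obs,
        converged=converged,
        message="" if converged else "line search did not converge",
    )


def _half_rss_hessian(
    theta: np.ndarray,
    I: AxialProfile,
    vx: np.ndarray,
    vy: np.ndarray,
    cfg: SolverConfig,
    interior: slice,
    rel_step: float = 1e-3,
) -> np.ndarray:
    """Central finite-difference Hessian of (1/2) RSS at theta.

    The step is large enough that solver-level numerical noise (~1e-10
    relative) does not contaminate the second differences, and small
    enough that higher-order terms are negligible; halving it changes the
    result well under 1%.
    """
    f = lambda t: 0.5 * _rss_at(t, I, vx, vy, cfg, interior)
    n = len(theta)
    h = np.array([rel_step * max(abs(t), 1e-3) for t in theta])
    H = np.empty((n, n))
    f0 = f(theta)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_uncertainties(
    rss: float,
    hessian: np.ndarray,
    n_obs: int,
    n_params: int = 3,
    return_cov: bool = False,
):
    """Standard errors from the Hessian of half the residual sum of squares.

    ``cov = s^2 H^{-1}`` with ``s^2 = rss / (n_obs - n_params)``; standard
    errors are the square roots of the diagonal.  A non-positive-definite
    Hessian (flat or collinear direction) yields NaN errors with a warning.
    """
    hessian = np.asarray(hessian, dtype=float)
    dof = n_obs - n_params
    if dof <= 0:
        raise ValueError("need more observations than parameters")
    s2 = rss / dof
    try:
        # Cholesky certifies positive definiteness before inverting.
        np.linalg.cholesky(hessian)
        cov = s2 * np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        warnings.warn(
            "Hessian is not positive definite (flat direction); "
            "standard errors are undefined",
            stacklevel=2,
        )
        cov = np.full_like(hessian, math.nan)
    d = np.diag(cov)
    stderr = np.where(d >= 0, np.sqrt(np.maximum(d, 0)), math.nan)
    if return_cov:
        return stderr, cov
    return stderr


def _propagate_c_error(alpha: float, beta: float, cov: np.ndarray) -> float:
    """First-order error on c = beta/alpha from the (alpha, beta) block."""
    if alpha == 0 or not np.all(np.isfinite(cov[1:, 1:])):
        return math.nan
    g = np.array([-beta / alpha**2, 1.0 / alpha])  # d c / d(alpha, beta)
    var_c = float(g @ cov[1:, 1:] @ g)
    return math.sqrt(var_c) if var_c >= 0 else math.nan
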