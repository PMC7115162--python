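"""Damped least-squares (Levenberg-Marquardt) engine.

A single small solver shared by Water Cloud Model calibration, the
dual-polarization inversion and the transfer-network trainer.  Each caller
supplies its own residual/Jacobian pair and stopping rule:

* calibration stops when the decrease in the sum of squared residuals
  between accepted iterations falls below ``sse_tol``;
* inversion stops when the parameter step between iterates falls below
  ``step_tol``;
* network training additionally stops when the gradient norm falls below
  ``grad_tol``.

The implementation is the classic Marquardt scheme: solve
``(J'J + lam * diag(J'J)) delta = -J'r``, accept the step only if it lowers
the SSE, and adapt the damping factor accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["LMResult", "levenberg_marquardt"]

_LAMBDA_MAX = 1e14
_LAMBDA_MIN = 1e-14


@dataclass
class LMResult:
    """Outcome of a damped least-squares minimization."""

    x: np.ndarray
    sse: float
    residuals: np.ndarray
    n_iter: int
    converged: bool
    status: str
    initial_sse: float


def levenberg_marquardt(
    residual: Callable[[np.ndarray], np.ndarray],
    jacobian: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    max_iter: int = 100,
    sse_tol: float | None = None,
    step_tol: float | None = None,
    grad_tol: float | None = None,
    lambda0: float = 1e-3,
) -> LMResult:
    """Minimize ``sum(residual(x)**2)`` from ``x0``.

    Parameters
    ----------
    residual, jacobian
        Residual vector r(x) of shape (m,) and its Jacobian of shape (m, p).
    x0
        Starting point, shape (p,).
    max_iter
        Maximum number of accepted iterations.
    sse_tol
        Stop once the SSE decrease of an accepted step falls below this.
    step_tol
        Stop once the infinity-norm of an accepted step falls below this.
    grad_tol
        Stop once the infinity-norm of the gradient J'r falls below this.

    At least one stopping tolerance must be given; hitting ``max_iter``
    returns ``converged=False``.
    """
    if sse_tol is None and step_tol is None and grad_tol is None:
        raise ValueError("at least one of sse_tol, step_tol, grad_tol is required")

    x = np.asarray(x0, dtype=float).copy()
    r = np.asarray(residual(x), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residual is not finite at the starting point")
    sse = float(r @ r)
    initial_sse = sse
    lam = float(lambda0)

    n_iter = 0
    status = "max_iter"
    converged = False
    for n_iter in range(1, max_iter + 1):
        J = np.asarray(jacobian(x), dtype=float)
        g = J.T @ r
        if grad_tol is not None and np.max(np.abs(g)) < grad_tol:
            n_iter -= 1
            status, converged = "grad_tol", True
            break
        H = J.T @ J
        scale = np.clip(np.diag(H), 1e-12, None)

        # inner damping loop: inflate lambda until a step lowers the SSE
        accepted = False
        while lam <= _LAMBDA_MAX:
            try:
                delta = np.linalg.solve(H + lam * np.diag(scale), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_new = x + delta
            r_new = np.asarray(residual(x_new), dtype=float)
            with np.errstate(over="ignore", invalid="ignore"):
                sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            # no descent direction at any damping: stationary point
            status, converged = "stalled", True
            n_iter -= 1
            break

        decrease = sse - sse_new
        step = float(np.max(np.abs(delta)))
        x, r, sse = x_new, r_new, sse_new
        lam = max(lam / 10.0, _LAMBDA_MIN)

        if sse_tol is not None and decrease < sse_tol:
            status, converged = "sse_tol", True
            break
        if step_tol is not None and step < step_tol:
            status, converged = "step_tol", True
            break

    return LMResult(
        x=x,
        sse=sse,
        residuals=r,
        n_iter=n_iter,
        converged=converged,
        status=status,
        initial_sse=initial_sse,
    )
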