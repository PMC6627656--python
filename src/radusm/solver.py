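"""Matrix-free preconditioned bi-conjugate gradient (PBCG) solver.

The diffusion module turns each lagged-diffusivity step into a sparse linear
system ``A u = b`` with ``A = D + alpha*L`` acting on a pixel grid.  For
radiograph-sized images (millions of unknowns) neither a dense matrix nor a
direct factorization is practical, so the system is solved with a Krylov
method that only ever touches ``A`` through matvec callables.  A Jacobi
(diagonal) preconditioner is used: for ``A = I + alpha*L`` with modest
``alpha`` the diagonal already captures most of the operator, and dividing it
out clusters the spectrum near 1.

PBCG handles general (nonsymmetric) systems by running two coupled residual
recurrences, one for ``A`` and one for ``A^T``.  The operator assembled by the
diffusion module happens to be symmetric, in which case PBCG reproduces
preconditioned CG iterate-for-iterate — a property the test suite checks — but
the implementation accepts a distinct transpose operator so it remains correct
for arbitrary systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .exceptions import BreakdownError

__all__ = ["SolverResult", "jacobi_preconditioner", "pbcg_solve"]

#: Absolute floor on the right-hand-side norm used in the relative residual,
#: so that b = 0 does not divide by zero.
_RHS_NORM_FLOOR = 1e-30

Operator = Callable[[np.ndarray], np.ndarray]


@dataclass
class SolverResult:
    """Outcome of a Krylov solve: solution grid plus convergence diagnostics."""

    solution: np.ndarray
    iterations: int
    final_residual: float  # relative: ||b - A x|| / max(||b||, floor)
    converged: bool
    residual_history: list[float] = field(default_factory=list)


def jacobi_preconditioner(coeffs, alpha_diff: float) -> np.ndarray:
    """Diagonal of ``A = D + alpha*L`` as a per-pixel grid: ``1 + alpha*s``.

    Applying the preconditioner means elementwise division by this grid.  The
    entries are >= 1 by construction (``alpha_diff >= 0``, ``s >= 0``), so the
    division is always safe.

    ``coeffs`` is any object with the summed half-pixel diffusivities on an
    ``s`` attribute (a :class:`radusm.diffusion.CoefficientField`).
    """
    return 1.0 + float(alpha_diff) * np.asarray(coeffs.s, dtype=np.float64)


def _dot(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a * b))


def pbcg_solve(
    apply_A: Operator,
    apply_At: Operator,
    rhs: np.ndarray,
    precond: np.ndarray,
    tol: float,
    maxiter: int,
    x0: Optional[np.ndarray] = None,
    callback: Optional[Callable[[np.ndarray], None]] = None,
) -> SolverResult:
    """Solve ``A x = rhs`` with the preconditioned bi-conjugate gradient method.

    Parameters
    ----------
    apply_A, apply_At
        Matvec callables for ``A`` and ``A^T`` on grids shaped like ``rhs``.
        For symmetric operators pass the same callable twice.
    rhs
        Right-hand side grid.
    precond
        Strictly positive per-pixel grid holding the (diagonal) preconditioner;
        preconditioning divides elementwise by it.
    tol
        Relative-residual stopping tolerance, ``||b - A x|| / ||b||``.
    maxiter
        Iteration budget.
    x0
        Initial guess; defaults to ``rhs`` itself, which for ``A = I + alpha*L``
        with small ``alpha`` starts very near the solution.
    callback
        Called with the current iterate after every update (diagnostics).

    Returns
    -------
    SolverResult
        ``converged`` reflects an *independently recomputed* residual
        ``||b - A x||/||b||``, not the recurrence's internal estimate.

    Raises
    ------
    BreakdownError
        When one of the recurrence's scalar denominators vanishes.

    Notes
    -----
    This is the standard textbook PBCG recurrence: residual pairs ``r, rbar``,
    preconditioned residuals ``z = M^-1 r``, ``zbar = M^-1 rbar``, direction
    pairs ``p, pbar``, with

    .. math::
       \\alpha_k = \\frac{\\bar r_k \\cdot z_k}{\\bar p_k \\cdot A p_k},\\qquad
       \\beta_k  = \\frac{\\bar r_{k+1} \\cdot z_{k+1}}{\\bar r_k \\cdot z_k},

    ``x += alpha*p``, ``r -= alpha*A p``, ``rbar -= alpha*A^T pbar``,
    ``p = z + beta*p``, ``pbar = zbar + beta*pbar``.
    """
    b = np.asarray(rhs, dtype=np.float64)
    M = np.asarray(precond, dtype=np.float64)
    if M.shape != b.shape:
        raise ValueError(f"preconditioner shape {M.shape} != rhs shape {b.shape}")
    if np.any(M <= 0):
        raise ValueError("preconditioner must be strictly positive")

    x = b.copy() if x0 is None else np.array(x0, dtype=np.float64)
    bnorm = max(float(np.linalg.norm(b)), _RHS_NORM_FLOOR)

    r = b - apply_A(x)
    rbar = r.copy()
    p = pbar = None
    rho_prev = 0.0
    history: list[float] = []
    iterations = 0

    for k in range(maxiter):
        relres = float(np.linalg.norm(r)) / bnorm
        history.append(relres)
        if relres <= tol:
            break

        z = r / M
        zbar = rbar / M
        rho = _dot(rbar, z)
        if rho == 0.0:
            raise BreakdownError(
                f"PBCG breakdown at iteration {k}: rbar.z = 0", iteration=k
            )
        if p is None:
            p, pbar = z, zbar
        else:
            beta = rho / rho_prev
            p = z + beta * p
            pbar = zbar + beta * pbar
        Ap = apply_A(p)
        denom = _dot(pbar, Ap)
        if denom == 0.0:
            raise BreakdownError(
                f"PBCG breakdown at iteration {k}: pbar.(A p) = 0", iteration=k
            )
        alpha = rho / denom
        x = x + alpha * p
        r = r - alpha * Ap
        rbar = rbar - alpha * apply_At(pbar)
        rho_prev = rho
        iterations = k + 1
        if callback is not None:
            callback(x)

    # Trust nothing from the recurrence: recompute the true residual.
    final_residual = float(np.linalg.norm(b - apply_A(x))) / bnorm
    return SolverResult(
        solution=x,
        iterations=iterations,
        final_residual=final_residual,
        converged=final_residual <= tol,
        residual_history=history,
    )
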