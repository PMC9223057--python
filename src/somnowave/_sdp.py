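"""Dense barrier solver for small semidefinite programs.

Solves the standard-form primal problem

    minimize    <C, X>
    subject to  <A_i, X> = b_i,   i = 1..m
                X  positive semidefinite

for a symmetric matrix variable ``X`` of modest size (tens of rows) via a
log-determinant barrier with infeasible-start Newton steps on the
equality-constrained centering problems.  Designed for the wavelet
filter-design Gram-matrix programs in this package, where the matrix
dimension never exceeds the filter length.
"""

from __future__ import annotations

import numpy as np


class SDPError(RuntimeError):
    """Raised when the barrier solver fails to converge."""


def _sym_basis(s: int) -> np.ndarray:
    """Orthonormal basis of the space of s x s symmetric matrices."""
    dim = s * (s + 1) // 2
    basis = np.zeros((dim, s, s))
    k = 0
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for i in range(s):
        basis[k, i, i] = 1.0
        k += 1
        for j in range(i + 1, s):
            basis[k, i, j] = inv_sqrt2
            basis[k, j, i] = inv_sqrt2
            k += 1
    return basis


def _is_pd(X: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(X)
        return True
    except np.linalg.LinAlgError:
        return False


def solve_sdp(
    C: np.ndarray,
    A: list[np.ndarray],
    b: np.ndarray,
    *,
    quad: list[tuple[float, np.ndarray]] | None = None,
    gap_tol: float = 1e-9,
    max_outer: int = 60,
    max_inner: int = 80,
    t_init: float = 1.0,
    mu: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Solve min <C,X> + sum_j w_j <M_j,X>**2 s.t. <A_i,X>=b_i, X >= 0.

    ``quad`` optionally lists ``(w_j, M_j)`` pairs with ``w_j >= 0`` forming a
    convex quadratic objective term.  Returns ``(X, objective)``; ``gap_tol``
    bounds the final duality gap ``s / t`` of the barrier (s = matrix
    dimension).
    """
    s = C.shape[0]
    m = len(A)
    basis = _sym_basis(s)
    nb = basis.shape[0]

    # Linear maps in the orthonormal symmetric coordinates.
    c_vec = np.einsum("kab,ab->k", basis, C)
    A_mat = np.array([np.einsum("kab,ab->k", basis, Ai) for Ai in A])  # m x nb
    if np.linalg.matrix_rank(A_mat) < m:
        raise SDPError("linearly dependent equality constraints")
    Q = np.zeros((nb, nb))
    if quad:
        for wj, Mj in quad:
            if wj < 0:
                raise ValueError("quadratic objective weights must be >= 0")
            mj = np.einsum("kab,ab->k", basis, Mj)
            Q += wj * np.outer(mj, mj)

    x_vec = np.einsum("kab,ab->k", basis, np.eye(s))  # start at identity
    nu = np.zeros(m)
    t = t_init

    def to_mat(x: np.ndarray) -> np.ndarray:
        return np.einsum("k,kab->ab", x, basis)

    for _outer in range(max_outer):
        for _inner in range(max_inner):
            X = to_mat(x_vec)
            Xi = np.linalg.inv(X)
            grad = t * (c_vec + 2.0 * Q @ x_vec) - np.einsum("kab,ab->k", basis, Xi)
            r_pri = A_mat @ x_vec - b
            r_dual = grad + A_mat.T @ nu
            res = np.sqrt(r_dual @ r_dual + r_pri @ r_pri)
            if res < 1e-9 * max(1.0, t):
                break
            # Hessian of -logdet in the orthonormal coordinates.
            F = np.einsum("ab,kbc,cd->kad", Xi, basis, Xi)
            H = np.einsum("kab,lab->kl", basis, F) + 2.0 * t * Q
            KKT = np.block([[H, A_mat.T], [A_mat, np.zeros((m, m))]])
            rhs = -np.concatenate([r_dual, r_pri])
            try:
                sol = np.linalg.solve(KKT, rhs)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SDPError(f"singular KKT system: {exc}") from exc
            dx, dnu = sol[:nb], sol[nb:]
            # Backtracking line search keeping X positive definite and
            # shrinking the combined residual.
            step = 1.0
            while step > 1e-14 and not _is_pd(to_mat(x_vec + step * dx)):
                step *= 0.5
            accepted = False
            while step > 1e-14:
                x_new = x_vec + step * dx
                nu_new = nu + step * dnu
                X_new = to_mat(x_new)
                Xi_new = np.linalg.inv(X_new)
                g_new = t * (c_vec + 2.0 * Q @ x_new) - np.einsum(
                    "kab,ab->k", basis, Xi_new
                )
                rd = g_new + A_mat.T @ nu_new
                rp = A_mat @ x_new - b
                if np.sqrt(rd @ rd + rp @ rp) <= (1.0 - 0.25 * step) * res:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break  # stalled: residual at numerical floor for this t
            x_vec, nu = x_new, nu_new
        if s / t < gap_tol:
            break
        t *= mu
    else:  # pragma: no cover
        raise SDPError("barrier method did not reach the requested gap")

    X = to_mat(x_vec)
    if abs(A_mat @ x_vec - b).max() > 1e-7:
        raise SDPError("equality constraints not satisfied at solution")
    return X, float(c_vec @ x_vec + x_vec @ Q @ x_vec)
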