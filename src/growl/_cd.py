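"""Numba-compiled cyclic coordinate descent for the box-constrained duals.

Both duals share the same structure.  Collect the multipliers in a matrix
``alpha`` of shape (n_rec, K).  With signs ``s_ij = +1`` if ``j`` equals the
record's group label and ``-1`` otherwise, define

    U[i, k] = sum_j alpha[i, j] * s_ij * W[j, k]          (n_rec, K-1)

* linear dual: the quadratic part is ``1/(2 n lam) * sum_k ||X^T U_k||^2``
  with ``X`` the intercept-augmented covariates, so the state kept is
  ``u_k = X^T U_k`` in feature space — O(p(K-1)) per coordinate update.
* kernel dual: the quadratic part is ``1/(2 n lam) * sum_k U_k^T (G + 1) U_k``
  (the all-ones matrix carries the unpenalised intercept), so the state kept
  is ``V = (G + 1) U`` — O(n_rec (K-1)) per update.

The linear part of both objectives is ``-(K-1) alpha[i, label]`` minus the
off-label multipliers.  Each single-coordinate update is the exact 1-D
quadratic minimiser clipped to the box ``[0, upper]``; the objective is
therefore non-increasing after every update.  A sweep visits all (record,
group) pairs in fixed cyclic order; iteration stops when the largest absolute
coordinate change in a sweep drops below ``tol`` or after ``max_sweeps``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cd_linear", "cd_kernel", "kkt_residual_linear", "kkt_residual_kernel"]


@njit(cache=True)
def cd_linear(X, W, labels0, upper, lin, inv_nlam, tol, max_sweeps):
    """Coordinate descent on the linear dual.

    Parameters are arrays only (numba): X (n_rec, p) augmented covariates,
    W (K, K-1) simplex code, labels0 (n_rec,) zero-based group labels,
    upper (n_rec, K) box bounds, lin (n_rec, K) linear coefficients,
    inv_nlam = 1/(n*lambda).

    Returns (alpha, u, obj_trace, n_sweeps, max_delta_last) where
    u has shape (K-1, p) and obj_trace[t] is the objective after sweep t.
    """
    n_rec, p = X.shape
    K = W.shape[0]
    Km1 = K - 1
    alpha = np.zeros((n_rec, K))
    u = np.zeros((Km1, p))
    xsq = np.empty(n_rec)
    for i in range(n_rec):
        s = 0.0
        for q in range(p):
            s += X[i, q] * X[i, q]
        xsq[i] = s
    obj_trace = np.empty(max_sweeps)
    max_delta = 0.0
    n_sweeps = 0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for i in range(n_rec):
            for j in range(K):
                up = upper[i, j]
                if up <= 0.0:
                    continue
                sgn = 1.0 if j == labels0[i] else -1.0
                # gradient = inv_nlam * s * sum_k W[j,k] <x_i, u_k> + lin
                g = 0.0
                for k in range(Km1):
                    dot = 0.0
                    for q in range(p):
                        dot += X[i, q] * u[k, q]
                    g += W[j, k] * dot
                g = inv_nlam * sgn * g + lin[i, j]
                h = inv_nlam * xsq[i]
                if h <= 0.0:
                    continue
                a_new = alpha[i, j] - g / h
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > up:
                    a_new = up
                d = a_new - alpha[i, j]
                if d != 0.0:
                    alpha[i, j] = a_new
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
                    for k in range(Km1):
                        c = d * sgn * W[j, k]
                        for q in range(p):
                            u[k, q] += c * X[i, q]
        # objective after this sweep
        quad = 0.0
        for k in range(Km1):
            for q in range(p):
                quad += u[k, q] * u[k, q]
        obj = 0.5 * inv_nlam * quad
        for i in range(n_rec):
            for j in range(K):
                obj += lin[i, j] * alpha[i, j]
        obj_trace[sweep] = obj
        n_sweeps = sweep + 1
        if max_delta < tol:
            break
    return alpha, u, obj_trace[:n_sweeps], n_sweeps, max_delta


@njit(cache=True)
def cd_kernel(Ktil, W, labels0, upper, lin, inv_nlam, tol, max_sweeps):
    """Coordinate descent on the kernel dual.

    Ktil is the Gram matrix plus the all-ones matrix (intercept block).
    Returns (alpha, U, obj_trace, n_sweeps, max_delta_last) with U of
    shape (n_rec, K-1); the primal coefficients are theta_k = U[:,k]/(n*lam).
    """
    n_rec = Ktil.shape[0]
    K = W.shape[0]
    Km1 = K - 1
    alpha = np.zeros((n_rec, K))
    U = np.zeros((n_rec, Km1))
    V = np.zeros((n_rec, Km1))  # V = Ktil @ U, maintained incrementally
    obj_trace = np.empty(max_sweeps)
    max_delta = 0.0
    n_sweeps = 0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for i in range(n_rec):
            for j in range(K):
                up = upper[i, j]
                if up <= 0.0:
                    continue
                sgn = 1.0 if j == labels0[i] else -1.0
                g = 0.0
                for k in range(Km1):
                    g += W[j, k] * V[i, k]
                g = inv_nlam * sgn * g + lin[i, j]
                h = inv_nlam * Ktil[i, i]
                if h <= 0.0:
                    continue
                a_new = alpha[i, j] - g / h
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > up:
                    a_new = up
                d = a_new - alpha[i, j]
                if d != 0.0:
                    alpha[i, j] = a_new
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
                    for k in range(Km1):
                        c = d * sgn * W[j, k]
                        U[i, k] += c
                        for m in range(n_rec):
                            V[m, k] += c * Ktil[m, i]
        quad = 0.0
        for k in range(Km1):
            for i in range(n_rec):
                quad += U[i, k] * V[i, k]
        obj = 0.5 * inv_nlam * quad
        for i in range(n_rec):
            for j in range(K):
                obj += lin[i, j] * alpha[i, j]
        obj_trace[sweep] = obj
        n_sweeps = sweep + 1
        if max_delta < tol:
            break
    return alpha, U, obj_trace[:n_sweeps], n_sweeps, max_delta


def kkt_residual_linear(X, W, labels0, upper, lin, inv_nlam, alpha, u):
    """Max projected-gradient residual over coordinates (numpy, not hot)."""
    signs = np.where(
        np.arange(W.shape[0])[None, :] == labels0[:, None], 1.0, -1.0
    )
    grad = inv_nlam * signs * ((X @ u.T) @ W.T) + lin
    proj = np.clip(alpha - grad, 0.0, upper)
    return float(np.max(np.abs(proj - alpha))) if alpha.size else 0.0


def kkt_residual_kernel(Ktil, W, labels0, upper, lin, inv_nlam, alpha, U):
    signs = np.where(
        np.arange(W.shape[0])[None, :] == labels0[:, None], 1.0, -1.0
    )
    grad = inv_nlam * signs * ((Ktil @ U) @ W.T) + lin
    proj = np.clip(alpha - grad, 0.0, upper)
    return float(np.max(np.abs(proj - alpha))) if alpha.size else 0.0
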