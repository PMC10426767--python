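"""Independent box-constrained QP oracle for checking the dual solvers.

Builds the explicit dual matrices directly from the displayed formulas —
Q[(i,j),(m,l)] = s_ij s_ml <W_j, W_l> k(x_i, x_m) with the appropriate
kernel matrix (X_aug X_aug' for the linear dual, G + 11' for the kernel
dual) — and minimises 0.5/(n lam) a'Qa + b'a over the box with L-BFGS-B.
Deliberately independent of the coordinate-descent implementation.
"""

import numpy as np
from scipy.optimize import minimize


def dual_matrices(records, code, gamma, kernel_matrix, n_subjects, lam):
    K = code.K
    nr = len(records)
    labels0 = records.labels - 1
    s = np.where(np.arange(K)[None, :] == labels0[:, None], 1.0, -1.0)
    WW = code.W @ code.W.T
    Q = np.zeros((nr * K, nr * K))
    for i in range(nr):
        for j in range(K):
            for m in range(nr):
                for l in range(K):
                    Q[i * K + j, m * K + l] = (
                        s[i, j] * s[m, l] * WW[j, l] * kernel_matrix[i, m]
                    )
    b = np.where(
        np.arange(K)[None, :] == labels0[:, None], -(K - 1.0), -1.0
    ).ravel()
    upper = np.where(
        np.arange(K)[None, :] == labels0[:, None],
        gamma * records.weights[:, None],
        (1 - gamma) * records.weights[:, None],
    ).ravel()
    inv = 1.0 / (n_subjects * lam)
    return Q, b, upper, inv


def solve_box_qp(Q, b, upper, inv):
    fun = lambda a: 0.5 * inv * a @ Q @ a + b @ a
    jac = lambda a: inv * Q @ a + b
    res = minimize(
        fun, np.zeros(len(b)), jac=jac, method="L-BFGS-B",
        bounds=[(0.0, u) for u in upper],
        options=dict(maxiter=20000, ftol=1e-16, gtol=1e-12),
    )
    return res.fun, res.x


def oracle_dual_optimum(records, code, gamma, kernel_matrix, n_subjects, lam):
    Q, b, upper, inv = dual_matrices(records, code, gamma, kernel_matrix,
                                     n_subjects, lam)
    return solve_box_qp(Q, b, upper, inv)
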