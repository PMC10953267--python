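"""Independent numerical oracles shared by the test modules."""

import numpy as np


def admm_glasso(S, lam, rho=1.0, n_iter=5000):
    """ADMM solver for the L1-penalized Gaussian likelihood.

    Splitting Theta = Z with an eigendecomposition primal step and a
    soft-threshold dual step — a different algorithm from the coordinate
    descent used by the implementation, so it can serve as an optimization
    oracle.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    off_mask = ~np.eye(p, dtype=bool)
    for _ in range(n_iter):
        w, V = np.linalg.eigh(rho * (Z - U) - S)
        d = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        Theta = (V * d) @ V.T
        A = Theta + U
        Z_new = A.copy()
        Z_new[off_mask] = np.sign(A[off_mask]) * np.maximum(
            np.abs(A[off_mask]) - lam / rho, 0)
        U = U + Theta - Z_new
        Z = Z_new
    return Z
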