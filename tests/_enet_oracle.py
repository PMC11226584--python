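"""Independent elastic-net minimizer used only as a test oracle.

A deliberately plain cyclic coordinate descent for

    (1/2n)||y - Xw||^2 + lam*(alpha*||w||_1 + (1-alpha)/2*||w||^2)

written without reference to the package's solver so the two routes stay
independent. Only suitable for small instances.
"""

import numpy as np


def soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def enet_coordinate_descent(X, y, lam, alpha, max_sweeps=50_000, tol=1e-12):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.zeros(p)
    col_ss = (X**2).sum(axis=0) / n
    r = y.copy()
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            old = w[j]
            z = X[:, j] @ r / n + col_ss[j] * old
            new = soft_threshold(z, lam * alpha) / (col_ss[j] + lam * (1 - alpha))
            if new != old:
                r += X[:, j] * (old - new)
                w[j] = new
                max_delta = max(max_delta, abs(new - old))
        if max_delta < tol:
            break
    return w
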