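"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the mixture estimate is
found by exhaustive search over simplex directions with the nonnegative
scale solved in closed form per direction (any x >= 0 factors as t*w with w
on the simplex and t = sum(x), so the argmin direction equals the
normalized NNLS solution up to grid resolution).
"""

import numpy as np


def simplex_grid(k: int, step: float = 1e-3) -> np.ndarray:
    """All points of the (k-1)-simplex on a regular grid with spacing ``step``."""
    n = round(1.0 / step)
    if k == 1:
        return np.array([[1.0]])
    if k == 2:
        a = np.arange(n + 1) / n
        return np.column_stack([a, 1.0 - a])
    if k == 3:
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = (i + j) <= n
        i, j = i[keep], j[keep]
        return np.column_stack([i, j, n - i - j]) / n
    raise NotImplementedError("grid oracle supports up to 3 components")


def grid_search_mixture(A: np.ndarray, b: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Brute-force normalized nonnegative mixture estimate.

    For every simplex direction w the best nonnegative scale is
    t* = max(0, <Aw, b> / ||Aw||^2); the direction minimizing the resulting
    residual is returned.
    """
    W = simplex_grid(A.shape[1], step)
    G = A.T @ A
    h = A.T @ b
    hw = W @ h
    wGw = np.einsum("ij,jk,ik->i", W, G, W)
    t = np.clip(hw / np.maximum(wGw, 1e-300), 0.0, None)
    resid = -2.0 * t * hw + t**2 * wGw  # ||b||^2 constant omitted
    return W[np.argmin(resid)]
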