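"""Vectorised Haley-Knott least-squares core.

All scans reduce to: regress one or many responses on a covariate block plus
the additive dosage ``x`` and dominance ``z`` at each position, and report
LOD = (n/2) * log10(RSS0 / RSS1) against the covariates-only null.
"""

from __future__ import annotations

import numpy as np

#: relative RSS floor; fits tighter than this are reported as capped
PERFECT_FIT_REL = 1e-16


def _orthonormal_basis(C: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(C)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def check_full_rank(C: np.ndarray, names: list[str]) -> None:
    """Raise naming aliased columns if the covariate matrix is rank-deficient."""
    if C.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify columns that do not increase rank
        aliased = []
        cols: list[int] = []
        for j in range(C.shape[1]):
            trial = C[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                aliased.append(names[j] if j < len(names) else f"col{j}")
            else:
                cols.append(j)
        raise ValueError(f"covariate matrix is rank-deficient; aliased columns: {aliased}")


def hk_scan_core(
    Y: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """LOD scores for every response x position pair.

    Parameters
    ----------
    Y : (n, q) responses (no missing values)
    C : (n, c) covariates including the intercept column
    X : (n, p) additive dosages
    Z : (n, p) dominance probabilities

    Returns
    -------
    lod : (q, p) array
    perfect : (q, p) boolean, True where the fit hit the numerical cap
    """
    Y = np.atleast_2d(Y.T).T  # ensure (n, q)
    n = Y.shape[0]
    Q = _orthonormal_basis(C)
    Yr = Y - Q @ (Q.T @ Y)
    rss0 = np.einsum("ij,ij->j", Yr, Yr)  # (q,)
    if np.any(rss0 <= 0):
        raise ValueError("constant response after covariate adjustment")
    Xr = X - Q @ (Q.T @ X)
    Zr = Z - Q @ (Q.T @ Z)

    a = np.einsum("ij,ij->j", Xr, Xr)  # (p,)
    d = np.einsum("ij,ij->j", Zr, Zr)
    m = np.einsum("ij,ij->j", Xr, Zr)
    U = Xr.T @ Yr  # (p, q)
    V = Zr.T @ Yr

    det = a * d - m * m
    scale = np.maximum(a * d, 1e-300)
    ok2 = det > 1e-12 * scale  # both regressors informative
    okx = a > 1e-12 * max(1.0, float(a.max(initial=0.0)))
    okz = d > 1e-12 * max(1.0, float(d.max(initial=0.0)))

    expl = np.zeros((len(a), Y.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        full = (d[:, None] * U**2 - 2 * m[:, None] * U * V + a[:, None] * V**2) / det[:, None]
        xonly = U**2 / a[:, None]
        zonly = V**2 / d[:, None]
    expl[ok2] = full[ok2]
    only_x = ~ok2 & okx
    expl[only_x] = xonly[only_x]
    only_z = ~ok2 & ~okx & okz
    expl[only_z] = zonly[only_z]

    expl = np.clip(expl, 0.0, rss0[None, :])
    rss1 = rss0[None, :] - expl
    floor = rss0[None, :] * PERFECT_FIT_REL
    perfect = rss1 <= floor
    rss1 = np.maximum(rss1, floor)
    lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
    return lod.T, perfect.T


def ols_rss(y: np.ndarray, D: np.ndarray) -> float:
    """Residual sum of squares of y on design D (least-squares, rank-safe)."""
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return float(resid @ resid)
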