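"""Shared dense linear-algebra helpers for the mixed-model code."""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .errors import FactorizationError


def orth_basis(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of ``X`` (rank-revealing SVD).

    The basis, not ``X`` itself, enters the projection ``P`` and the
    restricted likelihood, which makes both invariant to rank-deficient
    fixed-effect parameterizations.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return U[:, :0]
    return U[:, s > rtol * s[0]]


def sym_pinv(A: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Moore-Penrose inverse of a symmetric PSD matrix via eigenvalue
    thresholding (relative tolerance against the largest eigenvalue)."""
    w, V = np.linalg.eigh((A + A.T) / 2.0)
    if w.size == 0:
        return A.copy()
    keep = w > rtol * max(w[-1], 0.0)
    if not keep.any():
        return np.zeros_like(A)
    return (V[:, keep] / w[keep]) @ V[:, keep].T


def chol_factor(V: np.ndarray):
    """Cholesky factor of a symmetric positive-definite matrix, with a
    package-level error on failure."""
    try:
        return sla.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - message path
        raise FactorizationError(f"matrix is not positive definite: {exc}") from exc
    except sla.LinAlgError as exc:
        raise FactorizationError(f"matrix is not positive definite: {exc}") from exc


def chol_logdet(cf) -> float:
    c, _ = cf
    return 2.0 * float(np.sum(np.log(np.diag(c))))
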