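"""GBLUP via the conditional-expectation (CE) formulation.

The phenotype model is ``y = X b + Z a + Z d + e`` with
``Var(a) = G sigma2_a``, ``Var(d) = D sigma2_d``, ``Var(e) = I sigma2_e``,
where ``G`` and ``D`` are genomic additive and dominance relationship
matrices.  Writing ``V = Z G Z' s2a + Z D Z' s2d + I s2e`` the CE
solutions are

* ``b_hat = (X' V^-1 X)^- X' V^-1 y``  (BLUE; generalized inverse),
* ``a_hat = s2a G Z' V^-1 (y - X b_hat)``,
* ``d_hat = s2d D Z' V^-1 (y - X b_hat)``,
* ``g_hat = a_hat + d_hat``  (genotypic values).

With ``P = V^-1 - V^-1 X (X' V^-1 X)^- X' V^-1`` the prediction variances
are ``Var(a_hat) = s2a^2 G Z' P Z G`` (and analogously for ``d_hat`` plus a
cross term for ``g_hat``), giving per-individual reliabilities
``rel_a,i = Var(a_hat)_ii / (g_ii s2a)`` etc.  Nothing here ever inverts
``G`` or ``D``, so singular relationship matrices (q > m, duplicated
genotypes) are handled without special casing.

The CE system is ``n x n``: it is the efficient route when markers
outnumber individuals.  The rule of thumb implemented by
:func:`choose_formulation` is: use CE when ``q < 2m``, otherwise the
mixed-model-equation (QM) route whose system is ``2m x 2m``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from ._linalg import chol_factor, chol_logdet, orth_basis, sym_pinv
from .errors import DimensionError, InputError
from .grm import RelationshipPair

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "PredictionSet",
    "build_V",
    "gblup_ce",
    "gblup_ce_validation",
    "reliability_ce",
    "choose_formulation",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Additive, dominance and residual variances (squared phenotype units)."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float

    def __post_init__(self):
        for name in ("sigma2_a", "sigma2_d", "sigma2_e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InputError(f"{name} must be finite and non-negative, got {v}")

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_a, self.sigma2_d, self.sigma2_e])

    @classmethod
    def from_array(cls, arr) -> "VarianceComponents":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class PredictionSet:
    """GBLUP of breeding values, dominance deviations and genotypic values
    with per-individual reliabilities, plus the BLUE of fixed effects."""

    individual_ids: np.ndarray
    a_hat: np.ndarray
    d_hat: np.ndarray
    g_hat: np.ndarray
    b_hat: np.ndarray
    rel_a: np.ndarray
    rel_d: np.ndarray
    rel_g: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.individual_ids,
                "a_hat": self.a_hat,
                "rel_a": self.rel_a,
                "d_hat": self.d_hat,
                "rel_d": self.rel_d,
                "g_hat": self.g_hat,
                "rel_g": self.rel_g,
            }
        )


def choose_formulation(q: int, m: int) -> str:
    """``"ce"`` when ``q < 2m`` (CE system of size q is the cheaper one),
    ``"qm"`` otherwise — including the boundary ``q == 2m``."""
    if q < 1 or m < 1:
        raise DimensionError("q and m must be positive")
    return "ce" if q < 2 * m else "qm"


def build_V(Z: np.ndarray, G: np.ndarray, D: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """Phenotypic covariance ``V = Z G Z' s2a + Z D Z' s2d + I s2e``."""
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    if Z.shape[1] != G.shape[0] or G.shape != D.shape:
        raise DimensionError("Z/G/D dimensions do not conform")
    V = vc.sigma2_e * np.eye(n)
    if vc.sigma2_a > 0:
        V += vc.sigma2_a * (Z @ G @ Z.T)
    if vc.sigma2_d > 0:
        V += vc.sigma2_d * (Z @ D @ Z.T)
    return V


class CEWorkspace:
    """Caches the vc-independent pieces of a CE analysis (``Z G Z'``,
    ``Z D Z'``, the orthonormal fixed-effect basis) and, per variance
    component setting, the factorization-derived quantities (``V^-1``,
    ``P``, ``P y``) reused by GBLUP, reliabilities and REML."""

    def __init__(self, y, X, Z, G, D):
        self.y = np.asarray(y, float).ravel()
        self.X = np.atleast_2d(np.asarray(X, float))
        self.Z = np.asarray(Z, float)
        self.G = np.asarray(G, float)
        self.D = np.asarray(D, float)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise DimensionError("y, X, Z row counts do not agree")
        if self.Z.shape[1] != self.G.shape[0] or self.G.shape != self.D.shape:
            raise DimensionError("Z/G/D dimensions do not conform")
        self.n = n
        self.q = self.Z.shape[1]
        self.Va = self.Z @ self.G @ self.Z.T
        self.Vd = self.Z @ self.D @ self.Z.T
        self.Q = orth_basis(self.X)
        self.rank_X = self.Q.shape[1]
        self._vc = None

    # -- per-vc state ------------------------------------------------------
    def set_vc(self, vc: VarianceComponents):
        if vc.sigma2_e <= 0:
            raise InputError("sigma2_e must be > 0 for a solvable CE system")
        if self._vc is not None and np.array_equal(vc.as_array(), self._vc.as_array()):
            return self
        V = vc.sigma2_e * np.eye(self.n)
        if vc.sigma2_a > 0:
            V += vc.sigma2_a * self.Va
        if vc.sigma2_d > 0:
            V += vc.sigma2_d * self.Vd
        cf = chol_factor(V)
        Vinv = sla.cho_solve(cf, np.eye(self.n), check_finite=False)
        self.logdet_V = chol_logdet(cf)
        if self.rank_X:
            ViQ = Vinv @ self.Q
            M = self.Q.T @ ViQ
            cfM = chol_factor(M)
            self.logdet_XtViX = chol_logdet(cfM)
            self.P = Vinv - ViQ @ sla.cho_solve(cfM, ViQ.T, check_finite=False)
        else:
            self.logdet_XtViX = 0.0
            self.P = Vinv
        self.Vinv = Vinv
        self.Py = self.P @ self.y
        self.ytPy = float(self.y @ self.Py)
        self._vc = vc
        return self

    @property
    def vc(self) -> VarianceComponents:
        return self._vc

    def reml_loglik(self) -> float:
        """Restricted log-likelihood up to an additive constant."""
        return -0.5 * (self.logdet_V + self.logdet_XtViX + self.ytPy)

    def blue(self) -> np.ndarray:
        """BLUE of the fixed effects on the original (possibly rank
        deficient) parameterization, via an eigenvalue-thresholded
        generalized inverse of ``X' V^-1 X``."""
        if self.X.shape[1] == 0:
            return np.zeros(0)
        ViX = self.Vinv @ self.X
        XtViX = self.X.T @ ViX
        if np.linalg.matrix_rank(XtViX) < XtViX.shape[0]:
            logger.warning("rank-deficient X' V^-1 X; using a generalized inverse")
        return sym_pinv(XtViX) @ (ViX.T @ self.y)


def _reliability_from_P(ws: CEWorkspace, vc: VarianceComponents):
    """Training reliabilities from the prediction-variance algebra."""
    M = ws.Z.T @ ws.P @ ws.Z  # q x q
    G, D = ws.G, ws.D
    GM = G @ M
    DM = D @ M
    var_a = vc.sigma2_a**2 * np.einsum("ij,ji->i", GM, G)
    var_d = vc.sigma2_d**2 * np.einsum("ij,ji->i", DM, D)
    cross = vc.sigma2_a * vc.sigma2_d * (
        np.einsum("ij,ji->i", GM, D) + np.einsum("ij,ji->i", DM, G)
    )
    var_g = var_a + var_d + cross
    g_ii = np.diag(G)
    d_ii = np.diag(D)
    rel_a = _safe_ratio(var_a, g_ii * vc.sigma2_a, "additive")
    rel_d = _safe_ratio(var_d, d_ii * vc.sigma2_d, "dominance")
    rel_g = _safe_ratio(var_g, g_ii * vc.sigma2_a + d_ii * vc.sigma2_d, "genotypic")
    return rel_a, rel_d, rel_g


def _safe_ratio(num, den, label):
    out = np.zeros_like(np.asarray(num, float))
    ok = np.asarray(den) > 0
    if not ok.all():
        logger.warning(
            "null %s variance denominator for %d individual(s); reliability reported as 0",
            label,
            int((~ok).sum()),
        )
    out[ok] = np.asarray(num)[ok] / np.asarray(den)[ok]
    return out


def gblup_ce(
    y,
    X,
    Z,
    G,
    D,
    vc: VarianceComponents,
    individual_ids=None,
    workspace: CEWorkspace | None = None,
) -> PredictionSet:
    """GBLUP-CE with training reliabilities for all phenotyped individuals."""
    ws = workspace if workspace is not None else CEWorkspace(y, X, Z, G, D)
    ws.set_vc(vc)
    b_hat = ws.blue()
    # P y == V^-1 (y - X b_hat) for any generalized-inverse BLUE
    a_hat = vc.sigma2_a * (ws.G @ (ws.Z.T @ ws.Py))
    d_hat = vc.sigma2_d * (ws.D @ (ws.Z.T @ ws.Py))
    rel_a, rel_d, rel_g = _reliability_from_P(ws, vc)
    ids = _default_ids(individual_ids, ws.q)
    return PredictionSet(
        individual_ids=ids,
        a_hat=a_hat,
        d_hat=d_hat,
        g_hat=a_hat + d_hat,
        b_hat=b_hat,
        rel_a=rel_a,
        rel_d=rel_d,
        rel_g=rel_g,
    )


def reliability_ce(y, X, Z, G, D, vc: VarianceComponents, workspace: CEWorkspace | None = None):
    """Training reliabilities ``(rel_a, rel_d, rel_g)`` only."""
    ws = workspace if workspace is not None else CEWorkspace(y, X, Z, G, D)
    ws.set_vc(vc)
    return _reliability_from_P(ws, vc)


def gblup_ce_validation(
    y,
    X,
    Z,
    pair: RelationshipPair,
    train_idx,
    val_idx,
    vc: VarianceComponents,
    individual_ids=None,
) -> PredictionSet:
    """GBLUP-CE for individuals without phenotypes.

    ``pair`` holds relationship matrices over the *union* of training and
    validation individuals, built from codings that share one allele
    frequency vector.  ``Z`` (n x len(train_idx)) maps observations to
    training individuals in ``train_idx`` order.  Predictions use the
    validation-to-training blocks:
    ``a_hat_v = s2a G[v,t] Z' V^-1 (y - X b_hat)``, and reliabilities the
    corresponding prediction-variance blocks.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if val_idx.size == 0:
        raise DimensionError("empty validation set")
    G, D = pair.G, pair.D
    tt = np.ix_(train_idx, train_idx)
    vt = np.ix_(val_idx, train_idx)
    ws = CEWorkspace(y, X, Z, G[tt], D[tt])
    ws.set_vc(vc)
    b_hat = ws.blue()
    ZtPy = ws.Z.T @ ws.Py
    Gvt = G[vt]
    Dvt = D[vt]
    a_hat = vc.sigma2_a * (Gvt @ ZtPy)
    d_hat = vc.sigma2_d * (Dvt @ ZtPy)
    M = ws.Z.T @ ws.P @ ws.Z
    GM = Gvt @ M
    DM = Dvt @ M
    var_a = vc.sigma2_a**2 * np.einsum("ij,ij->i", GM, Gvt)
    var_d = vc.sigma2_d**2 * np.einsum("ij,ij->i", DM, Dvt)
    var_g = var_a + var_d + vc.sigma2_a * vc.sigma2_d * (
        np.einsum("ij,ij->i", GM, Dvt) + np.einsum("ij,ij->i", DM, Gvt)
    )
    g_vv = np.diag(G)[val_idx]
    d_vv = np.diag(D)[val_idx]
    rel_a = _safe_ratio(var_a, g_vv * vc.sigma2_a, "additive")
    rel_d = _safe_ratio(var_d, d_vv * vc.sigma2_d, "dominance")
    rel_g = _safe_ratio(var_g, g_vv * vc.sigma2_a + d_vv * vc.sigma2_d, "genotypic")
    if individual_ids is None:
        ids = np.asarray([f"ind{i + 1}" for i in val_idx], dtype=object)
    else:
        ids = np.asarray(individual_ids, dtype=object)[val_idx]
    return PredictionSet(
        individual_ids=ids,
        a_hat=a_hat,
        d_hat=d_hat,
        g_hat=a_hat + d_hat,
        b_hat=b_hat,
        rel_a=rel_a,
        rel_d=rel_d,
        rel_g=rel_g,
    )


def _default_ids(individual_ids, q):
    if individual_ids is None:
        return np.asarray([f"ind{i + 1}" for i in range(q)], dtype=object)
    ids = np.asarray(individual_ids, dtype=object)
    if len(ids) != q:
        raise DimensionError("individual_ids length does not match q")
    return ids
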