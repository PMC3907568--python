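"""GBLUP via mixed model equations on SNP effects (QM formulation).

Model 2 places the randomness on the ``2m`` marker effects: with scaled
coding matrices ``T_alpha*``, ``T_delta*`` (from
:meth:`gdblup.grm.RelationshipPair.scaled_codings`, so that
``T* T*' = G`` resp. ``D``), the model is
``y = X b + Z T_alpha* alpha + Z T_delta* delta + e`` with
``Var(alpha) = I s2_alpha``, ``Var(delta) = I s2_delta``.  Because the
codings carry the normalization, ``s2_alpha = sigma2_a`` and
``s2_delta = sigma2_d`` — no conversion between marker-level and
individual-level variances is needed.

After absorbing the fixed-effect equations with the projector
``S = I - X (X'X)^- X'`` the system is

    [W' S W + Lambda] [alpha_hat; delta_hat] = W' S y,

``W = Z [T_alpha*, T_delta*]``, ``Lambda = blockdiag(lambda_a I_m,
lambda_d I_m)``, ``lambda = sigma2_e / sigma2_component``.  Individual
predictions are back-transforms ``a_hat = T_alpha* alpha_hat``,
``d_hat = T_delta* delta_hat`` and reproduce GBLUP-CE exactly.
Reliabilities come from the inverse-coefficient submatrices ``C^aa``,
``C^ad``, ``C^dd``: the prediction error variance of ``a_hat`` is
``T_alpha* C^aa T_alpha*' sigma2_e``, etc.

The absorbed system is ``2m x 2m``: the efficient route when individuals
outnumber markers (``q >= 2m``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from ._linalg import chol_factor, orth_basis
from .errors import DimensionError, InputError
from .gblup_ce import PredictionSet, VarianceComponents, _default_ids, _safe_ratio

logger = logging.getLogger(__name__)

__all__ = ["MMESystem", "MMESolution", "assemble_mme", "solve_mme", "gblup_qm",
           "reliability_qm", "gblup_qm_validation"]


@dataclass
class MMESystem:
    """Absorbed mixed-model-equation system for SNP additive and dominance
    effects.  Blocks whose variance component is zero are dropped (the
    corresponding effects are fixed at 0 — an infinite ridge)."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    T_alpha_star: np.ndarray
    T_delta_star: np.ndarray
    vc: VarianceComponents
    Q: np.ndarray = field(repr=False)  # orthonormal basis of col(X)
    rank_X: int
    coef: np.ndarray = field(repr=False)  # active-block absorbed coefficient matrix
    rhs: np.ndarray = field(repr=False)
    Sy: np.ndarray = field(repr=False)
    SW: np.ndarray = field(repr=False)  # S-projected active W columns
    alpha_active: bool
    delta_active: bool

    @property
    def m(self) -> int:
        return self.T_alpha_star.shape[1]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def lambda_alpha(self) -> float:
        return self.vc.sigma2_e / self.vc.sigma2_a if self.alpha_active else np.inf

    @property
    def lambda_delta(self) -> float:
        return self.vc.sigma2_e / self.vc.sigma2_d if self.delta_active else np.inf

    @property
    def S(self) -> np.ndarray:
        """Absorption projector ``I - X (X'X)^- X'`` (idempotent, S X = 0)."""
        return np.eye(self.n) - self.Q @ self.Q.T

    @property
    def rank_r(self) -> int:
        """Rank of the pre-absorption coefficient matrix: rank(X) plus one
        equation per active marker effect."""
        n_active = self.m * (int(self.alpha_active) + int(self.delta_active))
        return self.rank_X + n_active


@dataclass
class MMESolution:
    system: MMESystem
    alpha_hat: np.ndarray
    delta_hat: np.ndarray
    b_hat: np.ndarray
    _C: np.ndarray | None = field(default=None, repr=False)

    @property
    def C(self) -> np.ndarray:
        """Inverse of the absorbed coefficient matrix (active blocks)."""
        if self._C is None:
            sys = self.system
            if sys.coef.shape[0] == 0:
                self._C = np.zeros((0, 0))
            else:
                cf = chol_factor(sys.coef)
                self._C = sla.cho_solve(cf, np.eye(sys.coef.shape[0]), check_finite=False)
        return self._C

    def C_blocks(self):
        """``(C_aa, C_ad, C_dd)`` with zero blocks for inactive effects."""
        sys = self.system
        m = sys.m
        Caa = np.zeros((m, m))
        Cad = np.zeros((m, m))
        Cdd = np.zeros((m, m))
        C = self.C
        if sys.alpha_active and sys.delta_active:
            Caa[:] = C[:m, :m]
            Cad[:] = C[:m, m:]
            Cdd[:] = C[m:, m:]
        elif sys.alpha_active:
            Caa[:] = C
        elif sys.delta_active:
            Cdd[:] = C
        return Caa, Cad, Cdd


def assemble_mme(y, X, Z, T_alpha_star, T_delta_star, vc: VarianceComponents) -> MMESystem:
    """Build the absorbed MME system (active blocks only)."""
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.asarray(Z, float)
    Ta = np.asarray(T_alpha_star, float)
    Td = np.asarray(T_delta_star, float)
    n = y.shape[0]
    if X.shape[0] != n or Z.shape[0] != n:
        raise DimensionError("y, X, Z row counts do not agree")
    if Ta.shape != Td.shape or Z.shape[1] != Ta.shape[0]:
        raise DimensionError("coding matrices do not conform with Z")
    if vc.sigma2_e <= 0:
        raise InputError("sigma2_e must be > 0")
    m = Ta.shape[1]
    Q = orth_basis(X)
    rank_X = Q.shape[1]
    alpha_active = vc.sigma2_a > 0
    delta_active = vc.sigma2_d > 0
    if not alpha_active:
        logger.info("sigma2_a = 0: additive marker effects fixed at 0")
    if not delta_active:
        logger.info("sigma2_d = 0: dominance marker effects fixed at 0")

    cols = []
    lambdas = []
    if alpha_active:
        cols.append(Z @ Ta)
        lambdas.append(np.full(m, vc.sigma2_e / vc.sigma2_a))
    if delta_active:
        cols.append(Z @ Td)
        lambdas.append(np.full(m, vc.sigma2_e / vc.sigma2_d))
    if cols:
        W = np.hstack(cols)
        SW = W - Q @ (Q.T @ W) if rank_X else W
        coef = W.T @ SW  # == SW' SW since S idempotent
        coef = (coef + coef.T) / 2.0
        coef[np.diag_indices_from(coef)] += np.concatenate(lambdas)
        Sy = y - Q @ (Q.T @ y) if rank_X else y.copy()
        rhs = W.T @ Sy
    else:
        W = np.zeros((n, 0))
        SW = W
        coef = np.zeros((0, 0))
        Sy = y - Q @ (Q.T @ y) if rank_X else y.copy()
        rhs = np.zeros(0)
    return MMESystem(
        y=y, X=X, Z=Z, T_alpha_star=Ta, T_delta_star=Td, vc=vc, Q=Q,
        rank_X=rank_X, coef=coef, rhs=rhs, Sy=Sy, SW=SW,
        alpha_active=alpha_active, delta_active=delta_active,
    )


def solve_mme(system: MMESystem) -> MMESolution:
    m = system.m
    if system.coef.shape[0]:
        cf = chol_factor(system.coef)
        u_hat = sla.cho_solve(cf, system.rhs, check_finite=False)
    else:
        u_hat = np.zeros(0)
    alpha_hat = np.zeros(m)
    delta_hat = np.zeros(m)
    if system.alpha_active and system.delta_active:
        alpha_hat = u_hat[:m]
        delta_hat = u_hat[m:]
    elif system.alpha_active:
        alpha_hat = u_hat
    elif system.delta_active:
        delta_hat = u_hat
    # back-solve fixed effects: OLS of y - W u_hat on X (min-norm if deficient)
    resid = system.y - system.Z @ (system.T_alpha_star @ alpha_hat + system.T_delta_star @ delta_hat)
    if system.X.shape[1]:
        b_hat = np.linalg.lstsq(system.X, resid, rcond=None)[0]
    else:
        b_hat = np.zeros(0)
    return MMESolution(system=system, alpha_hat=alpha_hat, delta_hat=delta_hat, b_hat=b_hat)


def reliability_qm(solution: MMESolution):
    """Training reliabilities ``(rel_a, rel_d, rel_g)`` from the inverse
    submatrices: ``rel_a,i = 1 - (T_a* C^aa T_a*')_ii s2e / (g_ii s2a)``
    and analogously for dominance and genotypic values (the genotypic PEV
    uses all four blocks)."""
    sys = solution.system
    vc = sys.vc
    Ta, Td = sys.T_alpha_star, sys.T_delta_star
    g_ii = np.einsum("ij,ij->i", Ta, Ta)
    d_ii = np.einsum("ij,ij->i", Td, Td)
    Caa, Cad, Cdd = solution.C_blocks()
    s2e = vc.sigma2_e
    pev_a = s2e * np.einsum("ij,jk,ik->i", Ta, Caa, Ta) if sys.alpha_active else np.zeros(len(g_ii))
    pev_d = s2e * np.einsum("ij,jk,ik->i", Td, Cdd, Td) if sys.delta_active else np.zeros(len(d_ii))
    pev_cross = s2e * np.einsum("ij,jk,ik->i", Ta, Cad, Td)
    pev_g = pev_a + pev_d + 2.0 * pev_cross
    rel_a = _safe_ratio(g_ii * vc.sigma2_a - pev_a, g_ii * vc.sigma2_a, "additive") \
        if sys.alpha_active else np.zeros(len(g_ii))
    rel_d = _safe_ratio(d_ii * vc.sigma2_d - pev_d, d_ii * vc.sigma2_d, "dominance") \
        if sys.delta_active else np.zeros(len(d_ii))
    den_g = g_ii * vc.sigma2_a + d_ii * vc.sigma2_d
    rel_g = _safe_ratio(den_g - pev_g, den_g, "genotypic")
    return rel_a, rel_d, rel_g


def gblup_qm(y, X, Z, T_alpha_star, T_delta_star, vc: VarianceComponents,
             individual_ids=None) -> tuple[PredictionSet, MMESolution]:
    """GBLUP-QM with training reliabilities; returns the prediction set and
    the MME solution (reusable for validation individuals)."""
    system = assemble_mme(y, X, Z, T_alpha_star, T_delta_star, vc)
    sol = solve_mme(system)
    a_hat = T_alpha_star @ sol.alpha_hat
    d_hat = T_delta_star @ sol.delta_hat
    rel_a, rel_d, rel_g = reliability_qm(sol)
    ids = _default_ids(individual_ids, T_alpha_star.shape[0])
    pred = PredictionSet(
        individual_ids=ids, a_hat=a_hat, d_hat=d_hat, g_hat=a_hat + d_hat,
        b_hat=sol.b_hat, rel_a=rel_a, rel_d=rel_d, rel_g=rel_g,
    )
    return pred, sol


def gblup_qm_validation(solution: MMESolution, T_alpha_star_val, T_delta_star_val,
                        individual_ids=None) -> PredictionSet:
    """Predictions and reliabilities for individuals without phenotypes.

    Validation individuals must be coded with the same allele frequencies
    and normalizers as the training set (``T*`` rows of the combined
    coding); a column-count mismatch raises :class:`DimensionError`.
    """
    sys = solution.system
    Ta_v = np.asarray(T_alpha_star_val, float)
    Td_v = np.asarray(T_delta_star_val, float)
    if Ta_v.shape[1] != sys.m or Td_v.shape[1] != sys.m:
        raise DimensionError(
            f"validation coding has {Ta_v.shape[1]} SNPs but the system has {sys.m}"
        )
    vc = sys.vc
    a_hat = Ta_v @ solution.alpha_hat
    d_hat = Td_v @ solution.delta_hat
    g_vv = np.einsum("ij,ij->i", Ta_v, Ta_v)
    d_vv = np.einsum("ij,ij->i", Td_v, Td_v)
    Caa, Cad, Cdd = solution.C_blocks()
    s2e = vc.sigma2_e
    nv = Ta_v.shape[0]
    pev_a = s2e * np.einsum("ij,jk,ik->i", Ta_v, Caa, Ta_v) if sys.alpha_active else np.zeros(nv)
    pev_d = s2e * np.einsum("ij,jk,ik->i", Td_v, Cdd, Td_v) if sys.delta_active else np.zeros(nv)
    pev_cross = s2e * np.einsum("ij,jk,ik->i", Ta_v, Cad, Td_v)
    # for an unphenotyped individual the "PEV" of a_hat is Var(a_v - a_hat_v)
    rel_a = _safe_ratio(g_vv * vc.sigma2_a - pev_a, g_vv * vc.sigma2_a, "additive") \
        if sys.alpha_active else np.zeros(nv)
    rel_d = _safe_ratio(d_vv * vc.sigma2_d - pev_d, d_vv * vc.sigma2_d, "dominance") \
        if sys.delta_active else np.zeros(nv)
    den_g = g_vv * vc.sigma2_a + d_vv * vc.sigma2_d
    rel_g = _safe_ratio(den_g - (pev_a + pev_d + 2.0 * pev_cross), den_g, "genotypic")
    ids = _default_ids(individual_ids, nv)
    return PredictionSet(
        individual_ids=ids, a_hat=a_hat, d_hat=d_hat, g_hat=a_hat + d_hat,
        b_hat=solution.b_hat, rel_a=rel_a, rel_d=rel_d, rel_g=rel_g,
    )
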