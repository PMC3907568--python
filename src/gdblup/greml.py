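"""Genomic REML estimation of additive, dominance and residual variances.

Two inverse-free EM-type iterations (conditional-expectation and
mixed-model-equation forms — the same iteration written in two algebras)
and a safeguarded average-information (AI) Newton algorithm.

With ``P`` the REML projection and ``V_a = Z G Z'``, ``V_d = Z D Z'``,
``V_e = I``, the EM updates are

    s2a <- s2a + (s2a^2 / q) [y'P V_a P y - tr(P V_a)]
    s2d <- s2d + (s2d^2 / q) [y'P V_d P y - tr(P V_d)]
    s2e <- s2e + (s2e^2 / (n - rank X)) [y'P P y - tr(P)]

whose fixed points are the REML score equations.  The MME form computes
the same numbers from ``alpha_hat' alpha_hat``, ``tr(C^aa)`` etc. of the
absorbed SNP-effect system — the two are algebraically identical, which
the test-suite certifies to machine precision.  The residual denominator
``n - rank(X)`` is the choice under which the MME form takes the familiar
shape ``[e'e + s2e (2m - lambda_a tr C^aa - lambda_d tr C^dd)] / (n - rank X)``
(the rank of the full SNP-effect mixed-model coefficient matrix,
``rank(X) + 2m``, enters through the trace identity).

AI-REML uses the average-information matrix ``AI_ij = y'P V_i P V_j P y / 2``
and scores ``-(tr(P V_i) - y'P V_i P y)/2``.  Safeguards: a genetic
component that an AI step pushes non-positive is floored at a tiny
positive value inside the proposal; a proposal that decreases the
restricted likelihood is replaced by an EM step (always uphill); and a
genetic component that sits at the floor while AI keeps pushing it
negative for three consecutive iterations is a boundary estimate and is
clamped to exactly zero for the remaining iterations (logged).  The
floor-then-clamp scheme self-corrects: if the optimum is interior, the
next AI step from the floor climbs back; EM alone can only approach a
zero boundary as O(1/iteration), which is why the clamp exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import sym_pinv
from .errors import InputError
from .gblup_ce import CEWorkspace, VarianceComponents, choose_formulation
from .gblup_qm import MMESystem, assemble_mme, solve_mme

logger = logging.getLogger(__name__)

__all__ = [
    "REMLTrace",
    "HeritabilityEstimates",
    "GREMLResult",
    "em_step_ce",
    "em_step_qm",
    "reml_loglik",
    "ai_reml",
    "heritabilities",
    "run_greml",
]

_EPS = 1e-12


@dataclass
class REMLTrace:
    """Per-iteration record of a REML run."""

    algorithm: str
    rows: list = field(default_factory=list)
    converged: bool = False

    def append(self, it, vc: VarianceComponents, loglik, step, change):
        self.rows.append(
            {
                "iteration": it,
                "sigma2_a": vc.sigma2_a,
                "sigma2_d": vc.sigma2_d,
                "sigma2_e": vc.sigma2_e,
                "loglik": loglik,
                "step": step,
                "max_rel_change": change,
            }
        )

    @property
    def n_iter(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


@dataclass(frozen=True)
class HeritabilityEstimates:
    h2_a: float
    h2_d: float
    H2: float
    sigma2_p: float


def heritabilities(vc: VarianceComponents) -> HeritabilityEstimates:
    """Narrow-sense, dominance and broad-sense heritabilities.

    ``h2_a = s2a/s2p``, ``h2_d = s2d/s2p``, ``H2 = h2_a + h2_d`` with
    ``s2p = s2a + s2d + s2e``."""
    s2p = vc.sigma2_p
    if s2p <= 0:
        raise InputError("all variance components are zero; heritability undefined")
    return HeritabilityEstimates(
        h2_a=vc.sigma2_a / s2p,
        h2_d=vc.sigma2_d / s2p,
        H2=(vc.sigma2_a + vc.sigma2_d) / s2p,
        sigma2_p=s2p,
    )


def reml_loglik(y, X, Z, G, D, vc: VarianceComponents, workspace: CEWorkspace | None = None) -> float:
    """Restricted log-likelihood (up to an additive constant)."""
    ws = workspace if workspace is not None else CEWorkspace(y, X, Z, G, D)
    ws.set_vc(vc)
    return ws.reml_loglik()


def _em_quantities(ws: CEWorkspace):
    """Quadratic forms and traces feeding both EM and AI updates."""
    Py = ws.Py
    ra = ws.Va @ Py
    rd = ws.Vd @ Py
    quad = np.array([Py @ ra, Py @ rd, Py @ Py])
    traces = np.array(
        [
            float(np.sum(ws.P * ws.Va)),
            float(np.sum(ws.P * ws.Vd)),
            float(np.trace(ws.P)),
        ]
    )
    return quad, traces, ra, rd


def _em_update(ws: CEWorkspace, vc: VarianceComponents, quad, traces) -> VarianceComponents:
    q = ws.q
    df_e = max(ws.n - ws.rank_X, 1)
    theta = vc.as_array()
    denom = np.array([q, q, df_e], dtype=float)
    new = theta + theta**2 / denom * (quad - traces)
    if np.any(new[:2] < 0):
        logger.info("EM update hit the zero boundary; clamping negative component(s)")
        new[:2] = np.maximum(new[:2], 0.0)
    floor = _EPS * max(float(np.var(ws.y)), _EPS)
    new[2] = max(new[2], floor)
    return VarianceComponents.from_array(new)


def em_step_ce(y, X, Z, G, D, vc: VarianceComponents, workspace: CEWorkspace | None = None) -> VarianceComponents:
    """One EM iteration in the conditional-expectation form."""
    ws = workspace if workspace is not None else CEWorkspace(y, X, Z, G, D)
    ws.set_vc(vc)
    quad, traces, _, _ = _em_quantities(ws)
    return _em_update(ws, vc, quad, traces)


def em_step_qm(system: MMESystem) -> VarianceComponents:
    """One EM iteration computed from the absorbed SNP-effect equations.

    Uses ``alpha_hat' alpha_hat``, ``delta_hat' delta_hat``, the traces of
    the inverse-coefficient blocks and the rank of the coefficient matrix;
    identical (not merely fixed-point-equivalent) to :func:`em_step_ce`.
    """
    vc = system.vc
    sol = solve_mme(system)
    Caa, _, Cdd = sol.C_blocks()
    m = system.m
    q = system.Z.shape[1]
    n = system.n
    s_a, s_d, s_e = vc.sigma2_a, vc.sigma2_d, vc.sigma2_e
    tr_caa = float(np.trace(Caa))
    tr_cdd = float(np.trace(Cdd))

    new_a = 0.0
    if system.alpha_active:
        aa = float(sol.alpha_hat @ sol.alpha_hat)
        new_a = s_a + (aa - m * s_a + s_e * tr_caa) / q
    new_d = 0.0
    if system.delta_active:
        dd = float(sol.delta_hat @ sol.delta_hat)
        new_d = s_d + (dd - m * s_d + s_e * tr_cdd) / q

    u_active = []
    if system.alpha_active:
        u_active.append(sol.alpha_hat)
    if system.delta_active:
        u_active.append(sol.delta_hat)
    resid = system.Sy - (system.SW @ np.concatenate(u_active) if u_active else 0.0)
    m_active = system.SW.shape[1]
    hat_trace = m_active
    if system.alpha_active:
        hat_trace -= system.lambda_alpha * tr_caa
    if system.delta_active:
        hat_trace -= system.lambda_delta * tr_cdd
    df_e = max(n - system.rank_X, 1)
    new_e = (float(resid @ resid) + s_e * hat_trace) / df_e

    new = np.array([max(new_a, 0.0), max(new_d, 0.0), new_e])
    floor = _EPS * max(float(np.var(system.y)), _EPS)
    new[2] = max(new[2], floor)
    return VarianceComponents.from_array(new)


def _ai_system(ws: CEWorkspace, quad, traces, ra, rd):
    """Average-information matrix and score vector (order a, d, e)."""
    P = ws.P
    Py = ws.Py
    vecs = [P @ ra, P @ rd, P @ Py]  # P V_i P y
    resid = [ra, rd, Py]  # V_i P y
    AI = np.empty((3, 3))
    for i in range(3):
        for j in range(i, 3):
            AI[i, j] = AI[j, i] = 0.5 * float(resid[i] @ vecs[j])
    score = -0.5 * (traces - quad)
    return AI, score


def ai_reml(
    y,
    X,
    Z,
    G,
    D,
    init_vc: VarianceComponents | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    algorithm: str = "hybrid",
) -> tuple[VarianceComponents, REMLTrace]:
    """REML by safeguarded average-information iteration (or pure EM).

    ``algorithm`` is ``"em"`` for pure EM or ``"ai"``/``"hybrid"`` for AI
    with EM fallback.  Returns the final components and the iteration
    trace; ``trace.converged`` is False when the iteration budget is
    exhausted (the best iterate is still returned).
    """
    if algorithm not in ("em", "ai", "hybrid"):
        raise InputError(f"unknown algorithm {algorithm!r}")
    ws = CEWorkspace(y, X, Z, G, D)
    vary = float(np.var(ws.y))
    if init_vc is None:
        init_vc = VarianceComponents(vary / 3.0, vary / 3.0, vary / 3.0)
    vc = init_vc
    trace = REMLTrace(algorithm=algorithm)
    frozen = np.zeros(3, dtype=bool)  # components clamped at the zero boundary
    neg_streak = np.zeros(3, dtype=int)
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        ws.set_vc(vc)
        ll = ws.reml_loglik()
        if algorithm == "em" and ll < ll_prev - 1e-8 * (1.0 + abs(ll_prev)):
            logger.warning("EM decreased the restricted likelihood at iteration %d", it)
        quad, traces, ra, rd = _em_quantities(ws)
        vc_em = _em_update(ws, vc, quad, traces)
        theta = vc.as_array()

        step = "em"
        theta_next = vc_em.as_array()
        if algorithm != "em":
            AI, score = _ai_system(ws, quad, traces, ra, rd)
            free = ~frozen
            delta = np.zeros(3)
            try:
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                delta[:] = 0.0
            proposal = theta + delta
            floor = 1e-6 * max(vary, _EPS)
            pushed = free & (proposal <= 0.0)
            at_floor = theta <= 1.01 * floor
            # a component already at the floor that AI keeps pushing
            # negative is heading for the boundary
            neg_streak[pushed & at_floor] += 1
            neg_streak[~pushed] = 0
            proposal[pushed] = floor
            proposal[2] = max(proposal[2], 1e-8 * max(vary, _EPS))
            cand = VarianceComponents.from_array(proposal)
            ws.set_vc(cand)
            ll_cand = ws.reml_loglik()
            if ll_cand >= ll - 1e-10 * (1.0 + abs(ll)):
                theta_next = proposal
                step = "ai" if not pushed.any() else "ai-floored"
            else:
                theta_next = vc_em.as_array()
                step = "em-fallback"
            clamp = (neg_streak >= 3) & ~frozen
            clamp[2] = False  # residual variance never clamped to zero
            if clamp.any():
                for k in np.where(clamp)[0]:
                    name = ("sigma2_a", "sigma2_d")[k]
                    logger.info("boundary event: %s clamped to 0 at iteration %d", name, it)
                frozen |= clamp
        theta_next[frozen] = 0.0
        free_now = ~frozen
        change = float(
            np.max(
                np.abs(theta_next[free_now] - theta[free_now])
                / np.maximum(theta[free_now], _EPS * max(vary, _EPS))
            )
        )
        vc = VarianceComponents.from_array(theta_next)
        trace.append(it, vc, ll, step, change)
        ll_prev = ll
        if change < tol:
            trace.converged = True
            break
    if not trace.converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    return vc, trace


@dataclass
class GREMLResult:
    vc: VarianceComponents
    heritability: HeritabilityEstimates
    se_vc: dict
    se_h2: dict
    trace: REMLTrace

    @property
    def converged(self) -> bool:
        return self.trace.converged


def _standard_errors(ws: CEWorkspace, vc: VarianceComponents):
    """Sampling covariance of the components from the inverse AI matrix at
    convergence; heritability SEs by the delta method."""
    ws.set_vc(vc)
    quad, traces, ra, rd = _em_quantities(ws)
    AI, _ = _ai_system(ws, quad, traces, ra, rd)
    cov = sym_pinv(AI)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    s2p = vc.sigma2_p
    grads = {
        "h2_a": np.array([s2p - vc.sigma2_a, -vc.sigma2_a, -vc.sigma2_a]) / s2p**2,
        "h2_d": np.array([-vc.sigma2_d, s2p - vc.sigma2_d, -vc.sigma2_d]) / s2p**2,
    }
    grads["H2"] = grads["h2_a"] + grads["h2_d"]
    se_h2 = {k: float(np.sqrt(max(g @ cov @ g, 0.0))) for k, g in grads.items()}
    se_vc = {
        "sigma2_a": float(se[0]),
        "sigma2_d": float(se[1]),
        "sigma2_e": float(se[2]),
    }
    return se_vc, se_h2


def run_greml(
    y,
    X,
    Z,
    G,
    D,
    t_alpha_star=None,
    t_delta_star=None,
    algorithm: str = "hybrid",
    formulation: str = "auto",
    init_vc: VarianceComponents | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> GREMLResult:
    """Estimate variance components and report heritabilities with SEs.

    ``formulation`` selects the algebra for pure-EM iteration: ``"auto"``
    applies the q-versus-2m rule when the scaled coding matrices are
    supplied (the QM form needs them); the AI/hybrid algorithms evaluate
    likelihoods and information in the CE algebra regardless, since both
    algebras give identical iterates.
    """
    if formulation not in ("auto", "ce", "qm"):
        raise InputError(f"unknown formulation {formulation!r}")
    y = np.asarray(y, float).ravel()
    q = np.asarray(G).shape[0]
    if formulation == "auto":
        if t_alpha_star is not None:
            formulation = choose_formulation(q, t_alpha_star.shape[1])
        else:
            formulation = "ce"
    if formulation == "qm" and (t_alpha_star is None or t_delta_star is None):
        raise InputError("the QM formulation needs the scaled coding matrices")

    if algorithm == "em" and formulation == "qm":
        vary = float(np.var(y))
        vc = init_vc or VarianceComponents(vary / 3.0, vary / 3.0, vary / 3.0)
        trace = REMLTrace(algorithm="em-qm")
        ws = CEWorkspace(y, X, Z, G, D)  # likelihood bookkeeping only
        for it in range(1, max_iter + 1):
            system = assemble_mme(y, X, Z, t_alpha_star, t_delta_star, vc)
            vc_new = em_step_qm(system)
            ws.set_vc(vc)
            ll = ws.reml_loglik()
            change = float(
                np.max(
                    np.abs(vc_new.as_array() - vc.as_array())
                    / np.maximum(vc.as_array(), _EPS * max(vary, _EPS))
                )
            )
            vc = vc_new
            trace.append(it, vc, ll, "em", change)
            if change < tol:
                trace.converged = True
                break
        if not trace.converged:
            logger.warning("REML did not converge in %d iterations", max_iter)
    else:
        vc, trace = ai_reml(
            y, X, Z, G, D, init_vc=init_vc, max_iter=max_iter, tol=tol, algorithm=algorithm
        )
    ws = CEWorkspace(y, X, Z, G, D)
    se_vc, se_h2 = _standard_errors(ws, vc)
    return GREMLResult(
        vc=vc,
        heritability=heritabilities(vc),
        se_vc=se_vc,
        se_h2=se_h2,
        trace=trace,
    )
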