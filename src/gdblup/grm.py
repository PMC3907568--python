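"""Genomic additive and dominance relationship matrices.

Starting from the raw Gram matrices ``T_alpha @ T_alpha.T`` and
``T_delta @ T_delta.T`` of the breeding-value and dominance-deviation
codings, three normalizations are supported:

* **Definition I** — divide by the *expected* variance of a diagonal
  element under HWE: ``sum_k 2 p_k (1-p_k)`` for the additive matrix
  (VanRaden's classical scaling) and ``sum_k (2 p_k (1-p_k))**2`` for the
  dominance matrix.
* **Definition II** — divide by the *observed* mean diagonal, so the mean
  diagonal of the result is exactly 1.
* **Definition III** — correlation transform: element ``(i, j)`` divided
  by ``sqrt(raw_ii * raw_jj)``; every diagonal is exactly 1.  The additive
  version is the genomic analogue of Wright's coefficient of relationship;
  under it the expected dominance correlation of non-inbred full sibs is
  0.25.

``definition="raw"`` returns the unnormalized Gram matrices; useful to
demonstrate why normalization matters for variance-component estimation
(raw diagonals, and hence implied variances, scale with the number of
markers).

All definitions can be written as ``K^{-1/2} T (K^{-1/2} T)^T`` for a
diagonal ``K`` (scalar for I/II, per-individual for III).  The scaled
codings ``T* = K^{-1/2} T`` reproduce the chosen relationship matrices
exactly and are the marker-effect model matrices used by the
mixed-model-equation (QM) formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateIndividualError, DimensionError, InputError

__all__ = ["RelationshipPair", "build_grm", "relationship_summary"]

DEFINITIONS = ("I", "II", "III", "raw")


@dataclass(frozen=True)
class RelationshipPair:
    """Additive (``G``) and dominance (``D``) relationship matrices plus the
    per-individual diagonal normalizers ``k_alpha``/``k_delta`` (constant
    vectors for Definitions I/II and raw) needed to rebuild the scaled
    coding matrices."""

    G: np.ndarray
    D: np.ndarray
    definition: str
    k_alpha: np.ndarray  # length-q diagonal of K_alpha
    k_delta: np.ndarray  # length-q diagonal of K_delta

    @property
    def q(self) -> int:
        return self.G.shape[0]

    def scaled_codings(self, T_alpha: np.ndarray, T_delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """``(T_alpha*, T_delta*)`` such that ``T* @ T*.T`` equals ``G``/``D``.

        ``T_alpha``/``T_delta`` must be the same coding matrices the pair
        was built from (rows may be a superset in the same order only if
        the definition's normalizers are scalar)."""
        if T_alpha.shape[0] != self.q or T_delta.shape[0] != self.q:
            raise DimensionError("coding matrices do not match the relationship pair")
        return (
            T_alpha / np.sqrt(self.k_alpha)[:, None],
            T_delta / np.sqrt(self.k_delta)[:, None],
        )

    def submatrix(self, idx: np.ndarray) -> "RelationshipPair":
        idx = np.asarray(idx)
        return RelationshipPair(
            G=self.G[np.ix_(idx, idx)],
            D=self.D[np.ix_(idx, idx)],
            definition=self.definition,
            k_alpha=self.k_alpha[idx],
            k_delta=self.k_delta[idx],
        )


def build_grm(
    T_alpha: np.ndarray,
    T_delta: np.ndarray,
    freqs: np.ndarray | None = None,
    definition: str = "II",
) -> RelationshipPair:
    """Build the genomic additive/dominance relationship pair.

    ``freqs`` is required for Definition I (expected diagonal variances
    under HWE use the allele frequencies that produced the codings).
    Definition III raises :class:`DegenerateIndividualError` when an
    individual's raw diagonal is zero (for the dominance matrix this
    happens when the individual is heterozygous at no SNP).
    """
    if definition not in DEFINITIONS:
        raise InputError(f"unknown definition {definition!r}; choose from {DEFINITIONS}")
    T_alpha = np.asarray(T_alpha, dtype=float)
    T_delta = np.asarray(T_delta, dtype=float)
    if T_alpha.shape != T_delta.shape or T_alpha.ndim != 2 or T_alpha.shape[1] < 1:
        raise DimensionError("coding matrices must be equal-shape q x m with m >= 1")
    q = T_alpha.shape[0]
    rawG = T_alpha @ T_alpha.T
    rawD = T_delta @ T_delta.T

    if definition == "raw":
        ones = np.ones(q)
        return RelationshipPair(rawG, rawD, "raw", ones, ones)

    if definition == "I":
        if freqs is None:
            raise InputError("Definition I requires the allele-frequency vector")
        het = 2.0 * np.asarray(freqs, float) * (1.0 - np.asarray(freqs, float))
        ka, kd = float(het.sum()), float((het**2).sum())
        _check_normalizer(ka, kd)
        return RelationshipPair(
            rawG / ka, rawD / kd, "I", np.full(q, ka), np.full(q, kd)
        )

    if definition == "II":
        ka = float(np.mean(np.diag(rawG)))
        kd = float(np.mean(np.diag(rawD)))
        _check_normalizer(ka, kd)
        return RelationshipPair(
            rawG / ka, rawD / kd, "II", np.full(q, ka), np.full(q, kd)
        )

    # Definition III: correlation transform
    da = np.diag(rawG).copy()
    dd = np.diag(rawD).copy()
    for name, d in (("additive", da), ("dominance", dd)):
        if np.any(d <= 0):
            i = int(np.argwhere(d <= 0)[0][0])
            raise DegenerateIndividualError(
                f"individual {i} has a zero raw {name} diagonal; "
                "the correlation transform (Definition III) is undefined for it"
            )
    sa = np.sqrt(da)
    sd = np.sqrt(dd)
    G = rawG / np.outer(sa, sa)
    D = rawD / np.outer(sd, sd)
    # enforce exact unit diagonals against rounding
    np.fill_diagonal(G, 1.0)
    np.fill_diagonal(D, 1.0)
    return RelationshipPair(G, D, "III", da, dd)


def _check_normalizer(ka: float, kd: float) -> None:
    if ka <= 0 or kd <= 0:
        raise DegenerateIndividualError(
            "zero normalizer: all SNPs are monomorphic or codings are all zero"
        )


def relationship_summary(
    pair: RelationshipPair,
    pair_labels: pd.DataFrame,
    z_threshold: float = 3.5,
    known_classes: tuple = ("full-sib", "half-sib", "unrelated"),
) -> pd.DataFrame:
    """Per-relationship-class summaries of off-diagonal elements.

    ``pair_labels`` has integer columns ``i``, ``j`` (0-based indices into
    the matrices, ``i != j``) and a string column ``class`` (e.g.
    ``full-sib``, ``half-sib``, ``unrelated``).  Returns one row per
    (matrix, class): mean, SD, min, max, count, and the number of outliers
    beyond ``z_threshold`` robust z-scores (used in practice to screen
    pedigree errors before comparing with theoretical expectations).
    """
    for col in ("i", "j", "class"):
        if col not in pair_labels.columns:
            raise InputError(f"pair_labels needs column {col!r}")
    if (pair_labels["i"] == pair_labels["j"]).any():
        raise InputError("pair_labels must reference off-diagonal pairs (i != j)")
    if known_classes is not None:
        unknown = set(pair_labels["class"]) - set(known_classes)
        if unknown:
            raise InputError(f"unknown relationship class label(s): {sorted(unknown)}")
    rows = []
    for matrix_name, M in (("additive", pair.G), ("dominance", pair.D)):
        vals_all = M[pair_labels["i"].to_numpy(), pair_labels["j"].to_numpy()]
        for cls, grp in pair_labels.assign(value=vals_all).groupby("class", sort=True):
            v = grp["value"].to_numpy()
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            if sd > 0:
                z = np.abs(v - v.mean()) / sd
                n_out = int((z > z_threshold).sum())
            else:
                n_out = 0
            rows.append(
                {
                    "matrix": matrix_name,
                    "class": cls,
                    "n_pairs": len(v),
                    "mean": v.mean(),
                    "sd": sd,
                    "min": v.min(),
                    "max": v.max(),
                    "n_outliers": n_out,
                }
            )
    return pd.DataFrame(rows)
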