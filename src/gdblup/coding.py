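"""Quantitative-genetics model matrices from SNP allele counts.

The genotypic value of a biallelic locus is partitioned, under
Hardy-Weinberg equilibrium, into a breeding value and a dominance
deviation (Falconer's classical decomposition).  With ``p`` the frequency
of the counted allele, ``q = 1 - p``, and ``x`` the allele count of an
individual (0, 1 or 2 copies), the contrast coefficients are

* additive (breeding value per unit gene-substitution effect):
  ``x - 2p``  — i.e. ``2q``, ``q - p``, ``-2p`` for ``x = 2, 1, 0``;
* dominance (dominance deviation per unit dominance effect):
  ``-2q**2``, ``2pq``, ``-2p**2`` for ``x = 2, 1, 0``.

Both contrasts have zero expectation over HWE genotype frequencies
``(p**2, 2pq, q**2)``, so with in-sample allele frequencies the additive
coding columns are exactly mean-zero and the dominance columns are
mean-zero in expectation.  Setting ``p = 0.5`` recovers the familiar
(-1, 0, 1) additive and (-0.5, 0.5, -0.5) dominance codings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSNPError, DimensionError, InputError, LinkageError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "DesignSet",
    "estimate_freqs",
    "additive_coding",
    "dominance_coding",
    "build_design",
]


def estimate_freqs(counts: np.ndarray) -> np.ndarray:
    """In-sample frequency of the counted allele, ``p_k = sum(col k)/(2q)``.

    Raises :class:`DimensionError` on an empty matrix.  Monomorphic SNPs
    (p of 0 or 1) are legal here; they are flagged and dropped by
    :meth:`GenotypeMatrix.filter_maf` before any coding is built.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 1:
        raise DimensionError(f"need a non-empty q x m count matrix, got shape {counts.shape}")
    _check_counts(counts)
    return counts.mean(axis=0) / 2.0


def _check_counts(counts: np.ndarray) -> None:
    bad = ~np.isin(counts, (0, 1, 2))
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise InputError(
            f"allele counts must be 0/1/2; found {counts[i, k]!r} at individual {i}, SNP {k}"
        )


def _check_freqs(freqs: np.ndarray) -> None:
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        k = int(np.argwhere((freqs <= 0.0) | (freqs >= 1.0))[0][0])
        raise DegenerateSNPError(
            f"SNP {k} has allele frequency {freqs[k]}; monomorphic SNPs must be "
            "filtered before coding (see GenotypeMatrix.filter_maf)"
        )


def additive_coding(counts: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Breeding-value contrast matrix ``T_alpha`` with entries ``x - 2p_k``."""
    counts = np.asarray(counts, dtype=float)
    _check_freqs(freqs)
    return counts - 2.0 * np.asarray(freqs, dtype=float)[None, :]


def dominance_coding(counts: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Dominance-deviation contrast matrix ``T_delta``.

    Entries per allele count: ``2 -> -2(1-p)^2``, ``1 -> 2p(1-p)``,
    ``0 -> -2p^2``.
    """
    counts = np.asarray(counts)
    _check_freqs(freqs)
    p = np.asarray(freqs, dtype=float)[None, :]
    q = 1.0 - p
    out = np.empty(counts.shape, dtype=float)
    c = counts.astype(int)
    # vectorised three-way select on the count value
    out = np.where(c == 2, -2.0 * q * q, np.where(c == 1, 2.0 * p * q, -2.0 * p * p))
    return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """A ``q x m`` matrix of reference-allele counts with SNP metadata.

    ``freqs`` holds the frequency of the counted allele per SNP; by
    default estimated in-sample, but an external vector may be supplied
    (needed when training and validation individuals must share one
    coding).
    """

    counts: np.ndarray
    snp_ids: np.ndarray
    individual_ids: np.ndarray
    freqs: np.ndarray

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        snp_ids: Sequence | None = None,
        individual_ids: Sequence | None = None,
        freqs: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.size == 0:
            raise DimensionError(f"need a non-empty q x m count matrix, got shape {counts.shape}")
        _check_counts(counts)
        counts = counts.astype(np.int8)
        q, m = counts.shape
        if snp_ids is None:
            snp_ids = [f"snp{k + 1}" for k in range(m)]
        if individual_ids is None:
            individual_ids = [f"ind{i + 1}" for i in range(q)]
        snp_ids = np.asarray(snp_ids, dtype=object)
        individual_ids = np.asarray(individual_ids, dtype=object)
        if len(snp_ids) != m or len(individual_ids) != q:
            raise DimensionError("id vectors do not match the count matrix shape")
        if len(set(individual_ids)) != q:
            raise InputError("duplicate individual IDs")
        if freqs is None:
            freqs = estimate_freqs(counts)
        else:
            freqs = np.asarray(freqs, dtype=float)
            if freqs.shape != (m,):
                raise DimensionError("freqs length does not match the number of SNPs")
        return cls(counts=counts, snp_ids=snp_ids, individual_ids=individual_ids, freqs=freqs)

    def filter_maf(self, threshold: float = 0.0) -> "GenotypeMatrix":
        """Drop monomorphic SNPs and SNPs with minor-allele frequency at or
        below ``threshold`` (default 0: monomorphic only).  Frequencies of
        the kept SNPs are preserved; the number dropped is logged."""
        maf = np.minimum(self.freqs, 1.0 - self.freqs)
        keep = maf > threshold
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d SNP(s) with MAF <= %g", n_drop, threshold)
        if not keep.any():
            raise DegenerateSNPError("no SNPs remain after MAF filtering")
        return GenotypeMatrix(
            counts=self.counts[:, keep],
            snp_ids=self.snp_ids[keep],
            individual_ids=self.individual_ids,
            freqs=self.freqs[keep],
        )

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset (individuals), keeping the frequency vector unchanged."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            counts=self.counts[idx],
            snp_ids=self.snp_ids,
            individual_ids=self.individual_ids[idx],
            freqs=self.freqs,
        )

    def codings(self) -> tuple[np.ndarray, np.ndarray]:
        """``(T_alpha, T_delta)`` for these counts and frequencies."""
        return (
            additive_coding(self.counts, self.freqs),
            dominance_coding(self.counts, self.freqs),
        )


@dataclass(frozen=True)
class DesignSet:
    """Model matrices for the mixed model ``y = Xb + Z T_alpha alpha + Z T_delta delta + e``.

    ``X`` is ``n x c`` (fixed effects after dummy encoding), ``Z`` the
    ``n x q`` incidence of observations to individuals (each row has
    exactly one 1), and ``T_alpha``/``T_delta`` the ``q x m`` coding
    matrices above.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    T_alpha: np.ndarray
    T_delta: np.ndarray
    individual_ids: np.ndarray
    fixed_names: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def c(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def m(self) -> int:
        return self.T_alpha.shape[1]


def build_design(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    trait: str,
    fixed_effects: Sequence[str] = (),
    id_col: str = "id",
) -> DesignSet:
    """Assemble ``y``, ``X``, ``Z`` and the coding matrices for a trait.

    ``fixed_effects`` names columns of the phenotype table: string or
    categorical columns are one-hot encoded (the first factor keeps all
    levels and plays the role of the intercept; further factors drop
    their first level), numeric columns enter as covariates.  With no
    fixed effects an intercept column is used.  Every phenotyped
    individual must have genotypes; unknown IDs raise
    :class:`LinkageError` listing them.
    """
    for col in (id_col, trait, *fixed_effects):
        if col not in phenotypes.columns:
            raise InputError(f"phenotype table has no column {col!r}")
    pheno = phenotypes.dropna(subset=[trait])
    if len(pheno) == 0:
        raise InputError(f"no non-missing observations for trait {trait!r}")

    geno_index = {gid: i for i, gid in enumerate(genotypes.individual_ids)}
    missing = [str(v) for v in pheno[id_col] if v not in geno_index]
    if missing:
        raise LinkageError(
            f"{len(missing)} phenotyped individual(s) without genotypes: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )

    n = len(pheno)
    q = genotypes.q
    y = pheno[trait].to_numpy(dtype=float)
    Z = np.zeros((n, q))
    rows = [geno_index[v] for v in pheno[id_col]]
    Z[np.arange(n), rows] = 1.0

    blocks: list[np.ndarray] = []
    names: list[str] = []
    saw_factor = False
    for col in fixed_effects:
        s = pheno[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=saw_factor)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
            saw_factor = True
        else:
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
    if not saw_factor:
        blocks.insert(0, np.ones((n, 1)))
        names.insert(0, "intercept")
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "fixed-effect matrix is rank deficient (rank %d < %d columns); "
            "a generalized inverse will be used downstream",
            rank,
            X.shape[1],
        )

    T_alpha, T_delta = genotypes.codings()
    return DesignSet(
        y=y,
        X=X,
        Z=Z,
        T_alpha=T_alpha,
        T_delta=T_delta,
        individual_ids=genotypes.individual_ids,
        fixed_names=names,
    )
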