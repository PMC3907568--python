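import numpy as np
import pytest

import gdblup as g


def random_mixed_instance(
    seed,
    q=10,
    m=20,
    duplicate=False,
    definition="II",
    vc=None,
    rank_deficient_X=False,
    two_obs=False,
):
    """A small, fully assembled GBLUP problem for equivalence tests.

    Optionally duplicates a genotype row (singular relationship matrices)
    or duplicates a fixed-effect column (rank-deficient X).
    """
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 3, size=(q, m))
    if duplicate and q >= 2:
        counts[1] = counts[0]
    # reroll monomorphic columns so the instance keeps all m SNPs
    for k in range(m):
        while len(np.unique(counts[:, k])) == 1:
            counts[:, k] = rng.integers(0, 3, size=q)
    gm = g.GenotypeMatrix.from_counts(counts)
    Ta, Td = gm.codings()
    pair = g.build_grm(Ta, Td, freqs=gm.freqs, definition=definition)
    if two_obs:
        n = q + 2
        Z = np.zeros((n, q))
        Z[np.arange(q), np.arange(q)] = 1.0
        Z[q, 0] = Z[q + 1, 1] = 1.0  # repeated records for two individuals
    else:
        n = q
        Z = np.eye(q)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    if rank_deficient_X:
        X = np.column_stack([X, X[:, 0]])
    y = rng.standard_normal(n)
    if vc is None:
        vc = g.VarianceComponents(*rng.uniform(0.2, 1.0, size=3))
    return dict(y=y, X=X, Z=Z, gm=gm, Ta=Ta, Td=Td, pair=pair, vc=vc)


@pytest.fixture(scope="session")
def sib_design():
    """Gene-dropped families reused by relationship tests: 30 sires x 2
    dams x 2 offspring (full- and half-sib pairs) plus 40 unrelated."""
    cfg = g.SimConfig(
        n_individuals=None, n_sires=30, dams_per_sire=2, offspring_per_dam=2,
        n_unrelated=40, m_qtl=4000, h2_a=0.3, seed=17,
    )
    rng = np.random.default_rng(17)
    gm, ped = g.simulate_genotypes(cfg, rng)
    return gm, ped
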