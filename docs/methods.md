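# Methods

## Model

A genotypic value at a biallelic locus is partitioned, under
Hardy–Weinberg equilibrium, into a breeding value and a dominance
deviation (Falconer's decomposition).  With `p` the frequency of the
counted allele, `q = 1 − p` and `x ∈ {0,1,2}` the allele count, the
per-genotype contrasts are `x − 2p` (additive; the coefficient of the
gene-substitution effect α) and `−2q², 2pq, −2p²` for `x = 2, 1, 0`
(dominance; the coefficient of the dominance effect δ).  Both contrasts
have zero mean over HWE genotype frequencies, so additive coding columns
are exactly mean-zero at in-sample allele frequencies and dominance
columns are mean-zero in expectation.  At `p = 0.5` the additive coding
reduces to the familiar (−1, 0, 1).

Phenotypes follow `y = Xb + Za + Zd + e` with `a = T_α α`, `d = T_δ δ`,
`Var(a) = G σ²_a`, `Var(d) = D σ²_d`, `Var(e) = I σ²_e`.  The covariance
between breeding values and dominance deviations is assumed null, which
is exact under HWE and random mating; the `rel_g` reliability
denominator `g_ii σ²_a + d_ii σ²_d` relies on this assumption (its
numerator keeps the cross-covariance of the two *predictors*, which does
not vanish).

## Relationship matrices

`G` and `D` are the Gram matrices of the codings divided by, per
definition: (I) their expected diagonal under HWE — `Σ_k 2p_k q_k`
additive, `Σ_k (2p_k q_k)²` dominance; (II) their observed mean
diagonal; (III) per-individual square roots of the raw diagonal (a
correlation transform).  Definition I's dominance normalizer is not
taken on faith: a Monte-Carlo test verifies that both raw diagonals have
expectation equal to the stated normalizers under HWE sampling.  All
three definitions factor as `K^{-1/2} T (K^{-1/2} T)'` for diagonal `K`,
and the scaled codings `T* = K^{-1/2} T` are what the SNP-effect (QM)
formulation uses, so `σ²_α = σ²_a` and `σ²_δ = σ²_d` with no unit
conversion.  A `raw` (unnormalized) option exists to demonstrate the
pathology normalization prevents: raw diagonals grow with the number of
markers and the implied variance components shrink correspondingly (a
characterization test shows the ~8-fold drop from m=50 to m=400 on
otherwise identical data).

In-sample centering of `T_α` puts the all-ones vector in the null space
of `G`; relationship matrices are therefore *always* singular at
in-sample frequencies.  Nothing downstream inverts `G` or `D`, so this
is harmless, but it is why per-individual reliabilities plateau below 1
in very small samples (the intercept direction carries no genomic
information).

## GBLUP, two routes

CE: with `V = ZGZ'σ²_a + ZDZ'σ²_d + Iσ²_e` (positive definite whenever
`σ²_e > 0`), `b̂` is the GLS estimate with an eigenvalue-thresholded
generalized inverse of `X'V⁻¹X` (relative tolerance 1e−10), and
`â = σ²_a G Z' Py`, `d̂ = σ²_d D Z' Py`, `ĝ = â + d̂`, where
`P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻X'V⁻¹` (computed on an orthonormal basis of
col(X), making it invariant to rank-deficient fixed-effect
parameterizations).  Reliabilities are `Var(â)_ii / (g_ii σ²_a)` with
`Var(â) = σ⁴_a G Z'PZ G`, and analogously for `d̂` and `ĝ` (with the
predictor cross term).  Validation individuals use the
validation-to-training blocks of relationship matrices built on the
union of both sets with one shared allele-frequency vector.

QM: after absorbing the fixed effects with `S = I − X(X'X)⁻X'`, the
system `[W'SW + Λ]û = W'Sy` (`W = Z[T_α*, T_δ*]`,
`Λ = diag(λ_α I, λ_δ I)`, `λ = σ²_e/σ²`) is solved by Cholesky; a zero
variance component drops its block (infinite ridge).  Back-transforms
`â = T_α* α̂` etc. and the inverse-coefficient blocks `C^{··}` give
predictions and prediction-error variances identical to CE — the test
suite certifies the identity to 1e−8 relative error over shapes
spanning q<m, q=m, q>m, singular matrices and repeated records.

Route selection: CE when `q < 2m`, else QM (the CE system has order n≈q,
the QM system order 2m).

## REML

EM updates (order a, d, e), with `V_a = ZGZ'`, `V_d = ZDZ'`:

    σ²_a ← σ²_a + (σ⁴_a/q)(y'P V_a P y − tr(P V_a))
    σ²_d ← σ²_d + (σ⁴_d/q)(y'P V_d P y − tr(P V_d))
    σ²_e ← σ²_e + (σ⁴_e/(n − rank X))(y'P P y − tr P)

These are the individual-level model's EM iteration; the restricted
likelihood is non-decreasing along it and its fixed points are the REML
score equations.  The same iteration re-expressed through the absorbed
SNP-effect system is
`σ²_α ← σ²_α + (α̂'α̂ − mσ²_α + σ²_e tr C^αα)/q` and
`σ²_e ← [ê'ê + σ²_e(2m − λ_α tr C^αα − λ_δ tr C^δδ)]/(n − rank X)`;
the residual denominator was fixed by requiring the two algebras to be
the *same* iteration (not merely fixed-point-equivalent), which the test
suite checks to machine precision.  The rank of the full SNP-effect
coefficient matrix, `rank X + 2m`, enters through the trace identity
`tr(C(C⁻¹ − Λ)) = 2m − λ_α tr C^αα − λ_δ tr C^δδ`.

AI-REML uses `AI_ij = y'P V_i P V_j P y / 2` and scores
`(y'P V_i P y − tr(P V_i))/2`.  Safeguards, in order: a genetic
component proposed non-positive is floored at `1e−6·var(y)` inside the
proposal; any proposal that lowers the restricted likelihood is
discarded in favour of an EM step; a component that sits at the floor
while AI pushes it negative three consecutive iterations is a boundary
estimate and is clamped to exactly 0 thereafter (logged).  The clamp is
needed because EM approaches a zero boundary only as O(1/iteration);
the floor variant (rather than clamping on the first negative proposal)
self-corrects when the optimum is interior, because the next AI step
climbs back from the floor.  The residual variance is never clamped.
Convergence: maximum relative component change below `tol` (default
1e−8), budget `max_iter` (default 1000); hybrid runs typically converge
in 6–15 iterations.  A converged hybrid solution was cross-checked
against direct Nelder–Mead maximization of the restricted likelihood
(agreement to ~7 digits), a check kept as a test.

Heritabilities are `h²_a = σ²_a/σ²_p`, `h²_d = σ²_d/σ²_p`,
`H² = h²_a + h²_d`, `σ²_p = σ²_a + σ²_d + σ²_e`.  Standard errors come
from the inverse AI matrix at convergence; heritability SEs use the
delta method.  Default initial values are `var(y)/3` for each component.

## Simulator

Founder genotypes are independent across SNPs, HWE within SNP, allele
frequencies Uniform(0.05, 0.95).  Families arise by Mendelian gene
dropping (each parent transmits one allele per locus with probability
count/2), which produces the textbook expectations checked in tests:
full-sib genomic correlation ≈ 0.5 additive / 0.25 dominance, half-sib
≈ 0.25 / 0, unrelated ≈ 0 / 0.  Per-locus effects are standard normal;
*directional* dominance takes |N(0,1)|, making every heterozygote's
dominance deviation positive (heterosis).  The genetic parts and the
residual are each rescaled so the realized in-sample variance shares
equal the target heritabilities exactly (phenotypic variance 1);
replicate-to-replicate variation in estimates is then attributable to
the estimator, not to sampling of the simulated heritability.  Default
family design for relationship studies: 50 sires × 2 dams × 2
offspring plus 100 unrelated individuals.

Fidelity gaps: no linkage disequilibrium between markers (founder SNPs
are independent; only the pedigree induces correlation), no selection,
no inbreeding, no genotyping error or missingness.  Consequently,
passing tests demonstrate the estimators' behaviour under the model's
own assumptions; quantities that depend on LD between typed markers and
untyped causal variants (e.g. the overestimation of null dominance
heritability by large linked-marker panels) are outside what this
generator can reproduce.

## Problem sizes and study settings

Replicated studies in the test suite and acceptance script use: 100
full-sib families at 5000 SNPs for relationship expectations; 10
replicates of q=1654 with 503 causal SNPs for the null-heritability
calibrations; and a 4×4 heritability grid (levels 0, 0.05, 0.15, 0.30)
with 10 replicates at q=500, m=1000 causal SNPs for recovery and
prediction-accuracy studies, REML run with `max_iter=150, tol=1e−6`.
Grid GBLUP and reliabilities are evaluated at the true simulated
components, which isolates prediction calibration from REML sampling
noise; GREML estimates are reported from the same replicates.

At q=500 the grid is a deliberately small design: single-replicate SDs
of heritability estimates are ≈0.05–0.09, so 10-replicate cell means
still move by a few hundredths, and cells adjacent in heritability can
overlap at the replicate level.  The same estimator at q=1500 recovers
the (0.30, 0) cell to within 0.002 of truth.  The recovery-grid test
records this sensitivity honestly rather than enlarging the design.

## Known limitations

* One observation per individual is the optimized path; repeated records
  run through `Z` but are only lightly exercised.
* Dense algebra throughout: practical up to a few thousand individuals
  (CE) or a few thousand markers (QM) on one CPU.
* No LD-aware simulation, no imputation, no sex chromosomes, no
  multi-trait or single-step extensions.
* Heritability SEs by the delta method are an extension beyond the core
  formulation and are only as good as the asymptotic AI covariance.
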