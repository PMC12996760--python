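# Methods

## Energy model

The package works in a canonical closed-shell spatial-orbital basis with
frozen-core orbitals removed at archive creation.  Because the reference
is canonical, the Fock operator enters only through its diagonal, the
orbital energies ε_p; no SCF is performed and E_SCF is carried as an
input scalar.  The first-order doubles are

    t[1]_ij^ab = g_ij^ab / (ε_i + ε_j − ε_a − ε_b),

with singles identically zero.  Denominators with magnitude below
`tol_denom = 1e-8` Hartree raise an error naming the offending index
quadruple: the closed-shell formulas assume a nondegenerate gapped
reference, and silently regularizing a vanishing denominator would
produce meaningless energies.

The correlation energy through third order is decomposed as
E_C + E_X (MP2 direct/exchange; the spin components follow as
E_OS = E_C/2 and E_SS = E_C/2 + E_X) plus ten third-order components in
a fixed documented order: the particle-particle ladder pair (prefactors
+2, −1, integrals ⟨ab|ef⟩), the hole-hole ladder pair (+2, −1, ⟨mn|ij⟩),
and six ring terms (+8, −4, −4, +2, −8, +4, integrals ⟨mb|ej⟩ and
⟨mb|je⟩).  Only opposite-spin integrals appear; all contractions are
dense `numpy.einsum` expressions.  Dense evaluation is a deliberate
choice: the subject here is factorization *accuracy*, and the
reduced-scaling contraction algorithms THC enables in production codes
would only obscure it.  The decomposition is validated diagram class by
diagram class against an independently coded spin-orbital
(antisymmetrized-integral) oracle, which shares neither the spin
adaptation nor any code with the production path.

## LS-THC machinery

Each orbital-pair type (oo, ov, vv) carries its own grid, pruned from a
parent collocation by pivoted Cholesky factorization of the pair metric

    S_PQ = Σ_pq X_p^P X_q^P X_p^Q X_q^Q = (X_lᵀX_l) ∘ (X_rᵀX_r).

Points are accepted in pivot order while the running residual diagonal
is at least 10^−δ times the **largest initial diagonal**; the relative
convention makes δ invariant under a global rescaling of the orbitals.
Ties take the lowest index, for determinism.  The core matrices are the
least-squares solutions in vectorized pair space,

    V = S_bra⁺ (Z_braᵀ B_bra)(Z_ketᵀ B_ket)ᵀ S_ket⁺,

evaluated by projecting each three-index DF factor onto its grid and
contracting over the auxiliary index.  S⁺ is an eigenvalue-cutoff
pseudo-inverse dropping eigenvalues below `1e-10 × λ_max`; pruned-grid
metrics are routinely rank-deficient and a hard inverse would be
numerically meaningless.  The amplitude core T1 applies the same normal
equations to the denominator-weighted THC integrals (dense, not
matrix-free — identical result at desk scale).  Four core matrices are
fitted (ov×ov, vv×vv, oo×oo and the oo×vv cross block needed by the
exchange ring term).

Variants: **MP2a** approximates only the integrals (amplitudes by exact
division of the THC integrals — the reading adopted for the "only g"
variant); **MP2b/MP3b** approximate both integrals and amplitudes via
T1.  The MP3d variant (an LS-THC fit of the *second-order*
wavefunction) is out of scope; the feature layer accepts its ten
components as optional external columns, giving a 34-feature mode on
top of the 24-feature default.

Exact-limit property: whenever the pruned grid's pair-space rank equals
the pair dimension (for symmetric oo/vv blocks, the symmetric pair
dimension n(n+1)/2 suffices, since every tensor touched is symmetric
there), all variants reproduce the density-fitted reference to well
below 1e-8 Hartree, and every downstream error label vanishes.  This is
enforced in the test suite and the acceptance script.

## Features, labels, units

Per species the default feature vector has 24 named entries: E_HF, the
MP2a and MP2b direct/exchange components, the ten MP3b components, the
HOMO–LUMO gap and the total active-orbital eigenvalue span, the three
fit measures transformed as f̃ = log(1 − f) (argument clamped at 1e-16,
since f = 1 occurs in the exact limit), and Frobenius/max norms of
g_ij^ab and t[1].  Size-extensive quantities (energies, Frobenius norms)
are divided by the number of active valence electrons; max-element
norms, gap/span and f̃ are intensive already.  Energy features are
reported in kcal/mol per valence electron — the same unit as the
molecule labels — so the component-scaling coefficients are
dimensionless numbers near one; gap/span and norms stay in atomic units
(the unit-normal scaler makes mixed units immaterial for the scaled
models).  Norm features are computed from the density-fitted (pre-THC)
quantities.

Label sets: `molecule` (canonical MP3 total per valence electron,
kcal/mol·e⁻¹), `delta_molecule` (THC error E_MP3 − E_MP3b, same unit),
`reaction` and `delta_reaction` (stoichiometric combinations of
unnormalized kcal/mol species energies).  The sum-|ν| normalization of
reaction energies is a training-time option for models trained directly
on reaction labels; in the standard protocol reaction sets are
*evaluated* from molecule-trained models (per-species predictions are
rescaled by the valence-electron count and combined with the
stoichiometric numbers), so it is off by default.

## Regression protocol

`scs` fits the ten unscaled MP3b components with zero intercept against
the part of the label the fixed MP3b baseline misses; the fitted
coefficients are the delta-basis scalings c′ = c − 1.  This makes the
absolute (molecule) and error (delta-molecule) formulations of the
linear models exactly equivalent — the identity E(c) − E(1) = Σ c′_n E_n
at the model level — which the test suite asserts.  `mlr` standardizes
features and labels on the training split and solves by exact least
squares (minimum-norm with a warning if the design is numerically
rank-deficient).  `krr` solves (K + αI)w = y in scaled space with a
Cholesky factorization and a least-squares fallback.

Hyperparameters (α, γ) are chosen by an exhaustive decade-spaced grid
search (defaults α ∈ 1e-9…1e3, γ ∈ 1e-7…1e1) followed by Nelder–Mead in
(log₁₀α, log₁₀γ) with standard coefficients (1, 2, 0.5, 0.5), a
200-iteration cap and 1e-4 relative tolerance; refinement that fails to
improve falls back to the grid optimum.  The same 10-fold split serves
hyperparameter search and final evaluation; this mirrors common
practice but means the reported CV error of the tuned kernel model
carries a mild optimistic bias.  Scalers are fitted inside each
training split only; the suite includes leakage tests.  Folds are a
seeded shuffle followed by round-robin assignment.  MAPE excludes rows
with |y| ≤ 1e-12 (logged), and reported improvement percentages round
half away from zero to integer percent; the summary table's %IMP column
always equals the rounded improvement recomputed from its own printed
error columns.

For reaction evaluation, each species receives its out-of-fold
prediction (from the model that held it out); reactions get their own
fold split for summary statistics.  This choice — not fully determined
by the molecule-level protocol — is leakage-free at the species level.

## Synthetic generator

The generator emulates the statistical shape of closed-shell correlated
inputs, not any real chemistry.  Design, with rationale:

- **Shared basis universe.**  All species in a corpus inherit sub-blocks
  of corpus-level master structures (orbital grid profiles, DF weight
  pattern, off-grid residual tail) with a small private jitter
  (default 0.003).  Real molecules share atomic basis functions and
  quadrature grids, which is why THC errors are *systematic* across a
  database; fully independent random tensors per species make the error
  unpredictable noise and no correction model can work.
- **Grid-importance decay.**  Grid-point importance decays geometrically
  (rate drawn per species from [0.85, 0.95]), so the pivoted-Cholesky
  diagonals fall smoothly and the tolerance 10^−δ prunes differently at
  δ = 1 and δ = 2.  DF weights scale with the square of the orbital
  amplitude at each point, so pruned pair directions carry little
  integral weight — the regime in which LS-THC is a useful
  approximation (typical fit qualities ~0.92 at δ = 1, ~0.99 at δ = 2).
- **Perturbative calibration.**  The interaction strength is normalized
  so the largest amplitude is ≈0.12 (lognormal spread 0.15).  Gapped
  closed-shell references are perturbative by selection; uncalibrated
  random tensors produce non-perturbative outliers whose heavy-tailed
  errors dominate every statistic.
- **Diversity.**  Species differ in size class ((3,8), (4,10), (5,12)
  occupied×virtual), orbital spectrum (occupied in [−1.5, −0.3] Eh, gap
  ≥ 0.15 Eh, virtuals ≤ 2.0 Eh), occupied/virtual block strengths
  (lognormal 0.15; these vary diagram-class ratios without touching fit
  quality), and overall strength.  The mean-field energy is roughly
  extensive in the electron count.  The auxiliary dimension is fixed at
  40 so the shared DF weight pattern stays commensurate across species.
- **PSD by construction.**  DF factors are built as symmetric
  three-index arrays (Gram structure over the auxiliary index), and all
  block scalings are congruences, so the pair-space integral matrix is
  positive semidefinite for every draw.

One global seed fans out to per-species streams via
`SeedSequence(seed, index)`, so corpora extend without reshuffling.

What the generator does **not** emulate: real basis sets, molecular
geometries or quadrature grids, chemical composition, the empirical
distribution of correlation energies, or database-scale sample sizes.
Consequently, passing tests demonstrate the *mechanics* (factorization,
decomposition, fitting, evaluation protocol) and the qualitative
error-correction behaviour — not quantitative transferability to real
molecular data.

## Known limitations

- At the desk-scale corpus size (60 species) the 24 features are highly
  collinear — within-pair diagram components correlate at |r| > 0.999
  because their ratios are near-constant structural properties of
  closed-shell amplitudes — and the unregularized linear models (scs,
  mlr) are variance-dominated along weak singular directions.  Their
  cross-validated errors therefore fluctuate between replicates, and
  the strict mean-RMSE ordering scs ≥ mlr ≥ krr, while holding on
  average (mean improvements ≈25%, ≈34%, ≈48% across replicates), is
  not reproduced in every replicate.  The ordering is demonstrated
  robustly on planted linear-plus-Gaussian-bump data, where each model
  family's deficit (no intercept; no nonlinearity) is controlled
  explicitly.  The kernel model's improvement over uncorrected THC is
  positive in every replicate.
- Open-shell references, the MP3d variant, factorized low-scaling
  contractions, and real-molecule data production are out of scope; an
  adapter can populate the archive format from a quantum-chemistry
  backend, but none is bundled.
- Energies are Hartree internally; the single conversion constant
  627.5094740631 kcal/mol per Hartree is applied exactly once, at label
  and feature construction.
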