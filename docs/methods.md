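# Methods

This note records the model implemented by `lrfit`, the conventions and
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the known limitations.  Nothing here states an
empirical result that the test-suite or `scripts/acceptance.py` does not
itself compute.

## Model

The interaction energy of two rigid molecules A and B at center-of-mass
separation R with orientations Ω_A, Ω_B (z-y-z Euler angles relative to
the dimer-fixed frame whose z axis points from A's to B's center of mass)
is represented as

    E = E_asym + E_elec + E_ind,A + E_ind,B + E_disp

    E_elec  =  Σ_{t,u} Q_t^A Q_u^B T_{t,u}
    E_ind,A = −½ Σ α^A_{t;t'} Q_u^B Q_{u'}^B T_{t,u} T_{t',u'}   (A↔B analogously)
    E_disp  = −Σ D_{t,u;t',u'} T_{t,u} T_{t',u'}

with real spherical multipole components t = (l, m, c/s), symmetric
polarizabilities α_{t;t'} = α_{t';t}, and dispersion coefficients D
symmetric under the joint swap (t,u)↔(t',u').  An order-n term varies as
R^−n: n = l_t + l_u + 1 for electrostatics and the sum of the two
T-tensor orders otherwise; everything through order 15 is available.  The
asymptote E_asym (the energy of the separated monomers) is an ordinary
model coefficient, so input energies need not be shifted to zero at
infinity.  All second-order coefficients (α, D) are fitted parameters of
the energy model; no sum-over-states evaluation and no Unsöld-type
approximation is used.

The geometric factor is the spherical interaction tensor.  In the dimer
frame only m_a′ = −m_b′ couplings survive (the irregular harmonic along
+z is ∝ δ_{m0}), giving the constant coupling matrix

    X^{(la,lb)}_{m,−m} = (−1)^la sqrt((2la+2lb+1)!/((2la)!(2lb)!))
                         · 3j(la lb la+lb; m −m 0) / R^(la+lb+1),

which two real Wigner rotation matrices transform into the molecule-fixed
frames: T^{(la,lb)} = M_la(Ω_A)ᵀ X M_lb(Ω_B).  Internally everything is
in Hartree atomic units (4πε₀ = 1); file I/O defaults to angstrom /
degree / cm⁻¹ with the conversion constants 1 hartree = 219474.6313632
cm⁻¹ and 1 bohr = 0.529177210903 Å.

### Conventions

* Real components: 10 ↦ z, 11c ↦ x, 11s ↦ y; for m ≥ 1,
  Q_lmc = ((−1)^m Q_{l,m} + Q_{l,−m})/√2 and
  Q_lms = ((−1)^m Q_{l,m} − Q_{l,−m})/(i√2) with Condon–Shortley complex
  harmonics.  The convention is pinned by tests on point-charge
  multipoles, not assumed.
* Euler angles are z-y-z; the attitude matrix Rz(α)Ry(β)Rz(γ) maps
  molecule-fixed to dimer-fixed coordinates, and the real rotation matrix
  is M_l = Re(C† D*_l C) with C the complex-from-real transform.  The
  l = 1 matrix is verified to equal the Cartesian rotation in (z, x, y)
  ordering, and the whole chain is validated against an exact pairwise
  Coulomb sum over point charges (truncation error decaying as
  R^−(N+1) after an order-N cap).
* Only the azimuth difference α_A − α_B is physical; datasets store a
  single α column.

### Symmetry adaptation

For every molecular point group the surviving rank-l combinations are the
column space of the group-averaged projector P_l = |G|⁻¹ Σ_g M_l(g),
where M_l(g) is obtained for an arbitrary orthogonal 3×3 element g by
solving a small linear system over solid-harmonic values — improper
elements automatically carry their (−1)^l parity.  Rank is decided at a
1e-8 singular-value threshold; the basis is made deterministic by pivoted
Gram–Schmidt over the projected standard basis vectors, so a single
surviving component appears as itself while cubic/icosahedral survivors
appear as explicit combination vectors (e.g. the rank-4 octahedral mix
√(7/12)·40 + √(5/12)·44c) with one free coefficient each.

Groups are built by closing the generator set of the orientation
convention (C_n about z, C_2 about x, σ_xy/σ_xz, i, S_n about z, the
cubic C_3 about x+y+z, the icosahedral C_5 about a vertex direction in
the xy plane) under multiplication with a 1e-9 matrix hash.  One
deliberate deviation: the D_nh generator pair (C_2^x, S_n^z) closes to
the full group only for odd n, so C_n^z and σ_xy are supplied explicitly;
for odd n this changes nothing and for even n it yields the correct full
group.  The continuous axial groups are realized by a finite surrogate
rotation C_N^z with N = 37: since every rank here satisfies l ≤ 15 < N/2,
the surrogate projector is *exactly* the continuous-group projector
(m ≡ 0 mod N forces m = 0); the closed-form rules (C∞v: m = 0; D∞h:
m = 0 and l even) are asserted against it in tests, together with a
sampled-rotation average.  Atoms are handled analytically (rank 0 only;
isotropic polarizability blocks).

Polarizability patterns per (l1, l2) block are the invariants of the
product representation M_{l1} ⊗ M_{l2} (symmetrized when l1 = l2);
dispersion coefficients live on the tensor product of the two molecules'
pattern spaces.  For blocks with l1 < l2 on A *and* k1 < k2 on B the two
inequivalent pairings of the T-tensor slots ("straight" l1–k1/l2–k2 and
"crossed" l1–k2/l2–k1) are enumerated as independent coefficients, so the
full double sums of the second-order energies carry no missing terms.

Rank 0 is always pinned to the declared charge (zero for neutral
molecules) and never fitted.

### Identical and chiral partners

For identical monomers the two coefficient blocks share one parameter
vector (the fit returns bitwise-equal blocks) and the dispersion
coordinates are restricted to the +1 eigenspace of the molecule-swap map.
For chiral partners (mirror-image pairs) molecule B's coefficients are
the numeric image of A's under the xz mirror — s-type components flip
sign, computed from the reflection's representation rather than
hand-derived — and the dispersion constraint composes the swap with the
mirror transform on both pattern spaces.  Constraints are eliminated
exactly from the free-parameter vector (θ_full = Φ θ_free + offset), not
penalized.

## Fitting strategy

1. **Initialization.** A linear least-squares fit on the largest-R 25%
   of the data (configurable fraction) estimates E_asym and the lumped
   coefficient products of the two leading orders; per-molecule values
   are back-assigned (square-root split for two unknown factors, direct
   division when one factor is known, e.g. a declared charge).
2. **Order-by-order staging.** Terms are introduced by increasing
   inverse-power order with separate caps per interaction type; each
   stage warm-starts from the previous optimum, so the training RMSE is
   non-increasing across stages by construction.  Newly activated
   coefficients start at 0.
3. **Optimizer.** Levenberg–Marquardt-type least squares
   (`scipy.optimize.least_squares`, trust-region reflective with
   `x_scale="jac"`), analytic Jacobians throughout (the energy is linear
   in E_asym, α, D and bilinear in the two multipole vectors), function /
   parameter tolerances 1e-12 / 1e-10, at most 2000 evaluations per
   stage.  Residuals are scaled by the dataset's energy spread so the
   tolerances act on relative quantities even when absolute long-range
   energies are ~1e-9 hartree.  Non-convergence is flagged in the stage
   history, not raised.
4. **Gauge.** For two neutral distinct molecules with nothing fixed, the
   data determine only products of coefficients: the model has an exact
   joint sign flip of both multipole sets and, when polarizabilities are
   free, a one-parameter scale gauge (A-multipoles × c, B-multipoles / c,
   α_A × c², α_B / c²).  The canonical reported gauge makes the leading
   nonzero multipole coordinate of molecule A nonnegative; recovery
   comparisons against a known truth first map the estimate along the
   gauge orbit (`gauge_align`).  A declared charge, a fixed coefficient,
   or an identical/chiral relation removes the scale freedom.

### Identifiability

Two exact degeneracies of the energy model are worth knowing:

* An induction contribution −½ α^B (Q^A)² T T has the A-side tensor
  q_A q_Aᵀ, which is always an invariant matrix and hence lies inside the
  span of the dispersion pattern space at the same orders.  Induction and
  dispersion coefficients are therefore separately determined only where
  their orders differ — in practice through the *charge-driven* induction
  terms of an ion (orders 4–5, below the dispersion onset at 6), or by
  fixing a known coefficient; this is the "cascade" that a single known
  coefficient triggers through the whole set.  Dipole-block
  polarizabilities are exactly the quantities this mechanism pins.
* For an atom partner, several dispersion pattern products can share one
  isotropic radial function at a given order (the classic lumping of a
  single C₈ out of distinct polarizability-block products).

The synthetic recovery campaign (below) is designed inside the
identifiable regime: charged systems carry full induction (cap 4, the
dipole blocks) plus dispersion, neutral systems electrostatics plus
dispersion.  Outside it, fits remain well-posed — the optimizer settles
on one representative of the degenerate set and every observable product
is reproduced — but individual α/D values should not be over-interpreted,
exactly as with real ab initio data.

## Diagnostics

* **Statistics.** Per stage: RMSE and R² about the data mean (R² omitted
  for zero-variance data).
* **Outlier detection.** Weighted residual w_i = |res_i| / max(|E_i −
  E_asym|, ε) with ε = 1e-3 of the interaction-energy scale, flagging
  w_i > 4 × 1.4826·MAD(w) — a relative-error weighting that grows more
  sensitive at large R where energies are small.  Residuals are measured
  against a trimmed least-squares reference (points beyond 6 robust sigma
  excluded, final stage refit, up to 3 rounds) so a gross outlier cannot
  hide by bending the fit, and a point is only ever flagged when its
  relative residual exceeds 25% and its absolute residual is above the
  numerical floor — numerically perfect fits flag nothing.
* **Residual histograms.** Plain binned counts; an under-fitted model
  (e.g. leading order only, strong second-order truth) shows the classic
  one-sided, skewed distribution.

## Synthetic data

`lrfit.synthetic` is the package's data source for testing and
benchmarks.  `random_coefficients` draws symmetry-respecting ground truth
through the same constrained parametrization the fitter uses, with
magnitudes decaying as 2^−l per rank (2^−(l1+l2) per polarizability
block) so leading terms dominate realistically, positive diagonal-type
α/D entries, and a small asymptote (~1e-4 hartree).  Datasets sample R
uniformly over 20–60 bohr (≈10–30 Å, a typical long-range fitting
window) and orientations uniformly on the sphere (uniform in cos β),
with optional i.i.d. Gaussian noise.  `symmetric_point_charge_model`
builds charge distributions exactly invariant under a chosen group by
orbit-summing random charges; these feed the Coulomb oracle.

What passing tests on such data do **not** show: real ab initio energies
carry structured, non-Gaussian noise (basis-set incompleteness,
convergence artifacts), exchange/overlap contributions that the pure
multipole series cannot represent at shorter R, and vibrational averaging
effects — none of which are emulated beyond i.i.d. noise plus injected
outliers.  Recovery rates and RMSE bands quoted by the acceptance studies
are statements about the estimator on its own model class.

## Numerical choices

* Wigner 3-j symbols from sympy (exact rationals, cached as floats);
  cross-checked against an exact integer Racah-sum oracle in tests.
* Wigner small-d by the explicit factorial sum (adequate to ~1e-12
  through rank 15); representation matrices of arbitrary orthogonal
  elements by a least-squares solve over unit-sphere solid-harmonic
  values (~1e-12).
* Production T-tensors: cached dimer-frame couplings and per-rank
  rotation matrices, vectorized over geometry batches; required to agree
  with the literal single-geometry contraction (tested at 1e-10, observed
  ~1e-15).
* Degenerate products in the symmetric double sums carry explicit
  multiplicity bookkeeping.  Worked 2-term example: for an α block with
  l1 < l2 the transposed block contributes equally (factor 2), and an
  induction term over two distinct source components (k1,i1) ≠ (k2,i2)
  sums both orderings, G(1,2) + G(2,1) — so a model with
  α = {P on (1,2)} and sources {dipole, quadrupole} evaluates to
  −½·2·a·q₁q₂·[G(1,2) + G(2,1)], reproducing the unrestricted double sum
  term by term.
* Duplicate geometries are kept as independent points (a warning lists
  exact duplicates with differing energies); objective weights are
  uniform — relative-error weighting is reserved for outlier detection.
* Exported evaluators: the machine-readable JSON term file (flattened
  linear/quadratic contractions of T-tensor entries) is the normative
  artifact; the self-contained Fortran source is templated from the same
  tables and compared against the library bit-for-bit in tests (compiled
  with gfortran).  Coefficient files serialize with deterministic term
  ordering, so two writes of the same fit are byte-identical.

## Problem sizes in the reference studies

The acceptance studies use desk-scale sizes chosen to keep every check a
sharp pass/fail at negligible cost: 8 radii in [20, 200] bohr × 4
orientations for the convergence slopes; 100 random geometries × all
label pairs with l_a + l_b ≤ 10 for the T-tensor path agreement; 5 random
systems per orientation-convention row for the invariance defects; 20
mixed-symmetry systems at orders ≤ 6 with n = 8× the free-parameter count
for the recovery campaign, plus one noisy fit at σ = 1e-9 hartree with
n = 40× parameters.

## Limitations

* Rigid monomers in nondegenerate electronic states; no degenerate-state
  potential matrices, no hyperpolarizabilities, no three-body terms, no
  damping functions, no site-distributed multipoles.
* Tensors to rank 15; interaction orders to R⁻¹⁵.
* Cartesian-representation energies are not evaluated (only the
  coefficient-counting identities); the spherical form is the
  implementation.
* Uncertainty reporting is limited to least-squares statistics; no
  multi-start global optimization (warm-started staging has proven
  sufficient on the model class, but pathological data can still find
  local minima).
* The input-file dialect (whitespace columns, `#` comments, optional
  header) and the chiral-partner sign convention (xz mirror) are this
  package's own documented choices.
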