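# Methods

`rcdmlp` implements a range-corrected Δ-machine-learning potential (ΔMLP)
workflow at desk scale: the correction models and their graph topology, the
committee training and data-selection machinery, a synthetic base/target
potential pair with Langevin umbrella sampling, and the free-energy
estimation stack (MBAR, wTP, gwTP, reweighting-entropy diagnostics).  This
note records the models, the parameter choices, and the places where the
design was genuinely open.

## The range-corrected ΔMLP

A ΔMLP corrects a cheap *base* potential toward an expensive *target*:
it is trained on `ΔE = E_target − E_base` and `ΔF = F_target − F_base`, and
at simulation time the system runs on `E_base + E_Δ`.  The correction is
restricted to the chemistry the two levels actually disagree on — the
internal QM region and short-range QM/MM interactions — which is enforced
structurally:

- **Graph restriction.** An edge `(i, j)` exists iff `|r_i − r_j| ≤ r_cut`
  and at least one of the pair is a QM atom.  MM–MM edges are excluded, so
  an MM atom whose only neighbors are MM atoms appears in no edge and is
  invisible to the model.
- **Species remapping.** MM atoms are assigned species code `Z + 50`, so an
  MM element's parameters can differ from the same element in the QM region.
- **Smooth radial features.** Distances are embedded in Bessel functions
  `sqrt(2/r_c)·sin(nπr/r_c)/r` under the polynomial envelope
  `f(u) = 1 − ((p+1)(p+2)/2)u^p + p(p+2)u^{p+1} − (p(p+1)/2)u^{p+2}`,
  `u = r/r_c`, clamped to zero for `u ≥ 1`.  With `p = 5` the envelope and
  its first two derivatives vanish at the cutoff, so energies and forces are
  continuous as MM atoms cross `r_cut` (default 6 Å, 8 Bessel functions).
- **Zero MM bias.** Per-species energy biases are pinned to zero for every
  MM code, so the energy is continuous as an MM atom leaves the last QM
  cutoff sphere.
- **Isolated-state readout subtraction.** Site readouts are measured
  relative to the readout of the atom's isolated (message-free) feature
  state.  An atom with no edges therefore contributes *exactly* its species
  bias — zero for MM atoms — rather than a residual network constant.  This
  is how the package realizes the isolated-atom contract while keeping
  residual connections in the message-passing stack.

Two architectures share this contract behind one interface:

**Many-body model (`mace_like`).**  An ACE-style equivariant
message-passing network.  Per layer: a two-body atomic basis
`A_i^{l₃} = Σ_j Σ_{(l₁,l₂)} R^{path}(r_ij) · C^{l₁l₂→l₃} · Y^{l₁}(r̂_ij) ⊗ h_j^{l₂}`
(radial MLP on the Bessel features, real spherical harmonics to `l_max`,
real Clebsch–Gordan coupling tensors); a product basis of symmetrized
tensor powers of `A` up to correlation order `ν` (body order `ν + 1`),
retaining outputs of angular order `≤ L`; and a linear node update with a
residual connection.  Intermediate layers are read out linearly, the final
layer through a small perceptron gated by the sigmoid linear unit.
Real-basis CG tensors are generated from the complex coefficients via the
standard real/complex transformation; parity-odd couplings take the
imaginary part, which is the SO(3)-equivariant real form (the `1×1→1`
coupling is the cross product).  Harmonics follow the standard real
convention (no Condon–Shortley phase in the real components), and all
rotation behavior is asserted in tests rather than assumed.  Reference
hyperparameters are `L=1, T=2, ν=3, N=128` channels and harmonics to order
3; the test suite runs reduced widths (`N=8–16`, `l_max ≤ 2`) for CPU
runtime, with the full surface still configurable.

**Two-body baseline (`dp_like`).**  A DeepPot-SE-style descriptor model: a
smooth neighbor weight `s(r) = f_env(r/r_c)/r` feeds an embedding MLP
conditioned on a one-hot neighbor species (functionally a species-specific
embedding network, practical for the small toy species sets); the
descriptor contracts the embedded coordinate matrix
`[s, s·x̂, s·ŷ, s·ẑ]` with its first `axis_filters` (default 12)
projections; a fitting network maps the flattened descriptor to a site
energy.  Reference widths are 25/50/100 (embedding) and 240³ (fitting);
desk defaults are 8/16/32 and 24³.

**Forces.**  Both models are differentiated by a small reverse-mode tape
(`autodiff.py`) whose backward rules are themselves traced, so the force
loss (which needs `∂²E/∂x∂θ`) is exact.  Forces agree with central finite
differences to better than 1e−5 eV/Å (asserted), and the normalization
constants inside both models are fixed numbers, never functions of the
graph, so distant atoms cannot leak into the energy through a
normalization denominator.

**Units.**  eV and Å throughout the model and simulation layers; masses in
amu (internal time unit `sqrt(amu·Å²/eV)` ≈ 10.18 fs); kcal/mol appears
only at reporting, with 1 eV = 23.060548 kcal/mol.

## Training

The loss per sample is
`L = p_e(t)·(ΔE_pred − ΔE_ref)² + p_f·(1/3N)·Σ‖ΔF_pred − ΔF_ref‖²`,
with the energy weight rising exponentially from 1 to 100 eV⁻² over the
optimization (`p_e(t) = 100^t` in normalized step) while the force weight
stays at 100 Å²·eV⁻².  The optimizer is Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8) under an exponential learning-rate decay from 1e−3 to 1e−5; the
reference schedule length is 400,000 steps, desk runs use 300–800 steps
with the same endpoint ratios.  Training is repeated with 4 seeds to form a
committee; partition and minibatch randomness comes from a dedicated
generator derived from (but independent of) the model-init seeds, so
partitions are reproducible.

**Committee filter.**  For a test sample, each member's force RMSE over the
3N force components is computed; the sample is discarded iff the *maximum*
across members is strictly below 0.08 eV/Å (a sample exactly at the
threshold is kept).

**Simplify workflow.**  Round 1 trains a fresh committee on a random 50% of
the database; the committee filters the remainder; each later round
restarts the optimization from the previous parameters on surviving test
samples capped at 25% of the original database size.  Because
0.5 + 0.25 + 0.25 ≥ 1, the loop cannot exceed 3 optimization rounds; it
stops earlier when the filtered test set empties.

**End-state augmentation.**  Selected end-state configurations are copied
with every QM heavy atom displaced in a uniformly random direction by a
magnitude uniform in [0, 0.15] Å, and every QM hydrogen moved along its
covalent bond (to the nearest QM heavy atom) so the bond length becomes
uniform in [0.7, 1.2] Å.  The sentence this rule encodes is ambiguous in
its source description; *setting* the bond length to a value in that range
was chosen over *adding* that amount, because adding 0.7–1.2 Å to a ~1 Å
X–H bond would be unphysically large.  MM atoms are never touched.

**Fine-tuning** is a single optimization restart from the end-state
parameters on the union of end-state and added-window data (the S:n window
selections via `stride_select`); whether the full simplify loop should
re-run instead is unspecified in the source description, and the single
restart was chosen.

## The toy system

The synthetic surrogate stands in for semiempirical (base) and ab initio
(target) QM/MM engines.  A triatomic O–P–O analog with optional H/O
spectators is the QM solute; `n_mm` soft-sphere particles confined to a
harmonic shell around the P atom are the MM solvent (an internal restraint,
so the potential stays translation invariant; periodic electrostatics are
out of scope).  The base potential has a symmetric double well along
`ξ = |R_A−R_P| − |R_P−R_B|` with basins at ξ = ±1.4 Å and a ~0.35 eV
barrier, a bond-sum restraint, an A–P–B angle term, and short-range QM/MM
pair repulsion under the same polynomial envelope at 6 Å.  The target adds

- a Gaussian intermediate well at ξ ≈ 0 (depth 0.30 eV, width 0.4 Å),
  giving the target profile two barriers and a metastable intermediate
  3–4 kT deep that the base entirely lacks;
- a small reactant/product tilt (`0.03·tanh(ξ/w)`);
- a modified QM/MM pair term inside the cutoff (strength change + a
  Gaussian well at 3 Å), so the correction has genuine QM/MM content that
  vanishes identically beyond 6 Å;
- a stiffer A–P–B angle (+0.2 eV), a genuinely 3-body correction term that
  separates the fitting power of ν = 3 from ν = 1 models.

These parameter values are fixtures chosen once so the intermediate is
several kT deep and the correction forces (~0.1 eV/Å rms) are comparable to
the committee filter threshold; they are plumbing, not literature values.
Gradients of both toy potentials are analytic and verified against finite
differences at 1e−8 eV/Å.

What the toy does *not* emulate: explicit water structure, electrostatics
and polarization, hydrogen-mass repartitioning, or real phosphorane
chemistry.  Passing tests therefore demonstrate the correctness of the
machinery (graph contracts, estimators, workflow arithmetic, reweighting
behavior) and the internal consistency of the method at toy scale — not
chemical accuracy on real systems.

**Sampling.**  Umbrella windows use the BAOAB Langevin splitting at 298 K
with a 5 ps⁻¹ friction and a 0.5 fs step, harmonic biases of
300 kcal mol⁻¹ Å⁻², and a ladder from −2.4 to 2.4 Å in 0.1 Å steps
(49 windows; at k = 300 the window width is σ ≈ 0.02–0.05 Å, so 0.1 Å is
the coarsest spacing with reliable adjacent-window overlap).  All windows
of a ladder integrate as one vectorized batch.  End-state training uses the
ξ = ∓2.0 Å windows.  Desk runs use 300–600 fs of equilibration and
400–750 fs of production with 40–100 saved frames per window; the reference
protocol (200 ps/200 ps, 500 samples; 20 ps/50 ps, 250 samples for
corrected-potential runs) is reachable through the same configuration
surface.  A microcanonical velocity-Verlet integrator exists for
energy-conservation checks (relative drift < 1e−4 over 10⁴ steps at
0.1 fs on base + correction).

## Free-energy analysis

**MBAR.**  Reduced potentials `u_k(x) = β[U_ref(x) + (k_red/2)(ξ(x)−ξ_k)²]`
over all windows (and, for gwTP, all committee members' windows jointly).
The solver runs damped Newton on the convex MBAR objective — the Hessian
`(diag(ΣP) − PPᵀ)/n` is cheap at K ≤ 200 states — followed by a bounded
self-consistent polish to a 1e−10 relative tolerance on `f_k`; the last
sweep's change is the reported residual, with the gradient norm as a
secondary certificate.  Pure self-consistent iteration is too slow for the
pooled 196-state problems gwTP produces.  Asymptotic standard errors use
the standard weight-matrix covariance estimate.  `f_1` is anchored to 0.

**FES.**  `F(b) = −kT ln Σ_{n∈b} w_n` on a 0.1 Å grid aligned with the
window centers, anchored so the occupied minimum is 0.  Empty bins are
reported as missing and never interpolated.

**wTP / gwTP.**  Sample weights under the target are
`w_n ∝ exp(−β U_target(x_n)) / D_n` with `D_n = Σ_k N_k exp(f_k − u_{kn})`;
for gwTP the denominator runs over all (member, window) states of one
pooled MBAR, which requires every member's energy on every pooled sample
(cross energies).  With a single reference, gwTP reduces to wTP
identically.

**Reweighting entropy.**  Per spatial bin,
`RE = −Σ w̃ ln w̃ / ln n` over the *normalized perturbation factors*
`exp(−ΔU_n)` of the bin's n ≥ 2 samples.  Computing RE on the perturbation
factors (rather than on the full MBAR×perturbation weights) is what makes
the self-perturbation limit exact: when `U_target ≡ U_ref`, every bin's
RE is 1 and the wTP surface equals the MBAR reference surface bit-for-bit.
RE near 0 flags bins whose estimate is carried by a few samples; the
conventional trust threshold is 0.6.

**Density-of-states smoothing.**  Within each spatial bin, ΔU values are
histogrammed into 0.2 kT energy bins and every sample in an energy bin
receives the common factor `exp(−ΔŪ_e)` with
`ΔŪ_e = −ln⟨exp(−ΔU)⟩_e` (the exponential mean).  This choice — rather
than the arithmetic mean of ΔU — preserves each energy bin's total weight,
so the perturbation estimate itself is untouched and the reweighting
entropy can only increase (equalizing weights within a group at fixed group
mass raises entropy).  Smoothing operates within spatial bins only; no
smoothing is ever applied across spatial bins.

**Surface averaging** is the per-bin arithmetic mean over surfaces defined
on that bin, re-anchored to minimum 0 (surfaces are compared by shape, not
absolute offset).

## Numerical choices and degenerate inputs

- Window-center and bin-grid matching uses a 1e−9 Å tolerance; stride
  selection anchors at the most negative center.
- Models evaluate all QM-containing candidate pairs with a smooth cutoff
  mask instead of rebuilding edge lists per frame; contributions beyond
  `r_cut` are exactly zero, and batched evaluation across windows shares
  one fixed topology.
- Bins with fewer than 2 samples have undefined RE and are excluded from
  RE statistics; bins with zero weight are flagged empty.
- An atom count of 1 QM atom is valid (no edges; bias-only energy);
  configurations without QM atoms are rejected.
- Checkpoints are single-file archives (parameters + hyperparameters +
  species table + the MM-bias-zero flag), format version 1.

## Known limitations

- The MACE-like product basis enumerates coupling paths with partial
  symmetry deduplication (l₁ ≤ l₂); it spans the feature space but is not
  the minimal symmetric basis, so channel counts are not directly
  comparable to other implementations weight-for-weight.
- Numpy-based evaluation is desk-scale: tens of atoms and tens of
  thousands of MD steps, not production molecular dynamics.
- The pooled gwTP assumes all members share the harmonic bias ladder
  (centers and force constant), which is how the workflow generates them.
- Toy MM particles are apolar soft spheres; nothing electrostatic is
  corrected, matching the nonelectrostatic scope of the correction.
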