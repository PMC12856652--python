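# Methods

## Scope and observable

The package models the recombination of a pair of lipid peroxyl
radicals in a membrane as a radical-pair reaction.  The observable is
the triplet yield Φ_T: the probability that the pair exits through the
spin-independent propagation channel while in a triplet state.  A
magnetic field effect (MFE) is the change ΔΦ_T(B) = Φ_T(B) − Φ_T(0).
Interradical couplings (exchange, dipolar) and more than two radicals
are out of scope; nuclear Zeeman terms are neglected.

## Units

All Hamiltonian and relaxation quantities are angular frequencies in
rad/ns; fields in mT, rates in 1/ns, lags in ns.  Covariances of
hyperfine components are rad²/ns², spectral densities rad²/ns.  File
formats store rate constants in 1/s and convert at the I/O boundary.
The conversion constant μ_B/ħ = 0.0879410 rad ns⁻¹ mT⁻¹ (per unit g)
follows from CODATA values.  The free-electron g used in the
spin-rotational estimate defaults to 2.0013; this is lower than the
accepted ≈2.00232 and is kept deliberately as the working value of the
analysis the package implements — it is a config parameter, not a
correction silently applied.

## Spin system and kinetics

The Hilbert space is the tensor product of two electron spin-1/2
spaces and all nuclear spaces, dim = 4·Π(2I+1), with factor order
(electron 1, electron 2, nuclei of radical 1, nuclei of radical 2)
fixed so operators are bit-reproducible.  The singlet state is
(|↑↓⟩−|↓↑⟩)/√2, which pins all sign conventions.  Hyperfine tensors are
symmetrized on input, (A+Aᵀ)/2, because the covariance bookkeeping
below presumes component-permutation symmetry.

The reaction operator is the Haberkorn form
K ρ = (k_S/2){P_S, ρ} + k_ST ρ.  The underlying kinetic scheme names
the two rate constants (singlet-selective recombination k_S, default
2×10⁸ s⁻¹; spin-independent propagation k_ST) but not an operator
form; the anticommutator is the standard choice for singlet-selective
recombination and is adopted here.

The master equation is dρ/dt = −Lρ with L = i[H,·] + K + ΣR.  Yields
come from the stationary integral x = L⁻¹ρ₀ (exact; no time
truncation): Φ_T = k_ST tr(P_T x), Φ_S,prop = k_ST tr(P_S x),
Φ_recomb = k_S tr(P_S x); the three sum to one identically.  k_ST > 0
guarantees invertibility; k_ST = 0 raises an error directing the user
to time-domain integration.  Vectorization is column-stacking,
vec(AρB) = (Bᵀ⊗A)vec(ρ).

As an independent oracle, `yields_time_domain` propagates ρ(t) through
the eigendecomposition of L over the finite horizon T = 20/k_ST
(relative tail error e⁻²⁰) and integrates the channel fluxes either
mode-by-mode in closed form (default; robust for arbitrarily
oscillatory dynamics) or by composite Simpson quadrature on a sampled
trajectory.  The two routes (LU solve of the stationary system vs
eigendecomposition plus finite-horizon time integral) agree to better
than 10⁻⁶ on randomized 16-dimensional pairs across 0–100 mT and
lifetimes 1 ns–10 μs.

## Covariance analysis

Fluctuation statistics enter through g_αβ(τ) = ⟨Δα(t)Δβ(t−τ)⟩ with the
biased 1/N FFT estimator after per-series mean removal (the estimator
choice is ours; the biased form is stable at long lags and exactly
matches the direct double sum, which the tests verify).  For a
symmetric 3×3 tensor, permutation symmetry of components plus exchange
symmetry of the pair leaves 21 distinct correlation functions (6 pure
autocovariances); without component symmetry, 45.

Curves are fitted, after normalization by the zero-lag value, with the
fixed basis exp(−τ/τ_j), τ_j log-spaced over [0.5 ps, 100 ns], 50
points, by non-negative least squares followed by renormalization to
Σc_j = 1.  The basis is severely ill-conditioned; non-negativity is
our regularization choice (the sum constraint is part of the model,
the sign constraint is not — it is what makes the fit well-posed
without a smoothness penalty).  Effective correlation time:
τ_eff = Σc_jτ_j; zero-frequency spectral density J(0) = cov·τ_eff,
one-sided integral convention without a factor 2; for g-tensor
components the (μ_B B_z/ħ)² field factor is *not* part of J(0) and is
applied at superoperator build time so that one fitted model serves
every field point.  Ensembles of equivalent lipids are reduced by
fitting each lipid separately and averaging the effective times (the
alternative — averaging weights, then reducing — gives the same number
for a common grid but is not used).

On noisy estimated curves, basis exponentials much slower than the
fitted window are unidentifiable and soak up correlated tail noise,
inflating τ_eff; the fit therefore accepts an optional basis cap
(`basis_cap_ns`), which the correlation-time measurement sets to its
lag window (12 τ_target by default).  Maximum fitted lag defaults to
50 ns, half the longest basis time.

## Relaxation channels

All channels obey the same contracts, enforced by tests rather than
sign bookkeeping: trace(Rρ) = 0 for all ρ, R(1) = 0, and coherences
decay under dρ/dt = −Lρ.

**Hyperfine.**  Fluctuation operators Â_ab = I_a S_b.  Default
"zero_frequency" mode (extreme narrowing): R = Σ_αβ J_αβ(0)·[Â_α,[Â_β,·]].
The general BRW form is an interaction-picture expression with
time-shifted operators; at ω = 0 evaluation it reduces to this
stationary Schrödinger-picture double commutator, which is what the
working formulas use.  The optional "eigenbasis" mode evaluates
Lorentzian J(ω) = cov·Σc_jτ_j/(1+(ωτ_j)²) at every transition
frequency of the static Hamiltonian; it reduces exactly to the
zero-frequency form when H = 0 and is weaker at high field, as it
should be.  Only the significant nucleus of each radical relaxes
(one proton dominates the coupling in the system modeled); other
nuclei would enter the static Hamiltonian only.  Cross-radical
fluctuation correlations are set to zero.  A component pair whose
members are in use but that has no covariance model raises an error
naming the pair; uncorrelated components are declared with explicit
zero-prefactor models.

**g-tensor.**  For B = (0,0,B_z) only the z-row components g_zk enter
the Zeeman term, so models are declared over pairs from {zx, zy, zz},
the fluctuation operators are the bare S_k, and the channel carries
the (μ_B B_z/ħ)² factor — hence exact B_z² scaling, which the pipeline
exploits by building the superoperator once at unit field.  Fields
with transverse components are rejected by this builder.

**Spin-rotational.**  k_sr = (Δg_xx²+Δg_yy²+Δg_zz²)/(9 τ_rot) with
Δg_nn the deviations of the g-eigenvalues from the free-electron value
and τ_rot the rotational correlation time of the spin-bearing fragment
(the peroxide-group rotation, the fastest rotation present, making the
estimate an upper bound; isotropic rotational diffusion assumed).  The
superoperator is the depolarizing form contributing
dρ/dt = −k_sr(3/2 ρ − Σ_i Σ_k S_ik ρ S_ik); since Σ_k S_kρS_k acting
on the identity gives 3/4 per electron, the identity is stationary.

## Synthetic dynamics

The generator emulates the statistics the analysis consumes, not the
physics that produces them:

- **Dihedral angle.**  A Metropolis random walk on the 1° grid with
  nearest-neighbour proposals.  Its stationary law is exactly the
  specified circular von-Mises mixture with a hard zero inside the
  excluded window (default 60° wide at 0°; the real unsampled range is
  known only graphically, so the width is a free parameter).  Discrete
  Metropolis rather than Langevin dynamics because it gives exact
  control of the stationary density including the hard wall, and a
  one-parameter handle on the time scale.  Since n attempts per frame
  compress the attempt-level autocorrelation by exactly n, τ·(hops per
  frame) is a constant of the dynamics; four automated ensemble
  pre-runs estimate that constant (pooling measurements rather than
  iterating on single noisy estimates) and set the hop rate for the
  target cos(Ω) correlation time (default 1.0 ns).  Unreachable
  targets raise an error carrying the calibration trace.
- **Orientation.**  An isotropic rotational random walk: per 1 ps
  frame, a rotation about a uniformly random axis by a Gaussian angle
  (default scale 0.8°/frame, giving reorientation several times slower
  than the dihedral rotation).  Long-run orientation distribution is
  uniform; steps ≥ 90°/frame are rejected as unphysical.
- **Tensors.**  A(Ω) = a_iso·1 + R_bond(Ω)·D·R_bond(Ω)ᵀ with D axial
  traceless (defaults a_iso = 0.176 rad/ns ≈ 1 mT ≈ 28 MHz, mostly
  isotropic with small anisotropy 0.03 rad/ns — EPR-plausible values
  for a peroxyl β-proton, not fitted constants); g(Ω) rotates fixed
  eigenvalues (2.0040, 2.0065, 2.0110 — a motionally narrowed peroxyl
  pattern) the same way, so eigenvalues are Ω-independent by
  construction.

All randomness flows from one integer seed through named child
streams; identical parameters and seed give bit-identical output.

What the surrogate does *not* reproduce: membrane structure (tail
distances, area per lipid), correlations between dihedral and
orientation motion, multi-coordinate tensor dependence, and
non-Markovian memory in the real dynamics.  Passing tests therefore
demonstrate that the analysis pipeline is correct and self-consistent
under its own statistical assumptions, not that those assumptions hold
for any particular membrane.

## Reference system and scan

The shipped reference pair: one spin-1/2 proton per radical with
isotropic coupling 0.176 rad/ns; identical average g-tensors
diag(2.0040, 2.0065, 2.0110) on both radicals (so static singlet–
triplet mixing is purely hyperfine); k_S = 2×10⁸ s⁻¹; single-mode
covariance models with hyperfine prefactor 2.5×10⁻⁵ rad²/ns² at
τ ≈ 0.92 ns and g prefactor 1×10⁻⁴ at τ ≈ 1.21 ns on the z-row
autocorrelations (crosses zero); τ_rot = 1.0 ns.  With these numbers
the hyperfine and spin-rotational rates sit near 10⁴–10⁵ s⁻¹
(negligible against ≥ 10 mT g-relaxation) and the g channel reaches
~10⁷ s⁻¹ at 100 mT — the regime where relaxation dominates the
high-field yield.

The default scan covers 60 log-spaced fields 0.01–100 mT (plus the
B = 0 reference), lifetimes 1 ns–10 μs (k_ST = 10⁹…10⁵ s⁻¹), and five
channel sets (static, hf, g, sr, all).  The scan shows: a hyperfine
low-field extremum near 1 mT in the static curve; yield suppression at
high field once relaxation is on; and g-channel dominance of the
ablations at ≥ 10 mT growing as B_z².

## Numerical choices and problem sizes

- Liouville dimension for the reference system is 256×256; dense LU
  and eigendecompositions are exact at this size.  Operator
  construction guards against dimensions above 4096.
- Yield-conservation tolerance 10⁻⁸; oracle agreement 10⁻⁶;
  Hermiticity preservation 10⁻⁹; channel contracts at machine
  precision.
- Nearest-neighbour Ω lookup ties break toward the lower angle; linear
  interpolation is available behind a flag.  Angles falling in the
  excluded window raise an error naming the window.
- Correlation-time recovery is validated on ensembles of 12
  trajectories × 1.36×10⁶ frames (the production geometry); the
  single-trajectory estimator carries ~10% noise at that length, the
  12-lipid ensemble average ~5%.  Unit tests use scaled-down ensembles
  (6 × 3×10⁵ frames) with a correspondingly wider 25% band.
- The acceptance script's randomized-oracle check uses 20 pairs; its
  field-scan features are computed on the full 60-point grid at two
  lifetimes.

## Known limitations

- Zero-frequency (extreme-narrowing) Redfield is the default; the
  eigenbasis mode exists but its non-secular terms can drive small
  transient positivity violations, as is generic for Redfield theory.
- The spin-rotational estimate is an upper bound tied to the fastest
  rotation; anisotropic rotational diffusion is not modeled.
- The Haberkorn operator is assumed, not derived; Jones–Hore and
  measurement-based reaction models are out of scope.
- Yields are computed for a single orientation of the field relative
  to the (implicit) membrane normal; no powder averaging.
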