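# lipidspin

Spin dynamics of lipid peroxyl radical pairs: does an applied magnetic
field change how often they recombine, even though thermal motion in a
membrane relaxes their spins?

`lipidspin` is a Python library for researchers in spin chemistry and
membrane biophysics.  It models the termination step of lipid
peroxidation — the pairwise encounter of two peroxyl radicals — as a
radical-pair (RP) reaction and computes the triplet reaction yield
Φ_T as a function of magnetic field strength, RP lifetime, and spin
relaxation, with the relaxation superoperators built from the
statistics of molecular motion (peroxide-group rotation and fragment
tumbling) rather than from phenomenological rates.

## The model

Two electron spins (one per radical), each coupled to its significant
proton, evolve under

- the spin Hamiltonian `H = Σ_i μ_B B·g_i·S_i/ħ + Σ_i I_i·A_i·S_i`
  (Zeeman with full 3×3 g-matrices; hyperfine tensors in rad/ns),
- Haberkorn reaction kinetics: singlet-selective recombination
  `(k_S/2){P_S, ρ}` plus spin-independent propagation `k_ST ρ`
  (an F-pair, formed by diffusive encounter, starts as the statistical
  mixture: singlet probability 1/4, triplet 3/4),
- Bloch–Redfield–Wangsness (BRW) relaxation from three channels:
  hyperfine-tensor fluctuations (operators `I_a S_b`), g-tensor
  fluctuations (operators `S_k`, scaling exactly as `B_z²`), and a
  spin-rotational channel with rate `k_sr = Δg²/(9 τ_rot)`.

The BRW channels are fed by covariance functions `g_αβ(τ)` of the
fluctuating tensor components, estimated from trajectories, fitted with
50 fixed exponentials (`τ_j` log-spaced 0.5 ps – 100 ns, weights
`c_j ≥ 0`, `Σc_j = 1`), and reduced to effective correlation times
`τ_eff = Σ c_j τ_j` and zero-frequency spectral densities
`J(0) = cov · τ_eff`.  Yields are computed exactly from the
Liouville-space linear solve `Φ_T = k_ST · tr(P_T · L⁻¹ρ_0)`.

A synthetic-dynamics module generates surrogate trajectories with the
statistical structure the analysis assumes — a dihedral angle with a
hard excluded window and ~1 ns cos(Ω) correlation time, slower
isotropic fragment tumbling, and Ω → tensor mapping tables on a 1°
grid — so the complete pipeline runs and is tested without any
external data.

## Worked example

```python
import numpy as np
import lipidspin as ls

nuc = ls.NucleusSpec("H13X", spin=0.5, hyperfine=0.176 * np.eye(3))  # ~1 mT
rad = ls.RadicalSpec.isotropic(2.0023, (nuc,))
spec = ls.SpinSystemSpec(rad, rad, k_s=0.2, k_st=0.01,  # 1/ns
                         field_mT=np.array([0.0, 0.0, 1.0]),
                         initial_state="triplet")
ops = ls.build_spin_operators(spec)
ps, pt = ls.singlet_triplet_projectors(spec)
h = ls.build_hamiltonian(spec, ops)
k = ls.reaction_superoperator(spec, ps)
liouv = ls.assemble_liouvillian(h, k)
y = ls.channel_yields(liouv, ls.initial_density(spec), spec, ps, pt)
print(y.phi_t)
```

prints `0.6183`: a triplet-born pair with a ~1 mT isotropic proton
coupling on each radical loses 38% of its population through the
singlet channels at B_z = 1 mT.  At zero field the same system gives
Φ_T = 0.7029 and at 10 mT Φ_T = 0.8338 — the non-monotonic low-field
effect, followed by high-field saturation as Zeeman splitting locks the
T± states out of the mixing.

The `examples/` directory holds one short script per capability
(closed-form yields, synthetic dynamics, covariance fitting, field
scans with channel ablation); each prints its numbers with a note on
what they mean.  A thin CLI (`lipidspin synth|analyze|fit|scan|report`)
wraps the same functions for shell use.

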