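"""Bloch-Redfield-Wangsness relaxation superoperators.

Three channels are built from fitted covariance models of the
fluctuating interactions:

hyperfine (``relax_hf``)
    Fluctuation operators A_ab = I_a S_b for the significant nucleus of
    each radical; in the default zero-frequency (extreme-narrowing) mode

        R rho = sum_ab J_ab(0) ( [A_a, A_b rho] - [A_a, rho A_b] ),

    with J_ab(0) = cov_ab * sum_j c_j tau_j in rad^2/ns.

g-tensor (``relax_g``)
    For a field along z only the z-row components g_zk fluctuate into
    the Hamiltonian; the fluctuation operators are the electron spin
    components S_k weighted by (mu_B Bz / hbar)^2, so the channel scales
    exactly as Bz^2 at fixed covariance models.

spin-rotational (``relax_sr``)
    Isotropic-tumbling estimate k_sr = (Dg_xx^2 + Dg_yy^2 + Dg_zz^2) /
    (9 tau_rot), an upper bound since the peroxide-group rotation is the
    fastest rotation considered, implemented as the depolarizing form

        drho/dt |_sr = -k_sr (3/2 rho - sum_i sum_k S_ik rho S_ik).

All channels are trace-preserving, leave the identity stationary, and
carry the sign convention that coherences decay under the assembled
master equation drho/dt = -L rho.  Cross-radical fluctuation
correlations are taken as negligible.  An optional ``eigenbasis`` mode
evaluates the spectral densities at the transition frequencies of the
static Hamiltonian (Lorentzian J(w)) instead of at zero frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.linalg

from .constants import CONSTANTS, PhysicalConstants
from .correlation import (
    CovarianceModel,
    canonical_pair,
    spectral_density,
    spectral_density_zero,
)
from .liouville import spre, spost
from .kinetics import Superoperator
from .spin_core import Operator, SpinOperators

__all__ = [
    "RelaxationInputs",
    "hyperfine_redfield",
    "g_redfield",
    "spin_rotational_rate",
    "spin_rotational_superoperator",
]

Mode = Literal["zero_frequency", "eigenbasis"]

PairMap = Mapping[tuple[str, str], CovarianceModel]

_AXES = "xyz"
_Z_ROW_PAIRS = ("zx", "zy", "zz")


@dataclass(frozen=True)
class RelaxationInputs:
    """Everything needed to build the three relaxation channels.

    ``hyperfine_models[i]`` maps canonical component pairs (alpha, beta)
    to covariance models for the significant nucleus of radical i (None
    disables the channel for that radical); ``g_models[i]`` does the
    same for the g-tensor z-row pairs.  ``tau_rot_ns`` is the rotational
    correlation time of the spin-bearing fragment and ``delta_g`` the
    three deviations of the g-eigenvalues from the free-electron value.
    """

    hyperfine_models: tuple[PairMap | None, PairMap | None] = (None, None)
    g_models: tuple[PairMap | None, PairMap | None] = (None, None)
    tau_rot_ns: float = 1.0
    delta_g: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.tau_rot_ns <= 0:
            raise ValueError("rotational correlation time must be > 0")
        dg = np.asarray(self.delta_g, dtype=float).reshape(3)
        object.__setattr__(self, "delta_g", dg)
        for maps in (self.hyperfine_models, self.g_models):
            for m in maps:
                if m is None:
                    continue
                for (a, b), model in m.items():
                    if a == b and model.prefactor < 0:
                        raise ValueError(
                            f"autocorrelation prefactor for pair ({a},{b}) must be >= 0"
                        )


def _expanded_j0(models: PairMap, components: Sequence[str], symmetric: bool):
    """J(0) for every ordered pair over ``components``; errors list absent pairs."""
    canon = {canonical_pair(p, symmetric): m for p, m in models.items()}
    used = sorted({c for p in models for c in (canonical_pair(p, symmetric))})
    missing = []
    j0 = {}
    for a in components:
        for b in components:
            key = canonical_pair((a, b), symmetric)
            if key[0] in used and key[1] in used:
                if key not in canon:
                    missing.append(key)
                else:
                    j0[(a, b)] = spectral_density_zero(canon[key])
            else:
                j0[(a, b)] = 0.0
    if missing:
        raise ValueError(
            "missing covariance model(s) for component pair(s): "
            + ", ".join(f"({a},{b})" for a, b in sorted(set(missing)))
        )
    return j0, canon


def _bwr_term(a_op: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Superoperator for rho -> [A, Theta rho] - [A, rho Theta^dagger]."""
    th_d = theta.conj().T
    return (
        spre(a_op @ theta)
        - spre(theta) @ spost(a_op)
        - spre(a_op) @ spost(th_d)
        + spost(th_d @ a_op)
    )


def _redfield_from_operators(
    ops_by_label: Mapping[str, np.ndarray],
    j0: Mapping[tuple[str, str], float],
    canon: Mapping[tuple[str, str], CovarianceModel],
    symmetric: bool,
    mode: Mode,
    hamiltonian: Operator | None,
) -> np.ndarray:
    dim = next(iter(ops_by_label.values())).shape[0]
    r = np.zeros((dim * dim, dim * dim), dtype=complex)
    if mode == "zero_frequency":
        for (a, b), j in j0.items():
            if j == 0.0:
                continue
            r += j * _bwr_term(ops_by_label[a], ops_by_label[b])
    elif mode == "eigenbasis":
        if hamiltonian is None:
            raise ValueError("eigenbasis mode requires the static Hamiltonian")
        evals, v = scipy.linalg.eigh(hamiltonian.matrix)
        omega = np.subtract.outer(evals, evals)  # w_mn = E_m - E_n, rad/ns
        for a in ops_by_label:
            for b in ops_by_label:
                key = canonical_pair((a, b), symmetric)
                model = canon.get(key)
                if model is None or model.prefactor == 0.0:
                    continue
                taus = model.lag_grid_ns
                # Lorentzian J at every transition frequency of the pair
                jw = model.prefactor * np.einsum(
                    "j,mnj->mn",
                    model.weights * taus,
                    1.0 / (1.0 + (omega[..., None] * taus) ** 2),
                )
                a_tilde = v.conj().T @ ops_by_label[b] @ v
                theta = v @ (jw * a_tilde) @ v.conj().T
                r += _bwr_term(ops_by_label[a], theta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return r


def hyperfine_redfield(
    inputs: RelaxationInputs,
    ops: SpinOperators,
    hamiltonian: Operator | None = None,
    mode: Mode = "zero_frequency",
    nucleus_index: int = 0,
) -> Superoperator:
    """Relaxation from hyperfine-tensor fluctuations of the significant nucleus.

    Fluctuation operators are A_ab = I_a S_b (component ab of I.A.S).
    Component pairs are expanded by tensor symmetry; a pair whose
    components are in use but that has no model raises an error naming
    the absent pair.
    """
    dim = ops.dim
    r = np.zeros((dim * dim, dim * dim), dtype=complex)
    for i, models in enumerate(inputs.hyperfine_models):
        if models is None or not models:
            continue
        if not ops.nuclear[i]:
            raise ValueError(f"radical {i} has hyperfine models but no nuclei")
        nuc = ops.nuclear[i][nucleus_index]
        a_ops = {
            a + b: nuc[a] @ ops.electron[i][b] for a in _AXES for b in _AXES
        }
        j0, canon = _expanded_j0(models, list(a_ops), symmetric=True)
        r += _redfield_from_operators(a_ops, j0, canon, True, mode, hamiltonian)
    return Superoperator(r, "relax_hf")


def g_redfield(
    inputs: RelaxationInputs,
    bz_mT: float,
    ops: SpinOperators,
    hamiltonian: Operator | None = None,
    mode: Mode = "zero_frequency",
    constants: PhysicalConstants = CONSTANTS,
    bx_mT: float = 0.0,
    by_mT: float = 0.0,
) -> Superoperator:
    """Relaxation from g-tensor fluctuations for a field along z.

    Only the z-row components g_zk couple to a Bz field, so the
    covariance models are drawn from pairs over {zx, zy, zz} and the
    fluctuation operators are the bare S_k; the (mu_B Bz / hbar)^2
    factor enters here, making the channel scale exactly as Bz^2.
    """
    if bx_mT != 0.0 or by_mT != 0.0:
        raise ValueError(
            "this builder handles fields along z only; transverse field "
            "components would need the general 9-component builder"
        )
    dim = ops.dim
    r = np.zeros((dim * dim, dim * dim), dtype=complex)
    factor = (constants.gamma_mT * bz_mT) ** 2
    if factor == 0.0:
        return Superoperator(r, "relax_g")
    for i, models in enumerate(inputs.g_models):
        if models is None or not models:
            continue
        bad = [p for pr in models for p in pr if p not in _Z_ROW_PAIRS]
        if bad:
            raise ValueError(
                f"g-channel models must use z-row components {_Z_ROW_PAIRS}, got {bad}"
            )
        # label 'zk' -> operator S_k of this radical
        a_ops = {zk: ops.electron[i][zk[1]] for zk in _Z_ROW_PAIRS}
        # z-row labels are already canonical under tensor symmetry only
        # via exchange; treat components as distinct (symmetric=False).
        j0, canon = _expanded_j0(models, list(a_ops), symmetric=False)
        r += factor * _redfield_from_operators(a_ops, j0, canon, False, mode, hamiltonian)
    return Superoperator(r, "relax_g")


def spin_rotational_rate(delta_g: np.ndarray, tau_rot_ns: float) -> float:
    """k_sr = (Dg_xx^2 + Dg_yy^2 + Dg_zz^2) / (9 tau_rot) in 1/ns.

    Upper-bound estimate assuming isotropic rotational diffusion with
    the (fast) peroxide-group rotation time as tau_rot.
    """
    if tau_rot_ns <= 0:
        raise ValueError("rotational correlation time must be > 0")
    dg = np.asarray(delta_g, dtype=float).reshape(3)
    return float(np.sum(dg**2) / (9.0 * tau_rot_ns))


def spin_rotational_superoperator(k_sr: float, ops: SpinOperators) -> Superoperator:
    """Depolarizing spin-rotational channel.

    Contributes drho/dt = -k_sr (3/2 rho - sum_i sum_k S_ik rho S_ik);
    since sum_k S_k rho S_k applied to the identity gives (3/4) each per
    radical, the identity is stationary and the map is trace-preserving.
    """
    if k_sr < 0:
        raise ValueError("spin-rotational rate must be >= 0")
    dim = ops.dim
    d2 = dim * dim
    sandwich = np.zeros((d2, d2), dtype=complex)
    for i in range(2):
        for k in _AXES:
            s = ops.electron[i][k]
            sandwich += spre(s) @ spost(s)
    r = k_sr * (1.5 * np.eye(d2) - sandwich)
    return Superoperator(r, "relax_sr")
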