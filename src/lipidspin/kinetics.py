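"""Reaction kinetics, Liouvillian assembly and reaction-yield computation.

The master equation is written as drho/dt = -L rho with

    L = i [H, .] + K + sum_channels R,

where K is the Haberkorn reaction superoperator,

    K rho = (k_S/2) {P_S, rho} + k_ST rho,

combining the singlet-selective recombination (anticommutator form) with
the spin-independent propagation decay k_ST, and each relaxation channel
R is built so that coherences decay and the identity is stationary.

Reaction yields follow from the stationary integral
x = integral_0^inf rho(t) dt = L^{-1} rho(0):

    Phi_T       = k_ST tr(P_T x)     (triplet propagation)
    Phi_S,prop  = k_ST tr(P_S x)     (singlet propagation)
    Phi_recomb  = k_S  tr(P_S x)     (singlet recombination)

which sum to one exactly.  Time-domain propagation is retained as an
independent numerical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.integrate import simpson

from .liouville import commutator_super, spre, spost, vec, unvec
from .spin_core import Operator, SpinSystemSpec

__all__ = [
    "Superoperator",
    "YieldBreakdown",
    "reaction_superoperator",
    "assemble_liouvillian",
    "channel_yields",
    "propagate_density",
    "yields_time_domain",
]

Channel = Literal["hamiltonian", "reaction", "relax_hf", "relax_g", "relax_sr"]


@dataclass(frozen=True)
class Superoperator:
    """A linear map on vectorized operators, with a channel tag."""

    matrix: np.ndarray
    channel: Channel

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("superoperator matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("superoperator contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def hilbert_dim(self) -> int:
        return round(np.sqrt(self.matrix.shape[0]))


@dataclass(frozen=True)
class YieldBreakdown:
    """Reaction yields of the three exit channels; they sum to one."""

    phi_t: float
    phi_s_prop: float
    phi_recomb: float

    @property
    def total(self) -> float:
        return self.phi_t + self.phi_s_prop + self.phi_recomb


def reaction_superoperator(spec: SpinSystemSpec, p_s: Operator) -> Superoperator:
    """Haberkorn reaction superoperator K rho = (k_S/2){P_S, rho} + k_ST rho."""
    if spec.k_s < 0 or spec.k_st < 0:
        raise ValueError("rate constants must be non-negative")
    ps = p_s.matrix
    d2 = ps.shape[0] ** 2
    k = 0.5 * spec.k_s * (spre(ps) + spost(ps)) + spec.k_st * np.eye(d2)
    return Superoperator(k, "reaction")


def assemble_liouvillian(
    h: Operator,
    k: Superoperator,
    r_list: Sequence[Superoperator] = (),
) -> Superoperator:
    """Total generator L with drho/dt = -L rho; relaxation channels add."""
    lh = commutator_super(h.matrix)
    total = 1j * lh + k.matrix
    for r in r_list:
        if r.matrix.shape != total.shape:
            raise ValueError(
                f"superoperator dimension mismatch: {r.matrix.shape} vs {total.shape}"
            )
        total = total + r.matrix
    return Superoperator(total, "hamiltonian")


def channel_yields(
    liouvillian: Superoperator,
    rho0: Operator,
    spec: SpinSystemSpec,
    p_s: Operator,
    p_t: Operator,
) -> YieldBreakdown:
    """Exact reaction yields from the Liouville-space linear solve.

    Solves L x = vec(rho0); no time truncation is involved.  Requires
    k_ST > 0 so that L is invertible.
    """
    if spec.k_st <= 0:
        raise ValueError(
            "k_ST = 0 makes the Liouvillian singular; integrate in the "
            "time domain instead (yields_time_domain)"
        )
    try:
        x = scipy.linalg.solve(liouvillian.matrix, vec(rho0.matrix))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(
            "singular Liouvillian; integrate in the time domain instead"
        ) from exc
    rho_int = unvec(x)
    phi_t = spec.k_st * np.trace(p_t.matrix @ rho_int).real
    phi_s = spec.k_st * np.trace(p_s.matrix @ rho_int).real
    phi_r = spec.k_s * np.trace(p_s.matrix @ rho_int).real
    return YieldBreakdown(phi_t=phi_t, phi_s_prop=phi_s, phi_recomb=phi_r)


def _modal_decomposition(liouvillian: Superoperator, rho0: Operator):
    """Eigendecomposition of L and the expansion coefficients of rho0."""
    lam, v = scipy.linalg.eig(liouvillian.matrix)
    c = scipy.linalg.solve(v, vec(rho0.matrix))
    return lam, v, c


def propagate_density(
    liouvillian: Superoperator,
    rho0: Operator,
    times_ns: np.ndarray,
) -> np.ndarray:
    """Density trajectory rho(t) = exp(-L t) rho0 on an explicit time grid.

    Uses the eigendecomposition of L (exponential integration, exact up to
    the eigensolver); returns an array of shape (n_times, d, d).
    """
    times = np.asarray(times_ns, dtype=float)
    lam, v, c = _modal_decomposition(liouvillian, rho0)
    # rho(t) = V (c * exp(-lam t)); evaluate all times at once.
    phases = np.exp(-np.outer(times, lam))  # (nt, d^2)
    xs = phases * c
    flat = xs @ v.T  # (nt, d^2) of vec(rho(t))
    d = rho0.matrix.shape[0]
    out = flat.reshape(len(times), d, d).transpose(0, 2, 1)  # undo column-major
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values during propagation (unstable generator?)")
    return out


def yields_time_domain(
    liouvillian: Superoperator,
    rho0: Operator,
    spec: SpinSystemSpec,
    p_s: Operator,
    p_t: Operator,
    horizon_lifetimes: float = 20.0,
    method: Literal["modal", "simpson"] = "modal",
    n_steps: int = 20000,
) -> YieldBreakdown:
    """Time-domain yield oracle, independent of the algebraic linear solve.

    Propagates rho(t) over a finite horizon T = horizon_lifetimes / k_ST
    (relative tail bound exp(-horizon_lifetimes)) and integrates the
    channel fluxes k tr(P rho(t)).  ``method="modal"`` integrates each
    propagated eigenmode exactly over [0, T]; ``method="simpson"``
    samples the propagated trajectory on a uniform grid of ``n_steps``
    intervals and applies composite Simpson quadrature.
    """
    t_max = horizon_lifetimes / spec.k_st
    lam, v, c = _modal_decomposition(liouvillian, rho0)
    w_t = vec(p_t.matrix.conj().T).conj()  # tr(P rho) = w . vec(rho)
    w_s = vec(p_s.matrix.conj().T).conj()
    # mode amplitudes of the two observables
    amp_t = (w_t @ v) * c
    amp_s = (w_s @ v) * c
    if method == "modal":
        with np.errstate(over="raise"):
            weights = (1.0 - np.exp(-lam * t_max)) / lam
        int_t = np.sum(amp_t * weights).real
        int_s = np.sum(amp_s * weights).real
    elif method == "simpson":
        times = np.linspace(0.0, t_max, n_steps + 1)
        phases = np.exp(-np.outer(times, lam))
        f_t = (phases @ amp_t).real
        f_s = (phases @ amp_s).real
        int_t = simpson(f_t, x=times)
        int_s = simpson(f_s, x=times)
    else:
        raise ValueError(f"unknown method {method!r}")
    return YieldBreakdown(
        phi_t=spec.k_st * int_t,
        phi_s_prop=spec.k_st * int_s,
        phi_recomb=spec.k_s * int_s,
    )
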