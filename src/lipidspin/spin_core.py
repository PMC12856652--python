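"""Spin-system data model and operator algebra for a two-radical pair.

The Hilbert space is the tensor product of the two electron spin-1/2
spaces with the spaces of all coupled nuclei,

    H = H_e1 (x) H_e2 (x) prod_i prod_n H_{I_i,n},

so dim(H) = 4 * prod (2 I + 1).  The factor ordering is fixed as
(electron 1, electron 2, nuclei of radical 1 in list order, nuclei of
radical 2 in list order); all operator matrices are therefore
bit-reproducible across runs.

Sign conventions: the singlet state is |S> = (|ud> - |du>)/sqrt(2) in the
electron Zeeman product basis (u = m_s +1/2 of electron 1 first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import yaml

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "NucleusSpec",
    "RadicalSpec",
    "SpinSystemSpec",
    "Operator",
    "SpinOperators",
    "spin_matrices",
    "hilbert_dimension",
    "build_spin_operators",
    "singlet_triplet_projectors",
    "build_hamiltonian",
    "initial_density",
    "load_spin_system",
    "save_spin_system",
]

InitialState = Literal["triplet", "singlet", "f_pair"]

#: Default guard against accidentally huge operator constructions.
DEFAULT_DIMENSION_CAP = 4096


def _as_tensor(t, name: str, symmetrize: bool = False) -> np.ndarray:
    a = np.array(t, dtype=float).reshape(3, 3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    if symmetrize:
        a = 0.5 * (a + a.T)
    return a


@dataclass(frozen=True)
class NucleusSpec:
    """One magnetic nucleus: label, spin quantum number and hyperfine tensor.

    The hyperfine tensor ``A`` is a 3x3 matrix in rad/ns; it is
    symmetrized on input as (A + A^T)/2, since the correlation-function
    bookkeeping downstream presumes permutation symmetry of components.
    """

    label: str
    spin: float
    hyperfine: np.ndarray

    def __post_init__(self):
        two_i = round(2 * self.spin)
        if abs(2 * self.spin - two_i) > 1e-12 or two_i < 1:
            raise ValueError(f"spin quantum number must be a positive half-integer, got {self.spin}")
        object.__setattr__(self, "hyperfine", _as_tensor(self.hyperfine, "hyperfine tensor", symmetrize=True))

    @property
    def multiplicity(self) -> int:
        return round(2 * self.spin) + 1


@dataclass(frozen=True)
class RadicalSpec:
    """g-tensor (dimensionless 3x3) and the coupled nuclei of one radical."""

    g_tensor: np.ndarray
    nuclei: tuple[NucleusSpec, ...] = ()
    g_sanity_window: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self):
        g = _as_tensor(self.g_tensor, "g tensor")
        object.__setattr__(self, "g_tensor", g)
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        lo, hi = self.g_sanity_window
        eigs = np.linalg.eigvalsh(0.5 * (g + g.T))
        if np.any(eigs < lo) or np.any(eigs > hi):
            raise ValueError(
                f"g-tensor eigenvalues {eigs} outside sanity window [{lo}, {hi}]"
            )

    @classmethod
    def isotropic(cls, g: float, nuclei: Sequence[NucleusSpec] = ()) -> "RadicalSpec":
        return cls(g_tensor=g * np.eye(3), nuclei=tuple(nuclei))


@dataclass(frozen=True)
class SpinSystemSpec:
    """Full static description of the radical pair.

    Parameters
    ----------
    radical_a, radical_b : RadicalSpec
        The two radicals of the pair.
    k_s : float
        Singlet-selective recombination rate constant in 1/ns
        (default 0.2 /ns = 2e8 /s).
    k_st : float
        Spin-independent propagation rate constant in 1/ns; must be > 0.
    field_mT : array-like of 3 floats
        External magnetic field vector in mT.
    initial_state : {"triplet", "singlet", "f_pair"}
        Electronic state in which the pair is generated.  An F-pair
        (diffusive encounter of independent radicals) is the statistical
        mixture: 1/4 singlet, 3/4 triplet.
    """

    radical_a: RadicalSpec
    radical_b: RadicalSpec
    k_s: float = 0.2
    k_st: float = 0.01
    field_mT: np.ndarray = field(default_factory=lambda: np.zeros(3))
    initial_state: InitialState = "triplet"

    def __post_init__(self):
        if self.k_s < 0:
            raise ValueError("k_s must be >= 0")
        if self.k_st <= 0:
            raise ValueError("k_st must be > 0")
        b = np.asarray(self.field_mT, dtype=float).reshape(3)
        if not np.all(np.isfinite(b)):
            raise ValueError("field vector contains non-finite entries")
        object.__setattr__(self, "field_mT", b)
        if self.initial_state not in ("triplet", "singlet", "f_pair"):
            raise ValueError(f"unknown initial-state mode {self.initial_state!r}")

    @property
    def radicals(self) -> tuple[RadicalSpec, RadicalSpec]:
        return (self.radical_a, self.radical_b)

    def with_field(self, bz_mT: float) -> "SpinSystemSpec":
        """Copy of this spec with the field set to (0, 0, bz_mT)."""
        return SpinSystemSpec(
            self.radical_a, self.radical_b, self.k_s, self.k_st,
            np.array([0.0, 0.0, bz_mT]), self.initial_state,
        )

    def with_kst(self, k_st: float) -> "SpinSystemSpec":
        return SpinSystemSpec(
            self.radical_a, self.radical_b, self.k_s, k_st,
            self.field_mT, self.initial_state,
        )


@dataclass(frozen=True)
class Operator:
    """A complex square matrix on the full Hilbert space with a role tag."""

    matrix: np.ndarray
    role: Literal["hamiltonian", "projector", "spin-component", "density"]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("operator matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def hilbert_dimension(spec: SpinSystemSpec) -> int:
    """dim(H) = 4 * prod over nuclei of (2I+1)."""
    d = 4
    for rad in spec.radicals:
        for nuc in rad.nuclei:
            d *= nuc.multiplicity
    return d


def spin_matrices(spin: float) -> dict[str, np.ndarray]:
    """Cartesian spin matrices S_x, S_y, S_z for arbitrary spin I.

    Standard ladder-operator construction in the |I, m> basis ordered
    m = I, I-1, ..., -I.
    """
    two_i = round(2 * spin)
    n = two_i + 1
    m = spin - np.arange(n)
    sz = np.diag(m).astype(complex)
    # <I, m+1 | I_+ | I, m> = sqrt(I(I+1) - m(m+1))
    mp = m[1:]
    raise_elems = np.sqrt(spin * (spin + 1) - mp * (mp + 1))
    splus = np.zeros((n, n), dtype=complex)
    splus[np.arange(n - 1), np.arange(1, n)] = raise_elems
    sx = 0.5 * (splus + splus.conj().T)
    sy = -0.5j * (splus - splus.conj().T)
    return {"x": sx, "y": sy, "z": sz}


def _embed(op: np.ndarray, dims: Sequence[int], position: int) -> np.ndarray:
    """Identity-pad ``op`` into the tensor-product space defined by ``dims``."""
    left = int(np.prod(dims[:position], dtype=np.int64)) if position > 0 else 1
    right = int(np.prod(dims[position + 1:], dtype=np.int64)) if position + 1 < len(dims) else 1
    return np.kron(np.kron(np.eye(left), op), np.eye(right))


@dataclass(frozen=True)
class SpinOperators:
    """x/y/z spin-component operators, embedded in the full space.

    ``electron[i][k]`` is the k-component (k in "xyz") of electron i's
    spin; ``nuclear[i][n][k]`` the same for nucleus n of radical i.
    """

    dim: int
    electron: tuple[dict[str, np.ndarray], dict[str, np.ndarray]]
    nuclear: tuple[tuple[dict[str, np.ndarray], ...], tuple[dict[str, np.ndarray], ...]]


def build_spin_operators(spec: SpinSystemSpec, dimension_cap: int = DEFAULT_DIMENSION_CAP) -> SpinOperators:
    """Construct all spin-component operators of the pair.

    Raises
    ------
    ValueError
        If the total Hilbert dimension exceeds ``dimension_cap``.
    """
    dim = hilbert_dimension(spec)
    if dim > dimension_cap:
        raise ValueError(
            f"Hilbert dimension {dim} exceeds the cap {dimension_cap}; "
            "raise dimension_cap explicitly if this is intentional"
        )
    dims = [2, 2]
    for rad in spec.radicals:
        for nuc in rad.nuclei:
            dims.append(nuc.multiplicity)

    half = spin_matrices(0.5)
    electron = tuple(
        {k: _embed(half[k], dims, i) for k in "xyz"} for i in range(2)
    )
    nuclear = []
    pos = 2
    for rad in spec.radicals:
        ops_rad = []
        for nuc in rad.nuclei:
            mats = spin_matrices(nuc.spin)
            ops_rad.append({k: _embed(mats[k], dims, pos) for k in "xyz"})
            pos += 1
        nuclear.append(tuple(ops_rad))
    return SpinOperators(dim=dim, electron=electron, nuclear=tuple(nuclear))


# Electron product basis: |uu>, |ud>, |du>, |dd>; singlet = (|ud>-|du>)/sqrt(2).
_SINGLET_VEC = np.array([0.0, 1.0, -1.0, 0.0]) / np.sqrt(2.0)


def singlet_triplet_projectors(spec: SpinSystemSpec) -> tuple[Operator, Operator]:
    """Projectors P_S and P_T: electronic projectors tensored with the nuclear identity.

    P_S + P_T is the identity; trace(P_S) = Z and trace(P_T) = 3 Z with Z
    the nuclear-space dimension.
    """
    dim = hilbert_dimension(spec)
    z = dim // 4
    ps4 = np.outer(_SINGLET_VEC, _SINGLET_VEC).astype(complex)
    ps = np.kron(ps4, np.eye(z))
    pt = np.eye(dim) - ps
    return Operator(ps, "projector"), Operator(pt, "projector")


def build_hamiltonian(
    spec: SpinSystemSpec,
    ops: SpinOperators | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> Operator:
    """Static spin Hamiltonian H = sum_i (mu_B/hbar) B.g_i.S_i + sum_n I_n.A_n.S_i in rad/ns.

    The Zeeman term uses the full 3x3 g matrices; for B = (0, 0, Bz) it
    reduces to mu_B Bz (g_zx S_x + g_zy S_y + g_zz S_z)/hbar per radical.
    Hyperfine tensors are already in rad/ns so they enter directly.
    """
    if ops is None:
        ops = build_spin_operators(spec)
    h = np.zeros((ops.dim, ops.dim), dtype=complex)
    b = spec.field_mT
    axes = "xyz"
    for i, rad in enumerate(spec.radicals):
        g = rad.g_tensor
        # B . g . S = sum_ab B_a g_ab S_b
        for a in range(3):
            if b[a] == 0.0:
                continue
            for bb in range(3):
                if g[a, bb] != 0.0:
                    h += constants.gamma_mT * b[a] * g[a, bb] * ops.electron[i][axes[bb]]
        for n, nuc in enumerate(rad.nuclei):
            A = nuc.hyperfine
            for a in range(3):
                for bb in range(3):
                    if A[a, bb] != 0.0:
                        h += A[a, bb] * (
                            ops.nuclear[i][n][axes[a]] @ ops.electron[i][axes[bb]]
                        )
    if not np.all(np.isfinite(h)):
        raise ValueError("Hamiltonian contains non-finite entries")
    return Operator(h, "hamiltonian")


def initial_density(spec: SpinSystemSpec) -> Operator:
    """Initial density operator for the requested generation mode.

    triplet -> P_T/tr(P_T); singlet -> P_S/tr(P_S); f_pair -> 1/dim
    (the statistical mixture with singlet probability 1/4 and triplet
    probability 3/4).
    """
    ps, pt = singlet_triplet_projectors(spec)
    if spec.initial_state == "triplet":
        rho = pt.matrix / np.trace(pt.matrix).real
    elif spec.initial_state == "singlet":
        rho = ps.matrix / np.trace(ps.matrix).real
    elif spec.initial_state == "f_pair":
        dim = hilbert_dimension(spec)
        rho = np.eye(dim, dtype=complex) / dim
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown initial-state mode {spec.initial_state!r}")
    return Operator(rho, "density")


# ---------------------------------------------------------------------------
# Serialization: structured key-value config with rates in 1/s on disk.

_PER_S_TO_PER_NS = 1e-9


def load_spin_system(path) -> SpinSystemSpec:
    """Read a spin-system YAML file.

    File layout: ``radicals`` (list of two entries with ``g`` as 9 row-major
    numbers and ``nuclei`` with ``label``, ``I`` and ``A`` as 9 row-major
    rad/ns numbers), ``kinetics`` with ``k_S``/``k_ST`` in 1/s (converted to
    1/ns internally), ``field`` with ``Bz_mT`` (scalar or list; the first
    entry seeds the spec) and ``initial_state``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rads = []
    for entry in doc["radicals"]:
        nuclei = [
            NucleusSpec(
                label=str(n.get("label", "?")),
                spin=float(n["I"]),
                hyperfine=np.array(n["A"], dtype=float).reshape(3, 3),
            )
            for n in entry.get("nuclei", []) or []
        ]
        rads.append(RadicalSpec(np.array(entry["g"], dtype=float).reshape(3, 3), tuple(nuclei)))
    if len(rads) != 2:
        raise ValueError(f"expected exactly two radicals, got {len(rads)}")
    kin = doc["kinetics"]
    bz = doc.get("field", {}).get("Bz_mT", 0.0)
    bz0 = float(np.atleast_1d(bz)[0])
    return SpinSystemSpec(
        radical_a=rads[0],
        radical_b=rads[1],
        k_s=float(kin["k_S"]) * _PER_S_TO_PER_NS,
        k_st=float(kin["k_ST"]) * _PER_S_TO_PER_NS,
        field_mT=np.array([0.0, 0.0, bz0]),
        initial_state=doc.get("initial_state", "triplet"),
    )


def save_spin_system(spec: SpinSystemSpec, path) -> None:
    """Write the YAML counterpart of :func:`load_spin_system`."""
    doc = {
        "radicals": [
            {
                "g": [float(x) for x in rad.g_tensor.ravel()],
                "nuclei": [
                    {
                        "label": nuc.label,
                        "I": float(nuc.spin),
                        "A": [float(x) for x in nuc.hyperfine.ravel()],
                    }
                    for nuc in rad.nuclei
                ],
            }
            for rad in spec.radicals
        ],
        "kinetics": {"k_S": spec.k_s / _PER_S_TO_PER_NS, "k_ST": spec.k_st / _PER_S_TO_PER_NS},
        "field": {"Bz_mT": [float(spec.field_mT[2])]},
        "initial_state": spec.initial_state,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
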