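"""Map dihedral-angle and orientation trajectories to lab-frame tensor trajectories.

The fragment-frame hyperfine and g tensors are tabulated on a 1-degree
grid of the peroxide dihedral angle Omega (the table plays the role of a
quantum-chemistry scan over the sampled angular range; angles inside the
excluded window the dynamics never visits are simply absent from the
table).  A frame's lab tensors are obtained by nearest-grid-point lookup
(tie broken toward the lower angle) followed by the active rotation

    T_lab = R . T_frag(Omega) . R^T

with R the fragment orientation of that frame, stored as a unit
quaternion (w, x, y, z; scalar first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .correlation import ScalarSeries

__all__ = [
    "MappingTable",
    "OrientationTrajectory",
    "TensorTrajectory",
    "lookup_tensors",
    "map_trajectory",
    "save_table",
    "load_table",
    "save_tensor_trajectory",
    "load_tensor_trajectory",
]


@dataclass(frozen=True)
class MappingTable:
    """Fragment-frame tensors on a 1-degree Omega grid.

    ``omega_deg`` holds the covered grid angles in [0, 360); gaps mark
    the excluded window.  Hyperfine tensors are in rad/ns and symmetric;
    g tensors dimensionless.
    """

    omega_deg: np.ndarray
    hyperfine: np.ndarray  # (n, 3, 3) rad/ns
    g_tensor: np.ndarray   # (n, 3, 3)

    def __post_init__(self):
        om = np.asarray(self.omega_deg, dtype=float)
        a = np.asarray(self.hyperfine, dtype=float)
        g = np.asarray(self.g_tensor, dtype=float)
        if om.ndim != 1 or a.shape != (om.size, 3, 3) or g.shape != (om.size, 3, 3):
            raise ValueError("inconsistent table shapes")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(g))):
            raise ValueError("table tensors must be finite")
        om_mod = np.mod(om, 360.0)
        order = np.argsort(om_mod)
        om_mod = om_mod[order]
        steps = np.diff(om_mod)
        if om_mod.size > 1 and not np.all(
            np.isclose(steps[steps < 1.5], 1.0, atol=1e-9)
        ):
            raise ValueError("grid step must be exactly 1 degree outside gaps")
        if not np.allclose(a, np.swapaxes(a, 1, 2), atol=1e-10):
            raise ValueError("hyperfine table entries must be symmetric")
        object.__setattr__(self, "omega_deg", om_mod)
        object.__setattr__(self, "hyperfine", a[order])
        object.__setattr__(self, "g_tensor", g[order])

    def excluded_window(self) -> tuple[float, float] | None:
        """(start, stop) in degrees of the largest gap in the grid, if any."""
        om = self.omega_deg
        if om.size == 0:
            return None
        gaps = np.diff(np.concatenate([om, [om[0] + 360.0]]))
        imax = int(np.argmax(gaps))
        if gaps[imax] <= 1.0 + 1e-9:
            return None
        return (float(om[imax]), float(np.mod(om[(imax + 1) % om.size], 360.0)))


@dataclass(frozen=True)
class OrientationTrajectory:
    """Unit quaternions (w, x, y, z) per frame at the trajectory time step."""

    quaternions: np.ndarray
    dt_ps: float = 1.0

    def __post_init__(self):
        q = np.asarray(self.quaternions, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError("quaternions must have shape (n, 4)")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("quaternions must be unit norm within 1e-8")
        # continuity: successive rotations must differ by less than 90 deg
        dots = np.abs(np.sum(q[1:] * q[:-1], axis=1))
        if np.any(dots < np.cos(np.pi / 4.0) - 1e-12):
            raise ValueError("frame-to-frame rotation exceeds 90 degrees")
        object.__setattr__(self, "quaternions", q)

    def __len__(self) -> int:
        return self.quaternions.shape[0]

    def as_matrices(self) -> np.ndarray:
        q = self.quaternions
        # scipy uses scalar-last ordering
        return Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()


@dataclass(frozen=True)
class TensorTrajectory:
    """Lab-frame hyperfine and g tensors per 1 ps frame (one radical)."""

    hyperfine: np.ndarray  # (n, 3, 3) rad/ns
    g_tensor: np.ndarray   # (n, 3, 3)
    dt_ps: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.hyperfine, dtype=float)
        g = np.asarray(self.g_tensor, dtype=float)
        if a.shape != g.shape or a.ndim != 3 or a.shape[1:] != (3, 3):
            raise ValueError("tensor trajectory arrays must have shape (n, 3, 3)")
        object.__setattr__(self, "hyperfine", a)
        object.__setattr__(self, "g_tensor", g)

    def __len__(self) -> int:
        return self.hyperfine.shape[0]

    def component_series(self, which: str, comp: str) -> ScalarSeries:
        """Scalar series of one tensor component, e.g. ('hyperfine', 'xx')."""
        idx = {"x": 0, "y": 1, "z": 2}
        arr = self.hyperfine if which == "hyperfine" else self.g_tensor
        return ScalarSeries(arr[:, idx[comp[0]], idx[comp[1]]], self.dt_ps, f"{which}_{comp}")


def lookup_tensors(omega_deg: float, table: MappingTable) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-grid-point fragment-frame tensors for a dihedral angle."""
    i = int(_nearest_bulk(np.array([np.mod(omega_deg, 360.0)]), table)[0])
    return table.hyperfine[i], table.g_tensor[i]


def map_trajectory(
    dihedrals: ScalarSeries,
    orientations: OrientationTrajectory,
    table: MappingTable,
    interpolation: str = "nearest",
) -> TensorTrajectory:
    """Lab-frame tensor trajectory T_lab(t) = R(t) T_frag(Omega(t)) R(t)^T.

    ``interpolation="linear"`` blends the two neighbouring grid entries
    instead of the default nearest-neighbour lookup.
    """
    n = dihedrals.values.size
    if n != len(orientations):
        raise ValueError(
            f"frame count mismatch: {n} dihedrals vs {len(orientations)} orientations"
        )
    om = np.mod(dihedrals.values, 360.0)
    grid = table.omega_deg
    if interpolation == "nearest":
        idx = _nearest_bulk(om, table)
        a_frag = table.hyperfine[idx]
        g_frag = table.g_tensor[idx]
    elif interpolation == "linear":
        lo = np.searchsorted(grid, om, side="right") - 1
        lo = np.clip(lo, 0, grid.size - 1)
        hi = (lo + 1) % grid.size
        span = np.mod(grid[hi] - grid[lo], 360.0)
        span[span == 0] = 1.0
        w = np.mod(om - grid[lo], 360.0) / span
        w = np.clip(w, 0.0, 1.0)[:, None, None]
        a_frag = (1 - w) * table.hyperfine[lo] + w * table.hyperfine[hi]
        g_frag = (1 - w) * table.g_tensor[lo] + w * table.g_tensor[hi]
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    rot = orientations.as_matrices()
    a_lab = np.einsum("nij,njk,nlk->nil", rot, a_frag, rot)
    g_lab = np.einsum("nij,njk,nlk->nil", rot, g_frag, rot)
    return TensorTrajectory(a_lab, g_lab, dihedrals.dt_ps)


def _nearest_bulk(om: np.ndarray, table: MappingTable) -> np.ndarray:
    """Vectorized nearest-grid lookup with the same tie/window rules."""
    grid = table.omega_deg
    ext = np.concatenate([grid - 360.0, grid, grid + 360.0])
    ext_idx = np.tile(np.arange(grid.size), 3)
    pos = np.searchsorted(ext, om)
    cand = np.stack([np.clip(pos - 1, 0, ext.size - 1), np.clip(pos, 0, ext.size - 1)])
    d = np.abs(ext[cand] - om)
    # tie toward lower angle: prefer the left candidate on equality
    pick = np.where(d[1] < d[0] - 1e-12, 1, 0)
    best_d = d[pick, np.arange(om.size)]
    if np.any(best_d > 0.5 + 1e-9):
        bad = om[best_d > 0.5 + 1e-9][0]
        raise ValueError(
            f"Omega = {bad} deg falls in the excluded window "
            f"{table.excluded_window()} not covered by the table"
        )
    return ext_idx[cand[pick, np.arange(om.size)]]


# ---------------------------------------------------------------------------
# File formats: plain-text tables, documented column layouts.


def save_table(table: MappingTable, path) -> None:
    """One row per grid point: Omega_deg, 9 hyperfine (rad/ns), 9 g components."""
    rows = np.column_stack(
        [table.omega_deg, table.hyperfine.reshape(-1, 9), table.g_tensor.reshape(-1, 9)]
    )
    header = (
        "Omega mapping table; grid step 1 deg\n"
        "omega_deg, A[9] row-major rad/ns, g[9] row-major"
    )
    np.savetxt(path, rows, delimiter="\t", header=header)


def load_table(path) -> MappingTable:
    data = np.atleast_2d(np.loadtxt(path))
    return MappingTable(
        omega_deg=data[:, 0],
        hyperfine=data[:, 1:10].reshape(-1, 3, 3),
        g_tensor=data[:, 10:19].reshape(-1, 3, 3),
    )


def save_tensor_trajectory(traj: TensorTrajectory, path) -> None:
    """One row per frame: t_ps, 9 hyperfine components, 9 g components."""
    n = len(traj)
    t = np.arange(n) * traj.dt_ps
    rows = np.column_stack([t, traj.hyperfine.reshape(n, 9), traj.g_tensor.reshape(n, 9)])
    np.savetxt(path, rows, delimiter="\t", header="t_ps, A[9] rad/ns, g[9]")


def load_tensor_trajectory(path) -> TensorTrajectory:
    data = np.atleast_2d(np.loadtxt(path))
    dt = data[1, 0] - data[0, 0] if data.shape[0] > 1 else 1.0
    return TensorTrajectory(
        hyperfine=data[:, 1:10].reshape(-1, 3, 3),
        g_tensor=data[:, 10:19].reshape(-1, 3, 3),
        dt_ps=float(dt),
    )
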