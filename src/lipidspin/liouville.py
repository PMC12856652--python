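"""Liouville-space helpers: vectorization and multiplication superoperators.

Convention: column stacking, vec(rho) = rho.flatten(order="F"), so that
vec(A rho B) = (B^T kron A) vec(rho).  Hence

    spre(A)  -> (I kron A)      implements rho -> A rho
    spost(B) -> (B^T kron I)    implements rho -> rho B
"""

from __future__ import annotations

import numpy as np

__all__ = ["vec", "unvec", "spre", "spost", "commutator_super", "double_commutator_super"]


def vec(rho: np.ndarray) -> np.ndarray:
    return np.asarray(rho, dtype=complex).flatten(order="F")


def unvec(x: np.ndarray) -> np.ndarray:
    n = round(np.sqrt(x.size))
    return np.asarray(x, dtype=complex).reshape((n, n), order="F")


def spre(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=complex)
    return np.kron(np.eye(a.shape[0]), a)


def spost(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=complex)
    return np.kron(b.T, np.eye(b.shape[0]))


def commutator_super(h: np.ndarray) -> np.ndarray:
    """Superoperator for rho -> [H, rho]."""
    return spre(h) - spost(h)


def double_commutator_super(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Superoperator for rho -> [A, [B, rho]] = [A, B rho] - [A, rho B]."""
    return spre(a @ b) - spre(b) @ spost(a) - spre(a) @ spost(b) + spost(b @ a)
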