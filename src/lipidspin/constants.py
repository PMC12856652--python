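"""Physical constants and the package's unit conventions.

Internal unit system
--------------------
All spin-Hamiltonian and relaxation quantities are handled as angular
frequencies in rad/ns.  Magnetic fields are in mT, first-order rate
constants in 1/ns, times and correlation lags in ns.  Conversions from
laboratory units (1/s rates, MHz couplings, ...) happen only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PhysicalConstants", "CONSTANTS"]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants plus the working free-electron g-factor.

    ``free_electron_g`` defaults to 2.0013, the value used in the
    spin-rotational estimate this package implements.  It deviates from
    the accepted free-electron value (about 2.00232); the default is kept
    as-is deliberately and can be overridden per call site.

    Attributes
    ----------
    bohr_magneton : float
        Bohr magneton in J/T.
    hbar : float
        Reduced Planck constant in J*s.
    free_electron_g : float
        Dimensionless g-factor used for the spin-rotational channel.
    """

    bohr_magneton: float = 9.2740100783e-24
    hbar: float = 1.054571817e-34
    free_electron_g: float = 2.0013

    def __post_init__(self) -> None:
        if not (self.bohr_magneton > 0 and self.hbar > 0 and self.free_electron_g > 0):
            raise ValueError("physical constants must be strictly positive")

    @property
    def gamma_mT(self) -> float:
        """Electron gyromagnetic prefactor mu_B/hbar in rad/ns per mT per unit g.

        Multiply by a g-value and a field in mT to get a Larmor angular
        frequency in rad/ns (= 0.0879410 rad/(ns*mT) for unit g with the
        default CODATA constants).
        """
        return self.bohr_magneton / self.hbar * 1e-12


#: Module-wide default constant set.
CONSTANTS = PhysicalConstants()
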