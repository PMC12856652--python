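"""Covariance-function estimation, multiexponential fits and spectral densities.

A fluctuating interaction component x(t) (a hyperfine-tensor component in
rad/ns, a g-tensor component, cos of a dihedral angle, ...) is
characterized by its covariance function

    g_xy(tau) = < dx(t) dy(t - tau) >,     dx = x - <x>,

estimated with the biased 1/N FFT estimator.  The lag-0-normalized curve
is fitted with a fixed basis of 50 exponential decays whose time
constants tau_j are logarithmically spaced between 0.5 ps and 100 ns,

    g(tau) ~ cov * sum_j c_j exp(-tau/tau_j),   sum_j c_j = 1,  c_j >= 0,

by non-negative least squares.  From the fit follow the effective
correlation time tau_eff = sum_j c_j tau_j and the zero-frequency
spectral density J(0) = cov * tau_eff (one-sided integral convention, no
factor of 2).  For g-tensor components the Zeeman field factor
(mu_B Bz / hbar)^2 is *not* applied here; it enters when the relaxation
superoperator is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.signal
import yaml

__all__ = [
    "ScalarSeries",
    "CovarianceCurve",
    "CovarianceModel",
    "LAG_GRID_NS",
    "TENSOR_COMPONENTS",
    "series_covariance",
    "distinct_component_pairs",
    "canonical_pair",
    "fit_covariance_model",
    "effective_correlation_time",
    "spectral_density_zero",
    "spectral_density",
    "model_curve",
    "save_model",
    "load_model",
    "save_curve",
    "load_curve",
]

#: The 9 tensor-component labels in row-major order.
TENSOR_COMPONENTS = ("xx", "xy", "xz", "yx", "yy", "yz", "zx", "zy", "zz")


def _make_lag_grid() -> np.ndarray:
    grid = np.logspace(np.log10(5e-4), np.log10(100.0), 50)
    grid[0], grid[-1] = 5e-4, 100.0  # endpoints exact by construction
    return grid


#: Fixed 50-point logarithmic lag grid, 0.5 ps .. 100 ns.
LAG_GRID_NS = _make_lag_grid()


@dataclass(frozen=True)
class ScalarSeries:
    """A uniformly sampled scalar time series.

    ``dt_ps`` defaults to 1 ps, the trajectory write-out interval the
    analysis assumes throughout.
    """

    values: np.ndarray
    dt_ps: float = 1.0
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("series needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        if self.dt_ps <= 0:
            raise ValueError("time step must be positive")
        object.__setattr__(self, "values", v)

    @property
    def dt_ns(self) -> float:
        return self.dt_ps * 1e-3

    @property
    def span_ns(self) -> float:
        return (self.values.size - 1) * self.dt_ns


@dataclass(frozen=True)
class CovarianceCurve:
    """Covariance values on a lag grid starting at zero.

    ``sigma2`` is the zero-lag value (the variance for an
    autocovariance).  ``normalized`` marks curves divided by sigma2.
    """

    lags_ns: np.ndarray
    values: np.ndarray
    sigma2: float
    normalized: bool = False
    label: str = ""

    def __post_init__(self):
        lags = np.asarray(self.lags_ns, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if lags.shape != vals.shape:
            raise ValueError("lag and value arrays differ in shape")
        if lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        object.__setattr__(self, "lags_ns", lags)
        object.__setattr__(self, "values", vals)

    def normalize(self) -> "CovarianceCurve":
        if self.normalized:
            return self
        if self.sigma2 == 0.0:
            raise ValueError("cannot normalize an all-zero covariance curve")
        return CovarianceCurve(
            self.lags_ns, self.values / self.sigma2, self.sigma2, True, self.label
        )


@dataclass(frozen=True)
class CovarianceModel:
    """Fitted multiexponential covariance model on the fixed lag grid.

    prefactor carries the units (rad^2/ns^2 for hyperfine components,
    dimensionless for g components); the 50 weights sum to one.
    """

    prefactor: float
    weights: np.ndarray
    pair: tuple[str, str] = ("xx", "xx")
    lag_grid_ns: np.ndarray = field(default_factory=lambda: LAG_GRID_NS.copy())
    residual_rms: float = 0.0
    degenerate: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        grid = np.asarray(self.lag_grid_ns, dtype=float)
        if w.shape != grid.shape:
            raise ValueError("weights and lag grid differ in length")
        if np.any(w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lag_grid_ns", grid)


def series_covariance(
    x: ScalarSeries,
    y: ScalarSeries | None = None,
    max_lag_ns: float = 50.0,
) -> CovarianceCurve:
    """Biased (1/N) covariance estimator cov(x(t), y(t - tau)) via FFT.

    The means are removed per series.  For ``y=None`` the autocovariance
    of ``x`` is returned.  Agrees with the direct double-loop sum to
    within floating-point round-off.
    """
    if y is None:
        y = x
    if x.values.size != y.values.size or x.dt_ps != y.dt_ps:
        raise ValueError("series must share length and time step")
    if max_lag_ns >= x.span_ns:
        raise ValueError(
            f"max_lag {max_lag_ns} ns is not shorter than the series span {x.span_ns} ns"
        )
    n = x.values.size
    n_lags = int(np.floor(max_lag_ns / x.dt_ns)) + 1
    dx = x.values - x.values.mean()
    dy = y.values - y.values.mean()
    # conv[n-1+k] = sum_t dx[t] dy[t-k]
    conv = scipy.signal.fftconvolve(dx, dy[::-1], mode="full")
    cov = conv[n - 1 : n - 1 + n_lags] / n
    lags = np.arange(n_lags) * x.dt_ns
    label = x.label if y is x else f"{x.label}*{y.label}"
    return CovarianceCurve(lags, cov, sigma2=float(cov[0]), normalized=False, label=label)


def _canonical_component(comp: str, symmetric: bool) -> str:
    if comp not in TENSOR_COMPONENTS:
        raise ValueError(f"unknown tensor component {comp!r}")
    if symmetric:
        return "".join(sorted(comp))
    return comp


def canonical_pair(pair: tuple[str, str], symmetric: bool = True) -> tuple[str, str]:
    """Representative of a component pair's equivalence class.

    Classes are generated by exchange g_ab = g_ba of the two members and,
    for ``symmetric=True``, by permutation symmetry of each tensor
    component (A_xy = A_yx).
    """
    a = _canonical_component(pair[0], symmetric)
    b = _canonical_component(pair[1], symmetric)
    return (a, b) if a <= b else (b, a)


def distinct_component_pairs(symmetric: bool = True) -> list[tuple[str, str]]:
    """One representative per distinct auto-/cross-covariance function.

    For a symmetric 3x3 tensor the 81 ordered component pairs collapse to
    21 distinct correlation functions (6 of them pure autocovariances);
    without component symmetry, exchange alone leaves 45.
    """
    comps = sorted({_canonical_component(c, symmetric) for c in TENSOR_COMPONENTS})
    return list(combinations_with_replacement(comps, 2))


def fit_covariance_model(
    curve: CovarianceCurve,
    lag_grid_ns: np.ndarray = LAG_GRID_NS,
    max_fit_lag_ns: float = 50.0,
    min_curve_span_ns: float = 10.0,
    pair: tuple[str, str] = ("xx", "xx"),
    basis_cap_ns: float | None = None,
) -> CovarianceModel:
    """Fit the lag-0-normalized curve with the fixed 50-exponential basis.

    Non-negative least squares with post-hoc renormalization to
    sum(c_j) = 1; the prefactor is the zero-lag covariance.  An all-zero
    curve yields a degenerate model (zero prefactor, uniform weights).

    ``basis_cap_ns`` optionally zeroes basis exponentials slower than the
    cap: time constants much longer than the fitted window are not
    identifiable from it, and on noisy estimated curves they soak up
    correlated tail noise and inflate the effective correlation time.
    """
    if curve.normalized:
        raise ValueError("fit expects an unnormalized covariance curve")
    if curve.lags_ns[-1] < min_curve_span_ns:
        raise ValueError(
            f"curve extends to {curve.lags_ns[-1]} ns; need >= {min_curve_span_ns} ns of lag"
        )
    grid = np.asarray(lag_grid_ns, dtype=float)
    if curve.sigma2 == 0.0 and np.allclose(curve.values, 0.0):
        w = np.full(grid.size, 1.0 / grid.size)
        return CovarianceModel(0.0, w, pair, grid, 0.0, degenerate=True)
    sel = curve.lags_ns <= max_fit_lag_ns
    lags = curve.lags_ns[sel]
    target = curve.values[sel] / curve.sigma2
    design = np.exp(-np.divide.outer(lags, grid))
    if basis_cap_ns is not None:
        active = grid <= basis_cap_ns
        if not np.any(active):
            raise ValueError("basis cap excludes every grid exponential")
        fitted, _ = scipy.optimize.nnls(design[:, active], target)
        weights = np.zeros(grid.size)
        weights[active] = fitted
    else:
        weights, _ = scipy.optimize.nnls(design, target)
    total = weights.sum()
    if total <= 0:
        w = np.full(grid.size, 1.0 / grid.size)
        return CovarianceModel(0.0, w, pair, grid, 0.0, degenerate=True)
    weights = weights / total
    resid = design @ (weights * total) - target
    rms = float(np.sqrt(np.mean(resid**2)))
    return CovarianceModel(
        prefactor=float(curve.sigma2),
        weights=weights,
        pair=pair,
        lag_grid_ns=grid,
        residual_rms=rms,
    )


def effective_correlation_time(model: CovarianceModel) -> float:
    """tau_eff = sum_j c_j tau_j in ns."""
    return float(np.dot(model.weights, model.lag_grid_ns))


def spectral_density_zero(model: CovarianceModel) -> float:
    """J(0) = cov * sum_j c_j tau_j.

    Units: rad^2/ns for hyperfine components; for g components the
    result is dimensionless * ns and the (mu_B Bz / hbar)^2 field factor
    is applied later at superoperator build time.
    """
    return model.prefactor * effective_correlation_time(model)


def spectral_density(model: CovarianceModel, omega: float) -> float:
    """Lorentzian spectral density J(w) = cov * sum_j c_j tau_j / (1 + (w tau_j)^2).

    One-sided convention; the imaginary part (dynamic frequency shift)
    is discarded.
    """
    taus = model.lag_grid_ns
    return float(model.prefactor * np.sum(model.weights * taus / (1.0 + (omega * taus) ** 2)))


def model_curve(model: CovarianceModel, lags_ns: np.ndarray) -> np.ndarray:
    """Evaluate the fitted covariance model (unnormalized) at given lags."""
    lags = np.asarray(lags_ns, dtype=float)
    return model.prefactor * (np.exp(-np.divide.outer(lags, model.lag_grid_ns)) @ model.weights)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: CovarianceModel, path) -> None:
    doc = {
        "pair": list(model.pair),
        "prefactor": float(model.prefactor),
        "grid_start_ns": float(model.lag_grid_ns[0]),
        "grid_stop_ns": float(model.lag_grid_ns[-1]),
        "grid_points": int(model.lag_grid_ns.size),
        "weights": [float(w) for w in model.weights],
        "residual_rms": float(model.residual_rms),
        "degenerate": bool(model.degenerate),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> CovarianceModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    grid = np.logspace(
        np.log10(doc["grid_start_ns"]), np.log10(doc["grid_stop_ns"]), doc["grid_points"]
    )
    grid[0], grid[-1] = doc["grid_start_ns"], doc["grid_stop_ns"]
    return CovarianceModel(
        prefactor=float(doc["prefactor"]),
        weights=np.array(doc["weights"], dtype=float),
        pair=tuple(doc["pair"]),
        lag_grid_ns=grid,
        residual_rms=float(doc.get("residual_rms", 0.0)),
        degenerate=bool(doc.get("degenerate", False)),
    )


def save_curve(curve: CovarianceCurve, path) -> None:
    """Two-column TSV: lag_ns, value."""
    header = f"lag_ns\tvalue  # sigma2={curve.sigma2!r} normalized={curve.normalized} label={curve.label}"
    np.savetxt(path, np.column_stack([curve.lags_ns, curve.values]), delimiter="\t", header=header)


def load_curve(path) -> CovarianceCurve:
    data = np.loadtxt(path)
    lags, vals = data[:, 0], data[:, 1]
    return CovarianceCurve(lags, vals, sigma2=float(vals[0]))
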