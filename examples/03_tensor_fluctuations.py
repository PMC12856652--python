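"""From trajectories to fluctuating tensors to spectral densities.

Maps a dihedral + orientation trajectory through a synthetic
Omega -> tensor table, estimates the covariance function of a hyperfine
component, fits the 50-exponential model and reports the effective
correlation time and zero-frequency spectral density that feed the
relaxation superoperators.
"""

from lipidspin.correlation import (
    effective_correlation_time,
    fit_covariance_model,
    series_covariance,
    spectral_density_zero,
)
from lipidspin.synth import SyntheticParams, make_synthetic_dataset

params = SyntheticParams(seed=7, n_frames=120_000, target_corr_time_ns=0.4,
                         rot_step_deg=2.0)
dataset = make_synthetic_dataset(params)
print(f"mapped {len(dataset.tensors)} frames; table covers "
      f"{dataset.table.omega_deg.size} grid angles")

series = dataset.tensors.component_series("hyperfine", "xx")
curve = series_covariance(series, max_lag_ns=12.0)
print(f"A_xx variance sigma^2 = {curve.sigma2:.3e} rad^2/ns^2")

model = fit_covariance_model(curve, max_fit_lag_ns=12.0, basis_cap_ns=12.0,
                             pair=("xx", "xx"))
tau = effective_correlation_time(model)
j0 = spectral_density_zero(model)
print(f"effective correlation time tau_eff = {tau:.3f} ns")
print(f"zero-frequency spectral density J(0) = {j0:.3e} rad^2/ns")
# J(0) = sigma^2 * tau_eff sets the extreme-narrowing relaxation rate
# contributed by this tensor component; the fluctuations here are driven
# jointly by the dihedral rotation (fast) and fragment tumbling (slower).
print(f"fit residual RMS = {model.residual_rms:.3e} (of the normalized curve)")
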