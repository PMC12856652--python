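"""Relaxation channels: trace preservation, closed-form rates, scaling laws."""

import numpy as np
import pytest

import lipidspin as ls
from lipidspin.constants import CONSTANTS
from lipidspin.liouville import unvec, vec
from lipidspin.pipeline import reference_system, single_mode_model
from lipidspin.relaxation import (
    RelaxationInputs,
    g_redfield,
    hyperfine_redfield,
    spin_rotational_rate,
    spin_rotational_superoperator,
)


@pytest.fixture(scope="module")
def reference():
    spec, inputs = reference_system()
    ops = ls.build_spin_operators(spec)
    return spec, inputs, ops


def _channels(inputs, ops, bz=50.0):
    k_sr = spin_rotational_rate(inputs.delta_g, inputs.tau_rot_ns)
    return {
        "hf": hyperfine_redfield(inputs, ops),
        "g": g_redfield(inputs, bz, ops),
        "sr": spin_rotational_superoperator(k_sr, ops),
    }


def _random_hermitian(rng, d):
    m = rng.normal(size=(d, d)) + 1j * rng.normal(size=(d, d))
    return m + m.conj().T


class TestChannelContracts:
    def test_trace_preserving_on_random_operators(self, reference, rng):
        _, inputs, ops = reference
        for name, r in _channels(inputs, ops).items():
            for _ in range(50):
                rho = _random_hermitian(rng, ops.dim)
                drho = unvec(r.matrix @ vec(rho))
                assert abs(np.trace(drho)) < 1e-12 * np.linalg.norm(rho), name

    def test_identity_is_stationary(self, reference):
        _, inputs, ops = reference
        ident = np.eye(ops.dim, dtype=complex)
        for name, r in _channels(inputs, ops).items():
            out = unvec(r.matrix @ vec(ident))
            assert np.linalg.norm(out) < 1e-12, name

    def test_hermiticity_preserved_under_each_channel(self, reference, rng):
        import scipy.linalg

        spec, inputs, ops = reference
        rho = _random_hermitian(rng, ops.dim)
        rho = rho @ rho.conj().T
        rho /= np.trace(rho)
        for name, r in _channels(inputs, ops).items():
            prop = scipy.linalg.expm(-r.matrix * 5.0)
            evolved = unvec(prop @ vec(rho))
            assert np.linalg.norm(evolved - evolved.conj().T) < 1e-9, name

    def test_coherence_decays_under_each_channel(self, reference):
        import scipy.linalg

        spec, inputs, ops = reference
        dim = ops.dim
        coh = ops.electron[0]["x"].astype(complex)  # S1x coherence pattern
        for name, r in _channels(inputs, ops).items():
            prop = scipy.linalg.expm(-r.matrix * 2.0)
            norms = [np.linalg.norm(coh)]
            v = vec(coh)
            for _ in range(5):
                v = prop @ v
                norms.append(np.linalg.norm(unvec(v)))
            diffs = np.diff(norms)
            assert np.all(diffs <= 1e-12), name
            assert norms[-1] < norms[0], name  # strict decay overall

    def test_channel_additivity(self, reference):
        spec, inputs, ops = reference
        chans = _channels(inputs, ops)
        h = ls.build_hamiltonian(spec.with_field(50.0), ops)
        k = ls.reaction_superoperator(spec, ls.singlet_triplet_projectors(spec)[0])
        l_all = ls.assemble_liouvillian(h, k, list(chans.values()))
        l_none = ls.assemble_liouvillian(h, k, [])
        total = sum(c.matrix for c in chans.values())
        np.testing.assert_allclose(l_all.matrix - l_none.matrix, total, atol=1e-14)

    def test_linearity_in_covariance_scale(self, reference):
        spec, inputs, ops = reference
        r1 = hyperfine_redfield(inputs, ops)
        scaled = RelaxationInputs(
            hyperfine_models=tuple(
                {p: single_mode_model(3.0 * m.prefactor, 0.92, p) for p, m in models.items()}
                for models in inputs.hyperfine_models
            ),
            g_models=inputs.g_models,
            tau_rot_ns=inputs.tau_rot_ns,
            delta_g=inputs.delta_g,
        )
        r3 = hyperfine_redfield(scaled, ops)
        np.testing.assert_allclose(r3.matrix, 3.0 * r1.matrix, atol=1e-14)


class TestHyperfineChannel:
    def test_zero_prefactors_give_zero_superoperator(self, reference):
        _, inputs, ops = reference
        zeroed = RelaxationInputs(
            hyperfine_models=tuple(
                {p: single_mode_model(0.0, 1.0, p) for p in models}
                for models in inputs.hyperfine_models
            ),
            g_models=(None, None),
        )
        r = hyperfine_redfield(zeroed, ops)
        np.testing.assert_allclose(r.matrix, 0.0, atol=1e-15)

    def test_missing_pair_error_names_pair(self, reference):
        spec, _, ops = reference
        models = {
            ("xx", "xx"): single_mode_model(1e-4, 1.0, ("xx", "xx")),
            ("yy", "yy"): single_mode_model(1e-4, 1.0, ("yy", "yy")),
        }
        with pytest.raises(ValueError, match=r"\(xx,yy\)"):
            hyperfine_redfield(RelaxationInputs(hyperfine_models=(models, None)), ops)

    def test_two_spin_dephasing_closed_form(self):
        """Pure zz fluctuation on one electron-nucleus pair: every coherence
        between eigenstates of A = Iz Sz decays at J0 (a_i - a_j)^2."""
        import scipy.linalg

        j0_target = 0.02  # rad^2/ns * ns
        cov, tau = 0.02 / 0.881, 0.881  # grid point near 1 ns
        nuc = ls.NucleusSpec("H", 0.5, np.zeros((3, 3)))
        rad = ls.RadicalSpec.isotropic(2.0, (nuc,))
        spec = ls.SpinSystemSpec(rad, ls.RadicalSpec.isotropic(2.0), k_st=0.01)
        ops = ls.build_spin_operators(spec)
        model = single_mode_model(cov, tau, ("zz", "zz"))
        j0 = model.prefactor * model.lag_grid_ns[np.argmax(model.weights)]
        inputs = RelaxationInputs(hyperfine_models=({("zz", "zz"): model}, None))
        r = hyperfine_redfield(inputs, ops)
        # independent oracle: eigenvalues of Iz Sz give analytic rates
        a_op = ops.nuclear[0][0]["z"] @ ops.electron[0]["z"]
        evals = np.diag(a_op).real  # diagonal in the product basis
        prop = scipy.linalg.expm(-r.matrix * 1.0)
        d = ops.dim
        for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
            coh = np.zeros((d, d), dtype=complex)
            coh[i, j] = 1.0
            evolved = unvec(prop @ vec(coh))
            rate_expected = j0 * (evals[i] - evals[j]) ** 2
            assert abs(evolved[i, j]) == pytest.approx(np.exp(-rate_expected), rel=0.05)

    def test_eigenbasis_mode_with_trivial_hamiltonian_matches_j0(self, reference):
        spec, inputs, ops = reference
        h0 = ls.Operator(np.zeros((ops.dim, ops.dim)), "hamiltonian")
        r_zero = hyperfine_redfield(inputs, ops)
        r_eig = hyperfine_redfield(inputs, ops, h0, mode="eigenbasis")
        np.testing.assert_allclose(r_eig.matrix, r_zero.matrix, atol=1e-12)

    def test_eigenbasis_mode_suppresses_fast_transitions(self, reference):
        # at a transition frequency w with (w tau) >> 1 the Lorentzian J(w)
        # is much smaller than J(0): eigenbasis relaxation must be weaker
        spec, inputs, ops = reference
        h = ls.build_hamiltonian(spec.with_field(100.0), ops)
        r0 = hyperfine_redfield(inputs, ops)
        re = hyperfine_redfield(inputs, ops, h, mode="eigenbasis")
        assert np.linalg.norm(re.matrix) < np.linalg.norm(r0.matrix)


class TestGChannel:
    def test_zero_field_gives_zero_superoperator(self, reference):
        _, inputs, ops = reference
        r = g_redfield(inputs, 0.0, ops)
        np.testing.assert_allclose(r.matrix, 0.0, atol=1e-15)

    def test_bz_squared_scaling(self, reference):
        _, inputs, ops = reference
        r1 = g_redfield(inputs, 10.0, ops)
        r2 = g_redfield(inputs, 20.0, ops)
        np.testing.assert_allclose(r2.matrix, 4.0 * r1.matrix, atol=1e-12)

    def test_transverse_field_rejected(self, reference):
        _, inputs, ops = reference
        with pytest.raises(ValueError, match="z only"):
            g_redfield(inputs, 10.0, ops, bx_mT=1.0)

    def test_pure_dephasing_closed_form(self):
        """Pure zz g-fluctuation: transverse electron coherence decays at
        (mu_B Bz / hbar)^2 J0."""
        import scipy.linalg

        bz = 30.0
        cov, tau = 1e-4, 1.129
        rad = ls.RadicalSpec.isotropic(2.0)
        spec = ls.SpinSystemSpec(rad, rad, k_st=0.01)
        ops = ls.build_spin_operators(spec)
        model = single_mode_model(cov, tau, ("zz", "zz"))
        j0 = model.prefactor * model.lag_grid_ns[np.argmax(model.weights)]
        inputs = RelaxationInputs(g_models=({("zz", "zz"): model}, None))
        r = g_redfield(inputs, bz, ops)
        rate_expected = (CONSTANTS.gamma_mT * bz) ** 2 * j0
        coh = np.zeros((4, 4), dtype=complex)
        coh[0, 2] = 1.0  # |up>< down| on electron 1 (m_s difference 1)
        evolved = unvec(scipy.linalg.expm(-r.matrix * 1.0) @ vec(coh))
        assert abs(evolved[0, 2]) == pytest.approx(np.exp(-rate_expected), rel=0.05)


class TestSpinRotational:
    def test_rate_arithmetic(self):
        assert spin_rotational_rate(np.zeros(3), 1.0) == 0.0
        rate = spin_rotational_rate(np.array([1e-3, 1e-3, 1e-3]), 1.0)
        assert rate == pytest.approx(3e-6 / 9.0, rel=1e-12)  # ~333 /s
        assert rate * 1e9 == pytest.approx(333.3, rel=1e-3)
        assert spin_rotational_rate(np.array([1e-3, 1e-3, 1e-3]), 2.0) == pytest.approx(rate / 2)

    def test_invalid_inputs(self, reference):
        *_, ops = reference
        with pytest.raises(ValueError):
            spin_rotational_rate(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            spin_rotational_superoperator(-0.1, ops)

    def test_zero_rate_zero_superoperator(self, reference):
        *_, ops = reference
        r = spin_rotational_superoperator(0.0, ops)
        np.testing.assert_allclose(r.matrix, 0.0, atol=1e-15)

    def test_identity_stationary_via_spin_algebra(self, reference):
        # sum_k S_k rho S_k applied to the identity gives 3/4 per electron,
        # cancelling the 3/2 rho term exactly
        *_, ops = reference
        r = spin_rotational_superoperator(0.5, ops)
        ident = np.eye(ops.dim, dtype=complex)
        assert np.linalg.norm(unvec(r.matrix @ vec(ident))) < 1e-12


class TestChannelOrdering:
    def test_g_channel_dominates_at_high_field(self):
        """With near-1-ns correlation times, the Bz^2-scaled g channel moves
        the triplet yield far more than hyperfine or spin-rotational
        relaxation at 10 mT and above (lifetime 1 us)."""
        from lipidspin.pipeline import ScanConfig, run_field_scan

        spec, inputs = reference_system(k_st_per_s=1e6)
        cfg = ScanConfig(
            spec=spec, relaxation=inputs,
            fields_mT=np.array([10.0, 31.6, 100.0]),
            kst_per_s=(1e6,),
            channel_sets=("static", "hf", "g", "sr", "all"),
        )
        res = run_field_scan(cfg)
        for bz in (10.0, 31.6, 100.0):
            rows = {
                cs: float(res.series(1e6, cs).set_index("Bz_mT").phi_T.loc[bz])
                for cs in ("static", "hf", "g", "sr", "all")
            }
            dev_g = abs(rows["g"] - rows["static"])
            assert dev_g > abs(rows["hf"] - rows["static"])
            assert dev_g > abs(rows["sr"] - rows["static"])
            # all-channel result is dominated by the g channel
            assert abs(rows["all"] - rows["g"]) < abs(rows["static"] - rows["all"])
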