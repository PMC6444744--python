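"""Parameter inference: gap removal, slope estimate, beta fit, recovery."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import radbundle as rb


def synthetic_stiffness(geom, deg, kin, schedule, device, noise=None, seed=None):
    trace = rb.simulate_trace(
        device, geom, kin, deg, schedule,
        noise=noise or rb.NoiseModel(0.0, 0.0, 0.0), seed=seed,
    )
    return rb.concatenate_irradiation(trace, schedule, device)


class TestConcatenateIrradiation:
    def test_single_window_is_identity_retiming(self, device):
        sched = rb.IrradiationSchedule((rb.Session(0.0, 10.0, 30.0),))
        t = np.arange(0.0, 10.0)
        F = np.full_like(t, 1002.0)
        trace = pd.DataFrame({"t": t, "F": F, "Q": np.full_like(t, 300.0)})
        st = rb.concatenate_irradiation(trace, sched, device)
        np.testing.assert_allclose(st.t, t)

    def test_four_session_protocol_spans_beam_on_time(self, device, geom, kin,
                                                      deg, schedule):
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        assert schedule.beam_on_time == 840.0
        assert st.t[0] == 0.0
        assert st.t[-1] < 840.0 <= st.t[-1] + 1.0  # 1 Hz sampling
        # gaps removed: beam-on axis has no 180 s discontinuities
        assert np.max(np.diff(st.t)) <= 1.0 + 1e-9

    def test_gap_samples_are_excluded(self, device):
        sched = rb.IrradiationSchedule((rb.Session(0.0, 5.0, 30.0),
                                        rb.Session(10.0, 5.0, 30.0)))
        trace = pd.DataFrame(
            {"t": [2.0, 7.0, 11.0], "F": [1002.0] * 3, "Q": [300.0] * 3}
        )
        st = rb.concatenate_irradiation(trace, sched, device)
        np.testing.assert_allclose(st.t, [2.0, 6.0])  # 7 s sample dropped

    def test_empty_overlap_raises(self, device):
        sched = rb.IrradiationSchedule((rb.Session(100.0, 10.0, 30.0),))
        trace = pd.DataFrame({"t": [0.0, 1.0], "F": [1002.0] * 2,
                              "Q": [300.0] * 2})
        with pytest.raises(ValueError, match="no trace samples"):
            rb.concatenate_irradiation(trace, sched, device)


class TestEstimatePhib:
    def test_noiseless_reference_trace_gives_phi_b(self, device, geom, kin,
                                                   deg, schedule):
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        phib = rb.estimate_phib(st, geom, window=20.0)
        assert phib == pytest.approx(0.7, rel=0.01)

    def test_constant_trace_gives_zero(self, geom):
        st = rb.StiffnessTrace(t=np.arange(30.0), k_eff=np.full(30, 0.1344))
        assert rb.estimate_phib(st, geom) == pytest.approx(0.0, abs=1e-12)

    def test_scaling_with_molecule_stiffness(self, device, geom, kin, deg,
                                             schedule):
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        half = rb.BundleGeometry(M=geom.M, E=geom.E / 2, R=geom.R, l=geom.l,
                                 A=geom.A)
        assert rb.estimate_phib(st, half, window=20.0) == pytest.approx(
            2 * rb.estimate_phib(st, geom, window=20.0)
        )

    def test_too_few_samples_raise(self, geom):
        st = rb.StiffnessTrace(t=np.arange(3.0), k_eff=np.full(3, 0.1))
        with pytest.raises(ValueError, match="5 samples"):
            rb.estimate_phib(st, geom, window=20.0)


class TestFitBeta:
    def test_noiseless_self_consistency(self, device, geom, kin, deg, schedule):
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        res = rb.fit_beta(st, geom, phib=0.7, b=1.0)
        assert res.converged
        assert res.beta_hat == pytest.approx(8.1e-7, rel=1e-6)

    def test_free_k0_mode(self, device, geom, kin, deg, schedule):
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        res = rb.fit_beta(st, geom, phib=0.7, b=1.0, fix_k0=False)
        assert res.converged
        assert res.k0 == pytest.approx(0.1344, rel=1e-4)
        assert res.beta_hat == pytest.approx(8.1e-7, rel=1e-4)

    def test_short_trace_flags_weak_identifiability(self, device, geom, kin,
                                                    deg):
        # 40 s of beam-on: b*sqrt(beta)*T = 0.036 << 1, no saturation visible
        sched = rb.IrradiationSchedule((rb.Session(0.0, 40.0, 30.0),))
        st = synthetic_stiffness(geom, deg, kin, sched, device,
                                 noise=rb.NoiseModel(0.002, 0.002, 0.0), seed=1)
        with pytest.warns(UserWarning, match="weakly identified"):
            res = rb.fit_beta(st, geom, phib=0.7, b=1.0)
        assert res.stderr_beta > 0.5 * res.beta_hat

    def test_invalid_inputs_raise(self, geom):
        st = rb.StiffnessTrace(t=np.arange(10.0), k_eff=np.full(10, 0.1))
        with pytest.raises(ValueError):
            rb.fit_beta(st, geom, phib=0.0, b=1.0)
        with pytest.raises(ValueError):
            rb.fit_beta(st, geom, phib=0.7, b=0.0)


class TestModelFit:
    def test_two_step_with_refinement_recovers_noiseless_parameters(
        self, device, geom, deg, schedule
    ):
        """On noiseless traces the pipeline recovers (phi*b, beta) to solver
        tolerance across operating points with b*sqrt(beta)*T in [0.5, 5]."""
        rng = np.random.default_rng(17)
        T = schedule.beam_on_time
        for _ in range(5):
            target = rng.uniform(0.5, 5.0)
            b = 1.0
            beta = (target / (b * T)) ** 2
            kin = rb.KineticsParams(b=b, beta=beta)
            st = synthetic_stiffness(geom, deg, kin, schedule, device)
            res = rb.BundleDegradationModel(st, geom, b=b).fit(refine=True)
            assert res.converged
            assert res.phib == pytest.approx(0.7, rel=1e-6)
            assert res.beta == pytest.approx(beta, rel=1e-6)

    def test_from_resonance_constructor(self, device, geom, kin, deg, schedule):
        trace = rb.simulate_trace(device, geom, kin, deg, schedule,
                                  noise=rb.NoiseModel(0, 0, 0))
        model = rb.BundleDegradationModel.from_resonance(
            trace, schedule, device, geom
        )
        res = model.fit()
        assert res.beta == pytest.approx(8.1e-7, rel=1e-4)

    def test_summary_and_diagnostics(self, device, geom, kin, deg, schedule):
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        res = rb.BundleDegradationModel(st, geom).fit()
        text = res.summary()
        for token in ("phi*b", "beta", "saturation breaks", "converged"):
            assert token in text
        assert len(res.resid) == len(st)
        assert np.max(np.abs(res.resid)) < 1e-8
        d = res.to_dict()
        assert d["n_obs"] == len(st)
        assert d["saturation_breaks"] == pytest.approx(
            1.0 / math.sqrt(res.beta)
        )

    def test_plot_fit_returns_axes(self, device, geom, kin, deg, schedule):
        import matplotlib

        matplotlib.use("Agg")
        st = synthetic_stiffness(geom, deg, kin, schedule, device)
        res = rb.BundleDegradationModel(st, geom).fit()
        ax = res.plot_fit()
        assert ax.get_xlabel().startswith("cumulative")


class TestRecoveryExperiment:
    def test_noiseless_recovery_has_negligible_bias(self, device, geom, kin,
                                                    deg, schedule):
        df = rb.recovery_experiment(kin, deg, geom, device, schedule,
                                    noise_sd=0.0, replicates=2, seed=0)
        s = df.attrs["summary"]
        assert abs(s["beta"]["bias"]) / kin.beta < 1e-5
        assert abs(s["phib"]["bias"]) / 0.7 < 1e-5

    def test_deterministic_under_seed(self, device, geom, kin, deg, schedule):
        a = rb.recovery_experiment(kin, deg, geom, device, schedule,
                                   noise_sd=0.01, replicates=3, seed=5)
        b = rb.recovery_experiment(kin, deg, geom, device, schedule,
                                   noise_sd=0.01, replicates=3, seed=5)
        np.testing.assert_allclose(a["beta_hat"], b["beta_hat"])

    def test_rmse_shrinks_with_trace_length(self, device, geom, kin, deg):
        """Estimator consistency: longer traces at fixed noise give lower
        RMSE on beta."""
        short = rb.make_schedule(1, 210.0, 0.0, 30.0)
        full = rb.make_schedule(4, 210.0, 180.0, 30.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_short = rb.recovery_experiment(kin, deg, geom, device, short,
                                             noise_sd=0.01, replicates=10,
                                             seed=8)
            r_full = rb.recovery_experiment(kin, deg, geom, device, full,
                                            noise_sd=0.01, replicates=10,
                                            seed=8)
        assert (
            r_full.attrs["summary"]["beta"]["rmse"]
            < r_short.attrs["summary"]["beta"]["rmse"]
        )


def test_stiffness_trace_validation():
    with pytest.raises(ValueError):
        rb.StiffnessTrace(t=np.array([0.0, 1.0]), k_eff=np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        rb.StiffnessTrace(t=np.array([1.0, 0.0]), k_eff=np.array([1.0, 1.0]))
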