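import numpy as np
import pytest
from scipy import stats

from lovfret.fitting import (
    CycleTraceSet,
    DegenerateControlError,
    FitResult,
    InsufficientDataError,
    InvalidComparisonError,
    ProtocolMismatchError,
    fit_cycle_exponentials,
    fit_dark_relaxation,
    fit_global_switch,
    fit_reversible_dose_series,
    fit_single_site,
    holm_sidak,
    nested_f_test,
    normalize_to_control,
    two_stage_relaxation,
)
from lovfret.photocycle import (
    PhotocycleParams,
    TraceModelParams,
    dose_series_trace,
)
from lovfret.synth import CycleProtocol, GeneratorSpec, gen_cycle_traces


def _noise_free_traces(truth, **kw):
    spec = GeneratorSpec(truth=truth, noise_sd=0.0, bleach_per_reading=0.0,
                         n_replicates=1, seed=0, **kw)
    return gen_cycle_traces(spec)


class TestNormalization:
    def test_self_normalization(self, mtq2_optones):
        ts = _noise_free_traces(mtq2_optones)
        ts.control_intensity = ts.intensity.copy()
        norm = normalize_to_control(ts)
        first = norm.intensity[0]
        assert np.allclose(norm.intensity, 1.0)
        assert first == pytest.approx(1.0)
        assert norm.normalized

    def test_bleach_cancellation(self, mtq2_optones):
        spec = GeneratorSpec(truth=mtq2_optones, noise_sd=0.003,
                             bleach_per_reading=0.002, n_replicates=3, seed=11)
        noisy = gen_cycle_traces(spec)
        clean = _noise_free_traces(mtq2_optones)
        norm = normalize_to_control(noisy)
        from lovfret.fitting import average_replicates

        avg = average_replicates(norm)
        # residual trend vs the bleach-free model, per reading
        anchor = clean.intensity[0]
        resid = avg.intensity - clean.intensity / anchor
        k = np.arange(len(resid))
        slope = np.polyfit(k, resid, 1)[0]
        assert abs(slope) < 5e-4

    def test_missing_control(self, mtq2_optones):
        ts = _noise_free_traces(mtq2_optones)
        ts.control_intensity = None
        with pytest.raises(DegenerateControlError):
            normalize_to_control(ts)

    def test_zero_control_value(self, mtq2_optones):
        ts = _noise_free_traces(mtq2_optones)
        ts.control_intensity = np.ones(len(ts.intensity))
        ts.control_intensity[5] = 0.0
        with pytest.raises(DegenerateControlError):
            normalize_to_control(ts)


class TestCsvRoundTrip:
    def test_dataframe_round_trip(self, mtq2_optones, tmp_path):
        import pandas as pd

        spec = GeneratorSpec(truth=mtq2_optones, noise_sd=0.004,
                             bleach_per_reading=0.002, n_replicates=2, seed=1)
        ts = gen_cycle_traces(spec)
        path = tmp_path / "traces.csv"
        ts.to_dataframe(construct="optoNES").to_csv(path, index=False)
        back = CycleTraceSet.from_dataframe(pd.read_csv(path))
        assert np.allclose(back.intensity, ts.intensity)
        assert np.allclose(back.control_intensity, ts.control_intensity)
        assert np.allclose(back.dark_times, ts.dark_times)
        assert back.dose_per_flash == ts.dose_per_flash

    def test_missing_columns(self):
        import pandas as pd

        with pytest.raises(ProtocolMismatchError):
            CycleTraceSet.from_dataframe(pd.DataFrame({"intensity_au": [1, 2, 3]}))


class TestCycleExponentialsFit:
    def test_zero_noise_exact(self):
        # exact per-cycle exponential data
        rng = np.random.default_rng(0)
        tau, f_limit = 8.0, 1.0
        amps = np.array([0.02, 0.05, 0.1, 0.15, 0.19])
        x = np.arange(20)
        cyc, read, y = [], [], []
        for c, a in enumerate(amps):
            cyc.extend([c] * len(x))
            read.extend(x)
            y.extend(f_limit - a * np.exp(-x / tau))
        ts = CycleTraceSet(
            cycle_index=np.array(cyc), reading_index=np.array(read),
            intensity=np.array(y), dark_times=np.array([600, 1, 5, 20, 180]),
            dose_per_flash=14.0, normalized=True,
        )
        fit = fit_cycle_exponentials(ts)
        assert fit.value("tau_flashes") == pytest.approx(tau, rel=1e-8)
        assert fit.value("F_limit") == pytest.approx(f_limit, rel=1e-8)
        for c, a in enumerate(amps):
            assert fit.value(f"A[{c}]") == pytest.approx(a, rel=1e-7)

    def test_noisy_recovery(self, mtq2_optones):
        spec = GeneratorSpec(truth=mtq2_optones, noise_sd=0.003,
                             bleach_per_reading=0.0, n_replicates=3, seed=1)
        ts = gen_cycle_traces(spec)
        fit = fit_cycle_exponentials(ts)
        # ground-truth tau in flashes: k_app/flash_rate per flash
        k_app = 56 / 162 + 1 / 6.8
        tau_true = 4.0 / k_app
        assert fit.value("tau_flashes") == pytest.approx(tau_true, rel=0.05)

    def test_single_cycle_flagged(self):
        x = np.arange(20)
        y = 1.0 - 0.2 * np.exp(-x / 6.0)
        ts = CycleTraceSet(
            cycle_index=np.zeros(20, dtype=int), reading_index=x, intensity=y,
            dark_times=np.array([600.0]), dose_per_flash=14.0, normalized=True,
        )
        fit = fit_cycle_exponentials(ts, drop_first=True)
        assert "single_cycle" in fit.flags
        assert fit.value("tau_flashes") == pytest.approx(6.0, rel=1e-6)


class TestDarkRelaxationFit:
    def test_exact_recovery(self):
        t = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 60.0, 180.0])
        a = 0.19 * (1 - np.exp(-t / 6.8))
        fit = fit_dark_relaxation(t, a)
        assert fit.value("A0") == pytest.approx(0.19, rel=1e-8)
        assert fit.value("r") == pytest.approx(6.8, rel=1e-8)
        assert fit.derived["max_dequench_pct"][0] == pytest.approx(15.97, abs=0.01)

    def test_noisy_median_error(self):
        t = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 60.0, 180.0])
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = 0.19 * (1 - np.exp(-t / 6.8)) + rng.normal(0, 0.05 * 0.19, len(t))
            fit = fit_dark_relaxation(t, a)
            errors.append(abs(fit.value("r") - 6.8) / 6.8)
        assert np.median(errors) < 0.10

    def test_insufficient_dark_times(self):
        with pytest.raises(InsufficientDataError):
            fit_dark_relaxation([1.0, 1.0, 1.0], [0.1, 0.1, 0.1])

    def test_non_identifiable(self):
        fit = fit_dark_relaxation([1.0, 5.0, 20.0, 60.0], [0.1, 0.1, 0.1, 0.1])
        assert "non_identifiable" in fit.flags
        assert not fit.converged


class TestGlobalSwitchFit:
    def test_zero_noise_exact_donor(self, mtq2_optones):
        ts = _noise_free_traces(mtq2_optones)
        fit = fit_global_switch(ts)
        assert fit.value("transfer_limit") == pytest.approx(0.189, rel=1e-6)
        assert fit.value("sensitivity") == pytest.approx(162.0, rel=1e-6)
        assert fit.value("r") == pytest.approx(6.8, rel=1e-6)

    def test_zero_noise_exact_acceptor(self, ypet_optones):
        proto = CycleProtocol(dose_per_flash=140.0)
        ts = _noise_free_traces(ypet_optones, protocol=proto)
        fit = fit_global_switch(ts, mode="acceptor")
        assert fit.value("transfer_limit") == pytest.approx(0.535, rel=1e-6)
        assert fit.value("sensitivity") == pytest.approx(559.0, rel=1e-6)
        assert fit.value("r") == pytest.approx(8.0, rel=1e-6)

    def test_noisy_recovery_donor(self, mtq2_optones):
        spec = GeneratorSpec(truth=mtq2_optones, noise_sd=0.005,
                             bleach_per_reading=0.002, n_replicates=3, seed=42)
        fit = fit_global_switch(normalize_to_control(gen_cycle_traces(spec)))
        assert fit.value("transfer_limit") == pytest.approx(0.189, rel=0.10)
        assert fit.value("sensitivity") == pytest.approx(162.0, rel=0.10)
        assert fit.value("r") == pytest.approx(6.8, rel=0.10)
        assert fit.value("offset") > 0

    def test_noisy_recovery_acceptor(self, ypet_optones):
        proto = CycleProtocol(dose_per_flash=140.0)
        spec = GeneratorSpec(truth=ypet_optones, protocol=proto, noise_sd=0.005,
                             bleach_per_reading=0.002, n_replicates=3, seed=7)
        fit = fit_global_switch(normalize_to_control(gen_cycle_traces(spec)),
                                mode="acceptor")
        assert fit.value("transfer_limit") == pytest.approx(0.535, rel=0.10)
        assert fit.value("sensitivity") == pytest.approx(559.0, rel=0.10)
        assert fit.value("r") == pytest.approx(8.0, rel=0.10)

    def test_derived_ed50_consistency(self, mtq2_optones):
        from lovfret.photocycle import ed50

        ts = _noise_free_traces(mtq2_optones)
        fit = fit_global_switch(ts)
        fitted = PhotocycleParams(
            sensitivity=fit.value("sensitivity"),
            relaxation_time=fit.value("r"),
            transfer_limit=fit.value("transfer_limit"),
        )
        assert fit.derived["ed50_umol_m2_per_flash"][0] == ed50(
            fitted, ts.flash_rate
        )


class TestTwoStageVsGlobal:
    def test_relaxation_estimates_agree(self, mtq2_optones):
        for seed in (1, 2, 3, 4, 5):
            spec = GeneratorSpec(truth=mtq2_optones, noise_sd=0.005,
                                 bleach_per_reading=0.0, n_replicates=3, seed=seed)
            ts = gen_cycle_traces(spec)
            _, stage2 = two_stage_relaxation(ts)
            glob = fit_global_switch(ts)
            r1, se1 = stage2.params["r"]
            r2, se2 = glob.params["r"]
            joint = np.hypot(se1, se2)
            assert abs(r1 - r2) <= 2.5 * joint


class TestReversibleDoseSeries:
    @staticmethod
    def _curves(truth, doses, n=50, offset=1.0):
        x = np.arange(n)
        out = []
        for d in doses:
            m = TraceModelParams(truth, offset=offset, flash_rate=4.0,
                                 dose_per_flash=d)
            out.append((x, np.asarray(dose_series_trace(m, x))))
        return out

    def test_zero_noise_exact(self):
        truth = PhotocycleParams(200.0, 5.0, 0.2, "donor")
        doses = [14.0, 42.0, 140.0, 420.0]
        fit = fit_reversible_dose_series(self._curves(truth, doses), doses)
        assert fit.value("sensitivity") == pytest.approx(200.0, rel=1e-7)
        assert fit.value("r") == pytest.approx(5.0, rel=1e-7)
        assert fit.value("transfer_limit") == pytest.approx(0.2, rel=1e-7)
        assert fit.derived["inv_k1_umol_m2"][0] == fit.value("sensitivity")

    def test_noisy_recovery(self):
        truth = PhotocycleParams(200.0, 5.0, 0.2, "donor")
        doses = [14.0, 42.0, 140.0, 420.0]
        curves = []
        rng = np.random.default_rng(3)
        for x, y in self._curves(truth, doses):
            curves.append((x, y + rng.normal(0, 0.004, len(y))))
        fit = fit_reversible_dose_series(curves, doses)
        assert fit.value("sensitivity") == pytest.approx(200.0, rel=0.10)
        assert fit.value("r") == pytest.approx(5.0, rel=0.10)

    def test_drop_first(self):
        truth = PhotocycleParams(200.0, 5.0, 0.2, "donor")
        doses = [14.0, 42.0, 140.0]
        curves = []
        for x, y in self._curves(truth, doses):
            y = y.copy()
            y[0] *= 1.05  # systematic first-reading artefact
            curves.append((x, y))
        fit = fit_reversible_dose_series(curves, doses, drop_first=True)
        assert fit.value("sensitivity") == pytest.approx(200.0, rel=1e-6)

    def test_too_few_doses(self):
        truth = PhotocycleParams(200.0, 5.0, 0.2, "donor")
        doses = [14.0, 42.0]
        with pytest.raises(InsufficientDataError):
            fit_reversible_dose_series(self._curves(truth, doses), doses)


class TestSingleSite:
    def test_exact(self):
        x = np.array([14.0, 42.0, 140.0, 420.0])
        y = 10.0 / (1 + 100.0 / x)
        fit = fit_single_site(x, y)
        assert fit.value("a") == pytest.approx(10.0, rel=1e-8)
        assert fit.value("b") == pytest.approx(100.0, rel=1e-8)

    def test_half_response_at_ed50(self):
        x = np.array([10.0, 50.0, 100.0, 400.0, 1600.0])
        y = 8.0 / (1 + 100.0 / x)
        fit = fit_single_site(x, y)
        a, b = fit.value("a"), fit.value("b")
        assert a / (1 + b / b) == pytest.approx(a / 2)

    def test_shared_max_groups_and_f_test(self):
        x = np.array([14.0, 42.0, 140.0, 420.0])
        rng = np.random.default_rng(9)
        rows_x, rows_y, grp = [], [], []
        for rep in range(6):
            for g, b in (("g1", 48.0), ("g2", 140.0)):
                rows_x.extend(x)
                rows_y.extend(10.0 / (1 + b / x) + rng.normal(0, 0.2, len(x)))
                grp.extend([g] * len(x))
        full = fit_single_site(rows_x, rows_y, groups=grp, shared_max=True)
        assert full.value("b[g1]") == pytest.approx(48.0, rel=0.10)
        assert full.value("b[g2]") == pytest.approx(140.0, rel=0.10)
        # restricted: one shared b for both groups
        restricted = fit_single_site(rows_x, rows_y)
        F, df1, df2, p = nested_f_test(restricted, full)
        assert p < 0.01

    def test_all_zero_degenerate(self):
        from lovfret.fitting import DegenerateFitError

        with pytest.raises(DegenerateFitError):
            fit_single_site([1.0, 2.0, 4.0], [0.0, 0.0, 0.0])


class TestNestedFTest:
    def test_arithmetic(self):
        fr = FitResult("m", {}, dof=10, ssr=10.0, n_points=12, converged=True)
        ff = FitResult("m", {}, dof=9, ssr=8.0, n_points=12, converged=True)
        F, df1, df2, p = nested_f_test(fr, ff)
        assert F == pytest.approx(2.25)
        assert (df1, df2) == (1, 9)
        assert p == pytest.approx(stats.f.sf(2.25, 1, 9), rel=1e-12)
        assert p == pytest.approx(0.168, abs=0.001)

    def test_identical_fits(self):
        fr = FitResult("m", {}, dof=10, ssr=5.0, n_points=12, converged=True)
        ff = FitResult("m", {}, dof=9, ssr=5.0, n_points=12, converged=True)
        F, _, _, p = nested_f_test(fr, ff)
        assert F == 0.0
        assert p == 1.0

    def test_non_nested_rejected(self):
        fr = FitResult("m", {}, dof=9, ssr=10.0, n_points=12, converged=True)
        ff = FitResult("m", {}, dof=10, ssr=8.0, n_points=12, converged=True)
        with pytest.raises(InvalidComparisonError):
            nested_f_test(fr, ff)
        with pytest.raises(InvalidComparisonError):
            nested_f_test(
                FitResult("m", {}, dof=10, ssr=5.0, n_points=12, converged=True),
                FitResult("m", {}, dof=9, ssr=7.0, n_points=12, converged=True),
            )

    def test_scale_invariance(self):
        # rescaling all intensities by c scales both ssr by c² — F unchanged
        fr = FitResult("m", {}, dof=10, ssr=10.0, n_points=12, converged=True)
        ff = FitResult("m", {}, dof=9, ssr=8.0, n_points=12, converged=True)
        c = 3.7
        fr2 = FitResult("m", {}, dof=10, ssr=10.0 * c**2, n_points=12, converged=True)
        ff2 = FitResult("m", {}, dof=9, ssr=8.0 * c**2, n_points=12, converged=True)
        assert nested_f_test(fr, ff)[0] == pytest.approx(
            nested_f_test(fr2, ff2)[0], rel=1e-12
        )


class TestHolmSidak:
    def test_single_p(self):
        adj, rej = holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_zeros(self):
        adj, _ = holm_sidak([0.0, 0.0])
        assert np.allclose(adj, 0.0)

    def test_hand_computed(self):
        adj, rej = holm_sidak([0.01, 0.04], alpha=0.05)
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)
        assert rej.all()

    def test_order_preserved(self):
        adj, _ = holm_sidak([0.04, 0.01])
        assert adj[0] == pytest.approx(0.04)
        assert adj[1] == pytest.approx(1 - 0.99**2)

    def test_monotone_enforced(self):
        adj, _ = holm_sidak([0.02, 0.021, 0.4])
        assert np.all(np.diff(adj) >= 0)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])
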