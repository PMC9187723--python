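"""MyoII kinetics: model evaluation, fitting, decomposition, synchronisation."""

import numpy as np
import pandas as pd
import pytest

from furrowshell.myosin_model import (
    CONFOCAL_RATE_FACTOR,
    IntensityModelParams,
    RowProfile,
    decompose_signal,
    eval_intensity,
    fit_intensity,
    prestress_schedule,
    synchronize_time,
)
from furrowshell.synthetic_data import (
    GeneratorSpec,
    default_row_profile_values,
    generate_tracking_table,
)

CONFOCAL = IntensityModelParams(i_c=4.0, amplitude=1.0, t_onset=0.0, tau=20.0)


class TestEvalIntensity:
    def test_onset_value_is_constant_signal(self):
        # inner exponent vanishes at t0, so I(t0) = I_c = 4 arb exactly
        assert eval_intensity(CONFOCAL, 0.0) == 4.0
        other = IntensityModelParams(i_c=7.5, amplitude=3.0, t_onset=-12.0, tau=5.0)
        assert eval_intensity(other, -12.0) == 7.5

    def test_early_time_limit(self):
        # t -> -inf: I_c - I (1 - e^-1)
        limit = 4.0 - (1.0 - np.exp(-1.0))
        assert eval_intensity(CONFOCAL, -1e5) == pytest.approx(limit, abs=1e-12)

    def test_monotone_increasing_after_onset(self):
        t = np.linspace(0, 40, 100)
        assert (np.diff(eval_intensity(CONFOCAL, t)) > 0).all()

    def test_overflow_guard(self):
        with pytest.raises(ValueError, match="overflow"):
            eval_intensity(CONFOCAL, 1e4)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            IntensityModelParams(tau=0.0)
        with pytest.raises(ValueError):
            IntensityModelParams(amplitude=-1.0)


class TestFitIntensity:
    def test_noiseless_roundtrip_recovers_all_parameters(self):
        t = np.linspace(-30, 15, 60)
        y = eval_intensity(CONFOCAL, t)
        fit, cost = fit_intensity(t, y)
        assert fit.i_c == pytest.approx(4.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.t_onset == pytest.approx(0.0, abs=1e-6)
        assert fit.tau == pytest.approx(20.0, rel=1e-6)
        assert cost < 1e-12

    def test_roundtrip_other_parameters(self):
        truth = IntensityModelParams(i_c=2.5, amplitude=0.7, t_onset=-6.0, tau=9.0)
        t = np.linspace(-25, 12, 80)
        fit, _ = fit_intensity(t, eval_intensity(truth, t))
        np.testing.assert_allclose(fit.as_array(), truth.as_array(), rtol=1e-6, atol=1e-6)

    def test_constant_series_gives_zero_amplitude(self):
        t = np.linspace(0, 10, 20)
        fit, _ = fit_intensity(t, np.full_like(t, 5.0))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert fit.i_c == pytest.approx(5.0, rel=1e-6)

    def test_noisy_tau_within_five_percent(self):
        # densely pooled sampling (many tracked cells over the full rise)
        t = np.linspace(-20, 30, 2000)
        y = eval_intensity(CONFOCAL, t)
        rng = np.random.default_rng(0)
        y_noisy = y * rng.lognormal(0.0, 0.02, size=y.shape)
        fit, _ = fit_intensity(t, y_noisy)
        assert fit.tau == pytest.approx(20.0, rel=0.05)

    def test_deterministic(self):
        t = np.linspace(-20, 20, 50)
        y = eval_intensity(CONFOCAL, t) + 0.01 * np.sin(t)
        f1, c1 = fit_intensity(t, y)
        f2, c2 = fit_intensity(t, y)
        assert f1 == f2 and c1 == c2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_intensity([0, 1, 2], [4, 4, 4])


class TestDecomposeSignal:
    def _table(self, profile_values, g, times, i_c=4.0):
        rows = []
        for i, p in enumerate(profile_values):
            for t, gv in zip(times, g):
                rows.append(dict(row_index=i, time=t, intensity=i_c + p * gv))
        return pd.DataFrame(rows)

    def test_exactly_separable_recovery(self):
        times = np.linspace(0, 10, 12)
        g = np.linspace(0.5, 4.0, 12)
        prof_true = np.array(default_row_profile_values())
        table = self._table(prof_true, g, times)
        profile, g_rec, resid = decompose_signal(table)
        assert resid < 1e-12
        np.testing.assert_allclose(profile.values, prof_true, atol=1e-10)
        np.testing.assert_allclose(g_rec.to_numpy(), g, atol=1e-10)

    def test_scale_consistency(self):
        # multiplying g by c and dividing the profile by c leaves the product
        # unchanged; normalisation at row 0 makes the factorisation unique
        times = np.linspace(0, 10, 8)
        g = np.linspace(1.0, 3.0, 8)
        prof = np.array([1.0, 0.6, 0.3])
        t1 = self._table(prof, g, times)
        t2 = self._table(prof / 2.0, 2.0 * g, times)
        p1, g1, _ = decompose_signal(t1)
        p2, g2, _ = decompose_signal(t2)
        prod1 = np.outer(p1.values, g1)
        prod2 = np.outer(np.asarray(p2.values) * 1.0, g2)
        np.testing.assert_allclose(prod1, prod2, atol=1e-10)

    def test_generator_ground_truth_recovered(self):
        table, truth = generate_tracking_table(GeneratorSpec(seed=7))
        profile, _, resid = decompose_signal(table)
        assert resid < 1e-6
        np.testing.assert_allclose(
            profile.values, truth["row_profile"], atol=1e-6
        )

    def test_non_separable_has_residual(self):
        times = np.linspace(0, 10, 8)
        g = np.linspace(1.0, 3.0, 8)
        prof = np.array([1.0, 0.6, 0.3])
        table = self._table(prof, g, times)
        table.loc[3, "intensity"] += 0.5  # break separability
        _, _, resid = decompose_signal(table)
        assert resid > 1e-3

    def test_zero_excess_rejected(self):
        times = np.linspace(0, 5, 6)
        table = self._table([1.0, 0.5], np.zeros(6), times)
        with pytest.raises(ValueError, match="zero"):
            decompose_signal(table)


class TestPrestressSchedule:
    def test_zero_at_onset_and_monotone(self):
        profile = RowProfile(default_row_profile_values())
        times = np.linspace(0.0, 30.0, 16)
        sched = prestress_schedule(CONFOCAL, profile, scale=50.0, times=times)
        assert sched["eps_midline"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert (np.diff(sched["eps_midline"]) > 0).all()
        # rows scale by the profile
        np.testing.assert_allclose(
            sched["eps_row_3"], sched["eps_midline"] * profile(3), rtol=1e-12
        )

    def test_scale_reaches_target_prestrains(self):
        # the calibration scale can place any target eps on the ramp
        profile = RowProfile(default_row_profile_values())
        times = np.array([0.0, 41.0])
        for target in (0.43, 5.25):
            excess = eval_intensity(CONFOCAL, times[-1]) - CONFOCAL.i_c
            scale = target * 50.0 / excess
            sched = prestress_schedule(CONFOCAL, profile, scale=scale, times=times)
            assert sched["eps_midline"].iloc[-1] == pytest.approx(target, rel=1e-12)

    def test_negative_scale_rejected(self):
        profile = RowProfile(default_row_profile_values())
        with pytest.raises(ValueError):
            prestress_schedule(CONFOCAL, profile, scale=-1.0, times=[0, 1])


class TestSynchronizeTime:
    def test_linear_area_decay_crossing(self):
        # A(t) = A0 (1 - 0.05 t) crosses 80% at t = 4
        times = np.arange(0.0, 9.0)
        rows = []
        for t in times:
            for r in range(5):
                rows.append(
                    dict(cell_id=r, time=t, row_index=r, apical_area=100 * (1 - 0.05 * t))
                )
        t0, synced = synchronize_time(pd.DataFrame(rows), "lightsheet")
        assert t0 == pytest.approx(4.0, abs=1e-12)
        assert synced["time_sync"].min() == pytest.approx(-4.0)

    def test_area_reduction_at_zero_is_twenty_percent(self):
        table, _ = generate_tracking_table(GeneratorSpec(seed=3))
        t0, _ = synchronize_time(table, "lightsheet")
        sel = table[table["row_index"] <= 4]
        rel = sel.groupby("time")["apical_area"].mean()
        rel = rel / rel.iloc[0]
        assert np.interp(t0, rel.index, rel.to_numpy()) == pytest.approx(0.8, abs=1e-9)

    def test_confocal_rescaled_by_factor_two(self):
        table, _ = generate_tracking_table(GeneratorSpec(seed=3))
        t0, ls = synchronize_time(table, "lightsheet")
        _, cf = synchronize_time(table, "confocal")
        np.testing.assert_allclose(
            cf["time_sync"], ls["time_sync"] / CONFOCAL_RATE_FACTOR, atol=1e-12
        )
        assert CONFOCAL_RATE_FACTOR == 2.0

    def test_no_crossing_rejected(self):
        rows = [
            dict(cell_id=0, time=t, row_index=0, apical_area=100.0 - t)
            for t in range(5)
        ]
        with pytest.raises(ValueError, match="never crosses"):
            synchronize_time(pd.DataFrame(rows), "lightsheet")


class TestModalityConsistency:
    def test_confocal_and_lightsheet_schedules_agree(self):
        # light-sheet development runs twice as fast: the confocal-fitted
        # model (T = 20 min) evaluated on confocal times t equals the
        # light-sheet model (T = 10 min) on the rescaled times t/2
        profile = RowProfile(default_row_profile_values())
        confocal = IntensityModelParams(i_c=4.0, amplitude=1.0, t_onset=0.0, tau=20.0)
        lightsheet = IntensityModelParams(i_c=4.0, amplitude=1.0, t_onset=0.0, tau=10.0)
        t_conf = np.linspace(0.0, 30.0, 12)
        sched_c = prestress_schedule(confocal, profile, scale=50.0, times=t_conf)
        sched_l = prestress_schedule(
            lightsheet, profile, scale=50.0, times=t_conf / CONFOCAL_RATE_FACTOR
        )
        np.testing.assert_allclose(
            sched_c["eps_midline"], sched_l["eps_midline"], rtol=1e-12
        )
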