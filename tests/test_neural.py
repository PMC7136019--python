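"""Design construction, BOLD simulation/fitting, collinearity diagnostics,
and regressor-specific decoding."""

import numpy as np
import pandas as pd
import pytest

from socstruct import neural, similarity


@pytest.fixture(scope="module")
def onset_events(example_session):
    return neural.schedule_onsets(example_session, seed=31)


@pytest.fixture(scope="module")
def run0_design(example_session, onset_events):
    series = similarity.dyadic_series(example_session.runs[0])
    return neural.build_design(onset_events[onset_events.run == 0], series)


def tiny_design(columns: dict, tr=1.0):
    frame = pd.DataFrame(columns)
    frame.index = np.arange(len(frame)) * tr
    return neural.DesignMatrix(matrix=frame, tr=tr, n_scans_per_run=len(frame), run_ids=(0,))


class TestHrf:
    def test_zero_at_onset_and_peak_location(self):
        kernel = neural.canonical_hrf(0.1)
        assert kernel[0] == pytest.approx(0.0, abs=1e-12)
        assert 4.0 <= 0.1 * kernel.argmax() <= 6.0
        assert kernel.max() == pytest.approx(1.0)

    def test_undershoot_present(self):
        kernel = neural.canonical_hrf(0.1)
        assert kernel[int(15 / 0.1)] < 0

    def test_invalid_tr_rejected(self):
        with pytest.raises(ValueError):
            neural.canonical_hrf(0.0)


class TestScheduleOnsets:
    def test_events_fit_in_run_and_are_ordered(self, onset_events):
        for _, run_events in onset_events.groupby("run"):
            onsets = run_events["onset_s"].to_numpy()
            assert (np.diff(onsets) > 0).all()
            assert onsets[-1] + 24.0 <= 720.0

    def test_jitter_respects_bounds(self, example_session):
        events = neural.schedule_onsets(example_session, seed=1, jitter=(3.0, 3.0))
        # with degenerate jitter the schedule is deterministic in structure
        gaps = events[events.run == 0]["onset_s"].diff().dropna()
        assert gaps.min() >= 3.0 - 1e-9

    def test_deterministic(self, example_session):
        a = neural.schedule_onsets(example_session, seed=5)
        b = neural.schedule_onsets(example_session, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestBuildDesign:
    def test_shape_and_columns(self, run0_design):
        assert run0_design.matrix.shape[0] == 480  # 12-minute run at TR 1.5
        assert set(run0_design.names) == {
            "self_onset", "guess_onset", "guess_x_modulator",
            "photo_A", "photo_B", "intercept_run0",
        }
        assert np.isfinite(run0_design.values).all()

    def test_constant_modulator_is_scaled_guess_column(self, example_session, onset_events):
        run = example_session.runs[0]
        const = similarity.ModulatorSeries(
            "dyadic", run.run_id,
            tuple([0.7] * 24), similarity.dyadic_series(run).events,
        )
        design = neural.build_design(onset_events[onset_events.run == 0], const)
        assert np.allclose(
            design.matrix["guess_x_modulator"], 0.7 * design.matrix["guess_onset"]
        )

    def test_modulator_column_linear_in_values(self, example_session, onset_events):
        run = example_session.runs[0]
        base = similarity.dyadic_series(run)
        doubled = similarity.ModulatorSeries(
            base.model, base.run_id, tuple(2 * v for v in base.values), base.events
        )
        events = onset_events[onset_events.run == 0]
        d1 = neural.build_design(events, base)
        d2 = neural.build_design(events, doubled)
        assert np.allclose(
            d2.matrix["guess_x_modulator"], 2 * d1.matrix["guess_x_modulator"]
        )

    def test_misaligned_modulator_rejected(self, example_session, onset_events):
        run0, run1 = example_session.runs[:2]
        wrong = similarity.dyadic_series(run1)  # run 1 ordering, run 0 events
        wrong = similarity.ModulatorSeries("dyadic", 0, wrong.values, wrong.events)
        events = onset_events[onset_events.run == 0]
        if list(wrong.events) == list(similarity.dyadic_series(run0).events):
            pytest.skip("agent orders happen to coincide")
        with pytest.raises(ValueError, match="misaligned"):
            neural.build_design(events, wrong)

    def test_multirun_concatenation(self, example_session, onset_events):
        mods = {r.run_id: similarity.dyadic_series(r) for r in example_session.runs[:2]}
        design = neural.build_design(onset_events[onset_events.run < 2], mods)
        assert design.matrix.shape[0] == 960
        assert (design.matrix["intercept_run0"].to_numpy()[:480] == 1).all()
        assert (design.matrix["intercept_run0"].to_numpy()[480:] == 0).all()


class TestFitAndSimulate:
    def test_noiseless_identity(self, run0_design):
        betas = [1.0, 1.0, 2.0, 1.0, 0.5, 0.3]
        vox = neural.simulate_bold(run0_design, betas, noise_sd=0.0, seed=0)
        fit = neural.fit_glm(run0_design, vox.Y)
        assert np.allclose(fit.betas.to_numpy().ravel(), betas, atol=1e-8)

    def test_estimates_unbiased_under_noise(self, run0_design):
        betas = np.array([1.0, 1.0, 2.0, 1.0, 0.5, 0.3])
        errors = []
        for rep in range(200):
            vox = neural.simulate_bold(run0_design, betas, noise_sd=1.0, seed=rep)
            fit = neural.fit_glm(run0_design, vox.Y)
            errors.append(fit.betas.to_numpy().ravel() - betas)
        errors = np.asarray(errors)
        mean_err = errors.mean(axis=0)
        se = errors.std(axis=0, ddof=1) / np.sqrt(len(errors))
        assert (np.abs(mean_err) < 2.5 * se + 1e-6).all()

    def test_rank_deficiency_warns_with_column_names(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        design = tiny_design({"a": x[:, 0], "b": 2 * x[:, 0], "intercept": np.ones(50)})
        with pytest.warns(UserWarning, match="a ~ b|b ~ a"):
            neural.fit_glm(design, x[:, 0])


class TestCollinearity:
    def test_identical_series_reported_as_infinite_vif(self):
        x = np.linspace(0, 1, 24)
        report = neural.collinearity_report([{"dyadic": x, "latent": x}])
        assert report.per_participant["r"].iloc[0] == pytest.approx(1.0)
        assert np.isinf(report.per_participant["vif"].iloc[0])

    def test_vif_formula_value(self):
        assert neural.vif_from_r(0.8) == pytest.approx(1 / (1 - 0.64))
        assert neural.vif_from_r(0.8) == pytest.approx(2.778, abs=1e-3)

    def test_vif_matches_independent_regression_r2(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=144)
        y = 0.6 * x + rng.normal(size=144)
        report = neural.collinearity_report([{"a": x, "b": y}])
        # independent oracle: R^2 from explicit OLS of b on a
        slope, intercept = np.polyfit(x, y, 1)
        r2 = 1 - np.sum((y - slope * x - intercept) ** 2) / np.sum((y - y.mean()) ** 2)
        assert report.per_participant["vif"].iloc[0] == pytest.approx(1 / (1 - r2))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            neural.collinearity_report([{"a": np.ones(24), "b": np.arange(24.0)}])

    def test_latent_not_collinear_with_dyadic(self, example_session):
        from socstruct import latent as latent_mod

        for run in example_session.runs[:2]:
            d = np.asarray(similarity.dyadic_series(run).values)
            l = np.asarray(latent_mod.latent_series(run).values)
            assert abs(np.corrcoef(d, l)[0, 1]) < 1.0 - 1e-6


class TestDecoding:
    def test_single_regressor_shrinkage(self):
        # beta = 3, lambda = 1: decoded = (3X) * 3 / 10 = 0.9 X
        x = np.sin(np.linspace(0, 8 * np.pi, 300))
        design = tiny_design({"target": x})
        y = 3.0 * x
        decoded = neural.decode_signal(design, y, "target", lam=1.0)
        assert np.allclose(decoded.ravel(), 0.9 * x, atol=1e-10)

    def test_lambda_zero_recovers_target_time_course(self, run0_design):
        # at lambda -> 0 the decoder returns (beta X) * beta / beta^2 = X:
        # the target regressor's time course at unit amplitude
        betas = [1.0, 1.0, 2.0, 1.0, 0.5, 0.3]
        vox = neural.simulate_bold(run0_design, betas, noise_sd=0.0, seed=0)
        decoded = neural.decode_signal(run0_design, vox.Y, "guess_x_modulator", lam=0.0)
        expected = run0_design.matrix["guess_x_modulator"].to_numpy()
        assert np.allclose(decoded.ravel(), expected, atol=1e-8)

    def test_large_lambda_shrinks_to_zero(self, run0_design):
        vox = neural.simulate_bold(run0_design, [1, 1, 2, 1, 0.5, 0.3], 0.0, seed=0)
        decoded = neural.decode_signal(run0_design, vox.Y, "guess_x_modulator", lam=1e12)
        assert np.abs(decoded).max() < 1e-6

    def test_decoded_components_reconstruct_signal(self):
        # noiseless orthogonal design, lambda -> 0: each decoded signal is
        # the unit-amplitude regressor, so the beta-weighted sum over all
        # regressors recovers Y exactly
        n = 240
        t = np.arange(n)
        cols = {
            "a": np.where(t % 2 == 0, 1.0, -1.0),
            "b": np.where((t // 2) % 2 == 0, 1.0, -1.0),
        }
        design = tiny_design(cols)
        y = 1.5 * cols["a"] - 0.7 * cols["b"]
        fit = neural.fit_glm(design, y)
        total = sum(
            fit.betas.loc[name].to_numpy()
            * neural.decode_signal(design, y, name, lam=0.0, fit=fit).ravel()
            for name in cols
        )
        assert np.allclose(total, y, atol=1e-10)

    def test_unknown_target_rejected(self, run0_design):
        with pytest.raises(ValueError, match="unknown target"):
            neural.decode_signal(run0_design, np.zeros(480), "photo_C")


class TestEventAmplitudes:
    def _design_with_photos(self, example_session, onset_events):
        series = similarity.dyadic_series(example_session.runs[0])
        return neural.build_design(onset_events[onset_events.run == 0], series)

    def test_planted_ratio_and_symmetry(self):
        # two well-separated planted HRF responses, amplitude_A = 2 x
        # amplitude_B: window means share the response shape, so the log
        # difference is exactly log 2
        tr = 1.5
        frame_times = np.arange(480) * tr
        kernel = neural.canonical_hrf(tr, oversampling=10)
        onsets = {"A": 99.0, "B": 300.0}  # both multiples of TR: same phase

        def response(onset, amp):
            grid = np.zeros(4800)
            grid[int(onset / (tr / 10))] = amp
            return np.convolve(grid, kernel)[:4800][::10]

        y = response(onsets["A"], 2.0) + response(onsets["B"], 1.0)
        amps = neural.event_amplitudes(y, frame_times, onsets)
        ld = neural.log_difference(np.array([amps["A"]]), np.array([amps["B"]]))
        assert ld[0] == pytest.approx(np.log(2), abs=1e-9)
        swapped = neural.log_difference(np.array([amps["B"]]), np.array([amps["A"]]))
        assert swapped[0] == pytest.approx(-ld[0])

    def test_identical_amplitudes_give_zero(self):
        assert neural.log_difference(np.array([1.3]), np.array([1.3]))[0] == 0.0

    def test_shift_applied_only_when_needed(self):
        ld = neural.log_difference(np.array([2.0, -1.0]), np.array([1.0, 1.0]))
        assert np.isfinite(ld).all()
        assert neural.log_difference(np.array([2.0]), np.array([1.0]))[0] == pytest.approx(
            np.log(2.0)
        )

    def test_window_outside_scan_rejected(self, example_session, onset_events):
        design = self._design_with_photos(example_session, onset_events)
        with pytest.raises(ValueError, match="outside"):
            neural.event_amplitudes(
                np.zeros(480), design.frame_times, {"A": 1e5}, window=(3, 7)
            )
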