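"""Electrical-fingerprint modelling: features, ridge fits, clustering,
electrode selection, signal extraction."""

import json

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression, Ridge

from angermarkers import cohort as ch
from angermarkers import efp
from angermarkers.series import SampledSeries, WindowSpec


def _toy_tensor(values, frame_s=3.0, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"ch{i}" for i in range(values.shape[0])]
    edges = np.arange(values.shape[1] + 1, dtype=float) + 1
    return efp.TimeFrequencyTensor(values, labels, edges, frame_s)


class TestSpectrogram:
    def test_pure_alpha_sinusoid_concentrates_in_alpha_band(self):
        rate = 100.0
        t = np.arange(0, 60.0, 1 / rate)
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        tf = efp.spectrogram(x, rate, frame_s=3.0, normalize=False)
        band_power = tf.values[0].mean(axis=1)
        assert np.argmax(band_power) == 2  # alpha is band index 2 (8-12 Hz)

    def test_zero_signal_constant_features(self):
        tf = efp.spectrogram(np.zeros((2, 3000)), 100.0, 3.0)
        assert np.ptp(tf.values) == 0.0

    def test_am_sinusoid_feature_tracks_envelope(self):
        rate = 100.0
        t = np.arange(0, 300.0, 1 / rate)
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t)
        x = (env * np.sin(2 * np.pi * 10.0 * t))[None, :]
        tf = efp.spectrogram(x, rate, frame_s=3.0)
        frames = env.reshape(-1, int(3 * rate)).mean(axis=1)
        r = np.corrcoef(tf.values[0, 2], frames)[0, 1]
        assert r > 0.9

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            efp.spectrogram(np.zeros((1, 100)), 50.0, 1.0)  # top edge 40 Hz

    def test_frame_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="frame longer"):
            efp.spectrogram(np.zeros((1, 100)), 100.0, 3.0)


class TestEmbedDelays:
    def test_single_delay_is_identity(self):
        vals = np.arange(2 * 3 * 10.0).reshape(2, 3, 10)
        tf = _toy_tensor(vals)
        X = efp.embed_delays(tf, "ch0", delays_frames=1)
        np.testing.assert_array_equal(X, vals[0].T)

    def test_row_count_drops_incomplete_lag_frames(self):
        tf = _toy_tensor(np.random.default_rng(0).normal(size=(1, 2, 10)))
        X = efp.embed_delays(tf, "ch0", delays_frames=3)
        assert X.shape == (8, 6)  # 10 - (3 - 1) rows, bands * delays columns

    def test_column_content_is_lagged_feature(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(1, 2, 12))
        tf = _toy_tensor(vals)
        D = 4
        X = efp.embed_delays(tf, "ch0", D)
        for f in range(2):
            for d in range(D):
                np.testing.assert_array_equal(
                    X[:, f * D + d], vals[0, f, D - 1 - d : 12 - d]
                )

    def test_shifting_features_shifts_column_identity_not_content(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(1, 2, 30))
        shifted = np.concatenate([base[:, :, :1], base[:, :, :-1]], axis=2)
        D = 3
        Xa = efp.embed_delays(_toy_tensor(base), "ch0", D)
        Xb = efp.embed_delays(_toy_tensor(shifted), "ch0", D)
        # delaying the feature stream by one frame moves each column's content
        # to the next-larger delay: column (f, d) of the shifted tensor equals
        # column (f, d+1) of the original
        for f in range(2):
            for d in range(D - 1):
                np.testing.assert_array_equal(Xb[:, f * D + d], Xa[:, f * D + d + 1])

    def test_excessive_delays_rejected(self):
        tf = _toy_tensor(np.zeros((1, 2, 10)))
        with pytest.raises(ValueError):
            efp.embed_delays(tf, "ch0", delays_frames=10)


class TestEFPRidge:
    def _data(self, n=60, p=8, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        w = rng.normal(size=p)
        y = X @ w + noise * rng.normal(size=n)
        return X, y

    def test_zero_penalty_matches_ols(self):
        X, y = self._data(noise=0.3)
        est = efp.EFPRidge(lambda_grid=[0.0]).fit(X, y)
        Xz = (X - X.mean(0)) / X.std(0)
        ref = LinearRegression().fit(Xz, y)
        np.testing.assert_allclose(est.coef_, ref.coef_, atol=1e-8)
        assert est.intercept_ == pytest.approx(y.mean())

    def test_matches_sklearn_ridge_at_fixed_penalty(self):
        X, y = self._data(noise=0.5, seed=3)
        lam = 2.0
        est = efp.EFPRidge(lambda_grid=[lam]).fit(X, y)
        Xz = (X - X.mean(0)) / X.std(0)
        ref = Ridge(alpha=lam * X.shape[0], solver="svd").fit(Xz, y - y.mean())
        np.testing.assert_allclose(est.coef_, ref.coef_, atol=1e-8)

    def test_exact_linear_target_perfect_heldout_r(self):
        X, y = self._data(noise=0.0)
        est = efp.EFPRidge().fit(X, y)
        assert est.cv_fit_r_ > 0.999

    def test_coefficient_norm_nonincreasing_in_penalty(self):
        X, y = self._data(noise=0.5, seed=5)
        Xz = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        G, b = Xz.T @ Xz, Xz.T @ yc
        norms = [
            np.linalg.norm(efp._ridge_solve(G, b, lam, X.shape[0]))
            for lam in (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(n2 <= n1 + 1e-12 for n1, n2 in zip(norms, norms[1:]))

    def test_rank_zero_design_rejected(self):
        X = np.ones((30, 4))
        with pytest.raises(ValueError, match="rank-0"):
            efp.EFPRidge().fit(X, np.random.default_rng(0).normal(size=30))

    def test_too_few_frames_rejected(self):
        X, y = self._data(n=10)
        with pytest.raises(ValueError, match="at least 20"):
            efp.EFPRidge().fit(X, y)

    def test_scale_equivariance_of_predictions(self):
        # affine rescaling of raw features leaves predictions unchanged
        X, y = self._data(noise=0.4, seed=6)
        est1 = efp.EFPRidge(lambda_grid=[1.0]).fit(X, y)
        scale = np.linspace(0.1, 8.0, X.shape[1])
        offset = np.linspace(-3, 3, X.shape[1])
        est2 = efp.EFPRidge(lambda_grid=[1.0]).fit(X * scale + offset, y)
        np.testing.assert_allclose(
            est1.predict(X), est2.predict(X * scale + offset), atol=1e-8
        )


class TestClusterModels:
    def _model(self, grid, r, sid):
        return efp.EFPModel(
            electrode="Fz", coefficients=grid, intercept=0.0, ridge_lambda=1.0,
            delays_frames=grid.shape[1], cv_fit_r=r, training_subject_ids=[sid],
        )

    def test_higher_fit_cluster_wins(self, rng):
        a = rng.normal(size=(5, 6))
        b = rng.normal(size=(5, 6))
        models = (
            [self._model(a + 0.01 * rng.normal(size=a.shape), 0.8, i) for i in range(3)]
            + [self._model(b + 0.01 * rng.normal(size=b.shape), 0.3, 3 + i) for i in range(3)]
        )
        chosen = efp.cluster_models(models)
        assert sorted(m.training_subject_ids[0] for m in chosen) == [0, 1, 2]

    def test_identical_models_all_returned(self, rng):
        g = rng.normal(size=(5, 6))
        models = [self._model(g.copy(), 0.5, i) for i in range(4)]
        assert len(efp.cluster_models(models)) == 4

    def test_outlier_excluded(self, rng):
        a = rng.normal(size=(5, 6))
        models = [self._model(a + 0.01 * rng.normal(size=a.shape), 0.6, i) for i in range(4)]
        models.append(self._model(-a, 0.9, 99))  # anti-correlated outlier
        chosen = efp.cluster_models(models)
        assert 99 not in [m.training_subject_ids[0] for m in chosen]

    def test_shape_mismatch_rejected(self, rng):
        m1 = self._model(rng.normal(size=(5, 6)), 0.5, 0)
        m2 = self._model(rng.normal(size=(5, 6)), 0.5, 1)
        m3 = self._model(rng.normal(size=(4, 3)), 0.5, 2)
        with pytest.raises(ValueError, match="shape"):
            efp.cluster_models([m1, m2, m3])

    def test_too_few_models_rejected(self, rng):
        m = self._model(rng.normal(size=(2, 2)), 0.5, 0)
        with pytest.raises(ValueError, match="at least 3"):
            efp.cluster_models([m, m])


class TestCommonModel:
    def test_identical_subjects_match_individual_fit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 12))
        w = rng.normal(size=12)
        y = X @ w
        yz = (y - y.mean()) / y.std()
        common = efp.fit_common([X, X, X], [yz, yz, yz], electrode="Fz",
                                delays_frames=4)
        ind = efp.EFPRidge().fit(X, yz)
        np.testing.assert_allclose(common.coefficients.ravel(), ind.coef_, atol=1e-6)

    def test_single_subject_degenerates_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8)
        with pytest.warns(UserWarning, match="single subject"):
            model = efp.fit_common([X], [y], electrode="Fz", delays_frames=4)
        assert model.coefficients.shape == (2, 4)

    def test_shared_weights_common_beats_median_individual(self, small_cohort):
        subs = small_cohort.subjects
        tensors = [s.eeg for s in subs]
        bolds = [s.bold.roi_mean for s in subs]
        individuals = [
            efp.fit_individual(tf, "Fz", b, subject_id=s.subject)
            for tf, b, s in zip(tensors, bolds, subs)
        ]
        common = efp.common_model_from_tensors(tensors, bolds, "Fz")
        assert common.cv_fit_r >= np.median([m.cv_fit_r for m in individuals]) - 0.05

    def test_individual_fits_have_heldout_predictive_power(self, small_cohort):
        # blocked contiguous folds on a single-bump recording leave some folds
        # nearly signal-free, so per-subject cv r sits well below the common
        # model's leave-one-subject-out r; it must still be clearly above chance
        rs = [
            efp.fit_individual(s.eeg, "Fz", s.bold.roi_mean).cv_fit_r
            for s in small_cohort.subjects
        ]
        assert np.median(rs) >= 0.2
        assert all(r > 0 for r in rs)


class TestSelectElectrode:
    def test_informative_channel_wins(self):
        rng = np.random.default_rng(6)
        z = np.cumsum(rng.normal(size=80))  # smooth target
        tensors, bolds = [], []
        for s in range(4):
            vals = rng.normal(size=(3, 2, 80))
            vals[1, 0] = z + 0.3 * rng.normal(size=80)  # only ch1 informative
            tensors.append(_toy_tensor(vals, labels=["chA", "chB", "chC"]))
            bolds.append(SampledSeries(z + 0.3 * rng.normal(size=80), 1 / 3.0))
        best, scores = efp.select_electrode(tensors, bolds, delays_frames=2)
        assert best == "chB"
        assert scores["chB"] > max(scores["chA"], scores["chC"])

    def test_recovers_generator_target(self, small_cohort):
        best, _ = efp.select_electrode(
            [s.eeg for s in small_cohort.subjects],
            [s.bold.roi_mean for s in small_cohort.subjects],
        )
        assert best == "Fz"

    def test_fixed_electrode_variant_bypasses_selection(self, small_cohort):
        # the frontal variant pins the electrode (e.g. F4) instead of selecting
        model = efp.common_model_from_tensors(
            [s.eeg for s in small_cohort.subjects],
            [s.bold.roi_mean for s in small_cohort.subjects],
            "F4",
        )
        assert model.electrode == "F4"


class TestApplyModel:
    def _model(self, n_bands=5, D=6, coef=None, intercept=0.0):
        grid = np.zeros((n_bands, D)) if coef is None else coef
        return efp.EFPModel("ch0", grid, intercept, 1.0, D, 0.5)

    def test_zero_coefficients_constant_at_intercept(self, rng):
        tf = _toy_tensor(rng.normal(size=(1, 5, 107)))
        out = efp.apply_model(tf, self._model(intercept=2.0))
        np.testing.assert_allclose(out.values, 2.0)

    def test_output_rate_equal_to_frame_rate_no_binning(self, rng):
        tf = _toy_tensor(rng.normal(size=(1, 5, 107)))
        out = efp.apply_model(tf, self._model(), output_rate_hz=1 / 3.0)
        assert out.n_samples == 107 - 5

    def test_nominal_rate_gives_nine_samples_for_full_film(self, rng):
        # 321 s at 3-s frames: 102 prediction frames -> 9 bins of 33.3 s
        tf = _toy_tensor(rng.normal(size=(1, 5, 107)))
        out = efp.apply_model(tf, self._model(), output_rate_hz=0.03)
        assert out.n_samples == 9

    def test_missing_electrode_lists_available(self, rng):
        tf = _toy_tensor(rng.normal(size=(2, 5, 107)), labels=["a", "b"])
        with pytest.raises(ValueError, match="available"):
            efp.apply_model(tf, self._model())

    def test_window_mean_of_ramp(self):
        series = SampledSeries(np.arange(9.0), rate_hz=1.0)
        assert efp.window_mean(series, WindowSpec("w", 2.0, 5.0)) == pytest.approx(3.0)

    def test_high_window_exceeds_low_for_coupled_subjects(self, small_cohort):
        model = efp.common_model_from_tensors(
            [s.eeg for s in small_cohort.subjects],
            [s.bold.roi_mean for s in small_cohort.subjects],
            "Fz",
        )
        low = WindowSpec("low-anger", 0.0, 100.0)
        high = WindowSpec("high-anger", 189.0, 289.0)
        diffs = [
            efp.window_mean(efp.apply_model(s.eeg, model), high)
            - efp.window_mean(efp.apply_model(s.eeg, model), low)
            for s in small_cohort.subjects
        ]
        assert np.mean(diffs) > 0


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        m = efp.EFPModel("Fz", rng.normal(size=(5, 6)), 0.3, 10.0, 6, 0.72,
                         ["sub-00"], efp.DEFAULT_BAND_EDGES_HZ, 3.0)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = efp.EFPModel.from_json(path)
        np.testing.assert_allclose(back.coefficients, m.coefficients)
        assert back.electrode == m.electrode
        assert back.ridge_lambda == m.ridge_lambda
        assert json.loads(path.read_text())["delays_frames"] == 6


class TestEndToEndRecovery:
    def test_common_grid_correlates_with_true_weights(self):
        # 20 training subjects at generator defaults
        co = ch.CohortSimulator(n_subjects=20).simulate(17)
        model = efp.common_model_from_tensors(
            [s.eeg for s in co.subjects], [s.bold.roi_mean for s in co.subjects], "Fz"
        )
        true_grid = ch.default_coupling().eeg_weights[
            list(ch.DEFAULT_CHANNELS).index("Fz")
        ]
        r = np.corrcoef(model.coefficients.ravel(), true_grid.ravel())[0, 1]
        assert r >= 0.7
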