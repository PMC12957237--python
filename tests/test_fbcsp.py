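"""CSP eigen-solution vs brute-force variance-ratio maximization, filter
bank response, and log-power feature construction."""

import numpy as np
import pytest

from scbam.core import make_grid_montage
from scbam.exceptions import InvalidArgumentError, NumericalError
from scbam.fbcsp import (
    BandSpec,
    FBCSPModel,
    apply_filter_bank,
    class_covariance,
    export_patterns_csv,
    featurize,
    fit_csp,
    log_power,
)
from scbam.preprocess import WindowSet


def _window_set(data, labels):
    n = data.shape[0]
    return WindowSet(data, np.asarray(labels), np.arange(n), np.ones(n, int),
                     data.shape[2], data.shape[2])


def _rayleigh(w, c1, c2):
    return (w @ c1 @ w) / (w @ c2 @ w)


def brute_force_csp_filter(c1, c2, n_draws=100_000, seed=0, maximize=True):
    """Independent oracle: random-search maximization of the variance
    ratio J(w) = w'C1w / w'C2w over unit vectors."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_draws, c1.shape[0]))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    num = np.einsum("ni,ij,nj->n", w, c1, w)
    den = np.einsum("ni,ij,nj->n", w, c2, w)
    ratios = num / den
    idx = np.argmax(ratios) if maximize else np.argmin(ratios)
    return w[idx], ratios[idx]


def angle_deg(u, v):
    c = abs(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


class TestClassCovariance:
    def test_white_noise_covariance_near_scaled_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20, 4, 5000))
        c = class_covariance(_window_set(data, [1] * 20), 1)
        np.testing.assert_allclose(c, np.eye(4) / 4, atol=0.01)

    def test_scalar_case_trace_normalizes_to_one(self):
        data = np.random.default_rng(1).standard_normal((1, 1, 100))
        c = class_covariance(_window_set(data, [1]), 1)
        assert c[0, 0] == pytest.approx(1.0, rel=1e-5)

    def test_duplicated_windows_leave_covariance_unchanged(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 3, 200))
        c1 = class_covariance(_window_set(data, [1] * 5), 1)
        c2 = class_covariance(_window_set(np.concatenate([data, data]), [1] * 10), 1)
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_missing_label_rejected(self):
        data = np.zeros((2, 3, 10))
        with pytest.raises(InvalidArgumentError):
            class_covariance(_window_set(data, [1, 1]), 2)


class TestFitCSP:
    def test_identical_classes_give_half_eigenvalues(self):
        c = np.diag([2.0, 1.0, 3.0])
        model = fit_csp(c, c, n_components=2)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-12)

    def test_diagonal_toy_matches_brute_force(self):
        """3-channel toy: first filter maximizes J (ratio 4), last
        minimizes it (ratio 1/4); both match random-search oracles."""
        c1 = np.diag([4.0, 1.0, 1.0])
        c2 = np.diag([1.0, 1.0, 4.0])
        model = fit_csp(c1, c2, n_components=2)
        w_first, j_max = brute_force_csp_filter(c1, c2, seed=0, maximize=True)
        w_last, j_min = brute_force_csp_filter(c1, c2, seed=1, maximize=False)
        assert angle_deg(model.W[:, 0], w_first) < 1.0
        assert angle_deg(model.W[:, 1], w_last) < 1.0
        assert _rayleigh(model.W[:, 0], c1, c2) == pytest.approx(4.0, rel=1e-6)
        assert _rayleigh(model.W[:, 1], c1, c2) == pytest.approx(0.25, rel=1e-6)
        assert j_max == pytest.approx(4.0, rel=1e-2)
        assert j_min == pytest.approx(0.25, rel=1e-2)

    def test_random_spd_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((4, 4))
        b = rng.standard_normal((4, 4))
        c1 = a @ a.T + 0.1 * np.eye(4)
        c2 = b @ b.T + 0.1 * np.eye(4)
        model = fit_csp(c1, c2, n_components=2)
        w_first, _ = brute_force_csp_filter(c1, c2, n_draws=500_000, seed=4)
        assert angle_deg(model.W[:, 0], w_first) < 1.0

    def test_whitening_convention(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((5, 5))
        c1 = a @ a.T + np.eye(5)
        c2 = np.eye(5)
        model = fit_csp(c1, c2, n_components=4)
        joint = c1 + c2
        for k in range(4):
            w = model.W[:, k]
            assert w @ joint @ w == pytest.approx(1.0, abs=1e-9)

    def test_class_swap_symmetry(self):
        """Swapping class roles maps eigenvalues lambda -> 1 - lambda."""
        rng = np.random.default_rng(6)
        a = rng.standard_normal((4, 4))
        c1 = a @ a.T + 0.5 * np.eye(4)
        c2 = np.diag([1.0, 2.0, 0.5, 1.5])
        m12 = fit_csp(c1, c2, n_components=4)
        m21 = fit_csp(c2, c1, n_components=4)
        np.testing.assert_allclose(
            np.sort(m12.eigenvalues), np.sort(1.0 - m21.eigenvalues), atol=1e-9)

    def test_scale_invariance_of_filters_from_windows(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((20, 4, 300))
        labels = [1] * 10 + [2] * 10
        data[:10, 0] *= 3.0  # class-1 variance concentrated on channel 0
        ws1 = _window_set(data, labels)
        ws2 = _window_set(data * 10.0, labels)
        m1 = fit_csp(class_covariance(ws1, 1), class_covariance(ws1, 2), 2)
        m2 = fit_csp(class_covariance(ws2, 1), class_covariance(ws2, 2), 2)
        for k in range(2):
            assert angle_deg(m1.W[:, k], m2.W[:, k]) < 1e-3

    def test_requested_component_count_returned(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((16, 16))
        c1 = a @ a.T + np.eye(16)
        c2 = np.eye(16)
        model = fit_csp(c1, c2, n_components=12)
        assert model.W.shape == (16, 12)
        assert model.eigenvalues.shape == (12,)
        # ordering: 6 largest first (descending), then 6 smallest
        assert (np.diff(model.eigenvalues[:6]) <= 1e-12).all()

    def test_patterns_are_pseudo_inverse_of_filters(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((5, 5))
        c1 = a @ a.T + np.eye(5)
        model = fit_csp(c1, np.eye(5), n_components=4)
        np.testing.assert_allclose(model.patterns, np.linalg.pinv(model.W), atol=1e-9)

    def test_non_spd_input_raises_numerical_error(self):
        c_bad = -np.eye(3)
        with pytest.raises(NumericalError):
            fit_csp(c_bad, c_bad, n_components=2)

    def test_agrees_with_mne_csp(self):
        """Independent oracle: mne's CSP on the same two-class window data
        spans the same extreme filters (up to sign/scale)."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(10)
        n, ch, t = 40, 4, 300
        data = rng.standard_normal((n, ch, t))
        data[:20, 0] *= 2.5
        data[20:, 3] *= 2.5
        labels = np.array([0] * 20 + [1] * 20)
        ws = _window_set(data, labels)
        ours = fit_csp(class_covariance(ws, 0), class_covariance(ws, 1),
                       n_components=2, class_pair=(0, 1))
        csp = mne.decoding.CSP(n_components=2, reg=1e-6, norm_trace=True,
                               transform_into="csp_space")
        csp.fit(data, labels)
        # compare spans: each of our extreme filters aligns with one of mne's
        for k in range(2):
            angles = [angle_deg(ours.W[:, k], csp.filters_[j]) for j in range(2)]
            assert min(angles) < 5.0


class TestFilterBank:
    bands = BandSpec()
    fs = 600.0

    def test_default_band_list(self):
        assert self.bands.n_bands == 6
        assert self.bands.edges == [(1.0, 4.0), (8.0, 12.0), (12.0, 30.0),
                                    (30.0, 50.0), (75.0, 115.0), (125.0, 150.0)]

    def test_alpha_sinusoid_survives_alpha_band_only(self):
        t = np.arange(3000) / self.fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        out = apply_filter_bank(x, self.bands, self.fs)
        rms = np.sqrt(np.mean(out[0, 0, :, 600:-600] ** 2, axis=1))
        in_rms = 1 / np.sqrt(2)
        assert rms[1] == pytest.approx(in_rms, rel=0.02)  # alpha passband
        assert rms[0] < 0.05 * in_rms  # delta stopband
        assert rms[3] < 0.05 * in_rms  # gamma stopband

    def test_zero_signal_zero_output(self):
        out = apply_filter_bank(np.zeros((2, 3, 600)), self.bands, self.fs)
        np.testing.assert_allclose(out, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            apply_filter_bank(np.zeros((1, 1, 600)), self.bands, 200.0)


class TestLogPower:
    def test_unit_sinusoid_log_half(self):
        t = np.arange(6000) / 600.0
        x = np.sin(2 * np.pi * 10.0 * t)
        assert log_power(x) == pytest.approx(np.log(0.5), abs=1e-3)

    def test_constant_floors_at_epsilon(self):
        assert log_power(np.full(100, 3.0)) == pytest.approx(np.log(1e-12))

    def test_feature_map_shape_12x6(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((6, 16, 600))
        labels = [1, 1, 1, 2, 2, 2]
        ws = _window_set(data, labels)
        model = fit_csp(class_covariance(ws, 1), class_covariance(ws, 2), 12)
        fm = featurize(ws, model, BandSpec(), 600.0)
        assert fm.values.shape == (6, 12, 6)
        assert np.isfinite(fm.values).all()


class TestFBCSPModel:
    def _two_class_windows(self, seed=12):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((30, 6, 600))
        labels = np.array([1] * 15 + [2] * 15)
        data[:15, 1] *= 2.0
        return _window_set(data, labels)

    def test_broadband_then_bank_shapes(self):
        ws = self._two_class_windows()
        m = FBCSPModel(BandSpec(), 600.0, n_components=4).fit(ws, (1, 2))
        fm = m.transform(ws)
        assert fm.values.shape == (30, 4, 6)

    def test_band_first_variant_shapes(self):
        ws = self._two_class_windows()
        m = FBCSPModel(BandSpec(), 600.0, n_components=4, band_first=True)
        m.fit(ws, (1, 2))
        fm = m.transform(ws)
        assert fm.values.shape == (30, 4, 6)
        assert len(m.per_band_csp) == 6

    def test_patterns_csv_export(self, tmp_path):
        import pandas as pd

        ws = self._two_class_windows()
        m = FBCSPModel(BandSpec(), 600.0, n_components=4).fit(ws, (1, 2))
        montage = make_grid_montage(2, 3, 8.6)
        path = tmp_path / "pattern.csv"
        export_patterns_csv(m.csp, montage, path, component=0)
        df = pd.read_csv(path)
        assert list(df.columns) == ["x_mm", "y_mm", "weight"]
        assert len(df) == 6
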