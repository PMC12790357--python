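import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helpers
import oracles
from specmon.datatypes import Spectrum, SpectrumSeries
from specmon.errors import ValidationError
from specmon.similarity import jaccard, similarity_trace, xcorr_similarity
from specmon import synthgen


def _spec(y, x=None, time=0.0):
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(len(y), dtype=float)
    return Spectrum(axis=x, intensity=y, time=time)


class TestJaccard:
    def test_self_similarity_is_one(self):
        s = helpers.gaussian_spectrum()
        assert jaccard(s, s).value == 1.0

    def test_rectangle_half(self):
        x = np.arange(-0.5, 1.5 + 0.0005, 0.001)
        inside = (x >= 0) & (x <= 1)
        a = _spec(np.where(inside, 1.0, 0.0), x)
        b = _spec(np.where(inside, 2.0, 0.0), x)
        res = jaccard(a, b)
        assert res.value == pytest.approx(0.5, abs=1e-3)
        assert res.value == pytest.approx(res.intersection_area / res.union_area)

    def test_disjoint_gaussians_near_zero(self):
        x = np.linspace(-10, 10, 2001)
        a = _spec(np.exp(-((x + 5) ** 2) / (2 * 0.3**2)), x)
        b = _spec(np.exp(-((x - 5) ** 2) / (2 * 0.3**2)), x)
        assert jaccard(a, b).value < 1e-6

    def test_epsilon_reduces_noise_sensitivity(self):
        # two noisy realizations of one spectrum: epsilon = 3 sigma never
        # scores lower than epsilon = 0
        x = np.linspace(0, 10, 300)
        signal = np.exp(-((x - 5) ** 2) / 0.5) + 0.5
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = _spec(signal + rng.normal(0, 0.02, x.size), x)
            b = _spec(signal + rng.normal(0, 0.02, x.size), x)
            a = a.with_intensity(np.maximum(a.intensity, 0))
            b = b.with_intensity(np.maximum(b.intensity, 0))
            assert jaccard(a, b, epsilon=0.06).value >= jaccard(a, b, epsilon=0.0).value

    def test_epsilon_monotonicity(self):
        rng = np.random.default_rng(77)
        a = _spec(rng.uniform(0, 1, 40))
        b = _spec(rng.uniform(0, 1, 40))
        values = [jaccard(a, b, epsilon=e).value for e in np.linspace(0, 1, 21)]
        assert np.all(np.diff(values) >= -1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = _spec(rng.uniform(0, 1, 64))
        b = _spec(rng.uniform(0, 1, 64))
        assert jaccard(a, b, epsilon=0.1).value == pytest.approx(
            jaccard(b, a, epsilon=0.1).value, abs=1e-12)

    def test_joint_scale_invariance(self):
        rng = np.random.default_rng(4)
        a = _spec(rng.uniform(0, 1, 64))
        b = _spec(rng.uniform(0, 1, 64))
        c = 37.5
        base = jaccard(a, b, epsilon=0.1).value
        scaled = jaccard(a.with_intensity(c * a.intensity),
                         b.with_intensity(c * b.intensity), epsilon=c * 0.1).value
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_window_restricts_comparison(self):
        x = np.linspace(0, 10, 500)
        left = np.exp(-((x - 2) ** 2) / 0.1)
        right = np.exp(-((x - 8) ** 2) / 0.1)
        a = _spec(left + right, x)
        b = _spec(left + 0.2 * right, x)
        full = jaccard(a, b).value
        left_only = jaccard(a, b, window=(0, 4)).value
        assert left_only == pytest.approx(1.0, abs=1e-9)
        assert full < 0.99

    def test_both_blank_convention(self):
        a = _spec(np.zeros(10))
        b = _spec(np.zeros(10))
        assert jaccard(a, b).value == 1.0

    def test_mismatched_grids_rejected(self):
        a = _spec(np.ones(10))
        b = _spec(np.ones(12))
        with pytest.raises(ValidationError, match="grid"):
            jaccard(a, b)

    def test_negative_intensity_directs_to_xcorr(self):
        a = _spec([1.0, -0.5, 1.0])
        b = _spec([1.0, 0.5, 1.0])
        with pytest.raises(ValidationError, match="xcorr"):
            jaccard(a, b)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = rng.integers(2, 17)
            x = np.sort(rng.choice(np.arange(40), size=n, replace=False)).astype(float)
            ya = rng.integers(0, 6, n).astype(float)
            yb = rng.integers(0, 6, n).astype(float)
            eps = float(rng.choice([0.0, 0.5, 1.0]))
            got = jaccard(_spec(ya, x), _spec(yb, x), epsilon=eps)
            want, want_i, want_u = oracles.jaccard_oracle(x, ya, yb, eps)
            assert got.value == pytest.approx(want, abs=1e-12)
            assert got.intersection_area == pytest.approx(want_i, abs=1e-12)
            assert got.union_area == pytest.approx(want_u, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=12),
           st.lists(st.floats(0, 10), min_size=2, max_size=12))
    def test_bounds_property(self, ya, yb):
        n = min(len(ya), len(yb))
        a, b = _spec(ya[:n]), _spec(yb[:n])
        v = jaccard(a, b).value
        assert 0.0 <= v <= 1.0


class TestXcorr:
    def test_identical_signal_scores_one_at_zero_lag(self):
        f = np.array([0.0, 1.0, 3.0, 2.0, 0.5])
        res = xcorr_similarity(f, f)
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.best_lag == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=32) + 1j * rng.normal(size=32)
        res = xcorr_similarity(f, 2.5 * f)
        assert res.value == pytest.approx(1.0, abs=1e-12)

    def test_impulse_delay(self):
        f = np.zeros(8); f[0] = 1.0
        g = np.zeros(8); g[3] = 1.0
        res = xcorr_similarity(f, g)
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.best_lag == 3

    def test_negative_correlation_below_one(self):
        # f=[1,0], g=[0,-1]: lag 0 -> 0, lag 1 -> -1; max real part is 0
        res = xcorr_similarity([1.0, 0.0], [0.0, -1.0])
        assert res.value == pytest.approx(0.0, abs=1e-12)
        assert res.value < 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            xcorr_similarity([0.0, 0.0], [1.0, 2.0])

    def test_zero_padding_of_shorter_series(self):
        f = np.array([1.0, 2.0, 3.0])
        g = np.array([1.0, 2.0, 3.0, 0.0, 0.0])
        res = xcorr_similarity(f, g)
        assert res.value == pytest.approx(1.0, abs=1e-12)

    def test_conjugate_symmetry_at_zero_lag(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=16) + 1j * rng.normal(size=16)
        g = rng.normal(size=16) + 1j * rng.normal(size=16)
        cfg = np.vdot(f, g)  # sum conj(f) g
        cgf = np.vdot(g, f)
        assert cfg == pytest.approx(np.conj(cgf), abs=1e-12)

    def test_modulus_flag_scores_sign_flip(self):
        f = np.array([0.5, 1.0, 2.0, 1.0])
        assert xcorr_similarity(f, -f).value < 0
        assert xcorr_similarity(f, -f, use_modulus=True).value == pytest.approx(1.0, abs=1e-12)

    def test_two_sided_finds_negative_lag(self):
        f = np.zeros(8); f[5] = 1.0
        g = np.zeros(8); g[2] = 1.0
        one_sided = xcorr_similarity(f, g)
        two_sided = xcorr_similarity(f, g, two_sided=True)
        assert one_sided.value < 1.0
        assert two_sided.value == pytest.approx(1.0, abs=1e-12)
        assert two_sided.best_lag == -3

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(321)
        for k in range(200):
            n = int(rng.integers(2, 17))
            if k % 2:
                f = rng.normal(size=n) + 1j * rng.normal(size=n)
                g = rng.normal(size=n) + 1j * rng.normal(size=n)
            else:
                f = rng.integers(-5, 6, n).astype(float)
                g = rng.integers(-5, 6, n).astype(float)
            if not np.any(f) or not np.any(g):
                continue
            got = xcorr_similarity(f, g)
            want, want_lag = oracles.xcorr_oracle(f, g)
            assert got.value == pytest.approx(want, abs=1e-12)
            assert got.best_lag == want_lag

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=16))
    def test_cauchy_schwarz_bound(self, vals):
        f = np.asarray(vals)
        if np.sum(np.abs(f) ** 2) == 0:  # includes underflow of tiny values
            return
        rng = np.random.default_rng(0)
        g = rng.normal(size=f.size)
        assert xcorr_similarity(f, g).value <= 1 + 1e-12


class TestSimilarityTrace:
    def test_identical_spectra_all_one(self):
        x = np.linspace(0, 10, 100)
        y = np.exp(-((x - 5) ** 2))
        series = SpectrumSeries(spectra=[
            Spectrum(axis=x, intensity=y.copy(), time=float(i)) for i in range(5)
        ])
        trace = similarity_trace(series, metric="jaccard")
        np.testing.assert_allclose(trace.values, 1.0)

    def test_first_order_monotone_non_increasing(self):
        spec = synthgen.first_order_preset(noise_sigma=0.0)
        trace = helpers.preset_trace(spec, epsilon=0.0)
        assert np.all(np.diff(trace.values) <= 1e-12)

    def test_reference_last_monotone_non_decreasing(self):
        spec = synthgen.first_order_preset(noise_sigma=0.0)
        trace = helpers.preset_trace(spec, epsilon=0.0, reference="last")
        assert np.all(np.diff(trace.values) >= -1e-12)
        assert trace.values[-1] == pytest.approx(1.0)

    def test_monotone_with_product_growth(self):
        # overlapping reactant decay + product growth still yields a
        # monotone trace against the first spectrum
        spec = synthgen.RunSpec(
            kinetics="first_order", rate=0.01,
            reactant_peaks=[synthgen.PeakSpec(4.0, 0.5, 1.0)],
            product_peaks=[synthgen.PeakSpec(5.0, 0.5, 0.7)],
            n_frames=40, dt=10.0, noise_sigma=0.0, axis_lo=0, axis_hi=10,
            axis_points=300,
        )
        trace = helpers.preset_trace(spec, epsilon=0.0)
        assert np.all(np.diff(trace.values) <= 1e-12)

    def test_integer_reference(self):
        x = np.linspace(0, 10, 50)
        series = SpectrumSeries(spectra=[
            Spectrum(axis=x, intensity=np.full(50, 1.0 + i), time=float(i))
            for i in range(4)
        ])
        trace = similarity_trace(series, metric="jaccard", reference=2)
        assert trace.values[2] == 1.0
        assert trace.reference == "2"

    def test_error_annotated_with_index(self):
        x = np.linspace(0, 10, 50)
        good = Spectrum(axis=x, intensity=np.ones(50), time=0.0)
        bad = Spectrum(axis=x, intensity=np.full(50, -1.0), time=1.0)
        with pytest.raises(ValidationError, match="acquisition 1"):
            similarity_trace(SpectrumSeries(spectra=[good, bad]), metric="jaccard")

    def test_fid_trace_with_xcorr(self):
        fids = [
            synthgen.simulate_fid([(50.0, 0.05, 1.0 - 0.1 * i, 0.0)],
                                  dwell=1e-3, n=128, time=float(i))
            for i in range(5)
        ]
        trace = similarity_trace(fids, metric="xcorr")
        assert trace.values[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(trace.values > 0.99)  # amplitude changes cancel
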