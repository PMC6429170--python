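"""Density backends: Silverman bandwidth, KDE/Gaussian likelihoods, Bayes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import norm

import erpleak as el
from erpleak.density import LOG2_DENSITY_FLOOR, _kde_log_density


class TestSilverman:
    def test_rule_value_n900_unit_sd(self, rng):
        """sd = 1 and IQR/1.34 >= 1 give h = 0.9 * 900^(-1/5) ~ 0.2309."""
        # uniform(-a, a) with unit sample sd has IQR/1.34 > 1
        x = rng.uniform(-np.sqrt(3), np.sqrt(3), 900)
        x = (x - x.mean()) / x.std(ddof=1)
        h = el.silverman_bandwidth(x)
        assert h == pytest.approx(0.9 * 900 ** (-0.2), rel=1e-3)

    def test_two_point_closed_form(self):
        """n=2, values {0,1}: sd = 1/sqrt(2), IQR = 0.5 by linear interpolation."""
        h = el.silverman_bandwidth(np.array([0.0, 1.0]))
        expected = 0.9 * min(np.sqrt(0.5), 0.5 / 1.34) * 2 ** (-0.2)
        assert h == pytest.approx(expected, rel=1e-12)
        assert h > 0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 50))
    def test_scale_equivariance(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(50)
        assert el.silverman_bandwidth(c * x) == pytest.approx(
            c * el.silverman_bandwidth(x), rel=1e-9)

    def test_zero_spread_error(self):
        with pytest.raises(ValueError, match="spread"):
            el.silverman_bandwidth(np.ones(10))


class TestFit:
    def test_empirical_priors_pin_mode(self, reduced_small):
        red, labels = reduced_small
        model = el.fit(red.scores, labels)
        i1 = model.class_index(1)
        assert model.priors[i1] == pytest.approx(labels.mean())
        assert model.priors.sum() == pytest.approx(1.0)

    def test_gaussian_recovery_large_n(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10_000), rng.normal(3, 1, 10_000)])
        y = np.repeat([0, 1], 10_000)
        model = el.fit(x, y, backend="gaussian")
        np.testing.assert_allclose(model.means[:, 0], [0.0, 3.0], atol=0.05)
        np.testing.assert_allclose(model.sds[:, 0], [1.0, 1.0], atol=0.05)

    def test_kde_two_points_closed_form(self):
        """Density at 0 for training points {-1, +1} equals the two-kernel mean."""
        train = np.array([-1.0, 1.0])
        h = el.silverman_bandwidth(train)
        ln = _kde_log_density(np.array([0.0]), train, h)
        expected = np.mean(norm.pdf(0.0, loc=train, scale=h))
        assert np.exp(ln[0]) == pytest.approx(expected, rel=1e-12)

    def test_missing_class_error(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            el.fit(rng.standard_normal(10), np.zeros(10, dtype=int))


class TestLog2Likelihood:
    def test_gaussian_closed_form_at_class_mean(self):
        """2-D unit-SD Gaussian model evaluated at its own mean:
        log2 f = 2 * log2(1/sqrt(2*pi))."""
        rngl = np.random.default_rng(1)
        x = np.vstack([rngl.normal(0, 1, (200, 2)), rngl.normal(5, 1, (200, 2))])
        y = np.repeat([0, 1], 200)
        model = el.fit(x, y, backend="gaussian")
        model.means[:] = [[0.0, 0.0], [5.0, 5.0]]
        model.sds[:] = 1.0
        ll = el.log2_likelihood(model, np.array([[0.0, 0.0]]))
        assert ll[0, 0] == pytest.approx(2 * np.log2(1 / np.sqrt(2 * np.pi)), rel=1e-12)

    def test_product_rule_over_dimensions(self, rng):
        x = rng.standard_normal((100, 2))
        y = (rng.random(100) > 0.5).astype(int)
        m2 = el.fit(x, y, backend="kde")
        ma = el.fit(x[:, 0], y, backend="kde")
        mb = el.fit(x[:, 1], y, backend="kde")
        joint = el.log2_likelihood(m2, x[:5])
        parts = el.log2_likelihood(ma, x[:5, 0]) + el.log2_likelihood(mb, x[:5, 1])
        np.testing.assert_allclose(joint, parts, rtol=1e-10)

    def test_training_point_finite_under_kde(self, rng):
        x = rng.standard_normal(20)
        y = np.repeat([0, 1], 10)
        model = el.fit(x, y, backend="kde")
        ll = el.log2_likelihood(model, x)
        assert np.isfinite(ll).all()
        assert (ll > 2 * LOG2_DENSITY_FLOOR).all()

    def test_kde_integrates_to_one(self, rng):
        x = rng.standard_normal(60)
        h = el.silverman_bandwidth(x)
        lo, hi = x.min() - 8 * h, x.max() + 8 * h
        val, _ = integrate.quad(
            lambda t: np.exp(_kde_log_density(np.array([t]), x, h)[0]), lo, hi,
            limit=200)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_backends_agree_on_large_gaussian_sample(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10_000), rng.normal(2, 1, 10_000)])
        y = np.repeat([0, 1], 10_000)
        kde = el.fit(x, y, backend="kde")
        gau = el.fit(x, y, backend="gaussian")
        grid = rng.normal(1, 1, 200)
        diff = np.abs(el.log2_likelihood(kde, grid) - el.log2_likelihood(gau, grid))
        assert diff.mean() < 0.1


class TestPosterior:
    def test_equal_likelihoods_uniform_prior(self, rng):
        x = rng.standard_normal(40)
        y = np.repeat([0, 1], 20)
        model = el.fit(x, y, backend="gaussian")
        model.means[:] = 0.0
        model.sds[:] = 1.0
        post = el.posterior(model, np.array([0.3]), prior_mode="uniform")
        np.testing.assert_allclose(post.probs, 0.5, atol=1e-12)

    def test_equal_likelihoods_empirical_prior(self, reduced_small):
        red, labels = reduced_small
        model = el.fit(red.scores, labels, backend="gaussian")
        model.means[:] = model.means.mean(axis=0)
        model.sds[:] = 1.0
        post = el.posterior(model, np.zeros((1, red.scores.shape[1])),
                            prior_mode="empirical")
        np.testing.assert_allclose(np.sort(post.probs[0]), np.sort(model.priors),
                                   atol=1e-12)

    def test_hand_bayes_oracle_two_class_1d(self):
        """Gaussian 1-D two-class posterior against the Bayes formula computed
        longhand with scipy.stats.norm."""
        rngl = np.random.default_rng(3)
        x = np.concatenate([rngl.normal(0, 1, 50), rngl.normal(2, 0.5, 50)])
        y = np.repeat([0, 1], 50)
        model = el.fit(x, y, backend="gaussian")
        pts = np.array([0.0, 1.0, 2.5])
        post = el.posterior(model, pts, prior_mode="empirical")
        f0 = norm.pdf(pts, model.means[0, 0], model.sds[0, 0])
        f1 = norm.pdf(pts, model.means[1, 0], model.sds[1, 0])
        expected = (f1 * model.priors[1]) / (f0 * model.priors[0] + f1 * model.priors[1])
        np.testing.assert_allclose(post.probs[:, 1], expected, rtol=1e-10)

    def test_rows_sum_to_one(self, reduced_small):
        red, labels = reduced_small
        model = el.fit(red.scores, labels)
        post = el.posterior(model, red.scores[:50])
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)


class TestClip:
    def test_below_floor_raised(self):
        p = el.PosteriorArray(probs=np.array([[0.0005, 0.9995]]),
                              classes=np.array([0, 1]), prior_mode="uniform")
        out = el.clip_posteriors(p)
        assert out.probs[0, 0] == 0.001
        assert out.probs[0, 1] == 0.9995        # no renormalization
        assert out.clipped

    def test_above_floor_unchanged(self):
        p = el.PosteriorArray(probs=np.array([[0.5, 0.5]]),
                              classes=np.array([0, 1]), prior_mode="uniform")
        out = el.clip_posteriors(p)
        np.testing.assert_array_equal(out.probs, p.probs)

    def test_invalid_floor(self):
        p = el.PosteriorArray(probs=np.array([[0.5, 0.5]]),
                              classes=np.array([0, 1]), prior_mode="uniform")
        with pytest.raises(ValueError):
            el.clip_posteriors(p, floor=0.7)


def test_model_json_roundtrip(tmp_path, rng):
    x = rng.standard_normal((40, 2))
    y = np.repeat([0, 1], 20)
    for backend in ("kde", "gaussian"):
        model = el.fit(x, y, backend=backend)
        path = tmp_path / f"{backend}.json"
        model.to_json(path)
        back = el.ClassConditionalDensity.from_json(path)
        pts = rng.standard_normal((5, 2))
        np.testing.assert_allclose(el.log2_likelihood(back, pts),
                                   el.log2_likelihood(model, pts), rtol=1e-12)
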