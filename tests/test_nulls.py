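"""iAAFT surrogates, time-point bootstrap, and Gaussian summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecmap.atlas import ROITimeSeries
from ecmap.nulls import (
    SurrogateConfig,
    _iaaft_block,
    bootstrap_ec_distribution,
    fit_gaussian,
    iaaft_surrogate,
    surrogate_ec_distribution,
)


def _periodogram_err(x, s):
    po = np.abs(np.fft.rfft(x)) ** 2
    ps = np.abs(np.fft.rfft(s)) ** 2
    return np.mean(np.abs(ps[1:] - po[1:]) / po[1:])


def _lag1(v):
    v = v - v.mean()
    return np.sum(v[1:] * v[:-1]) / np.sum(v * v)


class TestIAAFT:
    def test_constant_series_unchanged_with_warning(self, caplog):
        x = np.full(16, 3.0)
        with caplog.at_level("WARNING"):
            s = iaaft_surrogate(x, seed=0)
        assert np.array_equal(s, x)
        assert "constant" in caplog.text

    @given(st.integers(min_value=0, max_value=10_000))
    def test_value_multiset_conserved(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64) * rng.uniform(0.1, 10)
        s = iaaft_surrogate(x, rng=rng)
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_spectrum_and_autocorrelation_fidelity(self, rng, make_ar1):
        errs, dlag = [], []
        for _ in range(20):
            x = make_ar1(rng, 0.6, 260)[:, 0]
            s = iaaft_surrogate(x, rng=rng)
            errs.append(_periodogram_err(x, s))
            dlag.append(abs(_lag1(s) - _lag1(x)))
        assert np.mean(errs) < 0.05
        assert np.mean(dlag) < 0.1

    def test_spectrum_error_shrinks_with_iterations(self, make_ar1):
        """Average periodogram error is non-increasing over early iterations."""
        means = []
        for k in (1, 2, 3, 4, 5):
            rng = np.random.default_rng(99)
            errs = []
            for _ in range(30):
                x = make_ar1(rng, 0.6, 260)[:, 0]
                errs.append(_periodogram_err(x, iaaft_surrogate(x, max_iter=k, rng=rng)))
            means.append(np.mean(errs))
        assert all(means[i + 1] <= means[i] + 1e-9 for i in range(4))

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="T >= 4"):
            iaaft_surrogate(np.array([1.0, 2.0, 3.0]))


def _cohort(rng, n_sub=3, t=120, n_roi=12, shared=0.8):
    cohort = []
    for i in range(n_sub):
        common = rng.standard_normal((t, 1))
        data = shared * common + rng.standard_normal((t, n_roi))
        cohort.append(ROITimeSeries(data=data, roi_ids=list(range(n_roi)),
                                    tr=1.0, participant_id=f"s{i}"))
    return cohort


class TestSurrogateDistribution:
    def test_cross_roi_correlation_destroyed(self, rng):
        t = 260
        cohort = _cohort(rng, n_sub=1, t=t, n_roi=10, shared=1.5)
        surro = _iaaft_block(cohort[0].data, max_iter=20, rng=rng)
        r = np.corrcoef(surro.T)
        off = np.abs(r[~np.eye(10, dtype=bool)])
        assert off.mean() < 2 / np.sqrt(t) + 0.02

    def test_centered_near_uniform_centrality_not_zero(self, rng):
        n_roi = 25
        cohort = _cohort(rng, n_sub=2, t=150, n_roi=n_roi, shared=1.0)
        nd = surrogate_ec_distribution(
            cohort, SurrogateConfig(n_surrogates=15, max_iter=10, seed=7))
        center = nd.samples.mean()
        assert center == pytest.approx(1 / np.sqrt(n_roi), abs=0.01)
        assert center > 0.1  # emphatically not a zero-centered null

    def test_single_surrogate_sigma_zero(self, rng):
        cohort = _cohort(rng, n_sub=1, t=60, n_roi=5)
        nd = surrogate_ec_distribution(cohort, SurrogateConfig(n_surrogates=1, seed=1))
        assert np.all(nd.gauss_sigma == 0.0)


class _IdentityRNG(np.random.Generator):
    """Generator stub whose integer draws return the identity index vector."""

    def __init__(self):
        super().__init__(np.random.PCG64(0))

    def integers(self, low, high=None, size=None, **kwargs):  # noqa: D102
        n = size if isinstance(size, int) else int(np.prod(size))
        hi = high if high is not None else low
        return (np.arange(n) % hi).reshape(size if not isinstance(size, int) else (n,))


class TestBootstrapDistribution:
    def test_identity_resample_reproduces_point_estimate(self, rng):
        from ecmap.centrality import ec_from_ts

        cohort = _cohort(rng, n_sub=2, t=80, n_roi=8)
        nd = bootstrap_ec_distribution(cohort, n_boot=1, seed=_IdentityRNG())
        point = np.mean([ec_from_ts(ts).ec for ts in cohort], axis=0)
        assert np.allclose(nd.samples[0], point, atol=1e-12)

    def test_seeded_bit_reproducibility(self, rng):
        cohort = _cohort(rng, n_sub=2, t=60, n_roi=6)
        a = bootstrap_ec_distribution(cohort, n_boot=5, seed=11)
        b = bootstrap_ec_distribution(cohort, n_boot=5, seed=11)
        assert np.array_equal(a.samples, b.samples)

    def test_joint_resampling_preserves_planted_correlation_sign(self, rng):
        t = 150
        base = rng.standard_normal(t)
        x = np.column_stack([base, 0.8 * base + 0.6 * rng.standard_normal(t),
                             rng.standard_normal(t)])
        ts = ROITimeSeries(data=x, roi_ids=[0, 1, 2], tr=1.0, participant_id="s")
        rng2 = np.random.default_rng(5)
        for _ in range(20):
            idx = rng2.integers(0, t, size=t)
            r = np.corrcoef(x[idx, 0], x[idx, 1])[0, 1]
            assert r > 0

    def test_bootstrap_mean_close_to_point_estimate(self, rng):
        from ecmap.centrality import ec_from_ts

        cohort = _cohort(rng, n_sub=3, t=200, n_roi=10, shared=1.2)
        nd = bootstrap_ec_distribution(cohort, n_boot=60, seed=3)
        point = np.mean([ec_from_ts(ts).ec for ts in cohort], axis=0)
        se = nd.samples.std(axis=0, ddof=1)
        assert np.all(np.abs(nd.samples.mean(axis=0) - point) < 2.5 * se + 1e-3)

    def test_block_variant_runs(self, rng):
        cohort = _cohort(rng, n_sub=1, t=50, n_roi=5)
        nd = bootstrap_ec_distribution(cohort, n_boot=3, seed=0, block=True)
        assert nd.samples.shape == (3, 5)


class TestFitGaussian:
    @pytest.mark.parametrize("samples,expected", [
        ([1.0, 1.0, 1.0], (1.0, 0.0)),
        ([0.0, 2.0], (1.0, np.sqrt(2.0))),
    ])
    def test_closed_forms(self, samples, expected):
        mu, sigma = fit_gaussian(np.array(samples))
        assert mu == pytest.approx(expected[0])
        assert sigma == pytest.approx(expected[1])

    def test_single_sample_warns(self, caplog):
        with caplog.at_level("WARNING"):
            mu, sigma = fit_gaussian(np.array([4.2]))
        assert (mu, sigma) == (4.2, 0.0)

    def test_large_sample_recovery(self, rng):
        mu, sigma = fit_gaussian(rng.standard_normal(10_000))
        assert mu == pytest.approx(0.0, abs=0.05)
        assert sigma == pytest.approx(1.0, abs=0.05)


def test_surrogate_vs_bootstrap_separation(rng):
    """With strong planted correlation, bootstrap hub EC mass sits above the
    surrogate null's 99th percentile."""
    t, n_roi = 200, 12
    cohort = []
    for i in range(3):
        common = rng.standard_normal((t, 1))
        lam = np.full(n_roi, 0.5)
        lam[[2, 7]] = 2.0  # strong hubs
        data = lam * common + rng.standard_normal((t, n_roi))
        cohort.append(ROITimeSeries(data=data, roi_ids=list(range(n_roi)),
                                    tr=1.0, participant_id=f"s{i}"))
    sur = surrogate_ec_distribution(cohort, SurrogateConfig(n_surrogates=25,
                                                            max_iter=10, seed=2))
    boot = bootstrap_ec_distribution(cohort, n_boot=25, seed=3)
    for hub in (2, 7):
        cut = np.quantile(sur.for_roi(hub), 0.99)
        assert np.mean(boot.for_roi(hub) > cut) > 0.95
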