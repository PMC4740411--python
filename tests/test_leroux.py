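"""Leroux precision structure, Geweke diagnostic, posterior summaries."""

import numpy as np
import pytest

import caremap as cm
from caremap.errors import ValidationError
from caremap.leroux import _LAG_EXPONENT

from .test_moran import random_connected_graph


class TestPrecision:
    def test_rho_zero_is_identity(self, lattice44):
        q = cm.leroux_precision(0.0, lattice44).toarray()
        np.testing.assert_allclose(q, np.eye(16))

    def test_rho_to_one_limit_is_graph_laplacian(self, lattice44):
        w = lattice44.matrix().toarray()
        lap = np.diag(lattice44.degrees.astype(float)) - w
        q = cm.leroux_precision(1.0 - 1e-9, lattice44).toarray()
        np.testing.assert_allclose(q, lap, atol=1e-6)

    def test_rho_outside_range_rejected(self, lattice44):
        for rho in (-0.1, 1.0, 1.5):
            with pytest.raises(ValidationError):
                cm.leroux_precision(rho, lattice44)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_eigenvalue_logdet_matches_dense(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        adj = random_connected_graph(n, rng)
        eig = cm.structure_eigenvalues(adj)
        for rho in (0.0, 0.3, 0.8, 0.99):
            dense = cm.leroux_precision(rho, adj).toarray()
            sign, want = np.linalg.slogdet(dense)
            assert sign > 0
            assert cm.leroux_logdet(rho, eig) == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_positive_definite_for_all_rho_with_islands(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        adj = random_connected_graph(n, rng)
        # add two isolated islands
        ids = adj.area_ids + ("island1", "island2")
        edges = [
            (i, j) for i, nb in enumerate(adj.neighbors) for j in nb if i < j
        ]
        adj = cm.Adjacency.from_edges(ids, edges)
        assert adj.isolated.sum() == 2
        for rho in np.linspace(0.0, 0.999, 12):
            q = cm.leroux_precision(float(rho), adj).toarray()
            np.linalg.cholesky(q)  # raises LinAlgError if not PD


class TestGeweke:
    def test_engineered_drift_flagged(self):
        rng = np.random.default_rng(0)
        chain = np.concatenate(
            [-1 + 0.1 * rng.standard_normal(500), 1 + 0.1 * rng.standard_normal(500)]
        )
        z = cm.geweke(chain)
        assert abs(z) > 10

    def test_zero_variance_window_rejected(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            cm.geweke(np.ones(1000))

    def test_short_chain_rejected(self):
        with pytest.raises(ValidationError, match="100"):
            cm.geweke(np.arange(50.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_fft_spectral_oracle(self, seed):
        """Time-domain windowed autocovariance vs an FFT route, same window."""
        rng = np.random.default_rng(seed)
        # AR(1) chains with varying persistence
        phi = rng.uniform(-0.5, 0.9)
        eps = rng.standard_normal(2000)
        chain = np.empty(2000)
        chain[0] = eps[0]
        for t in range(1, 2000):
            chain[t] = phi * chain[t - 1] + eps[t]

        def fft_spectral0(x):
            x = np.asarray(x, float)
            n = len(x)
            z = x - x.mean()
            L = max(1, int(round(n**_LAG_EXPONENT)))
            nfft = 1 << (2 * n - 1).bit_length()
            acov = np.fft.irfft(np.abs(np.fft.rfft(z, nfft)) ** 2)[: L + 1] / n
            w = 1.0 - np.arange(1, L + 1) / (L + 1.0)
            return acov[0] + 2.0 * float(w @ acov[1:])

        n = len(chain)
        a, b = chain[: n // 10], chain[n - n // 2:]
        z_oracle = (a.mean() - b.mean()) / np.sqrt(
            fft_spectral0(a) / len(a) + fft_spectral0(b) / len(b)
        )
        assert cm.geweke(chain) == pytest.approx(z_oracle, abs=0.05)

    def test_iid_chain_rarely_flagged(self):
        rng = np.random.default_rng(99)
        flags = sum(
            abs(cm.geweke(rng.standard_normal(2000))) >= 1.96 for _ in range(100)
        )
        assert flags <= 15


class TestSummaries:
    def _fit_from_samples(self, beta, tau2, rho, names=("intercept",)):
        n_s = len(tau2)
        return cm.LerouxFit(
            beta=np.asarray(beta, float).reshape(n_s, -1),
            phi=np.zeros((n_s, 1)),
            tau2=np.asarray(tau2, float),
            rho=np.asarray(rho, float),
            coef_names=tuple(names),
            area_ids=("a",),
        )

    def test_constant_samples_collapse_interval(self):
        f = self._fit_from_samples(np.full(200, 2.5), np.full(200, 0.1), np.full(200, 0.5))
        t = cm.summarize(f).table
        assert t.loc["intercept", "median"] == 2.5
        assert t.loc["intercept", "q2.5"] == 2.5
        assert t.loc["intercept", "q97.5"] == 2.5

    def test_uniform_grid_quantiles(self):
        grid = np.arange(1, 10_001) / 10_000.0
        f = self._fit_from_samples(grid, grid, grid * 0.99)
        t = cm.summarize(f).table
        assert t.loc["intercept", "median"] == pytest.approx(0.5, abs=1e-4)
        assert t.loc["intercept", "q2.5"] == pytest.approx(0.025, abs=1e-3)
        assert t.loc["intercept", "q97.5"] == pytest.approx(0.975, abs=1e-3)

    def test_quantiles_match_full_sort_oracle(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(size=5001)
        f = self._fit_from_samples(samples, np.abs(samples), np.zeros(5001))
        t = cm.summarize(f).table

        def sort_quantile(x, q):
            s = np.sort(x)
            pos = (len(s) - 1) * q
            lo = int(np.floor(pos))
            frac = pos - lo
            hi = min(lo + 1, len(s) - 1)
            return s[lo] * (1 - frac) + s[hi] * frac

        assert t.loc["intercept", "median"] == sort_quantile(samples, 0.5)
        assert t.loc["intercept", "q2.5"] == pytest.approx(
            sort_quantile(samples, 0.025), abs=1e-12
        )
        assert t.loc["intercept", "q97.5"] == pytest.approx(
            sort_quantile(samples, 0.975), abs=1e-12
        )

    def test_rr_attached_for_covariates_with_ordered_bounds(self):
        rng = np.random.default_rng(2)
        beta = np.column_stack([rng.normal(size=300), 0.1 + 0.05 * rng.normal(size=300)])
        f = cm.LerouxFit(
            beta=beta,
            phi=np.zeros((300, 1)),
            tau2=np.abs(rng.normal(size=300)) + 0.01,
            rho=rng.uniform(0, 1, 300),
            coef_names=("intercept", "exposure"),
            area_ids=("a",),
        )
        t = cm.summarize(f).table
        row = t.loc["exposure"]
        assert row["rr"] == pytest.approx(np.exp(row["median"]))
        assert row["rr_lower"] <= row["rr"] <= row["rr_upper"]
        assert np.isnan(t.loc["intercept", "rr"])


class TestRRTransform:
    def test_published_physician_coefficient(self):
        rr = cm.rr_from_coef(0.015, 0.004, 0.026)
        assert round(rr["rr"], 3) == 1.015
        assert round(rr["rr_lower"], 3) == 1.004
        assert round(rr["rr_upper"], 3) == 1.026

    def test_published_psychiatrist_coefficient(self):
        rr = cm.rr_from_coef(-0.100, -0.148, -0.053)
        assert round(rr["rr"], 1) == 0.9
        assert rr["rr"] == pytest.approx(0.905, abs=5e-4)

    def test_zero_maps_to_unit_rr(self):
        rr = cm.rr_from_coef(0.0, -0.1, 0.1)
        assert rr["rr"] == 1.0
        assert rr["rr_lower"] < 1.0 < rr["rr_upper"]
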