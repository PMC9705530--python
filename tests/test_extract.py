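import numpy as np
import pytest

from conftest import gaussian_blob
from volca.errors import ParameterError
from volca.extract import (
    ExtractParams,
    FactorModel,
    correlation_image,
    evaluate_components,
    fit_model,
    merge_components,
    peak_snr,
    run_extraction,
    seed_components,
    spatial_correlation,
)
from volca.io import Movie4D


def planted_movie(meta, footprints, traces, noise=0.0, seed=0, baseline=0.0):
    """Movie = sum_i footprint_i x trace_i (+ noise), no background."""
    t = traces.shape[1]
    data = np.zeros((t, *footprints.shape[1:]))
    for fp, tr in zip(footprints, traces):
        data += fp[None] * tr[:, None, None, None]
    data += baseline
    if noise:
        data += noise * np.random.default_rng(seed).standard_normal(data.shape)
    return Movie4D(np.clip(data, 0, None), meta)


def kernel_trace(t_len, spike_frames, dt=0.2):
    from volca.synth import SensorKinetics, make_kernel

    k = make_kernel(SensorKinetics(), dt, 8.0)
    tr = np.zeros(t_len)
    tr[list(spike_frames)] = 1.0
    return np.convolve(tr, k)[:t_len]


class TestCorrelationImage:
    def test_independent_noise_near_zero(self, meta20x):
        rng = np.random.default_rng(0)
        movie = Movie4D(rng.random((200, 4, 8, 8)), meta20x)
        corr = correlation_image(movie)
        assert np.abs(corr).max() < 0.25
        assert abs(corr.mean()) < 0.02

    def test_matches_bruteforce_neighbor_loop(self, meta20x):
        rng = np.random.default_rng(1)
        movie = Movie4D(rng.random((30, 4, 8, 8)), meta20x)
        corr = correlation_image(movie)
        data = movie.data
        z, y, x = 2, 3, 4
        vals = []
        for dz, dy, dx in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < 4 and 0 <= ny < 8 and 0 <= nx < 8:
                a, b = data[:, z, y, x], data[:, nz, ny, nx]
                # population Pearson correlation
                vals.append(
                    np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
                )
        assert corr[z, y, x] == pytest.approx(np.mean(vals), abs=1e-10)

    def test_global_trace_gives_unit_correlation(self, meta20x):
        rng = np.random.default_rng(2)
        trace = rng.random(50)
        data = trace[:, None, None, None] * np.ones((1, 4, 8, 8))
        data += 1e-6 * rng.standard_normal(data.shape)
        corr = correlation_image(Movie4D(np.clip(data, 0, None), meta20x))
        assert corr.min() > 0.99

    def test_isolated_flickering_voxel_scores_low(self, meta20x):
        data = np.ones((40, 4, 8, 8))
        data[:, 2, 4, 4] += np.random.default_rng(3).random(40)
        data += 1e-4 * np.random.default_rng(4).standard_normal(data.shape)
        corr = correlation_image(Movie4D(np.clip(data, 0, None), meta20x))
        assert abs(corr[2, 4, 4]) < 0.3


class TestSeedComponents:
    def test_two_blobs_found_at_centers(self):
        corr = gaussian_blob((8, 24, 24), (4, 6, 6), (1.5, 2, 2))
        corr += gaussian_blob((8, 24, 24), (4, 16, 16), (1.5, 2, 2))
        seeds = seed_components(corr, ExtractParams(rf=None, K=5))
        assert len(seeds) == 2
        found = {tuple(s) for s in seeds}
        for target in [(4, 6, 6), (4, 16, 16)]:
            assert any(max(abs(np.subtract(s, target))) <= 1 for s in found)

    def test_flat_map_gives_no_seeds(self):
        assert seed_components(np.zeros((4, 12, 12)), ExtractParams()) == []

    def test_k_limits_to_strongest(self):
        corr = 1.0 * gaussian_blob((8, 24, 24), (4, 6, 6), (1.5, 2, 2))
        corr += 0.5 * gaussian_blob((8, 24, 24), (4, 16, 16), (1.5, 2, 2))
        seeds = seed_components(corr, ExtractParams(rf=None, K=1))
        assert len(seeds) == 1
        assert max(abs(np.subtract(seeds[0], (4, 6, 6)))) <= 1


class TestFitModel:
    def test_single_component_exact_factorization(self, meta20x):
        fp = gaussian_blob((8, 16, 16), (4, 8, 8), (1.2, 2, 2))
        fp[fp < 0.05] = 0
        trace = kernel_trace(60, [5, 25, 40])
        movie = planted_movie(meta20x, fp[None], trace[None])
        params = ExtractParams(rf=None, K=1, nb=0)
        model = fit_model(movie, [(4, 8, 8)], params, n_iter=50)
        assert model.n_components == 1
        rec = model.reconstruction()
        rel = np.linalg.norm(rec - movie.data) / np.linalg.norm(movie.data)
        assert rel < 1e-3
        r = np.corrcoef(model.C[0], trace)[0, 1]
        assert r > 0.999

    def test_objective_monotonically_nonincreasing(self, meta20x):
        rng = np.random.default_rng(5)
        fp = gaussian_blob((6, 12, 12), (3, 6, 6), (1.2, 2, 2))
        trace = kernel_trace(40, [3, 20])
        movie = planted_movie(meta20x, fp[None], trace[None], noise=0.05, seed=5)
        model = fit_model(movie, [(3, 6, 6)], ExtractParams(rf=None, nb=1), n_iter=25)
        obj = np.array(model.objective)
        assert np.all(np.diff(obj) <= 1e-8 * obj[0])

    def test_two_disjoint_neurons_identity_correlation(self, meta20x):
        fp1 = gaussian_blob((8, 24, 24), (4, 6, 6), (1.2, 2, 2))
        fp2 = gaussian_blob((8, 24, 24), (4, 18, 18), (1.2, 2, 2))
        for fp in (fp1, fp2):
            fp[fp < 0.05] = 0
        t1 = kernel_trace(80, [5, 40])
        t2 = kernel_trace(80, [20, 60])
        movie = planted_movie(meta20x, np.stack([fp1, fp2]), np.stack([t1, t2]))
        model = fit_model(movie, [(4, 6, 6), (4, 18, 18)], ExtractParams(rf=None, nb=0), n_iter=50)
        R = np.corrcoef(np.vstack([model.C, [t1, t2]]))[:2, 2:]
        matched = R[[0, 1], [0, 1]] if R[0, 0] > R[0, 1] else R[[0, 1], [1, 0]]
        off = R[[0, 1], [1, 0]] if R[0, 0] > R[0, 1] else R[[0, 1], [0, 1]]
        assert np.all(matched > 0.99)
        assert np.all(np.abs(off) < 0.5)

    def test_nan_movie_rejected(self, meta20x):
        data = np.ones((5, 4, 8, 8))
        data[0, 0, 0, 0] = np.nan
        with pytest.raises(ParameterError):
            fit_model(Movie4D(data, meta20x), [(2, 4, 4)], ExtractParams())

    def test_no_seeds_rejected(self, small_movie):
        with pytest.raises(ParameterError):
            fit_model(small_movie, [], ExtractParams())


class TestEvaluateComponents:
    def _model_with_trace(self, trace, shape=(4, 8, 8)):
        fp = np.zeros((1, *shape))
        fp[0, 2, 3:6, 3:6] = 1.0
        return FactorModel(
            A=fp, C=np.asarray(trace)[None], b=np.zeros((0, 0)), f=np.zeros((0, 0)),
            volume_shape=shape,
        )

    def test_flat_trace_has_zero_snr_and_is_rejected(self, meta20x):
        model = self._model_with_trace(np.ones(30))
        assert peak_snr(model.C[0]) == 0.0
        movie = Movie4D(np.ones((30, 4, 8, 8)), meta20x)
        assert not evaluate_components(model, movie)[0]

    def test_noiseless_planted_component_accepted(self, meta20x):
        fp = gaussian_blob((4, 8, 8), (2, 4, 4), (1, 1.5, 1.5))
        trace = kernel_trace(40, [5, 20])
        movie = planted_movie(meta20x, fp[None], trace[None], noise=1e-4, seed=6)
        model = FactorModel(
            A=fp[None], C=trace[None], b=np.zeros((0, 0)), f=np.zeros((0, 0)),
            volume_shape=(4, 8, 8),
        )
        assert spatial_correlation(model, movie, 0) > 0.95
        assert evaluate_components(model, movie)[0]

    def test_peak_snr_formula_on_seeded_noise(self):
        rng = np.random.default_rng(42)
        trace = rng.standard_normal(500)
        d = np.diff(trace)
        sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2)
        expected = (trace.max() - np.median(trace)) / sigma
        assert peak_snr(trace) == pytest.approx(expected, rel=1e-12)
        # a pure-noise trace peaks near 3 sigma, which passes a >= 1 threshold
        assert (peak_snr(trace) >= 1.0) == (expected >= 1.0)


class TestMergeComponents:
    def _two_component_model(self, fp1, fp2, c1, c2):
        return FactorModel(
            A=np.stack([fp1, fp2]), C=np.stack([c1, c2]),
            b=np.zeros((0, 0)), f=np.zeros((0, 0)), volume_shape=fp1.shape,
        )

    def test_duplicates_merge_to_one(self):
        fp = gaussian_blob((4, 8, 8), (2, 4, 4), (1, 1.5, 1.5))
        c = kernel_trace(30, [4])
        merged = merge_components(self._two_component_model(fp, fp, c, c))
        assert merged.n_components == 1

    def test_low_trace_correlation_not_merged(self):
        fp = gaussian_blob((4, 8, 8), (2, 4, 4), (1, 1.5, 1.5))
        rng = np.random.default_rng(7)
        c1 = rng.random(60)
        # construct a partner with correlation ~0.5
        c2 = 0.5 * (c1 - c1.mean()) / c1.std() + np.sqrt(0.75) * rng.standard_normal(60)
        c2 = c2 - c2.min()
        r = np.corrcoef(c1, c2)[0, 1]
        assert r < 0.8
        merged = merge_components(self._two_component_model(fp, fp, c1, c2), 0.8)
        assert merged.n_components == 2

    def test_transitive_merge_of_three(self):
        fp = gaussian_blob((4, 10, 10), (2, 5, 5), (1, 2, 2))
        base = kernel_trace(50, [5, 30])
        rng = np.random.default_rng(8)
        model = FactorModel(
            A=np.stack([fp, fp, fp]),
            C=np.stack([base, base + 0.01 * rng.random(50), base + 0.01 * rng.random(50)]),
            b=np.zeros((0, 0)), f=np.zeros((0, 0)), volume_shape=fp.shape,
        )
        merged = merge_components(model, 0.8)
        assert merged.n_components == 1

    def test_disjoint_footprints_never_merge(self):
        fp1 = np.zeros((4, 8, 8)); fp1[1, :3, :3] = 1
        fp2 = np.zeros((4, 8, 8)); fp2[3, 5:, 5:] = 1
        c = kernel_trace(30, [4])
        merged = merge_components(self._two_component_model(fp1, fp2, c, c))
        assert merged.n_components == 2


class TestRunExtraction:
    def test_pure_noise_yields_empty_set(self, meta20x):
        rng = np.random.default_rng(9)
        movie = Movie4D(rng.random((60, 8, 16, 16)).astype(np.float32), meta20x)
        with pytest.warns(UserWarning):
            cset = run_extraction(movie, ExtractParams(rf=None, K=5))
        assert len(cset) == 0

    def test_small_planted_movie_recovered(self, meta20x):
        fp1 = gaussian_blob((8, 24, 24), (3, 7, 7), (1.2, 2.5, 2.5))
        fp2 = gaussian_blob((8, 24, 24), (5, 16, 16), (1.2, 2.5, 2.5))
        for fp in (fp1, fp2):
            fp[fp < 0.05] = 0
        t1 = kernel_trace(100, [5, 40, 70])
        t2 = kernel_trace(100, [25, 55, 90])
        movie = planted_movie(
            meta20x, np.stack([fp1, fp2]), 10 * np.stack([t1, t2]),
            noise=0.1, seed=10, baseline=1.0,
        )
        cset = run_extraction(movie, ExtractParams(rf=None, K=4, nb=1))
        assert len(cset) >= 2
        R = np.corrcoef(np.vstack([cset.traces, [t1, t2]]))[: len(cset), len(cset):]
        assert R.max(axis=0).min() > 0.95

    def test_no_duplicate_pairs_in_output(self, meta20x):
        fp = gaussian_blob((8, 24, 24), (4, 12, 12), (1.2, 2.5, 2.5))
        fp[fp < 0.05] = 0
        tr = kernel_trace(80, [10, 50])
        movie = planted_movie(meta20x, fp[None], 10 * tr[None], noise=0.05, seed=11, baseline=1.0)
        cset = run_extraction(movie, ExtractParams(rf=None, K=6, nb=1))
        for i in range(len(cset)):
            for j in range(i + 1, len(cset)):
                overlap = np.any((cset.footprints[i] > 0) & (cset.footprints[j] > 0))
                r = np.corrcoef(cset.traces[i], cset.traces[j])[0, 1]
                assert not (overlap and r >= 0.8)
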