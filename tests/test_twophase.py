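"""Two-phase demixing, one-phase baseline, interleaving, metrics."""

import warnings

import numpy as np
import pytest

import decimix as dx
from decimix import pearson


@pytest.fixture(scope="module")
def pair_scene():
    """Two close neurons plus a bystander; at l=8 the pair shares its coarse
    block, so pixel averages mix the two traces."""
    centers = np.array([[18, 18], [22, 22], [8, 38]])
    spec = dx.SceneSpec(H=48, W=48, N=3, T=500, radius=2.5, spike_rate=0.03,
                        noise_sigma=0.2, min_spikes=3, centers=centers, seed=21)
    return dx.make_scene(spec)


@pytest.fixture(scope="module")
def merged_pairs_scene():
    """Four neuron pairs, each fully inside one 16x16 block, placed so the
    half-shifted grid separates them (the interleaving mechanism)."""
    centers = []
    for bi, bj in [(0, 1), (1, 3), (2, 0), (3, 2)]:
        centers.append((16 * bi + 4, 16 * bj + 4))
        centers.append((16 * bi + 11, 16 * bj + 11))
    spec = dx.SceneSpec(H=64, W=64, N=8, T=600, radius=2.0, spike_rate=0.03,
                        noise_sigma=0.15, min_spikes=3,
                        centers=np.array(centers), seed=8)
    return dx.make_scene(spec)


class TestDecimateModel:
    def test_l1_identity(self, pair_scene):
        m = pair_scene.truth_model()
        ml = dx.decimate_model(m, 1, 1)
        np.testing.assert_allclose(ml.A, m.A)
        np.testing.assert_allclose(ml.b, m.b)

    def test_linearity_with_reconstruction(self, pair_scene):
        m = pair_scene.truth_model()
        ml = dx.decimate_model(m, 4, 4)
        M = dx.decimation_matrix(48, 48, 4, 4)
        np.testing.assert_allclose(ml.reconstruction(), M @ m.reconstruction(),
                                   atol=1e-9)

    def test_one_hot_shape(self):
        m = dx.FactorModel(A=np.array([[1.0], [0], [0], [0]]),
                           C=np.ones((1, 2)), b=np.zeros(4), f=np.ones(2),
                           H=2, W=2)
        ml = dx.decimate_model(m, 2, 2)
        np.testing.assert_allclose(ml.A, [[0.25]])


class TestDemixLowres:
    def test_l1_matches_plain_fit(self, pair_scene):
        b = pair_scene
        model = b.truth_model()
        Y = dx.flatten(b.noisy)
        res = dx.demix_lowres(Y, dx.decimate_model(model, 1, 1), None,
                              deconvolve=False)
        # phase A is jointly convex: compare against a long direct HALS run
        ref = model.copy()
        ref.C = np.zeros_like(ref.C)
        ref.f = np.ones_like(ref.f)
        for _ in range(300):
            ref.C, ref.f = dx.hals_activity(Y, ref, inner=1)
        for n in range(3):
            assert pearson(res.C[n], ref.C[n]) >= 0.9999

    def test_noiseless_identifiable_exact(self, noiseless_scene):
        b = noiseless_scene
        model = b.truth_model()
        Y = dx.flatten(b.noiseless)
        ml = dx.decimate_model(model, 2, 2)
        Yl, _ = dx.decimate_spatial(Y, 2, 2, grid=(32, 32))
        res = dx.demix_lowres(Yl, ml, None, deconvolve=False, tol=1e-14,
                              max_sweeps=2000)
        for n in range(b.spec.N):
            assert pearson(res.C[n], b.C_true[n]) >= 1 - 1e-6

    def test_overlapping_pair_beats_pixel_average_baseline(self, pair_scene):
        b = pair_scene
        model = b.truth_model()
        Y = dx.flatten(b.noisy)
        l = 8
        ml = dx.decimate_model(model, l, l)
        Yl, (Hd, Wd) = dx.decimate_spatial(Y, l, l, grid=(48, 48))
        ar = dx.ARModel(np.tile(b.spec.gamma, (3, 1)))
        res = dx.demix_lowres(Yl, ml, ar)
        # baseline: average the coarse pixels under each footprint
        base = np.zeros((2, b.spec.T))
        for n in range(2):
            w = ml.A[:, n]
            base[n] = w @ Yl / w.sum()
        for n in range(2):
            assert pearson(res.C[n], b.C_true[n]) >= 0.9
        gap = min(pearson(res.C[n], b.C_true[n])
                  - pearson(base[n], b.C_true[n]) for n in range(2))
        assert gap >= 0.1

    def test_zero_column_flagged(self, pair_scene):
        b = pair_scene
        model = b.truth_model()
        model.A[:, 1] = 0.0
        with pytest.warns(RuntimeWarning, match="all-zero"):
            res = dx.demix_lowres(dx.flatten(b.noisy), model, None,
                                  deconvolve=False)
        assert res.zero_components == [1]
        np.testing.assert_array_equal(res.C[1], 0.0)


class TestOnePhase:
    def test_l1_clean_no_purges(self, noiseless_scene):
        b = noiseless_scene
        model = b.truth_model()
        centers = dx.CenterList(b.centers, expected_radius=2.5)
        model.patches = [p.copy() for p in
                         dx.build_patches(centers, 6, 32, 32).indices]
        Y = dx.flatten(b.noiseless)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, purged = dx.run_one_phase(
                Y, model, None, dx.NoiseMap(np.zeros(model.D)))
        assert purged == []
        assert fitted.N == b.spec.N

    def test_degenerate_merged_pair_collapses(self, merged_pairs_scene):
        """Two neurons merged into identical coarse signatures at l=16: the
        one-phase baseline purges one of them or its trace decorrelates —
        the qualitative single-phase failure mode."""
        b = merged_pairs_scene
        model = b.truth_model()
        l = 16
        ml = dx.decimate_model(model, l, l)
        ml.C = b.C_true.copy()
        Yl, _ = dx.decimate_spatial(dx.flatten(b.noisy), l, l, grid=(64, 64))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, purged = dx.run_one_phase(
                Yl, ml, dx.ARModel(np.tile(b.spec.gamma, (8, 1))),
                dx.estimate_pixel_noise(Yl))
        surv = fitted.meta["survivors"]
        cors = np.zeros(8)
        for n in range(8):
            if n not in purged:
                cors[n] = pearson(b.C_true[n], fitted.C[surv.index(n)])
        # at least one member of some pair purged or badly decorrelated
        pair_fail = any(len(purged) > 0 for _ in [0]) or np.min(cors) < 0.8
        assert pair_fail

    def test_purged_report_zero_correlation(self):
        report = dx.evaluate_recovery(
            np.random.default_rng(0).random((3, 50)),
            {8: {"C": np.random.default_rng(1).random((3, 50)), "purged": [1]}})
        assert report.correlations[8][1] == 0.0


class TestInterleaved:
    def test_reduces_to_plain_when_grids_identical(self, pair_scene):
        # at l=1 the half shift is zero, so both parity grids coincide and
        # interleaved demixing must match the plain path
        b = pair_scene
        model = b.truth_model()
        Y = dx.flatten(b.noisy)
        pair = dx.interleave_movie(b.noisy, 1, 1)
        res_i = dx.demix_interleaved(pair, model, None, tol=1e-12)
        res_p = dx.demix_lowres(Y.copy(), model.copy(), None, deconvolve=False,
                                tol=1e-12)
        np.testing.assert_allclose(res_i.C, res_p.C, atol=1e-5)

    def test_noiseless_exact(self):
        centers = np.array([[6, 6], [16, 16]])
        spec = dx.SceneSpec(H=24, W=24, N=2, T=300, radius=2.0, spike_rate=0.03,
                            noise="none", min_spikes=2, centers=centers, seed=2)
        b = dx.make_scene(spec)
        model = b.truth_model()
        pair = dx.interleave_movie(b.noiseless, 4, 4)
        res = dx.demix_interleaved(pair, model, None, tol=1e-14, max_sweeps=3000)
        for n in range(2):
            assert pearson(res.C[n], b.C_true[n]) >= 1 - 1e-6

    def test_interleaving_separates_merged_pairs(self, merged_pairs_scene):
        b = merged_pairs_scene
        model = b.truth_model()
        ar = dx.ARModel(np.tile(b.spec.gamma, (8, 1)))
        l = 16
        Y = dx.flatten(b.noisy)
        ml = dx.decimate_model(model, l, l)
        Yl, _ = dx.decimate_spatial(Y, l, l, grid=(64, 64))
        plain = dx.demix_lowres(Yl, ml, ar)
        inter = dx.demix_interleaved(dx.interleave_movie(b.noisy, l, l), model, ar)
        plain_c = [pearson(b.C_true[n], plain.C[n]) for n in range(8)]
        inter_c = [pearson(b.C_true[n], inter.C[n]) for n in range(8)]
        assert np.median(inter_c) >= np.median(plain_c)
        assert all(ic > pc for ic, pc in zip(inter_c, plain_c))


class TestReconstruct:
    def test_decoder_beats_raw_data_at_l8(self, standard_bundle, standard_fit,
                                          standard_demix):
        """The compression decoder (full-res shapes x coarse traces) tracks
        the noiseless truth far better than the raw noisy movie does:
        coarse acquisition plus demixing is a denoising compressor."""
        b = standard_bundle
        model = standard_fit["model"]
        res = standard_demix[8]["result"]
        clean = dx.flatten(b.noiseless)
        rec = model.A @ res.C + np.outer(model.b, res.f)
        cc = clean - clean.mean(axis=1, keepdims=True)
        rc = rec - rec.mean(axis=1, keepdims=True)
        Y = dx.flatten(b.noisy)
        yy = Y - Y.mean(axis=1, keepdims=True)
        corr_rec = pearson(rc.ravel(), cc.ravel())
        corr_raw = pearson(yy.ravel(), cc.ravel())
        assert corr_rec >= 0.85
        assert corr_rec > corr_raw

    def test_noiseless_scene_exact(self, noiseless_scene):
        b = noiseless_scene
        movie = dx.reconstruct(b.truth_model())
        np.testing.assert_allclose(movie.data, b.noiseless.data, atol=1e-6)

    def test_background_only(self):
        m = dx.FactorModel(A=np.zeros((4, 0)), C=np.zeros((0, 3)),
                           b=np.array([1.0, 2, 3, 4]), f=np.array([1.0, 0.5, 2]),
                           H=2, W=2)
        movie = dx.reconstruct(m)
        np.testing.assert_allclose(dx.flatten(movie),
                                   np.outer(m.b, m.f))


class TestRanking:
    def test_one_hot_score(self):
        m = dx.FactorModel(A=np.array([[1.0], [0], [0], [0]]),
                           C=np.array([[0.5, 2.0, 1.0]]), b=np.zeros(4),
                           f=np.ones(3), H=2, W=2)
        order, scores = dx.rank_components(m)
        np.testing.assert_allclose(scores, [2.0])

    def test_compact_ranks_above_spread(self):
        # equal unit-norm traces: a footprint spread uniformly over 16 pixels
        # scores 16^(-1/4), a compact one over 4 pixels scores 4^(-1/4)
        A = np.zeros((16, 2))
        A[:16, 0] = 1.0 / 4.0   # unit l2-norm, spread
        A[:4, 1] = 1.0 / 2.0    # unit l2-norm, compact
        m = dx.FactorModel(A=A, C=np.ones((2, 5)), b=np.zeros(16),
                           f=np.ones(5), H=4, W=4)
        order, scores = dx.rank_components(m)
        np.testing.assert_allclose(scores, [16**-0.25, 4**-0.25])
        assert order[0] == 1

    def test_scale_split_invariance(self):
        rng = np.random.default_rng(1)
        A = np.abs(rng.normal(size=(9, 2))) + 0.1
        C = np.abs(rng.normal(size=(2, 6))) + 0.1
        m1 = dx.FactorModel(A=A, C=C, b=np.zeros(9), f=np.ones(6), H=3, W=3)
        m2 = dx.FactorModel(A=A * [3.0, 0.2], C=C / np.array([[3.0], [0.2]]),
                            b=np.zeros(9), f=np.ones(6), H=3, W=3)
        np.testing.assert_allclose(dx.rank_components(m1)[1],
                                   dx.rank_components(m2)[1])


class TestDff:
    def test_background_proportional_to_shape(self):
        a = np.zeros(9)
        a[4] = 1.0
        beta = 2.5
        m = dx.FactorModel(A=a[:, None], C=np.array([[1.0, 4.0, 0.0]]),
                           b=beta * a, f=np.ones(3), H=3, W=3)
        dff, flagged = dx.compute_dff(m, 0)
        np.testing.assert_allclose(dff, m.C[0] / beta)
        assert not flagged.any()

    def test_scale_split_invariance(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.normal(size=9)) + 0.1
        C = np.array([[1.0, 2.0, 0.5]])
        b = np.abs(rng.normal(size=9)) + 0.1
        m1 = dx.FactorModel(A=a[:, None], C=C, b=b, f=np.ones(3), H=3, W=3)
        m2 = dx.FactorModel(A=5 * a[:, None], C=C / 5, b=b, f=np.ones(3),
                            H=3, W=3)
        np.testing.assert_allclose(dx.compute_dff(m1, 0)[0],
                                   dx.compute_dff(m2, 0)[0])

    def test_orthogonal_background_flagged(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        m = dx.FactorModel(A=a[:, None], C=np.ones((1, 2)), b=b,
                           f=np.ones(2), H=1, W=2)
        with pytest.warns(RuntimeWarning, match="baseline"):
            dff, flagged = dx.compute_dff(m, 0)
        assert flagged.all()


class TestRecoveryMetrics:
    def test_pearson_conventions(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pearson(x, -x) == pytest.approx(-1.0, abs=1e-12)
        assert pearson(x, np.full(4, 2.0)) == 0.0

    def test_report_reference_nmse_is_one(self):
        C = np.random.default_rng(3).random((4, 30))
        report = dx.evaluate_recovery(
            C, {1: {"C": C, "rss": 123.0}}, reference_rss=123.0)
        assert report.nmse[1] == 1.0
        np.testing.assert_allclose(report.correlations[1], 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dx.evaluate_recovery(np.zeros((2, 10)), {1: {"C": np.zeros((2, 9))}})
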