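import numpy as np
import pytest

from morphgen.evaluation import (
    SampleSet,
    conditioning_recovery,
    evaluate_datasets,
    failure_rate,
    fid,
    g4_ssim,
    gaussian_kl,
    mmd,
    ms_ssim,
    ms_ssim_diversity,
    random_projection_features,
    region_stats,
    ssim3d,
    voxelwise_tmap,
)
from morphgen.phantoms import (
    CovariateRecord,
    PhantomSpec,
    Volume,
    render_phantom,
    sample_covariates,
)

rng = np.random.default_rng(99)


class TestMMD:
    def test_identical_sets_zero(self):
        a = rng.normal(size=(10, 4))
        assert mmd(a, a) == 0.0

    def test_hand_computed_kernel_sums(self):
        # {0, 0} vs {1, 1} in 1D with fixed bandwidth 1:
        # k(a,a) terms all exp(0)=1; k(a,b) terms all exp(-1/2)
        a = np.array([[0.0], [0.0]])
        b = np.array([[1.0], [1.0]])
        expected = 1.0 + 1.0 - 2 * np.exp(-0.5)
        assert np.isclose(mmd(a, b, bandwidth=1.0), expected)

    def test_matches_double_loop_oracle(self):
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(6, 3))
        h = 1.3

        def k(x, y):
            return np.exp(-((x - y) ** 2).sum() / (2 * h * h))

        kaa = np.mean([[k(x, y) for y in a] for x in a])
        kbb = np.mean([[k(x, y) for y in b] for x in b])
        kab = np.mean([[k(x, y) for y in b] for x in a])
        assert np.isclose(mmd(a, b, bandwidth=h), kaa + kbb - 2 * kab, rtol=1e-10)

    def test_nonnegative(self):
        for _ in range(5):
            a, b = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
            assert mmd(a, b) >= -1e-12

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mmd(np.empty((0, 3)), rng.normal(size=(3, 3)))


class TestFID:
    def test_identical_sets_zero(self):
        a = rng.normal(size=(30, 4))
        assert abs(fid(a, a)) < 1e-8

    def test_mean_shift_closed_form(self):
        # same samples shifted by d: covariances equal -> FID = ||d||^2
        a = rng.normal(size=(200, 3))
        d = np.array([1.0, -2.0, 0.5])
        got = fid(a, a + d)
        assert np.isclose(got, d @ d, rtol=1e-6, atol=1e-8)

    def test_matches_two_gaussian_oracle(self):
        from scipy import linalg

        a, b = rng.normal(size=(50, 4)), rng.normal(0.3, 1.2, size=(60, 4))
        mu_a, mu_b = a.mean(0), b.mean(0)
        sa, sb = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
        srt = linalg.sqrtm(sa @ sb).real
        expected = ((mu_a - mu_b) ** 2).sum() + np.trace(sa + sb - 2 * srt)
        assert np.isclose(fid(a, b), expected, rtol=1e-7)


class TestSSIMFamily:
    def test_self_similarity_is_one(self):
        x = rng.random((16, 16, 16))
        assert np.isclose(ssim3d(x, x), 1.0)
        assert np.isclose(ms_ssim(x, x), 1.0)
        assert np.isclose(g4_ssim(x, x), 1.0)

    def test_anticorrelated_structure_low(self):
        spec = PhantomSpec(noise_sd=0.02, bias_field_strength=0.05, seed=4)
        x = render_phantom(sample_covariates(1, spec)[0], spec).data
        val = ms_ssim(x, 1.0 - x)
        assert val < 0.5

    def test_identical_set_diversity_one(self):
        x = rng.random((16, 16, 16))
        mean, sd = ms_ssim_diversity([x, x.copy(), x.copy()])
        assert np.isclose(mean, 1.0) and np.isclose(sd, 0.0)

    def test_constant_images_equal(self):
        x = np.full((16, 16, 16), 0.4)
        assert np.isclose(g4_ssim(x, x.copy()), 1.0)

    def test_g4_matches_pipeline_oracle(self):
        from scipy import ndimage

        x, y = rng.random((12, 12, 12)), rng.random((12, 12, 12))
        kernels = (
            np.array([[1.0, -1.0], [0.0, 0.0]]),
            np.array([[1.0, 0.0], [-1.0, 0.0]]),
            np.array([[1.0, 0.0], [0.0, -1.0]]),
            np.array([[0.0, 1.0], [-1.0, 0.0]]),
        )

        def gmag(a):
            acc = np.zeros_like(a)
            for k in kernels:
                r = ndimage.convolve(a, k[:, :, None], mode="nearest")
                acc += r * r
            return np.sqrt(acc)

        assert np.isclose(g4_ssim(x, y), ssim3d(gmag(x), gmag(y)), rtol=1e-12)

    def test_small_volume_reduces_scales(self):
        x, y = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        assert np.isfinite(ms_ssim(x, y))


class TestRegionStats:
    def test_identical_samples(self):
        v = rng.normal(10, 2, size=40)
        rs = region_stats(v, v)
        assert rs.wasserstein == 0.0
        assert np.isclose(rs.kl, 0.0, atol=1e-12)
        assert rs.glass_delta == 0.0
        assert rs.mannwhitney_p > 0.99

    def test_pure_shift_closed_form(self):
        v = rng.normal(10, 2, size=50)
        c = 3.7
        rs = region_stats(v, v + c)
        assert np.isclose(rs.wasserstein, c, rtol=1e-10)
        assert np.isclose(rs.glass_delta, c / v.std(ddof=1), rtol=1e-10)

    def test_u_statistic_matches_bruteforce_paircount(self):
        real = rng.normal(size=23)
        synth = rng.normal(0.4, 1.3, size=19)
        rs = region_stats(real, synth)
        u = sum(
            1.0 if s > r else (0.5 if s == r else 0.0)
            for s in synth for r in real
        )
        assert np.isclose(rs.mannwhitney_u, u)

    def test_u_bruteforce_with_ties(self):
        real = np.repeat([1.0, 2.0, 3.0], 5)
        synth = np.repeat([2.0, 3.0, 4.0], 5)
        rs = region_stats(real, synth)
        u = sum(
            1.0 if s > r else (0.5 if s == r else 0.0)
            for s in synth for r in real
        )
        assert np.isclose(rs.mannwhitney_u, u)

    def test_zero_real_variance_delta_nan(self):
        rs = region_stats(np.full(10, 5.0), rng.normal(size=10))
        assert np.isnan(rs.glass_delta)

    def test_gaussian_kl_oracle(self):
        p = rng.normal(0, 1, 4000)
        q = rng.normal(1, 2, 4000)
        got = gaussian_kl(p, q)
        mp, sp = p.mean(), p.std(ddof=1)
        mq, sq = q.mean(), q.std(ddof=1)
        expected = np.log(sq / sp) + (sp**2 + (mp - mq) ** 2) / (2 * sq**2) - 0.5
        assert np.isclose(got, expected, rtol=1e-12)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            region_stats([1.0], [1.0, 2.0])


class TestFailureRate:
    def test_all_at_reference_mean(self):
        synth = {"a": np.full(10, 5.0), "b": np.full(10, 2.0)}
        ref = {"a": (5.0, 1.0), "b": (2.0, 1.0)}
        assert failure_rate(synth, ref) == 0.0

    def test_exact_counting(self):
        vals = np.zeros(100)
        vals[17] = 6.0
        assert failure_rate({"a": vals}, {"a": (0.0, 1.0)}) == 0.01

    def test_matches_double_loop_oracle(self):
        regions = {f"r{i}": rng.normal(size=50) for i in range(4)}
        ref = {f"r{i}": (0.1 * i, 0.5 + 0.1 * i) for i in range(4)}
        thr = 1.5
        got = failure_rate(regions, ref, threshold=thr)
        count = 0
        for s in range(50):
            bad = False
            for i in range(4):
                m, sd = ref[f"r{i}"]
                if abs((regions[f"r{i}"][s] - m) / sd) > thr:
                    bad = True
            count += bad
        assert np.isclose(got, count / 50)

    def test_zero_sd_region_excluded(self, caplog):
        synth = {"a": np.zeros(5), "b": np.full(5, 9.0)}
        ref = {"a": (0.0, 1.0), "b": (0.0, 0.0)}
        assert failure_rate(synth, ref) == 0.0


class TestConditioningRecovery:
    def test_perfect_recovery(self):
        v = rng.random(20)
        r, p = conditioning_recovery(v, v)
        assert np.isclose(r, 1.0)

    def test_shuffled_pairs_mostly_null(self):
        # permutation distribution: |r| small, p large for shuffled pairings
        v = rng.random(200)
        perm_rng = np.random.default_rng(0)
        rs = []
        for _ in range(200):
            r, _ = conditioning_recovery(v, perm_rng.permutation(v))
            rs.append(abs(r))
        assert np.median(rs) < 0.1

    def test_zero_variance_undefined(self):
        r, p = conditioning_recovery(np.full(10, 2.0), rng.random(10))
        assert np.isnan(r)


class TestVoxelwiseTmap:
    def test_identical_groups_zero_map(self):
        g = rng.normal(size=(4, 6, 6, 6))
        t, valid = voxelwise_tmap(g, g.copy())
        np.testing.assert_array_equal(t, np.zeros((6, 6, 6)))

    def test_matches_scalar_welch_oracle(self):
        from scipy import stats

        a = rng.normal(size=(8, 1, 1, 1))
        b = rng.normal(0.5, 2.0, size=(9, 1, 1, 1))
        t, _ = voxelwise_tmap(a, b)
        expected = stats.ttest_ind(a[:, 0, 0, 0], b[:, 0, 0, 0], equal_var=False)
        assert np.isclose(t[0, 0, 0], expected.statistic)

    def test_signal_localized_in_ventricle_mask(self):
        spec = PhantomSpec(noise_sd=0.02, bias_field_strength=0.0, seed=8)
        base = CovariateRecord(sex=0, age=55, ventricle_volume=250, brain_size=1.0)
        small = [render_phantom(base.replace(age=55 + i * 0.5), spec) for i in range(6)]
        big = [render_phantom(base.replace(age=55 + i * 0.5,
                                           ventricle_volume=800), spec)
               for i in range(6)]
        t, _ = voxelwise_tmap(small, big)
        vent_union = np.zeros(spec.grid_shape, dtype=bool)
        for v in small + big:
            vent_union |= v.region_masks["ventricles"]
        thr = np.quantile(np.abs(t), 0.99)
        top = np.abs(t) >= thr
        frac = (top & vent_union).sum() / top.sum()
        assert frac > 0.8

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            voxelwise_tmap(rng.normal(size=(1, 4, 4, 4)), rng.normal(size=(3, 4, 4, 4)))


@pytest.fixture(scope="module")
def corpus():
    spec = PhantomSpec(noise_sd=0.02, bias_field_strength=0.05, seed=23)
    recs = sample_covariates(16, spec)
    return [render_phantom(r, spec) for r in recs]


class TestReport:
    def test_self_comparison_metric_identities(self, corpus, tmp_path):
        out = evaluate_datasets(corpus[:8], corpus[:8], out_dir=tmp_path)
        s = out["summary"]
        assert abs(s["mmd"]) < 1e-12
        assert abs(s["fid"]) < 1e-6
        assert (tmp_path / "regions.tsv").exists()
        assert (tmp_path / "summary.json").exists()

    def test_equal_size_protocol_enforced(self, corpus):
        with pytest.raises(ValueError, match="equal-size"):
            evaluate_datasets(corpus[:8], corpus[:5])
        out = evaluate_datasets(corpus[:8], corpus[:5], enforce_equal_size=False)
        assert out["summary"]["n_synth"] == 5

    def test_split_halves_null_calibration(self, corpus):
        out = evaluate_datasets(corpus[:8], corpus[8:])
        for region, rs in out["regions"].per_region.items():
            assert rs.mannwhitney_p > 0.01

    def test_doubled_ventricles_positive_delta(self):
        spec = PhantomSpec(noise_sd=0.02, bias_field_strength=0.05, seed=31)
        recs = sample_covariates(8, spec)
        real = [render_phantom(r, spec) for r in recs]
        synth = [render_phantom(r.replace(ventricle_volume=min(2 * r.ventricle_volume, 900.0)), spec)
                 for r in recs]
        out = evaluate_datasets(real, synth)
        assert out["regions"].per_region["ventricles"].glass_delta > 0

    def test_sample_set_validates_shapes(self):
        with pytest.raises(ValueError):
            SampleSet([Volume(np.zeros((4, 4, 4))), Volume(np.zeros((5, 4, 4)))])

    def test_features_deterministic(self):
        x = rng.random((5, 16, 16, 16))
        np.testing.assert_array_equal(
            random_projection_features(x, seed=3),
            random_projection_features(x, seed=3),
        )
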