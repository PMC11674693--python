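"""The 22 texture features: printed-formula fidelity against a naive oracle."""

import numpy as np
import pytest

import stripscan as ss
from stripscan.features import EPS, FEATURE_NAMES, compute_features, marginals


def random_p(rng, Ng):
    m = rng.random((Ng, Ng)) ** 2
    return m / m.sum()


def naive_features(p: np.ndarray) -> dict:
    """Independent double-loop implementation of every feature.

    Written deliberately without vectorisation so it shares nothing with the
    production path beyond the definitions themselves.
    """
    Ng = p.shape[0]
    log2e = lambda x: np.log2(x + EPS)

    px = [sum(p[i][j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(p[i][j] for i in range(Ng)) for j in range(Ng)]
    mu_x = sum((i + 1) * px[i] for i in range(Ng))
    mu_y = sum((j + 1) * py[j] for j in range(Ng))
    sig_x = (sum((i + 1) ** 2 * px[i] for i in range(Ng)) - mu_x**2) ** 0.5
    sig_y = (sum((j + 1) ** 2 * py[j] for j in range(Ng)) - mu_y**2) ** 0.5

    psum = {k: 0.0 for k in range(2, 2 * Ng + 1)}
    pdiff = {k: 0.0 for k in range(0, Ng)}
    for i in range(Ng):
        for j in range(Ng):
            psum[(i + 1) + (j + 1)] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    f = {}
    f["autoc"] = sum((i + 1) * (j + 1) * p[i][j] for i in range(Ng) for j in range(Ng))
    f["contr"] = sum((i - j) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng))
    cov = sum((i + 1 - mu_x) * (j + 1 - mu_y) * p[i][j] for i in range(Ng) for j in range(Ng))
    f["corrm"] = cov / (sig_x * sig_y) if sig_x * sig_y > 0 else 0.0
    f["corrp"] = (f["autoc"] - mu_x * mu_y) / (sig_x * sig_y) if sig_x * sig_y > 0 else 0.0
    f["cprom"] = sum(((i + 1) + (j + 1) - mu_x - mu_y) ** 4 * p[i][j]
                     for i in range(Ng) for j in range(Ng))
    f["cshad"] = sum(((i + 1) + (j + 1) - mu_x - mu_y) ** 3 * p[i][j]
                     for i in range(Ng) for j in range(Ng))
    f["dissi"] = sum(abs(i - j) * p[i][j] for i in range(Ng) for j in range(Ng))
    f["energ"] = sum(p[i][j] ** 2 for i in range(Ng) for j in range(Ng))
    f["entro"] = -sum(p[i][j] * log2e(p[i][j]) for i in range(Ng) for j in range(Ng))
    f["homom"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng))
    f["homop"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(Ng) for j in range(Ng))
    f["maxpr"] = max(p[i][j] for i in range(Ng) for j in range(Ng))
    f["sosvh"] = sum((i + 1 - mu_x) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng))
    f["savgh"] = sum(k * v for k, v in psum.items())
    f["senth"] = -sum(v * log2e(v) for v in psum.values())
    f["svarh"] = sum((k - f["senth"]) ** 2 * v for k, v in psum.items())
    mu_d = sum(k * v for k, v in pdiff.items())
    f["dvarh"] = sum((k - mu_d) ** 2 * v for k, v in pdiff.items())
    f["denth"] = -sum(v * log2e(v) for v in pdiff.values())
    hx = -sum(v * log2e(v) for v in px)
    hy = -sum(v * log2e(v) for v in py)
    hxy1 = -sum(p[i][j] * log2e(px[i] * py[j]) for i in range(Ng) for j in range(Ng))
    hxy2 = -sum(px[i] * py[j] * log2e(px[i] * py[j]) for i in range(Ng) for j in range(Ng))
    denom = max(hx, hy)
    f["inf1h"] = (f["entro"] - hxy1) / denom if denom > 0 else 0.0
    f["inf2h"] = (max(0.0, 1 - 2.0 ** (-2 * (hxy2 - f["entro"])))) ** 0.5
    f["indnc"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(Ng) for j in range(Ng))
    f["idmnc"] = sum(p[i][j] / (1 + (i - j) ** 2 / Ng**2) for i in range(Ng) for j in range(Ng))
    return f


class TestMarginals:
    def test_point_mass_moments(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0  # gray-level index 1
        st = marginals(p)
        assert st.mu_x == st.mu_y == 1.0
        assert st.sigma_x == st.sigma_y == 0.0

    def test_uniform_two_level_enumeration(self):
        p = np.full((2, 2), 0.25)
        st = marginals(p)
        assert st.mu_x == st.mu_y == pytest.approx(1.5)
        # pX+Y over k=2,3,4
        assert np.allclose(st.p_xplusy, [0.25, 0.5, 0.25])

    def test_distributions_normalised(self):
        rng = np.random.default_rng(0)
        st = marginals(random_p(rng, 8))
        for dist in (st.px, st.py, st.p_xplusy, st.p_xminusy):
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sigma_agrees_with_direct_definition(self):
        rng = np.random.default_rng(1)
        p = random_p(rng, 6)
        st = marginals(p)
        idx = np.arange(1, 7)
        direct = np.sqrt(np.sum(st.px * (idx - st.mu_x) ** 2))
        assert st.sigma_x == pytest.approx(direct, abs=1e-12)

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            marginals(np.ones((3, 3)))


class TestComputeFeatures:
    def test_degenerate_texture(self):
        """A constant patch concentrates all mass in one diagonal cell."""
        p = np.zeros((8, 8))
        p[2, 2] = 1.0
        f = compute_features(p)
        assert f["energ"] == pytest.approx(1.0, abs=1e-12)
        assert f["entro"] == pytest.approx(0.0, abs=1e-10)
        assert f["contr"] == 0.0
        assert f["homom"] == pytest.approx(1.0, abs=1e-12)
        assert f["maxpr"] == 1.0
        assert f["dissi"] == 0.0

    def test_toy_glcm_homogeneity_hand_value(self, toy_glcm_p):
        # sum over the 7 occupied cells of count/(1+|i-j|), divided by 12
        f = compute_features(toy_glcm_p)
        assert f["homom"] == pytest.approx(9.8333333333 / 12, abs=1e-9)

    def test_toy_glcm_max_probability(self, toy_glcm_p):
        assert compute_features(toy_glcm_p)["maxpr"] == pytest.approx(3 / 12)

    def test_checkerboard_contrast_is_one(self):
        board = np.indices((8, 8)).sum(axis=0) % 2  # levels {0,1}
        q = ss.quantise(board * 255.0, Ng=2)
        f = compute_features(ss.ahmo(q, d_max=1).p)
        assert f["contr"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_oracle(self):
        """All 22 features agree with the double-loop reference to 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            Ng = int(rng.integers(2, 9))
            p = random_p(rng, Ng)
            ours = compute_features(p)
            ref = naive_features(p)
            for name in FEATURE_NAMES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_output_order_and_cardinality(self):
        f = compute_features(random_p(np.random.default_rng(3), 8))
        assert tuple(f) == FEATURE_NAMES
        assert len(f) == 22

    def test_value_ranges(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            f = compute_features(random_p(rng, int(rng.integers(2, 17))))
            for name in ("energ", "homom", "indnc", "idmnc", "maxpr"):
                assert 0 < f[name] <= 1 + 1e-12, name
            for name in ("entro", "senth", "denth"):
                assert f[name] >= -1e-10, name
            assert -1 - 1e-12 <= f["corrm"] <= 1 + 1e-12
            assert all(np.isfinite(v) for v in f.values())

    def test_transpose_invariance_for_symmetric_matrix(self):
        rng = np.random.default_rng(5)
        p = random_p(rng, 6)
        p = (p + p.T) / 2
        f1 = compute_features(p)
        f2 = compute_features(p.T)
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)

    def test_relaxed_indnc_variant(self):
        rng = np.random.default_rng(6)
        p = random_p(rng, 8)
        strict = compute_features(p, strict_printed_formulas=True)
        relaxed = compute_features(p, strict_printed_formulas=False)
        assert strict["indnc"] == pytest.approx(strict["homop"])
        assert relaxed["indnc"] != pytest.approx(strict["indnc"])


class TestFeaturesForPatches:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_patches():
        images = ss.generate_dataset(ss.StripParams(), 1, seed=9)
        return ss.expand_dataset(images)

    def test_one_row_per_patch_with_metadata(self, small_patches):
        table = ss.features_for_patches(small_patches)
        assert table.shape[0] == len(small_patches)
        assert list(table.columns[:22]) == list(FEATURE_NAMES)
        assert {"label", "source_image", "side", "patch_index"} <= set(table.columns)

    def test_rerun_is_bitwise_identical(self, small_patches):
        t1 = ss.features_for_patches(small_patches)
        t2 = ss.features_for_patches(small_patches)
        assert t1.equals(t2)

    def test_single_patch(self, small_patches):
        table = ss.features_for_patches(small_patches[:1])
        assert table.shape[0] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ss.features_for_patches([])
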