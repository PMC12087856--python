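import numpy as np
import pytest
from scipy import stats as sps

from npskin.applicability import (
    fit_applicability_domain,
    generate_insilico,
    layer_ranges,
)
from npskin.datamodel import FeatureEncoder
from npskin.stats import dunn_test, kruskal_wallis
from npskin.synth import GeneratorConfig, generate_frame


def kruskal_oracle(groups):
    """Direct rank-based evaluation with tie correction."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie if tie > 0 else 0.0


@pytest.fixture(scope="module")
def domain():
    X = np.random.default_rng(0).normal(size=(80, 6))
    return X, fit_applicability_domain(X, d=3)


@pytest.fixture(scope="module")
def source():
    return generate_frame(GeneratorConfig(n_records=300, seed=9,
                                          missingness={}))


class TestApplicabilityDomain:
    def test_training_points_contained(self, domain):
        X, ad = domain
        assert ad.contains(X).all()

    def test_centroid_contained(self, domain):
        X, ad = domain
        assert ad.contains(X.mean(axis=0, keepdims=True))[0]

    def test_far_point_outside(self, domain):
        X, ad = domain
        far = X.mean(axis=0) + 100.0 * X.std(axis=0)
        assert not ad.contains(far[None, :])[0]

    def test_rank_deficient_reduces_d(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 2))
        X = np.column_stack([base, base @ [[1.0], [2.0]]])  # rank 2
        with pytest.warns(UserWarning, match="rank-deficient"):
            ad = fit_applicability_domain(X, d=3)
        assert ad.d == 2

    def test_membership_invariant_to_affine_pc_reparam(self, domain):
        """Scaling the PC basis does not change hull membership."""
        X, ad = domain
        rng = np.random.default_rng(2)
        probes = X.mean(axis=0) + rng.normal(size=(50, X.shape[1]))
        before = ad.contains(probes)
        scale = np.array([2.0, 0.5, 3.0])
        from scipy.spatial import Delaunay
        scores = ad.pca.transform(X)[:, :3] * scale
        tri = Delaunay(scores)
        after = tri.find_simplex(ad.pca.transform(probes)[:, :3] * scale) >= 0
        np.testing.assert_array_equal(before, after)


class TestInSilicoPopulation:
    def test_bounds_and_size(self, source):
        pop = generate_insilico(source, n=2000, seed=1)
        assert pop.n == 2000
        lo, hi = pop.bounds["core_diameter_nm"]
        d = pop.frame["core_diameter_nm"]
        assert d.between(lo, hi).all()
        c = pop.frame["concentration_ug_ml"]
        clo, chi = pop.bounds["concentration_ug_ml"]
        assert c.between(clo, chi).all()

    def test_fixed_human_context(self, source):
        pop = generate_insilico(source, n=500, seed=2)
        assert (pop.frame["species"] == "human").all()
        assert pop.frame["sc_thickness_um"].nunique() == 1

    def test_seed_reproducibility_and_divergence(self, source):
        a = generate_insilico(source, n=1500, seed=3).frame["core_diameter_nm"]
        b = generate_insilico(source, n=1500, seed=3).frame["core_diameter_nm"]
        c = generate_insilico(source, n=1500, seed=4).frame["core_diameter_nm"]
        assert sps.ks_2samp(a, b).statistic == 0.0
        assert sps.ks_2samp(a, c).statistic > 0.0

    def test_categoricals_from_observed_levels(self, source):
        pop = generate_insilico(source, n=500, seed=5)
        for col in ("shape", "medium", "np_class"):
            assert set(pop.frame[col]) <= set(source[col].dropna())


class TestLayerRanges:
    def test_kruskal_matches_rank_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 15, size=rng.integers(3, 12)).astype(float)
                      for _ in range(k)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_null_simulation_false_positive_rate(self, rng):
        """Under the null (all groups one distribution) the test rejects
        at ~alpha: the false-positive rate stays inside the 3-sigma
        binomial band around 0.05, i.e. ~94-95% of repetitions are
        non-significant."""
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(size=40) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            hits += p < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) <= band

    def test_disjoint_supports_extremely_significant(self):
        groups = [np.arange(50.0), np.arange(100.0, 150.0)]
        dt = dunn_test(groups)
        assert (dt["p_adjusted"] < 1e-6).all()

    def test_constant_groups_have_zero_h(self):
        h, p = kruskal_wallis([np.ones(10), np.ones(12)])
        assert h == 0.0 and p == 1.0

    def test_adjusted_p_at_least_raw(self, rng):
        groups = [rng.normal(loc=m, size=25) for m in (0.0, 0.2, 0.5, 1.0)]
        dt = dunn_test(groups)
        assert (dt["p_adjusted"] >= dt["p_raw"] - 1e-15).all()

    def test_layer_range_report_structure(self):
        """A size-thresholding surrogate model yields a full report: the
        size descriptor separates the predicted layers, and all p-values
        are proper probabilities."""
        source = generate_frame(GeneratorConfig(n_records=300, seed=10,
                                                missingness={}))
        enc = FeatureEncoder().fit(source)
        pop = generate_insilico(source, n=3000, seed=6)

        class SizeModel:
            def __init__(self, col):
                self.col = col

            def predict(self, X):
                z = X[:, self.col]
                out = np.where(z < -0.5, "Dermis",
                               np.where(z < 0.5, "Epidermis", "SC"))
                return out

        fm = enc.transform(pop.frame)
        model = SizeModel(fm.column("log10_core_diameter"))
        report = layer_ranges(pop, model, enc)
        assert report.kruskal["p"].between(0, 1).all()
        assert report.dunn["p_adjusted"].between(0, 1).all()
        kw = report.kruskal.set_index("descriptor")
        assert bool(kw.loc["core_diameter_nm", "significant"])
        assert set(report.ranges["layer"]) == {"SC", "Epidermis", "Dermis"}

    def test_domain_coverage_grows_with_training_size(self):
        """A hull fitted on more training data leaves fewer probes
        outside the applicability domain."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(400, 5))
        probes = rng.normal(size=(800, 5))
        out_small = 1.0 - fit_applicability_domain(X[:60], d=3).contains(probes).mean()
        out_large = 1.0 - fit_applicability_domain(X, d=3).contains(probes).mean()
        assert out_large <= out_small + 0.02
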