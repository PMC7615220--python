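"""LDA separability: Rand index vs brute-force pair enumeration, ellipsoid
coverage, feature construction, and planted-structure recovery."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import rand_score

from galpop import separability as sep
from galpop import synthgen as sg
from galpop import evoked
from galpop.datatypes import BoutFeatureMatrix


def all_label_vectors(n, max_labels=None):
    """Every labeling of n items with labels 0..n-1 (covers all partitions,
    with repeats)."""
    k = max_labels or n
    return product(range(k), repeat=n)


class TestRandIndex:
    def test_identical_partitions_score_one(self):
        assert sep.rand_index([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_crossed_partition_example(self):
        # {1,1,2,2} vs {1,2,1,2}: 0 pairs together-together, 2 apart-apart
        assert sep.rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(1 / 3)

    def test_one_cluster_vs_singletons_n3(self):
        assert sep.rand_index([1, 1, 1], [1, 2, 3]) == 0.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            sep.rand_index([1], [1])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_bruteforce_exhaustively_small_n(self, n):
        """Equality with pair enumeration over every label vector pair."""
        vecs = list(all_label_vectors(n, max_labels=min(n, 3)))
        for a in vecs:
            for b in vecs:
                assert sep.rand_index(a, b) == pytest.approx(
                    sep.rand_index_bruteforce(a, b))

    def test_matches_bruteforce_and_sklearn_n8(self):
        """Random partitions of n = 8: implementation, brute force, and the
        library routine all agree."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.integers(0, 4, size=8)
            b = rng.integers(0, 4, size=8)
            ri = sep.rand_index(a, b)
            assert ri == pytest.approx(sep.rand_index_bruteforce(a, b))
            assert ri == pytest.approx(rand_score(a, b))

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_label_bijection_invariance(self, labels):
        """Renaming labels on either side leaves the index unchanged."""
        a = np.asarray(labels)
        rng = np.random.default_rng(0)
        b = rng.integers(0, 3, size=len(a))
        sigma = {v: 100 - v for v in range(4)}
        a_renamed = np.array([sigma[v] for v in a])
        b_renamed = np.array([sigma[v] for v in b])
        assert sep.rand_index(a, b) == pytest.approx(sep.rand_index(a_renamed, b))
        assert sep.rand_index(a, b) == pytest.approx(sep.rand_index(a, b_renamed))
        assert 0.0 <= sep.rand_index(a, b) <= 1.0


class TestConfidenceEllipsoid:
    def test_gaussian_coverage_near_level(self):
        """~95% of 10,000 standard-normal points fall inside the fitted 95%
        ellipsoid."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10_000, 2))
        center, cov, radius = sep.confidence_ellipsoid(pts, level=0.95)
        inside = sep.points_inside_ellipsoid(pts, center, cov, radius)
        assert inside.mean() == pytest.approx(0.95, abs=0.01)

    def test_level_zero_degenerates_to_center(self):
        pts = np.random.default_rng(2).normal(size=(50, 2))
        center, cov, radius = sep.confidence_ellipsoid(pts, level=0.0)
        assert radius == 0.0
        inside = sep.points_inside_ellipsoid(pts, center, cov, radius)
        assert inside.sum() == 0

    def test_one_dimensional_closed_form(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, size=(5000, 1))
        center, cov, radius = sep.confidence_ellipsoid(pts, level=0.95)
        half_width = np.sqrt(radius * cov[0, 0])
        # chi2(0.95, 1) = 1.96^2, so the interval is mu +/- 1.96 sigma
        assert half_width == pytest.approx(1.96 * pts.std(ddof=1), rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="dim"):
            sep.confidence_ellipsoid(np.zeros((2, 2)))


class TestBuildFeatures:
    def test_bin_arithmetic_and_sample_count(self, small_session):
        _, tm, events = small_session
        feats = sep.build_features(tm, events, ["pup", "object"],
                                   window_s=4.0, bin_width_s=0.5)
        assert feats.n_features == 8
        n_bouts = len(events.of_label("pup")) + len(events.of_label("object"))
        assert feats.n_samples == tm.n_neurons * n_bouts

    def test_population_bins_mode(self, small_session):
        _, tm, events = small_session
        feats = sep.build_features(tm, events, ["pup", "object"],
                                   window_s=4.0, bin_width_s=0.5,
                                   sample_mode="population_bins")
        assert feats.n_features == tm.n_neurons
        n_bouts = len(events.of_label("pup")) + len(events.of_label("object"))
        assert feats.n_samples == n_bouts * 8

    def test_planted_contrast_in_response_bins_only(self):
        """Stimulus-specific amplitudes separate class means in early
        (response) bins, not in the pre-response tail."""
        cfg = sg.PopulationConfig(n_neurons=10, duration=400.0, silent_fraction=0.0,
                                  spontaneous_rate=0.0,
                                  stimulus_set=["pup", "object"],
                                  tuning_matrix=np.column_stack(
                                      [np.full(10, 4.0), np.zeros(10)]),
                                  response_latency_mean=0.5,
                                  n_bouts_per_stimulus=6, seed=0)
        tm, events = sg.generate_population_session(cfg)
        feats = sep.build_features(tm, events, ["pup", "object"],
                                   window_s=4.0, bin_width_s=0.5)
        pup = feats.X[feats.labels == "pup"].mean(axis=0)
        obj = feats.X[feats.labels == "object"].mean(axis=0)
        diff = pup - obj
        assert diff[1] > 3.0   # 0.5-1.0 s bin holds the evoked response
        assert abs(diff[0]) < diff[1] / 2   # pre-latency bin much weaker

    def test_too_few_bouts_rejected(self):
        cfg = sg.PopulationConfig(n_neurons=3, duration=200.0,
                                  stimulus_set=["pup", "object"],
                                  n_bouts_per_stimulus=2, seed=0)
        tm, events = sg.generate_population_session(cfg)
        with pytest.raises(ValueError, match="fewer than 3"):
            sep.build_features(tm, events, ["pup", "object"])


class TestFitLda:
    @staticmethod
    def gaussian_features(n=200, sep_means=3.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.normal(-sep_means, 1, (n // 2, 4)),
                            rng.normal(sep_means, 1, (n // 2, 4))])
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        return BoutFeatureMatrix(X=X, labels=y, bin_width_s=0.5, window=(0, 2),
                                 neuron_of_sample=np.zeros(n),
                                 bout_of_sample=np.arange(n))

    def test_separated_gaussians_high_training_accuracy(self):
        feats = self.gaussian_features()
        emb, lda = sep.fit_lda(feats)
        assert emb.shape == (200, 1)
        acc = np.mean(lda.predict(feats.X) == feats.labels)
        assert acc > 0.95
        # projection orders the classes
        assert emb[feats.labels == "a"].mean() < emb[feats.labels == "b"].mean()

    def test_identical_distributions_near_degenerate(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        y = np.array(["a", "b"] * 50)
        feats = BoutFeatureMatrix(X=X, labels=y, bin_width_s=0.5, window=(0, 2),
                                  neuron_of_sample=np.zeros(100),
                                  bout_of_sample=np.arange(100))
        emb, lda = sep.fit_lda(feats)
        between = abs(emb[y == "a"].mean() - emb[y == "b"].mean())
        within = emb.std()
        assert between < within

    def test_deterministic_and_sign_fixed(self):
        feats = self.gaussian_features(seed=7)
        emb1, _ = sep.fit_lda(feats)
        emb2, _ = sep.fit_lda(self.gaussian_features(seed=7))
        assert np.array_equal(emb1, emb2)


class TestSeparabilityPipeline:
    @staticmethod
    def planted_session(contrast, seed, n_neurons=30):
        """Every neuron responds to pup with the given amplitude contrast
        over its object response, so per-(neuron, bout) samples carry the
        stimulus identity."""
        tuning = np.column_stack([np.full(n_neurons, 0.5 + contrast),
                                  np.full(n_neurons, 0.5)])
        cfg = sg.PopulationConfig(n_neurons=n_neurons, duration=400.0,
                                  silent_fraction=0.0, spontaneous_rate=0.5,
                                  stimulus_set=["pup", "object"],
                                  tuning_matrix=tuning, noise_sd=0.2,
                                  response_latency_mean=0.3,
                                  n_bouts_per_stimulus=8, seed=seed)
        return sg.generate_population_session(cfg)

    def test_strongly_separated_population_high_ri(self):
        """Planted strong stimulus separation yields RI > 0.9 (10 seeds)."""
        ris = []
        for seed in range(10):
            tm, events = self.planted_session(contrast=6.0, seed=seed)
            res = sep.separability(tm, events, ["pup", "object"], seed=0)
            ris.append(res.rand_index)
        assert np.median(ris) > 0.9
        assert min(ris) > 0.8

    def test_symmetric_code_needs_population_vectors(self):
        """An antisymmetric two-group code (half the neurons prefer pup,
        half object) is invisible to per-neuron samples but perfectly
        separable from population-vector samples."""
        n = 30
        tuning = np.zeros((n, 2))
        tuning[: n // 2, 0] = 7.0
        tuning[: n // 2, 1] = 1.0
        tuning[n // 2:, 0] = 1.0
        tuning[n // 2:, 1] = 7.0
        cfg = sg.PopulationConfig(n_neurons=n, duration=400.0, silent_fraction=0.0,
                                  spontaneous_rate=0.5,
                                  stimulus_set=["pup", "object"],
                                  tuning_matrix=tuning, noise_sd=0.2,
                                  response_latency_mean=0.3,
                                  n_bouts_per_stimulus=8, seed=0)
        tm, events = sg.generate_population_session(cfg)
        per_neuron = sep.separability(tm, events, ["pup", "object"], seed=0)
        pop = sep.separability(tm, events, ["pup", "object"],
                               sample_mode="population_bins", seed=0)
        assert abs(per_neuron.rand_index - 0.5) < 0.1
        assert pop.rand_index > 0.9

    def test_null_population_within_permutation_band(self):
        """With no tuning at all, RI stays inside the null band of random
        partitions."""
        cfg = sg.PopulationConfig(n_neurons=20, duration=400.0, silent_fraction=0.0,
                                  spontaneous_rate=2.0,
                                  stimulus_set=["pup", "object"],
                                  n_bouts_per_stimulus=8, seed=1)
        tm, events = sg.generate_population_session(cfg)
        res = sep.separability(tm, events, ["pup", "object"], seed=0)
        # permutation null: RI of the k-means partition against shuffled labels
        rng = np.random.default_rng(0)
        null = [sep.rand_index(rng.permutation(res.labels), res.cluster_labels)
                for _ in range(200)]
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo - 0.05 <= res.rand_index <= hi + 0.05

    def test_monotone_in_contrast(self):
        """Median RI never decreases along an amplitude-contrast ladder."""
        medians = []
        for contrast in [0.0, 1.0, 2.0, 4.0, 6.0]:
            ris = [sep.separability(*self.planted_session(contrast, seed),
                                    ["pup", "object"], seed=0).rand_index
                   for seed in range(5)]
            medians.append(np.median(ris))
        assert all(b >= a - 0.02 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0]

    def test_embedding_dimension_is_classes_minus_one(self, small_session):
        _, tm, events = small_session
        res = sep.separability(tm, events, ["pup", "intruder", "object"], seed=0)
        assert res.embedding.shape[1] == 2
        assert set(res.ellipsoids) == {"pup", "intruder", "object"}


class TestSeparabilityVsSparseness:
    def test_planted_negative_coupling_recovered(self):
        """Sparser sessions (fewer retrieval-activated neurons) planted with
        stronger pup-tuning contrast: the RI-on-activated-fraction slope
        comes out negative, the sparsening/separability coupling."""
        fracs, ris = [], []
        for i, sparsen in enumerate(np.linspace(0.0, 1.0, 12)):
            contrast = 0.5 + 5.0 * sparsen
            n = 30
            rng = np.random.default_rng(1000 + i)
            tuning = sg.uniform_tuning_matrix(
                n, ["retrieval", "pup", "object"],
                amplitudes={"retrieval": 2.0, "pup": 0.5 + contrast, "object": 0.5},
                responsive_fraction={"retrieval": 0.8 - 0.6 * sparsen,
                                     "pup": 0.9, "object": 0.9},
                rng=rng)
            cfg = sg.PopulationConfig(n_neurons=n, duration=500.0,
                                      silent_fraction=0.1 + 0.4 * sparsen,
                                      spontaneous_rate=1.0,
                                      stimulus_set=["retrieval", "pup", "object"],
                                      tuning_matrix=tuning, noise_sd=0.2,
                                      n_bouts_per_stimulus=8, seed=i)
            tm, events = sg.generate_population_session(cfg)
            det = evoked.select_detected(tm, events)
            frac, _, _ = evoked.activated_fraction(tm, events, "retrieval")
            res = sep.separability(det, events, ["pup", "object"], seed=0)
            fracs.append(frac)
            ris.append(res.rand_index)
        slope, r2, p = sep.separability_vs_sparseness(ris, fracs)
        assert slope < 0
        assert p < 0.05

    def test_identical_sessions_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            sep.separability_vs_sparseness([0.5, 0.5, 0.5], [0.3, 0.3, 0.3])

    def test_null_p_uniform(self):
        """Independent planted RI and fraction give uniform p (K-S over 200
        seeds)."""
        from scipy import stats
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ris = rng.uniform(0.4, 0.9, 10)
            fr = rng.uniform(0.1, 0.9, 10)
            _, _, p = sep.separability_vs_sparseness(ris, fr)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
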