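"""Stress typology: phase binning arithmetic, k-means against a brute-force
partition oracle, planted-archetype recovery and labelling rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from barleywl.typology import (
    DEFAULT_BINS,
    fit_typology,
    label_clusters,
    pattern_frequencies,
    phase_stress_vector,
    zadoks_stage,
)


def make_daily(stages, stress):
    return pd.DataFrame({"stage": stages, "oxdef_photo": stress})


class TestPhaseStressVector:
    def test_unstressed_season_all_ones(self):
        stages = np.linspace(3.0, 9.0, 200)
        means, counts = phase_stress_vector(make_daily(stages, np.ones(200)))
        assert np.allclose(means, 1.0)
        assert (counts == 0).all()

    def test_half_open_bin_boundaries(self):
        # decimal stage 15 is early juvenile; 21.0 belongs to the late
        # juvenile bin (half-open [10,21) / [21,32))
        apsim_15 = 3.0 + (15.0 - 10.0) / 11.0  # inverse of the anchor map
        apsim_21 = 4.0
        assert 10 <= zadoks_stage(apsim_15) < 21
        assert zadoks_stage(apsim_21) == 21.0
        means, _ = phase_stress_vector(
            make_daily([apsim_15, apsim_21], [0.4, 1.0])
        )
        assert means[0] == pytest.approx(0.4)  # JV1 got the stressed day
        assert means[1] == pytest.approx(1.0)  # JV2 got the boundary day

    def test_mean_and_count_arithmetic(self):
        # 10 days at stress 0.5 and 10 at 1.0 inside GF1 (stage 7.0-7.5)
        gf1 = np.linspace(7.0, 7.45, 20)
        other = np.linspace(3.0, 5.9, 30)
        stages = np.concatenate([other, gf1])
        stress = np.concatenate([np.ones(30), [0.5] * 10 + [1.0] * 10])
        means, counts = phase_stress_vector(make_daily(stages, stress))
        assert means[4] == pytest.approx(0.75)
        assert counts[4] == 10

    def test_unentered_phase_is_nan(self):
        means, _ = phase_stress_vector(make_daily([3.5, 3.6], [1.0, 1.0]))
        assert np.isnan(means[5])  # GF2 never entered

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            phase_stress_vector(make_daily([], []))


def brute_force_min_wss(X, k):
    """Exhaustive minimum within-cluster sum of squares over all
    assignments of len(X) points to k labels (oracle, n <= 10)."""
    n = len(X)
    best, best_assign = np.inf, None
    for assign in itertools.product(range(k), repeat=n):
        wss = 0.0
        for c in range(k):
            pts = X[[i for i in range(n) if assign[i] == c]]
            if len(pts):
                wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if wss < best - 1e-12:
            best, best_assign = wss, assign
    return best, best_assign


class TestFitTypology:
    def test_four_distinct_points_k4(self):
        X = np.eye(4, 6)
        typ = fit_typology(X, k=4, seed=0)
        assert len(set(typ.assignments)) == 4
        assert typ.variance_explained == pytest.approx(1.0)

    def test_identical_points_k1(self):
        X = np.tile([0.5] * 6, (5, 1))
        typ = fit_typology(X, k=1, seed=0)
        assert typ.within_cluster_ss == pytest.approx(0.0, abs=1e-12)
        assert typ.variance_explained == 1.0

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_brute_force_partition_oracle(self, k):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(10, 6)).round(2)
        best_wss, _ = brute_force_min_wss(X, k)
        typ = fit_typology(X, k=k, seed=0, n_restarts=20)
        assert typ.within_cluster_ss == pytest.approx(best_wss, rel=1e-9)

    def test_variance_explained_non_decreasing_in_k(self):
        rng = np.random.default_rng(5)
        X = np.clip(rng.normal(0.8, 0.15, size=(60, 6)), 0, 1)
        ve = [fit_typology(X, k=k, seed=0, n_restarts=20).variance_explained
              for k in range(1, 7)]
        assert all(a <= b + 1e-9 for a, b in zip(ve, ve[1:]))

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            fit_typology(np.ones((3, 6)), k=4)

    def test_nan_vectors_rejected(self):
        X = np.ones((5, 6))
        X[0, 2] = np.nan
        with pytest.raises(ValueError):
            fit_typology(X, k=2)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(50, 6))
        a = fit_typology(X, k=4, seed=3)
        b = fit_typology(X, k=4, seed=3)
        assert np.array_equal(a.assignments, b.assignments)


ARCHETYPES = {
    "none": np.ones(6),
    "early_severe": np.array([0.3, 0.35, 0.8, 1.0, 1.0, 1.0]),
    "late_moderate": np.array([1.0, 1.0, 1.0, 0.9, 0.8, 0.85]),
    "late_severe": np.array([1.0, 1.0, 0.9, 0.5, 0.35, 0.3]),
}


def planted_vectors(n_per=100, noise=0.04, seed=99):
    rng = np.random.default_rng(seed)
    X, truth = [], []
    for i, (name, centre) in enumerate(ARCHETYPES.items()):
        X.append(np.clip(centre + rng.normal(0, noise, size=(n_per, 6)), 0, 1))
        truth.extend([i] * n_per)
    return np.vstack(X), np.array(truth)


class TestArchetypeRecovery:
    def test_planted_patterns_recovered(self):
        """400 seasons from 4 planted stress archetypes with small noise
        re-cluster to >= 95% assignment agreement (ARI reported)."""
        from sklearn.metrics import adjusted_rand_score
        from scipy.optimize import linear_sum_assignment

        X, truth = planted_vectors()
        typ = fit_typology(X, k=4, seed=0, n_restarts=10)
        # best label matching via the confusion matrix
        conf = np.zeros((4, 4))
        for t, a in zip(truth, typ.assignments):
            conf[t, a] += 1
        r, c = linear_sum_assignment(-conf)
        agreement = conf[r, c].sum() / len(truth)
        ari = adjusted_rand_score(truth, typ.assignments)
        assert agreement >= 0.95
        assert ari > 0.9


class TestLabelClusters:
    def test_severity_ordering_and_minimal_label(self):
        X, _ = planted_vectors()
        typ = label_clusters(fit_typology(X, k=4, seed=0), "spring")
        assert typ.labels == ["SW0", "SW1", "SW2", "SW3"]
        # the minimal-waterlogging cluster is rank 0
        idx0 = np.argmin(np.sum(1 - typ.centroids, axis=1))
        assert typ.order[idx0] == 0
        assert typ.descriptors[0] == "minimal waterlogging"

    def test_onset_descriptors(self):
        X, _ = planted_vectors()
        typ = label_clusters(fit_typology(X, k=4, seed=0), "winter")
        assert typ.labels[0].startswith("WW")
        by_rank = {typ.order[i]: typ.descriptors[typ.order[i]]
                   for i in range(4)}
        descs = " ".join(typ.descriptors)
        assert "early-onset" in descs and "late-onset" in descs

    def test_labelling_invariant_to_cluster_permutation(self):
        X, _ = planted_vectors()
        a = label_clusters(fit_typology(X, k=4, seed=0), "spring")
        b = label_clusters(fit_typology(X, k=4, seed=17), "spring")
        la = a.labelled_assignments()
        lb = b.labelled_assignments()
        assert (la == lb).mean() >= 0.95  # same data, same severity labels

    def test_invalid_maturity_class(self):
        X, _ = planted_vectors()
        with pytest.raises(ValueError):
            label_clusters(fit_typology(X, k=4, seed=0), "autumn")


class TestPatternFrequencies:
    def test_single_group_single_pattern(self):
        df = pd.DataFrame({"pattern": ["SW0"] * 10, "scenario": ["base"] * 10})
        out = pattern_frequencies(df, "scenario")
        assert out["percent"].tolist() == [100.0]

    def test_counting(self):
        df = pd.DataFrame(
            {"pattern": ["a", "a", "b", "c"], "scenario": ["s"] * 4}
        )
        out = pattern_frequencies(df, "scenario").set_index("pattern")
        assert out.loc["a", "percent"] == 50.0
        assert out.loc["b", "percent"] == 25.0
        assert out.loc["c", "count"] == 1

    def test_percentages_sum_to_100_per_group(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "pattern": rng.choice(list("abcd"), 200),
                "scenario": rng.choice(["base", "2080"], 200),
                "sowing": rng.choice(["ES", "LS"], 200),
            }
        )
        out = pattern_frequencies(df, ["scenario", "sowing"])
        sums = out.groupby(["scenario", "sowing"])["percent"].sum()
        assert np.allclose(sums, 100.0)
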