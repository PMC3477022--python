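from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stagewave.clustering_go import (
    enrichment_fold,
    go_enrichment,
    hypergeom_pvalue,
    kmeans_profiles,
)

AGES = ["0dpp", "4dpp", "8dpp", "12dpp", "16dpp"]


def _profiles(n, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet([1, 1, 1, 1, 1], size=n)
    return pd.DataFrame(p, columns=AGES, index=[f"g{i}" for i in range(n)])


class TestKmeans:
    def test_k1_closed_form(self):
        prof = _profiles(40, seed=1)
        res = kmeans_profiles(prof, k=1, seed=0, restarts=3)
        X = prof.to_numpy()
        assert np.allclose(res.centroids.iloc[0], X.mean(axis=0))
        assert res.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_separates_planted_archetypes(self):
        rng = np.random.default_rng(4)
        a = np.clip(rng.normal([0.45, 0.45, 0.04, 0.03, 0.03], 0.01, (30, 5)), 0, 1)
        b = np.clip(rng.normal([0.03, 0.03, 0.04, 0.45, 0.45], 0.01, (30, 5)), 0, 1)
        X = np.vstack([a, b])
        X = X / X.sum(axis=1, keepdims=True)
        prof = pd.DataFrame(X, columns=AGES, index=[f"g{i}" for i in range(60)])
        res = kmeans_profiles(prof, k=2, seed=0)
        labels = res.labels.to_numpy()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]  # adjusted Rand index 1 vs the planted split

    def test_deterministic_for_fixed_seed(self):
        prof = _profiles(100, seed=2)
        r1 = kmeans_profiles(prof, k=5, seed=9)
        r2 = kmeans_profiles(prof, k=5, seed=9)
        assert r1.labels.equals(r2.labels)
        assert r1.inertia == r2.inertia

    def test_inertia_monotone_over_iterations(self):
        prof = _profiles(300, seed=5)
        res = kmeans_profiles(prof, k=6, seed=1, restarts=1)
        h = res.inertia_history
        assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))

    def test_restarts_never_worse_than_single(self):
        prof = _profiles(200, seed=6)
        multi = kmeans_profiles(prof, k=8, seed=3, restarts=20).inertia
        single = kmeans_profiles(prof, k=8, seed=3, restarts=1).inertia
        assert multi <= single + 1e-9

    def test_agrees_with_sklearn_objective(self):
        cluster = pytest.importorskip("sklearn.cluster")
        prof = _profiles(150, seed=7)
        ours = kmeans_profiles(prof, k=4, seed=0, restarts=25).inertia
        ref = cluster.KMeans(n_clusters=4, n_init=25, random_state=0).fit(prof.to_numpy())
        assert ours == pytest.approx(ref.inertia_, rel=0.02)

    def test_invalid_k(self):
        prof = _profiles(10)
        with pytest.raises(ValueError):
            kmeans_profiles(prof, k=0)
        with pytest.raises(ValueError):
            kmeans_profiles(prof, k=11)


def brute_force_upper_tail(genome, category, set_size, overlap):
    """Exhaustive P(X >= overlap) over all C(genome, set_size) draws."""
    pop = [1] * category + [0] * (genome - category)
    hits = 0
    total = 0
    for combo in combinations(range(genome), set_size):
        total += 1
        if sum(pop[i] for i in combo) >= overlap:
            hits += 1
    return hits / total


class TestGoEnrichment:
    GENOME = {
        "stress": 0.25,
        "transport": 0.25,
        "other": 0.5,
    }

    def _map(self, assignments):
        return {g: set(c) for g, c in assignments.items()}

    def test_identity_when_set_matches_genome(self):
        gm = self._map(
            {f"g{i}": ["stress"] for i in range(5)}
            | {f"g{i}": ["transport"] for i in range(5, 10)}
            | {f"g{i}": ["other"] for i in range(10, 20)}
        )
        enr = go_enrichment(list(gm), gm, self.GENOME, genome_size=100, seed=0)
        assert np.allclose(enr["normalized_frequency"], 1.0)

    def test_arithmetic_example(self):
        gm = self._map({f"g{i}": ["rare"] for i in range(5)})
        enr = go_enrichment(
            [f"g{i}" for i in range(10)], gm, {"rare": 0.05}, genome_size=200, seed=0
        )
        assert enr.loc["rare", "normalized_frequency"] == pytest.approx(10.0)

    def test_hypergeometric_matches_enumeration(self):
        # small instance: genome 20, category 5, set 6, overlap 4
        expect = brute_force_upper_tail(20, 5, 6, 4)
        p = hypergeom_pvalue(4, 6, 5, 20)
        assert p["upper"] == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("genome,category,set_size", [(12, 4, 5), (18, 6, 7), (25, 10, 6)])
    def test_enumeration_sweep_small_genomes(self, genome, category, set_size):
        for overlap in range(0, min(category, set_size) + 1):
            expect = brute_force_upper_tail(genome, category, set_size, overlap)
            assert hypergeom_pvalue(overlap, set_size, category, genome)["upper"] == pytest.approx(
                expect, rel=1e-10
            )

    def test_bootstrap_sd_shrinks_with_set_size(self):
        rng = np.random.default_rng(0)
        small = {f"s{i}": {"stress"} if rng.random() < 0.3 else {"other"} for i in range(100)}
        big = {f"b{i}": {"stress"} if rng.random() < 0.3 else {"other"} for i in range(10_000)}
        sd_small = go_enrichment(list(small), small, self.GENOME, seed=1).loc["stress", "bootstrap_sd"]
        sd_big = go_enrichment(list(big), big, self.GENOME, seed=1).loc["stress", "bootstrap_sd"]
        assert sd_big < sd_small / 5

    def test_category_missing_from_genome_is_error(self):
        gm = {"g0": {"mystery"}}
        with pytest.raises(ValueError, match="mystery"):
            go_enrichment(["g0"], gm, self.GENOME)

    def test_p_value_in_unit_interval(self):
        gm = self._map({f"g{i}": ["stress"] for i in range(8)})
        enr = go_enrichment(list(gm), gm, self.GENOME, genome_size=1000, seed=2)
        assert ((enr["p_value"] > 0) & (enr["p_value"] <= 1)).all()


class TestFold:
    def test_transcription_factor_style_fold(self):
        assert enrichment_fold(0.16, 0.0645) == pytest.approx(2.48, abs=0.01)

    def test_equal_fractions(self):
        assert enrichment_fold(0.3, 0.3) == 1.0

    def test_zero_set_fraction(self):
        assert enrichment_fold(0.0, 0.2) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fold(0.1, 0.0)
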