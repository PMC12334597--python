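"""Host-microbe feature clustering, classification and pair calling."""

import numpy as np
import pytest

from microhost import (FeatureTable, IntegrationConfig, call_high_confidence,
                       class_counts, classify_clusters, cluster_features,
                       combine_tables, integrate_host_microbiome,
                       log2_transform)
from microhost.integration import HETEROLOGOUS, HOST_ONLY, MICROBE_ONLY


def _table(counts, kind, prefix):
    counts = np.asarray(counts, dtype=float)
    return FeatureTable(
        feature_ids=[f"{prefix}{i}" for i in range(counts.shape[0])],
        feature_kinds=[kind] * counts.shape[0],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
    )


class TestCombine:
    def test_size_additivity_and_kinds(self, rng):
        host = _table(rng.poisson(50, (5, 4)), "host_gene", "g")
        mic = _table(rng.poisson(5, (3, 4)), "microbe", "m")
        both = combine_tables(host, mic)
        assert both.n_features == 8
        assert both.feature_kinds == ["host_gene"] * 5 + ["microbe"] * 3

    def test_sample_alignment(self, rng):
        host = _table(rng.poisson(50, (4, 5)), "host_gene", "g")
        mic = _table(rng.poisson(5, (2, 5)), "microbe", "m")
        perm = [3, 1, 4, 0, 2]
        mic_perm = FeatureTable(mic.feature_ids, mic.feature_kinds,
                                [mic.sample_ids[i] for i in perm],
                                mic.counts[:, perm])
        np.testing.assert_array_equal(combine_tables(host, mic).counts,
                                      combine_tables(host, mic_perm).counts)

    def test_mismatch_and_collision_rejected(self, rng):
        host = _table(rng.poisson(50, (2, 3)), "host_gene", "g")
        mic_bad = _table(rng.poisson(5, (2, 4)), "microbe", "m")
        with pytest.raises(ValueError, match="mismatch"):
            combine_tables(host, mic_bad)
        mic_clash = _table(rng.poisson(5, (2, 3)), "microbe", "g")
        with pytest.raises(ValueError, match="collision"):
            combine_tables(host, mic_clash)


class TestClusterFeatures:
    def test_two_anticorrelated_blocks(self):
        up = np.arange(1.0, 11.0)
        down = up[::-1]
        counts = np.vstack([up * s for s in (1, 2, 3)] +
                           [down * s for s in (1, 2, 3)])
        t = _table(counts, "host_gene", "g")
        fc = cluster_features(t, k=2)
        a = fc.assignment()
        assert len({a["g0"], a["g1"], a["g2"]}) == 1
        assert len({a["g3"], a["g4"], a["g5"]}) == 1
        assert a["g0"] != a["g3"]

    def test_k_equals_features_singletons(self, rng):
        t = _table(rng.poisson(30, (6, 8)) + rng.random((6, 8)), "host_gene", "g")
        fc = cluster_features(t, k=6)
        assert sorted(fc.assignment().values()) == list(range(1, 7))

    def test_sample_permutation_invariance(self, rng):
        t = _table(rng.poisson(30, (10, 9)) + rng.random((10, 9)), "host_gene", "g")
        fc1 = cluster_features(t, k=4)
        perm = rng.permutation(9)
        t2 = FeatureTable(t.feature_ids, t.feature_kinds,
                          [t.sample_ids[i] for i in perm], t.counts[:, perm])
        fc2 = cluster_features(t2, k=4)
        assert fc1.assignment() == fc2.assignment()

    def test_constant_features_dropped_reported(self, rng):
        counts = rng.poisson(30, (5, 6)).astype(float) + rng.random((5, 6))
        counts[2] = 7.0
        t = _table(counts, "host_gene", "g")
        fc = cluster_features(t, k=3)
        assert fc.dropped_constant == ["g2"]
        assert "g2" not in fc.assignment()

    def test_k_exceeding_retained_rejected(self, rng):
        t = _table(rng.poisson(30, (4, 6)) + rng.random((4, 6)), "host_gene", "g")
        with pytest.raises(ValueError):
            cluster_features(t, k=5)


class TestClassify:
    def test_basic_classes(self):
        assignment = {"g0": 1, "g1": 1, "m0": 2, "g2": 3, "m1": 3}
        kinds = {"g0": "host_gene", "g1": "host_gene", "g2": "host_gene",
                 "m0": "microbe", "m1": "microbe"}
        recs = classify_clusters(assignment, kinds)
        by_id = {r.cluster_id: r.classification for r in recs}
        assert by_id == {1: HOST_ONLY, 2: MICROBE_ONLY, 3: HETEROLOGOUS}

    def test_class_counts_partition_k(self, rng):
        """#host_only + #microbe_only + #heterologous always equals K."""
        for _ in range(20):
            n = int(rng.integers(20, 200))
            k = int(rng.integers(2, max(3, n // 3)))
            kinds = {f"f{i}": ("host_gene" if rng.random() < 0.7 else "microbe")
                     for i in range(n)}
            labels = rng.integers(1, k + 1, size=n)
            # ensure every cluster id occurs
            labels[:k] = np.arange(1, k + 1)
            assignment = {f"f{i}": int(labels[i]) for i in range(n)}
            recs = classify_clusters(assignment, kinds)
            counts = class_counts(recs)
            assert sum(counts.values()) == len(set(labels.tolist()))
            # brute-force recount
            for r in recs:
                ks = {kinds[f] for f, _ in r.member_features}
                expect = (HETEROLOGOUS if len(ks) == 2
                          else HOST_ONLY if ks == {"host_gene"} else MICROBE_ONLY)
                assert r.classification == expect


class TestHighConfidence:
    def _combined(self, rng, gene_vals, mic_vals):
        host = _table(np.atleast_2d(gene_vals), "host_gene", "g")
        mic = _table(np.atleast_2d(mic_vals), "microbe", "m")
        return log2_transform(combine_tables(host, mic))

    def test_presence_gate_overrides_rho(self, rng):
        n = 20
        g = np.arange(1.0, n + 1)
        m = g.copy()
        m[: int(0.6 * n)] = 0.0  # perfectly ranked where present, 40% presence
        combined = self._combined(rng, g, m)
        recs = classify_clusters({"g0": 1, "m0": 1},
                                 dict(zip(combined.feature_ids, combined.feature_kinds)))
        out = call_high_confidence(recs, combined, IntegrationConfig(n_clusters=2))
        assert out[0].presence_ok is False
        assert out[0].high_confidence is False

    def test_strong_pair_called_with_best_pair(self, rng):
        n = 36
        z = rng.normal(size=n)
        g = np.exp(2.0 * z) * 50
        m = np.exp(2.0 * z) * 20 + rng.random(n)
        combined = self._combined(rng, np.vstack([g, rng.poisson(40, n)]),
                                  m)
        kinds = dict(zip(combined.feature_ids, combined.feature_kinds))
        recs = classify_clusters({f: 1 for f in combined.feature_ids}, kinds)
        out = call_high_confidence(recs, combined, IntegrationConfig(n_clusters=2))
        assert out[0].high_confidence
        assert out[0].best_pair == ("g0", "m0")
        assert out[0].best_rho > 0.7

    def test_monotone_in_thresholds(self, default_cohort):
        host, mic, _, _ = default_cohort
        base_cfg = IntegrationConfig(n_clusters=60)
        recs, _ = integrate_host_microbiome(host, mic, base_cfg)
        n_base = sum(r.high_confidence for r in recs)
        for stricter in (IntegrationConfig(n_clusters=60, rho_min=0.85),
                         IntegrationConfig(n_clusters=60, min_presence=0.9)):
            recs2, _ = integrate_host_microbiome(host, mic, stricter)
            assert sum(r.high_confidence for r in recs2) <= n_base

    def test_invariants_on_pipeline_output(self, default_cohort):
        host, mic, _, _ = default_cohort
        recs, fc = integrate_host_microbiome(host, mic,
                                             IntegrationConfig(n_clusters=72))
        counts = class_counts(recs)
        assert sum(counts.values()) == fc.k == 72
        for r in recs:
            if r.high_confidence:
                assert r.classification == HETEROLOGOUS
                assert r.presence_ok
                assert r.best_rho > 0.7
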