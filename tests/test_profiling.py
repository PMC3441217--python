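"""Z-standardization, complete-linkage clustering, correlation, tiers, patterns."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from smallrna_devatlas.profiling import (
    abundance_tiers,
    categorize_matrix,
    categorize_pattern,
    complete_linkage_cluster,
    replicate_correlation,
    zscore_matrix,
)


def _df(rows, cols=None):
    rows = np.asarray(rows, dtype=float)
    cols = cols or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, columns=cols)


class TestZscore:
    def test_hand_computed_row(self):
        z = zscore_matrix(_df([[10, 20, 30]]))
        assert np.allclose(z.to_numpy(), [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_constant_row_is_zero(self):
        z = zscore_matrix(_df([[5, 5, 5]]))
        assert (z.to_numpy() == 0).all()

    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        z = zscore_matrix(_df(rng.gamma(2, 100, size=(30, 6))))
        v = z.to_numpy()
        assert np.allclose(v.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(v.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            zscore_matrix(_df([[1], [2]]))

    def test_per_row_scale_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2, 100, size=(12, 5))
        scales = rng.uniform(0.5, 20, size=(12, 1))
        z1 = zscore_matrix(_df(X))
        z2 = zscore_matrix(_df(X * scales))
        assert np.allclose(z1.to_numpy(), z2.to_numpy())
        l1, o1 = complete_linkage_cluster(z1)
        l2, o2 = complete_linkage_cluster(z2)
        assert np.allclose(l1, l2) and o1 == o2


class TestCompleteLinkage:
    def test_three_point_example(self):
        linkage, order = complete_linkage_cluster(
            np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]])
        )
        assert (linkage[0][0], linkage[0][1]) == (0, 1)
        assert linkage[0][2] == pytest.approx(1.0)
        assert linkage[1][2] == pytest.approx(np.sqrt(200.0))
        # root children are clusters 2 and {0,1}; lower-index subtree first
        assert order == [2, 0, 1]

    def test_two_rows(self):
        linkage, order = complete_linkage_cluster(np.array([[0.0], [3.0]]))
        assert linkage.shape == (1, 4)
        assert linkage[0][2] == pytest.approx(3.0)

    def test_matches_naive_agglomeration(self):
        """Linkage equals an O(n^3) re-implementation scanning all pairs."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 4))

        def naive(X):
            n = len(X)
            D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
            clusters = {i: [i] for i in range(n)}
            merges = []
            nid = n
            while len(clusters) > 1:
                best = None
                for a in sorted(clusters):
                    for b in sorted(clusters):
                        if a >= b:
                            continue
                        h = max(D[i, j] for i in clusters[a] for j in clusters[b])
                        if best is None or (h, a, b) < best:
                            best = (h, a, b)
                h, a, b = best
                clusters[nid] = clusters.pop(a) + clusters.pop(b)
                merges.append((a, b, h, len(clusters[nid])))
                nid += 1
            return merges

        linkage, _ = complete_linkage_cluster(X)
        for got, want in zip(linkage, naive(X)):
            assert (got[0], got[1]) == want[:2]
            assert got[2] == pytest.approx(want[2])
            assert got[3] == want[3]

    def test_matches_scipy_on_generic_data(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(14, 5))
        ours, _ = complete_linkage_cluster(X)
        theirs = hierarchy.linkage(X, method="complete")
        assert np.allclose(np.sort(ours[:, 2]), np.sort(theirs[:, 2]))
        # same dendrogram: identical family of merged leaf sets

        def leafsets(Z, n):
            members = {i: frozenset([i]) for i in range(n)}
            out = set()
            for k, (a, b, _, _) in enumerate(Z):
                s = members[int(a)] | members[int(b)]
                members[n + k] = s
                out.add(s)
            return out

        assert leafsets(ours, 14) == leafsets(theirs, 14)

    def test_row_permutation_equivalence(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(9, 3))
        perm = rng.permutation(9)
        l1, o1 = complete_linkage_cluster(X)
        l2, o2 = complete_linkage_cluster(X[perm])
        assert np.allclose(np.sort(l1[:, 2]), np.sort(l2[:, 2]))
        assert sorted(perm[o2].tolist()) == sorted(o1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage_cluster(np.array([[0.0, np.nan], [1.0, 2.0]]))

    def test_correlation_metric(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
        linkage, _ = complete_linkage_cluster(X, metric="correlation")
        # rows 0 and 1 are perfectly correlated: first merge at distance ~0
        assert (linkage[0][0], linkage[0][1]) == (0, 1)
        assert linkage[0][2] == pytest.approx(0.0, abs=1e-12)


class TestReplicateCorrelation:
    def test_identical_counts_r1(self):
        c = {f"m{i}": v for i, v in enumerate([5, 50, 500, 5000])}
        assert replicate_correlation(c, c) == pytest.approx(1.0)

    def test_constant_scaling_near_one(self):
        counts = {f"m{i}": v for i, v in enumerate(np.geomspace(10, 1e4, 50))}
        scaled = {k: 100 * v for k, v in counts.items()}
        assert replicate_correlation(counts, scaled) > 0.999

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a = {f"m{i}": int(v) for i, v in enumerate(rng.integers(0, 1000, 30))}
        b = {f"m{i}": int(v) for i, v in enumerate(rng.integers(0, 1000, 30))}
        assert replicate_correlation(a, b) == pytest.approx(
            replicate_correlation(b, a)
        )

    def test_union_alignment_missing_zero(self):
        a = {"m1": 10, "m2": 100, "m3": 1000}
        b = {"m1": 10, "m2": 100, "m4": 1000}
        r = replicate_correlation(a, b)
        assert -1 <= r < 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation({"a": 1}, {"a": 2})


class TestTiers:
    def test_strict_bounds(self):
        m = _df([[299, 250, 100], [301, 0, 0], [1001, 500, 0]])
        tiers = abundance_tiers(m)
        assert tiers["per_stage"][300.0].tolist() == [2, 1, 0]
        assert tiers["per_stage"][1000.0].tolist() == [1, 0, 0]

    def test_multi_stage_and_low_summaries(self):
        m = _df([[400, 400, 0], [400, 0, 0], [299, 299, 299]])
        tiers = abundance_tiers(m)
        assert tiers["gt_first_threshold_multi_stage"] == 1
        assert tiers["lt_first_threshold_all_stages"] == 1


class TestPatterns:
    def test_monotone_series(self):
        assert categorize_pattern([1, 2, 4, 8, 16]) == "increasing"
        assert categorize_pattern([16, 8, 4, 2, 1]) == "decreasing"

    def test_mid_peak_rule(self):
        assert categorize_pattern([10, 10, 100, 10, 10]) == "mid_peak"

    def test_mid_trough_rule(self):
        assert categorize_pattern([100, 100, 10, 100, 100]) == "mid_trough"

    def test_flat_residual(self):
        assert categorize_pattern([10, 11, 10, 11, 10]) == "flat"

    def test_too_few_stages_rejected(self):
        with pytest.raises(ValueError):
            categorize_pattern([1, 2, 3])

    def test_planted_archetypes_recovered(self):
        """>=90% of structured archetype rows recover their planted label.

        Flat is the explicit residual class: Poisson noise on a flat row
        occasionally mimics a weak monotone trend, so for planted-flat rows
        only the majority call is asserted."""
        from smallrna_devatlas.simulate import (
            SimulationConfig,
            build_model,
            generate_reference_set,
            generate_stage_reads,
        )

        cfg = SimulationConfig(
            rng_seed=29, n_stages=6, mirna_count=40, reads_per_replicate=10_000,
            edit_plan=[], snp_plan=[], rrna_spike_stage=None,
        )
        refset = generate_reference_set(cfg)
        model = build_model(cfg)
        counts = {}
        for s, label in enumerate(cfg.labels()):
            _, _, truth = generate_stage_reads(refset, cfg, s)
            c = truth.reads[
                truth.reads.class_label == "miRNA"
            ].source_id.value_counts()
            counts[label] = c
        matrix = pd.DataFrame(counts).fillna(0.0)
        called = categorize_matrix(matrix)
        planted = pd.Series(model.archetypes)
        scored = planted[planted != "flat"].index.intersection(called.index)
        agreement = (called[scored] == planted[scored]).mean()
        assert agreement >= 0.9
        flat_rows = planted[planted == "flat"].index.intersection(called.index)
        assert (called[flat_rows] == "flat").mean() > 0.5
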