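import itertools
import math

import numpy as np
import pytest

from tadnmf.matrix_io import BinAnnotation
from tadnmf.evaluator import (
    NullDistribution,
    aggregate_hypergeom,
    aupr,
    dbi_per_cluster,
    dcc_per_cluster,
    empirical_significance,
    fold_enrichment,
    hypergeom_enrichment,
    jaccard,
    match_clusters_across_conditions,
    mean_signal_per_tad,
    mutual_information,
    rand_index,
    refine_labels,
    shuffle_tads,
)
from tadnmf.tad_caller import ClusterAssignment, run_lengths


def contiguous_assignment(rng, n, k):
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    lengths = np.diff(np.concatenate(([0], cuts, [n])))
    return ClusterAssignment(labels=np.repeat(np.arange(k), lengths))


def oracle_dbi(X, labels):
    ids = sorted(set(labels))
    cent = {c: X[labels == c].mean(axis=0) for c in ids}
    d = {
        c: np.mean([np.linalg.norm(row - cent[c]) for row in X[labels == c]])
        for c in ids
    }
    out = {}
    for ci in ids:
        out[ci] = max(
            (d[ci] + d[cj]) / np.linalg.norm(cent[ci] - cent[cj])
            for cj in ids
            if cj != ci
        )
    return out


def oracle_dcc(X, labels):
    n = len(labels)
    out = {}
    for c in sorted(set(labels)):
        inside, cross = [], []
        for p in range(n):
            for q in range(p + 1, n):
                if labels[p] == c and labels[q] == c:
                    inside.append(X[p, q])
                elif (labels[p] == c) != (labels[q] == c):
                    cross.append(X[p, q])
        out[c] = np.mean(inside) - np.mean(cross)
    return out


def oracle_rand(A, B):
    n = len(A)
    agree = sum(
        (A[p] == A[q]) == (B[p] == B[q])
        for p, q in itertools.combinations(range(n), 2)
    )
    return agree / math.comb(n, 2)


def oracle_mi(A, B):
    n = len(A)
    mi = 0.0
    for a in set(A):
        for b in set(B):
            p_ab = sum((x == a) and (y == b) for x, y in zip(A, B)) / n
            if p_ab == 0:
                continue
            p_a = sum(x == a for x in A) / n
            p_b = sum(y == b for y in B) / n
            mi += p_ab * math.log(p_ab / (p_a * p_b))
    return mi


def oracle_aupr(y_true, y_score):
    area = 0.0
    prev_recall = 0.0
    total_pos = int(np.sum(y_true))
    for t in sorted(set(y_score), reverse=True):
        called = y_score >= t
        tp = int(np.sum(y_true[called]))
        precision = tp / called.sum()
        recall = tp / total_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestDBI:
    def test_zero_scatter_blocks(self):
        X = np.array(
            [[5.0, 5, 0, 0], [5, 5, 0, 0], [0, 0, 5, 5], [0, 0, 5, 5]]
        )
        a = ClusterAssignment(labels=np.array([0, 0, 1, 1]))
        assert dbi_per_cluster(X, a) == {0: 0.0, 1: 0.0}

    def test_matches_reference_formula(self, rng):
        for _ in range(20):
            X = rng.poisson(6.0, size=(12, 12)).astype(float)
            X = (X + X.T) / 2
            a = contiguous_assignment(rng, 12, 3)
            got = dbi_per_cluster(X, a)
            want = oracle_dbi(X, a.labels)
            for c in want:
                assert got[c] == pytest.approx(want[c], rel=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            dbi_per_cluster(np.eye(4), ClusterAssignment(labels=np.zeros(4, dtype=int)))

    def test_coincident_centroids_infinite_with_warning(self):
        X = np.ones((4, 4))
        a = ClusterAssignment(labels=np.array([0, 0, 1, 1]))
        with pytest.warns(UserWarning, match="coincident"):
            out = dbi_per_cluster(X, a)
        assert all(np.isinf(v) for v in out.values())


class TestDCC:
    def test_block_contrast(self):
        X = np.full((6, 6), 1.0)
        for blk in (slice(0, 3), slice(3, 6)):
            X[blk, blk] = 5.0
        a = ClusterAssignment(labels=np.array([0, 0, 0, 1, 1, 1]))
        assert dcc_per_cluster(X, a) == {0: 4.0, 1: 4.0}

    def test_uniform_matrix_gives_zero(self):
        X = np.full((8, 8), 2.5)
        a = ClusterAssignment(labels=np.array([0] * 3 + [1] * 5))
        out = dcc_per_cluster(X, a)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_matches_pair_enumeration(self, rng):
        for _ in range(20):
            X = rng.poisson(6.0, size=(12, 12)).astype(float)
            X = (X + X.T) / 2
            a = contiguous_assignment(rng, 12, 3)
            sizes = {c: int((a.labels == c).sum()) for c in set(a.labels.tolist())}
            if min(sizes.values()) < 2:  # singletons have no within-pair mean
                continue
            got = dcc_per_cluster(X, a)
            want = oracle_dcc(X, a.labels)
            for c in want:
                assert got[c] == pytest.approx(want[c], rel=1e-9)

    def test_singleton_skipped_with_warning(self):
        a = ClusterAssignment(labels=np.array([0, 1, 1, 1]))
        with pytest.warns(UserWarning, match="singleton"):
            out = dcc_per_cluster(np.ones((4, 4)), a)
        assert 0 not in out and 1 in out


class TestShuffleTads:
    def test_length_multisets_conserved(self, rng):
        for _ in range(20):
            a = contiguous_assignment(rng, 40, 5)
            for sh in shuffle_tads(a, n_shuffles=4, seed=int(rng.integers(1e6))):
                assert sorted(l for _, l in run_lengths(sh.labels)) == sorted(
                    l for _, l in run_lengths(a.labels)
                )

    def test_background_gaps_preserved(self):
        labels = np.array([-1, -1, 0, 0, 0, -1, 1, 1, 1, 1, 1])
        a = ClusterAssignment(labels=labels)
        for sh in shuffle_tads(a, n_shuffles=10, seed=3):
            tad_lengths = sorted(
                l for lab, l in run_lengths(sh.labels) if lab != -1
            )
            gap_total = int(np.sum(sh.labels == -1))
            assert tad_lengths == [3, 5] and gap_total == 3

    def test_default_is_ten_shuffles(self):
        a = ClusterAssignment(labels=np.array([0, 0, 1, 1]))
        assert len(shuffle_tads(a, seed=0)) == 10

    def test_seeded_determinism(self):
        a = ClusterAssignment(labels=np.repeat([0, 1, 2], 5))
        s1 = shuffle_tads(a, seed=7)
        s2 = shuffle_tads(a, seed=7)
        for x, y in zip(s1, s2):
            assert np.array_equal(x.labels, y.labels)


class TestEmpiricalSignificance:
    def test_better_than_all_null(self):
        null = NullDistribution("dcc", np.arange(10.0), "higher_is_better")
        p, frac = empirical_significance(np.array([100.0]), null)
        assert p[0] == 0.0 and frac == 1.0

    def test_null_median_gives_half(self):
        null = NullDistribution("dcc", np.arange(1000.0), "higher_is_better")
        p, _ = empirical_significance(np.array([499.5]), null)
        assert p[0] == pytest.approx(0.5)

    def test_toy_strict_count(self):
        null = NullDistribution("dcc", np.array([1.0, 2, 3, 4]), "higher_is_better")
        p, _ = empirical_significance(np.array([3.5]), null)
        assert p[0] == pytest.approx(0.25)

    def test_direction_aware_for_dbi(self):
        null = NullDistribution("dbi", np.array([1.0, 2, 3, 4]), "lower_is_better")
        p, _ = empirical_significance(np.array([3.5]), null)
        assert p[0] == pytest.approx(0.75)

    def test_ties_count_as_not_better(self):
        null = NullDistribution("s", np.array([2.0, 2.0, 2.0]), "higher_is_better")
        p, _ = empirical_significance(np.array([2.0]), null)
        assert p[0] == 0.0

    def test_type_one_error_calibrated(self, rng):
        null_vals = rng.normal(size=4000)
        observed = rng.normal(size=2000)
        null = NullDistribution("stat", null_vals, "higher_is_better")
        _, frac = empirical_significance(observed, null, alpha=0.05)
        assert abs(frac - 0.05) < 0.03


class TestMeanSignal:
    def test_constant_track(self):
        a = ClusterAssignment(labels=np.array([0, 0, 1, 1]))
        assert mean_signal_per_tad(np.full(4, 3.0), a) == {0: 3.0, 1: 3.0}

    def test_stepped_track(self):
        a = ClusterAssignment(labels=np.array([0, 0, 1, 1]))
        assert mean_signal_per_tad(np.array([0.0, 0, 6, 6]), a) == {0: 0.0, 1: 6.0}

    def test_matches_direct_average(self, rng):
        a = contiguous_assignment(rng, 30, 4)
        sig = rng.normal(size=30)
        got = mean_signal_per_tad(sig, a)
        for c in range(4):
            assert got[c] == pytest.approx(sig[a.labels == c].mean(), rel=1e-12)

    def test_length_mismatch_rejected(self):
        a = ClusterAssignment(labels=np.array([0, 1]))
        with pytest.raises(ValueError):
            mean_signal_per_tad(np.zeros(3), a)


class TestAgreementMetrics:
    def test_rand_endpoints(self):
        A = np.array([0, 0, 1, 1])
        assert rand_index(A, A) == 1.0
        assert rand_index(np.zeros(5, dtype=int), np.arange(5)) == 0.0

    def test_rand_half_agreement(self):
        assert rand_index([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.5)

    def test_mi_constant_labeling_is_zero(self):
        assert mutual_information([0, 1, 2, 3], [5, 5, 5, 5]) == 0.0

    def test_mi_two_balanced_clusters(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(
            math.log(2), rel=1e-12
        )

    def test_agreement_matches_oracles_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 50))
            A = rng.integers(0, 5, size=n)
            B = rng.integers(0, 5, size=n)
            assert rand_index(A, B) == pytest.approx(oracle_rand(A, B), rel=1e-9)
            assert mutual_information(A, B) == pytest.approx(
                oracle_mi(A, B), rel=1e-9, abs=1e-12
            )
            assert mutual_information(A, B) == pytest.approx(
                mutual_information(B, A), rel=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rand_index([0, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 2])


class TestRefine:
    def test_splits_coarse_bins(self):
        assert refine_labels([0, 1], 2).tolist() == [0, 0, 1, 1]

    def test_identity_factor(self):
        assert refine_labels([3, 1, 4], 1).tolist() == [3, 1, 4]

    def test_refined_self_agreement_is_perfect(self, rng):
        labels = contiguous_assignment(rng, 20, 4).labels
        assert rand_index(refine_labels(labels, 5), refine_labels(labels, 5)) == 1.0

    def test_fractional_factor_rejected(self):
        with pytest.raises(ValueError):
            refine_labels([0, 1], 2.5)


class TestEnrichment:
    def test_fold_enrichment_formula(self):
        ann = BinAnnotation("chr1", 1, np.r_[np.ones(10), np.zeros(90)].astype(int))
        boundaries = set(range(4)) | set(range(50, 66))  # 20 bins, 4 bound
        assert fold_enrichment(boundaries, ann) == pytest.approx(2.0)

    def test_saturated_annotation_gives_unity(self, rng):
        ann = BinAnnotation("chr1", 1, np.ones(50, dtype=int))
        boundaries = set(rng.choice(50, size=12, replace=False).tolist())
        assert fold_enrichment(boundaries, ann) == pytest.approx(1.0)

    def test_random_boundaries_expect_unity(self, rng):
        ann = BinAnnotation("chr1", 1, (rng.uniform(size=200) < 0.3).astype(int))
        vals = []
        for _ in range(1000):
            b = set(rng.choice(200, size=20, replace=False).tolist())
            vals.append(fold_enrichment(b, ann))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_undefined_cases_rejected(self):
        ann = BinAnnotation("chr1", 1, np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            fold_enrichment({1, 2}, ann)
        ann2 = BinAnnotation("chr1", 1, np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            fold_enrichment(set(), ann2)


class TestHypergeom:
    def test_zero_observed_gives_one(self):
        assert hypergeom_enrichment((100, 10, 20, 0)) == pytest.approx(1.0)

    def test_exact_combinatorial_case(self):
        # all 5 draws are successes out of N=10 with 5 successes: 1/C(10,5)
        assert hypergeom_enrichment((10, 5, 5, 5)) == pytest.approx(
            1 / math.comb(10, 5), rel=1e-12
        )

    def test_matches_enumeration(self):
        # P[X >= x] by direct enumeration of the hypergeometric pmf
        N, K, n = 30, 8, 10
        for x in range(0, 9):
            expected = sum(
                math.comb(K, t) * math.comb(N - K, n - t) / math.comb(N, n)
                for t in range(x, min(K, n) + 1)
            )
            assert hypergeom_enrichment((N, K, n, x)) == pytest.approx(
                expected, rel=1e-9
            )

    def test_monotone_in_observed_count(self):
        ps = [hypergeom_enrichment((100, 20, 15, x)) for x in range(0, 16)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_aggregation_across_chromosomes(self):
        per_chrom = [(100, 10, 20, 4), (200, 30, 10, 5)]
        assert aggregate_hypergeom(per_chrom) == pytest.approx(
            hypergeom_enrichment((300, 40, 30, 9)), rel=1e-12
        )


class TestJaccardAndMatching:
    def test_endpoints(self):
        assert jaccard({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard({1, 2}, {3, 4}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_empty_sets_warn(self):
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 0.0

    def test_split_cluster_flagged(self):
        A = ClusterAssignment(labels=np.array([0] * 10 + [1] * 10))
        B = ClusterAssignment(labels=np.array([0] * 5 + [1] * 5 + [2] * 10))
        flags = match_clusters_across_conditions(A, B)
        assert len(flags) == 1
        ca, matches = flags[0]
        assert ca == 0
        assert {cb for cb, _ in matches} == {0, 1}
        assert all(j == pytest.approx(0.5) for _, j in matches)

    def test_identical_assignments_unflagged(self):
        A = ClusterAssignment(labels=np.repeat([0, 1, 2], 6))
        assert match_clusters_across_conditions(A, A) == []

    def test_threshold_is_exclusive_below(self):
        # overlap of 3/16 ~ 0.1875 < 0.2 on both halves: no flag
        A = ClusterAssignment(labels=np.array([0] * 16 + [1] * 4))
        B = ClusterAssignment(
            labels=np.array([0] * 3 + [2] * 10 + [1] * 3 + [3] * 4)
        )
        for ca, matches in match_clusters_across_conditions(A, B):
            for _, j in matches:
                assert j >= 0.2


class TestAUPR:
    @staticmethod
    def random_instance(rng, n_pairs=50):
        pairs = [(int(i), int(i + d)) for i, d in zip(range(n_pairs), rng.integers(1, 9, n_pairs))]
        scores = rng.uniform(size=n_pairs).round(2)  # rounding forces ties
        truth = {p for p, keep in zip(pairs, rng.uniform(size=n_pairs) < 0.3) if keep}
        if not truth:
            truth = {pairs[0]}
        preds = [(i, j, s) for (i, j), s in zip(pairs, scores)]
        return truth, preds, pairs, scores

    def test_perfect_ranking(self):
        preds = [(0, 1, 0.9), (0, 2, 0.8), (0, 3, 0.1), (0, 4, 0.2)]
        assert aupr({(0, 1), (0, 2)}, preds) == 1.0

    def test_constant_scores_give_prevalence(self):
        preds = [(0, j, 0.5) for j in range(1, 11)]
        assert aupr({(0, 1), (0, 2)}, preds) == pytest.approx(0.2)

    def test_matches_threshold_enumeration(self, rng):
        for _ in range(50):
            truth, preds, pairs, scores = self.random_instance(rng)
            y_true = np.array([p in truth for p in pairs], dtype=int)
            want = oracle_aupr(y_true, np.asarray(scores))
            assert aupr(truth, preds) == pytest.approx(want, rel=1e-9)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            aupr(set(), [(0, 1, 0.5)])

    def test_truth_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            aupr({(5, 6)}, [(0, 1, 0.5)])
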