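"""ROC/PR curves, FDR calibration, novel calls, concordance reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perturbmap.bench import (
    HIGHER,
    LOWER,
    call_novel,
    clustering_overlap,
    complex_concordance,
    fdr_cutoff,
    pr_curve,
    roc,
)
from perturbmap.cluster import ClusterAssignment
from perturbmap.dataio import ComplexCatalog
from perturbmap.score import LabeledPairs


def make_pairs(pos, neg, metric="umap_dist", unlabeled=(), pcc=None):
    """Build a LabeledPairs table from positive/negative score lists."""
    rows = []
    for i, s in enumerate(pos):
        rows.append((f"p{i:03d}a", f"p{i:03d}b", True, s))
    for i, s in enumerate(neg):
        rows.append((f"n{i:03d}a", f"n{i:03d}b", False, s))
    for i, s in enumerate(unlabeled):
        rows.append((f"u{i:03d}a", f"u{i:03d}b", np.nan, s))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "label", metric])
    if pcc is not None:
        df["pcc"] = list(pcc)
    return LabeledPairs(df)


def mann_whitney_auc(pos, neg, lower_is_hit=True):
    """Brute-force U-statistic AUC with ties counted half."""
    total = 0.0
    for p in pos:
        for n in neg:
            if p == n:
                total += 0.5
            elif (p < n) == lower_is_hit:
                total += 1.0
    return total / (len(pos) * len(neg))


def assignment_of(partition: dict[int, list[str]]) -> ClusterAssignment:
    rows = [
        (s, label, str(label)) for label, members in partition.items() for s in members
    ]
    return ClusterAssignment(
        pd.DataFrame(rows, columns=["strain", "main_cluster", "sub_cluster"])
    )


class TestROC:
    def test_perfect_separation(self):
        result = roc(make_pairs([0.1, 0.2], [0.5, 0.9]), "umap_dist")
        assert result.auc == 1.0

    def test_all_tied_is_half(self):
        result = roc(make_pairs([1.0, 1.0], [1.0, 1.0, 1.0]), "umap_dist")
        assert result.auc == pytest.approx(0.5)

    def test_interleaved_mann_whitney(self):
        result = roc(make_pairs([1, 3], [2, 4]), "umap_dist")
        assert result.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotone(self):
        result = roc(make_pairs([1, 3, 3.5], [2, 4]), "umap_dist")
        assert (result.fpr[0], result.tpr[0]) == (0.0, 0.0)
        assert (result.fpr[-1], result.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(result.fpr) >= 0)
        assert np.all(np.diff(result.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            roc(make_pairs([1.0], []), "umap_dist")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 9), min_size=1, max_size=20),
        neg=st.lists(st.integers(0, 9), min_size=1, max_size=20),
    )
    def test_auc_equals_mann_whitney_oracle(self, pos, neg):
        """Trapezoidal curve AUC == U estimator, ties half-weighted."""
        pos = [p / 3.0 for p in pos]
        neg = [n / 3.0 for n in neg]
        result = roc(make_pairs(pos, neg), "umap_dist", LOWER)
        assert result.auc == pytest.approx(
            mann_whitney_auc(pos, neg), abs=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.booleans(), st.floats(0, 1, width=32)),
            min_size=4,
            max_size=30,
        )
    )
    def test_direction_flip_inverts_auc(self, data):
        pos = [s for hit, s in data if hit]
        neg = [s for hit, s in data if not hit]
        if not pos or not neg or len(set(pos) | set(neg)) < len(pos) + len(neg):
            return  # needs both classes, tie-free scores
        pairs = make_pairs(pos, neg)
        a_lower = roc(pairs, "umap_dist", LOWER).auc
        a_higher = roc(pairs, "umap_dist", HIGHER).auc
        assert a_lower + a_higher == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            pos = rng.normal(0.4, 0.3, rng.integers(2, 15))
            neg = rng.normal(0.8, 0.3, rng.integers(2, 15))
            result = roc(make_pairs(list(pos), list(neg)), "umap_dist")
            y = [1] * len(pos) + [0] * len(neg)
            expected = roc_auc_score(y, np.r_[-pos, -neg])
            assert result.auc == pytest.approx(expected, abs=1e-12)


class TestPRCurve:
    def test_perfect_separation_precision_one(self):
        result = pr_curve(make_pairs([0.1, 0.2], [0.5, 0.9]), "umap_dist")
        gained = np.diff(np.r_[0.0, result.recall]) > 0
        assert np.allclose(result.precision[gained], 1.0)
        assert result.area == pytest.approx(1.0)

    def test_loosest_threshold_recall_one(self):
        result = pr_curve(make_pairs([1, 4], [2, 3]), "umap_dist")
        assert result.recall[-1] == 1.0

    def test_tiny_enumerated_case(self):
        result = pr_curve(make_pairs([1.0], [2.0, 3.0]), "umap_dist")
        assert result.recall[0] == 1.0
        assert result.precision[0] == 1.0
        assert result.area == pytest.approx(1.0)


class TestFDRCutoff:
    def test_worked_example(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.3, 0.5])
        cutoff = fdr_cutoff(pairs, "umap_dist", alpha=0.05)
        assert cutoff.threshold == pytest.approx(0.2)
        assert cutoff.achieved_fdr == 0.0
        assert cutoff.n_called == 2

    def test_perfect_separation_max_positive(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.6, 0.9])
        cutoff = fdr_cutoff(pairs, "umap_dist", alpha=0.05)
        assert cutoff.threshold == pytest.approx(0.3)
        assert cutoff.achieved_fdr == 0.0

    def test_alpha_zero_limit(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.3, 0.5])
        cutoff = fdr_cutoff(pairs, "umap_dist", alpha=0.0)
        assert cutoff.threshold == pytest.approx(0.2)

    def test_no_qualifying_threshold_explicit(self):
        pairs = make_pairs([0.9], [0.1, 0.2])
        cutoff = fdr_cutoff(pairs, "umap_dist", alpha=0.05)
        assert not cutoff.found
        assert cutoff.threshold is None
        assert cutoff.n_called == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 20), min_size=1, max_size=15),
        neg=st.lists(st.integers(0, 20), min_size=1, max_size=15),
        alpha=st.sampled_from([0.0, 0.01, 0.05, 0.2, 0.5]),
    )
    def test_achieved_fdr_never_exceeds_alpha(self, pos, neg, alpha):
        pairs = make_pairs([p / 5 for p in pos], [n / 5 for n in neg])
        cutoff = fdr_cutoff(pairs, "umap_dist", alpha=alpha)
        if cutoff.found:
            called = [p for p in pos if p / 5 <= cutoff.threshold]
            fp = [n for n in neg if n / 5 <= cutoff.threshold]
            assert cutoff.achieved_fdr <= alpha
            # recompute from scratch
            assert cutoff.achieved_fdr == pytest.approx(
                len(fp) / (len(fp) + len(called))
            )


class TestCallNovel:
    def test_pcc_filter_blocks_correlated_pair(self):
        pairs = make_pairs([0.1], [], unlabeled=(), pcc=[0.9])
        called, summary = call_novel(pairs, threshold=0.2)
        assert summary["n_called"] == 0

    def test_low_pcc_called(self):
        pairs = make_pairs([0.1], [0.5], pcc=[0.3, 0.1])
        called, summary = call_novel(pairs, threshold=0.2)
        assert summary["n_called"] == 1

    def test_unique_gene_count_set_union(self):
        df = pd.DataFrame(
            {
                "gene_a": ["a", "a"],
                "gene_b": ["b", "c"],
                "label": [np.nan, np.nan],
                "umap_dist": [0.1, 0.1],
                "pcc": [0.0, 0.0],
            }
        )
        _, summary = call_novel(LabeledPairs(df), threshold=0.2)
        assert summary["n_called"] == 2
        assert summary["n_unique_genes"] == 3

    def test_missing_pcc_excluded_and_counted(self):
        pairs = make_pairs([0.1, 0.15], [], pcc=[np.nan, 0.2])
        _, summary = call_novel(pairs, threshold=0.2)
        assert summary["n_called"] == 1
        assert summary["n_missing_pcc"] == 1


class TestComplexConcordance:
    def test_pair_in_same_cluster(self):
        catalog = ComplexCatalog({"C1": {"g1", "g2"}})
        assignment = assignment_of({1: ["g1", "g2", "g3"]})
        report = complex_concordance(catalog, assignment, level="main")
        row = report.per_complex.iloc[0]
        assert bool(row.co_clustered)
        assert row.member_fraction == 1.0
        assert report.fraction_co_clustered == 1.0

    def test_fully_split_complex(self):
        catalog = ComplexCatalog({"C1": {"g1", "g2", "g3"}})
        assignment = assignment_of({1: ["g1"], 2: ["g2"], 3: ["g3"]})
        report = complex_concordance(catalog, assignment, level="main")
        row = report.per_complex.iloc[0]
        assert not bool(row.co_clustered)
        assert row.member_fraction == pytest.approx(1 / 3)

    def test_singleton_complex_not_eligible(self):
        catalog = ComplexCatalog({"C1": {"g1", "zz"}})
        assignment = assignment_of({1: ["g1", "g2"]})
        report = complex_concordance(catalog, assignment, level="main")
        assert report.n_eligible == 0


class TestClusteringOverlap:
    def test_identical_partitions_all_perfect(self):
        a = assignment_of({0: ["s1", "s2"], 1: ["s3", "s4", "s5"]})
        report = clustering_overlap(a, a)
        assert report.n_perfect == 2
        assert report.ari == pytest.approx(1.0)

    def test_even_split_half_overlap(self):
        a = assignment_of({0: ["s1", "s2", "s3", "s4"]})
        b = assignment_of({0: ["s1", "s2"], 1: ["s3", "s4"]})
        report = clustering_overlap(a, b)
        assert report.per_cluster.iloc[0].overlap_fraction == 0.5

    def test_enumerated_overlap_counts(self):
        a = assignment_of({0: ["s1", "s2", "s3"], 1: ["s4", "s5"]})
        b = assignment_of({0: ["s1", "s2"], 1: ["s3", "s4", "s5"]})
        report = clustering_overlap(a, b)
        fractions = sorted(report.per_cluster.overlap_fraction)
        assert fractions == pytest.approx([2 / 3, 1.0])
        assert report.n_perfect == 1
        assert report.n_half == 2

    def test_universe_mismatch_rejected(self):
        a = assignment_of({0: ["s1", "s2"]})
        b = assignment_of({0: ["s1", "s3"]})
        with pytest.raises(ValueError, match="universe"):
            clustering_overlap(a, b)


def test_umap_auc_beats_label_shuffle(reference_run, rng):
    """Planted-pair AUC is far above the shuffled-label baseline."""
    pairs = reference_run["pairs"]
    real_auc = reference_run["auc_umap"]
    table = pairs.table.copy()
    table["label"] = rng.permutation(table["label"].to_numpy())
    shuffled_auc = roc(LabeledPairs(table), "umap_dist").auc
    assert real_auc > shuffled_auc + 0.2
    assert abs(shuffled_auc - 0.5) < 0.1
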