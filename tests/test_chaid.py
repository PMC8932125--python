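"""CHAID: Kass multiplier, merging, split selection, growth, prediction, CV.

Brute-force oracles: sympy's Stirling numbers and explicit set-partition
enumeration for the Bonferroni multiplier; argmax over plain 2x2
chi-squares for depth-1 binary split selection.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prodromes import (
    ChaidParams,
    Diagnosis,
    GeneratorSpec,
    best_split,
    cross_validate,
    evaluate_predictor,
    generate_cohort,
    grow,
    kass_multiplier,
    pearson_chi2,
    predict,
    render_tree,
    resubstitution_report,
)
from prodromes.chaid import ClassificationReport
from prodromes.univariate import ContingencyTable2x2
from conftest import cohort_from_counts, make_catalog


def partitions_into_r_groups(categories, r):
    """All ways to partition a set into exactly r non-empty groups."""

    def rec(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in rec(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1 :]
            yield part + [[first]]

    return [p for p in rec(list(categories)) if len(p) == r]


class TestKassMultiplier:
    def test_binary_predictor_multiplier_is_one(self):
        assert kass_multiplier(2, 2) == 1

    @pytest.mark.parametrize("c,r", [(3, 2), (4, 2), (4, 3), (5, 2), (5, 3), (6, 4)])
    def test_equals_partition_enumeration(self, c, r):
        assert kass_multiplier(c, r) == len(
            partitions_into_r_groups(range(c), r)
        )

    def test_equals_stirling_second_kind(self):
        from sympy.functions.combinatorial.numbers import stirling

        for c in range(1, 9):
            for r in range(1, c + 1):
                assert kass_multiplier(c, r) == int(stirling(c, r, kind=2))

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            kass_multiplier(2, 3)


class TestEvaluatePredictor:
    def test_binary_reduces_to_plain_2x2_chi2(self):
        # the root-node marginal table of the strongest published predictor
        x = np.array([1] * 62 + [0] * 61 + [1] * 10 + [0] * 72)
        y = np.array([1] * 123 + [0] * 82)
        cand = evaluate_predictor(x, y, "bizarre", ChaidParams())
        ref = pearson_chi2(ContingencyTable2x2(62, 61, 10, 72))
        assert cand.bonferroni_multiplier == 1
        assert cand.adjusted_p == pytest.approx(ref.p_value)
        assert cand.statistic == pytest.approx(ref.statistic)
        assert cand.merged_groups == ((0,), (1,))

    def test_constant_predictor_yields_no_candidate(self):
        x = np.zeros(30, dtype=int)
        y = np.array([1, 0] * 15)
        assert evaluate_predictor(x, y, "flat", ChaidParams()) is None

    def test_indistinguishable_categories_get_merged(self):
        """Three categories where two share the same class distribution:
        the similar pair merges; the final partition has 2 groups and a
        Bonferroni multiplier of S(3, 2) = 3."""
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(60), np.ones(60), np.full(60, 2)]).astype(int)
        y = np.concatenate(
            [
                rng.random(60) < 0.5,
                rng.random(60) < 0.5,
                rng.random(60) < 0.95,
            ]
        ).astype(int)
        cand = evaluate_predictor(x, y, "tri", ChaidParams())
        assert cand.merged_groups == ((0, 1), (2,))
        assert cand.bonferroni_multiplier == 3
        assert cand.adjusted_p == pytest.approx(min(1.0, cand.raw_p * 3))

    def test_adjusted_p_monotone_in_multiplier(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 200)
        y = rng.integers(0, 2, 200)
        with_b = evaluate_predictor(x, y, "s", ChaidParams(bonferroni=True))
        without = evaluate_predictor(x, y, "s", ChaidParams(bonferroni=False))
        assert with_b.adjusted_p >= without.adjusted_p
        assert without.adjusted_p == pytest.approx(without.raw_p)


class TestBestSplit:
    def test_perfect_separator_wins_and_children_pure(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([rng.integers(0, 2, 100), y])
        cand = best_split(X, y, ["noise", "oracle"], ChaidParams(min_child=1))
        assert cand.predictor == "oracle"

    @given(seed=st.integers(0, 300))
    def test_binary_depth1_equals_brute_force_chi2_argmax(self, seed):
        """With binary predictors and Bonferroni on, CHAID's selected split
        is the argmax of the plain 2x2 chi-square over predictors."""
        rng = np.random.default_rng(seed)
        n, k = 120, 6
        X = rng.integers(0, 2, (n, k))
        y = rng.integers(0, 2, n)
        params = ChaidParams(min_child=1, alpha_split=1.0)
        cand = best_split(X, y, [f"v{i}" for i in range(k)], params)
        stats = []
        for j in range(k):
            a = int(((X[:, j] == 1) & (y == 1)).sum())
            b = int(((X[:, j] == 0) & (y == 1)).sum())
            c = int(((X[:, j] == 1) & (y == 0)).sum())
            d = int(((X[:, j] == 0) & (y == 0)).sum())
            t = ContingencyTable2x2(a, b, c, d)
            try:
                stats.append(pearson_chi2(t).statistic)
            except Exception:
                stats.append(-1.0)
        if cand is not None:
            assert cand.predictor == f"v{int(np.argmax(stats))}"

    def test_min_child_blocks_split(self):
        y = np.array([1] * 50 + [0] * 50)
        x = np.array([1] * 3 + [0] * 97)  # tiny would-be child
        X = x[:, None]
        assert best_split(X, y, ["rare"], ChaidParams(min_child=7)) is None

    def test_alpha_split_blocks_weak_association(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (200, 1))
        y = rng.integers(0, 2, 200)
        weak = best_split(X, y, ["v"], ChaidParams(alpha_split=1e-12, min_child=1))
        assert weak is None


class TestGrow:
    def test_growth_is_deterministic(self, published_cohort):
        t1 = grow(published_cohort)
        t2 = grow(published_cohort)
        assert render_tree(t1, "plain") == render_tree(t2, "plain")
        assert render_tree(t1, "dot") == render_tree(t2, "dot")

    def test_child_counts_sum_to_parent(self, published_cohort):
        tree = grow(published_cohort)
        internal = [n for n in tree.nodes() if not n.is_leaf]
        assert internal, "expected at least one split on this cohort"
        for node in internal:
            sums = np.sum([ch.class_counts for ch in node.children.values()], axis=0)
            assert tuple(sums) == node.class_counts

    def test_depth_one_equals_single_best_split(self, published_cohort):
        params = ChaidParams(max_depth=1)
        tree = grow(published_cohort, params)
        X, y = published_cohort.presence_matrix()
        cand = best_split(X, y, published_cohort.catalog.names, params)
        assert tree.root.split == cand
        assert all(ch.is_leaf for ch in tree.root.children.values())

    def test_planted_strong_predictor_recovered(self):
        """One predictor with a 0.4 prevalence gap among null competitors
        is recovered as the root split in >= 95% of replicates."""
        catalog = make_catalog(
            [0.6, 0.3, 0.3, 0.3, 0.3], [0.2, 0.3, 0.3, 0.3, 0.3],
            with_onset=False,
        )
        planted = catalog.names[0]
        hits = 0
        reps = 40
        for seed in range(reps):
            cohort = generate_cohort(
                GeneratorSpec(n_sz=120, n_msd=120, catalog=catalog, seed=seed)
            )
            tree = grow(cohort)
            if tree.root.split is not None and tree.root.split.predictor == planted:
                hits += 1
        assert hits >= 0.95 * reps

    def test_pure_cohort_subset_never_splits(self):
        cohort = cohort_from_counts(10, 0, 0, 10)  # symptom == diagnosis
        tree = grow(cohort, ChaidParams(min_parent=2, min_child=1))
        for group, child in tree.root.children.items():
            assert child.is_leaf  # children are pure


class TestPredictAndReport:
    def test_single_leaf_tree_predicts_majority(self):
        cohort = cohort_from_counts(6, 6, 2, 2)
        tree = grow(cohort, ChaidParams(min_parent=1000))  # force leaf
        assert tree.root.is_leaf
        for p in cohort.patients:
            assert predict(tree, p) is Diagnosis.SZ

    def test_pure_split_classifies_training_data_perfectly(self):
        cohort = cohort_from_counts(15, 0, 0, 15)
        tree = grow(cohort, ChaidParams(min_parent=2, min_child=1))
        report = resubstitution_report(tree, cohort)
        assert report.overall_percent_correct == 100.0

    def test_resubstitution_equals_leaf_majority_counting(self, published_cohort):
        tree = grow(published_cohort)
        report = resubstitution_report(tree, published_cohort)
        leaf_correct = sum(
            max(n.class_counts) for n in tree.nodes() if n.is_leaf
        )
        assert report.correct_sz + report.correct_msd == leaf_correct

    def test_unseen_value_routes_to_largest_child(self, published_cohort):
        tree = grow(published_cohort, ChaidParams(max_depth=1))
        split_name = tree.root.split.predictor
        biggest = max(tree.root.children.values(), key=lambda n: n.n)
        got = predict(tree, {split_name: 99})
        assert got is biggest.majority

    def test_report_arithmetic(self):
        report = ClassificationReport(
            correct_sz=109, wrong_sz=14, correct_msd=50, wrong_msd=32
        )
        assert report.n == 205
        assert round(report.percent_correct_sz, 1) == 88.6
        assert round(report.percent_correct_msd, 1) == 61.0
        assert round(report.overall_percent_correct, 1) == 77.6


class TestCrossValidate:
    def test_separable_cohort_has_near_zero_risk(self):
        cohort = cohort_from_counts(40, 0, 0, 40)
        risk = cross_validate(
            cohort, ChaidParams(min_parent=2, min_child=1, cv_folds=5, seed=1)
        )
        assert risk == 0.0

    def test_null_cohort_risk_near_minority_share(self):
        catalog = make_catalog([0.5], [0.5], with_onset=False)
        cohort = generate_cohort(
            GeneratorSpec(n_sz=150, n_msd=50, catalog=catalog, seed=2)
        )
        risk = cross_validate(cohort, ChaidParams(cv_folds=5, seed=3))
        assert risk <= 0.4  # majority vote baseline is 0.25

    def test_too_small_class_rejected(self):
        cohort = cohort_from_counts(3, 3, 1, 1)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(cohort, ChaidParams(cv_folds=10))

    def test_seeded_folds_reproducible(self, published_cohort):
        params = ChaidParams(cv_folds=5, seed=42)
        assert cross_validate(published_cohort, params) == cross_validate(
            published_cohort, params
        )


class TestRender:
    def test_single_leaf_rendering(self):
        cohort = cohort_from_counts(6, 6, 2, 2)
        tree = grow(cohort, ChaidParams(min_parent=1000))
        plain = render_tree(tree, "plain")
        assert plain.count("node ") == 1
        dot = render_tree(tree, "dot")
        assert dot.count("[label=") == 1

    def test_plain_and_dot_share_node_multiset(self, published_cohort):
        tree = grow(published_cohort)
        ids = sorted(n.node_id for n in tree.nodes())
        plain = render_tree(tree, "plain")
        dot = render_tree(tree, "dot")
        assert sorted(
            int(line.split("node ")[1].split(":")[0].split(" ")[0])
            for line in plain.splitlines()
        ) == ids
        import re

        assert sorted(
            int(m.group(1))
            for line in dot.splitlines()
            if (m := re.match(r"\s*n(\d+) \[label=", line))
        ) == ids

    def test_internal_nodes_respect_alpha(self, published_cohort):
        tree = grow(published_cohort)
        for node in tree.nodes():
            if not node.is_leaf:
                assert node.split.adjusted_p <= tree.params.alpha_split

    def test_unknown_format_rejected(self, published_cohort):
        with pytest.raises(ValueError):
            render_tree(grow(published_cohort, ChaidParams(max_depth=1)), "png")
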