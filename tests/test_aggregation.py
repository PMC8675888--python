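import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegic.aggregation import (DEFAULT_PLAN, AggregationError, Annotation,
                               aggregate, build_label_matrix, majority_vote,
                               merge_classes, probabilistic_vote,
                               read_annotations, write_annotations)

CLASSES4 = ["Brain", "Eyes", "Muscle", "Heart"]


def ann(cid, eid, labels):
    return Annotation(cid, eid, frozenset(labels))


def vote_oracle(rows, classes, strategy, threshold):
    """Independent hand-rule voting: pure-python loops over raw tuples.

    ``rows`` are (component, expert, labels) triples; returns
    {(component, class): (probability, target)}.
    """
    out = {}
    for comp in sorted({c for c, _, _ in rows}):
        anns = [(e, labs) for c, e, labs in rows if c == comp]
        for cls in classes:
            if strategy == "majority":
                contribs = [1.0 if cls in labs else 0.0 for _, labs in anns]
            else:
                contribs = [1.0 / len(labs) if cls in labs else 0.0
                            for _, labs in anns]
            p = sum(contribs) / len(anns)
            out[(comp, cls)] = (p, round(p, 12) > threshold)
    return out


class TestAnnotation:
    def test_empty_label_set_rejected(self):
        with pytest.raises(AggregationError, match="empty"):
            Annotation("c", "e", frozenset())

    def test_unknown_label_rejected(self):
        with pytest.raises(AggregationError, match="vocabulary"):
            ann("c", "e", {"Blink"})

    def test_table_io_round_trip(self, tmp_path):
        table = [ann("c1", "e1", {"Eyes", "Brain"}),
                 ann("c1", "e2", {"Alpha"}),
                 ann("c2", "e1", {"Line noise"})]
        write_annotations(table, tmp_path / "ann.csv")
        back = read_annotations(tmp_path / "ann.csv")
        assert [(a.component_id, a.expert_id, a.labels) for a in back] == \
               [(a.component_id, a.expert_id, a.labels) for a in table]


class TestMergeClasses:
    @pytest.mark.parametrize("before, after", [
        ({"Horizontal eye movements", "Brain"}, {"Eyes", "Brain"}),
        ({"Vertical eye movements", "Horizontal eye movements"}, {"Eyes"}),
        ({"Alpha"}, {"Alpha", "Brain"}),
        ({"Mu", "Muscle"}, {"Mu", "Brain", "Muscle"}),
        ({"Line noise"}, {"Uncertain"}),
        ({"Line noise", "Heart"}, {"Heart"}),
        ({"Other", "Uncertain"}, {"Other", "Uncertain"}),
    ])
    def test_rules(self, before, after):
        out = merge_classes([ann("c", "e", before)])
        assert out[0].labels == frozenset(after)

    def test_ids_and_comments_preserved(self):
        out = merge_classes([Annotation("c9", "e3", frozenset({"Alpha"}),
                                        comment="faint")])
        assert (out[0].component_id, out[0].expert_id, out[0].comment) == \
               ("c9", "e3", "faint")


class TestLabelMatrix:
    def test_votes_layout(self):
        m = build_label_matrix(
            [ann("c1", "e1", {"Brain"}), ann("c1", "e2", {"Brain", "Mu"})],
            classes=["Brain", "Mu"])
        np.testing.assert_array_equal(m.expert_slice("c1", "e1"), [1, 0])
        np.testing.assert_array_equal(m.expert_slice("c1", "e2"), [1, 1])

    def test_absent_expert_is_missing(self):
        m = build_label_matrix(
            [ann("c1", "e1", {"Brain"}), ann("c2", "e1", {"Mu"}),
             ann("c2", "e2", {"Mu"})], classes=["Brain", "Mu"])
        assert np.isnan(m.expert_slice("c1", "e2")).all()

    def test_duplicate_annotation_rejected(self):
        with pytest.raises(AggregationError, match="duplicate"):
            build_label_matrix([ann("c1", "e1", {"Brain"}),
                                ann("c1", "e1", {"Mu"})])

    def test_row_sums_equal_label_set_sizes(self, rng):
        classes = CLASSES4
        rows = []
        for c in range(4):
            for e in range(3):
                k = rng.integers(1, len(classes) + 1)
                labels = rng.choice(classes, size=k, replace=False)
                rows.append(ann(f"c{c}", f"e{e}", set(labels)))
        m = build_label_matrix(rows, classes=classes)
        sums = np.nansum(m.votes, axis=2)
        expected = np.array([[len(a.labels) for a in rows[i * 3:(i + 1) * 3]]
                             for i in range(4)])
        np.testing.assert_array_equal(sums, expected)


class TestVoting:
    def test_majority_hand_values(self):
        rows = [ann("c", f"e{i}", {"Brain"} if v else {"Mu"})
                for i, v in enumerate((1, 1, 0))]
        m = build_label_matrix(rows, classes=["Brain"])
        agg = majority_vote(m, threshold=0.33)
        assert agg.probabilities.loc["c", "Brain"] == pytest.approx(2 / 3)
        assert bool(agg.targets.loc["c", "Brain"])

    def test_strict_threshold_on_one_of_three(self):
        # one positive vote out of three: p = 1/3 > 0.33 passes (strict
        # comparison against the stored 0.33, probabilities pre-rounded)
        rows = [ann("c", "e0", {"Brain"}), ann("c", "e1", {"Mu"}),
                ann("c", "e2", {"Mu"})]
        m = build_label_matrix(rows, classes=["Brain"])
        agg = majority_vote(m, threshold=0.33)
        assert agg.probabilities.loc["c", "Brain"] == pytest.approx(1 / 3)
        assert bool(agg.targets.loc["c", "Brain"])
        # but not strictly above a threshold of exactly 1/3
        agg = majority_vote(m, threshold=1 / 3)
        assert not bool(agg.targets.loc["c", "Brain"])

    def test_all_zero_votes(self):
        m = build_label_matrix([ann("c", "e0", {"Mu"})], classes=["Brain", "Mu"])
        agg = majority_vote(m, threshold=0.33)
        assert agg.probabilities.loc["c", "Brain"] == 0.0
        assert not bool(agg.targets.loc["c", "Brain"])

    def test_probabilistic_three_way_split(self):
        m = build_label_matrix([ann("c", "e", {"Eyes", "Muscle", "Heart"})],
                               classes=CLASSES4)
        agg = probabilistic_vote(m, threshold=0.33)
        for cls in ("Eyes", "Muscle", "Heart"):
            assert agg.probabilities.loc["c", cls] == pytest.approx(1 / 3)
            assert bool(agg.targets.loc["c", cls])
        assert agg.probabilities.loc["c", "Brain"] == 0.0

    def test_probabilistic_two_expert_hand_value(self):
        rows = [ann("c", "e1", {"Brain"}), ann("c", "e2", {"Brain", "Alpha"})]
        m = build_label_matrix(rows, classes=["Brain", "Alpha"])
        agg = probabilistic_vote(m, threshold=0.33)
        assert agg.probabilities.loc["c", "Brain"] == pytest.approx(0.75)
        assert agg.probabilities.loc["c", "Alpha"] == pytest.approx(0.25)
        assert bool(agg.targets.loc["c", "Brain"])
        assert not bool(agg.targets.loc["c", "Alpha"])

    def test_zero_annotator_component_rejected(self):
        m = build_label_matrix([ann("c1", "e1", {"Brain"})], classes=["Brain"])
        m.votes[0, 0, :] = np.nan  # simulate an orphaned component
        with pytest.raises(AggregationError, match="c1"):
            majority_vote(m)

    def test_split_vote_disambiguates_mixed_component(self):
        # one expert splits a vote four ways, the other is certain:
        # probabilistic voting keeps only Brain, majority voting keeps
        # every label the splitter mentioned
        rows = [ann("c", "e1", {"Eyes", "Muscle", "Heart", "Brain"}),
                ann("c", "e2", {"Brain"})]
        m = build_label_matrix(rows, classes=CLASSES4)
        prob = probabilistic_vote(m, 0.33)
        assert prob.probabilities.loc["c", "Brain"] == pytest.approx(0.625)
        assert list(prob.targets.columns[prob.targets.loc["c"]]) == ["Brain"]
        maj = majority_vote(m, 0.33)
        assert set(maj.targets.columns[maj.targets.loc["c"]]) == \
               {"Brain", "Eyes", "Muscle", "Heart"}


class TestAggregate:
    def test_default_plan_strategies(self):
        assert DEFAULT_PLAN["Brain"][0] == "probabilistic"
        assert DEFAULT_PLAN["Alpha"][0] == "majority"
        assert DEFAULT_PLAN["Mu"][0] == "majority"
        assert DEFAULT_PLAN["Eyes"][0] == "probabilistic"
        assert DEFAULT_PLAN["Muscle"][0] == "probabilistic"
        assert DEFAULT_PLAN["Heart"][0] == "majority"
        assert DEFAULT_PLAN["Channel noise"][0] == "probabilistic"
        assert all(thr == 0.33 for _, thr in DEFAULT_PLAN.values())

    def test_merging_applied_before_voting(self):
        table = [ann("c", "e1", {"Horizontal eye movements"}),
                 ann("c", "e2", {"Vertical eye movements"})]
        agg = aggregate(table)
        assert agg.probabilities.loc["c", "Eyes"] == pytest.approx(1.0)

    def test_plan_missing_class_errors(self):
        table = [ann("c", "e1", {"Brain"})]
        with pytest.raises(AggregationError, match="missing"):
            aggregate(table, plan={"Eyes": ("majority", 0.33)},
                      classes=["Brain"])

    def test_single_label_annotations_make_strategies_agree(self):
        table = [ann(f"c{i}", f"e{j}", {CLASSES4[(i + j) % 4]})
                 for i in range(5) for j in range(3)]
        m = build_label_matrix(table, classes=CLASSES4)
        maj = majority_vote(m, 0.33)
        prob = probabilistic_vote(m, 0.33)
        pd.testing.assert_frame_equal(maj.probabilities, prob.probabilities)

    def test_permutation_invariance(self, rng):
        table = [ann(f"c{i}", f"e{j}", set(rng.choice(
            CLASSES4, size=rng.integers(1, 5), replace=False)))
            for i in range(6) for j in range(3)]
        perm = list(table)
        rng.shuffle(perm)
        a = aggregate(table)
        b = aggregate(perm)
        pd.testing.assert_frame_equal(a.probabilities, b.probabilities)
        pd.testing.assert_frame_equal(a.targets, b.targets)


@st.composite
def annotation_tables(draw):
    n_comp = draw(st.integers(1, 4))
    n_exp = draw(st.integers(1, 3))
    rows = []
    for i in range(n_comp):
        annotators = draw(st.lists(st.integers(0, n_exp - 1), min_size=1,
                                   max_size=n_exp, unique=True))
        for j in annotators:
            labels = draw(st.sets(st.sampled_from(CLASSES4), min_size=1))
            rows.append((f"c{i}", f"e{j}", frozenset(labels)))
    return rows


class TestVotingProperties:
    @given(annotation_tables())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_probabilistic_never_exceeds_majority(self, rows):
        table = [ann(*r) for r in rows]
        m = build_label_matrix(table, classes=CLASSES4)
        maj = majority_vote(m).probabilities
        prob = probabilistic_vote(m).probabilities
        assert (prob.to_numpy() <= maj.to_numpy() + 1e-12).all()
        # equality holds exactly where every positive voter used a singleton
        singleton_only = all(len(r[2]) == 1 for r in rows)
        if singleton_only:
            pd.testing.assert_frame_equal(maj, prob)

    @given(annotation_tables())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_vote_conservation(self, rows):
        # each expert's probabilistic contributions over classes sum to 1
        table = [ann(*r) for r in rows]
        m = build_label_matrix(table, classes=CLASSES4)
        k = np.nansum(m.votes, axis=2)
        contrib = m.votes / k[:, :, None]
        sums = np.nansum(contrib, axis=2)
        annotated = ~np.isnan(m.votes).all(axis=2)
        np.testing.assert_allclose(sums[annotated], 1.0)

    @given(annotation_tables())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_hand_rule_oracle(self, rows):
        table = [ann(*r) for r in rows]
        m = build_label_matrix(table, classes=CLASSES4)
        for strategy, fn in (("majority", majority_vote),
                             ("probabilistic", probabilistic_vote)):
            agg = fn(m, 0.33)
            expected = vote_oracle(rows, CLASSES4, strategy, 0.33)
            for (comp, cls), (p, t) in expected.items():
                assert agg.probabilities.loc[comp, cls] == pytest.approx(p)
                assert bool(agg.targets.loc[comp, cls]) == t
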