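"""Cosine metrics and superfamily-weighted ROC/pAUC."""

import numpy as np
import pytest

from profgen.evaluation import (
    LabeledHit,
    RocCurve,
    ScopAnnotation,
    label_hits,
    mean_cosine_by_position,
    pauc,
    positional_cosine,
    read_annotation,
    read_hits,
    relative_sensitivity,
    weighted_roc,
)
from profgen.types import ProfileMatrix


def one_hot(j):
    v = np.zeros(20)
    v[j] = 1.0
    return v


class TestPositionalCosine:
    def test_identical_profiles_score_one(self, random_profile):
        p = random_profile(8)
        np.testing.assert_allclose(positional_cosine(p, p), 1.0, atol=1e-12)

    def test_disjoint_one_hots_score_zero(self):
        a = ProfileMatrix(one_hot(0)[None, :])
        b = ProfileMatrix(one_hot(5)[None, :])
        assert positional_cosine(a, b)[0] == 0.0

    def test_uniform_vs_one_hot_hand_value(self):
        a = ProfileMatrix(np.full((1, 20), 0.05))
        b = ProfileMatrix(one_hot(3)[None, :])
        # 0.05 / sqrt(20 * 0.05^2) = 1/sqrt(20)
        assert positional_cosine(a, b)[0] == pytest.approx(0.2236, abs=1e-4)

    def test_invariant_to_positive_row_rescaling(self, random_profile):
        p, t = random_profile(5, seed=3), random_profile(5, seed=4)
        scaled = ProfileMatrix(p.matrix * 7.5 / p.matrix.sum())
        np.testing.assert_allclose(
            positional_cosine(p, t), positional_cosine(scaled, t), atol=1e-12
        )

    def test_zero_row_raises(self):
        a = ProfileMatrix(np.zeros((1, 20)))
        b = ProfileMatrix(one_hot(0)[None, :])
        with pytest.raises(ValueError):
            positional_cosine(a, b)

    def test_mean_by_position_ignores_absent_positions(self, random_profile):
        long_pred, long_tgt = random_profile(4, seed=5), random_profile(4, seed=6)
        short_pred = ProfileMatrix(long_tgt.matrix[:2].copy())
        short_tgt = ProfileMatrix(long_tgt.matrix[:2].copy())
        curve = mean_cosine_by_position([(long_pred, long_tgt), (short_pred, short_tgt)])
        solo = positional_cosine(long_pred, long_tgt)
        assert curve.size == 4
        # positions 3-4 come from the long pair alone
        np.testing.assert_allclose(curve[2:], solo[2:], atol=1e-12)
        np.testing.assert_allclose(curve[:2], (solo[:2] + 1.0) / 2, atol=1e-12)


@pytest.fixture
def toy_annotation():
    # 4 domains: d1, d2 same superfamily; d3 same fold, different superfamily;
    # d4 different class entirely.
    return ScopAnnotation(
        {
            "d1": ("a", "a.1", "a.1.1", "a.1.1.1"),
            "d2": ("a", "a.1", "a.1.1", "a.1.1.2"),
            "d3": ("a", "a.1", "a.1.2", "a.1.2.1"),
            "d4": ("b", "b.1", "b.1.1", "b.1.1.1"),
        }
    )


class TestLabelHits:
    @pytest.mark.parametrize(
        "query, subject, expected",
        [
            ("d1", "d2", "TP"),  # same superfamily
            ("d1", "d4", "FP"),  # different class
            ("d1", "d3", "unknown"),  # same fold, different superfamily
            ("d1", "d1", "unknown"),  # self-hit
            ("d3", "d4", "FP"),  # different fold
        ],
    )
    def test_three_way_rule(self, toy_annotation, query, subject, expected):
        (hit,) = label_hits([(query, subject, 1e-5)], toy_annotation)
        assert hit.label == expected

    def test_unannotated_id_raises_naming_it(self, toy_annotation):
        with pytest.raises(KeyError, match="dX"):
            label_hits([("d1", "dX", 1.0)], toy_annotation)


class TestWeightedRoc:
    def test_all_tp_rises_vertically(self, toy_annotation):
        hits = [("d1", "d2", 1e-10), ("d2", "d1", 1e-9)]
        curve = weighted_roc(label_hits(hits, toy_annotation), toy_annotation)
        np.testing.assert_array_equal(curve.fp, 0.0)
        assert curve.tp[-1] == pytest.approx(1.0)  # 2 x 1/2

    def test_fp_weighting_by_query_superfamily_size(self, toy_annotation):
        # two queries from the 2-member superfamily a.1.1, one FP each: 2 x 1/2
        hits = [("d1", "d4", 1e-5), ("d2", "d4", 1e-4)]
        curve = weighted_roc(label_hits(hits, toy_annotation), toy_annotation)
        assert curve.fp[-1] == pytest.approx(1.0)

    def test_one_fp_per_query_totals_number_of_superfamilies(self, toy_annotation):
        """One FP per query -> total weighted FP = count of distinct superfamilies."""
        hits = [("d1", "d4", 1e-6), ("d2", "d4", 1e-5), ("d3", "d4", 1e-4), ("d4", "d3", 1e-3)]
        labeled = label_hits(hits, toy_annotation)
        assert all(h.label == "FP" for h in labeled)
        curve = weighted_roc(labeled, toy_annotation)
        assert curve.fp[-1] == pytest.approx(3.0)  # a.1.1, a.1.2, b.1.1
        assert toy_annotation.n_superfamilies == 3

    def test_unknowns_contribute_to_neither_axis(self, toy_annotation):
        hits = [("d1", "d1", 1e-9), ("d1", "d3", 1e-8)]
        curve = weighted_roc(label_hits(hits, toy_annotation), toy_annotation)
        assert curve.fp[-1] == 0.0 and curve.tp[-1] == 0.0


def brute_force_pauc(curve, fp_limit, tp_max):
    """Independent rectangle-sum integration on a dense FP grid."""
    fp, tp = curve.fp, curve.tp
    area = 0.0
    n_grid = 4000
    xs = np.linspace(0.0, fp_limit, n_grid + 1)
    for x0, x1 in zip(xs[:-1], xs[1:]):
        xm = 0.5 * (x0 + x1)
        # TP level at xm: the largest TP whose cumulative FP <= xm, with
        # linear interpolation inside vertical FP jumps
        y = np.interp(xm, fp, tp) if fp[-1] >= xm else tp[-1]
        area += y * (x1 - x0)
    return area / (fp_limit * tp_max)


def random_labeled_list(rng, n_hits=30):
    domains = {}
    lineage = {}
    for c in "ab":
        for f in range(2):
            for sf in range(2):
                for d in range(2):
                    name = f"{c}{f}{sf}{d}"
                    lineage[name] = (c, f"{c}.{f}", f"{c}.{f}.{sf}", f"{c}.{f}.{sf}.{d}")
    annot = ScopAnnotation(lineage)
    names = list(lineage)
    hits = []
    for _ in range(n_hits):
        q, s = rng.choice(names, size=2, replace=True)
        hits.append((str(q), str(s), float(rng.random())))
    return label_hits(hits, annot), annot


class TestPauc:
    def test_perfect_ranking_scores_one(self, toy_annotation):
        hits = [("d1", "d2", 1e-10), ("d1", "d4", 1e-3)]
        curve = weighted_roc(label_hits(hits, toy_annotation), toy_annotation)
        assert pauc(curve, fp_limit=3.0, tp_max=0.5) == pytest.approx(1.0, abs=1e-12)

    def test_no_tp_scores_zero(self, toy_annotation):
        hits = [("d1", "d4", 1e-5)]
        curve = weighted_roc(label_hits(hits, toy_annotation), toy_annotation)
        assert pauc(curve, fp_limit=3.0, tp_max=1.0) == 0.0

    def test_matches_brute_force_oracle_on_random_lists(self):
        for k in range(100):
            rng = np.random.default_rng(9000 + k)
            labeled, annot = random_labeled_list(rng)
            curve = weighted_roc(labeled, annot)
            tp_total = curve.tp[-1]
            if tp_total == 0:
                continue
            limit = annot.n_superfamilies * rng.uniform(0.05, 0.4)
            got = pauc(curve, limit, tp_total)
            want = brute_force_pauc(curve, limit, tp_total)
            # grid oracle carries O(n_jumps / n_grid) discretisation error
            assert got == pytest.approx(want, abs=1e-2)
            assert 0.0 <= got <= 1.0

    def test_exact_against_stepwise_oracle(self):
        """Rectangle sum over the exact step curve agrees to 1e-12."""
        for k in range(100):
            rng = np.random.default_rng(11000 + k)
            labeled, annot = random_labeled_list(rng)
            curve = weighted_roc(labeled, annot)
            if curve.tp[-1] == 0:
                continue
            limit = float(annot.n_superfamilies)
            # exact oracle: area = sum over FP increments of TP * dFP (step curve)
            area = 0.0
            fp, tp = curve.fp, curve.tp
            for i in range(1, fp.size):
                d = min(fp[i], limit) - min(fp[i - 1], limit)
                area += tp[i - 1] * d  # TP is constant across an FP increment
            if fp[-1] < limit:
                area += tp[-1] * (limit - fp[-1])
            want = area / (limit * curve.tp[-1])
            got = pauc(curve, limit, curve.tp[-1])
            assert got == pytest.approx(want, abs=1e-12)

    def test_relabeling_fp_as_tp_never_decreases_pauc(self):
        rng = np.random.default_rng(31)
        labeled, annot = random_labeled_list(rng)
        fps = [i for i, h in enumerate(labeled) if h.label == "FP"]
        tps = [h for h in labeled if h.label == "TP"]
        if not fps or not tps:
            pytest.skip("random list lacks both labels")
        curve = weighted_roc(labeled, annot)
        base = pauc(curve, 2.0, curve.tp[-1] + 1.0)
        i = fps[0]
        flipped = list(labeled)
        flipped[i] = LabeledHit(
            labeled[i].query, labeled[i].subject, labeled[i].evalue, "TP",
            labeled[i].query_superfamily,
        )
        curve2 = weighted_roc(flipped, annot)
        assert pauc(curve2, 2.0, curve.tp[-1] + 1.0) >= base - 1e-12

    def test_tie_permutation_changes_pauc_at_most_one_hit_weight(self, toy_annotation):
        hits = [("d1", "d2", 1e-5), ("d1", "d4", 1e-5)]  # tied e-values
        labeled = label_hits(hits, toy_annotation)
        annot = toy_annotation
        a = pauc(weighted_roc(labeled, annot), 3.0, 0.5)
        b = pauc(weighted_roc(list(reversed(labeled)), annot), 3.0, 0.5)
        max_w = 1.0 / 2  # heaviest hit weight involved
        assert abs(a - b) <= max_w + 1e-12

    def test_empty_curve_raises(self):
        with pytest.raises(ValueError):
            pauc(RocCurve(np.array([]), np.array([])), 1.0, 1.0)


class TestRelativeSensitivity:
    def test_equal_inputs_give_one(self):
        assert relative_sensitivity(0.3, 0.3) == 1.0

    def test_overall_pauc_ratio(self):
        # ratio of two overall pAUC values 0.217 and 0.140
        assert relative_sensitivity(0.217, 0.140) == pytest.approx(1.55, abs=0.01)

    def test_reciprocal_identity(self):
        assert relative_sensitivity(0.2, 0.5) * relative_sensitivity(0.5, 0.2) == pytest.approx(1.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            relative_sensitivity(0.1, 0.0)


class TestTabularInputs:
    def test_hits_and_annotation_roundtrip(self, tmp_path, toy_annotation):
        hits_path = tmp_path / "hits.tsv"
        hits_path.write_text("d1\td2\t1e-10\nd1\td4\t0.5\n")
        annot_path = tmp_path / "annot.tsv"
        annot_path.write_text(
            "d1\ta\ta.1\ta.1.1\ta.1.1.1\n"
            "d2\ta\ta.1\ta.1.1\ta.1.1.2\n"
            "d3\ta\ta.1\ta.1.2\ta.1.2.1\n"
            "d4\tb\tb.1\tb.1.1\tb.1.1.1\n"
        )
        hits = read_hits(hits_path)
        annot = read_annotation(annot_path)
        labeled = label_hits(hits, annot)
        assert [h.label for h in labeled] == ["TP", "FP"]
        assert annot.n_superfamilies == 3
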