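import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from probeval import (
    DegenerateDataError,
    class_conditional_summary,
    fraction_at_least,
    rate_histogram,
    roc_auc,
    top_fraction_unpaired,
    top_fraction_unpaired_pooled,
)

from conftest import make_reactivity, make_structure
from oracles import pairwise_auc


class TestRocAuc:
    def test_perfect_separation(self):
        prof = make_reactivity([0.9, 0.8, 0.1, 0.2])
        struct = make_structure("..()")
        assert roc_auc(prof, struct).auc == 1.0

    def test_all_ties_give_half(self):
        prof = make_reactivity([0.3, 0.3, 0.3, 0.3])
        struct = make_structure("..()")
        assert roc_auc(prof, struct).auc == 0.5

    def test_three_point_case_matches_pairwise_oracle(self):
        # scores: dot 0.3, dot 0.1, pair 0.2 (the pair enclosing a loop)
        prof = make_reactivity([0.2, 0.3, np.nan, np.nan, np.nan, np.nan,
                                0.1])
        struct = make_structure("(....).")
        scores = np.array([0.2, 0.3, 0.1])
        labels = np.array([False, True, True])
        expected = pairwise_auc(scores, labels)  # = 0.5: one win, one loss
        assert roc_auc(prof, struct).auc == pytest.approx(expected, abs=1e-15)

    def test_single_class_rejected(self):
        prof = make_reactivity([0.1, 0.2])
        with pytest.raises(DegenerateDataError):
            roc_auc(prof, make_structure(".."))

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(5)
        prof = make_reactivity(rng.random(60))
        db = list("." * 60)
        for i in range(0, 20, 2):
            db[i], db[59 - i] = "(", ")"
        struct = make_structure("".join(db))
        roc = roc_auc(prof, struct)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr))

    @given(st.integers(0, 10_000))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        """Trapezoidal AUC == Mann–Whitney pairwise statistic, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 120))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # heavy ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        db = "".join("." if u else "(" for u in labels)
        # close brackets on appended helper positions marked invalid
        db = db + ")" * db.count("(")
        valid = np.zeros(len(db), bool)
        valid[:n] = True
        prof = make_reactivity(
            np.concatenate([scores, np.zeros(len(db) - n)]), valid=valid
        )
        struct = make_structure(db)
        assert roc_auc(prof, struct).auc == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )

    def test_cross_check_against_sklearn(self):
        """Independent library cross-check of the in-repo AUC."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(6, 200))
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                labels[:2] = [True, False]
            db = "".join("." if u else "(" for u in labels)
            db += ")" * db.count("(")
            valid = np.zeros(len(db), bool)
            valid[:n] = True
            prof = make_reactivity(
                np.concatenate([scores, np.zeros(len(db) - n)]), valid=valid
            )
            ours = roc_auc(prof, make_structure(db)).auc
            theirs = roc_auc_score(labels, scores)
            assert ours == pytest.approx(theirs, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform_and_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.choice([0.0, 0.1, 0.4, 0.9], size=n)
        db = "".join(rng.choice([".", "("], n))
        if "." not in db or "(" not in db:
            db = ".(" + db[2:]
        full_db = db + ")" * db.count("(")
        valid = np.zeros(len(full_db), bool)
        valid[:n] = True

        def auc_of(values):
            prof = make_reactivity(
                np.concatenate([values, np.zeros(len(full_db) - n)]),
                valid=valid,
            )
            return roc_auc(prof, make_structure(full_db)).auc

        base = auc_of(scores)
        assert auc_of(np.exp(3 * scores)) == pytest.approx(base, abs=1e-12)
        assert auc_of(-scores) == pytest.approx(1 - base, abs=1e-12)


class TestTopFractionUnpaired:
    def test_perfect_profile_top10_all_unpaired(self):
        db = "." * 4 + "(" * 3 + ")" * 3
        prof = make_reactivity([0.9, 0.8, 0.7, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert top_fraction_unpaired(prof, make_structure(db), 10) == 1.0

    def test_x100_equals_overall_unpaired_fraction(self):
        rng = np.random.default_rng(7)
        db = "..((..)).."
        prof = make_reactivity(rng.random(10))
        struct = make_structure(db)
        assert top_fraction_unpaired(prof, struct, 100) == pytest.approx(
            struct.unpaired_fraction
        )

    def test_six_position_toy_at_x50(self):
        # reactivities 0.9,0.5,0.4,0.3,0.2,0.1 on "..(())": top 3 ranked
        # positions are 1,2,3 -> dots at 1,2, bracket at 3 -> 2/3
        prof = make_reactivity([0.9, 0.5, 0.4, 0.3, 0.2, 0.1])
        struct = make_structure("..(())")
        assert top_fraction_unpaired(prof, struct, 50) == pytest.approx(2 / 3)

    def test_tie_break_is_ascending_position(self):
        # all-equal scores: top 2 of 4 are positions 1,2 (the dots)
        prof = make_reactivity([0.5, 0.5, 0.5, 0.5])
        struct = make_structure("..()")
        assert top_fraction_unpaired(prof, struct, 50) == 1.0

    def test_x_out_of_range_rejected(self):
        from probeval import ValidationError

        struct = make_structure(".(....)")
        for bad in (0, -5, 101):
            with pytest.raises(ValidationError):
                top_fraction_unpaired(make_reactivity([0.1] * 7), struct, bad)

    def test_pooled_mode_ranks_across_molecules(self):
        # molecule A has globally higher reactivity; pooled top-50% takes
        # all of A (3 dots of 6 positions), per-molecule takes top half of
        # each
        a = make_reactivity([0.9, 0.8, 0.7], rna_id="a")
        b = make_reactivity([0.2, 0.1, 0.05], rna_id="b")
        sa = make_structure("...", rna_id="a")
        sb = make_structure("(.)", rna_id="b")
        pooled = top_fraction_unpaired_pooled([a, b], [sa, sb], 50)
        assert pooled == 1.0  # pooled top 3 = all of molecule a (all dots)


class TestRateHistogram:
    def test_all_zero_profile_in_first_bin(self):
        hist = rate_histogram(make_reactivity([0.0] * 5), 0.1, 1.0)
        assert hist.counts[0] == 5 and hist.counts[1:].sum() == 0

    def test_two_values_two_bins(self):
        hist = rate_histogram(make_reactivity([0.05, 0.15]), 0.1, 1.0)
        assert hist.counts[0] == 1 and hist.counts[1] == 1

    def test_edge_value_goes_to_bin_starting_there(self):
        hist = rate_histogram(make_reactivity([0.1]), 0.1, 1.0)
        assert hist.counts[1] == 1 and hist.counts[0] == 0

    def test_overflow_pooled(self):
        hist = rate_histogram(make_reactivity([0.05, 0.2]), 0.05, 0.1)
        assert hist.counts.sum() == 1 and hist.overflow == 1

    def test_zoomed_view_consistent_with_full_view(self):
        prof = make_reactivity([0.005, 0.02, 0.5])
        full = rate_histogram(prof, 0.1, 1.0)
        zoom = rate_histogram(prof, 0.01, 0.1)
        assert full.counts[0] == 2 and full.counts[5] == 1
        assert zoom.counts.sum() + zoom.overflow == 3


class TestFractionAtLeast:
    def test_half_above_threshold(self):
        prof = make_reactivity([0.0, 0.0, 0.2, 0.5])
        assert fraction_at_least(prof, 0.1) == 0.5

    def test_zero_threshold_on_nonnegative(self):
        assert fraction_at_least(make_reactivity([0.0, 0.3]), 0.0) == 1.0

    def test_empty_valid_set_rejected(self):
        prof = make_reactivity([np.nan], valid=[False])
        with pytest.raises(DegenerateDataError):
            fraction_at_least(prof, 0.1)


class TestClassConditionalSummary:
    def test_identical_distributions_overlap_one(self):
        prof = make_reactivity([0.2, 0.2, 0.2, 0.2])
        summary = class_conditional_summary(prof, make_structure("..()"))
        assert summary.overlap == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        prof = make_reactivity([0.8, 0.9, 0.1, 0.15])
        summary = class_conditional_summary(prof, make_structure("..()"))
        assert summary.overlap == pytest.approx(0.0)

    def test_two_bin_discrete_overlap_half(self):
        # unpaired mass (1, 0) over 2 bins vs paired mass (0.5, 0.5):
        # overlap = min(1,.5) + min(0,.5) = 0.5
        prof = make_reactivity([0.01, 0.01, 0.01, 0.01, 0.11, 0.01, 0.11])
        struct = make_structure("...(())")
        summary = class_conditional_summary(prof, struct, bin_width=0.1)
        assert summary.overlap == pytest.approx(0.5)
        assert summary.unpaired.n == 3 and summary.paired.n == 4

    def test_unpaired_class_higher_mean(self):
        prof = make_reactivity([0.5, 0.6, 0.05, 0.1])
        summary = class_conditional_summary(prof, make_structure("..()"))
        assert summary.unpaired.mean > summary.paired.mean

    def test_degenerate_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            class_conditional_summary(
                make_reactivity([0.1, 0.2]), make_structure("..")
            )
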