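"""Exclusion filters, threshold classifiers, grouped CV and statistics.

AUC and kappa are checked against independent brute-force oracles
(exhaustive pair enumeration; direct contingency-table formula).
"""

import itertools

import numpy as np
import pytest

from gutmotion.classify import (
    ClassifierThresholds,
    SegmentRecord,
    accuracy,
    apply_exclusion_filters,
    cohens_kappa,
    cohort_summary,
    contingency_matrix,
    cross_validate,
    fit_thresholds,
    grouped_kfold,
    percent,
    predict,
    roc_auc,
)
from gutmotion.errors import ConfigurationError


def make_record(i, subject="s0", cohort="synthetic", length=80.0, motility=None,
                direction=None, mv=None, mav=None, failed=False, dup=None):
    return SegmentRecord(
        segment_id=f"seg{i}", subject_id=subject, cohort=cohort, length_mm=length,
        extraction_failed=failed, duplicate_of=dup, reference_motility=motility,
        reference_direction=direction, mean_velocity=mv, mean_absolute_velocity=mav,
    )


def auc_bruteforce(scores, labels):
    """Exhaustive pair enumeration: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1
        conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


def kappa_bruteforce(a, b):
    """Direct (p_o - p_e) / (1 - p_e) from the contingency table."""
    labels = sorted(set(a) | set(b))
    n = len(a)
    table = np.array([[sum(1 for x, y in zip(a, b) if x == la and y == lb) for lb in labels] for la in labels])
    po = np.trace(table) / n
    pe = (table.sum(1) * table.sum(0)).sum() / n**2
    return (po - pe) / (1 - pe)


class TestExclusionFilters:
    def test_reported_tally_arithmetic(self):
        """333 generated, 41 too short, 9 shorter duplicates, 69 rater-flagged
        failures (disjoint) leave 214 unique segments."""
        records = []
        i = 0
        for _ in range(41):
            records.append(make_record(i, length=30.0)); i += 1
        kept_for_dups = []
        for _ in range(9):
            keeper = make_record(i, length=90.0); i += 1
            shorter = make_record(i, length=60.0, dup=keeper.segment_id); i += 1
            records += [keeper, shorter]
            kept_for_dups.append(keeper)
        for _ in range(69):
            records.append(make_record(i, failed=True)); i += 1
        while len(records) < 333:
            records.append(make_record(i)); i += 1
        assert len(records) == 333
        included, tally = apply_exclusion_filters(records)
        assert tally == {
            "generated": 333,
            "excluded_length": 41,
            "excluded_duplicate": 9,
            "excluded_failed": 69,
            "included": 214,
        }
        assert len(included) == 214

    def test_empty_input(self):
        included, tally = apply_exclusion_filters([])
        assert included == [] and tally["included"] == 0

    def test_matches_bruteforce_set_difference(self):
        rng = np.random.default_rng(7)
        records = []
        for i in range(60):
            dup = f"seg{rng.integers(0, i)}" if i > 0 and rng.random() < 0.2 else None
            records.append(
                make_record(i, length=float(rng.uniform(20, 120)),
                            failed=bool(rng.random() < 0.2), dup=dup)
            )
        included, _ = apply_exclusion_filters(records)
        by_id = {r.segment_id: r for r in records}
        # oracle: independent reimplementation of the three rules
        alive = {r.segment_id for r in records if r.length_mm > 40.0}
        drop = set()
        for r in records:
            if r.segment_id in alive and r.duplicate_of in alive:
                other = by_id[r.duplicate_of]
                pair = sorted([r, other], key=lambda x: (x.length_mm, [other.segment_id, r.segment_id][x is r]))
                a, b = sorted([r, other], key=lambda x: (-x.length_mm, x.segment_id))
                drop.add(b.segment_id)
        alive -= drop
        alive = {sid for sid in alive if not by_id[sid].extraction_failed}
        assert {r.segment_id for r in included} == alive

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        records = [
            make_record(i, length=float(rng.uniform(20, 120)), failed=bool(rng.random() < 0.3))
            for i in range(40)
        ]
        a, _ = apply_exclusion_filters(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        b, _ = apply_exclusion_filters(shuffled)
        assert {r.segment_id for r in a} == {r.segment_id for r in b}

    def test_circular_duplicates_rejected(self):
        r1 = make_record(1, dup="seg2")
        r2 = make_record(2, dup="seg3")
        r3 = make_record(3, dup="seg1")
        with pytest.raises(ConfigurationError):
            apply_exclusion_filters([r1, r2, r3])


def synthetic_training_set(rng, n_per=12, sep=True):
    records = []
    i = 0
    specs = [
        ("motile", "forward", 1.5, 2.0),
        ("motile", "backward", -1.5, 2.0),
        ("motile", "bidirectional", 0.0, 1.4),
        ("non_motile", None, 0.0, 0.2),
    ]
    for mot, direc, mv0, mav0 in specs:
        for _ in range(n_per):
            jitter = rng.normal(0, 0.05 if sep else 0.8, size=2)
            records.append(
                make_record(i, subject=f"subj{i % 10}", motility=mot, direction=direc,
                            mv=mv0 + jitter[0], mav=abs(mav0 + jitter[1])))
            i += 1
    return records


class TestThresholds:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        records = synthetic_training_set(rng)
        thr = fit_thresholds(records)
        pred = predict(records, thr)
        assert accuracy([r.reference_class for r in pred], [r.predicted_class for r in pred]) == 1.0

    def test_overlapping_gaussians_near_analytic_optimum(self):
        """Equal-size Gaussians N(0,1) vs N(2,1): the accuracy-optimal cut
        is the midpoint 1.0 (grid-search oracle on the distributions)."""
        rng = np.random.default_rng(1)
        n = 4000
        records = []
        for i in range(n):
            motile = i % 2 == 0
            mav = rng.normal(2.0 if motile else 0.0, 1.0)
            records.append(
                make_record(i, motility="motile" if motile else "non_motile",
                            direction="forward" if motile else None,
                            mv=1.0 if motile else None, mav=mav))
        thr = fit_thresholds(records)
        assert abs(thr.motility_threshold - 1.0) < 0.2

    def test_tie_break_picks_lowest_threshold(self):
        # two candidate cuts achieve identical accuracy; the lower wins
        records = [
            make_record(0, motility="non_motile", mv=0.0, mav=1.0),
            make_record(1, motility="motile", direction="forward", mv=1.0, mav=2.0),
            make_record(2, motility="motile", direction="backward", mv=-1.0, mav=3.0),
            make_record(3, motility="motile", direction="bidirectional", mv=0.0, mav=4.0),
        ]
        thr = fit_thresholds(records)
        assert thr.motility_threshold == pytest.approx(1.5)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierThresholds(1.0, 0.5, -0.5)
        with pytest.raises(ConfigurationError):
            ClassifierThresholds(-1.0, -0.5, 0.5)

    def test_single_class_training_rejected(self):
        records = [make_record(i, motility="motile", direction="forward", mv=1.0, mav=2.0)
                   for i in range(5)]
        with pytest.raises(ConfigurationError):
            fit_thresholds(records)


class TestPredict:
    thr = ClassifierThresholds(1.0, -0.5, 0.5)

    @pytest.mark.parametrize(
        "mav,mv,expected",
        [
            (0.3, 5.0, "non_motile"),  # motility gate dominates
            (2.0, 1.5, "forward"),
            (2.0, -1.5, "backward"),
            (2.0, 0.0, "bidirectional"),
            (2.0, 0.5, "bidirectional"),  # boundary belongs to bidirectional
        ],
    )
    def test_serial_decision(self, mav, mv, expected):
        rec = make_record(0, motility="motile", direction="forward", mv=mv, mav=mav)
        assert predict([rec], self.thr)[0].predicted_class == expected


class TestGroupedKFold:
    def _records(self, n_subj=10, per=3):
        return [make_record(i, subject=f"s{i % n_subj}", mv=0.0, mav=1.0) for i in range(n_subj * per)]

    def test_subjects_never_split(self):
        records = self._records()
        folds = grouped_kfold(records, k=5, seed=3)
        for subj in {r.subject_id for r in records}:
            fs = {f for r, f in zip(records, folds) if r.subject_id == subj}
            assert len(fs) == 1

    def test_balanced_subject_counts(self):
        records = self._records(n_subj=10)
        folds = grouped_kfold(records, k=5, seed=4)
        subj_fold = {r.subject_id: f for r, f in zip(records, folds)}
        counts = np.bincount(list(subj_fold.values()), minlength=5)
        assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_seed_determinism(self):
        records = self._records()
        np.testing.assert_array_equal(
            grouped_kfold(records, 5, seed=11), grouped_kfold(records, 5, seed=11)
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            grouped_kfold(self._records(n_subj=3), k=5)


class TestCrossValidation:
    def test_every_record_predicted_once_without_own_subject(self):
        rng = np.random.default_rng(5)
        records = synthetic_training_set(rng)
        predicted, fold_info = cross_validate(records, k=5, seed=1)
        assert all(r.predicted_class is not None for r in predicted)
        assert len(predicted) == len(records)
        assert len(fold_info) == 5

    def test_separable_synthetic_cv_is_perfect(self):
        rng = np.random.default_rng(6)
        records = synthetic_training_set(rng)
        predicted, _ = cross_validate(records, k=5, seed=2)
        assert accuracy([r.reference_class for r in predicted],
                        [r.predicted_class for r in predicted]) == 1.0


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_tie_handling_exhaustive_case(self):
        # positives {1,2,3}, negative {2}: concordant 1 (3>2), tied 1 (2=2),
        # discordant 1 (1<2) -> AUC = (1 + 0.5)/3 = 0.5
        scores, labels = [1, 2, 3, 2], [1, 1, 1, 0]
        assert roc_auc(scores, labels) == pytest.approx((1 + 0.5) / 3)
        assert roc_auc(scores, labels) == pytest.approx(auc_bruteforce(scores, labels))

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            scores = rng.normal(size=30).round(1)  # rounding forces ties
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(auc_bruteforce(scores, labels))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert abs(roc_auc(scores, labels) - 0.5) < 0.03

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(2.0 * scores), labels)
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestKappa:
    def test_identical_labelings(self):
        assert cohens_kappa(list("aabbc"), list("aabbc")) == pytest.approx(1.0)

    def test_constant_vs_balanced_is_zero(self):
        # closed form: p_o = 0.5, p_e = 0.5 -> kappa 0
        assert cohens_kappa(["a"] * 10, ["a"] * 5 + ["b"] * 5) == pytest.approx(0.0)

    def test_matches_contingency_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = rng.choice(list("abcd"), size=60)
            b = rng.choice(list("abcd"), size=60)
            assert cohens_kappa(a, b) == pytest.approx(kappa_bruteforce(a, b))

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = rng.choice(list("xyz"), size=40)
        b = rng.choice(list("xyz"), size=40)
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_degenerate_identical_constants_undefined(self):
        assert np.isnan(cohens_kappa(["a"] * 5, ["a"] * 5))


class TestCohortSummary:
    def test_reported_percentages(self):
        assert percent(30, 87) == 34
        assert percent(44, 127) == 35
        assert percent(10, 87) == 11
        assert percent(14, 127) == 11

    def test_identical_samples_t_statistic_zero(self):
        records = [make_record(i, cohort="healthy", mv=0.0, mav=v) for i, v in enumerate([1.0, 2.0, 3.0])]
        records += [make_record(i + 10, cohort="crohns", mv=0.0, mav=v) for i, v in enumerate([1.0, 2.0, 3.0])]
        out = cohort_summary(records)
        assert out["t_test"]["t"] == pytest.approx(0.0)
        assert out["t_test"]["p"] == pytest.approx(1.0)
        assert not out["t_test"]["significant"]

    def test_median_iqr_and_class_percent(self):
        rng = np.random.default_rng(14)
        records = []
        for i in range(50):
            records.append(make_record(i, cohort="healthy", subject=f"h{i%7}",
                                       motility="motile", direction="forward",
                                       mv=1.0, mav=float(rng.uniform(1, 3))))
        for i in range(30):
            records.append(make_record(100 + i, cohort="crohns", subject=f"c{i%5}",
                                       motility="non_motile",
                                       mv=0.0, mav=float(rng.uniform(0.1, 1))))
        out = cohort_summary(records)
        h = out["cohorts"]["healthy"]
        mavs = [r.mean_absolute_velocity for r in records if r.cohort == "healthy"]
        assert h["median"] == pytest.approx(np.median(mavs))
        assert h["iqr"][0] == pytest.approx(np.percentile(mavs, 25))
        assert h["class_percent"]["forward"] == 100
        assert out["cohorts"]["crohns"]["class_percent"]["non_motile"] == 100
        assert out["t_test"]["significant"]


class TestContingency:
    def test_counts_match_manual(self):
        ref = ["forward", "forward", "non_motile", "bidirectional"]
        pred = ["forward", "backward", "non_motile", "bidirectional"]
        mat = contingency_matrix(ref, pred)
        # classes: non_motile, backward, bidirectional, forward
        assert mat[0, 0] == 1 and mat[2, 2] == 1 and mat[3, 3] == 1 and mat[3, 1] == 1
        assert mat.sum() == 4
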