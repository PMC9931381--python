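"""Exceedance counting, cutoff classification, cutoff ROC, pairing, group tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import manugrip as mg
from manugrip.threshold import N_CUTOFFS

from conftest import random_loads

_BASE = np.full(7, 100.0 / 7)

# A zero-sum difference vector with every area strictly past 3 points.
_ALL_SEVEN = np.array([5.0, -5.0, 4.0, -4.0, 4.0, -8.0, 4.0])


def _diff_vector(pattern):
    """Zero-sum per-area differences whose exceedance set (|d| > 3) is
    exactly the areas flagged in the 7-bit ``pattern``."""
    pattern = np.asarray(pattern, dtype=bool)
    k = int(pattern.sum())
    if k == 7:
        return _ALL_SEVEN.copy()
    d = np.zeros(7)
    signs = [4.0 if i % 2 == 0 else -4.0 for i in range(k)]
    d[pattern] = signs
    leftover = d.sum()
    if k and leftover != 0.0:
        d[~pattern] = -leftover / (7 - k)  # at most 2 points: never exceeds
    return d


def _pair_from_pattern(pattern, truth="unknown"):
    d = _diff_vector(pattern)
    left = _BASE + d / 2
    right = _BASE - d / 2
    return mg.HandPair(
        left=mg.AreaLoads.from_array(300.0, left),
        right=mg.AreaLoads.from_array(250.0, right),
        truth=truth,
    )


def _pairs_with_counts(counts, labels):
    """Labelled pairs engineered to carry exact exceedance counts."""
    return [
        _pair_from_pattern([1] * int(c) + [0] * (7 - int(c)), truth=lab)
        for c, lab in zip(counts, labels)
    ]


def _exact_pair(left_pct, right_pct, truth="unknown"):
    return mg.HandPair(
        left=mg.AreaLoads.from_array(300.0, left_pct),
        right=mg.AreaLoads.from_array(250.0, right_pct),
        truth=truth,
    )


class TestDiffProfile:
    def test_identical_hands_give_zero_profile(self):
        pct = [20, 12, 16, 13, 8, 16, 15]
        prof = mg.diff_profile(_exact_pair(pct, pct))
        assert prof.count_exceeding == 0
        assert all(v == 0.0 for v in prof.diff.values())

    def test_five_area_exceedance_example(self):
        """Differences (I=4, II=5, III=1, IV=6, V=7, TH=3.5, HY=2) put five
        areas -- I, II, IV, V and TH -- over the 3-point threshold."""
        left = [22.0, 14.5, 15.5, 10.0, 4.5, 17.75, 15.75]
        right = [18.0, 9.5, 14.5, 16.0, 11.5, 14.25, 16.25]
        assert sum(left) == 100 and sum(right) == 100
        prof = mg.diff_profile(_exact_pair(left, right))
        assert prof.count_exceeding == 5
        assert prof.exceeding == {
            mg.HandArea.I, mg.HandArea.II, mg.HandArea.IV, mg.HandArea.V, mg.HandArea.TH
        }

    def test_exact_threshold_does_not_count(self):
        left = [21.5, 11.5, 16, 13, 8, 16, 14]
        right = [18.5, 14.5, 16, 13, 8, 16, 14]
        prof = mg.diff_profile(_exact_pair(left, right))  # diffs exactly 3.0 on I, II
        assert prof.count_exceeding == 0

    def test_count_matches_brute_force_tally(self, rng):
        for _ in range(50):
            pair = mg.HandPair(left=random_loads(rng), right=random_loads(rng))
            prof = mg.diff_profile(pair)
            tally = 0
            for a in mg.AREAS:
                if abs(pair.left.percent[a] - pair.right.percent[a]) > 3.0:
                    tally += 1
            assert prof.count_exceeding == tally

    def test_symmetric_under_hand_swap(self, rng):
        pair = mg.HandPair(left=random_loads(rng), right=random_loads(rng))
        swapped = mg.HandPair(left=pair.right, right=pair.left)
        assert mg.diff_profile(pair).diff == mg.diff_profile(swapped).diff


class TestClassifyPair:
    def test_rule_application(self):
        prof = mg.diff_profile(_pair_from_pattern([1, 1, 1, 1, 1, 0, 0]))
        assert prof.count_exceeding == 5
        assert mg.classify_pair(prof, 4) == "insincere"
        assert mg.classify_pair(prof, 6) == "sincere"

    def test_cutoff_zero_labels_everything_insincere(self):
        pct = [20, 12, 16, 13, 8, 16, 15]
        prof = mg.diff_profile(_exact_pair(pct, pct))
        assert prof.count_exceeding == 0
        assert mg.classify_pair(prof, 0) == "insincere"

    def test_exhaustive_truth_table(self):
        """All 2^7 exceedance patterns x all 9 cutoffs agree with the
        enumerated count >= cutoff rule, on exactly-constructed pairs."""
        for pattern in itertools.product([0, 1], repeat=7):
            prof = mg.diff_profile(_pair_from_pattern(pattern))
            true_count = sum(pattern)
            assert prof.count_exceeding == true_count
            assert prof.exceeding == {a for a, bit in zip(mg.AREAS, pattern) if bit}
            for cutoff in range(N_CUTOFFS):
                expected = "insincere" if true_count >= cutoff else "sincere"
                assert mg.classify_pair(prof, cutoff) == expected

    def test_monotone_in_single_area_difference(self):
        """Growing one area's bimanual difference never flips an insincere
        call back to sincere at a fixed cutoff."""
        for bump in (0.0, 2.0, 4.0, 8.0, 12.0):
            d = np.array([bump, 4.0, -4.0, -bump, 0.0, 0.0, 0.0])
            pair = _exact_pair(_BASE + d / 2, _BASE - d / 2)
            prof = mg.diff_profile(pair)
            assert prof.count_exceeding >= 2
            assert mg.classify_pair(prof, 2) == "insincere"


def _mann_whitney_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCutoffROC:
    def test_perfect_separation(self):
        pairs = _pairs_with_counts([7] * 5 + [0] * 5, ["insincere"] * 5 + ["sincere"] * 5)
        roc = mg.cutoff_roc(pairs)
        assert roc.auc == pytest.approx(1.0)

    def test_null_labels_give_half_auc(self, rng):
        counts = rng.integers(0, 8, size=400)
        labels = np.where(rng.random(400) < 0.5, "insincere", "sincere").tolist()
        roc = mg.cutoff_roc(_pairs_with_counts(counts, labels))
        assert roc.auc == pytest.approx(0.5, abs=0.08)

    def test_auc_equals_u_statistic(self, rng):
        for _ in range(5):
            n = 40
            counts = rng.integers(0, 8, size=n)
            labels = ["insincere"] * (n // 2) + ["sincere"] * (n - n // 2)
            roc = mg.cutoff_roc(_pairs_with_counts(counts, labels))
            pos = counts[: n // 2]
            neg = counts[n // 2:]
            assert roc.auc == pytest.approx(_mann_whitney_auc(pos, neg), abs=1e-12)

    def test_staircase_monotone_with_correct_endpoints(self, rng):
        counts = rng.integers(0, 8, size=60)
        labels = ["insincere"] * 30 + ["sincere"] * 30
        roc = mg.cutoff_roc(_pairs_with_counts(counts, labels))
        sens, spec = np.array(roc.sensitivity), np.array(roc.specificity)
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)
        assert sens[0] == 1.0 and spec[0] == 0.0
        assert sens[-1] == 0.0 and spec[-1] == 1.0

    def test_tie_break_prefers_higher_specificity(self):
        # insincere all count 7, sincere all 0 -> Youden J = 1 at cutoffs 1..7
        pairs = _pairs_with_counts([7] * 4 + [0] * 4, ["insincere"] * 4 + ["sincere"] * 4)
        roc = mg.cutoff_roc(pairs)
        assert roc.chosen_cutoff == 7  # the most specific of the tied cutoffs
        assert roc.chosen_specificity == 1.0

    def test_single_class_rejected(self):
        pairs = _pairs_with_counts([3, 4], ["insincere", "insincere"])
        with pytest.raises(ValueError):
            mg.cutoff_roc(pairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_staircase_property_on_arbitrary_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 80))
        counts = rng.integers(0, 8, size=n)
        labels = np.where(rng.random(n) < 0.5, "insincere", "sincere").tolist()
        if "insincere" not in labels:
            labels[0] = "insincere"
        if "sincere" not in labels:
            labels[-1] = "sincere"
        roc = mg.cutoff_roc(_pairs_with_counts(counts, labels))
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)
        assert 0.0 <= roc.auc <= 1.0


class TestBuildPairs:
    def test_default_study_pair_counts(self, default_pairs):
        truths = [p.truth for p in default_pairs]
        assert truths.count("insincere") == 324
        assert truths.count("sincere") == 162

    def test_single_session_emits_warning_and_no_sincere_pairs(self):
        design = mg.StudyDesign(n_subjects=1, n_males=1, n_right_handed=1, sessions=1, seed=0)
        records = mg.simulate_study(design)
        with pytest.warns(UserWarning, match="single-session"):
            pairs = mg.build_pairs(records)
        assert all(p.truth == "insincere" for p in pairs)

    def test_missing_counterpart_is_an_error(self, default_study):
        broken = [r for r in default_study if not (r.subject_id == "S001" and r.effort == "maximal"
                                                   and r.session == 1 and r.trial == 2)]
        with pytest.raises(ValueError, match="missing counterpart"):
            mg.build_pairs(broken)


class TestGroupAreaComparison:
    def test_identical_samples_give_zero_mean_and_p_one(self, default_study):
        maxr = [r for r in default_study if r.effort == "maximal"][:20]
        clones = [
            mg.TrialRecord(subject_id=r.subject_id, session=r.session, trial=r.trial,
                           hand="left" if r.hand == "right" else "right", effort="submaximal",
                           loads=r.loads, age=r.age, sex=r.sex, handedness=r.handedness)
            for r in maxr
        ]
        table = mg.group_area_comparison(maxr, clones)
        assert (table["mean_diff"] == 0).all()
        assert (table["p_value"] == 1.0).all()

    def test_constant_shift_detected(self, default_study):
        maxr = [r for r in default_study if r.effort == "maximal"][:10]
        shifted = []
        for r in maxr:
            pct = r.loads.as_array()
            pct[0] -= 5.0  # submaximal thumb 5 points lower -> diff +5
            pct[1:] += 5.0 / 6
            shifted.append(
                mg.TrialRecord(subject_id=r.subject_id, session=r.session, trial=r.trial,
                               hand="left" if r.hand == "right" else "right", effort="submaximal",
                               loads=mg.AreaLoads.from_array(r.loads.total_force, pct),
                               age=r.age, sex=r.sex, handedness=r.handedness)
            )
        table = mg.group_area_comparison(maxr, shifted).set_index("area")
        assert table.loc["I", "mean_diff"] == pytest.approx(5.0)
        assert table.loc["I", "p_value"] < 0.05

    def test_signed_rank_p_matches_exact_enumeration(self, rng):
        """The two-sided signed-rank p-value in the report agrees with a
        brute-force enumeration of all 2^n sign assignments."""
        from scipy.stats import rankdata

        maxr_template, subr_template = None, None
        for _ in range(5):
            d = rng.normal(0.5, 1.0, size=9)
            d = d[d != 0]
            n = len(d)
            ranks = rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            mirror = ranks.sum() - w_obs
            stat_obs = min(w_obs, mirror)
            count = 0
            for signs in itertools.product([0, 1], repeat=n):
                w = ranks[np.array(signs, dtype=bool)].sum()
                if min(w, ranks.sum() - w) <= stat_obs:
                    count += 1
            p_exact = count / 2 ** n
            table = _report_for_diffs(d)
            assert table.loc["I", "p_value"] == pytest.approx(p_exact, abs=1e-10)

    def test_too_few_pairs_rejected(self, default_study):
        maxr = [r for r in default_study if r.effort == "maximal"][:1]
        subr = [r for r in default_study if r.effort == "submaximal"][:1]
        with pytest.raises(ValueError):
            mg.group_area_comparison(maxr, subr)

    def test_default_effect_direction_on_simulated_study(self, default_study):
        """Under the default redistribution the thumb gains relative load in
        submaximal grips (negative max-minus-submax difference) and the
        thenar loses it."""
        maxr = [r for r in default_study if r.effort == "maximal"]
        subr = [r for r in default_study if r.effort == "submaximal"]
        table = mg.group_area_comparison(maxr, subr).set_index("area")
        assert table.loc["I", "mean_diff"] < 0
        assert table.loc["TH", "mean_diff"] > 0
        assert table.loc["I", "p_value"] < 1e-6


def _report_for_diffs(diffs):
    """Build matched max/submax records whose thumb percent differs by
    exactly ``diffs`` and run the group comparison on them."""
    maxr, subr = [], []
    for i, d in enumerate(diffs):
        base = np.array([20.0, 12, 16, 13, 8, 16, 15])
        shifted = base.copy()
        shifted[0] -= d
        shifted[1:] += d / 6
        sid = f"S{i + 1:03d}"
        common = dict(session=1, trial=1, age=30.0, sex="male", handedness="right")
        maxr.append(mg.TrialRecord(subject_id=sid, hand="left", effort="maximal",
                                   loads=mg.AreaLoads.from_array(300.0, base), **common))
        subr.append(mg.TrialRecord(subject_id=sid, hand="right", effort="submaximal",
                                   loads=mg.AreaLoads.from_array(200.0, shifted), **common))
    return mg.group_area_comparison(maxr, subr).set_index("area")
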