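"""Conventional threshold-based sincerity classification.

The conventional rule compares the two hands of one subject area by area on
the percent-contribution scale.  An area "exceeds" when the absolute
bimanual difference is strictly greater than a significance threshold
(default 3 percentage points, the physiological between-hand difference
bound established for cylinder-grip load maps).  A hand pair is called
insincere when at least ``cutoff`` of the seven areas exceed; sweeping the
cutoff over 0..8 traces a 9-point ROC staircase from which an operating
point is picked by Youden's J (ties resolved toward higher specificity,
i.e. the larger cutoff, since falsely branding a sincere subject carries
the greater harm).

Also provided: pairing of simulated trial records into labelled hand pairs,
and the group-level paired area-to-area comparison (signed-rank test).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .loadmap import AREAS, AreaLoads, HandArea, TrialRecord

__all__ = [
    "HandPair",
    "DiffProfile",
    "CutoffROC",
    "diff_profile",
    "classify_pair",
    "cutoff_roc",
    "build_pairs",
    "group_area_comparison",
    "DEFAULT_THRESHOLD",
]

#: Default bimanual significance threshold, in percentage points.
DEFAULT_THRESHOLD = 3.0

#: Number of distinct count cutoffs (0..8 inclusive: counts range over 0..7).
N_CUTOFFS = 9


@dataclass(frozen=True)
class HandPair:
    """Left and right per-area loads of one bimanual comparison."""

    left: AreaLoads
    right: AreaLoads
    truth: str = "unknown"  # sincere | insincere | unknown
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.truth not in ("sincere", "insincere", "unknown"):
            raise ValueError(f"truth must be sincere/insincere/unknown, got {self.truth!r}")


@dataclass(frozen=True)
class DiffProfile:
    """Absolute bimanual percent differences and the exceedance count."""

    diff: Mapping[HandArea, float]
    count_exceeding: int
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.count_exceeding <= len(AREAS)):
            raise ValueError("count_exceeding out of range")
        expected = sum(1 for a in AREAS if self.diff[a] > self.threshold)
        if expected != self.count_exceeding:
            raise ValueError("count_exceeding inconsistent with diff and threshold")

    @property
    def exceeding(self) -> frozenset[HandArea]:
        return frozenset(a for a in AREAS if self.diff[a] > self.threshold)


@dataclass(frozen=True)
class CutoffROC:
    """ROC over the integer count cutoffs 0..8, plus the chosen point."""

    cutoffs: tuple[int, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    chosen_cutoff: int
    chosen_sensitivity: float
    chosen_specificity: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def diff_profile(pair: HandPair, threshold: float = DEFAULT_THRESHOLD) -> DiffProfile:
    """Per-area absolute bimanual differences and the count exceeding ``threshold``.

    The exceedance is strict (``> threshold``): a difference of exactly 3.0
    percentage points does not count at the default threshold.
    """
    if not (threshold > 0):
        raise ValueError("threshold must be > 0")
    diff = {a: abs(pair.left.percent[a] - pair.right.percent[a]) for a in AREAS}
    count = sum(1 for a in AREAS if diff[a] > threshold)
    return DiffProfile(diff=diff, count_exceeding=count, threshold=threshold)


def classify_pair(profile: DiffProfile, cutoff: int) -> str:
    """Label a pair insincere iff at least ``cutoff`` areas exceed the threshold."""
    if not (0 <= cutoff <= len(AREAS) + 1):
        raise ValueError(f"cutoff must be in 0..{len(AREAS) + 1}, got {cutoff}")
    return "insincere" if profile.count_exceeding >= cutoff else "sincere"


def cutoff_roc(pairs: Sequence[HandPair], threshold: float = DEFAULT_THRESHOLD) -> CutoffROC:
    """ROC of the exceedance-count rule over all integer cutoffs.

    Sensitivity and specificity are evaluated at every cutoff in 0..8;
    cutoff 0 labels everything insincere (sens 1, spec 0) and cutoff 8
    nothing (sens 0, spec 1).  The AUC is the trapezoidal area over the
    staircase in (1-specificity, sensitivity) space, which for a discrete
    score equals the tie-corrected Mann-Whitney probability.  The chosen
    cutoff maximises Youden's J; ties break toward the higher cutoff
    (higher specificity).
    """
    counts = np.array([diff_profile(p, threshold).count_exceeding for p in pairs])
    truth = np.array([p.truth for p in pairs])
    if np.any(truth == "unknown"):
        raise ValueError("cutoff_roc requires labelled pairs")
    pos = counts[truth == "insincere"]
    neg = counts[truth == "sincere"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("cutoff_roc needs at least one sincere and one insincere pair")
    cutoffs = tuple(range(N_CUTOFFS))
    sens = tuple(float(np.mean(pos >= c)) for c in cutoffs)
    spec = tuple(float(np.mean(neg < c)) for c in cutoffs)
    # in cutoff order both coordinates are non-increasing; reversing gives
    # the staircase from (0,0) to (1,1) with vertical steps kept in order
    fpr = np.array([1.0 - s for s in spec])[::-1]
    tpr = np.array(sens)[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    j = np.array(sens) + np.array(spec) - 1.0
    # argmax on the reversed array prefers the largest cutoff among ties
    best = len(j) - 1 - int(np.argmax(j[::-1]))
    return CutoffROC(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        chosen_cutoff=best,
        chosen_sensitivity=sens[best],
        chosen_specificity=spec[best],
    )


def build_pairs(records: Iterable[TrialRecord]) -> list[HandPair]:
    """Assemble labelled hand pairs from study records.

    Positive (insincere) pairs: within one subject, session and trial
    index, the maximal-effort hand against the submaximal-effort hand.
    Negative (sincere) pairs: within one subject and trial index, the
    maximal-effort hand of session 1 against the maximal-effort hand of
    session 2 — both sincere maximal grips on opposite hands, mimicking an
    honest bimanual test.  This negative-class construction is a design
    choice of this package (see the methods note).
    """
    by_key: dict[tuple, TrialRecord] = {}
    for r in records:
        key = (r.subject_id, r.session, r.trial, r.effort)
        if key in by_key:
            raise ValueError(f"duplicate record for {key}")
        by_key[key] = r

    def _oriented(a: TrialRecord, b: TrialRecord) -> tuple[AreaLoads, AreaLoads]:
        if {a.hand, b.hand} != {"left", "right"}:
            raise ValueError("a hand pair needs one left and one right record")
        left, right = (a, b) if a.hand == "left" else (b, a)
        return left.loads, right.loads

    pairs: list[HandPair] = []
    subjects = sorted({k[0] for k in by_key})
    sessions = sorted({k[1] for k in by_key})
    trials = sorted({k[2] for k in by_key})
    for sid in subjects:
        for session in sessions:
            for trial in trials:
                mx = by_key.get((sid, session, trial, "maximal"))
                sub = by_key.get((sid, session, trial, "submaximal"))
                if mx is None or sub is None:
                    raise ValueError(f"missing counterpart record for {sid} session {session} trial {trial}")
                left, right = _oriented(mx, sub)
                pairs.append(
                    HandPair(left=left, right=right, truth="insincere", pair_id=f"{sid}-s{session}-t{trial}-sub")
                )
        if len(sessions) >= 2:
            s1, s2 = sessions[0], sessions[1]
            for trial in trials:
                m1 = by_key[(sid, s1, trial, "maximal")]
                m2 = by_key[(sid, s2, trial, "maximal")]
                left, right = _oriented(m1, m2)
                pairs.append(HandPair(left=left, right=right, truth="sincere", pair_id=f"{sid}-t{trial}-max"))
    if len(sessions) < 2:
        warnings.warn("single-session input: no sincere (maximal-vs-maximal) pairs can be formed")
    return pairs


def group_area_comparison(
    max_records: Sequence[TrialRecord],
    submax_records: Sequence[TrialRecord],
) -> pd.DataFrame:
    """Group-level paired comparison of each area under maximal vs submaximal effort.

    Records are paired by (subject, session, trial).  For every area the
    report gives the mean, min, max and standard deviation of the paired
    percent differences (maximal minus submaximal) and a two-sided Wilcoxon
    signed-rank p-value.
    """
    sub_by_key = {(r.subject_id, r.session, r.trial): r for r in submax_records}
    diffs: dict[HandArea, list[float]] = {a: [] for a in AREAS}
    n_pairs = 0
    for r in max_records:
        other = sub_by_key.get((r.subject_id, r.session, r.trial))
        if other is None:
            continue
        n_pairs += 1
        for a in AREAS:
            diffs[a].append(r.loads.percent[a] - other.loads.percent[a])
    if n_pairs < 2:
        raise ValueError("group_area_comparison needs at least 2 matched pairs")
    rows = []
    for a in AREAS:
        d = np.array(diffs[a])
        if np.allclose(d, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
        rows.append(
            {
                "area": a.value,
                "n": len(d),
                "mean_diff": float(d.mean()),
                "min_diff": float(d.min()),
                "max_diff": float(d.max()),
                "sd_diff": float(d.std(ddof=1)),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
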