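"""Synthetic manugraphy cohort generator.

Emulates the bimanual grip-sincerity study design: each subject attends two
sessions and performs three 5-second grip trials per hand per session, with
one hand instructed to grip maximally and the other submaximally (half to
three-quarters of capacity); the submaximal hand is randomised in session 1
and swapped in session 2.  The default design (54 subjects, 25 male,
52 right-handed, ages 19-53) yields 324 maximal and 324 submaximal records.

The generative model:

* each subject has a latent grip capacity (``strength``, N) and a per-hand
  baseline load composition over the seven contact areas, drawn around a
  configurable population mean composition;
* between-hand physiological asymmetry is Gaussian on the percent scale
  with a small spread, so sincere bimanual differences rarely exceed the
  3-percentage-point significance threshold used downstream;
* a trial's total force is capacity × effort fraction × multiplicative
  trial noise, with the effort fraction 1 for maximal effort and uniform on
  [0.5, 0.75] for submaximal effort;
* a trial's composition is Dirichlet-distributed around the hand baseline,
  shifted by a configurable redistribution profile under submaximal effort
  (by default the thumb and index gain relative load while the palm
  eminences and ulnar digits lose it) and renormalised to 100.

All randomness flows through :class:`numpy.random.Generator` streams keyed
on ``(seed, subject, session, hand, trial)``, so any record can be
regenerated in isolation and record order never affects values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .loadmap import (
    AREAS,
    BACKGROUND,
    AreaLoads,
    AreaMask,
    HandArea,
    SensorGrid,
    TrialRecord,
)

__all__ = [
    "StudyDesign",
    "SubjectProfile",
    "EffortModel",
    "make_cohort",
    "simulate_trial",
    "simulate_study",
    "render_map",
    "DEFAULT_POPULATION_COMPOSITION",
    "DEFAULT_REDISTRIBUTION",
]

#: Population mean percent composition of the seven areas.  A configuration
#: default chosen as a plausible cylinder-grip pattern (radial digits and
#: palm eminences carry most load); it is NOT an empirical value.
DEFAULT_POPULATION_COMPOSITION: dict[HandArea, float] = {
    HandArea.I: 20.0,
    HandArea.II: 12.0,
    HandArea.III: 16.0,
    HandArea.IV: 13.0,
    HandArea.V: 8.0,
    HandArea.TH: 16.0,
    HandArea.HY: 15.0,
}

#: Default percentage-point shift of the composition under submaximal
#: effort (applied before renormalisation; sums to zero).  Direction:
#: thumb and index are neglected the least (their relative share rises),
#: the thenar is neglected the most.  The hypothenar's sign is debatable
#: on the evidence and is fully configurable.
DEFAULT_REDISTRIBUTION: dict[HandArea, float] = {
    HandArea.I: +2.5,
    HandArea.II: +1.5,
    HandArea.III: -0.5,
    HandArea.IV: -0.5,
    HandArea.V: -0.5,
    HandArea.TH: -1.5,
    HandArea.HY: -1.0,
}


@dataclass(frozen=True)
class StudyDesign:
    """Cohort and visit structure of the simulated study."""

    n_subjects: int = 54
    n_males: int = 25
    n_right_handed: int = 52
    sessions: int = 2
    trials_per_hand_per_session: int = 3
    age_range: tuple[int, int] = (19, 53)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.sessions <= 0 or self.trials_per_hand_per_session <= 0:
            raise ValueError("counts must be > 0")
        if not (0 <= self.n_males <= self.n_subjects):
            raise ValueError("n_males must be between 0 and n_subjects")
        if not (0 <= self.n_right_handed <= self.n_subjects):
            raise ValueError("n_right_handed must be between 0 and n_subjects")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low <= high")


@dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject parameters of the generative model.

    ``baseline_composition`` maps hand -> {area -> mean percent}; each
    hand's composition sums to 100.  ``trial_concentration`` is the
    Dirichlet concentration governing trial-to-trial compositional noise
    (``inf`` = no noise); ``asymmetry_sd`` is the scale (percentage points)
    of the physiological between-hand composition difference.
    """

    subject_id: str
    age: float
    sex: str
    handedness: str
    strength: float
    baseline_composition: Mapping[str, Mapping[HandArea, float]]
    asymmetry_sd: float
    trial_concentration: float
    submax_hand_session1: str

    def __post_init__(self) -> None:
        if not (self.strength > 0):
            raise ValueError("strength must be > 0")
        if not (self.trial_concentration > 0):
            raise ValueError("trial_concentration must be > 0")
        for hand in ("left", "right"):
            s = sum(self.baseline_composition[hand][a] for a in AREAS)
            if abs(s - 100.0) > 1e-6:
                raise ValueError(f"{hand} baseline composition sums to {s}, expected 100")
        if self.submax_hand_session1 not in ("left", "right"):
            raise ValueError("submax_hand_session1 must be 'left' or 'right'")


@dataclass(frozen=True)
class EffortModel:
    """How submaximal effort changes force and load composition."""

    force_fraction_low: float = 0.5
    force_fraction_high: float = 0.75
    redistribution_delta: Mapping[HandArea, float] = field(
        default_factory=lambda: dict(DEFAULT_REDISTRIBUTION)
    )
    delta_jitter_sd: float = 0.5
    force_noise_sd: float = 0.04

    def __post_init__(self) -> None:
        if not (0 < self.force_fraction_low <= self.force_fraction_high <= 1):
            raise ValueError("need 0 < force_fraction_low <= force_fraction_high <= 1")
        delta_sum = sum(self.redistribution_delta.get(a, 0.0) for a in AREAS)
        if abs(delta_sum) > 0.5:
            raise ValueError(
                f"redistribution_delta should be approximately zero-sum, sums to {delta_sum}"
            )
        if self.delta_jitter_sd < 0 or self.force_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")

    def delta_array(self) -> np.ndarray:
        return np.array([self.redistribution_delta.get(a, 0.0) for a in AREAS], dtype=float)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, subject_index]))


def _trial_rng(seed: int, subject_index: int, session: int, hand: str, trial: int) -> np.random.Generator:
    hand_code = 0 if hand == "left" else 1
    return np.random.default_rng(np.random.SeedSequence([seed, 2, subject_index, session, hand_code, trial]))


# Latent strength (N) on a 200-mm cylinder: log-normal around sex-specific
# medians with ~20% coefficient of variation.
_STRENGTH_MEDIAN = {"male": 420.0, "female": 280.0}
_STRENGTH_LOG_SD = 0.20


def make_cohort(
    design: StudyDesign,
    population_mean: Mapping[HandArea, float] | None = None,
    mean_concentration: float = 150.0,
    asymmetry_sd: float = 1.0,
    trial_concentration: float = 600.0,
) -> list[SubjectProfile]:
    """Draw the simulated cohort: one :class:`SubjectProfile` per subject.

    Sex and handedness counts match the design exactly; ages are uniform on
    the design's range.  Subject mean compositions are Dirichlet draws
    around ``population_mean`` (spread set by ``mean_concentration``); each
    hand then receives an independent Gaussian perturbation of scale
    ``asymmetry_sd/sqrt(2)`` per area so the between-hand difference has
    scale ``asymmetry_sd``.  The submaximal hand of session 1 is assigned
    by a seeded pseudo-randomiser.  Deterministic given ``design.seed``.
    """
    if population_mean is None:
        population_mean = DEFAULT_POPULATION_COMPOSITION
    mean_vec = np.array([population_mean[a] for a in AREAS], dtype=float)
    if abs(mean_vec.sum() - 100.0) > 1e-6:
        raise ValueError("population_mean must sum to 100")

    assign_rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    sexes = np.array(["male"] * design.n_males + ["female"] * (design.n_subjects - design.n_males))
    hands = np.array(
        ["right"] * design.n_right_handed + ["left"] * (design.n_subjects - design.n_right_handed)
    )
    assign_rng.shuffle(sexes)
    assign_rng.shuffle(hands)

    profiles: list[SubjectProfile] = []
    lo, hi = design.age_range
    for i in range(design.n_subjects):
        rng = _subject_rng(design.seed, i)
        age = float(rng.integers(lo, hi + 1))
        sex = str(sexes[i])
        strength = float(_STRENGTH_MEDIAN[sex] * math.exp(rng.normal(0.0, _STRENGTH_LOG_SD)))
        subject_mean = rng.dirichlet(mean_vec / 100.0 * mean_concentration) * 100.0
        baseline: dict[str, dict[HandArea, float]] = {}
        for hand in ("left", "right"):
            comp = subject_mean + rng.normal(0.0, asymmetry_sd / math.sqrt(2.0), size=len(AREAS))
            comp = np.clip(comp, 0.1, None)
            comp = comp / comp.sum() * 100.0
            baseline[hand] = dict(zip(AREAS, comp.tolist()))
        submax_hand = "left" if rng.random() < 0.5 else "right"
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                age=age,
                sex=sex,
                handedness=str(hands[i]),
                strength=strength,
                baseline_composition=baseline,
                asymmetry_sd=asymmetry_sd,
                trial_concentration=trial_concentration,
                submax_hand_session1=submax_hand,
            )
        )
    return profiles


def _draw_composition(
    rng: np.random.Generator,
    baseline: np.ndarray,
    concentration: float,
    delta: np.ndarray | None,
    jitter_sd: float,
) -> np.ndarray:
    """Draw one trial composition (percent scale, sums to 100)."""
    mean = baseline.copy()
    if delta is not None:
        if jitter_sd > 0:
            mean = mean + delta + rng.normal(0.0, jitter_sd, size=len(mean))
        else:
            mean = mean + delta
    mean = np.clip(mean, 0.05, None)
    mean = mean / mean.sum() * 100.0
    if math.isinf(concentration):
        return mean
    pct = rng.dirichlet(mean / 100.0 * concentration) * 100.0
    # Dirichlet can return exact zeros at tiny alphas; keep strictly valid.
    pct = np.clip(pct, 0.0, None)
    return pct / pct.sum() * 100.0


def simulate_trial(
    profile: SubjectProfile,
    session: int,
    trial: int,
    hand: str,
    effort: str,
    model: EffortModel,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate one grip trial for one hand.

    Total force is ``strength × f × ε`` with effort fraction ``f = 1``
    (maximal) or ``f ~ U(force_fraction_low, force_fraction_high)``
    (submaximal), and ``ε`` a mean-one log-normal trial noise.  The percent
    composition is Dirichlet around the hand baseline, shifted by the
    redistribution profile when the effort is submaximal.  The realised
    ``f`` is recorded on the returned record (``effort_fraction``).
    """
    if effort not in ("maximal", "submaximal"):
        raise ValueError(f"effort must be 'maximal' or 'submaximal', got {effort!r}")
    # the fraction is drawn unconditionally so the maximal and submaximal
    # paths consume the stream identically (null effect => identical records)
    drawn = float(rng.uniform(model.force_fraction_low, model.force_fraction_high))
    if effort == "submaximal":
        fraction = drawn
        delta = model.delta_array()
    else:
        fraction = 1.0
        delta = None
    sd = model.force_noise_sd
    noise = math.exp(rng.normal(-0.5 * sd * sd, sd)) if sd > 0 else 1.0
    total = profile.strength * noise * fraction
    baseline = np.array([profile.baseline_composition[hand][a] for a in AREAS], dtype=float)
    pct = _draw_composition(rng, baseline, profile.trial_concentration, delta, model.delta_jitter_sd)
    return TrialRecord(
        subject_id=profile.subject_id,
        session=session,
        trial=trial,
        hand=hand,
        effort=effort,
        loads=AreaLoads.from_array(total, pct),
        age=profile.age,
        sex=profile.sex,
        handedness=profile.handedness,
        effort_fraction=fraction,
    )


def simulate_study(
    design: StudyDesign,
    model: EffortModel | None = None,
    cohort: Sequence[SubjectProfile] | None = None,
) -> list[TrialRecord]:
    """Simulate the full study: every subject, session, hand and trial.

    Within a session one hand grips maximally and the other submaximally;
    the hands swap between sessions.  The default design yields
    ``54 × 2 × 3 × 2 = 648`` records, half of them maximal.
    """
    if model is None:
        model = EffortModel()
    if cohort is None:
        cohort = make_cohort(design)
    records: list[TrialRecord] = []
    for i, profile in enumerate(cohort):
        for session in range(1, design.sessions + 1):
            # Alternate the submaximal hand between sessions.
            if (session - 1) % 2 == 0:
                submax_hand = profile.submax_hand_session1
            else:
                submax_hand = "left" if profile.submax_hand_session1 == "right" else "right"
            for hand in ("left", "right"):
                effort = "submaximal" if hand == submax_hand else "maximal"
                for trial in range(1, design.trials_per_hand_per_session + 1):
                    rng = _trial_rng(design.seed, i, session, hand, trial)
                    records.append(simulate_trial(profile, session, trial, hand, effort, model, rng))
    return records


# --- Rendering synthetic pressure-sensor grids -----------------------------

# Base geometry of the rendered contact patch, in sensor cells at
# 2 sensors/cm² on the unrolled 200-mm cylinder surface.  Five fingertip
# contact blobs sit in a distal row; the thenar and hypothenar blobs sit
# proximally.  Radii are chosen so a full default grip activates on the
# order of 150 sensors, in the 120-200 range typical of a cylinder grip.
_TIP_RADIUS = 2.35
_PALM_RADIUS = 3.0
_TIP_ROW = 6.0
_PALM_ROW = 17.0
_TIP_COLS = (4.0, 9.0, 14.0, 19.0, 24.0)
_PALM_COLS = (8.0, 20.0)
_BASE_SHAPE = (26, 30)

_TEMPLATE_AREAS: tuple[HandArea, ...] = (
    HandArea.I,
    HandArea.II,
    HandArea.III,
    HandArea.IV,
    HandArea.V,
    HandArea.TH,
    HandArea.HY,
)


def render_map(
    loads: AreaLoads,
    hand_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[SensorGrid, AreaMask]:
    """Render per-area loads as a synthetic pressure grid plus area mask.

    Seven disjoint circular templates (five fingertips, two palm
    eminences) receive smooth Gaussian force blobs scaled so that each
    area's force sum equals ``loads.total_force × percent/100`` exactly;
    aggregating the rendered grid therefore reproduces the input loads.
    Template centres are jittered sub-cell by ``rng`` so repeated renders
    vary realistically in footprint.

    Raises
    ------
    ValueError
        If ``hand_scale`` is too small to place seven disjoint templates
        (or any two scaled templates would overlap).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if hand_scale * _TIP_RADIUS < 1.0:
        raise ValueError(f"hand_scale {hand_scale} too small to place 7 disjoint sensor templates")
    shape = (
        int(math.ceil(_BASE_SHAPE[0] * max(1.0, hand_scale))),
        int(math.ceil(_BASE_SHAPE[1] * max(1.0, hand_scale))),
    )
    centres = [(_TIP_ROW, c) for c in _TIP_COLS] + [(_PALM_ROW, c) for c in _PALM_COLS]
    radii = [_TIP_RADIUS] * 5 + [_PALM_RADIUS] * 2
    centres = [(r * hand_scale, c * hand_scale) for r, c in centres]
    radii = [rad * hand_scale for rad in radii]

    grid = np.zeros(shape, dtype=float)
    mask = np.full(shape, BACKGROUND, dtype=object)
    rows, cols = np.indices(shape)
    for area, (cy, cx), radius in zip(_TEMPLATE_AREAS, centres, radii):
        cy = cy + rng.uniform(-0.5, 0.5)
        cx = cx + rng.uniform(-0.5, 0.5)
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        inside = d2 <= radius * radius
        if not inside.any():
            raise ValueError("template degenerated to zero sensors; increase hand_scale")
        if np.any(mask[inside] != BACKGROUND):
            raise ValueError("hand_scale places overlapping area templates")
        mask[inside] = area.value
        weights = np.exp(-d2[inside] / (2.0 * (radius / 2.0) ** 2))
        area_force = loads.total_force * loads.percent[area] / 100.0
        grid[inside] = weights / weights.sum() * area_force
    return SensorGrid(values=grid), AreaMask(assignment=mask)
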