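"""Subject-level reporting: hexagon-web summary and recommendations.

The hexagon web condenses the 21 feature scores into six axes — the
cardiovascular block, trunk endurance, plank endurance/asymmetry, leg
strength and movement transitions, static balance, and tapping — each
min–max scaled to [0, 1] against a reference cohort.  Red-dot asymmetry
flags mark left/right score differences of 2 or more points on the
paired tests (side planks, leg strength, balance).

Recommendations are rule-based on the three subsystem classes: C3
everywhere yields a maintenance message; every subsystem at C2 or worse
receives a 4-week training plan with a retest instruction; any C1
subsystem raises a doctor-referral flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import SampleSizeError
from .labeling import CLASS_NAMES

#: default hexagon axes: axis name -> contributing feature scores
HEXAGON_AXES: dict[str, tuple[str, ...]] = {
    "cardiovascular": ("BPhigh", "BPlow", "RFTest"),
    "trunk_endurance": ("Back", "Abdomen"),
    "plank": ("LeftPlank", "RightPlank", "PlankAs"),
    "legs_transitions": (
        "LeftLeg", "RightLeg", "SitDown", "Bend", "TurnToRight", "TurnToLeft",
    ),
    "balance": ("LeftOpened", "RightOpened", "LeftClosed", "RightClosed"),
    "tapping": ("Mobility", "Poverty", "Mistakes"),
}

#: left/right scored pairs checked for asymmetry: axis -> pairs
ASYMMETRY_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "plank": (("LeftPlank", "RightPlank"),),
    "legs_transitions": (("LeftLeg", "RightLeg"),),
    "balance": (("LeftOpened", "RightOpened"), ("LeftClosed", "RightClosed")),
}

ASYMMETRY_SCORE_GAP = 2.0

#: recommendation plan horizon for C2-level findings, weeks
PLAN_WEEKS = 4


@dataclass(frozen=True)
class HexagonSummary:
    """Six-axis radar summary of one subject against a cohort norm."""

    subject_id: str
    axes: dict[str, float]
    reference: dict[str, float]
    asymmetry: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "axes": {k: round(v, 6) for k, v in self.axes.items()},
            "reference": {k: round(v, 6) for k, v in self.reference.items()},
            "asymmetry": dict(self.asymmetry),
        }


def hexagon_summary(
    scored_row: pd.Series,
    reference: pd.DataFrame,
    axes: Mapping[str, Sequence[str]] | None = None,
) -> HexagonSummary:
    """Build the hexagon-web summary for one scored subject.

    Parameters
    ----------
    scored_row : Series
        One row of the per-feature score table.
    reference : DataFrame
        Scored cohort used as the scaling norm (min–max per axis; at
        least 4 subjects).
    axes : mapping, optional
        Axis layout overriding :data:`HEXAGON_AXES`.
    """
    if len(reference) < 4:
        raise SampleSizeError(
            f"reference cohort needs at least 4 subjects, got {len(reference)}"
        )
    axes = dict(axes) if axes is not None else HEXAGON_AXES
    values: dict[str, float] = {}
    norms: dict[str, float] = {}
    for name, feats in axes.items():
        feats = list(feats)
        subject_sum = float(scored_row[feats].sum())
        ref_sums = reference[feats].sum(axis=1)
        lo, hi = float(ref_sums.min()), float(ref_sums.max())
        span = hi - lo
        if span == 0:
            values[name] = 0.5
            norms[name] = 0.5
        else:
            values[name] = min(max((subject_sum - lo) / span, 0.0), 1.0)
            norms[name] = float((ref_sums.median() - lo) / span)

    flags = {}
    for axis, pairs in ASYMMETRY_PAIRS.items():
        if axis not in axes:
            continue
        flags[axis] = any(
            abs(float(scored_row[a]) - float(scored_row[b])) >= ASYMMETRY_SCORE_GAP
            for a, b in pairs
        )
    return HexagonSummary(
        subject_id=str(scored_row.name),
        axes=values,
        reference=norms,
        asymmetry=flags,
    )


@dataclass(frozen=True)
class Recommendation:
    """Rule-based guidance derived from the three subsystem classes."""

    subject_id: str
    classes: dict[str, str]
    messages: tuple[str, ...]
    plan_weeks: int | None
    refer_to_doctor: bool

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "classes": dict(self.classes),
            "messages": list(self.messages),
            "plan_weeks": self.plan_weeks,
            "refer_to_doctor": self.refer_to_doctor,
        }


#: message templates keyed by code
MESSAGES = {
    "maintain": "All systems in good condition: maintain current activity level.",
    "plan": (
        "{subsystem} system at {cls}: follow the {weeks}-week training plan "
        "and repeat the same tests afterwards."
    ),
    "refer": (
        "One or more systems show possible health issues (class C1): "
        "contact a doctor for further investigation."
    ),
}


def recommend(
    classes: Mapping[str, int], subject_id: str = ""
) -> Recommendation:
    """Generate a recommendation from per-subsystem class labels (0/1/2)."""
    named = {s: CLASS_NAMES[int(c)] for s, c in classes.items()}
    messages: list[str] = []
    plan_weeks = None
    refer = any(int(c) == 0 for c in classes.values())
    needs_plan = [s for s, c in classes.items() if int(c) <= 1]
    if not needs_plan:
        messages.append(MESSAGES["maintain"])
    else:
        plan_weeks = PLAN_WEEKS
        for s in needs_plan:
            messages.append(
                MESSAGES["plan"].format(
                    subsystem=s.capitalize(), cls=named[s], weeks=PLAN_WEEKS
                )
            )
    if refer:
        messages.append(MESSAGES["refer"])
    return Recommendation(
        subject_id=str(subject_id),
        classes=named,
        messages=tuple(messages),
        plan_weeks=plan_weeks,
        refer_to_doctor=refer,
    )
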