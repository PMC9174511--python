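"""Item labels, factor structure and trauma-checklist classification.

The ITQ has 12 symptom items (two per first-order factor) and 6 functional
impairment items (three tied to the PTSD block, three to the DSO block), all
scored 0 ("Not at all") to 4 ("Extremely").  The trauma checklist (ITEM) has
21 lifetime-event items, each recorded for three developmental periods.
"""

from __future__ import annotations

#: The six first-order symptom factors: re-experiencing, avoidance, sense of
#: current threat (hyperarousal), affective dysregulation, negative
#: self-concept, disturbed relationships.
FACTORS = ("Re", "Av", "Th", "AD", "NSC", "DR")

#: Symptom items in canonical order; two consecutive items per factor.
SYMPTOM_ITEMS = (
    "Re1", "Re2",
    "Av1", "Av2",
    "Hyp1", "Hyp2",
    "Dys1", "Dys2",
    "Nsc1", "Nsc2",
    "Rel1", "Rel2",
)

PTSD_ITEMS = SYMPTOM_ITEMS[:6]
DSO_ITEMS = SYMPTOM_ITEMS[6:]

#: Symptom clusters as (item, item) pairs, diagnostic order.
PTSD_CLUSTERS = (("Re1", "Re2"), ("Av1", "Av2"), ("Hyp1", "Hyp2"))
DSO_CLUSTERS = (("Dys1", "Dys2"), ("Nsc1", "Nsc2"), ("Rel1", "Rel2"))

#: Functional impairment items: PTSD block then DSO block.
PTSD_IMPAIRMENT = ("Pimp1", "Pimp2", "Pimp3")
DSO_IMPAIRMENT = ("Dimp1", "Dimp2", "Dimp3")
IMPAIRMENT_ITEMS = PTSD_IMPAIRMENT + DSO_IMPAIRMENT

#: Likert endorsement cut: a score >= 2 ("Moderately") counts as present.
ENDORSEMENT_CUT = 2

#: Developmental periods recorded for each checklist event.
PERIODS = ("childhood", "adolescence", "six_months")

#: Short column suffixes used in cohort tables for the three periods.
PERIOD_SUFFIXES = {"childhood": "child", "adolescence": "adol", "six_months": "6mo"}

#: Default intentional / unintentional / excluded classification of the 21
#: checklist events, as adjudicated by independent trauma clinicians in the
#: Italian validation study.  Items 12 ("caused extreme suffering or death to
#: another person") and 13 ("witnessed another person experiencing suffering
#: or death") are excluded as neither intentional nor unintentional harm to
#: the respondent.
DEFAULT_EVENT_CLASSES: dict[int, str] = {
    1: "unintentional",   # life-threatening illness
    2: "unintentional",   # someone close died in an awful manner
    3: "unintentional",   # someone close had life-threatening illness/accident
    4: "intentional",     # threatened with a weapon
    5: "intentional",     # physically assaulted by parent/guardian
    6: "intentional",     # physically assaulted by non-parent
    7: "intentional",     # sexually assaulted by parent/guardian
    8: "intentional",     # sexually assaulted by non-parent
    9: "intentional",     # sexually harassed
    10: "intentional",    # war or combat
    11: "intentional",    # held captive / tortured
    12: "excluded",
    13: "excluded",
    14: "unintentional",  # technological accident
    15: "unintentional",  # natural disaster
    16: "unintentional",  # man-made disaster
    17: "intentional",    # stalked
    18: "intentional",    # bullied
    19: "intentional",    # humiliated / put down
    20: "intentional",    # made to feel unloved/unwelcome/worthless
    21: "intentional",    # neglected / ignored / rejected / isolated
}

N_CHECKLIST_ITEMS = 21

EXPOSURE_CLASSES = ("intentional", "unintentional")


def exposure_column(item: int, period: str) -> str:
    """Cohort-table column name for checklist item ``item`` in ``period``."""
    if not 1 <= item <= N_CHECKLIST_ITEMS:
        raise ValueError(f"unknown checklist item id: {item}")
    if period not in PERIOD_SUFFIXES:
        raise ValueError(f"unknown period: {period!r}")
    return f"item{item:02d}_{PERIOD_SUFFIXES[period]}"


#: All 63 exposure-flag columns, item-major then period.
EXPOSURE_COLUMNS = tuple(
    exposure_column(i, p) for i in range(1, N_CHECKLIST_ITEMS + 1) for p in PERIODS
)
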