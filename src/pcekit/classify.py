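"""Clinical classification of episodes.

Each episode is assigned exactly one of 12 mutually exclusive clinical
groupings from its anchor (first) encounter, by the first matching rule
in rank order:

 1. Pregnancy — most responsible diagnosis (MRD) matches the pregnancy
    prefixes;
 2. Low Birth Weight / Perinatal / Congenital — MRD match;
 3. Post-Admission Events — any diagnosis on the anchor record flagged
    as arising after admission, irrespective of the MRD (not assessed
    when ranks 1–2 already fired);
 4. Trauma / Accidents / Injuries / Poisonings — any diagnosis code on
    the record matches, irrespective of the MRD;
 5. Mental Illness & Addictions — anchor at an inpatient mental-health
    facility, or MRD match;
 6. Ambulatory Care Sensitive Conditions — MRD match;
 7. Cancer — MRD match;
 8–11. Acute Planned/Unplanned × Surgical/Medical from the admission and
    service type of the anchor;
 12. Other Causes.

A missing MRD with no triggering flags falls through to the
admission/service-type rules (rule 8–11) and otherwise to Other Causes;
such anchors are logged and countable.
"""

from __future__ import annotations

import logging

import pandas as pd

from .records_io import (
    GROUPING_LABELS,
    GROUPINGS,
    AdmissionType,
    CodeMap,
    DxType,
    Encounter,
    Sector,
    ServiceType,
    round_half_up,
)

logger = logging.getLogger("pcekit")

__all__ = ["classify_episode", "classify_all", "match_code", "grouping_census", "grouping_rank"]

_RANK = {name: i + 1 for i, name in enumerate(GROUPINGS)}

_TYPE_RULES = {
    (AdmissionType.planned, ServiceType.surgical): "acute_planned_surgical",
    (AdmissionType.planned, ServiceType.medical): "acute_planned_medical",
    (AdmissionType.unplanned, ServiceType.surgical): "acute_unplanned_surgical",
    (AdmissionType.unplanned, ServiceType.medical): "acute_unplanned_medical",
}


def grouping_rank(name: str) -> int:
    return _RANK[name]


def match_code(code: str | None, prefixes) -> bool:
    """True iff *code* starts with any prefix, case-insensitively."""
    if not code:
        return False
    c = code.upper()
    return any(c.startswith(p.upper()) for p in prefixes)


def classify_episode(anchor: Encounter, codemap: CodeMap) -> str:
    """Assign the clinical grouping for an episode from its anchor record."""
    mrd = anchor.mrd_code
    if match_code(mrd, codemap.prefixes("pregnancy")):
        return "pregnancy"
    if match_code(mrd, codemap.prefixes("perinatal_congenital_lbw")):
        return "perinatal_congenital_lbw"
    if any(dxt == DxType.post_admission for _, dxt in anchor.dx_codes):
        return "post_admission_events"
    all_codes = ([mrd] if mrd else []) + [code for code, _ in anchor.dx_codes]
    trauma = codemap.prefixes("trauma_injury_poisoning")
    if any(match_code(code, trauma) for code in all_codes):
        return "trauma_injury_poisoning"
    if anchor.sector == Sector.inpatient_mental_health or match_code(
        mrd, codemap.prefixes("mental_illness_addictions")
    ):
        return "mental_illness_addictions"
    if match_code(mrd, codemap.prefixes("acsc")):
        return "acsc"
    if match_code(mrd, codemap.prefixes("cancer")):
        return "cancer"
    if not mrd:
        logger.info("anchor %s has no MRD; using admission/service type", anchor.encounter_id)
    rule = _TYPE_RULES.get((anchor.admission_type, anchor.service_type))
    return rule if rule is not None else "other_causes"


def classify_all(episodes: list, encounters_by_id: dict, codemap: CodeMap) -> None:
    """Classify every episode in place from its anchor encounter."""
    for ep in episodes:
        ep.grouping = classify_episode(encounters_by_id[ep.anchor_encounter_id], codemap)


def grouping_census(episodes: list) -> pd.DataFrame:
    """Episode counts and percentages per clinical grouping.

    Percentages are of total episodes, rounded half-up to one decimal.
    All 12 groupings appear, in hierarchy order, including empty ones.
    """
    counts = {g: 0 for g in GROUPINGS}
    for ep in episodes:
        counts[ep.grouping] += 1
    n_total = len(episodes)
    rows = []
    for g in GROUPINGS:
        pct = round_half_up(100.0 * counts[g] / n_total, 1) if n_total else 0.0
        rows.append({"grouping": g, "label": GROUPING_LABELS[g], "n": counts[g], "percent": pct})
    return pd.DataFrame(rows)
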