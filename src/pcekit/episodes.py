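"""Construction of person-centred episodes of care (PCE).

An episode opens at an acute-start admission (inpatient acute, same-day
surgery, inpatient mental health, and by default the emergency
department) and absorbs every subsequent institutional stay admitted
within ``window_days`` of the running discharge date; each absorbed stay
re-opens the window from its own discharge.  The episode closes once
``window_days`` pass with no institutional admission, and community care
dated within the episode span — from the anchor admission through
``window_days`` after the final discharge — belongs to the episode.

Gap arithmetic is in whole days with a closed boundary: a gap of exactly
``window_days`` chains, ``window_days + 1`` does not.  Episode ends are
censored at death and at study end.  Non-acute inpatient stays
(``inpatient_nonacute``) never anchor, extend, or join an episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

from .records_io import (
    COMMUNITY_SECTORS,
    INSTITUTIONAL_SECTORS,
    PER_DIEM_SECTORS,
    Encounter,
    Person,
    Sector,
    StudyConfig,
    ValidationError,
    acute_start_sectors,
)

__all__ = [
    "Episode",
    "build_episodes",
    "attach_community_care",
    "episode_cost",
    "allocated_amount_cents",
    "effective_discharge",
    "build_all_episodes",
]

#: Sort priority on identical admit dates: acute-start settings first so
#: that a same-day acute admission anchors before a co-admitted stay is
#: considered for absorption.
_SECTOR_PRIORITY = {
    Sector.inpatient_acute: 0,
    Sector.same_day_surgery: 1,
    Sector.inpatient_mental_health: 2,
    Sector.emergency: 3,
    Sector.inpatient_rehab: 4,
    Sector.complex_continuing_care: 5,
    Sector.long_term_care: 6,
    Sector.inpatient_nonacute: 7,
}


@dataclass
class Episode:
    """A chain of institutional stays plus attached community care."""

    episode_key: str
    person_id: str
    anchor_encounter_id: str
    start_date: date
    member_institutional_ids: list
    final_discharge_date: date
    end_date: date
    community_ids: list = field(default_factory=list)
    grouping: str | None = None
    total_cost_cents: int = 0
    per_sector_cost_cents: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.total_cost_cents / 100.0


def effective_discharge(enc: Encounter, person: Person | None, config: StudyConfig) -> date:
    """Discharge date used for chaining: censored at study end and death."""
    d = enc.discharge_date if enc.discharge_date is not None else config.study_end
    d = min(d, config.study_end)
    if person is not None and person.death_date is not None:
        d = min(d, person.death_date)
    return d


def institutional_sort_key(enc: Encounter):
    return (
        enc.admit_date,
        enc.discharge_date or date.max,
        _SECTOR_PRIORITY.get(enc.sector, 99),
        enc.encounter_id,
    )


def build_episodes(
    encounters: list, person: Person | None, config: StudyConfig
) -> tuple:
    """Chain one person's institutional encounters into episodes.

    Returns ``(episodes, unallocated_ids)`` where *unallocated_ids* are
    institutional encounters unreachable from any acute-start anchor
    (including every ``inpatient_nonacute`` stay).  Community encounters
    are ignored here; see :func:`attach_community_care`.
    """
    seen = set()
    insts = []
    for enc in encounters:
        if enc.encounter_id in seen:
            raise ValidationError(f"duplicate encounter id {enc.encounter_id}")
        seen.add(enc.encounter_id)
        if enc.sector in INSTITUTIONAL_SECTORS:
            insts.append(enc)
    insts.sort(key=institutional_sort_key)

    starters = acute_start_sectors(config)
    window = timedelta(days=config.window_days)
    death = person.death_date if person is not None else None

    episodes: list = []
    unallocated: list = []
    members: list = []  # open episode member encounters
    window_end: date | None = None
    final_discharge: date | None = None

    def close_open():
        nonlocal members, window_end, final_discharge
        if not members:
            return
        anchor = members[0]
        end = final_discharge + window
        end = min(end, config.study_end)
        if death is not None:
            end = min(end, death)
        key = f"{anchor.person_id}-E{len(episodes) + 1:03d}"
        episodes.append(
            Episode(
                episode_key=key,
                person_id=anchor.person_id,
                anchor_encounter_id=anchor.encounter_id,
                start_date=anchor.admit_date,
                member_institutional_ids=[m.encounter_id for m in members],
                final_discharge_date=final_discharge,
                end_date=max(end, final_discharge),
            )
        )
        members, window_end, final_discharge = [], None, None

    for enc in insts:
        if enc.sector is Sector.inpatient_nonacute:
            unallocated.append(enc.encounter_id)
            continue
        eff = effective_discharge(enc, person, config)
        eff = max(eff, enc.admit_date)  # death/censor never precedes admission here
        if members and enc.admit_date <= window_end:
            members.append(enc)
            window_end = max(window_end, eff + window)
            final_discharge = max(final_discharge, eff)
        else:
            close_open()
            if enc.sector in starters:
                members = [enc]
                window_end = eff + window
                final_discharge = eff
            else:
                unallocated.append(enc.encounter_id)
    close_open()
    return episodes, unallocated


def attach_community_care(episodes: list, encounters: list, config: StudyConfig) -> list:
    """Attach community encounters dated within an episode span.

    A community service on a day in the closed interval
    ``[start_date, end_date]`` of an episode of the same person is
    attached to that episode (episode spans of one person are disjoint,
    so the target is unique); returns the ids left unattached.
    """
    by_person: dict = {}
    for ep in episodes:
        by_person.setdefault(ep.person_id, []).append(ep)
    for eps in by_person.values():
        eps.sort(key=lambda e: e.start_date)
    unattached = []
    for enc in sorted(encounters, key=lambda e: (e.admit_date, e.encounter_id)):
        if enc.sector not in COMMUNITY_SECTORS:
            continue
        hit = None
        for ep in by_person.get(enc.person_id, ()):
            if ep.start_date <= enc.admit_date <= ep.end_date:
                hit = ep
                break
        if hit is None:
            unattached.append(enc.encounter_id)
        else:
            hit.community_ids.append(enc.encounter_id)
    return unattached


def allocated_amount_cents(enc: Encounter, episode: Episode, config: StudyConfig) -> int:
    """Cost of *enc* attributed to *episode*, prorating per-diem stays.

    A per-diem stay (long-term care, complex continuing care) extending
    past the episode end contributes ``cost * days_inside / stay_days``
    rounded to the cent, where days are counted inclusively.
    """
    if enc.sector not in PER_DIEM_SECTORS:
        return enc.cost_cents
    discharge = enc.discharge_date if enc.discharge_date is not None else config.study_end
    if discharge <= episode.end_date:
        return enc.cost_cents
    stay_days = (discharge - enc.admit_date).days + 1
    inside_days = (min(discharge, episode.end_date) - enc.admit_date).days + 1
    inside_days = max(inside_days, 0)
    return int(round(enc.cost_cents * inside_days / stay_days))


def episode_cost(episode: Episode, encounters_by_id: dict, config: StudyConfig) -> tuple:
    """Total and per-sector episode cost in cents (fills the episode in place)."""
    per_sector: dict = {}
    for eid in episode.member_institutional_ids + episode.community_ids:
        enc = encounters_by_id[eid]
        amount = allocated_amount_cents(enc, episode, config)
        per_sector[enc.sector] = per_sector.get(enc.sector, 0) + amount
    total = sum(per_sector.values())
    episode.total_cost_cents = total
    episode.per_sector_cost_cents = per_sector
    return total, per_sector


def build_all_episodes(encounters: list, persons: list, config: StudyConfig) -> tuple:
    """Run the grouper for every person.

    Returns ``(episodes, membership)`` where *membership* maps every
    encounter id to its episode key or ``"unallocated"``.
    """
    persons_by_id = {p.person_id: p for p in persons}
    by_person: dict = {}
    for enc in encounters:
        by_person.setdefault(enc.person_id, []).append(enc)
    all_episodes: list = []
    membership: dict = {}
    for pid in sorted(by_person):
        person = persons_by_id.get(pid)
        encs = by_person[pid]
        episodes, unallocated = build_episodes(encs, person, config)
        unattached = attach_community_care(episodes, encs, config)
        enc_index = {e.encounter_id: e for e in encs}
        for ep in episodes:
            episode_cost(ep, enc_index, config)
            for eid in ep.member_institutional_ids + ep.community_ids:
                membership[eid] = ep.episode_key
        for eid in unallocated + unattached:
            membership[eid] = "unallocated"
        all_episodes.extend(episodes)
    return all_episodes, membership
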