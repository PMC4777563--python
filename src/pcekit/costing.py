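"""Cost attribution: per-sector ledger of costs inside vs. outside episodes.

All arithmetic is in integer cents so that allocated + remaining equals
the grand total of encounter costs exactly, sector by sector and
overall.  Per-diem stays (long-term care, complex continuing care) that
extend past their episode's end date split their cost between the
allocated and remaining columns by day-count proration.
"""

from __future__ import annotations

import pandas as pd

from .records_io import Sector, StudyConfig, round_half_up
from .episodes import allocated_amount_cents

__all__ = ["allocate_costs", "unallocated_person_summary", "ledger_conservation_error_cents"]

SECTOR_ORDER = [s for s in Sector]


def allocate_costs(
    encounters: list, membership: dict, episodes: list, config: StudyConfig
) -> pd.DataFrame:
    """Build the allocation ledger.

    *membership* must map every encounter id to an episode key or
    ``"unallocated"`` — a missing entry is an error, since conservation
    could no longer be guaranteed.  Returns one row per sector plus an
    ``all_services`` total row, with allocated / remaining dollar amounts
    and the percent allocated (half-up to one decimal).
    """
    episodes_by_key = {ep.episode_key: ep for ep in episodes}
    allocated = {s: 0 for s in Sector}
    remaining = {s: 0 for s in Sector}
    for enc in encounters:
        if enc.encounter_id not in membership:
            raise KeyError(
                f"encounter {enc.encounter_id} missing from episode membership; "
                "cost conservation would break"
            )
        key = membership[enc.encounter_id]
        if key == "unallocated":
            remaining[enc.sector] += enc.cost_cents
        else:
            amount = allocated_amount_cents(enc, episodes_by_key[key], config)
            allocated[enc.sector] += amount
            remaining[enc.sector] += enc.cost_cents - amount
    rows = []
    for s in SECTOR_ORDER:
        total = allocated[s] + remaining[s]
        pct = round_half_up(100.0 * allocated[s] / total, 1) if total else 0.0
        rows.append(
            {
                "sector": s.value,
                "allocated": allocated[s] / 100.0,
                "remaining": remaining[s] / 100.0,
                "percent_allocated": pct,
            }
        )
    tot_a = sum(allocated.values())
    tot_r = sum(remaining.values())
    grand = tot_a + tot_r
    rows.append(
        {
            "sector": "all_services",
            "allocated": tot_a / 100.0,
            "remaining": tot_r / 100.0,
            "percent_allocated": round_half_up(100.0 * tot_a / grand, 1) if grand else 0.0,
        }
    )
    return pd.DataFrame(rows)


def ledger_conservation_error_cents(ledger: pd.DataFrame, encounters: list) -> int:
    """Cents by which the ledger total differs from the raw encounter total."""
    body = ledger[ledger["sector"] != "all_services"]
    ledger_cents = int(round((body["allocated"].sum() + body["remaining"].sum()) * 100))
    raw_cents = sum(enc.cost_cents for enc in encounters)
    return ledger_cents - raw_cents


def unallocated_person_summary(membership: dict, encounters: list, cohort_ids: list) -> tuple:
    """Count and total cost of cohort members with no episode at all.

    Returns ``(n_persons, total_cost_dollars)`` over persons in
    *cohort_ids* none of whose encounters belong to an episode.
    """
    cohort = set(cohort_ids)
    has_episode: set = set()
    cost_by_person: dict = {pid: 0 for pid in cohort}
    for enc in encounters:
        if enc.person_id not in cohort:
            continue
        cost_by_person[enc.person_id] = cost_by_person.get(enc.person_id, 0) + enc.cost_cents
        if membership.get(enc.encounter_id, "unallocated") != "unallocated":
            has_episode.add(enc.person_id)
    without = [pid for pid in cohort if pid not in has_episode]
    total_cents = sum(cost_by_person.get(pid, 0) for pid in without)
    return len(without), total_cents / 100.0
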