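"""Episode-level summary tables and end-to-end pipeline orchestration.

Cost distributions are summarised by mean (sample SD) and median
(interquartile range); quartiles use linear interpolation.  Grouping
rows are ordered by descending total episode cost, matching the
convention of the modelled study tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .records_io import (
    GROUPING_LABELS,
    GROUPINGS,
    Sector,
    StudyConfig,
    round_half_up,
    write_table,
)
from .episodes import allocated_amount_cents, build_all_episodes
from .classify import classify_all, grouping_census
from .cohort import (
    characterize_cohort,
    high_cost_threshold,
    person_annual_costs,
    select_cohort,
    upc_index,
)
from .costing import allocate_costs, unallocated_person_summary
from .synthetic_data import (
    ScenarioConfig,
    generate_encounters,
    generate_population,
)

logger = logging.getLogger("pcekit")

__all__ = ["grouping_summary", "sector_use_summary", "run_pipeline", "episodes_frame", "membership_frame"]


def _dist_stats(costs: np.ndarray) -> dict:
    """Mean/SD/median/IQR of a cost vector (blank stats when empty)."""
    if costs.size == 0:
        return {"mean_cost": np.nan, "sd_cost": np.nan, "median_cost": np.nan,
                "q1_cost": np.nan, "q3_cost": np.nan}
    return {
        "mean_cost": float(costs.mean()),
        "sd_cost": float(costs.std(ddof=1)) if costs.size > 1 else 0.0,
        "median_cost": float(np.percentile(costs, 50)),
        "q1_cost": float(np.percentile(costs, 25)),
        "q3_cost": float(np.percentile(costs, 75)),
    }


def grouping_summary(episodes: list) -> pd.DataFrame:
    """Per-grouping episode counts and cost distribution (Table-2 analogue).

    One row per clinical grouping (empty groupings keep n=0 and blank
    statistics), ordered by descending total cost; percentages half-up
    to one decimal.
    """
    by_grouping: dict = {g: [] for g in GROUPINGS}
    for ep in episodes:
        by_grouping[ep.grouping].append(ep.total_cost)
    n_total = len(episodes)
    grand_total = sum(ep.total_cost_cents for ep in episodes) / 100.0
    rows = []
    for g in GROUPINGS:
        costs = np.array(by_grouping[g], dtype=float)
        total = float(costs.sum())
        row = {
            "grouping": g,
            "label": GROUPING_LABELS[g],
            "n_episodes": costs.size,
            "percent_episodes": round_half_up(100.0 * costs.size / n_total, 1) if n_total else 0.0,
        }
        row.update(_dist_stats(costs))
        row["total_cost"] = total
        row["percent_of_total_cost"] = (
            round_half_up(100.0 * total / grand_total, 1) if grand_total else 0.0
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("total_cost", ascending=False, kind="mergesort").reset_index(drop=True)


def sector_use_summary(episodes: list, encounters: list, config: StudyConfig) -> pd.DataFrame:
    """Per-sector service use within episodes (Table-3 analogue).

    For each sector: number of episodes with any event of that sector,
    total events, mean and SD events per using episode, and total
    within-episode cost (per-diem stays prorated to the episode span).
    """
    enc_by_id = {e.encounter_id: e for e in encounters}
    events: dict = {s: [] for s in Sector}  # per sector: event count per using episode
    cost_cents: dict = {s: 0 for s in Sector}
    for ep in episodes:
        counts: dict = {}
        for eid in ep.member_institutional_ids + ep.community_ids:
            enc = enc_by_id[eid]
            counts[enc.sector] = counts.get(enc.sector, 0) + 1
            cost_cents[enc.sector] += allocated_amount_cents(enc, ep, config)
        for s, k in counts.items():
            events[s].append(k)
    rows = []
    for s in Sector:
        per_ep = np.array(events[s], dtype=float)
        rows.append(
            {
                "sector": s.value,
                "n_episodes_with_any": per_ep.size,
                "total_events": int(per_ep.sum()),
                "mean_events_per_using_episode": float(per_ep.mean()) if per_ep.size else 0.0,
                "sd_events_per_using_episode": (
                    float(per_ep.std(ddof=1)) if per_ep.size > 1 else 0.0
                ),
                "total_cost_within_episodes": cost_cents[s] / 100.0,
            }
        )
    return pd.DataFrame(rows)


def episodes_frame(episodes: list) -> pd.DataFrame:
    rows = []
    for ep in sorted(episodes, key=lambda e: e.episode_key):
        rows.append(
            {
                "episode_key": ep.episode_key,
                "person_id": ep.person_id,
                "anchor_encounter_id": ep.anchor_encounter_id,
                "start_date": ep.start_date.isoformat(),
                "final_discharge_date": ep.final_discharge_date.isoformat(),
                "end_date": ep.end_date.isoformat(),
                "n_institutional": len(ep.member_institutional_ids),
                "n_community": len(ep.community_ids),
                "grouping": ep.grouping or "",
                "total_cost": ep.total_cost_cents / 100.0,
            }
        )
    return pd.DataFrame(rows)


def membership_frame(membership: dict) -> pd.DataFrame:
    rows = [
        {"encounter_id": eid, "episode_key": key}
        for eid, key in sorted(membership.items())
    ]
    return pd.DataFrame(rows)


def run_pipeline(
    config: StudyConfig,
    scenario: ScenarioConfig | None = None,
    persons: list | None = None,
    encounters: list | None = None,
    codemap=None,
    out_dir=None,
    select_high_cost: bool = True,
) -> dict:
    """Run cohort selection, episode construction, classification,
    costing and reporting end to end.

    Either pass loaded *persons* / *encounters*, or a *scenario* to
    simulate them first.  With ``select_high_cost=False`` the cohort is
    every community-dwelling person alive at index (used when the input
    population already represents a high-cost cohort).  Returns a dict
    of report tables; with *out_dir* they are also written as CSV.
    """
    from .records_io import read_code_map

    if codemap is None:
        codemap = read_code_map()
    if encounters is None or persons is None:
        if scenario is None:
            raise ValueError("provide persons+encounters or a scenario to simulate")
        logger.info("simulating scenario: n_persons=%d seed=%d", scenario.n_persons, scenario.seed)
        persons = generate_population(scenario)
        encounters, _ = generate_encounters(persons, scenario, codemap, config)
    logger.info("input: %d persons, %d encounters", len(persons), len(encounters))

    # cohort selection
    costs = person_annual_costs(encounters, config)
    if select_high_cost and costs:
        threshold = high_cost_threshold(costs, config.percentile, config.quantile_method)
        cohort_ids = select_cohort(persons, costs, threshold, config)
    elif select_high_cost:
        threshold, cohort_ids = 0.0, []
    else:
        threshold = 0.0
        cohort_ids = select_cohort(persons, costs, -1.0, config)
    cohort_set = set(cohort_ids)
    cohort_persons = [p for p in persons if p.person_id in cohort_set]
    logger.info("cohort: %d of %d persons (threshold $%.2f)", len(cohort_ids), len(persons), threshold)

    # person-level characteristics (UPC over attributed ambulatory visits)
    upc_values, upc_categories = {}, {}
    amb: dict = {pid: [] for pid in cohort_set}
    any_contact = {pid: False for pid in cohort_set}
    for enc in encounters:
        if enc.person_id in cohort_set:
            any_contact[enc.person_id] = True
            if enc.ambulatory_flag:
                amb[enc.person_id].append(enc.provider_id)
    for pid in cohort_ids:
        value, category = upc_index(amb[pid])
        if category == "no_contact" and any_contact[pid]:
            category = "insufficient"
        upc_values[pid] = value
        upc_categories[pid] = category
    characteristics = characterize_cohort(cohort_persons, upc_categories)

    # episodes for the cohort
    cohort_encounters = [e for e in encounters if e.person_id in cohort_set]
    episodes, membership = build_all_episodes(cohort_encounters, cohort_persons, config)
    enc_by_id = {e.encounter_id: e for e in cohort_encounters}
    classify_all(episodes, enc_by_id, codemap)
    census = grouping_census(episodes)
    g_summary = grouping_summary(episodes)
    s_summary = sector_use_summary(episodes, cohort_encounters, config)
    ledger = allocate_costs(cohort_encounters, membership, episodes, config)
    n_without, cost_without = unallocated_person_summary(membership, cohort_encounters, cohort_ids)
    logger.info(
        "episodes: %d; persons without any episode: %d ($%.2f)",
        len(episodes), n_without, cost_without,
    )

    bundle = {
        "cohort": pd.DataFrame({"person_id": cohort_ids}),
        "characteristics": characteristics,
        "episodes": episodes_frame(episodes),
        "membership": membership_frame(membership),
        "census": census,
        "grouping_summary": g_summary,
        "sector_summary": s_summary,
        "ledger": ledger,
        "unallocated_persons": pd.DataFrame(
            [{"n_persons_without_episode": n_without, "total_cost": cost_without}]
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        for name, table in bundle.items():
            write_table(table, out / f"{name}.csv")
    # keep object-level results available to library callers
    bundle["_episodes"] = episodes
    bundle["_membership"] = membership
    bundle["_threshold"] = threshold
    return bundle
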