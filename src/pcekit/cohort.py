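"""High-cost cohort selection and person-level characteristics.

Person-level annual costs are summed across every sector; the high-cost
cohort is the set of persons strictly above a chosen percentile of the
person-total distribution (default the 95th) who were community-dwelling
(not long-term-care residents) and alive at the index date.

The usual-provider-of-care (UPC) index is the share of a person's
ambulatory physician visits made to their most-visited provider; it is
defined only for persons with at least three such visits, and a value of
0.75 or more denotes high continuity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records_io import Person, StudyConfig, round_half_up

logger = logging.getLogger("pcekit")

__all__ = [
    "PersonAnnualCost",
    "person_annual_costs",
    "high_cost_threshold",
    "select_cohort",
    "upc_index",
    "characterize_cohort",
]


@dataclass
class PersonAnnualCost:
    person_id: str
    total_cost_cents: int
    per_sector_cost_cents: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.total_cost_cents / 100.0


def person_annual_costs(encounters: list, config: StudyConfig | None = None) -> list:
    """Sum encounter costs per person and sector over the study year.

    Returns one record per person appearing in *encounters*; persons with
    no encounters are absent.  Encounter costs are taken in full as given
    (input rows already carry within-year amounts).
    """
    acc: dict = {}
    for enc in encounters:
        rec = acc.setdefault(enc.person_id, {})
        rec[enc.sector] = rec.get(enc.sector, 0) + enc.cost_cents
    out = []
    for pid in sorted(acc):
        per_sector = acc[pid]
        out.append(
            PersonAnnualCost(
                person_id=pid,
                total_cost_cents=sum(per_sector.values()),
                per_sector_cost_cents=dict(per_sector),
            )
        )
    return out


def high_cost_threshold(costs: list, percentile: float, method: str = "linear_interpolation") -> float:
    """Percentile of person annual totals, in dollars.

    ``method`` selects the quantile convention: ``linear_interpolation``
    (numpy's default) or ``lower_value`` (the largest observed value at
    or below the percentile rank).  Cohort selection downstream is
    strictly greater-than the returned threshold.
    """
    if not costs:
        raise ValueError("cannot compute a threshold from zero persons")
    totals = np.array([c.total_cost for c in costs], dtype=float)
    np_method = {"linear_interpolation": "linear", "lower_value": "lower"}[method]
    return float(np.percentile(totals, percentile, method=np_method))


def select_cohort(persons: list, costs: list, threshold: float, config: StudyConfig) -> list:
    """Person ids with total cost strictly above *threshold*, community-dwelling
    and alive at the index date."""
    totals = {c.person_id: c.total_cost for c in costs}
    out = []
    for p in persons:
        if totals.get(p.person_id, 0.0) <= threshold:
            continue
        if p.ltc_resident_at_index:
            continue
        if p.death_date is not None and p.death_date < config.study_start:
            continue
        out.append(p.person_id)
    return sorted(out)


def upc_index(provider_ids: list) -> tuple:
    """Usual-provider-of-care index for one person's ambulatory visits.

    *provider_ids* is the provider of each ambulatory visit; ``None``
    entries (unattributed visits) are excluded from both numerator and
    denominator and logged.  Returns ``(value, category)`` where the
    value is ``None`` when fewer than three attributed visits exist, and
    the category is one of ``no_contact`` (zero visits), ``insufficient``
    (one or two), ``low`` (< 0.75) or ``high`` (>= 0.75).
    """
    dropped = sum(1 for p in provider_ids if p is None)
    if dropped:
        logger.info("UPC: excluded %d visit(s) without provider_id", dropped)
    visits = [p for p in provider_ids if p is not None]
    if len(visits) == 0:
        return None, "no_contact"
    if len(visits) < 3:
        return None, "insufficient"
    counts: dict = {}
    for p in visits:
        counts[p] = counts.get(p, 0) + 1
    value = max(counts.values()) / len(visits)
    return value, ("high" if value >= 0.75 else "low")


# ---------------------------------------------------------------------------
# Cohort characteristics (Table-1 style binning)
# ---------------------------------------------------------------------------

_AGE_BINS = (("0-17", 0, 17), ("18-44", 18, 44), ("45-64", 45, 64), ("65-84", 65, 84), ("85+", 85, 10**4))
_DRUG_BINS = (("0", 0, 0), ("1-5", 1, 5), ("6-9", 6, 9), ("10-19", 10, 19), ("20+", 20, 10**6))


def _bin(value, bins):
    for name, lo, hi in bins:
        if lo <= value <= hi:
            return name
    raise ValueError(f"value {value} fits no bin")


def _age_group(age: float) -> str:
    return _bin(int(age), _AGE_BINS)


def _rurality(score) -> str:
    if score is None:
        return "missing"
    return "rural" if score >= 40 else "urban"


def _morbidity(count) -> str:
    if count is None:
        return "no_contact"
    if count == 0:
        return "0_adgs"
    return "1-7_adgs" if count <= 7 else "8plus_adgs"


def _upc_display(category: str) -> str:
    # Persons with some contact but <3 attributed visits are shown with
    # low continuity; both raw counts are retained internally.
    return {"no_contact": "no_contact", "insufficient": "low", "low": "low", "high": "high"}[category]


def characterize_cohort(persons: list, upc_categories: dict) -> pd.DataFrame:
    """Binned counts and percentages for the selected cohort.

    *upc_categories* maps person_id to the raw UPC category from
    :func:`upc_index`.  Percentages are of the cohort size (drug-count
    bins: of drug-benefit-eligible persons), half-up to one decimal.
    """
    n = len(persons)

    def tally(characteristic: str, values, denominator: int, order):
        counts = {k: 0 for k in order}
        for v in values:
            counts[v] += 1
        rows = []
        for k in order:
            pct = round_half_up(100.0 * counts[k] / denominator, 1) if denominator else 0.0
            rows.append(
                {
                    "characteristic": characteristic,
                    "category": k,
                    "count": counts[k],
                    "percent": pct,
                }
            )
        return rows

    rows = []
    rows += tally("age_group", [_age_group(p.age_at_index) for p in persons], n,
                  [b[0] for b in _AGE_BINS])
    rows += tally("sex", [p.sex for p in persons], n, ["female", "male"])
    rows += tally("rurality", [_rurality(p.rurality_score) for p in persons], n,
                  ["urban", "rural", "missing"])
    rows += tally(
        "primary_care_model",
        [p.primary_care_model for p in persons],
        n,
        ["family_health_team", "fee_for_service", "capitation", "other"],
    )
    rows += tally(
        "upc_category",
        [_upc_display(upc_categories.get(p.person_id, "no_contact")) for p in persons],
        n,
        ["no_contact", "low", "high"],
    )
    rows += tally("morbidity", [_morbidity(p.morbidity_adg_count) for p in persons], n,
                  ["no_contact", "0_adgs", "1-7_adgs", "8plus_adgs"])
    rows += tally(
        "drug_benefit",
        ["eligible" if p.drug_benefit_eligible else "not_eligible" for p in persons],
        n,
        ["not_eligible", "eligible"],
    )
    eligible = [p for p in persons if p.drug_benefit_eligible]
    rows += tally(
        "drugs_dispensed_among_eligible",
        [_bin(p.prior_year_drug_count or 0, _DRUG_BINS) for p in eligible],
        len(eligible),
        [b[0] for b in _DRUG_BINS],
    )
    rows += tally(
        "palliative",
        ["yes" if p.palliative_flag else "no" for p in persons],
        n,
        ["yes", "no"],
    )
    rows += tally(
        "died",
        ["yes" if p.death_date is not None else "no" for p in persons],
        n,
        ["yes", "no"],
    )
    return pd.DataFrame(rows)
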