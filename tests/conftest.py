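"""Shared fixtures and the independent brute-force episode oracle."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from pcekit import (
    AdmissionType,
    Encounter,
    Person,
    ScenarioConfig,
    Sector,
    ServiceType,
    StudyConfig,
    read_code_map,
)
from pcekit.records_io import INSTITUTIONAL_SECTORS

START = date(2010, 4, 1)


def day(n: int) -> date:
    """Day *n* of the study year (day 0 = study start)."""
    return START + timedelta(days=n)


def make_enc(
    eid,
    pid="p1",
    sector=Sector.inpatient_acute,
    admit=0,
    discharge=None,
    cost=100.0,
    mrd=None,
    dx=(),
    admission=AdmissionType.unplanned,
    service=ServiceType.medical,
    provider=None,
    ambulatory=False,
):
    """Build an encounter with day-offset dates."""
    if discharge is None:
        discharge = admit
    return Encounter(
        encounter_id=str(eid),
        person_id=pid,
        sector=sector,
        admit_date=day(admit),
        discharge_date=None if discharge == "open" else day(discharge),
        cost_cents=int(round(cost * 100)),
        mrd_code=mrd,
        dx_codes=list(dx),
        admission_type=admission,
        service_type=service,
        provider_id=provider,
        ambulatory_flag=ambulatory,
    )


def make_person(pid="p1", **kw):
    defaults = dict(age_at_index=60, sex="female")
    defaults.update(kw)
    return Person(person_id=pid, **defaults)


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def codemap():
    return read_code_map()


@pytest.fixture(scope="session")
def small_synthetic(config, codemap):
    """A small planted scenario shared across read-only tests."""
    from pcekit import generate_encounters, generate_population

    scenario = ScenarioConfig(n_persons=120, seed=11)
    persons = generate_population(scenario)
    encounters, gt = generate_encounters(persons, scenario, codemap, config)
    return persons, encounters, gt


# ---------------------------------------------------------------------------
# Independent oracle: transitive closure over the "gap <= window" relation,
# intersected with acute-anchor reachability.  Kept separate from the scan
# implementation in pcekit.episodes.
# ---------------------------------------------------------------------------

_PRIORITY = {
    Sector.inpatient_acute: 0,
    Sector.same_day_surgery: 1,
    Sector.inpatient_mental_health: 2,
    Sector.emergency: 3,
    Sector.inpatient_rehab: 4,
    Sector.complex_continuing_care: 5,
    Sector.long_term_care: 6,
}


def _key(enc):
    return (enc.admit_date, enc.discharge_date or date.max, _PRIORITY.get(enc.sector, 99), enc.encounter_id)


def brute_force_partition(encounters, person, config):
    """Reference grouping of one person's institutional encounters.

    Returns ``(partition, unallocated)`` where *partition* is a set of
    frozensets of encounter ids.  Episodes are grown as the fixed point
    of the "admitted within window_days of a member's effective
    discharge" relation, seeded from each successive acute-start anchor.
    """
    from pcekit.records_io import acute_start_sectors

    window = config.window_days
    starters = acute_start_sectors(config)
    death = person.death_date if person is not None else None

    def eff(enc):
        d = enc.discharge_date if enc.discharge_date is not None else config.study_end
        d = min(d, config.study_end)
        if death is not None:
            d = min(d, death)
        return max(d, enc.admit_date)

    pool = [
        e
        for e in encounters
        if e.sector in INSTITUTIONAL_SECTORS and e.sector != Sector.inpatient_nonacute
    ]
    unconsumed = set(e.encounter_id for e in pool)
    by_id = {e.encounter_id: e for e in pool}
    partition = set()
    while True:
        anchors = [e for e in pool if e.encounter_id in unconsumed and e.sector in starters]
        if not anchors:
            break
        anchor = min(anchors, key=_key)
        members = {anchor.encounter_id}
        changed = True
        while changed:
            changed = False
            wend = max(eff(by_id[m]) + timedelta(days=window) for m in members)
            for e in pool:
                if (
                    e.encounter_id in unconsumed
                    and e.encounter_id not in members
                    and _key(e) > _key(anchor)
                    and e.admit_date <= wend
                ):
                    members.add(e.encounter_id)
                    changed = True
        partition.add(frozenset(members))
        unconsumed -= members
    nonacute = {
        e.encounter_id
        for e in encounters
        if e.sector == Sector.inpatient_nonacute
    }
    return partition, unconsumed | nonacute
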