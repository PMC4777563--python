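"""Seeded synthetic persons and multi-sector encounter streams.

The generator emulates the statistical structure the episode grouper
assumes: readmission chains whose inter-stay gaps straddle the 30-day
stabilisation boundary, per-sector log-normal costs, per-category toy
diagnosis codes, and community care scattered inside and outside
episode spans.  Episodes are planted first and encounters serialized
from them, so the planted labels are ground truth by construction and
give an exact oracle for the grouper: a gap of at most ``window_days``
chains, a larger gap starts a new episode (when the next stay can
anchor) or leaves the stay unallocated (when it cannot).

Default rates mirror the published high-cost community cohort this
package models: ~83% of persons with at least one episode and ~1.2
episodes per person, 9% annual mortality, 52% drug-benefit eligibility,
and a clinical-grouping mix matching the reported episode distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .records_io import (
    CODE_DRIVEN_CATEGORIES,
    GROUPINGS,
    AdmissionType,
    CodeMap,
    ConfigError,
    DxType,
    Encounter,
    Person,
    Sector,
    ServiceType,
    StudyConfig,
    acute_start_sectors,
    serialize_dx_codes,
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_population",
    "generate_encounters",
    "summarize_scenario",
    "write_synthetic_dataset",
    "DEFAULT_GROUPING_MIX",
]

#: Episode clinical-grouping mix (probabilities over the 12 categories),
#: matching the reported distribution of episodes in the modelled cohort.
DEFAULT_GROUPING_MIX = {
    "acute_planned_surgical": 0.350,
    "acute_unplanned_medical": 0.210,
    "post_admission_events": 0.108,
    "cancer": 0.074,
    "trauma_injury_poisoning": 0.064,
    "mental_illness_addictions": 0.059,
    "acute_unplanned_surgical": 0.041,
    "acsc": 0.039,
    "pregnancy": 0.026,
    "perinatal_congenital_lbw": 0.015,
    "acute_planned_medical": 0.011,
    "other_causes": 0.003,
}

#: Per-sector log-normal cost parameters (meanlog, sdlog), dollars.
DEFAULT_COST_PARAMS = {
    Sector.inpatient_acute: (9.0, 0.8),
    Sector.same_day_surgery: (7.2, 0.6),
    Sector.emergency: (6.0, 0.6),
    Sector.inpatient_mental_health: (9.6, 0.8),
    Sector.inpatient_rehab: (9.6, 0.5),
    Sector.complex_continuing_care: (9.9, 0.5),
    Sector.long_term_care: (9.2, 0.5),
    Sector.inpatient_nonacute: (8.5, 0.6),
    Sector.home_care: (4.8, 0.7),
    Sector.physician: (4.7, 0.5),
    Sector.laboratory: (3.3, 0.5),
    Sector.drug: (4.0, 0.9),
    Sector.dialysis_outpatient: (6.3, 0.3),
    Sector.oncology_outpatient: (6.7, 0.5),
    Sector.assistive_device: (5.3, 0.8),
}

#: Per-sector inclusive length-of-stay range in days (uniform integer).
DEFAULT_LOS_PARAMS = {
    Sector.inpatient_acute: (1, 14),
    Sector.same_day_surgery: (0, 0),
    Sector.emergency: (0, 1),
    Sector.inpatient_mental_health: (3, 30),
    Sector.inpatient_rehab: (7, 30),
    Sector.complex_continuing_care: (10, 60),
    Sector.long_term_care: (20, 90),
    Sector.inpatient_nonacute: (3, 30),
}

_AGE_GROUPS = [(0, 17, 0.048), (18, 44, 0.152), (45, 64, 0.279), (65, 84, 0.407), (85, 99, 0.114)]
_PRIMARY_CARE = [("family_health_team", 0.179), ("fee_for_service", 0.591), ("capitation", 0.214), ("other", 0.016)]
_MORBIDITY = [("missing", 0.024), ("zero", 0.005), ("few", 0.386), ("many", 0.585)]
_DRUG_COUNT_BINS = [((0, 0), 0.027), ((1, 5), 0.178), ((6, 9), 0.248), ((10, 19), 0.441), ((20, 30), 0.106)]


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic scenario; defaults are the study conditions."""

    n_persons: int = 500
    seed: int = 7
    grouping_mix: dict = field(default_factory=lambda: dict(DEFAULT_GROUPING_MIX))
    p_readmit: float = 0.35  # probability a stay chains a further institutional stay
    chain_cap: int = 4  # max institutional stays per chain, anchor included
    gap_min: int = 1  # inter-stay gap (days), uniform, straddles the window
    gap_max: int = 45
    p_no_episode: float = 0.17  # persons with no acute anchor at all
    extra_chain_rate: float = 0.45  # Poisson mean of additional episode chains
    community_rate_in: float = 0.25  # community contacts per in-episode day
    community_rate_out: float = 0.03  # and per out-of-episode day
    mortality_rate: float = 0.09
    drug_eligibility_rate: float = 0.521
    ltc_resident_rate: float = 0.03
    p_standalone_inst: float = 0.06  # institutional stay with no acute anchor
    p_nonacute_stay: float = 0.03  # inpatient_nonacute stay (never allocated)
    cost_params: dict = field(default_factory=lambda: dict(DEFAULT_COST_PARAMS))
    los_params: dict = field(default_factory=lambda: dict(DEFAULT_LOS_PARAMS))

    def __post_init__(self):
        total = sum(self.grouping_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"grouping_mix must sum to 1 (got {total!r})")
        for g in self.grouping_mix:
            if g not in GROUPINGS:
                raise ConfigError(f"unknown grouping {g!r} in grouping_mix")
        for name in (
            "p_readmit",
            "p_no_episode",
            "community_rate_in",
            "community_rate_out",
            "mortality_rate",
            "drug_eligibility_rate",
            "ltc_resident_rate",
            "p_standalone_inst",
            "p_nonacute_stay",
        ):
            v = getattr(self, name)
            if name.startswith("community"):
                if v < 0:
                    raise ConfigError(f"{name} must be >= 0")
            elif not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.gap_min < 0 or self.gap_max < self.gap_min:
            raise ConfigError("gap range must satisfy 0 <= gap_min <= gap_max")


@dataclass
class GroundTruth:
    """Planted labels: episode key or 'unallocated' per institutional
    encounter, and the intended clinical grouping per planted episode."""

    encounter_labels: dict = field(default_factory=dict)
    episode_groupings: dict = field(default_factory=dict)
    episode_anchor: dict = field(default_factory=dict)

    def partition(self) -> set:
        """Planted partition of in-episode institutional encounters."""
        groups: dict = {}
        for eid, label in self.encounter_labels.items():
            if label != "unallocated":
                groups.setdefault(label, set()).add(eid)
        return {frozenset(v) for v in groups.values()}

    def unallocated(self) -> set:
        return {e for e, lab in self.encounter_labels.items() if lab == "unallocated"}


def _choice(rng, items_with_probs):
    names = [n for n, _ in items_with_probs]
    probs = np.array([p for _, p in items_with_probs], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def generate_population(scenario: ScenarioConfig) -> list:
    """Sample ``n_persons`` demographic records (deterministic per seed)."""
    rng = np.random.default_rng([scenario.seed, 0])
    persons = []
    study = StudyConfig()
    for i in range(scenario.n_persons):
        pid = f"p{i:05d}"
        lo, hi, _ = _AGE_GROUPS[int(rng.choice(len(_AGE_GROUPS), p=[g[2] for g in _AGE_GROUPS]))]
        age = int(rng.integers(lo, hi + 1))
        sex = "female" if rng.random() < 0.535 else "male"
        u = rng.random()
        if u < 0.01:
            rurality = None
        elif u < 0.105:
            rurality = float(rng.integers(40, 101))
        else:
            rurality = float(rng.integers(0, 40))
        pcm = _choice(rng, _PRIMARY_CARE)
        eligible = bool(rng.random() < scenario.drug_eligibility_rate)
        morb = _choice(rng, _MORBIDITY)
        if morb == "missing":
            adg = None
        elif morb == "zero":
            adg = 0
        elif morb == "few":
            adg = int(rng.integers(1, 8))
        else:
            adg = int(rng.integers(8, 25))
        drug_count = None
        if eligible:
            weights = [w for _, w in _DRUG_COUNT_BINS]
            dlo, dhi = _DRUG_COUNT_BINS[int(rng.choice(len(_DRUG_COUNT_BINS), p=weights))][0]
            drug_count = int(rng.integers(dlo, dhi + 1))
        death = None
        if scenario.mortality_rate > 0 and rng.random() < scenario.mortality_rate:
            offset = int(rng.integers(150, (study.study_end - study.study_start).days + 1))
            death = study.study_start + timedelta(days=offset)
        persons.append(
            Person(
                person_id=pid,
                age_at_index=age,
                sex=sex,
                rurality_score=rurality,
                primary_care_model=pcm,
                drug_benefit_eligible=eligible,
                death_date=death,
                ltc_resident_at_index=bool(rng.random() < scenario.ltc_resident_rate),
                palliative_flag=bool(rng.random() < 0.117),
                morbidity_adg_count=adg,
                prior_year_drug_count=drug_count,
            )
        )
    return persons


def _toy_code(rng, codemap: CodeMap, category: str) -> str:
    prefixes = codemap.prefixes(category)
    if not prefixes:
        raise ConfigError(f"grouping {category!r} has no code prefixes in the code map")
    return str(rng.choice(prefixes)) + str(int(rng.integers(100, 1000)))


def _other_code(rng) -> str:
    return "OTH" + str(int(rng.integers(100, 1000)))


def _anchor_attrs(rng, grouping: str, codemap: CodeMap, starters) -> tuple:
    """(sector, mrd, dx_codes, admission_type, service_type) for an anchor
    that the hierarchy classifier will place in *grouping*."""
    med, sur = ServiceType.medical, ServiceType.surgical
    unp, pla, na = AdmissionType.unplanned, AdmissionType.planned, AdmissionType.not_applicable
    acute = Sector.inpatient_acute
    ed_ok = Sector.emergency in starters
    dx: list = []
    if rng.random() < 0.5:
        dx.append((_other_code(rng), DxType.pre_admission))
    if grouping == "pregnancy":
        return acute, _toy_code(rng, codemap, "pregnancy"), dx, unp, med
    if grouping == "perinatal_congenital_lbw":
        return acute, _toy_code(rng, codemap, "perinatal_congenital_lbw"), dx, unp, med
    if grouping == "post_admission_events":
        dx.append(("CMP" + str(int(rng.integers(100, 1000))), DxType.post_admission))
        return acute, _other_code(rng), dx, unp, sur if rng.random() < 0.5 else med
    if grouping == "trauma_injury_poisoning":
        sector = Sector.emergency if (ed_ok and rng.random() < 0.25) else acute
        return sector, _toy_code(rng, codemap, "trauma_injury_poisoning"), dx, unp, med
    if grouping == "mental_illness_addictions":
        if rng.random() < 0.6:
            return Sector.inpatient_mental_health, _other_code(rng), dx, unp, med
        return acute, _toy_code(rng, codemap, "mental_illness_addictions"), dx, unp, med
    if grouping == "acsc":
        sector = Sector.emergency if (ed_ok and rng.random() < 0.3) else acute
        return sector, _toy_code(rng, codemap, "acsc"), dx, unp, med
    if grouping == "cancer":
        return acute, _toy_code(rng, codemap, "cancer"), dx, pla if rng.random() < 0.4 else unp, med
    if grouping == "acute_planned_surgical":
        sector = Sector.same_day_surgery if rng.random() < 0.45 else acute
        return sector, _other_code(rng), dx, pla, sur
    if grouping == "acute_planned_medical":
        return acute, _other_code(rng), dx, pla, med
    if grouping == "acute_unplanned_surgical":
        return acute, _other_code(rng), dx, unp, sur
    if grouping == "acute_unplanned_medical":
        sector = Sector.emergency if (ed_ok and rng.random() < 0.3) else acute
        return sector, _other_code(rng), dx, unp, med
    return acute, _other_code(rng), dx, na, ServiceType.not_applicable  # other_causes


#: Sector mix of follow-up (non-anchor) institutional stays.
_FOLLOWUP_SECTORS = [
    (Sector.inpatient_acute, 0.45),
    (Sector.emergency, 0.15),
    (Sector.inpatient_rehab, 0.17),
    (Sector.complex_continuing_care, 0.10),
    (Sector.long_term_care, 0.07),
    (Sector.inpatient_mental_health, 0.06),
]

_COMMUNITY_SECTORS_MIX = [
    (Sector.physician, 0.52),
    (Sector.laboratory, 0.15),
    (Sector.drug, 0.12),
    (Sector.home_care, 0.10),
    (Sector.oncology_outpatient, 0.04),
    (Sector.dialysis_outpatient, 0.04),
    (Sector.assistive_device, 0.03),
]


def _sample_cost_cents(rng, scenario: ScenarioConfig, sector: Sector) -> int:
    meanlog, sdlog = scenario.cost_params[sector]
    return max(0, int(round(float(rng.lognormal(meanlog, sdlog)) * 100)))


def generate_encounters(
    persons: list,
    scenario: ScenarioConfig,
    codemap: CodeMap,
    config: StudyConfig,
) -> tuple:
    """Plant episode chains and serialize the encounter stream.

    Returns ``(encounters, ground_truth)``.  Every institutional
    encounter carries a planted label (episode key or ``unallocated``);
    labels are assigned while sampling, by the same closed 30-day gap
    convention the builder uses, so the partition is exact by
    construction.
    """
    if not persons:
        raise ConfigError("persons must be nonempty")
    for cat in CODE_DRIVEN_CATEGORIES:
        if scenario.grouping_mix.get(cat, 0) > 0 and not codemap.prefixes(cat):
            raise ConfigError(f"grouping {cat!r} has no code prefixes in the code map")
    rng = np.random.default_rng([scenario.seed, 1])
    starters = acute_start_sectors(config)
    window = config.window_days
    year_days = (config.study_end - config.study_start).days
    gt = GroundTruth()
    encounters: list = []

    mix_names = list(scenario.grouping_mix)
    mix_probs = np.array([scenario.grouping_mix[g] for g in mix_names], dtype=float)

    for person in persons:
        pid = person.person_id
        horizon = config.study_end
        if person.death_date is not None:
            horizon = min(horizon, person.death_date)
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{pid}-N{counter:04d}"

        def sample_grouping():
            return mix_names[int(rng.choice(len(mix_names), p=mix_probs))]

        def stay(sector, admit, mrd, dx, adm_type, svc_type, label):
            lo, hi = scenario.los_params[sector]
            los = int(rng.integers(lo, hi + 1))
            discharge = min(admit + timedelta(days=los), horizon)
            enc = Encounter(
                encounter_id=new_id(),
                person_id=pid,
                sector=sector,
                admit_date=admit,
                discharge_date=discharge,
                cost_cents=_sample_cost_cents(rng, scenario, sector),
                mrd_code=mrd,
                dx_codes=dx,
                admission_type=adm_type,
                service_type=svc_type,
            )
            encounters.append(enc)
            gt.encounter_labels[enc.encounter_id] = label
            return enc

        # --- planted episode chains -----------------------------------
        n_chains = 0
        if rng.random() >= scenario.p_no_episode:
            n_chains = 1 + int(rng.poisson(scenario.extra_chain_rate))
        episode_no = 0
        spans: list = []  # (start, end) planted episode spans
        cursor = config.study_start + timedelta(days=int(rng.integers(0, 331)))
        for _ in range(n_chains):
            if cursor > horizon:
                break
            grouping = sample_grouping()
            episode_no += 1
            key = f"{pid}-T{episode_no:03d}"
            sector, mrd, dx, adm, svc = _anchor_attrs(rng, grouping, codemap, starters)
            anchor = stay(sector, cursor, mrd, dx, adm, svc, key)
            gt.episode_groupings[key] = grouping
            gt.episode_anchor[key] = anchor.encounter_id
            open_key = key
            span_start = anchor.admit_date
            last_discharge = anchor.discharge_date
            final_discharge = last_discharge
            n_follow = 0
            while (
                1 + n_follow < scenario.chain_cap
                and rng.random() < scenario.p_readmit
                and last_discharge < horizon
            ):
                gap = int(rng.integers(scenario.gap_min, scenario.gap_max + 1))
                admit = last_discharge + timedelta(days=gap)
                if admit > horizon:
                    break
                n_follow += 1
                if open_key is not None and gap <= window:
                    label = open_key
                    sector = _choice(rng, _FOLLOWUP_SECTORS)
                    enc = stay(
                        sector, admit, _other_code(rng), [],
                        AdmissionType.unplanned, ServiceType.not_applicable, label,
                    )
                    final_discharge = max(final_discharge, enc.discharge_date)
                else:
                    # gap beyond the window: close the open span, then the
                    # stay either anchors a new episode or goes unallocated
                    if open_key is not None:
                        spans.append((span_start, min(final_discharge + timedelta(days=window), horizon)))
                        open_key = None
                    if rng.random() < 0.6:
                        grouping = sample_grouping()
                        episode_no += 1
                        key = f"{pid}-T{episode_no:03d}"
                        sector, mrd, dx, adm, svc = _anchor_attrs(rng, grouping, codemap, starters)
                        enc = stay(sector, admit, mrd, dx, adm, svc, key)
                        gt.episode_groupings[key] = grouping
                        gt.episode_anchor[key] = enc.encounter_id
                        open_key = key
                        span_start = enc.admit_date
                        final_discharge = enc.discharge_date
                    else:
                        sector = _choice(
                            rng,
                            [(Sector.inpatient_rehab, 0.4), (Sector.long_term_care, 0.35),
                             (Sector.complex_continuing_care, 0.25)],
                        )
                        enc = stay(
                            sector, admit, _other_code(rng), [],
                            AdmissionType.unplanned, ServiceType.not_applicable, "unallocated",
                        )
                last_discharge = enc.discharge_date
            if open_key is not None:
                spans.append((span_start, min(final_discharge + timedelta(days=window), horizon)))
            # next planted chain starts strictly beyond the window
            cursor = last_discharge + timedelta(days=window + 1 + int(rng.integers(5, 91)))

        # --- standalone institutional stays (never anchored) -----------
        if rng.random() < scenario.p_standalone_inst:
            blocked = [(s, e + timedelta(days=0)) for s, e in spans]
            for _try in range(20):
                admit = config.study_start + timedelta(days=int(rng.integers(0, year_days + 1)))
                if admit > horizon:
                    continue
                if all(not (s <= admit <= e) for s, e in blocked):
                    sector = _choice(
                        rng,
                        [(Sector.inpatient_rehab, 0.4), (Sector.long_term_care, 0.35),
                         (Sector.complex_continuing_care, 0.25)],
                    )
                    stay(
                        sector, admit, _other_code(rng), [],
                        AdmissionType.unplanned, ServiceType.not_applicable, "unallocated",
                    )
                    break
        if rng.random() < scenario.p_nonacute_stay:
            admit = config.study_start + timedelta(days=int(rng.integers(0, year_days + 1)))
            if admit <= horizon:
                stay(
                    Sector.inpatient_nonacute, admit, _other_code(rng), [],
                    AdmissionType.unplanned, ServiceType.not_applicable, "unallocated",
                )

        # --- community care inside and outside episode spans ------------
        main_provider = f"{pid}-GP0"
        other_providers = [f"{pid}-GP{k}" for k in (1, 2, 3)]
        loyalty = float(rng.beta(3.5, 1.5))

        def community_visit(day: date):
            sector = _choice(rng, _COMMUNITY_SECTORS_MIX)
            if sector is Sector.drug and not person.drug_benefit_eligible:
                sector = Sector.physician
            provider = None
            ambulatory = False
            if sector is Sector.physician:
                ambulatory = rng.random() < 0.9
                if rng.random() < 0.98:
                    provider = (
                        main_provider
                        if rng.random() < loyalty
                        else str(rng.choice(other_providers))
                    )
            enc = Encounter(
                encounter_id=new_id(),
                person_id=pid,
                sector=sector,
                admit_date=day,
                discharge_date=day,
                cost_cents=_sample_cost_cents(rng, scenario, sector),
                admission_type=AdmissionType.not_applicable,
                service_type=ServiceType.not_applicable,
                provider_id=provider,
                ambulatory_flag=ambulatory,
            )
            encounters.append(enc)

        in_days: set = set()
        for s, e in spans:
            d = s
            while d <= e:
                in_days.add(d)
                d += timedelta(days=1)
        if scenario.community_rate_in > 0 and in_days:
            in_list = sorted(in_days)
            n_visits = int(rng.poisson(scenario.community_rate_in * len(in_list)))
            for _ in range(n_visits):
                community_visit(in_list[int(rng.integers(0, len(in_list)))])
        all_days = [
            config.study_start + timedelta(days=k)
            for k in range((horizon - config.study_start).days + 1)
        ]
        out_list = [d for d in all_days if d not in in_days]
        if scenario.community_rate_out > 0 and out_list:
            n_visits = int(rng.poisson(scenario.community_rate_out * len(out_list)))
            for _ in range(n_visits):
                community_visit(out_list[int(rng.integers(0, len(out_list)))])

    encounters.sort(key=lambda e: (e.person_id, e.admit_date, e.encounter_id))
    return encounters, gt


def summarize_scenario(encounters: list) -> pd.DataFrame:
    """Per-sector counts and cost moments, for eyeballing scenario realism."""
    rows: dict = {}
    for enc in encounters:
        rows.setdefault(enc.sector.value, []).append(enc.cost)
    out = []
    for sector in sorted(rows):
        costs = np.array(rows[sector])
        out.append(
            {
                "sector": sector,
                "n": len(costs),
                "total_cost": float(costs.sum()),
                "mean_cost": float(costs.mean()),
                "sd_cost": float(costs.std(ddof=1)) if len(costs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(out, columns=["sector", "n", "total_cost", "mean_cost", "sd_cost"])


def _date_str(d: date | None) -> str:
    return "" if d is None else d.isoformat()


def encounters_frame(encounters: list) -> pd.DataFrame:
    """Serialize encounters to the standard CSV column layout."""
    rows = []
    for e in encounters:
        rows.append(
            {
                "encounter_id": e.encounter_id,
                "person_id": e.person_id,
                "sector": e.sector.value,
                "admit_date": _date_str(e.admit_date),
                "discharge_date": _date_str(e.discharge_date),
                "cost": f"{e.cost_cents / 100.0:.2f}",
                "mrd_code": e.mrd_code or "",
                "dx_codes": serialize_dx_codes(e.dx_codes),
                "admission_type": e.admission_type.value,
                "service_type": e.service_type.value,
                "provider_id": e.provider_id or "",
                "ambulatory_flag": str(e.ambulatory_flag).lower(),
            }
        )
    return pd.DataFrame(rows)


def persons_frame(persons: list) -> pd.DataFrame:
    rows = []
    for p in persons:
        rows.append(
            {
                "person_id": p.person_id,
                "age_at_index": p.age_at_index,
                "sex": p.sex,
                "rurality_score": "" if p.rurality_score is None else p.rurality_score,
                "primary_care_model": p.primary_care_model,
                "drug_benefit_eligible": str(p.drug_benefit_eligible).lower(),
                "death_date": _date_str(p.death_date),
                "ltc_resident_at_index": str(p.ltc_resident_at_index).lower(),
                "palliative_flag": str(p.palliative_flag).lower(),
                "morbidity_adg_count": "" if p.morbidity_adg_count is None else p.morbidity_adg_count,
                "prior_year_drug_count": "" if p.prior_year_drug_count is None else p.prior_year_drug_count,
            }
        )
    return pd.DataFrame(rows)


def write_synthetic_dataset(persons: list, encounters: list, gt: GroundTruth, out_dir) -> None:
    """Write encounters / persons / ground-truth CSVs (byte-stable per seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    encounters_frame(encounters).to_csv(out / "encounters.csv", index=False, lineterminator="\n")
    persons_frame(persons).to_csv(out / "persons.csv", index=False, lineterminator="\n")
    rows = [
        {
            "encounter_id": eid,
            "planted_episode_key": label,
            "planted_grouping": gt.episode_groupings.get(label, ""),
        }
        for eid, label in sorted(gt.encounter_labels.items())
    ]
    pd.DataFrame(rows).to_csv(out / "ground_truth.csv", index=False, lineterminator="\n")
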