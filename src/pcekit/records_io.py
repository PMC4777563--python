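"""Data model and file I/O for person-centred episode (PCE) analysis.

Defines the fixed sector vocabulary, the encounter / person / code-map /
study-configuration records, and readers that validate every input row.
All dates are calendar dates (day granularity); all intervals are closed
``[admit, discharge]``.  Money is carried internally as integer cents so
that downstream cost-conservation checks can be exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger("pcekit")

__all__ = [
    "Sector",
    "DxType",
    "AdmissionType",
    "ServiceType",
    "Encounter",
    "Person",
    "CodeMap",
    "StudyConfig",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "INSTITUTIONAL_SECTORS",
    "COMMUNITY_SECTORS",
    "PER_DIEM_SECTORS",
    "GROUPINGS",
    "GROUPING_LABELS",
    "CODE_DRIVEN_CATEGORIES",
    "DEFAULT_CODE_MAP",
    "acute_start_sectors",
    "round_half_up",
    "read_encounters",
    "read_persons",
    "read_code_map",
    "write_table",
    "read_table",
]


class SchemaError(ValueError):
    """An input file does not match the expected column schema."""


class ValidationError(ValueError):
    """One or more input rows violate a record invariant."""


class ConfigError(ValueError):
    """A configuration value is invalid."""


class Sector(str, Enum):
    inpatient_acute = "inpatient_acute"
    same_day_surgery = "same_day_surgery"
    emergency = "emergency"
    inpatient_mental_health = "inpatient_mental_health"
    inpatient_rehab = "inpatient_rehab"
    complex_continuing_care = "complex_continuing_care"
    long_term_care = "long_term_care"
    inpatient_nonacute = "inpatient_nonacute"
    home_care = "home_care"
    physician = "physician"
    laboratory = "laboratory"
    drug = "drug"
    dialysis_outpatient = "dialysis_outpatient"
    oncology_outpatient = "oncology_outpatient"
    assistive_device = "assistive_device"


#: Facility-based settings whose stays can belong to an episode chain.
INSTITUTIONAL_SECTORS = frozenset(
    {
        Sector.inpatient_acute,
        Sector.same_day_surgery,
        Sector.emergency,
        Sector.inpatient_mental_health,
        Sector.inpatient_rehab,
        Sector.complex_continuing_care,
        Sector.long_term_care,
        Sector.inpatient_nonacute,
    }
)

#: Point-in-time community services attached to episodes by date.
COMMUNITY_SECTORS = frozenset(set(Sector) - INSTITUTIONAL_SECTORS)

#: Sectors costed as a single stay-level amount that is prorated by day
#: when the stay extends past an episode end.
PER_DIEM_SECTORS = frozenset({Sector.long_term_care, Sector.complex_continuing_care})

#: Settings whose admission may open (anchor) an episode.  The emergency
#: department is included by default and is configurable.
_BASE_ACUTE_START = frozenset(
    {Sector.inpatient_acute, Sector.same_day_surgery, Sector.inpatient_mental_health}
)


def acute_start_sectors(config: "StudyConfig") -> frozenset:
    """Sectors allowed to anchor an episode under *config*."""
    if config.ed_starts_episode:
        return _BASE_ACUTE_START | {Sector.emergency}
    return _BASE_ACUTE_START


class DxType(str, Enum):
    pre_admission = "pre_admission"
    post_admission = "post_admission"
    other = "other"


class AdmissionType(str, Enum):
    planned = "planned"
    unplanned = "unplanned"
    not_applicable = "not_applicable"


class ServiceType(str, Enum):
    medical = "medical"
    surgical = "surgical"
    not_applicable = "not_applicable"


# ---------------------------------------------------------------------------
# Clinical grouping vocabulary (rank order = classification hierarchy)
# ---------------------------------------------------------------------------

#: The 12 mutually exclusive clinical groupings, in hierarchy rank order.
GROUPINGS = (
    "pregnancy",
    "perinatal_congenital_lbw",
    "post_admission_events",
    "trauma_injury_poisoning",
    "mental_illness_addictions",
    "acsc",
    "cancer",
    "acute_planned_surgical",
    "acute_planned_medical",
    "acute_unplanned_surgical",
    "acute_unplanned_medical",
    "other_causes",
)

GROUPING_LABELS = {
    "pregnancy": "Pregnancy",
    "perinatal_congenital_lbw": "Low Birth Weight, Perinatal and Congenital",
    "post_admission_events": "Post-Admission Events",
    "trauma_injury_poisoning": "Trauma, Accidents, Injuries, Poisonings",
    "mental_illness_addictions": "Mental Illness & Addictions",
    "acsc": "Ambulatory Care Sensitive Conditions",
    "cancer": "Cancer",
    "acute_planned_surgical": "Acute Planned Surgical",
    "acute_planned_medical": "Acute Planned Medical",
    "acute_unplanned_surgical": "Acute Unplanned Surgical",
    "acute_unplanned_medical": "Acute Unplanned Medical",
    "other_causes": "Other Causes",
}

#: Groupings driven by diagnosis-code prefix lists (the remainder are
#: driven by admission/service type or diagnosis-type flags).
CODE_DRIVEN_CATEGORIES = (
    "pregnancy",
    "perinatal_congenital_lbw",
    "trauma_injury_poisoning",
    "mental_illness_addictions",
    "acsc",
    "cancer",
)

#: Bundled toy code map: synthetic prefixes, not real ICD codes.
DEFAULT_CODE_MAP = {
    "pregnancy": ["PRG", "OBS", "DLV"],
    "perinatal_congenital_lbw": ["PER", "LBW", "CON"],
    "trauma_injury_poisoning": ["TRM", "INJ", "POI", "FRC"],
    "mental_illness_addictions": ["MNT", "PSY", "ADD"],
    "acsc": ["ACS", "CHF", "CPD", "DIA"],
    "cancer": ["CAN", "NEO", "ONC"],
}


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class Encounter:
    """One dated, costed contact with the health system.

    Institutional stays have ``admit_date <= discharge_date`` (a missing
    discharge means the stay was ongoing at study end); community services
    are point-in-time with ``admit_date == discharge_date``.
    """

    encounter_id: str
    person_id: str
    sector: Sector
    admit_date: date
    discharge_date: date | None
    cost_cents: int
    mrd_code: str | None = None
    dx_codes: list = field(default_factory=list)  # list of (code, DxType)
    admission_type: AdmissionType = AdmissionType.not_applicable
    service_type: ServiceType = ServiceType.not_applicable
    provider_id: str | None = None
    ambulatory_flag: bool = False

    @property
    def cost(self) -> float:
        return self.cost_cents / 100.0

    def problems(self) -> list:
        """Invariant violations for this record (empty list if valid)."""
        out = []
        if self.cost_cents < 0:
            out.append(f"encounter {self.encounter_id}: negative cost")
        if self.discharge_date is not None and self.admit_date > self.discharge_date:
            out.append(
                f"encounter {self.encounter_id}: discharge_date "
                f"{self.discharge_date} before admit_date {self.admit_date}"
            )
        if self.sector in COMMUNITY_SECTORS:
            if self.discharge_date is None or self.discharge_date != self.admit_date:
                out.append(
                    f"encounter {self.encounter_id}: community sector "
                    f"{self.sector.value} must be point-in-time "
                    "(admit_date == discharge_date)"
                )
        return out


@dataclass
class Person:
    """Demographic and eligibility record at the study index date."""

    person_id: str
    age_at_index: float
    sex: str  # "female" | "male"
    rurality_score: float | None = None
    primary_care_model: str = "fee_for_service"
    drug_benefit_eligible: bool = False
    death_date: date | None = None
    ltc_resident_at_index: bool = False
    palliative_flag: bool = False
    morbidity_adg_count: int | None = None
    prior_year_drug_count: int | None = None

    def problems(self) -> list:
        out = []
        if self.age_at_index < 0:
            out.append(f"person {self.person_id}: negative age_at_index")
        if self.sex not in ("female", "male"):
            out.append(f"person {self.person_id}: unknown sex {self.sex!r}")
        if self.primary_care_model not in (
            "family_health_team",
            "fee_for_service",
            "capitation",
            "other",
        ):
            out.append(
                f"person {self.person_id}: unknown primary_care_model "
                f"{self.primary_care_model!r}"
            )
        return out


@dataclass
class CodeMap:
    """Ordered mapping from clinical category to diagnosis-code prefixes.

    A code may appear under several categories; the classification
    hierarchy resolves the overlap.
    """

    categories: dict  # category -> list of prefixes

    def __post_init__(self):
        for cat, prefixes in self.categories.items():
            if cat not in GROUPINGS:
                raise ConfigError(
                    f"unknown clinical category {cat!r}; valid names: "
                    + ", ".join(GROUPINGS)
                )
            for p in prefixes:
                if not isinstance(p, str) or not p:
                    raise ConfigError(f"category {cat!r}: prefixes must be non-empty strings")

    def prefixes(self, category: str) -> list:
        return self.categories.get(category, [])


@dataclass
class StudyConfig:
    """Study window and episode-construction parameters.

    ``window_days`` is the stabilisation window: an episode stays open
    while the next institutional admission falls within this many days of
    the running discharge date, and community care within the same number
    of days after the final discharge belongs to the episode.
    """

    study_start: date = date(2010, 4, 1)
    study_end: date = date(2011, 3, 31)
    window_days: int = 30
    percentile: float = 95.0
    ed_starts_episode: bool = True
    quantile_method: str = "linear_interpolation"  # or "lower_value"
    currency_label: str = "2010 CAD"

    def __post_init__(self):
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if not (0 < self.percentile < 100):
            raise ConfigError("percentile must lie strictly between 0 and 100")
        if self.window_days < 1:
            raise ConfigError("window_days must be >= 1")
        if self.quantile_method not in ("linear_interpolation", "lower_value"):
            raise ConfigError(
                "quantile_method must be 'linear_interpolation' or 'lower_value'"
            )


# ---------------------------------------------------------------------------
# Small shared numerics
# ---------------------------------------------------------------------------


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (report-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def cents_from_dollars(text) -> int:
    """Parse a dollar amount to integer cents exactly."""
    d = Decimal(str(text))
    return int((d * 100).quantize(Decimal(1), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

ENCOUNTER_COLUMNS = [
    "encounter_id",
    "person_id",
    "sector",
    "admit_date",
    "discharge_date",
    "cost",
    "mrd_code",
    "dx_codes",
    "admission_type",
    "service_type",
    "provider_id",
    "ambulatory_flag",
]

PERSON_COLUMNS = [
    "person_id",
    "age_at_index",
    "sex",
    "rurality_score",
    "primary_care_model",
    "drug_benefit_eligible",
    "death_date",
    "ltc_resident_at_index",
    "palliative_flag",
    "morbidity_adg_count",
    "prior_year_drug_count",
]


def _parse_date(text) -> date | None:
    if text is None or text == "" or (isinstance(text, float) and pd.isna(text)):
        return None
    return date.fromisoformat(str(text))


def _parse_dx_codes(text) -> list:
    """Parse ``CODE:dxtype;CODE:dxtype`` pairs."""
    if text is None or text == "" or (isinstance(text, float) and pd.isna(text)):
        return []
    pairs = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        code, _, dxt = item.partition(":")
        pairs.append((code, DxType(dxt or "other")))
    return pairs


def serialize_dx_codes(pairs) -> str:
    return ";".join(f"{code}:{dxt.value}" for code, dxt in pairs)


def _parse_bool(text) -> bool:
    return str(text).strip().lower() in ("1", "true", "t", "yes", "y")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])


def read_encounters(path, config: StudyConfig | None = None) -> list:
    """Read and validate an encounter CSV.

    Every row either yields an :class:`Encounter` or contributes a
    diagnostic naming its ``encounter_id``; any diagnostic aborts the read
    with a :class:`ValidationError` listing all offending rows.
    """
    df = _read_csv(path)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"encounter file {path}: missing columns {missing}")
    encounters, problems, seen = [], [], set()
    for row in df.itertuples(index=False):
        rid = str(row.encounter_id)
        try:
            enc = Encounter(
                encounter_id=rid,
                person_id=str(row.person_id),
                sector=Sector(row.sector),
                admit_date=_parse_date(row.admit_date),
                discharge_date=_parse_date(row.discharge_date),
                cost_cents=cents_from_dollars(row.cost),
                mrd_code=None if pd.isna(row.mrd_code) else str(row.mrd_code),
                dx_codes=_parse_dx_codes(row.dx_codes),
                admission_type=AdmissionType(row.admission_type),
                service_type=ServiceType(row.service_type),
                provider_id=None if pd.isna(row.provider_id) else str(row.provider_id),
                ambulatory_flag=_parse_bool(row.ambulatory_flag),
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"encounter {rid}: {exc}")
            continue
        if enc.admit_date is None:
            problems.append(f"encounter {rid}: missing admit_date")
            continue
        if rid in seen:
            problems.append(f"encounter {rid}: duplicate encounter_id")
            continue
        seen.add(rid)
        row_problems = enc.problems()
        problems.extend(row_problems)
        if not row_problems:
            encounters.append(enc)
    if problems:
        raise ValidationError(
            f"encounter file {path}: {len(problems)} invalid row(s):\n"
            + "\n".join(problems)
        )
    if not encounters:
        logger.warning("encounter file %s is empty", path)
    return encounters


def read_persons(path) -> list:
    """Read and validate a person CSV; duplicate ``person_id`` is an error."""
    df = _read_csv(path)
    missing = [c for c in PERSON_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"person file {path}: missing columns {missing}")
    persons, problems, seen = [], [], set()
    for row in df.itertuples(index=False):
        pid = str(row.person_id)
        if pid in seen:
            problems.append(f"person {pid}: duplicate person_id")
            continue
        seen.add(pid)
        try:
            person = Person(
                person_id=pid,
                age_at_index=float(row.age_at_index),
                sex=str(row.sex),
                rurality_score=(
                    None if pd.isna(row.rurality_score) else float(row.rurality_score)
                ),
                primary_care_model=str(row.primary_care_model),
                drug_benefit_eligible=_parse_bool(row.drug_benefit_eligible),
                death_date=_parse_date(row.death_date),
                ltc_resident_at_index=_parse_bool(row.ltc_resident_at_index),
                palliative_flag=_parse_bool(row.palliative_flag),
                morbidity_adg_count=(
                    None
                    if pd.isna(row.morbidity_adg_count)
                    else int(float(row.morbidity_adg_count))
                ),
                prior_year_drug_count=(
                    None
                    if pd.isna(row.prior_year_drug_count)
                    else int(float(row.prior_year_drug_count))
                ),
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"person {pid}: {exc}")
            continue
        row_problems = person.problems()
        problems.extend(row_problems)
        if not row_problems:
            persons.append(person)
    if problems:
        raise ValidationError(
            f"person file {path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    if not persons:
        logger.warning("person file %s is empty", path)
    return persons


def read_code_map(path=None) -> CodeMap:
    """Load a category -> prefix-list code map (JSON or YAML).

    With ``path=None`` the bundled toy map (synthetic prefixes) is used.
    """
    if path is None:
        return CodeMap({k: list(v) for k, v in DEFAULT_CODE_MAP.items()})
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"code map {path}: expected a mapping of category -> prefixes")
    return CodeMap({str(k): [str(p) for p in v] for k, v in raw.items()})


def write_table(table: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write a report table deterministically (bit-stable for fixed input)."""
    if fmt != "csv":
        raise ConfigError(f"unsupported table format {fmt!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
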