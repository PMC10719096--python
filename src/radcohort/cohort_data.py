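"""Cohort data model: tables, outcome classification, follow-up derivation.

The cohort is held as four plain tables (persons, examinations, outcomes and
a morphology->endpoint mapping) with all dates expressed as decimal calendar
years, so that ages are exact differences of floats rather than calendar
arithmetic.  Follow-up is derived per person as a half-open at-risk window
``[entry_age, exit_age)``: entry is the later of (first CT + 2 years) and the
age at which complete cancer registration began in the person's country,
exit is the earliest of diagnosis, death, emigration and administrative end
of follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ENDPOINT_GROUPS",
    "GROUP_PARENT",
    "Cohort",
    "FollowUpInterval",
    "SchemaError",
    "apply_inclusion_exclusion",
    "classify_outcome",
    "default_morphology_mapping",
    "derive_followup",
    "derive_followup_interval",
    "read_cohort_tables",
    "write_cohort_tables",
]

# ---------------------------------------------------------------------------
# Schemas

PERSON_COLUMNS = [
    "person_id", "sex", "country", "birth_date", "registry_start",
    "death_date", "emigration_date", "admin_end_date", "ses",
    "transplant", "low_reporting_hospital", "vital_status_known",
]
PERSON_REQUIRED = ["person_id", "sex", "country", "birth_date",
                   "registry_start", "admin_end_date"]
EXAM_COLUMNS = ["exam_id", "person_id", "age_at_exam", "calendar_year",
                "body_region", "hospital_id"]
OUTCOME_COLUMNS = ["person_id", "age_at_diagnosis", "morphology_code",
                   "behavior_code"]
MAPPING_COLUMNS = ["morphology_code", "groups", "therapy_related"]

BODY_REGIONS = ("head_neck", "chest", "abdomen_pelvis", "spine", "other")

#: endpoint labels usable in analyses
ENDPOINT_GROUPS = (
    "all_heme", "lymphoid", "HL", "NHL", "matureB", "matureTNK", "precursor",
    "myeloid_AL", "AML_ALMP_ALAL", "MPN_MDS", "leukemia_excl_CLL",
    "histiocytic", "unspecified",
)

#: containment hierarchy; classify_outcome closes over ancestors.
GROUP_PARENT = {
    "HL": "lymphoid",
    "NHL": "lymphoid",
    "matureB": "NHL",
    "matureTNK": "NHL",
    "precursor": "NHL",
    "AML_ALMP_ALAL": "myeloid_AL",
    "MPN_MDS": "myeloid_AL",
    "lymphoid": "all_heme",
    "myeloid_AL": "all_heme",
    "histiocytic": "all_heme",
    "unspecified": "all_heme",
    # leukemia_excl_CLL is a cross-cutting comparison group with no parent
    # other than all_heme
    "leukemia_excl_CLL": "all_heme",
}


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


# ---------------------------------------------------------------------------
# Morphology mapping

# Representative ICD-O-3 morphology code blocks for the WHO lymphoid/myeloid
# groupings.  This default ships as an editable table: real analyses replace
# it with the registry's full code list.  Codes are 4-digit strings.
_DEFAULT_MAPPING_ROWS = [
    # Hodgkin lymphoma
    ("9650", "HL", 0), ("9651", "HL", 0), ("9652", "HL", 0),
    ("9653", "HL", 0), ("9659", "HL", 0), ("9663", "HL", 0),
    # mature B cell neoplasms
    ("9673", "matureB", 0), ("9680", "matureB", 0), ("9690", "matureB", 0),
    ("9699", "matureB", 0), ("9687", "matureB;leukemia_excl_CLL", 0),
    ("9823", "matureB", 0),           # CLL: lymphoid but NOT leukemia_excl_CLL
    # mature T / NK cell neoplasms
    ("9702", "matureTNK", 0), ("9714", "matureTNK", 0), ("9717", "matureTNK", 0),
    # precursor cell neoplasms (lymphoblastic leukemia/lymphoma)
    ("9811", "precursor;leukemia_excl_CLL", 0),
    ("9835", "precursor;leukemia_excl_CLL", 0),
    ("9836", "precursor;leukemia_excl_CLL", 0),
    ("9837", "precursor;leukemia_excl_CLL", 0),
    # NHL not otherwise specified
    ("9590", "NHL", 0), ("9591", "NHL", 0),
    # AML and related + ambiguous-lineage acute leukemia
    ("9840", "AML_ALMP_ALAL;leukemia_excl_CLL", 0),
    ("9861", "AML_ALMP_ALAL;leukemia_excl_CLL", 0),
    ("9867", "AML_ALMP_ALAL;leukemia_excl_CLL", 0),
    ("9873", "AML_ALMP_ALAL;leukemia_excl_CLL", 0),
    ("9801", "AML_ALMP_ALAL;leukemia_excl_CLL", 0),
    ("9805", "AML_ALMP_ALAL;leukemia_excl_CLL", 0),
    # MPN / MDS / MDS-MPN
    ("9875", "MPN_MDS;leukemia_excl_CLL", 0),   # CML
    ("9950", "MPN_MDS", 0), ("9960", "MPN_MDS", 0), ("9961", "MPN_MDS", 0),
    ("9963", "MPN_MDS", 0), ("9980", "MPN_MDS", 0), ("9982", "MPN_MDS", 0),
    ("9989", "MPN_MDS", 0),
    # myeloid NOS
    ("9860", "myeloid_AL;leukemia_excl_CLL", 0),
    # lymphoid NOS
    ("9820", "lymphoid", 0),
    # histiocytic and dendritic cell
    ("9750", "histiocytic", 0), ("9751", "histiocytic", 0),
    # therapy-related / syndrome-associated codes: dropped from all endpoints
    ("9920", "AML_ALMP_ALAL", 1),     # therapy-related AML
    ("9987", "MPN_MDS", 1),           # therapy-related MDS
    ("9898", "AML_ALMP_ALAL", 1),     # Down-syndrome-associated myeloid leukemia
]


def default_morphology_mapping() -> pd.DataFrame:
    """Editable default morphology->endpoint mapping table."""
    df = pd.DataFrame(_DEFAULT_MAPPING_ROWS, columns=MAPPING_COLUMNS)
    df["morphology_code"] = df["morphology_code"].astype(str)
    return df


def _close_hierarchy(groups: Iterable[str]) -> frozenset[str]:
    out: set[str] = set()
    stack = list(groups)
    while stack:
        g = stack.pop()
        if g in out:
            continue
        out.add(g)
        parent = GROUP_PARENT.get(g)
        if parent is not None:
            stack.append(parent)
    return frozenset(out)


def classify_outcome(morphology_code: str, behavior_code: int,
                     mapping: pd.DataFrame | None = None) -> frozenset[str]:
    """Map one diagnosis to the set of endpoint groups it contributes to.

    Only malignant diagnoses (behavior code 3) are analysable; anything else
    returns the empty set.  Codes flagged as therapy-related (or associated
    with predisposing syndromes) are dropped from every endpoint.  A
    malignant code absent from the mapping table is routed to
    ``unspecified`` with a warning rather than silently discarded.
    """
    if mapping is None:
        mapping = default_morphology_mapping()
    if int(behavior_code) != 3:
        return frozenset()
    code = str(morphology_code).split("/")[0].strip()
    row = mapping.loc[mapping["morphology_code"].astype(str) == code]
    if row.empty:
        warnings.warn(
            f"morphology code {code!r} not in mapping table; "
            "classified as 'unspecified'", stacklevel=2)
        return _close_hierarchy(["unspecified"])
    row = row.iloc[0]
    if int(row["therapy_related"]):
        return frozenset()
    groups = [g for g in str(row["groups"]).split(";") if g]
    return _close_hierarchy(groups)


# ---------------------------------------------------------------------------
# Follow-up

@dataclass(frozen=True)
class FollowUpInterval:
    """Half-open at-risk window [entry_age, exit_age) for one person."""

    person_id: str
    entry_age: float
    exit_age: float
    exit_reason: str            # diagnosis | death | emigration | admin_end
    included: bool
    exclusion_reason: str | None = None


def derive_followup_interval(person: Mapping, exams: pd.DataFrame,
                             outcome: Mapping | None) -> FollowUpInterval:
    """Derive the at-risk window for a single person.

    Entry is ``max(first CT age + 2, age at registry start)``; exit is the
    earliest of diagnosis, death, emigration and administrative end of
    follow-up.  Persons whose exit does not exceed entry are flagged not
    included.
    """
    birth = float(person["birth_date"])
    ages = exams.loc[exams["person_id"] == person["person_id"], "age_at_exam"]
    if ages.empty:
        raise ValueError(f"person {person['person_id']} has no examinations")
    first_ct = float(ages.min())
    entry = max(first_ct + 2.0, float(person["registry_start"]) - birth)

    candidates: list[tuple[float, str]] = []
    if outcome is not None:
        candidates.append((float(outcome["age_at_diagnosis"]), "diagnosis"))
    for col, reason in (("death_date", "death"),
                        ("emigration_date", "emigration"),
                        ("admin_end_date", "admin_end")):
        v = person.get(col)
        if v is not None and not pd.isna(v):
            candidates.append((float(v) - birth, reason))
    # ties resolved in the order diagnosis < death < emigration < admin_end
    exit_age, exit_reason = min(candidates, key=lambda c: (c[0],
                                ["diagnosis", "death", "emigration",
                                 "admin_end"].index(c[1])))
    if exit_age <= entry:
        return FollowUpInterval(person["person_id"], entry, exit_age,
                                exit_reason, included=False,
                                exclusion_reason="followup_lt_2y_or_late_entry")
    return FollowUpInterval(person["person_id"], entry, exit_age,
                            exit_reason, included=True)


def derive_followup(persons: pd.DataFrame, exams: pd.DataFrame,
                    outcomes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized follow-up derivation for the whole cohort.

    Returns one row per person: entry_age, exit_age, exit_reason, included,
    exclusion_reason, first_ct_age, age_at_diagnosis (NaN when no outcome).
    """
    first_ct = exams.groupby("person_id")["age_at_exam"].min()
    df = persons.set_index("person_id", drop=False).copy()
    missing = df.index.difference(first_ct.index)
    if len(missing):
        raise ValueError(f"{len(missing)} persons have no examinations")
    df["first_ct_age"] = first_ct.reindex(df.index)

    dx = outcomes.drop_duplicates("person_id").set_index("person_id")
    df["age_at_diagnosis"] = dx["age_at_diagnosis"].reindex(df.index)

    birth = df["birth_date"].to_numpy(float)
    entry = np.maximum(df["first_ct_age"].to_numpy(float) + 2.0,
                       df["registry_start"].to_numpy(float) - birth)

    # candidate exit ages, NaN when the event does not apply
    cand = np.column_stack([
        df["age_at_diagnosis"].to_numpy(float),
        df["death_date"].to_numpy(float) - birth
        if "death_date" in df else np.full(len(df), np.nan),
        df["emigration_date"].to_numpy(float) - birth
        if "emigration_date" in df else np.full(len(df), np.nan),
        df["admin_end_date"].to_numpy(float) - birth,
    ])
    reasons = np.array(["diagnosis", "death", "emigration", "admin_end"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN rows barred by schema
        which = np.nanargmin(cand, axis=1)
        exit_age = np.nanmin(cand, axis=1)

    out = pd.DataFrame({
        "person_id": df["person_id"].to_numpy(),
        "entry_age": entry,
        "exit_age": exit_age,
        "exit_reason": reasons[which],
        "first_ct_age": df["first_ct_age"].to_numpy(float),
        "age_at_diagnosis": df["age_at_diagnosis"].to_numpy(float),
    })
    out["included"] = out["exit_age"] > out["entry_age"]
    out["exclusion_reason"] = np.where(
        out["included"], None, "followup_lt_2y_or_late_entry")
    return out


# ---------------------------------------------------------------------------
# Cohort container and I/O

@dataclass
class Cohort:
    """In-memory bundle of the cohort tables plus derived artifacts."""

    persons: pd.DataFrame
    exams: pd.DataFrame
    outcomes: pd.DataFrame
    mapping: pd.DataFrame = field(default_factory=default_morphology_mapping)
    #: per-exam summarized doses: exam_id, abm_dose_mean, abm_dose_median
    dose_summary: pd.DataFrame | None = None
    followup: pd.DataFrame | None = None

    def with_followup(self) -> "Cohort":
        if self.followup is None:
            self.followup = derive_followup(self.persons, self.exams,
                                            self.outcomes)
        return self

    @property
    def n_persons(self) -> int:
        return len(self.persons)


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table lacks required column(s): "
                          + ", ".join(missing))


def read_cohort_tables(paths: Mapping[str, str | Path] | str | Path,
                       schema_version: str = "1") -> Cohort:
    """Read persons/exams/outcomes (and optional mapping, dose summary) CSVs.

    ``paths`` is either a directory containing ``persons.csv``, ``exams.csv``,
    ``outcomes.csv`` (plus optional ``mapping.csv`` and ``doses_summary.csv``)
    or a mapping from those names to file paths.
    """
    if schema_version != "1":
        raise SchemaError(f"unknown schema_version {schema_version!r}")
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        paths = {n: d / f"{n}.csv"
                 for n in ("persons", "exams", "outcomes", "mapping",
                           "doses_summary")
                 if (d / f"{n}.csv").exists()}
    persons = pd.read_csv(paths["persons"], dtype={"person_id": str})
    exams = pd.read_csv(paths["exams"],
                        dtype={"person_id": str, "exam_id": str,
                               "hospital_id": str})
    outcomes = pd.read_csv(paths["outcomes"], dtype={"person_id": str,
                                                     "morphology_code": str})
    _check_columns(persons, PERSON_REQUIRED, "persons")
    _check_columns(exams, EXAM_COLUMNS[:5], "exams")
    _check_columns(outcomes, OUTCOME_COLUMNS, "outcomes")

    if persons["person_id"].duplicated().any():
        dup = persons.loc[persons["person_id"].duplicated(), "person_id"].iloc[0]
        raise SchemaError(f"duplicate person_id {dup!r} in persons table")
    bad = ~persons["sex"].isin(["male", "female"])
    if bad.any():
        raise SchemaError(f"unparseable sex at persons row {int(np.argmax(bad.to_numpy()))}")
    bad = ~exams["body_region"].isin(BODY_REGIONS)
    if bad.any():
        raise SchemaError(f"unknown body_region at exams row {int(np.argmax(bad.to_numpy()))}")
    if (exams["age_at_exam"] < 0).any():
        raise SchemaError("negative age_at_exam in exams table")

    mapping = (pd.read_csv(paths["mapping"], dtype={"morphology_code": str})
               if "mapping" in paths else default_morphology_mapping())
    dose_summary = (pd.read_csv(paths["doses_summary"], dtype={"exam_id": str})
                    if "doses_summary" in paths else None)
    return Cohort(persons, exams, outcomes, mapping, dose_summary)


def write_cohort_tables(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort tables as CSV; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in (("persons", cohort.persons), ("exams", cohort.exams),
                     ("outcomes", cohort.outcomes), ("mapping", cohort.mapping)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    if cohort.dose_summary is not None:
        p = out / "doses_summary.csv"
        cohort.dose_summary.to_csv(p, index=False)
        written["doses_summary"] = p
    return written


# ---------------------------------------------------------------------------
# Inclusion / exclusion

def apply_inclusion_exclusion(cohort: Cohort,
                              rules: Mapping[str, bool] | None = None
                              ) -> tuple[Cohort, dict[str, int]]:
    """Apply the cohort inclusion rules; return filtered cohort + counts.

    Baseline rules (always applied): drop persons with a cancer diagnosis
    before, or within 1 year of, the first CT; drop persons whose at-risk
    window is empty (follow-up shorter than 2 years, or registration started
    after their exit).  Diagnoses between 1 and 2 years after the first CT
    leave the window empty and are logged under ``cancer_1_to_2y``.

    Optional ``rules`` toggles (all default False): ``drop_transplant``,
    ``drop_low_reporting_hospital``, ``drop_no_vital_status``,
    ``drop_born_before_registry``.
    """
    rules = dict(rules or {})
    cohort = cohort.with_followup()
    fu = cohort.followup.set_index("person_id")
    persons = cohort.persons.set_index("person_id", drop=False)

    log: dict[str, int] = {}
    excluded = pd.Series(False, index=persons.index)
    reason = pd.Series(None, index=persons.index, dtype=object)

    def mark(mask: pd.Series, why: str) -> None:
        fresh = mask & ~excluded
        log[why] = int(fresh.sum())
        excluded.loc[fresh] = True
        reason.loc[fresh] = why

    dx_rel = fu["age_at_diagnosis"] - fu["first_ct_age"]
    mark(dx_rel < 0, "prior_cancer")
    mark((dx_rel >= 0) & (dx_rel < 1), "cancer_within_1y")
    mark((dx_rel >= 1) & (dx_rel < 2), "cancer_1_to_2y")
    mark(~fu["included"], "followup_lt_2y_or_late_entry")

    if rules.get("drop_transplant") and "transplant" in persons:
        mark(persons["transplant"].fillna(0).astype(bool), "transplant")
    if rules.get("drop_low_reporting_hospital") and \
            "low_reporting_hospital" in persons:
        mark(persons["low_reporting_hospital"].fillna(0).astype(bool),
             "low_reporting_hospital")
    if rules.get("drop_no_vital_status") and "vital_status_known" in persons:
        mark(~persons["vital_status_known"].fillna(1).astype(bool),
             "no_vital_status")
    if rules.get("drop_born_before_registry"):
        mark(persons["birth_date"] < persons["registry_start"],
             "born_before_registry")

    keep = persons.index[~excluded]
    if len(keep) == 0:
        raise ValueError("no persons remain after exclusions")

    out = Cohort(
        persons=cohort.persons[cohort.persons["person_id"].isin(keep)].copy(),
        exams=cohort.exams[cohort.exams["person_id"].isin(keep)].copy(),
        outcomes=cohort.outcomes[cohort.outcomes["person_id"].isin(keep)].copy(),
        mapping=cohort.mapping,
        dose_summary=cohort.dose_summary,
        followup=cohort.followup[cohort.followup["person_id"].isin(keep)].copy(),
    )
    log["included"] = len(keep)
    return out, log
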