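"""Variable schema for ICU episode cohorts.

An *episode* is one ICU admission; each episode carries 12 input variables
(demographic, clinical, antibiotic exposure, mechanical ventilation) and a
binary multi-drug-resistance (MDR) label for the first 48 h of the stay.
Variables are typed so downstream code can dispatch: proportion tests and
2x2 mutual-information tables for binary indicators, median tests and
discretized mutual information for numeric scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

NUMERIC = "numeric"
BINARY = "binary"
CATEGORICAL = "categorical"
#: a group of co-occurring binary exposure flags presented as one logical
#: variable (an episode may receive several antibiotic families at once)
BINARY_GROUP = "binary_group"

KINDS = (NUMERIC, BINARY, CATEGORICAL, BINARY_GROUP)


@dataclass(frozen=True)
class Variable:
    """One raw cohort variable.

    ``categories`` lists the legal category labels for categorical
    variables, or the flag names for a binary group; it is empty for
    numeric and plain binary variables.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind in (CATEGORICAL, BINARY_GROUP):
            if not self.categories:
                raise ValueError(f"{self.name}: {self.kind} needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"{self.name}: duplicate category labels")
        elif self.categories:
            raise ValueError(f"{self.name}: {self.kind} takes no categories")

    @property
    def width(self) -> int:
        """Number of encoded design-matrix columns this variable yields."""
        if self.kind in (CATEGORICAL, BINARY_GROUP):
            return len(self.categories)
        return 1

    def columns(self) -> list[str]:
        """Raw-table column names (a binary group spans several columns)."""
        if self.kind == BINARY_GROUP:
            return [f"{self.name}_{c}" for c in self.categories]
        return [self.name]


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of :class:`Variable` describing a cohort table."""

    variables: tuple[Variable, ...]
    label: str = "mdr"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def columns(self) -> list[str]:
        """All raw-table columns in schema order (label excluded)."""
        cols: list[str] = []
        for v in self.variables:
            cols.extend(v.columns())
        return cols

    @property
    def encoded_width(self) -> int:
        """Design-matrix width after one-hot encoding."""
        return sum(v.width for v in self.variables)


# -- default 12-variable ICU schema -----------------------------------------

DEPARTMENTS: tuple[str, ...] = (
    "general_surgery", "emergency", "internal_medicine", "otorhinolaryngology",
    "gynecology", "cardiology", "neurology", "urology", "traumatology",
    "digestive", "pneumology", "nephrology", "oncology", "hematology",
    "other_hospital", "operating_room", "hospitalization_ward", "psychiatry",
    "dermatology", "ophthalmology", "maxillofacial_surgery",
    "vascular_surgery", "thoracic_surgery", "plastic_surgery",
    "rehabilitation", "pediatrics", "home",
)

ADMISSION_REASONS: tuple[str, ...] = (
    "serious_infection", "acute_respiratory_failure",
    "acute_chronic_respiratory_failure", "postoperative_care", "polytrauma",
    "septic_shock", "cardiac_arrest", "acute_coronary_syndrome",
    "heart_failure", "arrhythmia", "stroke", "seizures", "coma",
    "intoxication", "gastrointestinal_bleeding", "pancreatitis",
    "hepatic_failure", "renal_failure", "metabolic_disorder",
    "diabetic_ketoacidosis", "respiratory_infection", "urinary_sepsis",
    "abdominal_sepsis", "neurosurgery", "scheduled_surgery",
    "urgent_surgery", "obstetric_complication", "burns",
    "hemorrhagic_shock", "hypovolemic_shock", "monitoring", "other",
)

#: comorbidity groups: A cardiovascular, B renal/arthritis, C respiratory,
#: D pancreatic/endocrine, E neuro-degenerative, F metabolic/vascular,
#: G neoplasms
DISEASE_GROUPS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")

ANTIBIOTIC_FAMILIES: tuple[str, ...] = (
    "AMG", "ANF", "ATF", "CAR", "CF1", "CF2", "CF3", "CF4", "GLI", "LIN",
    "MAC", "MON", "NTI", "OXA", "PAP", "PEN", "POL", "QUI", "SUL", "TTC",
    "Others",
)


def default_schema() -> CohortSchema:
    """The 12-variable ICU episode schema.

    Five numeric variables (age, Apache II, Charlson, SAPS III, MV ratio),
    three standalone binaries (gender, patient category, illness), three
    categoricals (27 departments of origin, 32 admission reasons, 7 disease
    groups) and one group of 21 antibiotic-family exposure flags.  One-hot
    encoding of this schema yields 27+32+7+21+3+5 = 95 features.
    """
    return CohortSchema(variables=(
        Variable("age", NUMERIC),
        Variable("gender", BINARY),
        Variable("origin", CATEGORICAL, DEPARTMENTS),
        Variable("admission_reason", CATEGORICAL, ADMISSION_REASONS),
        Variable("patient_category", BINARY),
        Variable("apache_ii", NUMERIC),
        Variable("charlson", NUMERIC),
        Variable("saps_iii", NUMERIC),
        Variable("disease_group", CATEGORICAL, DISEASE_GROUPS),
        Variable("illness", BINARY),
        Variable("antibiotics", BINARY_GROUP, ANTIBIOTIC_FAMILIES),
        Variable("mv_ratio", NUMERIC),
    ))
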