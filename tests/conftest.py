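"""Shared fixtures and synthetic study designs used across the suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from mdrisk import (
    BetaSpec,
    ClassConditionalModel,
    Cohort,
    CohortConfig,
    NumericSpec,
    default_generator_config,
    encode_one_hot,
    generate_cohort,
)
from mdrisk.schema import (
    ANTIBIOTIC_FAMILIES,
    BINARY,
    BINARY_GROUP,
    CATEGORICAL,
    NUMERIC,
    CohortSchema,
    Variable,
    default_schema,
)

PLANTED_ABX = ("AMG", "CAR", "CF3", "GLI", "MAC", "PAP", "PEN", "POL",
               "QUI", "SUL")

#: encoded names of the 18 features carrying a planted class effect in the
#: recovery design (5 numeric scores, 3 standalone binaries, 10 exposure
#: flags); all one-hot categorical columns are exact nulls there.
PLANTED_FEATURES = frozenset(
    {"age", "apache_ii", "charlson", "saps_iii", "mv_ratio",
     "gender", "patient_category", "illness"}
    | {f"antibiotics={f}" for f in PLANTED_ABX})


def recovery_config(seed: int) -> CohortConfig:
    """Cohort design with 18 informative features among the 95.

    Effects are confined to variables generated independently of each
    other (numerics, standalone binaries, exposure flags) so the
    remaining 77 one-hot columns are exact nulls: categorical vectors
    are uniform and identical in both classes.  Effect sizes mirror a
    moderately separable clinical cohort: ~0.4 SD mean shifts on the
    scores and 0.15 absolute gaps on the binary rates.
    """
    sch = default_schema()
    uniform = {v.name: {c: 1.0 / len(v.categories) for c in v.categories}
               for v in sch if v.kind == CATEGORICAL}
    abx_null = {f: 0.10 for f in ANTIBIOTIC_FAMILIES}
    abx_mdr = dict(abx_null, **{f: 0.25 for f in PLANTED_ABX})
    non = ClassConditionalModel(
        numeric={"age": NumericSpec(60, 15, 18, 100),
                 "apache_ii": NumericSpec(17.43, 7.66, 0, 71),
                 "charlson": NumericSpec(1.24, 1.52, 0, 33),
                 "saps_iii": NumericSpec(17.5, 8.5, 0, 120),
                 "mv_ratio": BetaSpec(0.39, 5.0)},
        binary={"gender": 0.65, "patient_category": 0.40, "illness": 0.70},
        categorical=uniform, exposures={"antibiotics": abx_null})
    mdr = ClassConditionalModel(
        numeric={"age": NumericSpec(66, 15, 18, 100),
                 "apache_ii": NumericSpec(20.5, 7.66, 0, 71),
                 "charlson": NumericSpec(1.85, 1.52, 0, 33),
                 "saps_iii": NumericSpec(20.9, 8.5, 0, 120),
                 "mv_ratio": BetaSpec(0.47, 5.0)},
        binary={"gender": 0.50, "patient_category": 0.55, "illness": 0.85},
        categorical=uniform, exposures={"antibiotics": abx_mdr})
    return CohortConfig(n_total=3013, n_mdr=270, seed=seed,
                        mdr_model=mdr, non_mdr_model=non)


def flags_null_config(seed: int, n_flags: int = 50,
                      n_total: int = 3013, n_mdr: int = 270) -> CohortConfig:
    """Effect-free design: identical class models over well-populated flags.

    ``n_flags`` Bernoulli exposure flags with rates spread over
    [0.05, 0.5] plus the five numeric scores; both classes share the
    same model, so every feature is null-distributed.
    """
    flags = tuple(f"f{i:02d}" for i in range(n_flags))
    schema = CohortSchema(variables=(
        Variable("age", NUMERIC),
        Variable("apache_ii", NUMERIC),
        Variable("charlson", NUMERIC),
        Variable("saps_iii", NUMERIC),
        Variable("mv_ratio", NUMERIC),
        Variable("flags", BINARY_GROUP, flags),
    ))
    rates = np.linspace(0.05, 0.5, n_flags)
    model = ClassConditionalModel(
        numeric={"age": NumericSpec(60, 15, 18, 100),
                 "apache_ii": NumericSpec(17.43, 7.66, 0, 71),
                 "charlson": NumericSpec(1.24, 1.52, 0, 33),
                 "saps_iii": NumericSpec(17.5, 8.5, 0, 120),
                 "mv_ratio": BetaSpec(0.39, 5.0)},
        binary={}, categorical={},
        exposures={"flags": dict(zip(flags, rates))})
    return CohortConfig(n_total=n_total, n_mdr=n_mdr, seed=seed,
                        mdr_model=model, non_mdr_model=model, schema=schema)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return generate_cohort(default_generator_config(seed=0))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return encode_one_hot(default_cohort)


@pytest.fixture()
def small_config():
    base = default_generator_config(seed=3)
    return dataclasses.replace(base, n_total=120, n_mdr=20)


@pytest.fixture()
def small_cohort(small_config) -> Cohort:
    return generate_cohort(small_config)
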