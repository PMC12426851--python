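"""Feature schema for the AF stroke-risk cohort.

A schema is an ordered list of 40 feature descriptors covering demographics,
comorbidity flags, laboratory values and echocardiographic measurements — the
kinds of variables recorded at irregular hospital visits in the two years
before a first atrial-fibrillation diagnosis.  Each descriptor carries the
marginal distribution used by the synthetic generator and a per-visit
missingness rate; real EHR labs and echo parameters are missing at most
visits, which is the regime the model is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["FeatureDescriptor", "FeatureSchema", "default_schema", "N_FEATURES"]

N_FEATURES = 40


@dataclass(frozen=True)
class FeatureDescriptor:
    """One visit-level clinical variable.

    Parameters
    ----------
    name : str
        Unique feature name.
    kind : {"numeric", "binary", "categorical"}
        Numeric features are summarized by interval means; binary and
        categorical features by interval modes.
    units : str
        Display units ("" for dimensionless).
    mean, sd : float
        Marginal mean / between-patient standard deviation (numeric only).
    prevalence : float
        P(flag = 1) for binary features.
    category_probs : tuple of float
        Category probabilities for categorical features (codes 0, 1, ...).
    missing_rate : float
        Probability that the value is unrecorded at any given visit.
    """

    name: str
    kind: str
    units: str = ""
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    category_probs: tuple = ()
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "binary", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate must be in [0, 1]")
        if self.kind == "categorical":
            total = float(sum(self.category_probs))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: category probabilities must sum to 1")
        if self.kind == "binary" and not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence must be in [0, 1]")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of feature descriptors (40 for the standard cohort)."""

    entries: tuple

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list:
        return [e.name for e in self.entries]

    @property
    def kinds(self) -> list:
        return [e.kind for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key):
        if isinstance(key, str):
            for e in self.entries:
                if e.name == key:
                    return e
            raise KeyError(key)
        return self.entries[key]

    def index(self, name: str) -> int:
        for i, e in enumerate(self.entries):
            if e.name == name:
                return i
        raise KeyError(name)


def _num(name, units, mean, sd, miss):
    return FeatureDescriptor(name, "numeric", units, mean=mean, sd=sd, missing_rate=miss)


def _bin(name, prev, miss):
    return FeatureDescriptor(name, "binary", "", prevalence=prev, missing_rate=miss)


def default_schema() -> FeatureSchema:
    """The standard 40-feature AF visit schema.

    Marginal means/SDs follow typical values for an elderly AF cohort
    (age ~74 y, eGFR ~64 mL/min/1.73 m2, high diabetes prevalence).  Missing
    rates are per-visit: demographics are recorded at most encounters, routine
    labs at most blood draws, and echocardiographic parameters only when an
    echo was performed, hence rates from 0.05 up to 0.9.
    """
    entries = (
        # demographics / vitals
        _num("age", "years", 74.0, 10.2, 0.05),
        _num("bmi", "kg/m2", 25.3, 4.3, 0.5),
        _num("sbp", "mmHg", 130.0, 16.0, 0.4),
        _num("heart_rate", "bpm", 82.0, 16.0, 0.4),
        # laboratory
        _num("fpg", "mg/dL", 135.3, 68.7, 0.75),
        _num("hba1c", "%", 6.9, 1.4, 0.8),
        _num("tcho", "mg/dL", 161.6, 45.1, 0.75),
        _num("tg", "mg/dL", 139.3, 103.3, 0.75),
        _num("ldl", "mg/dL", 94.9, 32.7, 0.8),
        _num("hdl", "mg/dL", 42.8, 13.1, 0.8),
        _num("alt", "U/L", 23.9, 20.0, 0.75),
        _num("ast", "U/L", 26.0, 18.0, 0.75),
        _num("bun", "mg/dL", 22.0, 10.0, 0.75),
        _num("creatinine", "mg/dL", 1.2, 0.5, 0.7),
        _num("egfr", "mL/min/1.73m2", 64.8, 32.2, 0.7),
        _num("hscrp", "mg/dL", 0.55, 0.8, 0.85),
        _num("hematocrit", "%", 39.5, 5.2, 0.7),
        _num("ntprobnp", "pg/mL", 1500.0, 1800.0, 0.9),
        _num("wbc", "10^3/uL", 7.5, 2.2, 0.7),
        _num("platelet", "10^3/uL", 220.0, 62.0, 0.7),
        # echocardiography
        _num("la_size", "cm", 4.3, 0.85, 0.85),
        _num("lvef", "%", 62.0, 13.5, 0.85),
        _num("lvids", "cm", 3.2, 0.8, 0.85),
        _num("lvidd", "cm", 4.8, 0.7, 0.85),
        _num("lv_mass", "g", 212.0, 68.0, 0.87),
        _num("tr_vmax", "cm/s", 31.6, 12.8, 0.87),
        _num("e_vel", "mm/s", 96.3, 35.0, 0.87),
        _num("a_vel", "mm/s", 90.8, 30.4, 0.87),
        _num("dt", "s", 0.2, 0.07, 0.87),
        _num("ivsd", "cm", 1.1, 0.2, 0.87),
        _num("pwd", "cm", 1.0, 0.18, 0.87),
        # comorbidity / status flags
        _bin("sex_male", 0.57, 0.05),
        _bin("htn", 0.40, 0.3),
        _bin("dm", 0.83, 0.3),
        _bin("cad", 0.205, 0.3),
        _bin("paod", 0.08, 0.3),
        _bin("hf", 0.065, 0.3),
        _bin("history_tia_is", 0.055, 0.2),
        _bin("proteinuria", 0.12, 0.5),
        FeatureDescriptor(
            "smoking_status", "categorical",
            category_probs=(0.55, 0.25, 0.20), missing_rate=0.4,
        ),
    )
    schema = FeatureSchema(entries=entries)
    assert len(schema) == N_FEATURES
    return schema
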