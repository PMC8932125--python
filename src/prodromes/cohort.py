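"""Patient-level cohort data model and delimited-text I/O.

A cohort couples a :class:`SymptomCatalog` (the symptom grid: one row per
symptom, with its clinical dimension and group-wise prevalence / onset-age
parameters) with a list of :class:`PatientRecord` objects (one row per
patient: a two-level diagnosis, binary presence flags and, for present
symptoms, an optional age at onset in years).

Files are plain CSV.  The patient table has columns ``patient_id``,
``diagnosis``, then one ``<symptom>`` presence column (0/1) and one
``<symptom>_onset`` column per catalog symptom, in catalog order.  Symptom
names may contain commas; standard CSV quoting applies.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Diagnosis",
    "Dimension",
    "SymptomDefinition",
    "SymptomCatalog",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "ONSET_WINDOW",
]

#: Chart-review window in years: symptoms are documented from birth to age 17.
ONSET_WINDOW = (0.0, 17.0)


class CohortValidationError(ValueError):
    """Raised when a cohort, catalog or patient file violates an invariant."""


class Diagnosis(str, enum.Enum):
    """Adult outcome diagnosis: schizophrenia or mood spectrum disorder."""

    SZ = "SZ"
    MSD = "MSD"


class Dimension(str, enum.Enum):
    """Clinical dimension a symptom belongs to."""

    cognitive_developmental = "cognitive_developmental"
    functional = "functional"
    anxiety = "anxiety"
    behavioural_impulse = "behavioural_impulse"
    mood = "mood"
    negative = "negative"
    positive_discordant = "positive_discordant"
    other = "other"


@dataclass(frozen=True)
class SymptomDefinition:
    """One symptom of the grid with its group-wise population parameters.

    Prevalences are stored as exact count/group-size fractions.  Onset
    parameters (years) are ``None`` where no onset age was recorded for
    that group.
    """

    name: str
    dimension: Dimension
    prev_sz: float
    prev_msd: float
    onset_mean_sz: float | None = None
    onset_sd_sz: float | None = None
    onset_mean_msd: float | None = None
    onset_sd_msd: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortValidationError("symptom name must be non-empty")
        for attr in ("prev_sz", "prev_msd"):
            p = getattr(self, attr)
            if not 0.0 <= p <= 1.0:
                raise CohortValidationError(
                    f"{self.name}: {attr}={p} outside [0, 1]"
                )
        for attr in ("onset_sd_sz", "onset_sd_msd"):
            sd = getattr(self, attr)
            if sd is not None and sd < 0:
                raise CohortValidationError(f"{self.name}: {attr}={sd} < 0")

    def prevalence(self, group: Diagnosis) -> float:
        return self.prev_sz if group is Diagnosis.SZ else self.prev_msd

    def onset_params(self, group: Diagnosis) -> tuple[float, float] | None:
        """(mean, sd) of onset age for *group*, or None if not recorded.

        An absent SD with a recorded mean (a single-patient table cell)
        degenerates to sd = 0.
        """
        mean, sd = (
            (self.onset_mean_sz, self.onset_sd_sz)
            if group is Diagnosis.SZ
            else (self.onset_mean_msd, self.onset_sd_msd)
        )
        if mean is None:
            return None
        return mean, 0.0 if sd is None else sd


class SymptomCatalog:
    """Ordered, name-unique collection of :class:`SymptomDefinition`.

    Catalog order is semantically meaningful: it is the deterministic
    tie-break order used by the CHAID split search and by trajectory
    summaries.
    """

    def __init__(self, symptoms: Sequence[SymptomDefinition]):
        symptoms = list(symptoms)
        if not symptoms:
            raise CohortValidationError("catalog must be non-empty")
        names = [s.name for s in symptoms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CohortValidationError(f"duplicate symptom names: {dupes}")
        self._symptoms = symptoms
        self._index = {s.name: i for i, s in enumerate(symptoms)}

    @property
    def symptoms(self) -> list[SymptomDefinition]:
        return list(self._symptoms)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._symptoms]

    def __len__(self) -> int:
        return len(self._symptoms)

    def __iter__(self) -> Iterator[SymptomDefinition]:
        return iter(self._symptoms)

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> SymptomDefinition:
        try:
            return self._symptoms[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown symptom: {name!r}") from None

    def position(self, name: str) -> int:
        """Rank of *name* in catalog order (the tie-break key)."""
        return self._index[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymptomCatalog):
            return NotImplemented
        return self._symptoms == other._symptoms

    def __repr__(self) -> str:
        return f"SymptomCatalog({len(self)} symptoms)"


@dataclass
class PatientRecord:
    """One patient: diagnosis, binary symptom flags, onset ages (years)."""

    patient_id: str
    diagnosis: Diagnosis
    presence: dict[str, int] = field(default_factory=dict)
    onset_age: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        for name, flag in self.presence.items():
            if flag not in (0, 1):
                raise CohortValidationError(
                    f"patient {self.patient_id}: presence[{name!r}]={flag} "
                    "not in {0, 1}"
                )
        for name, age in self.onset_age.items():
            if self.presence.get(name, 0) != 1:
                raise CohortValidationError(
                    f"patient {self.patient_id}: onset age for {name!r} "
                    "recorded although the symptom is absent"
                )
            if not np.isfinite(age):
                raise CohortValidationError(
                    f"patient {self.patient_id}: non-finite onset for {name!r}"
                )


class Cohort:
    """Patients plus the catalog their columns refer to.

    Invariants enforced at construction: every presence/onset key is a
    catalog symptom; both diagnosis groups are non-empty; onset ages lie in
    the chart-review window (warning by default, error under ``strict``).
    """

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        catalog: SymptomCatalog,
        *,
        strict: bool = False,
        meta: Mapping[str, object] | None = None,
    ):
        patients = list(patients)
        known = set(catalog.names)
        for p in patients:
            unknown = (set(p.presence) | set(p.onset_age)) - known
            if unknown:
                raise CohortValidationError(
                    f"patient {p.patient_id}: symptoms not in catalog: "
                    f"{sorted(unknown)}"
                )
        lo, hi = ONSET_WINDOW
        outside = [
            (p.patient_id, name, age)
            for p in patients
            for name, age in p.onset_age.items()
            if not lo <= age <= hi
        ]
        if outside:
            msg = (
                f"{len(outside)} onset age(s) outside the [{lo:g}, {hi:g}] "
                f"chart-review window, e.g. {outside[0]}"
            )
            if strict:
                raise CohortValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        n_sz = sum(p.diagnosis is Diagnosis.SZ for p in patients)
        n_msd = len(patients) - n_sz
        if n_sz == 0 or n_msd == 0:
            raise CohortValidationError(
                f"both diagnosis groups must be non-empty (n_sz={n_sz}, "
                f"n_msd={n_msd})"
            )
        self.patients = patients
        self.catalog = catalog
        self.meta: dict[str, object] = dict(meta or {})

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def group_sizes(self) -> tuple[int, int]:
        """(n_sz, n_msd)."""
        n_sz = sum(p.diagnosis is Diagnosis.SZ for p in self.patients)
        return n_sz, len(self.patients) - n_sz

    def group(self, diagnosis: Diagnosis) -> list[PatientRecord]:
        diagnosis = Diagnosis(diagnosis)
        return [p for p in self.patients if p.diagnosis is diagnosis]

    def presence_matrix(
        self, symptoms: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): X[i, j] = presence of symptom j for patient i, y = 1 for SZ.

        Column order follows *symptoms* (default: catalog order).
        """
        names = list(symptoms) if symptoms is not None else self.catalog.names
        for name in names:
            if name not in self.catalog:
                raise KeyError(f"unknown symptom: {name!r}")
        X = np.array(
            [[p.presence.get(name, 0) for name in names] for p in self.patients],
            dtype=np.int64,
        ).reshape(len(self.patients), len(names))
        y = np.array(
            [int(p.diagnosis is Diagnosis.SZ) for p in self.patients],
            dtype=np.int64,
        )
        return X, y

    def onset_ages(self, symptom: str, group: Diagnosis) -> np.ndarray:
        """Recorded onset ages of *symptom* among symptom-positive patients."""
        if symptom not in self.catalog:
            raise KeyError(f"unknown symptom: {symptom!r}")
        return np.array(
            [
                p.onset_age[symptom]
                for p in self.group(group)
                if symptom in p.onset_age
            ],
            dtype=float,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.catalog == other.catalog and self.patients == other.patients


# ---------------------------------------------------------------------------
# delimited-text I/O

_CATALOG_COLUMNS = [
    "name",
    "dimension",
    "prev_sz",
    "prev_msd",
    "onset_mean_sz",
    "onset_sd_sz",
    "onset_mean_msd",
    "onset_sd_msd",
]


def _opt(value: object) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_catalog(path) -> SymptomCatalog:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(
            f"catalog file {path}: missing columns {sorted(missing)}"
        )
    symptoms = []
    for row in df.itertuples(index=False):
        try:
            dimension = Dimension(row.dimension)
        except ValueError:
            raise CohortValidationError(
                f"catalog file {path}: unknown dimension {row.dimension!r}"
            ) from None
        symptoms.append(
            SymptomDefinition(
                name=str(row.name),
                dimension=dimension,
                prev_sz=float(row.prev_sz),
                prev_msd=float(row.prev_msd),
                onset_mean_sz=_opt(row.onset_mean_sz),
                onset_sd_sz=_opt(row.onset_sd_sz),
                onset_mean_msd=_opt(row.onset_mean_msd),
                onset_sd_msd=_opt(row.onset_sd_msd),
            )
        )
    return SymptomCatalog(symptoms)


def write_catalog(catalog: SymptomCatalog, path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": s.name,
                "dimension": s.dimension.value,
                "prev_sz": s.prev_sz,
                "prev_msd": s.prev_msd,
                "onset_mean_sz": s.onset_mean_sz,
                "onset_sd_sz": s.onset_sd_sz,
                "onset_mean_msd": s.onset_mean_msd,
                "onset_sd_msd": s.onset_sd_msd,
            }
            for s in catalog
        ],
        columns=_CATALOG_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_cohort(path_patients, path_catalog, *, strict: bool = False) -> Cohort:
    """Read a patient table + catalog and return a validated :class:`Cohort`.

    Unknown symptom columns are an error; empty presence cells are coerced
    to 0 with a warning (chart review: not documented = not observed);
    onset recorded for an absent symptom, a diagnosis outside {SZ, MSD} or
    a non-numeric onset cell are errors.
    """
    catalog = read_catalog(path_catalog)
    df = pd.read_csv(
        path_patients, dtype={"patient_id": str}, float_precision="round_trip"
    )
    if "patient_id" not in df.columns or "diagnosis" not in df.columns:
        raise CohortValidationError(
            f"patient file {path_patients}: header must contain "
            "'patient_id' and 'diagnosis'"
        )
    expected = {"patient_id", "diagnosis"}
    for name in catalog.names:
        expected |= {name, f"{name}_onset"}
    unknown = set(df.columns) - expected
    if unknown:
        raise CohortValidationError(
            f"patient file {path_patients}: columns not derived from the "
            f"catalog: {sorted(unknown)}"
        )

    patients = []
    n_coerced = 0
    for i, row in enumerate(df.itertuples(index=False)):
        # itertuples mangles punctuated names; index positionally instead
        values = dict(zip(df.columns, row))
        try:
            diagnosis = Diagnosis(str(values["diagnosis"]))
        except ValueError:
            raise CohortValidationError(
                f"patient file {path_patients}, row {i}: diagnosis "
                f"{values['diagnosis']!r} not in {{SZ, MSD}}"
            ) from None
        presence: dict[str, int] = {}
        onset: dict[str, float] = {}
        for name in catalog.names:
            cell = values.get(name)
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                presence[name] = 0
                if name in df.columns:
                    n_coerced += 1
            else:
                try:
                    flag = int(cell)
                except (TypeError, ValueError):
                    raise CohortValidationError(
                        f"patient file {path_patients}, row {i}: non-numeric "
                        f"presence cell for {name!r}: {cell!r}"
                    ) from None
                if flag not in (0, 1):
                    raise CohortValidationError(
                        f"patient file {path_patients}, row {i}: presence "
                        f"cell for {name!r} must be 0 or 1, got {flag}"
                    )
                presence[name] = flag
            ocell = values.get(f"{name}_onset")
            if ocell is not None and not (
                isinstance(ocell, float) and np.isnan(ocell)
            ):
                try:
                    age = float(ocell)
                except (TypeError, ValueError):
                    raise CohortValidationError(
                        f"patient file {path_patients}, row {i}: non-numeric "
                        f"onset cell for {name!r}: {ocell!r}"
                    ) from None
                if presence[name] != 1:
                    raise CohortValidationError(
                        f"patient file {path_patients}, row {i}: onset age "
                        f"for {name!r} recorded although presence is 0"
                    )
                onset[name] = age
        patients.append(
            PatientRecord(
                patient_id=str(values["patient_id"]),
                diagnosis=diagnosis,
                presence=presence,
                onset_age=onset,
            )
        )
    if n_coerced:
        warnings.warn(
            f"{n_coerced} empty presence cell(s) coerced to 0 "
            "(not documented = not observed)",
            stacklevel=2,
        )
    return Cohort(patients, catalog, strict=strict)


def write_cohort(cohort: Cohort, path_patients, path_catalog) -> None:
    """Write a cohort as two CSV files readable by :func:`read_cohort`.

    Column order is deterministic (catalog order); absent onset ages are
    written as empty cells.  ``write_cohort`` then ``read_cohort`` is the
    identity on valid cohorts.
    """
    write_catalog(cohort.catalog, path_catalog)
    columns: dict[str, list] = {
        "patient_id": [p.patient_id for p in cohort.patients],
        "diagnosis": [p.diagnosis.value for p in cohort.patients],
    }
    for name in cohort.catalog.names:
        columns[name] = [p.presence.get(name, 0) for p in cohort.patients]
        columns[f"{name}_onset"] = [
            p.onset_age.get(name) for p in cohort.patients
        ]
    pd.DataFrame(columns).to_csv(path_patients, index=False)
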