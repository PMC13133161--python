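"""Patient-level data model for multi-centre chemoradiotherapy cohorts.

This module owns the raw-record representation (one row per patient with
demographics, staging, tumour volume, treatment and outcome fields), the
derivation of the three survival endpoints — overall survival (OS),
locoregional control (LRC) and freedom from distant metastases (FFDM) —
from the raw event/censoring fields, the covariate encoding used by the
Cox models, EQD2 dose conversion, and the federated median-of-means
imputation of missing gross tumour volume (GTV).

Patient rows never leave a :class:`CentreDataset`; cross-centre exchange
(here only the scalar per-centre GTV means) goes through the payload
audit in :mod:`fedsurv.messages`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataConsistencyError,
    EncodingError,
    ImputationError,
    InvalidInputError,
)

__all__ = [
    "PatientRecord",
    "OutcomeRecord",
    "ModelConfig",
    "CentreDataset",
    "OUTCOMES",
    "CATEGORICAL_LEVELS",
    "CSV_COLUMNS",
    "compute_eqd2",
    "derive_outcome",
    "encode_covariates",
    "reference_covariates",
    "default_model_config",
    "impute_gtv_median_of_means",
    "read_centre_csv",
    "write_centre_csv",
    "write_data_dictionary",
]

#: The three modelled endpoints.
OUTCOMES = ("OS", "LRC", "FFDM")

#: Allowed levels per categorical column; the first level is the
#: reference level (dummy-coded 0).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "t_stage": ("T1-2", "T3-4"),
    "n_stage": ("N0", "N+"),
    "m_stage": ("M0", "M1"),
    "histology": ("SCC", "basaloid-SCC"),
    "rt_technique": ("3D-CRT", "IMRT/VMAT"),
    "chemo": ("none", "mitomycin", "cisplatin", "other"),
}

#: Upper bound on plausible follow-up, in months from first radiotherapy.
MAX_FOLLOWUP_MONTHS = 360.0

#: Months per day when converting calendar intervals.
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class PatientRecord:
    """One patient's raw covariates, treatment and outcome fields.

    Times are months from the first radiotherapy fraction. Event-time
    fields are ``None`` when the event did not occur. ``gtv_cm3`` may be
    ``None`` before imputation.
    """

    patient_id: str
    sex: str
    age_years: float
    t_stage: str
    n_stage: str
    m_stage: str
    gtv_cm3: float | None
    histology: str
    rt_technique: str
    chemo: str
    total_dose_gy: float
    dose_per_fraction_gy: float
    followup_months: float
    death_months: float | None = None
    lrf_months: float | None = None
    dm_months: float | None = None
    apr_nondisease_months: float | None = None

    def validate(self) -> None:
        """Raise if any invariant is violated."""
        for fname, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, fname)
            if value not in levels:
                raise EncodingError(
                    f"patient {self.patient_id}: field {fname!r} has level "
                    f"{value!r}, allowed: {levels}"
                )
        if not self.age_years > 0:
            raise InvalidInputError(
                f"patient {self.patient_id}: age_years must be > 0"
            )
        if self.gtv_cm3 is not None and not self.gtv_cm3 > 0:
            raise InvalidInputError(
                f"patient {self.patient_id}: gtv_cm3 must be > 0 when present"
            )
        if self.total_dose_gy < 0:
            raise InvalidInputError(
                f"patient {self.patient_id}: total_dose_gy must be >= 0"
            )
        if self.followup_months is None or not np.isfinite(self.followup_months):
            raise InvalidInputError(
                f"patient {self.patient_id}: followup_months missing"
            )
        for fname in (
            "followup_months",
            "death_months",
            "lrf_months",
            "dm_months",
            "apr_nondisease_months",
        ):
            value = getattr(self, fname)
            if value is None:
                continue
            if not 0 <= value <= MAX_FOLLOWUP_MONTHS:
                raise InvalidInputError(
                    f"patient {self.patient_id}: {fname}={value} outside "
                    f"[0, {MAX_FOLLOWUP_MONTHS}]"
                )
        for fname in ("death_months", "lrf_months", "dm_months"):
            value = getattr(self, fname)
            if value is not None and value > self.followup_months + 1e-9:
                raise DataConsistencyError(
                    f"patient {self.patient_id}: {fname}={value} exceeds "
                    f"followup_months={self.followup_months}"
                )


@dataclass(frozen=True)
class OutcomeRecord:
    """A derived (time, event) pair for one endpoint."""

    time_months: float
    event: int
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise InvalidInputError(f"unknown outcome {self.outcome!r}")
        if self.event not in (0, 1):
            raise InvalidInputError("event indicator must be 0 or 1")
        if not self.time_months > 0:
            raise InvalidInputError("time_months must be > 0")


# ---------------------------------------------------------------------------
# Covariate terms
# ---------------------------------------------------------------------------

#: Ordered covariate terms of the full model specification. Each maps to
#: one column of the design matrix; reference levels encode to 0.
FULL_TERMS = (
    "sex_female",
    "t_stage_t34",
    "n_stage_npos",
    "age_per_decade",
    "log10_gtv",
    "eqd2_per_10gy",
    "histology_basaloid",
    "rt_imrt_vmat",
    "chemo_mitomycin",
    "chemo_cisplatin",
    "chemo_other",
)


@dataclass(frozen=True)
class ModelConfig:
    """Specification of one Cox model: endpoint, ordered covariate terms,
    and model-level filters.

    ``dose_log10`` switches the dose term from linear EQD2/10 (default)
    to log10(EQD2); the reference dose value tracks the choice.
    """

    outcome: str
    covariates: tuple[str, ...] = FULL_TERMS
    exclude_m1: bool = False
    dose_log10: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise InvalidInputError(f"unknown outcome {self.outcome!r}")
        if len(set(self.covariates)) != len(self.covariates):
            raise InvalidInputError("covariate names must be unique")
        unknown = set(self.covariates) - set(FULL_TERMS)
        if unknown:
            raise InvalidInputError(f"unknown covariate terms: {sorted(unknown)}")

    @property
    def n_parameters(self) -> int:
        return len(self.covariates)


def default_model_config(outcome: str) -> ModelConfig:
    """The primary model specification for one endpoint.

    The FFDM model omits radiotherapy technique and excludes patients
    with metastatic disease at baseline.
    """
    if outcome == "FFDM":
        covariates = tuple(t for t in FULL_TERMS if t != "rt_imrt_vmat")
        return ModelConfig(outcome=outcome, covariates=covariates, exclude_m1=True)
    return ModelConfig(outcome=outcome)


@dataclass(frozen=True)
class CentreDataset:
    """A centre's private patient table. Rows never leave the node; only
    aggregates derived by node-side operations are exchanged."""

    centre_id: str
    records: tuple[PatientRecord, ...]
    role: str = "training"

    def __post_init__(self) -> None:
        if self.role not in ("training", "validation"):
            raise InvalidInputError(f"unknown role {self.role!r}")
        if self.role == "training" and len(self.records) == 0:
            raise InvalidInputError(
                f"centre {self.centre_id}: training dataset must be non-empty"
            )

    @property
    def n(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        for record in self.records:
            record.validate()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_eqd2(
    total_dose_gy: float, dose_per_fraction_gy: float, alpha_beta: float = 10.0
) -> float:
    """Equivalent total dose in 2 Gy fractions under the linear-quadratic
    model: ``EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)``.

    At d = 2 Gy per fraction this is the identity.
    """
    if dose_per_fraction_gy <= 0:
        raise InvalidInputError("dose_per_fraction_gy must be > 0")
    if alpha_beta <= 0:
        raise InvalidInputError("alpha_beta must be > 0")
    if total_dose_gy < 0:
        raise InvalidInputError("total_dose_gy must be >= 0")
    return total_dose_gy * (dose_per_fraction_gy + alpha_beta) / (2.0 + alpha_beta)


def _min_present(*values: float | None) -> float | None:
    present = [v for v in values if v is not None]
    return min(present) if present else None


def derive_outcome(record: PatientRecord, outcome: str) -> OutcomeRecord:
    """Derive the (time, event) pair for one endpoint from a raw record.

    OS: death from any cause is the event; otherwise censored at last
    follow-up. LRC: locoregional failure is the event; censored at the
    earliest of death, abdominoperineal resection for non-disease
    reasons, distant metastasis, or last follow-up. FFDM: distant
    metastasis is the event; censored at the earliest of locoregional
    recurrence, death, or last follow-up.

    A censoring cause occurring strictly before the endpoint's event
    time takes precedence (the patient leaves observation first).
    """
    if outcome not in OUTCOMES:
        raise InvalidInputError(f"unknown outcome {outcome!r}")
    record.validate()
    fu = record.followup_months

    if outcome == "OS":
        if record.death_months is not None:
            return OutcomeRecord(record.death_months, 1, "OS")
        return OutcomeRecord(fu, 0, "OS")

    if outcome == "LRC":
        censor = _min_present(
            record.death_months,
            record.apr_nondisease_months,
            record.dm_months,
            fu,
        )
        if record.lrf_months is not None and record.lrf_months <= censor:
            return OutcomeRecord(record.lrf_months, 1, "LRC")
        return OutcomeRecord(censor, 0, "LRC")

    # FFDM
    censor = _min_present(record.lrf_months, record.death_months, fu)
    if record.dm_months is not None and record.dm_months <= censor:
        return OutcomeRecord(record.dm_months, 1, "FFDM")
    return OutcomeRecord(censor, 0, "FFDM")


def _dummy(value: str, fname: str, level: str) -> float:
    levels = CATEGORICAL_LEVELS[fname]
    if value not in levels:
        raise EncodingError(f"field {fname!r}: unknown level {value!r}")
    return 1.0 if value == level else 0.0


def _encode_term(record: PatientRecord, term: str, config: ModelConfig) -> float:
    if term == "sex_female":
        return _dummy(record.sex, "sex", "female")
    if term == "t_stage_t34":
        return _dummy(record.t_stage, "t_stage", "T3-4")
    if term == "n_stage_npos":
        return _dummy(record.n_stage, "n_stage", "N+")
    if term == "age_per_decade":
        return record.age_years / 10.0
    if term == "log10_gtv":
        if record.gtv_cm3 is None:
            raise EncodingError(
                f"patient {record.patient_id}: gtv_cm3 missing (impute first)"
            )
        return math.log10(record.gtv_cm3)
    if term == "eqd2_per_10gy":
        eqd2 = compute_eqd2(record.total_dose_gy, record.dose_per_fraction_gy)
        if config.dose_log10:
            return math.log10(eqd2) if eqd2 > 0 else 0.0
        return eqd2 / 10.0
    if term == "histology_basaloid":
        return _dummy(record.histology, "histology", "basaloid-SCC")
    if term == "rt_imrt_vmat":
        return _dummy(record.rt_technique, "rt_technique", "IMRT/VMAT")
    if term == "chemo_mitomycin":
        return _dummy(record.chemo, "chemo", "mitomycin")
    if term == "chemo_cisplatin":
        return _dummy(record.chemo, "chemo", "cisplatin")
    if term == "chemo_other":
        return _dummy(record.chemo, "chemo", "other")
    raise EncodingError(f"unknown covariate term {term!r}")


def encode_covariates(record: PatientRecord, config: ModelConfig) -> np.ndarray:
    """Encode one record into the ordered numeric design vector of a
    model configuration.

    Dummy codes put the reference level (male, T1-2, N0, SCC, 3D-CRT,
    no chemotherapy) at 0; age is years/10; GTV is log10(cm³); dose is
    EQD2/10 Gy (or log10 EQD2 when configured); chemotherapy enters as
    three dummies relative to no chemotherapy.
    """
    x = np.array(
        [_encode_term(record, term, config) for term in config.covariates],
        dtype=float,
    )
    if not np.all(np.isfinite(x)):
        raise EncodingError(
            f"patient {record.patient_id}: non-finite encoded covariate"
        )
    return x


#: Reference values per term for the reference ("baseline") patient:
#: all categoricals at reference, age 35 years, GTV fixed at the study's
#: published log10 value, prescribed dose 40 EQD2.
_REFERENCE_VALUES = {
    "age_per_decade": 3.5,
    "log10_gtv": 0.02572,
    "eqd2_per_10gy": 4.0,
}


def reference_covariates(config: ModelConfig) -> np.ndarray:
    """The encoded reference covariate vector used for reference outcome
    rates: categorical dummies 0, age term 3.5, log10 GTV 0.02572, dose
    term 4.0 (or log10(40) when the dose term is log-transformed)."""
    values = dict(_REFERENCE_VALUES)
    if config.dose_log10:
        values["eqd2_per_10gy"] = math.log10(40.0)
    return np.array([values.get(term, 0.0) for term in config.covariates])


def impute_gtv_median_of_means(
    nodes: Sequence[CentreDataset], audit=None
) -> list[CentreDataset]:
    """Federated GTV imputation: a centre with missing GTV values fills
    them with the median of the per-centre mean GTVs of all *other*
    centres' observed values. Only scalar means cross node boundaries.

    Parameters
    ----------
    audit : AuditLog, optional
        When given, each exchanged scalar mean is logged as a payload.
    """
    means: dict[str, float] = {}
    for node in nodes:
        observed = [r.gtv_cm3 for r in node.records if r.gtv_cm3 is not None]
        if observed:
            means[node.centre_id] = float(np.mean(observed))
            if audit is not None:
                audit.record(
                    kind="gtv_mean",
                    sender=node.centre_id,
                    payload={"gtv_mean_cm3": means[node.centre_id]},
                )

    out: list[CentreDataset] = []
    for node in nodes:
        if all(r.gtv_cm3 is not None for r in node.records):
            out.append(node)
            continue
        donor_means = [m for cid, m in means.items() if cid != node.centre_id]
        if not donor_means:
            raise ImputationError(
                f"centre {node.centre_id}: no other centre has observed GTV"
            )
        fill = float(np.median(donor_means))
        filled = tuple(
            r if r.gtv_cm3 is not None else replace(r, gtv_cm3=fill)
            for r in node.records
        )
        out.append(replace(node, records=filled))
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "t_stage",
    "n_stage",
    "m_stage",
    "gtv_cm3",
    "histology",
    "rt_technique",
    "chemo",
    "total_dose_gy",
    "dose_per_fraction_gy",
    "followup_months",
    "death_months",
    "lrf_months",
    "dm_months",
    "apr_nondisease_months",
)

_OPTIONAL_FLOATS = (
    "gtv_cm3",
    "death_months",
    "lrf_months",
    "dm_months",
    "apr_nondisease_months",
)


def centre_to_dataframe(node: CentreDataset) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in CSV_COLUMNS} for r in node.records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_centre_csv(node: CentreDataset, path) -> None:
    """Write one centre's table in the study CSV dialect (UTF-8, header
    row, empty string for missing)."""
    df = centre_to_dataframe(node)
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_centre_csv(path, centre_id: str, role: str = "training") -> CentreDataset:
    """Read one centre's table, validating every record."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing_cols)}")
    records = []
    for row in df.to_dict(orient="records"):
        kwargs = {col: row[col] for col in CSV_COLUMNS}
        for col in _OPTIONAL_FLOATS:
            v = kwargs[col]
            kwargs[col] = None if pd.isna(v) else float(v)
        for col in ("age_years", "total_dose_gy", "dose_per_fraction_gy", "followup_months"):
            kwargs[col] = float(kwargs[col])
        record = PatientRecord(**kwargs)
        record.validate()
        records.append(record)
    return CentreDataset(centre_id=centre_id, records=tuple(records), role=role)


def write_data_dictionary(path) -> None:
    """Write the machine-readable data dictionary: allowed levels per
    categorical column, units for numeric columns, missing-value token."""
    dictionary = {
        "missing_value_token": "",
        "time_unit": "months from first radiotherapy",
        "columns": {
            **{k: {"type": "categorical", "levels": list(v), "reference": v[0]}
               for k, v in CATEGORICAL_LEVELS.items()},
            "patient_id": {"type": "string"},
            "age_years": {"type": "float", "unit": "years"},
            "gtv_cm3": {"type": "float", "unit": "cm^3", "missing_allowed": True},
            "total_dose_gy": {"type": "float", "unit": "Gy"},
            "dose_per_fraction_gy": {"type": "float", "unit": "Gy"},
            "followup_months": {"type": "float", "unit": "months"},
            "death_months": {"type": "float", "unit": "months", "missing_allowed": True},
            "lrf_months": {"type": "float", "unit": "months", "missing_allowed": True},
            "dm_months": {"type": "float", "unit": "months", "missing_allowed": True},
            "apr_nondisease_months": {"type": "float", "unit": "months", "missing_allowed": True},
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dictionary, fh, sort_keys=False)
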