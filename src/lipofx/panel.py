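"""Data model and I/O for Nightingale-style NMR lipoprotein panels.

The canonical on-disk representation is a pair of UTF-8 CSV files:

``measurements.csv`` (long format)
    columns ``subject_id, visit, metabolite_id, concentration, status``
    with ``visit`` in ``{baseline, week16}`` and ``status`` in
    ``{observed, below_lod, qc_rejected}``.  ``concentration`` is present
    if and only if ``status == observed``.

``subjects.csv``
    columns ``subject_id, arm, statin, ezetimibe`` plus optional
    demographics (``age, sex, bmi, sbp, dbp, smoking, cvd``).  ``arm`` is
    1 for active treatment (PCSK9 inhibitor) and 0 for placebo.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subclass",
    "SubclassCatalog",
    "CohortDataset",
    "NIGHTINGALE_SUBCLASSES",
    "VISITS",
    "STATUSES",
    "read_cohort",
    "write_cohort",
    "read_wide_measurements",
    "convert_units",
    "friedewald_ldl",
    "standardize_baseline",
]

VISITS = ("baseline", "week16")
STATUSES = ("observed", "below_lod", "qc_rejected")

#: Friedewald applicability bound for triglycerides, mmol/L (= 400 mg/dL).
FRIEDEWALD_TG_MAX = 4.52


class SchemaError(ValueError):
    """A table does not conform to the documented column schema."""


class ValidationError(ValueError):
    """A value violates a dataset invariant."""


@dataclasses.dataclass(frozen=True)
class Subclass:
    subclass_id: str
    lipo_class: str  # one of VLDL, IDL, LDL, HDL
    size_label: str
    diameter_nm: float


#: The 14 NMR-resolved lipoprotein subclasses with their average particle
#: diameters.  The extremely-large VLDL diameter is a lower bound (>75 nm);
#: 75.0 is stored as its nominal value.  IDs follow the Nightingale public
#: naming for particle concentrations.
NIGHTINGALE_SUBCLASSES: tuple[Subclass, ...] = (
    Subclass("XXL_VLDL_P", "VLDL", "extremely large", 75.0),
    Subclass("XL_VLDL_P", "VLDL", "very large", 64.0),
    Subclass("L_VLDL_P", "VLDL", "large", 53.6),
    Subclass("M_VLDL_P", "VLDL", "medium", 44.5),
    Subclass("S_VLDL_P", "VLDL", "small", 36.8),
    Subclass("XS_VLDL_P", "VLDL", "very small", 31.3),
    Subclass("IDL_P", "IDL", "intermediate", 28.6),
    Subclass("L_LDL_P", "LDL", "large", 25.5),
    Subclass("M_LDL_P", "LDL", "medium", 23.0),
    Subclass("S_LDL_P", "LDL", "small", 18.7),
    Subclass("XL_HDL_P", "HDL", "very large", 14.3),
    Subclass("L_HDL_P", "HDL", "large", 12.1),
    Subclass("M_HDL_P", "HDL", "medium", 10.9),
    Subclass("S_HDL_P", "HDL", "small", 8.7),
)


class SubclassCatalog:
    """Ordered catalog of lipoprotein subclasses.

    The ordering is canonical: largest to smallest particle within
    VLDL → IDL → LDL → HDL, matching the conventional forest-plot layout.
    """

    def __init__(self, entries: Sequence[Subclass] = NIGHTINGALE_SUBCLASSES):
        entries = tuple(entries)
        seen: set[str] = set()
        for e in entries:
            if e.diameter_nm <= 0:
                raise ValidationError(f"non-positive diameter for {e.subclass_id}")
            if e.subclass_id in seen:
                raise ValidationError(f"duplicate subclass id {e.subclass_id}")
            seen.add(e.subclass_id)
        for cls in {e.lipo_class for e in entries}:
            diam = [e.diameter_nm for e in entries if e.lipo_class == cls]
            if any(b >= a for a, b in zip(diam, diam[1:])):
                raise ValidationError(f"diameters not strictly decreasing within {cls}")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, subclass_id: str) -> bool:
        return any(e.subclass_id == subclass_id for e in self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.subclass_id for e in self.entries]

    def order_index(self, subclass_id: str) -> int:
        return self.ids.index(subclass_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.subclass_id, e.lipo_class, e.size_label, e.diameter_nm) for e in self.entries],
            columns=["subclass_id", "class", "size_label", "diameter_nm"],
        )

    def to_csv(self, path: str | Path) -> None:
        """Export as a small reference CSV (plotting order)."""
        self.to_frame().to_csv(path, index=False)


MEASUREMENT_COLUMNS = ["subject_id", "visit", "metabolite_id", "concentration", "status"]
SUBJECT_REQUIRED = ["subject_id", "arm", "statin", "ezetimibe"]


@dataclasses.dataclass
class CohortDataset:
    """Subject × visit × metabolite records plus subject covariates.

    ``measurements`` is long format (one row per subject/visit/metabolite);
    ``subjects`` has one row per subject.  An optional hidden ``truth``
    frame holds uncensored concentrations for synthetic cohorts; it is
    never serialized by :func:`write_cohort`, so fits cannot peek at it.
    """

    subjects: pd.DataFrame
    measurements: pd.DataFrame
    catalog: SubclassCatalog = dataclasses.field(default_factory=SubclassCatalog)
    truth: pd.DataFrame | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.subjects = _validate_subjects(self.subjects)
        self.measurements = _validate_measurements(self.measurements)
        known = set(self.subjects["subject_id"])
        unknown = set(self.measurements["subject_id"]) - known
        if unknown:
            raise ValidationError(f"measurements reference unknown subjects: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(pd.unique(self.measurements["metabolite_id"]))

    def arm_subjects(self, arm: int) -> list[str]:
        return list(self.subjects.loc[self.subjects["arm"] == arm, "subject_id"])

    def pivot(self, metabolite_id: str, column: str = "concentration") -> pd.DataFrame:
        """Subject × visit wide table for one metabolite (NaN where unobserved)."""
        sub = self.measurements[self.measurements["metabolite_id"] == metabolite_id]
        wide = sub.pivot(index="subject_id", columns="visit", values=column)
        return wide.reindex(index=self.subjects["subject_id"], columns=list(VISITS))

    def status_pivot(self, metabolite_id: str) -> pd.DataFrame:
        sub = self.measurements[self.measurements["metabolite_id"] == metabolite_id]
        wide = sub.pivot(index="subject_id", columns="visit", values="status")
        return wide.reindex(index=self.subjects["subject_id"], columns=list(VISITS))

    def restrict_to_arm(self, arm: int) -> "CohortDataset":
        subj = self.subjects[self.subjects["arm"] == arm].reset_index(drop=True)
        keep = self.measurements["subject_id"].isin(subj["subject_id"])
        meas = self.measurements[keep].reset_index(drop=True)
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["subject_id"].isin(subj["subject_id"])].reset_index(drop=True)
        return CohortDataset(subj, meas, self.catalog, truth)

    def minimal_observed(self, metabolite_id: str) -> float:
        """Smallest observed concentration — the censoring ceiling for below-LOD values."""
        sub = self.measurements[
            (self.measurements["metabolite_id"] == metabolite_id)
            & (self.measurements["status"] == "observed")
        ]
        if sub.empty:
            raise ValidationError(f"no observed values for {metabolite_id}")
        return float(sub["concentration"].min())


def _validate_subjects(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUBJECT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"subjects table missing columns {missing}")
    df = df.copy().reset_index(drop=True)
    if df["subject_id"].duplicated().any():
        raise SchemaError("duplicate subject_id in subjects table")
    for col in ("arm", "statin", "ezetimibe"):
        vals = set(pd.unique(df[col].astype(int)))
        if not vals <= {0, 1}:
            raise ValidationError(f"{col} must be binary 0/1, got {sorted(vals)}")
        df[col] = df[col].astype(int)
    return df


def _validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements table missing columns {missing}")
    df = df.copy().reset_index(drop=True)
    bad_visit = set(pd.unique(df["visit"])) - set(VISITS)
    if bad_visit:
        raise SchemaError(f"unknown visit labels {sorted(bad_visit)}; expected {VISITS}")
    bad_status = set(pd.unique(df["status"])) - set(STATUSES)
    if bad_status:
        raise SchemaError(f"unknown status labels {sorted(bad_status)}")
    if df.duplicated(subset=["subject_id", "visit", "metabolite_id"]).any():
        raise SchemaError("duplicate (subject, visit, metabolite) records")
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    obs = df["status"] == "observed"
    if df.loc[obs, "concentration"].isna().any():
        raise ValidationError("observed record with missing concentration")
    if (df.loc[obs, "concentration"] <= 0).any():
        raise ValidationError(
            "observed concentrations must be strictly positive (record zeros as below_lod)"
        )
    if df.loc[~obs, "concentration"].notna().any():
        raise ValidationError("non-observed record carries a concentration")
    return df


def read_cohort(
    measurements_path: str | Path | io.IOBase,
    subjects_path: str | Path | io.IOBase,
    catalog: SubclassCatalog | None = None,
) -> CohortDataset:
    """Read and validate a cohort from the two canonical CSV files."""
    meas = pd.read_csv(measurements_path, float_precision="round_trip")
    subj = pd.read_csv(subjects_path)
    return CohortDataset(subj, meas, catalog or SubclassCatalog())


def write_cohort(dataset: CohortDataset, measurements_path: str | Path, subjects_path: str | Path) -> None:
    """Write the two canonical CSVs.  The hidden truth channel is not written.

    Observed concentrations round-trip bit-identically (full repr precision).
    """
    meas = dataset.measurements.copy()
    meas["concentration"] = meas["concentration"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    meas.to_csv(measurements_path, index=False)
    dataset.subjects.to_csv(subjects_path, index=False)


def read_wide_measurements(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Convenience reader for wide-format tables; normalizes to long format.

    Expected columns: ``subject_id, visit`` then one column per metabolite.
    Empty cells become ``qc_rejected`` (no LOD information survives a wide
    table); zeros become ``below_lod``.
    """
    wide = pd.read_csv(path)
    for col in ("subject_id", "visit"):
        if col not in wide.columns:
            raise SchemaError(f"wide table missing column {col}")
    long = wide.melt(
        id_vars=["subject_id", "visit"], var_name="metabolite_id", value_name="concentration"
    )
    long["concentration"] = pd.to_numeric(long["concentration"], errors="coerce")
    status = np.where(
        long["concentration"].isna(), "qc_rejected",
        np.where(long["concentration"] == 0, "below_lod", "observed"),
    )
    long["status"] = status
    long.loc[long["status"] != "observed", "concentration"] = np.nan
    return long[MEASUREMENT_COLUMNS]


#: mmol/L → mg/dL multipliers (Lp(a) is nmol/L → mg/dL, a division by 2.5).
_CONVERSIONS = {
    "cholesterol": 38.7,
    "triglycerides": 88.6,
    "lipoprotein_a": 1 / 2.5,
}


def convert_units(value: float, quantity: str, direction: str) -> float:
    """Convert between SI laboratory units and mg/dL.

    cholesterol: mmol/L ×38.7; triglycerides: mmol/L ×88.6;
    lipoprotein_a: nmol/L ÷2.5.
    """
    if quantity not in _CONVERSIONS:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {sorted(_CONVERSIONS)}")
    if direction not in ("to_mg_dl", "from_mg_dl"):
        raise ValueError(f"unknown direction {direction!r}")
    if value < 0:
        raise ValueError("concentration must be non-negative")
    factor = _CONVERSIONS[quantity]
    return value * factor if direction == "to_mg_dl" else value / factor


def friedewald_ldl(total_chol: float, hdl_chol: float, triglycerides: float) -> float:
    """Friedewald estimate of LDL cholesterol, mmol/L convention.

    LDL-C = TC − HDL-C − TG/2.2, valid for TG ≤ 4.52 mmol/L (400 mg/dL);
    above that bound direct measurement is required.
    """
    if min(total_chol, hdl_chol, triglycerides) < 0:
        raise ValueError("inputs must be non-negative")
    if triglycerides > FRIEDEWALD_TG_MAX:
        raise ValueError(
            f"triglycerides {triglycerides} mmol/L exceed {FRIEDEWALD_TG_MAX}: "
            "ultracentrifugation required"
        )
    return total_chol - hdl_chol - triglycerides / 2.2


def standardize_baseline(values: Iterable[float]) -> np.ndarray:
    """Center and scale to mean 0 / sample SD 1 over observed (non-NaN) entries.

    Missing entries propagate as NaN.  Uses the n−1 (sample) SD.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    obs = ~np.isnan(arr)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed values to standardize")
    sd = float(np.std(arr[obs], ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant baseline")
    out = arr.copy()
    out[obs] = (arr[obs] - float(np.mean(arr[obs]))) / sd
    return out
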