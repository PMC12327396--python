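"""Domain types and I/O for multi-dose lactation residue-depletion studies.

Concentration records live in a long-format table: one row per
animal / matrix / study time / replicate, with an explicit censoring state
relative to the assay's limit of detection (LOD) and lower limit of
quantification (LLOQ).  All concentrations are ng/mL, all times are hours on
the study clock (first dose = 0 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PLASMA",
    "MILK",
    "QUANTIFIED",
    "BELOW_LOD",
    "BETWEEN_LOD_LLOQ",
    "MEASURED",
    "SIMULATED",
    "LOD_FILLED",
    "DosingRegimen",
    "AssayLimits",
    "ConcentrationRecord",
    "StudyDataset",
    "ValidationError",
    "FormatError",
    "apply_censoring",
    "depletion_usable_mask",
    "geometric_summary",
    "GeometricSummary",
    "read_dataset",
    "write_dataset",
]

PLASMA = "plasma"
MILK = "milk"
MATRICES = frozenset({PLASMA, MILK})

QUANTIFIED = "quantified"
BELOW_LOD = "below_lod"
BETWEEN_LOD_LLOQ = "between_lod_lloq"
CENSOR_STATES = frozenset({QUANTIFIED, BELOW_LOD, BETWEEN_LOD_LLOQ})

MEASURED = "measured"
SIMULATED = "simulated"
LOD_FILLED = "lod_filled"
PROVENANCE_STATES = frozenset({MEASURED, SIMULATED, LOD_FILLED})

#: column order of the on-disk CSV representation
RECORD_COLUMNS = [
    "animal_id",
    "matrix",
    "time_h",
    "replicate",
    "conc",
    "censor",
    "provenance",
]


class ValidationError(ValueError):
    """A record or dataset violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not have the expected shape."""


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated fixed-interval dosing schedule.

    Parameters
    ----------
    dose_per_kg : float
        Dose per administration, mg/kg body weight.
    interval_tau : float
        Dosing interval tau, hours.
    n_doses : int
        Number of administrations.
    first_dose_time : float
        Study-clock time of the first dose, hours (conventionally 0).
    route_label : str
        Free-text route descriptor (e.g. ``"oral"``).
    """

    dose_per_kg: float = 1.0
    interval_tau: float = 24.0
    n_doses: int = 6
    first_dose_time: float = 0.0
    route_label: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_per_kg <= 0:
            raise ValidationError("dose_per_kg must be positive")
        if self.interval_tau <= 0:
            raise ValidationError("interval_tau must be positive")
        if self.n_doses < 1:
            raise ValidationError("n_doses must be >= 1")

    @property
    def last_dose_time(self) -> float:
        return self.first_dose_time + (self.n_doses - 1) * self.interval_tau

    @property
    def dose_times(self) -> np.ndarray:
        return self.first_dose_time + self.interval_tau * np.arange(self.n_doses)


@dataclass(frozen=True)
class AssayLimits:
    """Analytical limits of the assay, ng/mL."""

    lod: float = 4.0
    lloq: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.lod <= self.lloq):
            raise ValidationError(
                f"require 0 < lod <= lloq, got lod={self.lod}, lloq={self.lloq}"
            )


@dataclass(frozen=True)
class ConcentrationRecord:
    """One (possibly censored) concentration measurement."""

    animal_id: str
    matrix: str
    time_h: float
    replicate: str
    conc: float | None
    censor: str = QUANTIFIED
    provenance: str = MEASURED

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValidationError(f"unknown matrix {self.matrix!r}")
        if self.censor not in CENSOR_STATES:
            raise ValidationError(f"unknown censor state {self.censor!r}")
        if self.provenance not in PROVENANCE_STATES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.time_h < 0:
            raise ValidationError("time_h must be >= 0")
        if self.conc is not None and self.conc < 0:
            raise ValidationError(
                f"negative concentration {self.conc} for {self.animal_id}"
            )
        if self.censor == BELOW_LOD and self.conc is not None:
            # a below-LOD record may carry the true value (simulation) but
            # never a reportable one
            pass


def apply_censoring(conc_true: float, limits: AssayLimits) -> tuple[float | None, str]:
    """Censor a true concentration against the assay limits.

    Returns ``(reported concentration or None, censor flag)``:
    below the LOD the value is not reported; between LOD (inclusive) and
    LLOQ the value is reported but flagged; at or above the LLOQ it is
    fully quantified.
    """
    if conc_true < 0:
        raise ValidationError("concentration must be non-negative")
    if conc_true < limits.lod:
        return None, BELOW_LOD
    if conc_true < limits.lloq:
        return float(conc_true), BETWEEN_LOD_LLOQ
    return float(conc_true), QUANTIFIED


@dataclass(frozen=True)
class GeometricSummary:
    gm: float
    gsd: float | None
    min: float
    max: float
    n: int


def geometric_summary(values: Iterable[float]) -> GeometricSummary:
    """Geometric mean / geometric SD / range of strictly positive values.

    ``gm = exp(mean(ln v))``; ``gsd = exp(sd(ln v))`` with the n-1
    denominator; ``gsd`` is None for a single value.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("geometric_summary requires at least one value")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValidationError("geometric_summary requires positive finite values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else None
    return GeometricSummary(gm=gm, gsd=gsd, min=float(v.min()), max=float(v.max()), n=int(v.size))


@dataclass
class StudyDataset:
    """A full residue-depletion study: regimen, assay limits and records.

    The record table is a pandas DataFrame with columns
    ``animal_id, matrix, time_h, replicate, conc, censor, provenance``;
    ``conc`` is NaN for unreported (below-LOD) measurements.
    """

    regimen: DosingRegimen
    limits: AssayLimits
    frame: pd.DataFrame
    milking_interval: float = 12.0
    first_milking_time: float = 10.0
    body_weights: Mapping[str, float] = field(default_factory=dict)
    true_parameters: pd.DataFrame | None = None  # simulator sidecar, not persisted

    def __post_init__(self) -> None:
        self.frame = _normalise_frame(self.frame)
        self.validate()

    # ------------------------------------------------------------------ api
    def validate(self) -> None:
        df = self.frame
        if not df["matrix"].isin(MATRICES).all():
            bad = sorted(set(df["matrix"]) - MATRICES)
            raise ValidationError(f"unknown matrix value(s): {bad}")
        bad_censor = sorted(set(df["censor"]) - CENSOR_STATES)
        if bad_censor:
            raise ValidationError(f"unknown censor value(s): {bad_censor}")
        bad_prov = sorted(set(df["provenance"]) - PROVENANCE_STATES)
        if bad_prov:
            raise ValidationError(f"unknown provenance value(s): {bad_prov}")
        if (df["time_h"] < 0).any():
            raise ValidationError("negative time_h")
        if (df["conc"].dropna() < 0).any():
            raise ValidationError("negative concentration")
        dup = df.duplicated(subset=["animal_id", "matrix", "time_h", "replicate"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValidationError(
                "duplicate record for "
                f"({first.animal_id}, {first.matrix}, {first.time_h}, {first.replicate})"
            )
        # censor flags must be consistent with the assay limits
        quantified = df["censor"] == QUANTIFIED
        if (df.loc[quantified, "conc"].isna()).any():
            raise ValidationError("quantified record without a concentration")
        if (df.loc[quantified, "conc"] < self.limits.lod).any():
            raise ValidationError("quantified concentration below the LOD")
        between = df["censor"] == BETWEEN_LOD_LLOQ
        if (df.loc[between, "conc"] >= self.limits.lloq).any():
            raise ValidationError("between_lod_lloq concentration at/above the LLOQ")
        if self.body_weights:
            missing = sorted(set(df["animal_id"]) - set(self.body_weights))
            if missing:
                raise ValidationError(f"animals without body weight: {missing}")

    @property
    def animal_ids(self) -> list[str]:
        return sorted(self.frame["animal_id"].unique())

    def matrix_frame(self, matrix: str) -> pd.DataFrame:
        return self.frame[self.frame["matrix"] == matrix]

    def records(self) -> Iterator[ConcentrationRecord]:
        for row in self.frame.itertuples(index=False):
            yield ConcentrationRecord(
                animal_id=row.animal_id,
                matrix=row.matrix,
                time_h=float(row.time_h),
                replicate=str(row.replicate),
                conc=None if pd.isna(row.conc) else float(row.conc),
                censor=row.censor,
                provenance=row.provenance,
            )

    def with_frame(self, frame: pd.DataFrame) -> "StudyDataset":
        return StudyDataset(
            regimen=self.regimen,
            limits=self.limits,
            frame=frame,
            milking_interval=self.milking_interval,
            first_milking_time=self.first_milking_time,
            body_weights=dict(self.body_weights),
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[ConcentrationRecord],
        regimen: DosingRegimen,
        limits: AssayLimits,
        **kwargs,
    ) -> "StudyDataset":
        rows = [
            {
                "animal_id": r.animal_id,
                "matrix": r.matrix,
                "time_h": r.time_h,
                "replicate": r.replicate,
                "conc": np.nan if r.conc is None else r.conc,
                "censor": r.censor,
                "provenance": r.provenance,
            }
            for r in records
        ]
        return cls(regimen=regimen, limits=limits, frame=pd.DataFrame(rows, columns=RECORD_COLUMNS), **kwargs)


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns and c != "provenance"]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    df = df.copy()
    if "provenance" not in df.columns:
        df["provenance"] = MEASURED
    df["animal_id"] = df["animal_id"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    df["time_h"] = df["time_h"].astype(float)
    df["conc"] = pd.to_numeric(df["conc"], errors="raise")
    df = df[RECORD_COLUMNS].reset_index(drop=True)
    return df.sort_values(["matrix", "animal_id", "time_h", "replicate"], kind="stable").reset_index(drop=True)


def depletion_usable_mask(frame: pd.DataFrame, include_measured_bloq: bool = False) -> pd.Series:
    """Rows usable as depletion-regression observations.

    Quantified (at/above-LLOQ) measurements always qualify, as do assigned
    (``lod_filled``) and simulated values; measured concentrations between
    the LOD and the LLOQ are detected-but-not-quantifiable and excluded
    unless ``include_measured_bloq``.  Below-LOD rows never qualify.
    """
    usable = frame["conc"].notna() & (frame["censor"] != BELOW_LOD)
    if not include_measured_bloq:
        usable &= (frame["censor"] == QUANTIFIED) | (frame["provenance"] != MEASURED)
    return usable


def read_dataset(
    path: str | Path,
    regimen: DosingRegimen,
    limits: AssayLimits,
    *,
    milking_interval: float = 12.0,
    first_milking_time: float = 10.0,
    body_weights: Mapping[str, float] | None = None,
) -> StudyDataset:
    """Read a long-format concentration CSV into a validated StudyDataset.

    The CSV must carry a header with at least
    ``animal_id, matrix, time_h, replicate, conc, censor``; empty ``conc``
    fields encode unreported (below-LOD) values.
    """
    try:
        df = pd.read_csv(path, dtype={"animal_id": str, "replicate": str})
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(str(exc)) from exc
    return StudyDataset(
        regimen=regimen,
        limits=limits,
        frame=df,
        milking_interval=milking_interval,
        first_milking_time=first_milking_time,
        body_weights=dict(body_weights or {}),
    )


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write the record table as CSV (nulls as empty fields, lossless)."""
    dataset.frame.to_csv(path, index=False, na_rep="")
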