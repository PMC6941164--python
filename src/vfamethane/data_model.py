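"""Domain types and CSV input/output for rumen VFA / methane-yield datasets.

A dataset is a flat table of individual-cow records nested as
experiment -> treatment -> cow.  Each record carries the molar proportions
of the major ruminal volatile fatty acids (acetate A, propionate P and
total butyrate B, each in mol/100 mol total VFA), optionally the
propionate concentration (mmol/L), and the observed methane yield
(g CH4 per kg dry-matter intake).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "VFAProfile",
    "CowRecord",
    "Dataset",
    "SchemaError",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "summarize",
    "CANONICAL_COLUMNS",
]

#: Canonical CSV column order.  Bracketed (optional) columns are written
#: only when at least one record sets the corresponding field.
CANONICAL_COLUMNS = [
    "experiment_id",
    "treatment_id",
    "cow_id",
    "acetate",
    "propionate",
    "butyrate",
    "methane_yield",
    "propionate_conc",
    "total_vfa_conc",
    "dmi",
]

#: Methane yields outside this range (g CH4/kg DMI) trigger a warning;
#: they are implausible for cattle but not impossible records.
PLAUSIBLE_MY_RANGE = (2.0, 50.0)


class SchemaError(ValueError):
    """A required column is missing or unresolvable in an input file."""


class DataValidationError(ValueError):
    """A cell or record violates a domain invariant."""


@dataclass
class VFAProfile:
    """Molar composition of one rumen-fluid sample.

    Parameters
    ----------
    acetate, propionate, butyrate
        Molar proportions (mol/100 mol total VFA).  Butyrate is *total*
        butyrate, i.e. n-butyrate plus iso-butyrate.  All must be strictly
        positive and sum to at most 100; the remainder is minor VFA
        (valerate, caproate, ...).
    propionate_conc
        Optional propionate concentration in ruminal fluid, mmol/L.
    total_vfa_conc
        Optional total VFA concentration, mmol/L.  When both
        concentrations are present they must be consistent with the
        molar proportion: ``propionate_conc == propionate/100 * total_vfa_conc``.
    """

    acetate: float
    propionate: float
    butyrate: float
    propionate_conc: float | None = None
    total_vfa_conc: float | None = None

    def __post_init__(self) -> None:
        for name in ("acetate", "propionate", "butyrate"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise DataValidationError(f"{name} must be > 0, got {value!r}")
        total = self.acetate + self.propionate + self.butyrate
        if total > 100.0 + 1e-9:
            raise DataValidationError(
                f"acetate + propionate + butyrate = {total:.4f} exceeds "
                "100 mol/100 mol total VFA"
            )
        for name in ("propionate_conc", "total_vfa_conc"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value <= 0):
                raise DataValidationError(f"{name} must be > 0, got {value!r}")
        if self.propionate_conc is not None and self.total_vfa_conc is not None:
            implied = self.propionate / 100.0 * self.total_vfa_conc
            if abs(self.propionate_conc - implied) > 1e-6 * max(abs(implied), 1e-12):
                raise DataValidationError(
                    f"propionate_conc={self.propionate_conc} inconsistent with "
                    f"propionate/100 * total_vfa_conc = {implied:.8f} mmol/L"
                )


@dataclass
class CowRecord:
    """One animal's identifiers, VFA profile and observed methane yield."""

    experiment_id: str
    treatment_id: str
    cow_id: str
    vfa: VFAProfile
    methane_yield: float
    dmi: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.methane_yield) or self.methane_yield <= 0:
            raise DataValidationError(
                f"methane_yield must be > 0, got {self.methane_yield!r}"
            )
        lo, hi = PLAUSIBLE_MY_RANGE
        if not lo <= self.methane_yield <= hi:
            warnings.warn(
                f"methane_yield {self.methane_yield} g/kg DMI outside the "
                f"plausible range [{lo}, {hi}]",
                stacklevel=2,
            )
        if self.dmi is not None and self.dmi <= 0:
            raise DataValidationError(f"dmi must be > 0, got {self.dmi!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.experiment_id, self.treatment_id, self.cow_id)


@dataclass
class Dataset:
    """An ordered collection of cow records with hierarchical identifiers."""

    records: list[CowRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise DataValidationError(
                    f"duplicate (experiment, treatment, cow) key {rec.key}"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def experiment_ids(self) -> list[str]:
        """Distinct experiment identifiers in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.experiment_id not in out:
                out.append(rec.experiment_id)
        return out

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    @property
    def n_treatments(self) -> int:
        return len({(r.experiment_id, r.treatment_id) for r in self.records})

    def subset(self, experiment_ids) -> "Dataset":
        wanted = set(experiment_ids)
        return Dataset(
            records=[r for r in self.records if r.experiment_id in wanted],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame with canonical column names (optional cols included)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "experiment_id": r.experiment_id,
                    "treatment_id": r.treatment_id,
                    "cow_id": r.cow_id,
                    "acetate": r.vfa.acetate,
                    "propionate": r.vfa.propionate,
                    "butyrate": r.vfa.butyrate,
                    "methane_yield": r.methane_yield,
                    "propionate_conc": r.vfa.propionate_conc,
                    "total_vfa_conc": r.vfa.total_vfa_conc,
                    "dmi": r.dmi,
                }
            )
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


_REQUIRED = [
    "experiment_id",
    "treatment_id",
    "cow_id",
    "acetate",
    "propionate",
    "butyrate",
    "methane_yield",
]
_OPTIONAL_NUMERIC = ["propionate_conc", "total_vfa_conc", "dmi"]


def _cell(row: pd.Series, column: str, row_number: int) -> float:
    value = row[column]
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise DataValidationError(
            f"row {row_number}: non-numeric value {value!r} in column {column!r}"
        ) from None
    if math.isnan(out):
        raise DataValidationError(
            f"row {row_number}: missing value in required column {column!r}"
        )
    return out


def read_dataset(path, column_map: dict[str, str] | None = None) -> Dataset:
    """Read a validated :class:`Dataset` from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row (comma separated, UTF-8, "." decimal).
    column_map
        Optional mapping from canonical names (``experiment_id`` ...) to the
        actual header names in the file.

    Columns ``n_butyrate`` and ``iso_butyrate`` are accepted in place of
    ``butyrate`` and summed to total butyrate on read.

    Raises
    ------
    SchemaError
        A required column cannot be resolved.
    DataValidationError
        A cell is non-numeric or a record violates a domain invariant; the
        message carries the offending 1-based data row number.
    """
    frame = pd.read_csv(path, dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        frame = frame.rename(columns=rename)

    if "butyrate" not in frame.columns and {"n_butyrate", "iso_butyrate"} <= set(
        frame.columns
    ):
        frame["butyrate"] = frame["n_butyrate"].astype(float) + frame[
            "iso_butyrate"
        ].astype(float)

    for column in _REQUIRED:
        if column not in frame.columns:
            raise SchemaError(f"required column {column!r} not found in {path}")

    records: list[CowRecord] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        optional: dict[str, float | None] = {}
        for column in _OPTIONAL_NUMERIC:
            if column in frame.columns and pd.notna(row[column]) and str(row[column]) != "":
                optional[column] = _cell(row, column, i)
            else:
                optional[column] = None
        try:
            profile = VFAProfile(
                acetate=_cell(row, "acetate", i),
                propionate=_cell(row, "propionate", i),
                butyrate=_cell(row, "butyrate", i),
                propionate_conc=optional["propionate_conc"],
                total_vfa_conc=optional["total_vfa_conc"],
            )
            record = CowRecord(
                experiment_id=str(row["experiment_id"]),
                treatment_id=str(row["treatment_id"]),
                cow_id=str(row["cow_id"]),
                vfa=profile,
                methane_yield=_cell(row, "methane_yield", i),
                dmi=optional["dmi"],
            )
        except DataValidationError as err:
            raise DataValidationError(f"row {i}: {err}") from None
        records.append(record)
    return Dataset(records=records, provenance=f"read from {path}")


def write_dataset(data: Dataset, path) -> None:
    """Write a dataset to CSV with the canonical header.

    Optional columns are emitted only when at least one record sets them,
    so ``read_dataset(write_dataset(d))`` reproduces ``d`` field for field.
    """
    frame = data.to_frame()
    for column in _OPTIONAL_NUMERIC:
        if frame.empty or frame[column].isna().all():
            frame = frame.drop(columns=[column])
    frame.to_csv(path, index=False, float_format="%.12g")


def summarize(data: Dataset) -> pd.DataFrame:
    """Per-variable descriptive statistics in the style of a study summary table.

    Returns a DataFrame indexed by variable (``methane_yield``, ``acetate``,
    ``propionate``, ``butyrate``) with columns ``mean``, ``sd`` (sample,
    n-1 divisor; NaN for a single record), ``min``, ``max``, plus scalar
    attributes ``n_experiments``, ``n_treatments`` and ``n_records`` in
    ``DataFrame.attrs``.
    """
    if len(data) == 0:
        raise DataValidationError("cannot summarize an empty dataset")
    frame = data.to_frame()
    variables = ["methane_yield", "acetate", "propionate", "butyrate"]
    out = pd.DataFrame(
        {
            "mean": frame[variables].mean(),
            "sd": frame[variables].std(ddof=1),
            "min": frame[variables].min(),
            "max": frame[variables].max(),
        }
    )
    out.attrs["n_experiments"] = data.n_experiments
    out.attrs["n_treatments"] = data.n_treatments
    out.attrs["n_records"] = len(data)
    return out
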