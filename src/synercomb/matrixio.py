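"""Checkerboard assay I/O: reading, validation, normalization and reports.

A checkerboard (combination matrix) crosses increasing concentrations of two
drugs so that every dose pair is measured once per replicate and timepoint.
The long-format CSV schema follows SynergyFinder column semantics:

    block_id, drug_row, drug_col, conc_r, conc_c, conc_unit,
    response, response_scale, time_h, replicate

All synergy computation downstream runs on the % inhibition scale
(0 = untreated, 100 = complete kill); viability inputs are converted on
ingestion.  Concentrations are kept in nM.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "block_id",
    "drug_row",
    "drug_col",
    "conc_r",
    "conc_c",
    "response",
    "response_scale",
    "time_h",
    "replicate",
)

VIABILITY = "viability"
INHIBITION = "inhibition"


class SchemaError(ValueError):
    """Input table does not carry the required columns."""


class ValidationError(ValueError):
    """Input table carries malformed values (negative doses, ragged grids)."""


@dataclass
class ResponseMatrix:
    """One replicate/timepoint checkerboard of % responses on a dose grid.

    ``response[i, j]`` is the measured % response at
    ``(doses_row[i], doses_col[j])``.  A dose of 0 denotes the vehicle
    control; the (0, 0) cell, when present, is the untreated control.
    """

    drug_row_name: str
    drug_col_name: str
    doses_row: np.ndarray
    doses_col: np.ndarray
    response: np.ndarray
    response_scale: str = INHIBITION
    timepoint_h: float = 0.0
    replicate_id: int = 1
    assay_label: str = ""

    def __post_init__(self) -> None:
        self.doses_row = np.asarray(self.doses_row, dtype=float)
        self.doses_col = np.asarray(self.doses_col, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (len(self.doses_row), len(self.doses_col)):
            raise ValidationError(
                f"response grid {self.response.shape} does not match dose axes "
                f"({len(self.doses_row)}, {len(self.doses_col)})"
            )
        for name, doses in (("row", self.doses_row), ("col", self.doses_col)):
            if np.any(doses < 0):
                raise ValidationError(f"negative concentration on {name} axis")
            if np.any(np.diff(doses) <= 0):
                raise ValidationError(f"{name} doses must be strictly increasing")
        if self.response_scale not in (VIABILITY, INHIBITION):
            raise ValidationError(f"unknown response scale {self.response_scale!r}")
        if self.timepoint_h < 0:
            raise ValidationError("timepoint must be >= 0 h")

    @property
    def has_control_cell(self) -> bool:
        return self.doses_row[0] == 0 and self.doses_col[0] == 0

    def to_inhibition(self) -> "ResponseMatrix":
        """Return the matrix on the % inhibition scale (identity if already)."""
        if self.response_scale == INHIBITION:
            return self
        out = self.copy()
        out.response = 100.0 - self.response
        out.response_scale = INHIBITION
        return out

    def clipped(self) -> "ResponseMatrix":
        """Inhibition clipped to [0, 100]; required by probabilistic models."""
        out = self.to_inhibition()
        out = out.copy()
        out.response = np.clip(out.response, 0.0, 100.0)
        return out

    def transposed(self) -> "ResponseMatrix":
        return ResponseMatrix(
            drug_row_name=self.drug_col_name,
            drug_col_name=self.drug_row_name,
            doses_row=self.doses_col.copy(),
            doses_col=self.doses_row.copy(),
            response=self.response.T.copy(),
            response_scale=self.response_scale,
            timepoint_h=self.timepoint_h,
            replicate_id=self.replicate_id,
            assay_label=self.assay_label,
        )

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            drug_row_name=self.drug_row_name,
            drug_col_name=self.drug_col_name,
            doses_row=self.doses_row.copy(),
            doses_col=self.doses_col.copy(),
            response=self.response.copy(),
            response_scale=self.response_scale,
            timepoint_h=self.timepoint_h,
            replicate_id=self.replicate_id,
            assay_label=self.assay_label,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table in the input CSV schema."""
        rr, cc = np.meshgrid(
            np.arange(len(self.doses_row)), np.arange(len(self.doses_col)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "block_id": 1,
                "drug_row": self.drug_row_name,
                "drug_col": self.drug_col_name,
                "conc_r": self.doses_row[rr.ravel()],
                "conc_c": self.doses_col[cc.ravel()],
                "conc_unit": "nM",
                "response": self.response.ravel(),
                "response_scale": self.response_scale,
                "time_h": self.timepoint_h,
                "replicate": self.replicate_id,
            }
        )


def read_checkerboard(
    path, dialect: dict | None = None
) -> list[ResponseMatrix]:
    """Read a long-format checkerboard CSV into one matrix per
    (block, timepoint, replicate).

    Doses are sorted ascending.  Duplicate (dose, dose) cells within a
    block/timepoint/replicate are averaged with a logged warning.  A
    ``conc_multiplier`` in *dialect* rescales concentrations to nM.
    """
    dialect = dialect or {}
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    mult = float(dialect.get("conc_multiplier", 1.0))
    df = df.copy()
    df["conc_r"] = df["conc_r"].astype(float) * mult
    df["conc_c"] = df["conc_c"].astype(float) * mult
    if (df["conc_r"] < 0).any() or (df["conc_c"] < 0).any():
        raise ValidationError("negative concentration in input")

    matrices: list[ResponseMatrix] = []
    for (block, time_h, rep), grp in df.groupby(
        ["block_id", "time_h", "replicate"], sort=True
    ):
        dup = grp.duplicated(subset=["conc_r", "conc_c"], keep=False)
        if dup.any():
            logger.warning(
                "block %s t=%s rep=%s: %d duplicate dose cells averaged",
                block, time_h, rep, int(dup.sum()),
            )
            grp = (
                grp.groupby(["conc_r", "conc_c"], as_index=False)
                .agg(
                    {
                        "response": "mean",
                        "drug_row": "first",
                        "drug_col": "first",
                        "response_scale": "first",
                    }
                )
            )
        doses_row = np.sort(grp["conc_r"].unique())
        doses_col = np.sort(grp["conc_c"].unique())
        pivot = grp.pivot(index="conc_r", columns="conc_c", values="response")
        pivot = pivot.reindex(index=doses_row, columns=doses_col)
        if pivot.isna().any().any():
            cells = [
                (float(r), float(c))
                for r in doses_row
                for c in doses_col
                if pd.isna(pivot.loc[r, c])
            ]
            raise ValidationError(
                f"block {block}: non-rectangular grid, missing cells {cells}"
            )
        scales = grp["response_scale"].unique()
        if len(scales) != 1:
            raise ValidationError(f"block {block}: mixed response scales {scales}")
        matrices.append(
            ResponseMatrix(
                drug_row_name=str(grp["drug_row"].iloc[0]),
                drug_col_name=str(grp["drug_col"].iloc[0]),
                doses_row=doses_row,
                doses_col=doses_col,
                response=pivot.to_numpy(dtype=float),
                response_scale=str(scales[0]),
                timepoint_h=float(time_h),
                replicate_id=int(rep),
                assay_label=str(dialect.get("assay_label", "")),
            )
        )
    return matrices


def write_checkerboard(matrices: Iterable[ResponseMatrix], path) -> None:
    """Write matrices back to the long-format CSV schema (read round-trips)."""
    frames = []
    for i, m in enumerate(matrices, start=1):
        long = m.to_long()
        long["block_id"] = i if long["block_id"].nunique() == 1 else long["block_id"]
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def normalize(matrix: ResponseMatrix, control: float | str = "auto") -> ResponseMatrix:
    """Normalize a raw-signal matrix to % viability and convert to inhibition.

    *control* is either an external control signal (> 0) or ``"auto"`` to use
    the (0, 0) untreated cell.  viability% = 100 * signal / control;
    inhibition% = 100 - viability%, clipped to [0, 100].
    """
    if matrix.response_scale == INHIBITION:
        warnings.warn("matrix already on inhibition scale; normalize is identity")
        return matrix.copy()
    if control == "auto":
        if not matrix.has_control_cell:
            raise ValidationError("no (0, 0) control cell; supply a control signal")
        control_value = float(matrix.response[0, 0])
    else:
        control_value = float(control)
    if control_value <= 0:
        raise ValidationError("control signal must be > 0")
    viability = 100.0 * matrix.response / control_value
    inhibition = 100.0 - viability
    if (inhibition < 0).any() or (inhibition > 100).any():
        warnings.warn("inhibition outside [0, 100] clipped")
    out = matrix.copy()
    out.response = np.clip(inhibition, 0.0, 100.0)
    out.response_scale = INHIBITION
    return out


# ---------------------------------------------------------------------------
# analysis report


@dataclass
class AnalysisReport:
    """Structured analysis output: per-matrix scores plus aggregation tables.

    Non-finite fit values serialize as explicit nulls with a flag so the JSON
    round-trips losslessly.
    """

    per_matrix: list[dict] = field(default_factory=list)
    aggregates: dict[str, Any] = field(default_factory=dict)
    classifications: list[dict] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_matrix": _encode(self.per_matrix),
            "aggregates": _encode(self.aggregates),
            "classifications": _encode(self.classifications),
            "provenance": _encode(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(
            per_matrix=_decode(d.get("per_matrix", [])),
            aggregates=_decode(d.get("aggregates", {})),
            classifications=_decode(d.get("classifications", [])),
            provenance=_decode(d.get("provenance", {})),
        )


_NONFINITE = {"nan": float("nan"), "inf": float("inf"), "-inf": float("-inf")}


def _encode(obj):
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return {"__array__": True, "data": _encode(obj.tolist())}
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if not np.isfinite(f):
            name = "nan" if np.isnan(f) else ("inf" if f > 0 else "-inf")
            return {"__nonfinite__": name, "value": None}
        return f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if obj.get("__array__"):
            return np.asarray(_decode(obj["data"]))
        if "__nonfinite__" in obj:
            return _NONFINITE[obj["__nonfinite__"]]
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_report(report: AnalysisReport, path) -> None:
    """Serialize a report to JSON with stable field order."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> AnalysisReport:
    with open(path) as fh:
        return AnalysisReport.from_dict(json.load(fh))
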