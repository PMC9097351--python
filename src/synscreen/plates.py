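"""Plate-format screening IO, viability normalization, and Z'-factor QC.

A screening plate is stored long-format, one row per well, with a role
marking each well as part of the dose matrix (``sample``), vehicle control
(``neg_ctrl``), cytotoxic positive control (``pos_ctrl``), or cell-free
blank (``blank``).  Raw optical densities are normalized to percent-of-
vehicle viability; plate robustness is summarized by the Z'-factor on the
control wells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    IncompleteBlockError,
    InputFormatError,
    InsufficientControlsError,
    UndefinedSeparationError,
)

PLATE_COLUMNS = [
    "plate_id", "row", "col", "compound_a", "dose_a",
    "compound_b", "dose_b", "role", "od",
]
ROLES = frozenset({"sample", "neg_ctrl", "pos_ctrl", "blank"})


@dataclass(frozen=True)
class WellRecord:
    """One well of a screening plate (doses in μM, od dimensionless)."""

    plate_id: str
    row: int
    col: int
    compound_a: str
    dose_a: float
    compound_b: str
    dose_b: float
    role: str
    od: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InputFormatError(
                f"well ({self.plate_id},{self.row},{self.col}): unknown role {self.role!r}"
            )
        if self.dose_a < 0 or self.dose_b < 0:
            raise InputFormatError(
                f"well ({self.plate_id},{self.row},{self.col}): negative dose"
            )
        if self.od < 0:
            raise InputFormatError(
                f"well ({self.plate_id},{self.row},{self.col}): negative OD"
            )
        if self.role in ("neg_ctrl", "pos_ctrl") and (self.dose_a > 0 or self.dose_b > 0):
            raise InputFormatError(
                f"well ({self.plate_id},{self.row},{self.col}): control well with "
                "nonzero library dose"
            )


@dataclass(frozen=True)
class PlateQC:
    """Control-well summary and Z'-factor pass/fail for one plate."""

    plate_id: str
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    z_factor: float
    passed: bool


@dataclass
class DoseMatrix:
    """One compound-pair checkerboard in percent-of-vehicle viability.

    ``doses_a`` and ``doses_b`` are strictly ascending and begin with the
    vehicle level 0; ``viability`` has shape ``(len(doses_a), len(doses_b))``
    with the vehicle cell ``viability[0, 0] == 100`` by construction.
    """

    compound_a: str
    compound_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    cell_line: str = ""
    replicate: int = 1
    plate_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise InputFormatError("dose vectors must begin with the vehicle level 0")
        if np.any(np.diff(self.doses_a) <= 0) or np.any(np.diff(self.doses_b) <= 0):
            raise InputFormatError("dose vectors must be strictly ascending")
        if self.viability.shape != (self.doses_a.size, self.doses_b.size):
            raise InputFormatError("viability grid shape does not match dose vectors")

    @property
    def n_combo_wells(self) -> int:
        return (self.doses_a.size - 1) * (self.doses_b.size - 1)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format view: one row per well with both doses and viability."""
        ia, ib = np.meshgrid(
            np.arange(self.doses_a.size), np.arange(self.doses_b.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "compound_a": self.compound_a,
                "compound_b": self.compound_b,
                "cell_line": self.cell_line,
                "dose_a": self.doses_a[ia.ravel()],
                "dose_b": self.doses_b[ib.ravel()],
                "viability": self.viability.ravel(),
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "compound_a": self.compound_a,
            "compound_b": self.compound_b,
            "cell_line": self.cell_line,
            "replicate": self.replicate,
            "plate_id": self.plate_id,
            "doses_a": self.doses_a.tolist(),
            "doses_b": self.doses_b.tolist(),
            "viability": self.viability.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "DoseMatrix":
        return cls(
            compound_a=d["compound_a"],
            compound_b=d["compound_b"],
            doses_a=np.array(d["doses_a"]),
            doses_b=np.array(d["doses_b"]),
            viability=np.array(d["viability"]),
            cell_line=d.get("cell_line", ""),
            replicate=d.get("replicate", 1),
            plate_id=d.get("plate_id", ""),
        )


def read_plate_table(path: str | Path) -> list[WellRecord]:
    """Read a long-format plate CSV into validated :class:`WellRecord` objects.

    Required columns: ``plate_id,row,col,compound_a,dose_a,compound_b,dose_b,
    role,od``.  Duplicate well addresses and unparseable doses are rejected
    with the offending row named.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"plate_id": str, "compound_a": str, "compound_b": str},
            float_precision="round_trip",
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise InputFormatError(f"cannot read plate table {path}: {exc}") from exc
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    for col in ("plate_id", "compound_a", "compound_b"):
        df[col] = df[col].fillna("")  # control wells carry empty compound names
    for col in ("dose_a", "dose_b", "od"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise InputFormatError(
                f"{path}: unparseable {col} at data row {bad + 1}"
            ) from exc
    dup = df.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(df.loc[df.index[i], ["plate_id", "row", "col"]])
        raise InputFormatError(f"{path}: duplicate well address {key} at data row {i + 1}")
    return [
        WellRecord(
            plate_id=str(r.plate_id), row=int(r.row), col=int(r.col),
            compound_a=str(r.compound_a), dose_a=float(r.dose_a),
            compound_b=str(r.compound_b), dose_b=float(r.dose_b),
            role=str(r.role), od=float(r.od),
        )
        for r in df.itertuples(index=False)
    ]


def write_plate_table(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write well records in the exact CSV dialect :func:`read_plate_table` expects.

    Floats are written with ``repr`` (shortest round-trip form) so a
    write-read cycle reproduces the records bit-identically.
    """
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PLATE_COLUMNS)
        for r in records:
            w.writerow([r.plate_id, r.row, r.col, r.compound_a, repr(r.dose_a),
                        r.compound_b, repr(r.dose_b), r.role, repr(r.od)])


def z_factor(pos_ods: Sequence[float], neg_ods: Sequence[float]) -> float:
    """Z'-factor: ``1 - 3*(sd_pos + sd_neg) / |mu_pos - mu_neg|``.

    Standard deviations are sample SDs (ddof=1).  Z' <= 1 always, with
    equality iff both control populations have zero spread.  The statistic
    is invariant under any affine OD transform with positive scale.
    """
    pos = np.asarray(pos_ods, dtype=float)
    neg = np.asarray(neg_ods, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientControlsError(
            f"need >= 2 control wells per side, got {pos.size} pos / {neg.size} neg"
        )
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise UndefinedSeparationError("positive and negative control means coincide")
    # SDs on shifted values: exact 0 for constant controls, so Z' = 1 exactly
    sd_p = (pos - pos[0]).std(ddof=1)
    sd_n = (neg - neg[0]).std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


def plate_qc(records: Iterable[WellRecord], z_min: float = 0.6) -> PlateQC:
    """Compute control summaries and the Z'-factor for one plate's records."""
    recs = list(records)
    plate_id = recs[0].plate_id if recs else ""
    pos = np.array([r.od for r in recs if r.role == "pos_ctrl"])
    neg = np.array([r.od for r in recs if r.role == "neg_ctrl"])
    z = z_factor(pos, neg)
    return PlateQC(
        plate_id=plate_id,
        mu_pos=float(pos.mean()), sd_pos=float(pos.std(ddof=1)),
        mu_neg=float(neg.mean()), sd_neg=float(neg.std(ddof=1)),
        z_factor=z, passed=bool(z > z_min),
    )


def qc_table(qcs: Iterable[PlateQC]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"plate_id": q.plate_id, "z_factor": q.z_factor, "passed": q.passed} for q in qcs]
    )


def normalize_matrix(
    records: Iterable[WellRecord],
    qc: PlateQC | None = None,
    *,
    force: bool = False,
    cell_line: str = "",
    replicate: int = 1,
) -> DoseMatrix:
    """Assemble one checkerboard block and normalize OD to percent viability.

    viability = 100 * (od - blank_mean) / (vehicle_mean - blank_mean), clipped
    below at 0 and not clipped above (stimulation above vehicle is retained).
    The vehicle cell is set to 100 exactly.  Blank wells are optional and
    default to a blank mean of 0.

    Raises :class:`IncompleteBlockError` if any grid position has no well:
    missing wells are never imputed.
    """
    recs = list(records)
    if qc is not None and not qc.passed and not force:
        raise IncompleteBlockError(
            f"plate {qc.plate_id} failed QC (Z'={qc.z_factor:.3f}); "
            "pass force=True to normalize anyway"
        )
    samples = [r for r in recs if r.role == "sample"]
    vehicles = [r.od for r in recs if r.role == "neg_ctrl"]
    blanks = [r.od for r in recs if r.role == "blank"]
    if not samples or not vehicles:
        raise IncompleteBlockError("block needs sample wells and >= 1 vehicle control")
    blank_mean = float(np.mean(blanks)) if blanks else 0.0
    veh_mean = float(np.mean(vehicles))
    if veh_mean <= blank_mean:
        raise DegenerateControlError(
            f"vehicle mean OD {veh_mean:.4g} <= blank mean {blank_mean:.4g}"
        )
    compound_a = samples[0].compound_a
    compound_b = samples[0].compound_b
    plate_id = samples[0].plate_id
    doses_a = np.array(sorted({r.dose_a for r in samples} | {0.0}))
    doses_b = np.array(sorted({r.dose_b for r in samples} | {0.0}))
    grid_sum = np.zeros((doses_a.size, doses_b.size))
    grid_n = np.zeros_like(grid_sum)
    ia = {d: i for i, d in enumerate(doses_a)}
    ib = {d: j for j, d in enumerate(doses_b)}
    for r in samples:
        grid_sum[ia[r.dose_a], ib[r.dose_b]] += r.od
        grid_n[ia[r.dose_a], ib[r.dose_b]] += 1
    grid_n[0, 0] = 1  # vehicle position is filled from neg_ctrl wells below
    grid_sum[0, 0] = veh_mean
    if np.any(grid_n == 0):
        i, j = np.argwhere(grid_n == 0)[0]
        raise IncompleteBlockError(
            f"plate {plate_id}: no well at dose_a={doses_a[i]:g}, dose_b={doses_b[j]:g} μM"
        )
    od = grid_sum / grid_n
    viability = 100.0 * (od - blank_mean) / (veh_mean - blank_mean)
    viability = np.clip(viability, 0.0, None)
    viability[0, 0] = 100.0
    return DoseMatrix(
        compound_a=compound_a, compound_b=compound_b,
        doses_a=doses_a, doses_b=doses_b, viability=viability,
        cell_line=cell_line, replicate=replicate, plate_id=plate_id,
    )


def group_blocks(records: Iterable[WellRecord]) -> dict[str, list[WellRecord]]:
    """Split a record stream into per-plate blocks keyed by plate_id."""
    blocks: dict[str, list[WellRecord]] = {}
    for r in records:
        blocks.setdefault(r.plate_id, []).append(r)
    return blocks


def write_matrices_json(matrices: Iterable[DoseMatrix], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([m.to_json_dict() for m in matrices], indent=1) + "\n"
    )


def read_matrices_json(path: str | Path) -> list[DoseMatrix]:
    return [DoseMatrix.from_json_dict(d) for d in json.loads(Path(path).read_text())]
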