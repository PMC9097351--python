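"""ExcessHSA / Bliss-excess synergy scoring, classification, and ranking.

Each checkerboard is scored on the percent-viability scale with negative
excess meaning synergy:

* ExcessHSA — per combination well, observed viability minus the lower
  (more effective) of the two single-agent viabilities at the well's
  marginal doses; the matrix score is the SUM over combination wells.
* Bliss excess — observed viability minus the Bliss-independence
  expectation ``V_a * V_b / 100`` of the marginal survival fractions.

A matrix is called synergistic when the ExcessHSA sum falls below the lower
threshold (default -20), antagonistic above the upper (+20), additive on
the closed interval in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncompleteBlockError, OutOfRangeError
from .plates import DoseMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (-20.0, 20.0)


@dataclass
class SynergyScore:
    """Per-well excess grids and matrix-sum scores for one checkerboard."""

    compound_a: str
    compound_b: str
    cell_line: str
    excess_hsa_grid: np.ndarray
    excess_bliss_grid: np.ndarray
    excess_hsa_sum: float
    excess_bliss_sum: float
    interaction_class: str
    plate_id: str = ""
    metadata: dict = field(default_factory=dict)


def excess_hsa_grid(matrix: DoseMatrix) -> np.ndarray:
    """Per-combination-well excess over the highest-single-agent reference.

    Returns an ``(n_a - 1) x (n_b - 1)`` grid (combination wells only):
    ``excess[i-1, j-1] = V[i, j] - min(V[i, 0], V[0, j])``.
    """
    _check_margins(matrix)
    v = matrix.viability
    hsa_ref = np.minimum.outer(v[1:, 0], v[0, 1:])
    return v[1:, 1:] - hsa_ref


def excess_bliss_grid(matrix: DoseMatrix) -> np.ndarray:
    """Per-combination-well deviation from the Bliss-independence expectation
    ``V_exp[i, j] = V[i, 0] * V[0, j] / 100``."""
    _check_margins(matrix)
    v = matrix.viability
    expected = np.outer(v[1:, 0], v[0, 1:]) / 100.0
    return v[1:, 1:] - expected


def _check_margins(matrix: DoseMatrix) -> None:
    if matrix.doses_a.size < 2 or matrix.doses_b.size < 2:
        raise IncompleteBlockError("matrix needs single-agent margins on both axes")
    if not np.all(np.isfinite(matrix.viability)):
        raise IncompleteBlockError("matrix has non-finite viability values")


def classify_interaction(
    score: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify an ExcessHSA sum: synergistic below ``lo``, antagonistic
    above ``hi``, additive on the closed interval ``[lo, hi]``."""
    lo, hi = thresholds
    if lo >= hi:
        raise OutOfRangeError(f"thresholds must satisfy lo < hi, got {thresholds}")
    if not np.isfinite(score):
        raise OutOfRangeError(f"score must be finite, got {score}")
    if score < lo:
        return "synergistic"
    if score > hi:
        return "antagonistic"
    return "additive"


def score_matrix(
    matrix: DoseMatrix, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> SynergyScore:
    """Compute both excess grids, their sums, and the interaction class."""
    hsa = excess_hsa_grid(matrix)
    bliss = excess_bliss_grid(matrix)
    hsa_sum = float(hsa.sum())
    return SynergyScore(
        compound_a=matrix.compound_a,
        compound_b=matrix.compound_b,
        cell_line=matrix.cell_line,
        excess_hsa_grid=hsa,
        excess_bliss_grid=bliss,
        excess_hsa_sum=hsa_sum,
        excess_bliss_sum=float(bliss.sum()),
        interaction_class=classify_interaction(hsa_sum, thresholds),
        plate_id=matrix.plate_id,
    )


@dataclass
class RankEntry:
    """One library compound in the synergy ranking (most negative = rank 1)."""

    compound: str
    moa_class: str
    per_cell_line: dict[str, float]
    average_excess_hsa: float
    rank: int
    interaction_class: str


def rank_compounds(
    scores: list[SynergyScore],
    annotations: dict[str, str] | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    *,
    key: str = "compound_b",
) -> list[RankEntry]:
    """Average ExcessHSA sums per library compound across cell lines and rank.

    ``scores`` should contain only matrices from QC-passing plates; failed
    plates are dropped upstream so a compound's average uses its remaining
    cell lines.  Ranking is ascending (most synergistic first) with a
    deterministic lexicographic tie-break on compound name.  Compounds
    missing from ``annotations`` are labelled ``unannotated`` with a logged
    warning.
    """
    annotations = annotations or {}
    per: dict[str, dict[str, float]] = {}
    for s in scores:
        compound = getattr(s, "compound_b" if key == "compound_b" else "compound_a")
        per.setdefault(compound, {})[s.cell_line] = s.excess_hsa_sum
    entries = []
    for compound, by_line in per.items():
        if compound not in annotations:
            logger.warning("compound %r missing from annotation table", compound)
        avg = float(np.mean(list(by_line.values())))
        entries.append(
            RankEntry(
                compound=compound,
                moa_class=annotations.get(compound, "unannotated"),
                per_cell_line=dict(sorted(by_line.items())),
                average_excess_hsa=avg,
                rank=0,
                interaction_class=classify_interaction(avg, thresholds),
            )
        )
    entries.sort(key=lambda e: (e.average_excess_hsa, e.compound))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return entries


def class_average(entries: list[RankEntry]) -> dict[str, float]:
    """Arithmetic mean of average ExcessHSA per mechanism-of-action class."""
    by_class: dict[str, list[float]] = {}
    for e in entries:
        by_class.setdefault(e.moa_class, []).append(e.average_excess_hsa)
    return {c: float(np.mean(v)) for c, v in sorted(by_class.items())}


def rank_table(entries: list[RankEntry]) -> pd.DataFrame:
    """Ranked table: compound, MoA class, per-cell-line sums, average, class."""
    cell_lines = sorted({cl for e in entries for cl in e.per_cell_line})
    rows = []
    for e in entries:
        row = {"rank": e.rank, "compound": e.compound, "moa_class": e.moa_class}
        for cl in cell_lines:
            row[cl] = e.per_cell_line.get(cl, np.nan)
        row["average_excess_hsa"] = e.average_excess_hsa
        row["interaction_class"] = e.interaction_class
        rows.append(row)
    return pd.DataFrame(rows)


def excess_table(score: SynergyScore, matrix: DoseMatrix) -> pd.DataFrame:
    """Well-level long-format table of both excess grids for one matrix."""
    ia, ib = np.meshgrid(
        np.arange(1, matrix.doses_a.size), np.arange(1, matrix.doses_b.size),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "dose_a": matrix.doses_a[ia.ravel()],
            "dose_b": matrix.doses_b[ib.ravel()],
            "viability": matrix.viability[1:, 1:].ravel(),
            "excess_hsa": score.excess_hsa_grid.ravel(),
            "excess_bliss": score.excess_bliss_grid.ravel(),
        }
    )
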