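"""Tumor growth inhibition (TGI) and the immuno-reactive score (IRS).

TGI compares arm-mean tumor volume changes between a treated and a control
(vehicle) xenograft arm::

    TGI% = 100 * [1 - (TVf_t - TVi_t) / (TVf_c - TVi_c)]

where TVi / TVf are mean volumes at the first and last measurement days
shared by both arms.  TGI > 60% marks a responder arm; TGI > 100% net
regression (both strict).

IRS summarizes immunohistochemistry staining as intensity (0-3) times the
positive-cell percentage category (0-4), giving an integer score 0-12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputFormatError, OutOfRangeError, UndefinedTGIError

logger = logging.getLogger(__name__)

RESPONDER_MIN = 60.0
REGRESSION_MIN = 100.0


@dataclass
class GrowthCurve:
    """Per-animal tumor-volume time series (days from treatment start, mm³)."""

    animal_id: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.size < 2:
            raise InputFormatError(f"animal {self.animal_id}: needs >= 2 timepoints")
        if np.any(np.diff(self.days) <= 0):
            raise InputFormatError(
                f"animal {self.animal_id}: timepoints must be strictly increasing"
            )
        if np.any(self.volumes <= 0):
            raise InputFormatError(f"animal {self.animal_id}: volumes must be > 0")


@dataclass(frozen=True)
class TGIResult:
    """Arm-level TGI with responder / regression flags."""

    arm: str
    tvi_treated: float
    tvf_treated: float
    tvi_control: float
    tvf_control: float
    tgi: float
    responder: bool
    regression: bool
    day_start: float
    day_end: float
    n_treated: int
    n_control: int


def read_growth_table(path: str | Path) -> list[GrowthCurve]:
    """Read per-animal growth curves from CSV (animal_id, arm, day, volume_mm3)."""
    df = pd.read_csv(path)
    required = ["animal_id", "arm", "day", "volume_mm3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    curves = []
    for (animal, arm), g in df.groupby(["animal_id", "arm"], sort=True):
        g = g.sort_values("day")
        curves.append(
            GrowthCurve(
                animal_id=str(animal), arm=str(arm),
                days=g["day"].to_numpy(float), volumes=g["volume_mm3"].to_numpy(float),
            )
        )
    return curves


def write_growth_table(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = [
        {"animal_id": c.animal_id, "arm": c.arm, "day": d, "volume_mm3": v}
        for c in curves
        for d, v in zip(c.days, c.volumes)
    ]
    pd.DataFrame(rows, columns=["animal_id", "arm", "day", "volume_mm3"]).to_csv(
        path, index=False
    )


def _arm_mean(curves: Sequence[GrowthCurve], day: float) -> tuple[float, int]:
    """Mean volume across animals measured at ``day``; animals without that
    day (removed early) are excluded with a logged count."""
    vols = []
    dropped = 0
    for c in curves:
        hit = np.flatnonzero(c.days == day)
        if hit.size:
            vols.append(c.volumes[hit[0]])
        else:
            dropped += 1
    if dropped:
        logger.warning("%d animal(s) in arm %r missing day %g; excluded from mean",
                       dropped, curves[0].arm, day)
    if not vols:
        raise AlignmentError(f"no animal in arm {curves[0].arm!r} measured at day {day:g}")
    return float(np.mean(vols)), len(vols)


def tgi(
    treated: Sequence[GrowthCurve],
    control: Sequence[GrowthCurve],
    *,
    responder_min: float = RESPONDER_MIN,
    regression_min: float = REGRESSION_MIN,
) -> TGIResult:
    """Tumor growth inhibition of a treated arm against a control arm.

    Start and end are the first and last days present in both arms'
    measurement schedules; means at those days are taken across the animals
    still measured.  The statistic is invariant under any positive
    rescaling of all volumes.
    """
    if not treated or not control:
        raise AlignmentError("both arms must be non-empty")
    days_t = set().union(*(c.days.tolist() for c in treated))
    days_c = set().union(*(c.days.tolist() for c in control))
    shared = sorted(days_t & days_c)
    if len(shared) < 2:
        raise AlignmentError(
            f"arms {treated[0].arm!r} and {control[0].arm!r} share "
            f"{len(shared)} measurement day(s); need >= 2"
        )
    d0, d1 = shared[0], shared[-1]
    tvi_t, n_t0 = _arm_mean(treated, d0)
    tvf_t, n_t = _arm_mean(treated, d1)
    tvi_c, _ = _arm_mean(control, d0)
    tvf_c, n_c = _arm_mean(control, d1)
    delta_c = tvf_c - tvi_c
    if delta_c == 0:
        raise UndefinedTGIError(
            f"control arm {control[0].arm!r} shows zero net volume change"
        )
    value = 100.0 * (1.0 - (tvf_t - tvi_t) / delta_c)
    responder, regression = classify_response(
        value, responder_min=responder_min, regression_min=regression_min
    )
    return TGIResult(
        arm=treated[0].arm,
        tvi_treated=tvi_t, tvf_treated=tvf_t,
        tvi_control=tvi_c, tvf_control=tvf_c,
        tgi=value, responder=responder, regression=regression,
        day_start=d0, day_end=d1, n_treated=n_t, n_control=n_c,
    )


def classify_response(
    tgi_pct: float,
    *,
    responder_min: float = RESPONDER_MIN,
    regression_min: float = REGRESSION_MIN,
) -> tuple[bool, bool]:
    """(responder, regression) flags at strict thresholds (default 60 / 100)."""
    if not np.isfinite(tgi_pct):
        raise OutOfRangeError(f"TGI must be finite, got {tgi_pct}")
    return bool(tgi_pct > responder_min), bool(tgi_pct > regression_min)


def tgi_table(arms: dict[str, Sequence[GrowthCurve]], control_arm: str,
              **thresholds) -> pd.DataFrame:
    """TGI for every non-control arm against the named control arm."""
    if control_arm not in arms:
        raise AlignmentError(f"control arm {control_arm!r} not present")
    rows = []
    for name in sorted(arms):
        if name == control_arm:
            continue
        r = tgi(arms[name], arms[control_arm], **thresholds)
        rows.append({"arm": name, "tgi_pct": r.tgi,
                     "responder": r.responder, "regression": r.regression})
    return pd.DataFrame(rows)


def pct_positive_category(pct: float) -> int:
    """Positive-cell percentage category: 0%=0, 1-10%=1, 11-50%=2, 51-80%=3,
    81-100%=4.  Fractional percentages in (0, 1) round up to category 1."""
    if not 0 <= pct <= 100:
        raise OutOfRangeError(f"percentage must lie in [0, 100], got {pct}")
    if pct == 0:
        return 0
    if pct <= 10:
        return 1
    if pct <= 50:
        return 2
    if pct <= 80:
        return 3
    return 4


def irs(intensity: int, pct_positive: float) -> int:
    """Immuno-reactive score: staining intensity (0-3) times percentage
    category (0-4); integer in 0-12."""
    if intensity not in (0, 1, 2, 3):
        raise OutOfRangeError(f"intensity must be an integer 0-3, got {intensity}")
    return int(intensity) * pct_positive_category(pct_positive)


def volume_from_caliper(length_mm: float, width_mm: float) -> float:
    """Optional ellipsoid convention ``V = L * W^2 / 2`` (mm³).  Provided as
    a labelled convenience only; the pipeline itself consumes volumes."""
    if length_mm <= 0 or width_mm <= 0:
        raise OutOfRangeError("caliper measurements must be positive")
    return length_mm * width_mm**2 / 2.0
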