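"""Synthetic checkerboard screens and xenograft growth arms with known truth.

Checkerboard plates are built from parametric response surfaces: each
single agent follows the median-effect equation ``fa = 1/(1 + (Dm/D)^m)``,
and the combination inhibition is the Bliss expectation
``fa_a + fa_b - fa_a*fa_b`` plus a synergy offset δ on the inhibition
scale (δ > 0 synergy, δ < 0 antagonism, 0 exactly Bliss-null), clipped to
[0, 1].  Optical densities carry multiplicative lognormal noise, the
plate-reader-like model that keeps signals positive and scale-free.

Xenograft arms grow exponentially, ``V(t) = V0 * exp(k*(1-e)*t)``, with a
per-arm drug-effect fraction ``e`` (0 = no effect, 1 = stasis, > 1 =
regression) and per-measurement lognormal noise.

Every generator is deterministic for a fixed seed and returns the
noiseless ground truth alongside the noisy records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .invivo import GrowthCurve
from .plates import DoseMatrix, WellRecord
from .synergy import DEFAULT_THRESHOLDS, SynergyScore, score_matrix


def dose_series(top: float, fold: float, n: int) -> np.ndarray:
    """Serial-dilution series ``[top, top/fold, ..., top/fold**(n-1)]``
    (descending, μM).  A 5-point 1:5 series from 20 μM runs 20 → 0.032;
    a 9-point 1:3 series from 20 μM runs 20 → ~0.003."""
    if fold <= 1:
        raise InputFormatError(f"dilution fold must exceed 1, got {fold}")
    if n < 1:
        raise InputFormatError(f"series needs >= 1 point, got {n}")
    if top <= 0:
        raise InputFormatError(f"top dose must be positive, got {top}")
    return top / fold ** np.arange(n, dtype=float)


@dataclass(frozen=True)
class SurfaceSpec:
    """Parametric description of one simulated checkerboard plate.

    Defaults mirror the discovery-screen design: a 6×6 block from 5-point
    1:5 dilutions topping at 20 μM plus a vehicle level, with a cytotoxic
    positive control and multiplicative OD noise σ = 0.03.
    """

    dm_a: float = 1.0
    m_a: float = 1.0
    dm_b: float = 1.0
    m_b: float = 1.0
    bliss_offset: float = 0.0      # added inhibition on combo wells
    noise_sigma: float = 0.03      # lognormal sigma on OD
    top_a: float = 20.0
    fold_a: float = 5.0
    n_a: int = 5                   # nonzero dose levels per drug
    top_b: float = 20.0
    fold_b: float = 5.0
    n_b: int = 5
    n_pos: int = 4
    n_neg: int = 4                 # extra vehicle wells beyond the matrix vehicle
    n_blank: int = 4
    vehicle_od: float = 1.0
    blank_od: float = 0.05
    pos_residual: float = 0.02     # surviving fraction under the positive control
    compound_a: str = "anchor"
    compound_b: str = "library_compound"
    cell_line: str = "CL1"
    plate_id: str = "P1"
    seed: int = 0


@dataclass
class SimulatedPlate:
    """Noisy well records plus the noiseless truth for one checkerboard."""

    records: list[WellRecord]
    truth_matrix: DoseMatrix
    truth_score: SynergyScore
    clipped_fraction: float
    clip_warning: bool


def _single_agent_fa(doses: np.ndarray, dm: float, m: float) -> np.ndarray:
    out = np.zeros_like(doses)
    pos = doses > 0
    out[pos] = 1.0 / (1.0 + (dm / doses[pos]) ** m)
    return out


def true_surface(spec: SurfaceSpec) -> DoseMatrix:
    """Noiseless percent-viability surface implied by a :class:`SurfaceSpec`."""
    doses_a = np.concatenate([[0.0], dose_series(spec.top_a, spec.fold_a, spec.n_a)[::-1]])
    doses_b = np.concatenate([[0.0], dose_series(spec.top_b, spec.fold_b, spec.n_b)[::-1]])
    fa_a = _single_agent_fa(doses_a, spec.dm_a, spec.m_a)
    fa_b = _single_agent_fa(doses_b, spec.dm_b, spec.m_b)
    # Bliss independence on the inhibition scale, offset applied to combos only
    inhibition = fa_a[:, None] + fa_b[None, :] - np.outer(fa_a, fa_b)
    inhibition[1:, 1:] += spec.bliss_offset
    clipped = (inhibition < 0) | (inhibition > 1)
    inhibition = np.clip(inhibition, 0.0, 1.0)
    matrix = DoseMatrix(
        compound_a=spec.compound_a, compound_b=spec.compound_b,
        doses_a=doses_a, doses_b=doses_b,
        viability=100.0 * (1.0 - inhibition),
        cell_line=spec.cell_line, plate_id=spec.plate_id,
        metadata={"clipped_fraction": float(clipped.mean())},
    )
    return matrix


def simulate_matrix(spec: SurfaceSpec) -> SimulatedPlate:
    """Generate one plate: matrix wells, controls, blanks, and the truth.

    OD = blank + (vehicle_od - blank) * survival * lognormal(0, σ).  The
    matrix occupies rows 1..n_a+1 × cols 1..n_b+1 with the vehicle well at
    (1, 1) carrying role ``neg_ctrl``; positive controls, extra vehicle
    wells, and blanks sit in the three columns to the right of the block.
    """
    rng = np.random.default_rng(spec.seed)
    truth = true_surface(spec)
    clipped_fraction = truth.metadata["clipped_fraction"]
    survival = truth.viability / 100.0
    na, nb = truth.viability.shape

    def noisy(x: np.ndarray) -> np.ndarray:
        if spec.noise_sigma == 0:
            return np.asarray(x, dtype=float)
        return x * rng.lognormal(0.0, spec.noise_sigma, size=np.shape(x))

    span = spec.vehicle_od - spec.blank_od
    od_grid = spec.blank_od + span * noisy(survival)
    records: list[WellRecord] = []
    for i in range(na):
        for j in range(nb):
            role = "neg_ctrl" if i == 0 and j == 0 else "sample"
            records.append(
                WellRecord(
                    plate_id=spec.plate_id, row=i + 1, col=j + 1,
                    compound_a=spec.compound_a, dose_a=float(truth.doses_a[i]),
                    compound_b=spec.compound_b, dose_b=float(truth.doses_b[j]),
                    role=role, od=float(od_grid[i, j]),
                )
            )
    ctrl_cols = {"pos_ctrl": nb + 1, "neg_ctrl": nb + 2, "blank": nb + 3}
    pos_od = spec.blank_od + span * noisy(np.full(spec.n_pos, spec.pos_residual))
    neg_od = spec.blank_od + span * noisy(np.ones(spec.n_neg))
    blank_od = noisy(np.full(spec.n_blank, spec.blank_od))
    for role, ods in (("pos_ctrl", pos_od), ("neg_ctrl", neg_od), ("blank", blank_od)):
        for k, od in enumerate(ods):
            records.append(
                WellRecord(
                    plate_id=spec.plate_id, row=k + 1, col=ctrl_cols[role],
                    compound_a="", dose_a=0.0, compound_b="", dose_b=0.0,
                    role=role, od=float(od),
                )
            )
    return SimulatedPlate(
        records=records,
        truth_matrix=truth,
        truth_score=score_matrix(truth),
        clipped_fraction=clipped_fraction,
        clip_warning=clipped_fraction > 0.05,
    )


@dataclass
class ScreenBundle:
    """A full simulated library screen with its ground truth."""

    plates: list[SimulatedPlate]
    annotations: pd.DataFrame          # compound, moa_class
    truth: pd.DataFrame                # per compound: delta, true class

    @property
    def n_plates(self) -> int:
        return len(self.plates)

    @property
    def n_combo_wells(self) -> int:
        return sum(p.truth_matrix.n_combo_wells for p in self.plates)


# Library screening conditions: compounds are dosed an order of magnitude
# below their single-agent median-effect dose, so a Bliss-null pair stays
# inside the additive ExcessHSA band and interaction class is driven by δ.
# (With potent single agents the HSA reference sits far above the Bliss
# expectation and a non-interacting pair would already read as synergistic.)
DEFAULT_LIBRARY_SPEC = SurfaceSpec(dm_a=200.0, dm_b=200.0)


def simulate_library(
    n_compounds: int,
    class_specs: dict[str, dict] | None = None,
    seed: int = 0,
    *,
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3", "CL4"),
    base_spec: SurfaceSpec = DEFAULT_LIBRARY_SPEC,
) -> ScreenBundle:
    """Simulate an ``n_compounds × len(cell_lines)`` checkerboard screen.

    ``class_specs`` maps a mechanism-of-action class name to
    ``{"n": count, "delta": δ}`` (or ``{"n": count, "delta": (lo, hi)}`` for
    a uniform δ range); counts must sum to ``n_compounds``.  When omitted,
    every compound is Bliss-null (δ = 0) in class ``inactive``.  One plate
    is emitted per compound × cell line; the truth table records each
    compound's δ and its noiseless interaction class.
    """
    if n_compounds < 1:
        raise InputFormatError("library needs >= 1 compound")
    if class_specs is None:
        class_specs = {"inactive": {"n": n_compounds, "delta": 0.0}}
    total = sum(cs["n"] for cs in class_specs.values())
    if total != n_compounds:
        raise InputFormatError(
            f"class counts sum to {total}, expected n_compounds={n_compounds}"
        )
    rng = np.random.default_rng(seed)
    compounds: list[tuple[str, str, float]] = []
    idx = 1
    for moa, cs in class_specs.items():
        delta = cs["delta"]
        for _ in range(cs["n"]):
            d = float(rng.uniform(*delta)) if isinstance(delta, (tuple, list)) else float(delta)
            compounds.append((f"CPD{idx:03d}", moa, d))
            idx += 1
    plates = []
    truth_rows = []
    for name, moa, delta in compounds:
        for cl in cell_lines:
            spec = replace(
                base_spec,
                compound_b=name, cell_line=cl, bliss_offset=delta,
                plate_id=f"{name}-{cl}",
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            plates.append(simulate_matrix(spec))
        per_line = [p.truth_score.excess_hsa_sum for p in plates[-len(cell_lines):]]
        avg = float(np.mean(per_line))
        truth_rows.append(
            {
                "compound": name, "moa_class": moa, "delta": delta,
                "true_average_excess_hsa": avg,
                "true_class": _classify(avg),
            }
        )
    annotations = pd.DataFrame(
        [{"compound": c, "moa_class": m} for c, m, _ in compounds]
    )
    return ScreenBundle(plates=plates, annotations=annotations,
                        truth=pd.DataFrame(truth_rows))


def _classify(score: float) -> str:
    from .synergy import classify_interaction

    return classify_interaction(score, DEFAULT_THRESHOLDS)


@dataclass(frozen=True)
class GrowthSpec:
    """Exponential-growth xenograft study design.

    ``effects`` maps arm name → drug-effect fraction e; the control arm has
    e = 0 by construction.  Volumes are mm³, rates per day.
    """

    v0: float = 100.0
    growth_rate: float = 0.1
    effects: dict = field(default_factory=lambda: {"treated": 0.5})
    control_arm: str = "vehicle"
    noise_sigma: float = 0.1
    n_animals: int = 8
    days: tuple = (0, 3, 7, 10, 14, 17, 21)
    seed: int = 0


def true_tgi(spec: GrowthSpec, arm: str) -> float:
    """Closed-form TGI of ``arm`` from the noiseless exponential means."""
    e = spec.effects[arm]
    t0, t1 = spec.days[0], spec.days[-1]
    k = spec.growth_rate

    def delta(rate: float) -> float:
        return spec.v0 * (np.exp(rate * t1) - np.exp(rate * t0))

    return float(100.0 * (1.0 - delta(k * (1.0 - e)) / delta(k)))


def simulate_growth(spec: GrowthSpec) -> tuple[dict[str, list[GrowthCurve]], dict[str, float]]:
    """Simulate all arms (control included); returns (arms, truth TGI per arm)."""
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    arms: dict[str, list[GrowthCurve]] = {}
    all_effects = {spec.control_arm: 0.0, **spec.effects}
    for arm, e in all_effects.items():
        rate = spec.growth_rate * (1.0 - e)
        curves = []
        for a in range(spec.n_animals):
            noise = (
                rng.lognormal(0.0, spec.noise_sigma, size=days.size)
                if spec.noise_sigma > 0 else np.ones(days.size)
            )
            curves.append(
                GrowthCurve(
                    animal_id=f"{arm}-{a + 1:02d}", arm=arm,
                    days=days, volumes=spec.v0 * np.exp(rate * days) * noise,
                )
            )
        arms[arm] = curves
    truth = {arm: true_tgi(spec, arm) for arm in spec.effects}
    return arms, truth


def write_screen(bundle: ScreenBundle, outdir: str | Path) -> None:
    """Write a simulated screen in the pipeline's input dialects:
    one plate CSV per block, an annotation CSV, and a truth table CSV."""
    from .plates import write_plate_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in bundle.plates:
        write_plate_table(p.records, outdir / f"{p.records[0].plate_id}.csv")
    bundle.annotations.to_csv(outdir / "annotations.csv", index=False)
    bundle.truth.to_csv(outdir / "truth.csv", index=False)
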