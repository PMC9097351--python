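"""Single-agent dose-response models and the Chou-Talalay combination index.

Two estimators follow the scikit-learn protocol (``fit`` / ``predict``,
fitted attributes with a trailing underscore, ``get_params``):

* :class:`MedianEffectModel` — the median-effect equation
  ``fa/fu = (D/Dm)^m`` fitted by ordinary least squares on the linearized
  plot ``log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm)``.
* :class:`FourParamLogistic` — the 4-parameter logistic viability curve,
  reporting the relative (inflection-point) IC50.

On top of the median-effect fits, :func:`combination_index` computes the
per-well combination index ``CI = d1/Dx1 + d2/Dx2`` where ``Dx_i`` is the
single-agent dose of drug *i* that alone produces the observed fraction
affected; CI < 1 marks synergy, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FitFailureError, InsufficientDataError, OutOfRangeError
from .plates import DoseMatrix


class MedianEffectModel(BaseEstimator, RegressorMixin):
    """Chou-Talalay median-effect dose-response model.

    The model relates dose ``D`` to fraction affected ``fa`` through
    ``fa/(1-fa) = (D/Dm)^m``; ``Dm`` is the median-effect dose (fa = 0.5)
    and ``m`` the sigmoidicity slope.  Fitting is unweighted OLS on the
    log-linearized coordinates, the classical median-effect-plot method.

    Parameters
    ----------
    eps : float
        Usable-range clip for fraction affected: points with
        ``fa <= eps`` or ``fa >= 1 - eps`` are excluded from the fit
        (and counted in ``excluded_points_``).

    Attributes
    ----------
    dm_ : float
        Median-effect dose in the units of the fitted doses (μM).
    m_ : float
        Slope of the median-effect plot.
    r_ : float
        Linear correlation coefficient of the median-effect plot.
    n_points_ : int
        Number of points used in the regression.
    excluded_points_ : int
        Points dropped by the usable-range clip.
    extrapolation_warning_ : bool
        True when all usable fa lie on one side of 0.5, so ``dm_`` is an
        extrapolation beyond the observed effect range.
    """

    def __init__(self, eps: float = 0.005):
        self.eps = eps

    def fit(self, doses, fa) -> "MedianEffectModel":
        D = np.asarray(doses, dtype=float)
        f = np.asarray(fa, dtype=float)
        if D.shape != f.shape:
            raise InsufficientDataError("doses and fa must have the same length")
        usable = (D > 0) & (f > self.eps) & (f < 1 - self.eps)
        self.excluded_points_ = int((~usable).sum())
        D, f = D[usable], f[usable]
        if D.size < 2:
            raise InsufficientDataError(
                f"median-effect fit needs >= 2 usable points, got {D.size}"
            )
        res = stats.linregress(np.log10(D), np.log10(f / (1 - f)))
        if res.slope == 0:
            raise FitFailureError("median-effect slope is zero; Dm undefined")
        self.m_ = float(res.slope)
        self.dm_ = float(10 ** (-res.intercept / res.slope))
        self.r_ = float(res.rvalue)
        self.n_points_ = int(D.size)
        self.extrapolation_warning_ = bool(np.all(f < 0.5) or np.all(f > 0.5))
        return self

    def predict(self, doses) -> np.ndarray:
        """Fraction affected at each dose: ``fa = 1 / (1 + (Dm/D)^m)``."""
        check_is_fitted(self, "dm_")
        D = np.asarray(doses, dtype=float)
        with np.errstate(divide="ignore"):
            out = 1.0 / (1.0 + (self.dm_ / D) ** self.m_)
        return np.where(D > 0, out, 0.0 if self.m_ > 0 else 1.0)

    def dose_for_fa(self, fa) -> np.ndarray:
        """Inverse curve: single-agent dose producing ``fa`` alone,
        ``Dx = Dm * (fa/(1-fa))^(1/m)``."""
        check_is_fitted(self, "dm_")
        f = np.asarray(fa, dtype=float)
        if np.any((f <= 0) | (f >= 1)):
            raise OutOfRangeError("fa must lie strictly inside (0, 1)")
        return self.dm_ * (f / (1 - f)) ** (1.0 / self.m_)


def _four_pl(D, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (D / ic50) ** hill)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic viability curve fitted by nonlinear least squares.

    ``v(D) = bottom + (top - bottom) / (1 + (D/ic50)^hill)``; ``ic50_`` is
    the inflection dose (relative IC50), not the absolute-50% crossing.

    Attributes
    ----------
    ic50_, hill_, top_, bottom_ : float
    hill_sign_warning_ : bool
        True when the fitted slope is negative, i.e. the response rises
        with dose instead of falling.
    """

    def __init__(self, max_iter: int = 10000):
        self.max_iter = max_iter

    def fit(self, doses, viability) -> "FourParamLogistic":
        D = np.asarray(doses, dtype=float)
        v = np.asarray(viability, dtype=float)
        if D.size < 4:
            raise InsufficientDataError("4PL fit needs >= 4 dose levels")
        pos = D > 0
        p0 = [float(v.max()), float(v.min()),
              float(np.exp(np.mean(np.log(D[pos])))), 1.0]
        try:
            popt, _ = optimize.curve_fit(
                _four_pl, D[pos], v[pos], p0=p0, maxfev=self.max_iter,
            )
        except RuntimeError as exc:
            raise FitFailureError(f"4PL fit did not converge: {exc}") from exc
        self.top_, self.bottom_, self.ic50_, self.hill_ = map(float, popt)
        if self.ic50_ <= 0:
            raise FitFailureError(f"4PL fit returned nonpositive IC50 {self.ic50_:g}")
        # A negative fitted hill means viability increases with dose.
        self.hill_sign_warning_ = bool(self.hill_ < 0)
        if self.top_ < self.bottom_:  # canonicalize so top is the high asymptote
            self.top_, self.bottom_ = self.bottom_, self.top_
            self.hill_ = -self.hill_
            self.hill_sign_warning_ = True
        return self

    def predict(self, doses) -> np.ndarray:
        check_is_fitted(self, "ic50_")
        return _four_pl(np.asarray(doses, dtype=float),
                        self.top_, self.bottom_, self.ic50_, self.hill_)


@dataclass(frozen=True)
class CombinationPoint:
    """One combination well on the Fa-CI plot."""

    d1: float
    d2: float
    fa: float
    dx1: float
    dx2: float
    ci: float

    def classify(self, tol: float = 0.0) -> str:
        if self.ci < 1 - tol:
            return "synergistic"
        if self.ci > 1 + tol:
            return "antagonistic"
        return "additive"


def combination_index(
    fit1: MedianEffectModel,
    fit2: MedianEffectModel,
    d1: float,
    d2: float,
    fa: float,
    *,
    form: str = "mutually_exclusive",
) -> CombinationPoint:
    """Combination index for one well at observed fraction affected ``fa``.

    The default mutually-exclusive (two-term) form is
    ``CI = d1/Dx1 + d2/Dx2``; the mutually-nonexclusive form adds the cross
    term ``(d1*d2)/(Dx1*Dx2)``.  A zero dose degenerates to the single-agent
    one-term form.
    """
    if not 0 < fa < 1:
        raise OutOfRangeError(f"fa must lie in (0, 1), got {fa}")
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise OutOfRangeError("need at least one positive dose")
    dx1 = float(fit1.dose_for_fa(fa)) if d1 > 0 else float("nan")
    dx2 = float(fit2.dose_for_fa(fa)) if d2 > 0 else float("nan")
    ci = 0.0
    if d1 > 0:
        ci += d1 / dx1
    if d2 > 0:
        ci += d2 / dx2
    if form == "mutually_nonexclusive":
        if d1 > 0 and d2 > 0:
            ci += (d1 * d2) / (dx1 * dx2)
    elif form != "mutually_exclusive":
        raise OutOfRangeError(f"unknown CI form {form!r}")
    return CombinationPoint(d1=float(d1), d2=float(d2), fa=float(fa),
                            dx1=dx1, dx2=dx2, ci=float(ci))


@dataclass
class FaCICurve:
    """Fa-CI points for one checkerboard, ordered by fa ascending."""

    points: list[CombinationPoint]
    n_dropped: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"fa": p.fa, "d1": p.d1, "d2": p.d2,
              "Dx1": p.dx1, "Dx2": p.dx2, "ci": p.ci} for p in self.points]
        )


def fa_ci_curve(
    matrix: DoseMatrix,
    fit1: MedianEffectModel,
    fit2: MedianEffectModel,
    *,
    eps: float = 0.005,
    form: str = "mutually_exclusive",
) -> FaCICurve:
    """Per-well combination indices for every usable combination well.

    ``fa = 1 - viability/100`` per well; wells with fa outside
    ``(eps, 1-eps)`` are dropped and counted, never imputed.  The screen is
    a checkerboard (non-constant-ratio design), so CI is computed per well.
    """
    points: list[CombinationPoint] = []
    dropped = 0
    for i in range(1, matrix.doses_a.size):
        for j in range(1, matrix.doses_b.size):
            fa = 1.0 - matrix.viability[i, j] / 100.0
            if not eps < fa < 1 - eps:
                dropped += 1
                continue
            points.append(
                combination_index(
                    fit1, fit2, matrix.doses_a[i], matrix.doses_b[j], fa, form=form
                )
            )
    points.sort(key=lambda p: p.fa)
    return FaCICurve(points=points, n_dropped=dropped)


def fit_single_agent_margins(
    matrix: DoseMatrix, eps: float = 0.005
) -> tuple[MedianEffectModel, MedianEffectModel]:
    """Fit median-effect models to the two single-agent margins of a block."""
    fa_a = 1.0 - matrix.viability[1:, 0] / 100.0
    fa_b = 1.0 - matrix.viability[0, 1:] / 100.0
    fit_a = MedianEffectModel(eps=eps).fit(matrix.doses_a[1:], fa_a)
    fit_b = MedianEffectModel(eps=eps).fit(matrix.doses_b[1:], fa_b)
    return fit_a, fit_b
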