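"""Median-effect fits, 4PL fits, and the combination index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from synscreen import (
    FourParamLogistic,
    MedianEffectModel,
    combination_index,
    fa_ci_curve,
    fit_single_agent_margins,
    normalize_matrix,
)
from synscreen.doseresponse import _four_pl
from synscreen.errors import InsufficientDataError, OutOfRangeError

from conftest import matrix_from_grid


def median_effect_fa(D, dm, m):
    return 1.0 / (1.0 + (dm / np.asarray(D, float)) ** m)


class TestMedianEffect:
    def test_exact_recovery(self):
        D = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        fit = MedianEffectModel().fit(D, median_effect_fa(D, 1.0, 1.0))
        assert fit.dm_ == pytest.approx(1.0, rel=1e-9)
        assert fit.m_ == pytest.approx(1.0, rel=1e-9)
        assert fit.r_ == pytest.approx(1.0, abs=1e-9)

    @given(
        dm=st.floats(0.05, 10.0),
        m=st.floats(0.3, 4.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_on_any_median_effect_data(self, dm, m, seed):
        """r = 1 and exact parameter recovery on model-generated data."""
        rng = np.random.default_rng(seed)
        D = np.sort(rng.uniform(dm / 20, dm * 20, size=6))
        fa = median_effect_fa(D, dm, m)
        fit = MedianEffectModel(eps=1e-9).fit(D, fa)
        assert fit.r_ == pytest.approx(1.0, abs=1e-6)
        assert fit.dm_ == pytest.approx(dm, rel=1e-6)
        assert fit.predict([fit.dm_])[0] == pytest.approx(0.5, abs=1e-12)

    def test_fa_at_dm_is_half(self):
        D = np.array([0.5, 1.5, 3.0])
        fit = MedianEffectModel().fit(D, [0.2, 0.6, 0.9])
        assert fit.predict([fit.dm_])[0] == pytest.approx(0.5, abs=1e-12)

    def test_noisy_recovery_within_5pct_median(self):
        """Dm recovered within 5% (median over 200 seeds) at 1% multiplicative
        signal noise with a 9-point 1:2 series bracketing Dm."""
        dm, m = 2.5, 1.7
        D = 20.0 / 2.0 ** np.arange(9)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fu = (1 - median_effect_fa(D, dm, m)) * rng.lognormal(0, 0.01, D.size)
            fa = np.clip(1 - fu, 1e-6, 1 - 1e-6)
            fit = MedianEffectModel().fit(D, fa)
            errs.append(abs(fit.dm_ - dm) / dm)
        assert np.median(errs) < 0.05

    def test_extrapolation_warning_when_one_sided(self):
        D = np.array([0.01, 0.02, 0.04])
        fit = MedianEffectModel().fit(D, median_effect_fa(D, 1.0, 1.0))
        assert fit.extrapolation_warning_

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            MedianEffectModel().fit([1.0], [0.5])
        with pytest.raises(InsufficientDataError):
            # all points clipped out of the usable range
            MedianEffectModel().fit([1.0, 2.0, 4.0], [0.001, 0.002, 0.999])

    def test_excluded_points_counted(self):
        D = np.array([0.25, 0.5, 1.0, 2.0])
        fa = np.array([0.001, 0.3, 0.5, 0.7])
        fit = MedianEffectModel().fit(D, fa)
        assert fit.excluded_points_ == 1
        assert fit.n_points_ == 3

    def test_sklearn_protocol(self):
        est = MedianEffectModel(eps=0.01)
        assert est.get_params() == {"eps": 0.01}
        clone(est)  # must not raise


def fitted_pair(dm=1.0, m=1.0):
    D = np.array([0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0]) * dm
    fa = median_effect_fa(D, dm, m)
    f = MedianEffectModel(eps=1e-9).fit(D, fa)
    return f, MedianEffectModel(eps=1e-9).fit(D, fa)


class TestCombinationIndex:
    def test_loewe_additive_closed_form(self):
        f1, f2 = fitted_pair(1.0, 1.0)
        p = combination_index(f1, f2, 0.5, 0.5, fa=0.5)
        assert p.dx1 == pytest.approx(1.0, rel=1e-9)
        assert p.dx2 == pytest.approx(1.0, rel=1e-9)
        assert p.ci == pytest.approx(1.0, rel=1e-9)
        assert p.classify(tol=1e-6) == "additive"

    def test_synergistic_closed_form(self):
        f1, f2 = fitted_pair(1.0, 1.0)
        p = combination_index(f1, f2, 0.25, 0.25, fa=0.5)
        assert p.ci == pytest.approx(0.5, rel=1e-9)
        assert p.classify() == "synergistic"

    def test_single_agent_degenerate(self):
        f1, f2 = fitted_pair(1.0, 1.0)
        dx1 = f1.dose_for_fa(0.7)
        p = combination_index(f1, f2, float(dx1), 0.0, fa=0.7)
        assert p.ci == pytest.approx(1.0, rel=1e-9)

    def test_nonexclusive_form_adds_cross_term(self):
        f1, f2 = fitted_pair(1.0, 1.0)
        p2 = combination_index(f1, f2, 0.5, 0.5, fa=0.5)
        p3 = combination_index(f1, f2, 0.5, 0.5, fa=0.5, form="mutually_nonexclusive")
        assert p3.ci == pytest.approx(p2.ci + 0.25, rel=1e-9)

    @given(
        d1=st.floats(0.05, 5.0), d2=st.floats(0.05, 5.0),
        fa=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_under_drug_relabeling(self, d1, d2, fa):
        f1, f2 = fitted_pair(1.0, 1.3)
        f2 = MedianEffectModel(eps=1e-9).fit(
            [0.5, 1, 2, 4], median_effect_fa([0.5, 1, 2, 4], 2.0, 0.8)
        )
        a = combination_index(f1, f2, d1, d2, fa=fa)
        b = combination_index(f2, f1, d2, d1, fa=fa)
        assert a.ci == pytest.approx(b.ci, rel=1e-9)

    def test_ci_decreasing_in_fa(self):
        f1, f2 = fitted_pair(1.0, 1.5)
        fas = np.linspace(0.1, 0.9, 17)
        cis = [combination_index(f1, f2, 0.5, 0.5, fa=f).ci for f in fas]
        assert np.all(np.diff(cis) < 0)

    def test_fa_out_of_range(self):
        f1, f2 = fitted_pair()
        with pytest.raises(OutOfRangeError):
            combination_index(f1, f2, 0.5, 0.5, fa=1.0)


class TestFaCICurve:
    def loewe_matrix(self):
        """Identical drugs (Dm=1, m=1); combo fa equals the single-agent fa
        at dose d1+d2, so CI = 1 at every well by the dose-sum construction."""
        doses = np.array([0.0, 0.2, 0.4, 0.8, 1.6])
        grid = np.empty((5, 5))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                d = da + db
                grid[i, j] = 100 * (1 - d / (1 + d))
        return matrix_from_grid(grid, doses_a=doses, doses_b=doses)

    def test_loewe_oracle_all_ci_one(self):
        m = self.loewe_matrix()
        f1, f2 = fit_single_agent_margins(m, eps=1e-9)
        curve = fa_ci_curve(m, f1, f2, eps=1e-6)
        assert len(curve.points) == 16
        for p in curve.points:
            assert p.ci == pytest.approx(1.0, abs=1e-6)
        fas = [p.fa for p in curve.points]
        assert fas == sorted(fas)

    def test_all_vehicle_like_wells_dropped(self):
        grid = np.full((4, 4), 100.0)
        grid[1:, 0] = [60, 50, 40]  # margins must stay fittable
        grid[0, 1:] = [60, 50, 40]
        m = matrix_from_grid(grid, doses_a=np.array([0.0, 1, 2, 4.0]),
                             doses_b=np.array([0.0, 1, 2, 4.0]))
        f1, f2 = fit_single_agent_margins(m)
        curve = fa_ci_curve(m, f1, f2)
        assert curve.points == []
        assert curve.n_dropped == 9

    def test_bliss_synergistic_matrix_median_ci_below_one(self, synergistic_plate):
        m = normalize_matrix(synergistic_plate.records)
        f1, f2 = fit_single_agent_margins(m)
        curve = fa_ci_curve(m, f1, f2)
        assert np.median([p.ci for p in curve.points]) < 1.0


class TestFourParamLogistic:
    def test_noiseless_recovery(self):
        D = 20.0 / 4.0 ** np.arange(8)
        v = _four_pl(D, 100.0, 0.0, 1.0, 1.0)
        fit = FourParamLogistic().fit(D, v)
        assert fit.top_ == pytest.approx(100.0, abs=1e-6)
        assert fit.bottom_ == pytest.approx(0.0, abs=1e-6)
        assert fit.ic50_ == pytest.approx(1.0, rel=1e-6)
        assert fit.hill_ == pytest.approx(1.0, rel=1e-6)
        assert not fit.hill_sign_warning_

    def test_monotone_increasing_flags_hill_sign(self):
        D = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        v = _four_pl(D, 10.0, 100.0, 1.0, 1.0)  # rises with dose
        fit = FourParamLogistic().fit(D, v)
        assert fit.hill_sign_warning_
        assert fit.top_ > fit.bottom_

    def test_noisy_ic50_within_10pct_median(self):
        """IC50 within 10% of truth (median over 200 seeds) at 3% noise."""
        D = 20.0 / 4.0 ** np.arange(8)
        truth = _four_pl(D, 100.0, 0.0, 1.0, 1.2)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            v = truth * rng.lognormal(0, 0.03, D.size)
            fit = FourParamLogistic().fit(D, v)
            errs.append(abs(fit.ic50_ - 1.0))
        assert np.median(errs) < 0.10

    def test_too_few_doses(self):
        with pytest.raises(InsufficientDataError):
            FourParamLogistic().fit([1.0, 2.0, 4.0], [90.0, 50.0, 10.0])

    def test_sklearn_protocol(self):
        est = FourParamLogistic(max_iter=500)
        assert est.get_params() == {"max_iter": 500}
        clone(est)
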