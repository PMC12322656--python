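"""Rate law, hydrolysis ODE vs analytic solution, cascade model, ratio sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from psicascade import (
    CascadeConfig,
    EnzymeSpec,
    InvalidInputError,
    KineticParams,
    ProgressCurve,
    YeiNParams,
    calibrate_yein_kcat,
    enzyme_ratio_sweep,
    hydrolysis_time,
    kcat_to_specific_activity,
    rate_eq1,
    simulate_cascade,
    simulate_hydrolysis,
    subunit_molarity,
    vmax_mM_per_min,
    yein_rate,
)
from psicascade.synth import default_cascade_config


def _enzyme_with_vmax(vmax_mM_min: float) -> tuple[EnzymeSpec, float]:
    """EnzymeSpec whose loading yields the requested Vmax at kcat = 1 s⁻¹."""
    mass = 50000.0
    kcat = 1.0
    load = vmax_mM_min * mass / (kcat * 60.0 * 1000.0)
    return EnzymeSpec("E", mass, load), kcat


class TestRateLaw:
    def test_half_saturation(self):
        enzyme, kcat = _enzyme_with_vmax(1.0)
        p = KineticParams(kcat=kcat, km=1.0)
        assert rate_eq1(p, enzyme, 1.0, 0.0) == pytest.approx(0.5, rel=1e-12)

    def test_apparent_km_shift_wt(self):
        """Competitive inhibition scales Km by (1 + I/Ki): the wild type at
        10 mM inhibitor has apparent Km = 1.1·(1 + 10/0.1) = 111.1 mM."""
        enzyme = EnzymeSpec("WT", 51794.0, 2.0)
        p = KineticParams(kcat=2.6, km=1.1, ki=0.1)
        km_app = 1.1 * (1.0 + 10.0 / 0.1)
        assert km_app == pytest.approx(111.1)
        vmax = vmax_mM_per_min(p.kcat, enzyme)
        s = 7.0
        assert rate_eq1(p, enzyme, s, 10.0) == pytest.approx(vmax * s / (km_app + s), rel=1e-12)

    def test_saturation_limit_independent_of_inhibitor(self):
        enzyme, kcat = _enzyme_with_vmax(2.0)
        p = KineticParams(kcat=kcat, km=5.0, ki=0.5)
        for inh in (0.0, 10.0, 100.0):
            assert rate_eq1(p, enzyme, 1e12, inh) == pytest.approx(2.0, rel=1e-6)

    def test_reduces_to_michaelis_menten_without_ki(self):
        enzyme, kcat = _enzyme_with_vmax(1.0)
        with_ki = rate_eq1(KineticParams(kcat, 2.0, ki=1.0), enzyme, 3.0, 0.0)
        without = rate_eq1(KineticParams(kcat, 2.0), enzyme, 3.0, 5.0)
        assert with_ki == pytest.approx(rate_eq1(KineticParams(kcat, 2.0), enzyme, 3.0, 0.0))
        assert without == pytest.approx(with_ki)

    def test_negative_concentration_errors(self):
        enzyme, kcat = _enzyme_with_vmax(1.0)
        p = KineticParams(kcat, 1.0, ki=1.0)
        with pytest.raises(InvalidInputError):
            rate_eq1(p, enzyme, -1.0, 0.0)
        with pytest.raises(InvalidInputError):
            rate_eq1(p, enzyme, 1.0, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        s=st.floats(0.01, 200.0),
        i_lo=st.floats(0.0, 50.0),
        delta=st.floats(0.1, 50.0),
    )
    def test_competitive_signature(self, s, i_lo, delta):
        """Strictly decreasing in inhibitor at fixed substrate, strictly
        increasing in substrate at fixed inhibitor."""
        enzyme, kcat = _enzyme_with_vmax(1.0)
        p = KineticParams(kcat, km=5.0, ki=1.0)
        assert rate_eq1(p, enzyme, s, i_lo + delta) < rate_eq1(p, enzyme, s, i_lo)
        assert rate_eq1(p, enzyme, s + delta, i_lo) > rate_eq1(p, enzyme, s, i_lo)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParams(kcat=-1.0, km=1.0)
        with pytest.raises(InvalidInputError):
            KineticParams(kcat=1.0, km=0.0)
        with pytest.raises(InvalidInputError):
            KineticParams(kcat=1.0, km=1.0, ki=0.0)


def _analytic_substrate(t: float, s0: float, vmax: float, km: float, ki) -> float:
    """Invert the implicit solution t(S) by root bracketing (independent
    oracle for the ODE path)."""
    if t == 0:
        return s0
    f = lambda s: hydrolysis_time(s, s0, vmax, km, ki) - t
    return brentq(f, 1e-12 * s0, s0, xtol=1e-14, rtol=1e-15)


class TestHydrolysis:
    def test_initial_condition(self, ry_preset, t_grid_120):
        curve = simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 100.0, t_grid_120)
        assert curve.ump[0] == pytest.approx(100.0)
        assert curve.ura[0] == 0.0 and curve.rib5p[0] == 0.0

    def test_mass_balance(self, ry_preset, t_grid_120):
        curve = simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 100.0, t_grid_120)
        np.testing.assert_allclose(curve.ump + curve.ura, 100.0, atol=1e-8 * 100.0)
        np.testing.assert_allclose(curve.ura, curve.rib5p, atol=1e-12)

    def test_matches_analytic_solution_ry(self, ry_preset):
        vmax = vmax_mM_per_min(ry_preset.params.kcat, ry_preset.enzyme)
        t = np.linspace(0.0, 120.0, 21)
        curve = simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 100.0, t)
        expected = [
            _analytic_substrate(tj, 100.0, vmax, ry_preset.params.km, ry_preset.params.ki)
            for tj in t
        ]
        np.testing.assert_allclose(curve.ump, expected, rtol=1e-6)

    def test_uninhibited_matches_integrated_michaelis_menten(self):
        """With no inhibition term the trajectory satisfies the integrated
        relation Km·ln(S0/S) + (S0 − S) = Vmax·t."""
        enzyme, kcat = _enzyme_with_vmax(2.0)
        p = KineticParams(kcat, km=3.0)
        # stop near 97% conversion: past that, S is so small that the log
        # term amplifies solver round-off beyond the comparison tolerance
        t = np.linspace(0.0, 30.0, 13)
        curve = simulate_hydrolysis(enzyme, p, 50.0, t)
        lhs = 3.0 * np.log(50.0 / curve.ump) + (50.0 - curve.ump)
        np.testing.assert_allclose(lhs, 2.0 * t, rtol=1e-6, atol=1e-8)

    def test_ry_reaches_92_percent_by_120_min(self, ry_preset):
        """RY at 2.0 mg/mL converts ≥92% of 100 mM substrate within 120 min."""
        t = np.linspace(0.0, 120.0, 121)
        curve = simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 100.0, t)
        assert curve.conversion()[-1] >= 0.92

    def test_invalid_grids_and_s0(self, ry_preset):
        with pytest.raises(InvalidInputError):
            simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 0.0, [0.0, 1.0])
        with pytest.raises(InvalidInputError):
            simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 10.0, [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 10.0, [0.0, 2.0, 1.0])


class TestYeiNRate:
    def test_zero_substrates(self, yein_preset):
        assert yein_rate(yein_preset.params, yein_preset.enzyme, 0.0, 0.0) == 0.0
        assert yein_rate(yein_preset.params, yein_preset.enzyme, 5.0, 0.0) == 0.0

    def test_saturation(self, yein_preset):
        vmax = vmax_mM_per_min(yein_preset.params.kcat, yein_preset.enzyme)
        assert yein_rate(yein_preset.params, yein_preset.enzyme, 1e7, 1e7) == pytest.approx(
            vmax, rel=1e-5
        )

    def test_calibration_anchor(self, yein_preset):
        """At the assay point (15 mM of each substrate) the default model
        predicts the measured 7.0 U/mg within 1%."""
        enzyme = yein_preset.enzyme
        rate = yein_rate(yein_preset.params, enzyme.with_mass_conc(1.0), 15.0, 15.0)
        # rate (mM/min) per (g/L) is U/mg numerically: µmol/min per mg
        assert rate == pytest.approx(7.0, rel=0.01)

    def test_calibrate_yein_kcat_closed_form(self):
        kcat = calibrate_yein_kcat(7.0, 32909.0, 1.0, 1.0, 15.0)
        sat = (15.0 / 16.0) ** 2
        assert kcat * sat == pytest.approx(7.0 * 32909.0 / 60000.0, rel=1e-12)

    def test_reversible_flag_rejected(self):
        with pytest.raises(InvalidInputError):
            YeiNParams(kcat=1.0, reversible=True)


class TestCascade:
    def test_mass_balances_and_monotonicity(self):
        cfg = default_cascade_config(ump0=100.0, t_end=60.0)
        curve = simulate_cascade(cfg)
        np.testing.assert_allclose(curve.ump + curve.ura + curve.psimp, 100.0, atol=1e-6)
        np.testing.assert_allclose(curve.ump + curve.rib5p + curve.psimp, 100.0, atol=1e-6)
        assert np.all(np.diff(curve.ump) <= 1e-9)
        assert np.all(np.diff(curve.psimp) >= -1e-9)

    def test_final_yield_at_default_excess(self):
        """YeiN in twofold mass excess over RY converts ≥95% of 100 mM
        substrate into product, with little uracil left at steady state."""
        cfg = default_cascade_config(ump0=100.0, ry_load=0.5, yein_load=1.0, t_end=240.0)
        curve = simulate_cascade(cfg)
        assert curve.psimp[-1] >= 95.0
        assert curve.ura[-1] < 5.0

    def test_instantaneous_pull_limit(self, ry_preset):
        """With an effectively infinite YeiN capacity the intermediate never
        accumulates and substrate depletion matches uninhibited kinetics."""
        yein = EnzymeSpec("YeiN", 32909.0, 1.0)
        cfg = CascadeConfig(
            ry_preset.enzyme, ry_preset.params, yein,
            YeiNParams(kcat=1e6, km_rib5p=1e-3, km_ura=1e-3), 100.0, 60.0,
        )
        t = np.linspace(0.0, 60.0, 31)
        curve = simulate_cascade(cfg, t)
        assert np.max(curve.rib5p) < 0.05
        uninhibited = simulate_hydrolysis(
            ry_preset.enzyme, KineticParams(ry_preset.params.kcat, ry_preset.params.km),
            100.0, t,
        )
        np.testing.assert_allclose(curve.ump, uninhibited.ump, atol=0.2)

    def test_no_catalyst_is_inert(self, ry_preset, yein_preset):
        cfg = CascadeConfig(
            ry_preset.enzyme.with_mass_conc(0.0), ry_preset.params,
            yein_preset.enzyme, yein_preset.params, 100.0, 60.0,
        )
        curve = simulate_cascade(cfg)
        np.testing.assert_allclose(curve.ump, 100.0, atol=1e-9)
        np.testing.assert_allclose(curve.psimp, 0.0, atol=1e-9)


@pytest.fixture(scope="module")
def sweep():
    cfg = default_cascade_config(ump0=100.0, t_end=30.0)
    return enzyme_ratio_sweep(1.5, [0.0, 0.25, 1.0, 2.0], cfg, 30.0)


class TestRatioSweep:
    def test_equal_and_twofold_splits_agree(self, sweep):
        """1:1 and 1:2 nucleosidase:glycosidase splits convert within 5% of
        each other — the plateau where the cascade runs at full speed."""
        conv = dict(zip(sweep["ratio"], sweep["conversion"]))
        assert abs(conv[1.0] - conv[2.0]) / conv[2.0] < 0.05

    def test_substoichiometric_yein_drops(self, sweep):
        conv = dict(zip(sweep["ratio"], sweep["conversion"]))
        assert conv[0.25] < conv[2.0] - 0.05
        assert conv[0.0] < conv[2.0] - 0.05

    def test_no_nucleosidase_no_conversion(self):
        cfg = default_cascade_config(ump0=100.0, t_end=30.0)
        sweep = enzyme_ratio_sweep(1.5, [1e6], cfg, 30.0)
        assert sweep["conversion"].iloc[0] < 0.01

    def test_empty_ratios_error(self):
        cfg = default_cascade_config()
        with pytest.raises(InvalidInputError):
            enzyme_ratio_sweep(1.5, [], cfg, 30.0)


class TestProgressCurveIO:
    def test_round_trip(self, ry_preset, tmp_path):
        t = np.linspace(0.0, 60.0, 7)
        curve = simulate_hydrolysis(ry_preset.enzyme, ry_preset.params, 50.0, t)
        path = tmp_path / "curve.csv"
        curve.write_csv(path)
        back = ProgressCurve.read_csv(path)
        np.testing.assert_allclose(back.ump, curve.ump, rtol=1e-9)
        np.testing.assert_allclose(back.time, curve.time, rtol=1e-9)

    def test_missing_species_columns_fill_with_zeros(self, tmp_path):
        path = tmp_path / "partial.csv"
        path.write_text("time_min,UMP_mM\n0,100\n10,80\n")
        curve = ProgressCurve.read_csv(path)
        np.testing.assert_allclose(curve.psimp, 0.0)
        np.testing.assert_allclose(curve.ump, [100.0, 80.0])

    def test_missing_time_column_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("UMP_mM\n100\n")
        with pytest.raises(InvalidInputError):
            ProgressCurve.read_csv(path)
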