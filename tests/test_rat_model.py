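import numpy as np
import pytest
from dataclasses import replace

from respsnn.metrics import segment_breaths
from respsnn.rat_model import (
    CalibrationError,
    PlantParams,
    PlantState,
    RatPlant,
    calibrate_plant,
    combine_activation,
    dynamical_rr,
    lung_step,
    metabolism_step,
    native_drive,
    recruitment,
)
from respsnn.snn_core import DT_S


class TestNativeDrive:
    def test_complete_injury_silences_drive(self):
        assert all(native_drive(p, 0.0) == 0.0 for p in np.linspace(0, 0.999, 50))

    def test_peak_at_ramp_end_equals_wi(self):
        assert native_drive(0.3499, 1.0, ti_frac=0.35) == pytest.approx(1.0, abs=1e-3)
        assert native_drive(0.5, 1.0, ti_frac=0.35) == 0.0

    def test_injury_scales_pointwise(self):
        for p in np.linspace(0, 0.999, 40):
            assert native_drive(p, 0.75) == pytest.approx(0.75 * native_drive(p, 1.0))


class TestActivation:
    @pytest.mark.parametrize("nat,stim,out", [
        (0.4, 0.0, 0.4), (0.9, 0.3, 1.0), (0.0, 0.35, 0.35),
    ])
    def test_linear_sum_with_clip(self, nat, stim, out):
        assert combine_activation(nat, stim) == out

    def test_recruitment_monotone_saturating(self):
        u = np.linspace(0, 1, 21)
        f = np.array([recruitment(x) for x in u])
        assert f[0] == 0.0 and f[-1] == pytest.approx(1.0)
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(f, 2) < 0)  # concave


class TestLungMechanics:
    def test_rest_is_equilibrium(self, plant_params):
        s = PlantState()
        for _ in range(1000):
            s = lung_step(s, 0.0, plant_params)
        assert abs(s.x) < 1e-12 and abs(s.volume) < 1e-12

    def test_step_release_returns_without_ringing(self, plant_params):
        s = PlantState()
        for _ in range(2000):
            s = lung_step(s, 0.8, plant_params)
        xs = []
        for _ in range(2000):
            s = lung_step(s, 0.0, plant_params)
            xs.append(s.x)
        xs = np.array(xs)
        # overdamped relaxation: no undershoot below rest
        assert xs.min() > -1e-6
        assert xs[-1] == pytest.approx(0.0, abs=1e-6)

    def test_damping_dominates_at_operating_point(self, plant_params):
        # zeta >= 1 for the linearized spring anywhere in the working range
        for x in np.linspace(0.0, 1.0, 11):
            k = plant_params.stiffness(x)
            zeta = plant_params.damping / (2 * np.sqrt(k * plant_params.mass))
            assert zeta >= 1.0

    def test_non_finite_state_rejected(self, plant_params):
        with pytest.raises(ValueError):
            lung_step(PlantState(x=float("nan")), 0.0, plant_params)


class TestMetabolism:
    def test_zero_ventilation_grows_linearly(self, plant_params):
        co2 = 1.0
        for _ in range(100):
            co2 = metabolism_step(co2, 0.0, 1.0, plant_params)
        assert co2 == pytest.approx(1.0 + 100 * plant_params.mbc0_rate * DT_S)

    def test_eupnea_is_mass_balanced_per_breath(self, plant_params):
        plant = RatPlant(replace(plant_params, wi=1.0, mbc=1.0), dynamic_rr=False)
        plant.run(14 * 60.0 / 56.0)
        d = np.diff(plant.co2_at_breath)[7:]
        production = plant_params.mbc0_rate * 60.0 / 56.0
        assert abs(np.mean(d)) < 0.005 * production + 0.005 * plant_params.co2_ref

    def test_raised_demand_at_fixed_rate_accumulates_co2(self, plant_params):
        plant = RatPlant(replace(plant_params, wi=1.0, mbc=1.11), dynamic_rr=False)
        plant.run(12 * 60.0 / 56.0)
        d = np.diff(plant.co2_at_breath)[6:]
        assert np.all(d > 0)

    def test_negative_co2_rejected(self, plant_params):
        with pytest.raises(ValueError):
            metabolism_step(-0.1, 0.0, 1.0, plant_params)

    def test_mass_balance_identity(self, plant_params):
        plant = RatPlant(plant_params)
        plant.run(5.0)
        lhs = plant.state.co2 - plant_params.co2_ref
        assert lhs == pytest.approx(plant.co2_produced - plant.co2_cleared, abs=1e-9)


class TestDynamicalRr:
    def test_eupneic_rate(self, plant_params):
        rr = dynamical_rr(1.0, plant_params.regression)
        assert rr == pytest.approx(56.0, rel=0.02)

    def test_raised_demand_raises_rate(self, plant_params):
        assert dynamical_rr(1.11, plant_params.regression) > dynamical_rr(
            1.0, plant_params.regression
        )

    def test_positive_slope(self, plant_params):
        assert plant_params.regression.b > 0

    def test_unfitted_regression_rejected(self):
        with pytest.raises(ValueError):
            dynamical_rr(1.0, None)

    def test_co2_excess_speeds_pacing(self, plant_params):
        lo = dynamical_rr(1.0, plant_params.regression, co2_ratio=1.0)
        hi = dynamical_rr(1.0, plant_params.regression, co2_ratio=1.05)
        assert hi > lo


@pytest.fixture(scope="module")
def calibrated():
    return calibrate_plant()


class TestCalibration:
    def test_reproduces_shipped_reference(self, calibrated, plant_params):
        params, report = calibrated
        assert params.vol_gain == pytest.approx(plant_params.vol_gain, rel=1e-6)
        assert params.k_ex == pytest.approx(plant_params.k_ex, rel=1e-6)
        assert params.regression.a == pytest.approx(plant_params.regression.a, rel=1e-6)
        assert params.regression.b == pytest.approx(plant_params.regression.b, rel=1e-6)

    def test_meets_eupneic_contract(self, calibrated):
        _, report = calibrated
        assert report["rr"] == pytest.approx(56.0, rel=0.02)
        assert report["vt"] == pytest.approx(2.0, rel=0.02)
        assert report["dco2_per_breath"] < 0.005

    def test_idempotent(self, calibrated):
        params, _ = calibrated
        again, _ = calibrate_plant(params)
        assert again.vol_gain == pytest.approx(params.vol_gain, rel=1e-3)
        assert again.k_ex == pytest.approx(params.k_ex, rel=1e-3)

    def test_injured_model_breathes_shallower(self, plant_params):
        plant = RatPlant(replace(plant_params, wi=0.9), dynamic_rr=False)
        trace = plant.run(12 * 60.0 / 56.0)
        recs = segment_breaths(trace["volume_mL"], DT_S)
        vt = np.mean([r.vt for r in recs[-5:]])
        assert vt < 2.0

    def test_injured_rate_ordering_with_controller_off(self, plant_params):
        rates = []
        for wi in (1.0, 0.9, 0.8, 0.75):
            plant = RatPlant(replace(plant_params, wi=wi), dynamic_rr=True)
            trace = plant.run(35.0)
            recs = segment_breaths(trace["volume_mL"], DT_S)
            rates.append(np.mean([r.rr for r in recs[-10:]]))
        assert rates[0] < rates[1] < rates[2] < rates[3]

    def test_minute_ventilation_identity(self, plant_params):
        plant = RatPlant(plant_params, dynamic_rr=True)
        trace = plant.run(30.0)
        recs = segment_breaths(trace["volume_mL"], DT_S)
        recs = recs[5:]
        mv = np.mean([r.minute_ventilation for r in recs])
        duration_min = (recs[-1].t_start + recs[-1].period - recs[0].t_start) / 60.0
        inspired_rate = plant.inspired_volume / (plant.state.t / 60.0)
        assert mv == pytest.approx(inspired_rate, rel=0.02)

    def test_impossible_target_raises(self):
        bad = PlantParams(f_max=0.0)  # no muscle force, no oscillation
        with pytest.raises(CalibrationError):
            calibrate_plant(bad)
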