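import numpy as np
import pytest

from psitunnel.accuracy import angular_deviation, entry_distance
from psitunnel.error_simulation import (
    ErrorModel,
    QuartileSpec,
    calibrate_lognormal,
    perturb_tunnel,
    sample_magnitudes,
)
from psitunnel.planning import Ligament, Tunnel


def test_calibration_closed_form():
    mu, sigma = calibrate_lognormal(QuartileSpec(5.7, 4.0, 8.2))
    assert mu == pytest.approx(1.7405, abs=1e-3)
    assert sigma == pytest.approx(0.5321, abs=1e-3)


def test_degenerate_spec_is_point_mass():
    spec = QuartileSpec(6.0, 6.0, 6.0)
    assert calibrate_lognormal(spec)[1] == 0.0
    draws = sample_magnitudes(spec, 100, np.random.default_rng(0))
    assert np.all(draws == 6.0)


def test_invalid_quartiles_rejected():
    with pytest.raises(ValueError):
        QuartileSpec(5.0, 6.0, 7.0)  # q1 > median
    with pytest.raises(ValueError):
        calibrate_lognormal(QuartileSpec(1.0, 0.0, 2.0))  # q1 = 0, q3 > 0


def test_calibrated_draws_reproduce_median_and_iqr():
    rng = np.random.default_rng(12)
    for spec in (QuartileSpec(17.4, 12.7, 23.8), QuartileSpec(4.4, 2.6, 8.3)):
        x = sample_magnitudes(spec, 1_000_000, rng)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        assert med == pytest.approx(spec.median, rel=0.005)
        assert q3 / q1 == pytest.approx(spec.q3 / spec.q1, rel=0.005)


def test_default_model_loads_all_cells():
    model = ErrorModel.default()
    for group in ("freehand", "psi"):
        for lig in Ligament:
            for outcome in ("angular", "entry"):
                spec = model.spec(group, lig, outcome)
                assert spec.q1 <= spec.median <= spec.q3


def _point_mass_model(angle_deg: float, entry_mm: float) -> ErrorModel:
    cell = {
        "angular": QuartileSpec(angle_deg, angle_deg, angle_deg),
        "entry": QuartileSpec(entry_mm, entry_mm, entry_mm),
    }
    return ErrorModel({("psi", lig): dict(cell) for lig in Ligament})


class TestPerturbTunnel:
    planned = Tunnel([10.0, 0.0, 0.0], [-1.0, 0.5, 0.2], 8.0, 25.0, "LCL")

    def test_zero_error_model_is_identity(self):
        out = perturb_tunnel(
            self.planned, _point_mass_model(0.0, 0.0), "psi", np.random.default_rng(0)
        )
        assert angular_deviation(self.planned, out) == pytest.approx(0.0, abs=1e-9)
        assert entry_distance(self.planned, out) == pytest.approx(0.0, abs=1e-9)

    def test_fixed_angular_draw_tilts_by_exactly_that_angle(self):
        rng = np.random.default_rng(1)
        model = _point_mass_model(10.0, 0.0)
        for _ in range(10):  # any azimuth
            out = perturb_tunnel(self.planned, model, "psi", rng)
            assert angular_deviation(self.planned, out) == pytest.approx(10.0, abs=1e-6)

    def test_fixed_entry_draw_without_surface(self):
        out = perturb_tunnel(
            self.planned, _point_mass_model(0.0, 3.0), "psi", np.random.default_rng(2)
        )
        assert entry_distance(self.planned, out) == pytest.approx(3.0, abs=1e-9)
        assert out.diameter_mm == self.planned.diameter_mm
        assert out.depth_mm == self.planned.depth_mm

    def test_entry_stays_on_bone_with_surface(self, femur):
        surf = femur.surface()
        planned = Tunnel(
            femur.footprints[Ligament.LCL], [-1.0, 0.5, 0.0], 8.0, 25.0, "LCL"
        )
        model = _point_mass_model(0.0, 4.0)
        rng = np.random.default_rng(3)
        for _ in range(5):
            out = perturb_tunnel(planned, model, "psi", rng, surface=surf)
            d = surf.query(out.entry[None, :])[0][0]
            assert d <= 1e-6  # re-projected onto the surface
            # curvature shrinks the realized offset slightly below the draw
            assert 2.0 <= entry_distance(planned, out) <= 4.5

    def test_psi_mcl_median_matches_calibration(self):
        model = ErrorModel.default()
        planned = Tunnel([0, 0, 0], [1, 0, 0], 7.0, 25.0, "MCL")
        rng = np.random.default_rng(4)
        devs = [
            angular_deviation(planned, perturb_tunnel(planned, model, "psi", rng))
            for _ in range(10_000)
        ]
        assert 7.0 <= np.median(devs) <= 8.0


def test_freehand_dominates_psi_in_distribution():
    """Freehand angular error stochastically dominates PSI over the working
    quantile range for every ligament (its quartiles dominate row-wise)."""
    model = ErrorModel.default()
    rng = np.random.default_rng(5)
    probs = np.linspace(0.05, 0.95, 19)
    for lig in Ligament:
        f = sample_magnitudes(model.spec("freehand", lig, "angular"), 40_000, rng)
        p = sample_magnitudes(model.spec("psi", lig, "angular"), 40_000, rng)
        assert np.all(np.quantile(f, probs) > np.quantile(p, probs))


class TestSimulateStudy:
    def test_record_cardinality_and_schema(self, small_study):
        # 2 groups x 2 knees x 4 tunnels
        assert len(small_study) == 16
        assert set(small_study["group"]) == {"freehand", "psi"}
        assert set(small_study["ligament"]) == {"LCL", "PT", "MCL", "POL"}

    def test_same_seed_reproduces_identical_records(self):
        from psitunnel.error_simulation import simulate_study
        from psitunnel.synthetic_femur import FemurParams

        kw = dict(
            n_knees_per_group=1,
            seed=21,
            femur_params=FemurParams(pitch_mm=2.5),
            icp_sample_size=1000,
        )
        a = simulate_study(**kw)
        b = simulate_study(**kw)
        assert a.equals(b)
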