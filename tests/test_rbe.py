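import numpy as np
import pytest
from hypothesis import given, strategies as st

from orncausal.rbe import (ExtrapolationError, GENERIC_RBE, ToleranceCurve,
                           build_curve, empirical_rbe, equivalent_dose,
                           rbe_with_ci, volume_at)

# photon tolerance-curve knots in the shape the analysis produces:
# (dose level Gy, critical volume cc)
PHOTON_KNOTS = {40.0: 82.92, 50.0: 76.25, 60.0: 57.77, 70.0: 7.05}


@pytest.fixture()
def photon_curve():
    return build_curve(PHOTON_KNOTS, modality="VMAT")


class TestBuildCurve:
    def test_four_point_monotone_curve(self, photon_curve):
        assert photon_curve.dose_levels.tolist() == [40.0, 50.0, 60.0, 70.0]
        assert (np.diff(photon_curve.volumes) < 0).all()

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            build_curve({40.0: 80.0})

    def test_duplicate_dose_level_rejected(self):
        with pytest.raises(ValueError):
            ToleranceCurve("VMAT", np.array([40.0, 40.0]), np.array([5.0, 4.0]))

    def test_shuffled_input_order_is_irrelevant(self, photon_curve):
        shuffled = build_curve({60.0: 57.77, 40.0: 82.92, 70.0: 7.05,
                                50.0: 76.25}, modality="VMAT")
        assert np.array_equal(shuffled.dose_levels, photon_curve.dose_levels)
        assert np.array_equal(shuffled.volumes, photon_curve.volumes)

    def test_non_monotone_volumes_warn_but_build(self):
        with pytest.warns(RuntimeWarning, match="not monotone"):
            build_curve({40.0: 50.0, 50.0: 60.0, 60.0: 30.0})


class TestEquivalentDose:
    def test_segment_midpoint(self):
        curve = build_curve({60.0: 57.77, 70.0: 7.05})
        assert equivalent_dose(curve, (57.77 + 7.05) / 2) == pytest.approx(65.0)

    def test_knot_volume_returns_knot_dose(self, photon_curve):
        assert equivalent_dose(photon_curve, 57.77) == pytest.approx(60.0)

    def test_target_outside_volume_range_raises(self, photon_curve):
        with pytest.raises(ExtrapolationError):
            equivalent_dose(photon_curve, 100.0)
        with pytest.raises(ExtrapolationError):
            equivalent_dose(photon_curve, 1.0)

    def test_non_monotone_curve_returns_lowest_dose_with_warning(self):
        with pytest.warns(RuntimeWarning):
            curve = build_curve({40.0: 50.0, 50.0: 20.0, 60.0: 40.0, 70.0: 5.0})
        with pytest.warns(RuntimeWarning, match="multiple"):
            d = equivalent_dose(curve, 30.0)
        assert d == pytest.approx(40.0 + 10 * 20 / 30)

    @given(st.integers(0, 10_000))
    def test_round_trip_on_strictly_monotone_curve(self, seed):
        rng = np.random.default_rng(seed)
        doses = np.sort(rng.uniform(30, 80, 5))
        doses += np.arange(5) * 1e-3  # ensure strictly increasing
        vols = np.sort(rng.uniform(1, 100, 5))[::-1]
        vols -= np.arange(5) * 1e-3
        curve = ToleranceCurve("VMAT", doses, vols)
        for d in np.linspace(doses[0], doses[-1], 7):
            v = volume_at(curve, d)
            assert equivalent_dose(curve, v) == pytest.approx(d, abs=1e-9)


class TestEmpiricalRBE:
    @pytest.mark.parametrize("equiv,nominal,expected", [
        (58.58, 40.0, 1.611),
        (59.10, 50.0, 1.300),
        (61.75, 60.0, 1.132),
    ])
    def test_reference_equivalent_doses(self, equiv, nominal, expected):
        assert empirical_rbe(equiv, nominal) == pytest.approx(expected, abs=1e-3)

    def test_identity_when_equivalent_equals_physical(self):
        assert empirical_rbe(40.0 / 1.1, 40.0) == pytest.approx(1.0)

    def test_scaling_photon_curve_scales_rbe(self, photon_curve):
        c = 1.3
        scaled = ToleranceCurve("VMAT", photon_curve.dose_levels * c,
                                photon_curve.volumes)
        for target in (20.0, 57.77, 70.0):
            r1 = empirical_rbe(equivalent_dose(photon_curve, target), 50.0)
            r2 = empirical_rbe(equivalent_dose(scaled, target), 50.0)
            assert r2 == pytest.approx(c * r1, rel=1e-9)

    def test_non_positive_dose_rejected(self):
        with pytest.raises(ValueError):
            empirical_rbe(0.0, 40.0)
        with pytest.raises(ValueError):
            empirical_rbe(60.0, -1.0)


class TestRBEWithCI:
    def test_zero_variance_replicates_collapse_ci(self, photon_curve):
        boots = [photon_curve] * 10
        pv = {50.0: 30.0}
        pb = {50.0: np.full(10, 30.0)}
        table = rbe_with_ci(photon_curve, pv, boots, pb)
        row = table.iloc[0]
        assert row.ci_lo == pytest.approx(row.rbe)
        assert row.ci_hi == pytest.approx(row.rbe)
        assert not row.ci_unreliable

    def test_identical_cohorts_give_rbe_near_one(self):
        # proton nominal = photon physical * 1.1 at equal critical volumes
        curve = build_curve(PHOTON_KNOTS)
        for d, v in PHOTON_KNOTS.items():
            if d == 70.0:
                continue
            rbe = empirical_rbe(equivalent_dose(curve, v), d * GENERIC_RBE)
            assert rbe == pytest.approx(1.0, rel=1e-9)

    def test_known_dose_scale_shift_recovers_planted_rbe(self):
        """Compressing the proton dose axis by 1/1.2 relative to photon
        plants an RBE of exactly 1.2 at every matched volume."""
        photon = build_curve({40.0: 80.0, 50.0: 60.0, 60.0: 40.0, 70.0: 20.0})
        for nominal in (45.0, 55.0, 60.0):
            physical = nominal / GENERIC_RBE
            # proton reaches the same critical volume at physical dose
            # equal to photon_dose / 1.2
            photon_dose_same_volume = physical * 1.2
            target = volume_at(photon, photon_dose_same_volume)
            rbe = empirical_rbe(equivalent_dose(photon, target), nominal)
            assert rbe == pytest.approx(1.2, rel=1e-9)

    def test_excess_dropped_replicates_flag_unreliable(self, photon_curve):
        boots = [photon_curve] * 10
        pv = {50.0: 30.0}
        pb = {50.0: np.array([30.0, 30.0, 300.0, 300.0, 300.0, 300.0,
                              300.0, 300.0, 300.0, 300.0])}
        table = rbe_with_ci(photon_curve, pv, boots, pb)
        assert table.iloc[0].dropped_replicates == 8
        assert bool(table.iloc[0].ci_unreliable)

    def test_deterministic_table(self, photon_curve):
        rng = np.random.default_rng(0)
        boots = [build_curve({k: v * (1 + 0.01 * rng.standard_normal())
                              for k, v in PHOTON_KNOTS.items()})
                 for _ in range(20)]
        pv = {50.0: 30.0}
        pb = {50.0: rng.uniform(25, 35, 20)}
        t1 = rbe_with_ci(photon_curve, pv, boots, pb)
        t2 = rbe_with_ci(photon_curve, pv, boots, pb)
        assert t1.equals(t2)
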