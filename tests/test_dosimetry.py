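"""Calibration, local-deposition dose, DVH/D-metrics, and lung shunt."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxdose90 import (
    CalibrationInput,
    CompartmentSet,
    ScalarVolume,
    VoxelGrid,
    Y90_J_PER_GBQ,
    calibrate_activity,
    d_metric,
    dose_report,
    dvh,
    ldm_dose,
    lung_dose,
    lung_shunt_fraction,
    mean_dose,
    tn_ratio,
    v_metric,
)

from conftest import random_dose_volume, single_compartment


def counts_volume(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    grid = VoxelGrid(shape=values.shape, spacing_mm=spacing)
    return ScalarVolume(grid, values, "counts")


class TestCalibration:
    def test_uniform_split(self):
        vol = counts_volume(np.full((5, 5, 4), 3.0))
        act = calibrate_activity(CalibrationInput(vol, 2.0))
        np.testing.assert_allclose(act.values, 2.0 / 100.0, rtol=1e-12)

    def test_proportional_allocation(self):
        vol = counts_volume(np.array([1.0, 3.0]).reshape(2, 1, 1))
        act = calibrate_activity(CalibrationInput(vol, 1.0))
        np.testing.assert_allclose(act.values.ravel(), [0.25, 0.75], rtol=1e-12)

    def test_total_is_net_activity(self, rng):
        vol = counts_volume(rng.gamma(2.0, 50.0, size=(8, 8, 8)))
        act = calibrate_activity(CalibrationInput(vol, 2.0))
        assert act.total() == pytest.approx(2.0, rel=1e-9)

    def test_fov_masks_out_background(self, rng):
        values = rng.gamma(2.0, 50.0, size=(6, 6, 6))
        fov = np.zeros(values.shape, bool)
        fov[:3] = True
        act = calibrate_activity(CalibrationInput(counts_volume(values), 1.5, fov))
        assert act.values[~fov].max() == 0.0
        assert act.total() == pytest.approx(1.5, rel=1e-9)

    def test_empty_field_rejected(self):
        vol = counts_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty field"):
            calibrate_activity(CalibrationInput(vol, 1.0))


class TestLdmDose:
    def test_unit_activity_unit_mass_gives_constant(self):
        # one voxel of exactly 1 kg holding 1 GBq -> 49.67 Gy
        side = (1e6 / 1.03) ** (1.0 / 3.0)  # mm; voxel mass = 1.000 kg at 1.03 g/mL
        grid = VoxelGrid(shape=(1, 1, 1), spacing_mm=(side, side, side))
        act = ScalarVolume(grid, np.array([[[1.0]]]), "activity_GBq")
        dose = ldm_dose(act, 1.03)
        assert dose.values[0, 0, 0] == pytest.approx(49.67, rel=1e-12)

    def test_milli_scale(self):
        # 0.001 GBq in a 0.001 kg voxel -> same 49.67 Gy
        side = (1e3 / 1.03) ** (1.0 / 3.0)
        grid = VoxelGrid(shape=(1, 1, 1), spacing_mm=(side, side, side))
        act = ScalarVolume(grid, np.array([[[1e-3]]]), "activity_GBq")
        assert ldm_dose(act, 1.03).values.item() == pytest.approx(49.67, rel=1e-12)

    def test_zero_maps_to_zero(self):
        grid = VoxelGrid(shape=(4, 4, 4), spacing_mm=(2, 2, 2))
        act = ScalarVolume(grid, np.zeros(grid.shape), "activity_GBq")
        assert ldm_dose(act).total() == 0.0

    def test_energy_bookkeeping(self, rng):
        act_vals = rng.gamma(2.0, 1e-3, size=(10, 10, 10))
        grid = VoxelGrid(shape=(10, 10, 10), spacing_mm=(4.42, 4.42, 2.50))
        act = ScalarVolume(grid, act_vals, "activity_GBq")
        dose = ldm_dose(act, 1.03)
        voxel_mass_kg = 1.03 * grid.voxel_volume_mL / 1000.0
        energy = (dose.values * voxel_mass_kg).sum()
        assert energy == pytest.approx(Y90_J_PER_GBQ * act.total(), rel=1e-9)


class TestCompartmentMetrics:
    def test_mean_dose_examples(self):
        grid = VoxelGrid(shape=(2, 1, 1), spacing_mm=(1, 1, 1))
        dose = ScalarVolume(grid, np.array([10.0, 30.0]).reshape(2, 1, 1), "dose_Gy")
        comp = single_compartment(grid)
        assert mean_dose(dose, comp, "roi") == pytest.approx(20.0)

    def test_mean_dose_matches_accumulation_oracle(self, rng):
        dose = random_dose_volume(rng)
        mask = rng.random(dose.grid.shape) > 0.4
        comp = CompartmentSet(dose.grid, {"roi": mask})
        oracle = sum(dose.values[mask].tolist()) / mask.sum()
        assert mean_dose(dose, comp, "roi") == pytest.approx(oracle, rel=1e-12)

    def test_tn_ratio(self):
        grid = VoxelGrid(shape=(2, 1, 1), spacing_mm=(1, 1, 1))
        dose = ScalarVolume(grid, np.array([100.0, 40.0]).reshape(2, 1, 1), "dose_Gy")
        masks = {
            "perfused_tumor": np.array([True, False]).reshape(2, 1, 1),
            "perfused_normal": np.array([False, True]).reshape(2, 1, 1),
        }
        comp = CompartmentSet(grid, masks)
        assert tn_ratio(dose, comp) == pytest.approx(2.5)

    def test_tn_undefined_for_zero_normal(self):
        grid = VoxelGrid(shape=(2, 1, 1), spacing_mm=(1, 1, 1))
        dose = ScalarVolume(grid, np.array([100.0, 0.0]).reshape(2, 1, 1), "dose_Gy")
        comp = CompartmentSet(
            grid,
            {
                "perfused_tumor": np.array([True, False]).reshape(2, 1, 1),
                "perfused_normal": np.array([False, True]).reshape(2, 1, 1),
            },
        )
        with pytest.raises(ValueError, match="undefined T/N"):
            tn_ratio(dose, comp)


class TestDvhAndDMetrics:
    def test_uniform_dose_step_function(self):
        grid = VoxelGrid(shape=(5, 5, 4), spacing_mm=(1, 1, 1))
        dose = ScalarVolume(grid, np.full(grid.shape, 40.0), "dose_Gy")
        comp = single_compartment(grid)
        g, v = dvh(dose, comp, "roi", n_bins=100)
        assert np.all(v[g <= 40.0] == 100.0)
        for x in (10, 50, 90, 100):
            assert d_metric(dose, comp, "roi", x) == 40.0

    def test_two_level_field(self):
        grid = VoxelGrid(shape=(10, 1, 1), spacing_mm=(1, 1, 1))
        vals = np.array([0.0] * 5 + [100.0] * 5).reshape(10, 1, 1)
        dose = ScalarVolume(grid, vals, "dose_Gy")
        comp = single_compartment(grid)
        assert v_metric(dose, comp, "roi", 50.0) == 50.0
        g, v = dvh(dose, comp, "roi", n_bins=201)
        assert v[np.searchsorted(g, 50.0)] == 50.0

    def test_decile_oracle(self):
        # doses 10..100 Gy on 10 voxels: D10=100, D50=60, D90=20, D100=10
        grid = VoxelGrid(shape=(10, 1, 1), spacing_mm=(1, 1, 1))
        dose = ScalarVolume(
            grid, np.arange(10.0, 101.0, 10.0).reshape(10, 1, 1), "dose_Gy"
        )
        comp = single_compartment(grid)
        assert d_metric(dose, comp, "roi", 10) == 100.0
        assert d_metric(dose, comp, "roi", 50) == 60.0
        assert d_metric(dose, comp, "roi", 90) == 20.0
        assert d_metric(dose, comp, "roi", 100) == 10.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 500))
    def test_d_metric_matches_sort_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        doses = rng.gamma(2.0, 40.0, size=n)
        grid = VoxelGrid(shape=(n, 1, 1), spacing_mm=(1, 1, 1))
        vol = ScalarVolume(grid, doses.reshape(n, 1, 1), "dose_Gy")
        comp = single_compartment(grid)
        desc = sorted(doses, reverse=True)
        for x in (10, 33.3, 50, 70, 90, 100):
            k = math.ceil(x * n / 100.0)
            assert d_metric(vol, comp, "roi", x) == desc[k - 1]

    def test_d_metric_monotone_in_x(self, rng):
        dose = random_dose_volume(rng)
        comp = single_compartment(dose.grid)
        ds = [d_metric(dose, comp, "roi", x) for x in (10, 50, 90, 100)]
        assert ds[0] >= ds[1] >= ds[2] >= ds[3]
        assert ds[3] == dose.values.min()

    def test_dvh_mean_consistency(self, rng):
        # mean dose equals the integral of the survival curve (Riemann sum)
        dose = random_dose_volume(rng, shape=(20, 20, 20))
        comp = single_compartment(dose.grid)
        g, v = dvh(dose, comp, "roi", n_bins=4000)
        implied_mean = np.trapezoid(v / 100.0, g)
        assert implied_mean == pytest.approx(mean_dose(dose, comp, "roi"), rel=2e-3)


class TestDoseLinearity:
    def test_scaling_activity_scales_doses_not_ratios(self, rng):
        counts = rng.gamma(2.0, 50.0, size=(8, 8, 8))
        grid = VoxelGrid(shape=(8, 8, 8), spacing_mm=(4, 4, 4))
        vol = ScalarVolume(grid, counts, "counts")
        masks = {
            "perfused_tumor": counts > np.quantile(counts, 0.8),
            "perfused_normal": counts <= np.quantile(counts, 0.8),
        }
        comp = CompartmentSet(grid, masks)
        k = 2.7
        results = {}
        for label, net in (("base", 1.0), ("scaled", k)):
            act = calibrate_activity(CalibrationInput(vol, net))
            dose = ldm_dose(act)
            results[label] = (
                mean_dose(dose, comp, "perfused_tumor"),
                d_metric(dose, comp, "perfused_tumor", 50),
                tn_ratio(dose, comp),
            )
        assert results["scaled"][0] == pytest.approx(k * results["base"][0], rel=1e-12)
        assert results["scaled"][1] == pytest.approx(k * results["base"][1], rel=1e-12)
        assert results["scaled"][2] == pytest.approx(results["base"][2], rel=1e-12)


class TestLungShunt:
    def _views(self, lung_counts, liver_counts):
        ant = np.zeros((4, 4))
        post = np.zeros((4, 4))
        lung = np.zeros((4, 4), bool)
        liver = np.zeros((4, 4), bool)
        lung[0, 0] = liver[3, 3] = True
        ant[0, 0], post[0, 0] = lung_counts
        ant[3, 3], post[3, 3] = liver_counts
        return ant, post, lung, liver

    def test_hand_arithmetic(self):
        res = lung_shunt_fraction(*self._views((100.0, 100.0), (900.0, 900.0)))
        assert res.gm_lung == pytest.approx(100.0)
        assert res.gm_liver == pytest.approx(900.0)
        assert res.lsf == pytest.approx(0.10)

    def test_zero_lung_counts(self):
        res = lung_shunt_fraction(*self._views((0.0, 0.0), (500.0, 500.0)))
        assert res.lsf == 0.0

    def test_equal_views_reduce_to_count_fraction(self):
        res = lung_shunt_fraction(*self._views((30.0, 30.0), (70.0, 70.0)))
        assert res.lsf == pytest.approx(0.30)

    def test_zero_liver_rejected(self):
        with pytest.raises(ValueError, match="liver"):
            lung_shunt_fraction(*self._views((10.0, 10.0), (0.0, 0.0)))


class TestLungDose:
    def test_examples(self):
        assert lung_dose(1.0, 0.0, 1.0) == 0.0
        assert lung_dose(1.0, 0.10, 1.0) == pytest.approx(4.967)

    def test_limit_inversion(self):
        # 30 Gy at lsf 0.10 over 1 kg needs 30/4.967 = 6.040 GBq
        a_30 = 30.0 / lung_dose(1.0, 0.10, 1.0)
        assert a_30 == pytest.approx(6.040, abs=1e-3)
        assert lung_dose(a_30 * 1.01, 0.10, 1.0) > 30.0


def test_dose_report_assembles_consistent_metrics(rng):
    dose = random_dose_volume(rng, shape=(15, 15, 15))
    vals = dose.values
    masks = {
        "perfused_tumor": vals > np.quantile(vals, 0.85),
        "perfused_normal": vals <= np.quantile(vals, 0.85),
    }
    comp = CompartmentSet(dose.grid, masks)
    report = dose_report(dose, comp, modality="test")
    for role, st_ in report.roles.items():
        assert st_.min_dose_Gy <= st_.mean_dose_Gy <= st_.max_dose_Gy
        assert st_.dvh_volume_percent[0] == 100.0
        assert np.all(np.diff(st_.dvh_volume_percent) <= 0)
        d = st_.d_metrics_Gy
        assert d[10] >= d[50] >= d[90]
    assert report.tn_ratio == pytest.approx(
        tn_ratio(dose, comp), rel=1e-12
    )
    payload = report.to_dict()
    assert set(payload["roles"]) == {"perfused_tumor", "perfused_normal"}
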