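"""Derived thermodynamic tables, experiment conversions and ring analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from sugarosp import compare
from sugarosp.compare import (
    EXP_CONDITIONS,
    SIM_CONDITIONS,
    anomer_delta,
    anomer_table,
    binding_vs_km_table,
    classify_ring_conformation,
    cremer_pople,
    deviation_stats,
    dg_to_ratio,
    enantiomer_report,
    exp_average_anomers,
    free_energy_range,
    km_to_relative_dg,
    load_table,
    ratio_to_dg,
    relative_solvation,
)


@pytest.fixture(scope="module")
def t1():
    return load_table("solvation")


@pytest.fixture(scope="module")
def t2():
    return load_table("anomers")


@pytest.fixture(scope="module")
def t3():
    return load_table("binding")


@pytest.fixture(scope="module")
def t4():
    return load_table("km")


class TestSolvation:
    def test_row_identity_holds_for_all_rows(self, t1):
        vac = t1.rename(columns={"dg_vac": "value", "dg_vac_err": "stderr"})
        wat = t1.rename(columns={"dg_water": "value", "dg_water_err": "stderr"})
        cols = ["index", "value", "stderr"]
        out = relative_solvation(vac[cols], wat[cols])
        # reproduces the published ddG_solv column within the rounding of
        # the two one-decimal inputs (each carries up to 0.05 of rounding)
        assert np.allclose(out["ddg_solv"], t1["ddg_solv"], atol=0.1001)
        assert (out["ddg_solv_err"] >= out["stderr_vac"] - 1e-12).all()
        assert (out["ddg_solv_err"] >= out["stderr_water"] - 1e-12).all()

    def test_published_glucose_rows(self, t1):
        row = t1[t1["index"] == 1].iloc[0]
        assert row["dg_water"] - row["dg_vac"] == pytest.approx(5.0)
        row5 = t1[t1["index"] == 5].iloc[0]
        assert row5["dg_water"] - row5["dg_vac"] == pytest.approx(13.9)

    def test_identical_columns_give_zero(self, t1):
        vac = t1.rename(columns={"dg_vac": "value", "dg_vac_err": "stderr"})
        cols = ["index", "value", "stderr"]
        out = relative_solvation(vac[cols], vac[cols])
        assert np.allclose(out["ddg_solv"], 0.0)


class TestAnomers:
    def test_galactose_delta_exact(self, t1):
        water = t1.rename(columns={"dg_water": "value"})
        assert anomer_delta(water, "galactose") == pytest.approx(-1.7)

    def test_all_d_rows_match_published_within_input_rounding(self, t1, t2):
        water = t1.rename(columns={"dg_water": "value"})
        table = anomer_table(water, experiment=t2)
        merged = table.set_index("base_name")
        for _, row in t2.iterrows():
            assert merged.loc[row["base_name"], "dg_beta_alpha"] == pytest.approx(
                row["dg_beta_alpha_simulation"], abs=0.1001)

    def test_missing_anomer_rejected(self, t1):
        water = t1.rename(columns={"dg_water": "value"})
        only_beta = water[water["anomer"] == "beta"]
        with pytest.raises(ValueError):
            anomer_delta(only_beta, "glucose")

    def test_equal_values_give_zero_delta(self):
        df = pd.DataFrame({
            "base_name": ["glucose"] * 2, "series": ["d"] * 2,
            "anomer": ["alpha", "beta"], "value": [10.0, 10.0]})
        assert anomer_delta(df, "glucose") == 0.0


class TestRatioConversion:
    def test_unit_ratio_gives_zero(self):
        assert ratio_to_dg(1.0) == 0.0

    def test_ratio_e_gives_minus_kBT(self):
        assert ratio_to_dg(math.e) == pytest.approx(-EXP_CONDITIONS.kBT)

    def test_round_trip(self):
        for dg in (-4.8, -1.2, 0.0, 1.8):
            assert ratio_to_dg(dg_to_ratio(dg)) == pytest.approx(dg)

    def test_glucose_experimental_ratio(self):
        # dG = -1.2 kJ/mol at 30 C corresponds to ~61.7% beta pyranose
        r = dg_to_ratio(-1.2)
        beta_frac = r / (1 + r)
        assert beta_frac == pytest.approx(0.617, abs=0.001)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ratio_to_dg(0.0)


class TestKmConversion:
    def test_published_conversions_to_one_decimal(self, t4):
        out = km_to_relative_dg(t4, "glucose")
        got = out.set_index("base_name")["ddg_bind_exp"]
        assert got["glucose"] == 0.0
        assert got["mannose"] == pytest.approx(12.3, abs=0.05)
        assert got["talose"] == pytest.approx(11.5, abs=0.05)
        assert got["galactose"] == pytest.approx(0.6, abs=0.05)

    def test_scale_invariance_of_differences(self, t4):
        doubled = t4.copy()
        doubled["km_mM"] *= 2
        a = km_to_relative_dg(t4, "glucose")["ddg_bind_exp"]
        b = km_to_relative_dg(doubled, "glucose")["ddg_bind_exp"]
        assert np.allclose(a, b)

    def test_antisymmetry_under_reference_swap(self, t4):
        a = km_to_relative_dg(t4, "glucose").set_index("base_name")
        b = km_to_relative_dg(t4, "mannose").set_index("base_name")
        assert a.loc["mannose", "ddg_bind_exp"] == pytest.approx(
            -b.loc["glucose", "ddg_bind_exp"])

    def test_missing_reference_rejected(self, t4):
        with pytest.raises(ValueError):
            km_to_relative_dg(t4, "sucrose")


class TestAnomerAveraging:
    def test_equal_values_are_fixed_point(self):
        v, err = exp_average_anomers(7.0, 7.0, err_alpha=0.3, err_beta=0.3)
        assert v == pytest.approx(7.0) and err == pytest.approx(0.3)

    def test_one_unsampled_adds_kBT_ln2(self):
        v, _ = exp_average_anomers(5.0, math.inf)
        assert v == pytest.approx(5.0 + SIM_CONDITIONS.kBT * math.log(2))

    def test_both_unsampled_rejected(self):
        with pytest.raises(ValueError):
            exp_average_anomers(math.inf, math.inf)

    def test_published_pose_a_mannose(self, t1, t3):
        # anomer-combined relative binding of d-mannose in pose A, from the
        # published per-anomer free energies, reproduces the summary table
        water = t1.rename(columns={"dg_water": "value"})
        bound = t3.rename(columns={"dg_poseA": "value"}).assign(pose="A")
        t4 = load_table("km")
        table = binding_vs_km_table(water, bound, t4)
        got = table.set_index("base_name")
        assert got.loc["mannose", "ddg_bind_poseA"] == pytest.approx(10.9, abs=0.25)
        assert got.loc["glucose", "ddg_bind_poseA"] == pytest.approx(0.0, abs=1e-9)

    def test_published_pose_b_columns(self, t1, t3, t4):
        water = t1.rename(columns={"dg_water": "value"})
        bound = t3.rename(columns={"dg_poseB": "value"}).assign(pose="B")
        got = binding_vs_km_table(water, bound, t4).set_index("base_name")
        assert got.loc["mannose", "ddg_bind_poseB"] == pytest.approx(5.4, abs=0.25)
        assert got.loc["galactose", "ddg_bind_poseB"] == pytest.approx(3.4, abs=0.25)
        assert got.loc["talose", "ddg_bind_poseB"] == pytest.approx(3.6, abs=0.25)


class TestEnantiomerReport:
    def test_pose_a_extremes(self, t3):
        rep = enantiomer_report(t3.rename(columns={"dg_poseA": "value"}))
        assert rep["abs_difference"].max() == pytest.approx(60.1)
        assert rep["abs_difference"].min() == pytest.approx(0.7)

    def test_pose_b_maximum(self, t3):
        rep = enantiomer_report(t3.rename(columns={"dg_poseB": "value"}))
        assert rep["abs_difference"].max() == pytest.approx(24.1)

    def test_vacuum_pair_difference_range(self, t1):
        rep = enantiomer_report(t1.rename(columns={"dg_vac": "value"}))
        assert rep["abs_difference"].min() == pytest.approx(0.1)
        assert rep["abs_difference"].max() == pytest.approx(1.8)

    def test_identical_values_give_zero_pairs(self):
        df = pd.DataFrame({"index": range(1, 33), "value": 5.0})
        rep = enantiomer_report(df)
        assert (rep["abs_difference"] == 0).all()


class TestRanges:
    def test_published_free_energy_spreads(self, t1):
        assert free_energy_range(t1["dg_vac"]) == pytest.approx(13.6)
        assert free_energy_range(t1["dg_water"]) == pytest.approx(18.7)
        assert free_energy_range(t1["dg_water"],
                                 exclude_max=True) == pytest.approx(13.9)


class TestDeviationStats:
    def test_published_anomer_deviation_summary(self, t2):
        stats = deviation_stats(t2["dg_beta_alpha_simulation"],
                                t2["dg_beta_alpha_experiment"])
        assert round(stats.mean_signed, 1) == 0.5
        assert round(stats.sd, 1) == 1.3
        assert stats.max_abs == pytest.approx(2.3)
        assert stats.min_abs == pytest.approx(0.0)

    def test_identical_columns(self):
        stats = deviation_stats([1.0, 2.0], [1.0, 2.0])
        assert stats.mean_signed == 0.0 and stats.sd == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deviation_stats([1.0], [1.0, 2.0])


def _hexagon(z, radius=0.15):
    ang = np.radians(np.arange(6) * 60.0)
    return np.c_[radius * np.cos(ang), radius * np.sin(ang), np.asarray(z)]


class TestRingConformation:
    # atom ordering O5, C1, C2, C3, C4, C5

    def test_ideal_chair_is_4C1(self):
        # C4 above, C1 below the mean plane
        ring = _hexagon(0.025 * np.array([1, -1, 1, -1, 1, -1]))
        conf = classify_ring_conformation(ring)
        assert conf.label == "4C1" and conf.theta < 45

    def test_mirror_image_is_1C4(self):
        ring = _hexagon(0.025 * np.array([1, -1, 1, -1, 1, -1]))
        mirrored = ring * np.array([1, 1, -1])
        assert classify_ring_conformation(mirrored).label == "1C4"

    def test_ideal_boat_labels(self):
        # O5 and C3 displaced to the same side -> 3,OB; opposite -> B3,O
        up = _hexagon([0.03, -0.01, -0.01, 0.03, -0.01, -0.01])
        down = _hexagon([-0.03, 0.01, 0.01, -0.03, 0.01, 0.01])
        assert classify_ring_conformation(up).label == "3,OB"
        assert classify_ring_conformation(down).label == "B3,O"

    def test_boat_family_stable_under_ring_rotation_by_two(self):
        ring = _hexagon([0.03, -0.01, -0.01, 0.03, -0.01, -0.01])
        rotated = np.roll(ring, 2, axis=0)
        conf = classify_ring_conformation(rotated)
        assert conf.label in compare._BOATS  # same family, relabeled phase
        assert conf.theta == pytest.approx(90.0, abs=1.0)

    def test_planar_ring_rejected(self):
        with pytest.raises(ValueError):
            classify_ring_conformation(_hexagon(np.zeros(6)))

    def test_fourteen_conformers_reachable(self):
        # sweep theta/phi space and confirm the classification is total over
        # the 14 canonical labels
        seen = set()
        for theta in (5, 90, 175):
            for phi in range(0, 360, 15):
                j = np.arange(6)
                z = (math.cos(math.radians(theta)) * np.cos(np.pi * j)
                     + math.sin(math.radians(theta)) * np.sqrt(2)
                     * np.cos(math.radians(phi) + 2 * np.pi * j / 3)) * 0.02
                # invert the normal convention used by the classifier
                seen.add(classify_ring_conformation(_hexagon(-z)).label)
        assert seen == set(compare.RING_CONFORMERS)
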