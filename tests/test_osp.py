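"""Zwanzig estimation, frame classification and reference combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sugarosp import (
    DiscreteToySystem,
    FreeEnergyEstimate,
    ThermoConditions,
    Trajectory,
    all_identities,
    classify_frames,
    code_to_identity,
    combine_references,
    enantiomer_of,
    occurrence_stats,
    perturbation_energy_series,
    reference_topology,
    reference_transfer,
    reweight_free_energy,
    zwanzig,
)

KBT = 2.4943386  # 300 K


def _traj(xi, phi=None, theta=None):
    n = len(xi)
    return Trajectory(
        xi=np.asarray(xi, dtype=float),
        phi=np.zeros((n, 6)) if phi is None else np.asarray(phi, float),
        theta=np.full((n, 6), 109.5) if theta is None else np.asarray(theta, float),
    )


class TestPerturbationSeries:
    def test_level_a_depends_only_on_improper_angles(self, conditions):
        ref = reference_topology("a")
        xi = np.array([[10.0, -20, 30, -5, 50], [0.0, 1, 2, 3, 4]])
        t1 = _traj(xi, phi=np.full((2, 6), 10.0), theta=np.full((2, 6), 100.0))
        t2 = _traj(xi, phi=np.full((2, 6), 170.0), theta=np.full((2, 6), 120.0))
        s1 = perturbation_energy_series(t1, ref)
        s2 = perturbation_energy_series(t2, ref)
        assert np.allclose(s1.dH, s2.dH)

    def test_single_frame_hand_check(self):
        # frame at the parent minimum: dH to the parent is the sum of the
        # remaining centers' improper energies, here zero at every center
        ref = reference_topology("a")
        xi0 = 35.264
        t = _traj([[xi0, xi0, xi0, xi0, xi0]])
        s = perturbation_energy_series(t, ref, [code_to_identity("22222")])
        assert s.dH[0, 0] == pytest.approx(0.0, abs=1e-12)
        # flipping center 2 to the mirrored well costs 1/2 k (2 xi0)^2
        s2 = perturbation_energy_series(t, ref, [code_to_identity("24222")])
        assert s2.dH[0, 0] == pytest.approx(0.5 * 0.102 * (2 * xi0) ** 2)

    def test_proper_and_angle_terms_enter_only_above_level_a(self):
        t = _traj([[0.0] * 5], phi=np.full((1, 6), 15.0),
                  theta=np.full((1, 6), 100.0))
        target = [code_to_identity("22222")]
        dh_a = perturbation_energy_series(t, reference_topology("a"), target)
        dh_ab = perturbation_energy_series(t, reference_topology("ab"), target)
        dh_abc = perturbation_energy_series(t, reference_topology("abc"), target)
        assert dh_ab.dH[0, 0] != pytest.approx(dh_a.dH[0, 0])
        assert dh_abc.dH[0, 0] != pytest.approx(dh_ab.dH[0, 0])


class TestZwanzig:
    def test_zero_series_gives_zero(self, conditions):
        est = zwanzig(np.zeros(100), conditions)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_passes_through(self, conditions):
        est = zwanzig(np.full(50, 7.25), conditions)
        assert est.value == pytest.approx(7.25)

    def test_two_value_closed_form(self, conditions):
        dH = np.tile([0.0, 5.0], 500)
        expected = -KBT * math.log((1 + math.exp(-5 / KBT)) / 2)
        est = zwanzig(dH, conditions)
        assert est.value == pytest.approx(expected, rel=1e-9)

    def test_logsumexp_contract_no_overflow(self, conditions):
        for scale in (1e4, -1e4):
            est = zwanzig(np.full(20, scale), conditions, with_stderr=False)
            assert est.value == pytest.approx(scale)

    def test_all_infinite_dH_reports_unsampled(self, conditions):
        est = zwanzig(np.full(10, np.inf), conditions)
        assert est.unsampled and est.value == math.inf

    def test_empty_input_rejected(self, conditions):
        with pytest.raises(ValueError):
            zwanzig(np.array([]), conditions)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=200))
    def test_gibbs_bogoliubov_bound(self, dh):
        # exponential averaging never exceeds the arithmetic mean
        cond = ThermoConditions(300.0)
        est = zwanzig(np.array(dh), cond, with_stderr=False)
        assert est.value <= np.mean(dh) + 1e-9

    def test_dominant_weight_flagged_unreliable(self, conditions):
        dH = np.concatenate([[-50.0], np.zeros(99)])
        est = zwanzig(dH, conditions)
        assert est.max_weight > 0.5 and est.unreliable


class TestClassifyFrames:
    def test_parent_and_mirror_wells(self):
        t = _traj([[30.0] * 5, [-30.0] * 5])
        states = classify_frames(t)
        assert states[0] == 1 and states[1] == 32

    def test_mirrored_frame_maps_to_enantiomer(self):
        rng = np.random.default_rng(0)
        xi = rng.uniform(-60, 60, (50, 5))
        xi[xi == 0] = 1.0
        s1 = classify_frames(_traj(xi))
        s2 = classify_frames(_traj(-xi))
        for a, b in zip(s1, s2):
            ident = next(i for i in all_identities() if i.index == a)
            assert enantiomer_of(ident).index == b

    def test_tie_break_at_zero_assigns_digit_two(self):
        # measure-zero event, resolved deterministically toward digit 2
        t = _traj([[0.0] * 5])
        assert classify_frames(t)[0] == 1


class TestOccurrenceStats:
    def test_hand_run_length_enumeration(self):
        stats = occurrence_stats(np.array([1, 1, 1, 2, 1]), dt_ps=0.5,
                                 min_lifetime_ps=1.0)
        assert stats.qualifying_runs[0] == 1  # the 3-frame run of state 1
        assert stats.qualifying_runs[1] == 0  # 1 frame * 0.5 ps < 1 ps
        assert stats.time_fraction[0] == pytest.approx(0.8)

    def test_constant_series_single_run(self):
        stats = occurrence_stats(np.full(100, 17), dt_ps=0.5)
        assert stats.qualifying_runs[16] == 1
        assert stats.time_fraction[16] == pytest.approx(1.0)

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(1)
        stats = occurrence_stats(rng.integers(1, 33, 1000), dt_ps=0.5)
        assert stats.time_fraction.sum() == pytest.approx(1.0)


class TestReferenceTransfer:
    def test_identity_transfer_is_zero(self, small_trajectory, ab_reference,
                                       conditions):
        est = reference_transfer(small_trajectory, ab_reference, ab_reference,
                                 conditions)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_discrete_system_transfer_matches_partition_functions(self):
        # brute-force oracle: free energies by direct summation over states
        cond = ThermoConditions(300.0)
        e_r2 = np.array([0.0, 1.0, 3.0, 0.5])
        e_r1 = np.array([2.0, 0.0, 1.0, 4.0])
        s2 = DiscreteToySystem(tuple(e_r2), cond.kBT)
        s1 = DiscreteToySystem(tuple(e_r1), cond.kBT)
        states = s2.sample(200_000, seed=9)
        dH = (e_r1 - e_r2)[states]
        est = zwanzig(dH, cond)
        exact = s1.free_energy() - s2.free_energy()
        assert abs(est.value - exact) < 3 * est.stderr

    def test_cycle_closure_is_frame_algebraic(self, small_trajectory,
                                              conditions):
        # dG_{R1->i} from R2 equals dG_{R2->i} - dG_{R2->R1} exactly
        r2 = reference_topology("ab")
        r1 = reference_topology("a")
        target = code_to_identity("24222")
        via = reweight_free_energy(small_trajectory, r2, r1, target, conditions)
        direct_i = zwanzig(perturbation_energy_series(
            small_trajectory, r2, [target]).dH[:, 0], conditions)
        transfer = reference_transfer(small_trajectory, r2, r1, conditions)
        assert via.value == pytest.approx(direct_i.value - transfer.value,
                                          abs=1e-12)

    def test_negligible_overlap_flagged(self, conditions):
        # a reference differing by a huge constant term leaves one frame
        # carrying all the weight -> effective sample size collapses
        r2 = reference_topology("ab")
        r1 = reference_topology("abc")
        xi = np.zeros((50, 5))
        phi = np.full((50, 6), 60.0)
        theta = np.tile(np.linspace(60, 160, 50)[:, None], (1, 6))
        est = reference_transfer(_traj(xi, phi, theta), r2, r1, conditions)
        assert est.unsampled


class TestCombineReferences:
    def _est(self, v, err=0.1):
        return FreeEnergyEstimate("x", v, err, 10)

    def test_equal_values_are_a_fixed_point(self, conditions):
        out = combine_references([self._est(4.2)] * 3, conditions)
        assert out.value == pytest.approx(4.2)
        assert out.stderr == pytest.approx(0.1)

    def test_two_unsampled_references_add_kBT_ln3(self, conditions):
        inf = FreeEnergyEstimate("x", math.inf, 0.0, 10, unsampled=True)
        out = combine_references([self._est(5.0), inf, inf], conditions)
        assert out.value == pytest.approx(5.0 + KBT * math.log(3), rel=1e-9)

    def test_partial_combination_closed_form(self, conditions):
        vals = [self._est(0.0), self._est(KBT * math.log(2)),
                FreeEnergyEstimate("x", math.inf, 0.0, 10, unsampled=True)]
        out = combine_references(vals, conditions)
        assert out.value == pytest.approx(-KBT * math.log(1.5 / 3), rel=1e-6)

    def test_all_unsampled_propagates_flag(self, conditions):
        inf = FreeEnergyEstimate("x", math.inf, 0.0, 10, unsampled=True)
        out = combine_references([inf, inf, inf], conditions)
        assert out.unsampled

    def test_empty_input_rejected(self, conditions):
        with pytest.raises(ValueError):
            combine_references([], conditions)
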