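import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegconf import (
    ClassifierConfig,
    Trajectory,
    build_topology,
    classify_dihedrals,
    ensemble_average,
    equilibrium_window,
    helicality,
    measure_geometry,
)
from pegconf.builder import build_ideal_helix
from pegconf.measure import rg_of_points


@pytest.fixture(scope="module")
def meas(helix6):
    return measure_geometry(helix6)


class TestCrystalParameterMeasurement:
    """The ideal helix reproduces every crystal parameter it was built from."""

    def test_oc_dihedrals(self, meas):
        np.testing.assert_allclose(meas.oc_dihedrals, 177.41, atol=1e-6)

    def test_oc_bond_lengths(self, meas):
        np.testing.assert_allclose(meas.oc_lengths, 1.43, atol=1e-6)

    def test_hch_angles(self, meas):
        np.testing.assert_allclose(meas.hch_angles, 109.01, atol=1e-6)

    def test_coc_angles(self, meas):
        np.testing.assert_allclose(meas.coc_angles, 115.64, atol=1e-6)


@pytest.mark.parametrize(
    "value,state",
    [
        (75.0, "g+"),
        (-74.95, "g-"),
        (120.0, "other"),
        (50.0, "g+"),  # inclusive lower band edge
        (100.0, "g+"),  # inclusive upper band edge
        (-50.0, "g-"),
        (150.0, "trans"),  # inclusive trans edge
        (-165.0, "trans"),
        (180.0, "trans"),
        (-149.9, "other"),
        (0.0, "other"),
    ],
)
def test_dihedral_classification_bands(value, state):
    assert classify_dihedrals([value]) == [state]


class TestHelicality:
    def test_single_qualifying_run_of_four_in_eight(self):
        states = ["g+"] * 4 + ["trans"] * 4
        assert helicality(states) == 0.5

    def test_mixed_sign_runs_do_not_merge(self):
        states = ["g+"] * 3 + ["g-"] * 3
        assert helicality(states) == 0.0

    def test_full_single_handed_run(self):
        assert helicality(["g-"] * 20) == 1.0

    def test_below_min_run_total_returns_zero(self):
        assert helicality(["g+"] * 3) == 0.0

    def test_bounded_by_gauche_fraction(self):
        states = ["g+", "g+", "g+", "g+", "other", "g-", "g-", "trans"]
        h = helicality(states)
        gauche = sum(s in ("g+", "g-") for s in states) / len(states)
        assert 0.0 <= h <= gauche


def _helical_positions_brute_force(states, min_run):
    """Oracle: a position is helical iff some window of >= min_run equal
    same-signed gauche states contains it (exhaustive window scan)."""
    n = len(states)
    helical = set()
    for a in range(n):
        for b in range(a + min_run - 1, n):
            window = states[a : b + 1]
            if window[0] in ("g+", "g-") and all(s == window[0] for s in window):
                helical.update(range(a, b + 1))
    return helical


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["g+", "g-", "trans"]), min_size=1, max_size=12))
def test_helicality_matches_window_enumeration_oracle(states):
    expected = len(_helical_positions_brute_force(states, 4)) / len(states)
    assert helicality(states) == pytest.approx(expected)


def test_helicality_exhaustive_short_strings():
    """Every gauche/trans string of length <= 8 agrees with the oracle."""
    for length in range(1, 9):
        for states in itertools.product(["g+", "g-", "trans"], repeat=length):
            expected = len(_helical_positions_brute_force(states, 4)) / length
            assert helicality(list(states)) == pytest.approx(expected)


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert rg_of_points(coords) == pytest.approx(1.0)

    def test_three_collinear_unit_masses(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert rg_of_points(coords) == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_unit_cube_corners(self):
        corners = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        assert rg_of_points(corners) == pytest.approx(np.sqrt(3.0) / 2.0)

    def test_mass_weighting_matters(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        heavy_one_side = rg_of_points(coords, weights=[3.0, 1.0])
        assert heavy_one_side < rg_of_points(coords)


class TestEquilibriumWindow:
    def test_iid_noise_starts_at_zero_mostly(self):
        rng = np.random.default_rng(0)
        hits = sum(
            equilibrium_window(rng.normal(size=200)).start == 0 for _ in range(100)
        )
        assert hits >= 90

    def test_ramp_then_plateau_found_near_transition(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([np.linspace(0, 1, 150), np.ones(150)])
        y = y + rng.normal(0, 0.05, size=300)
        w = equilibrium_window(y)
        assert w.stationary
        assert 120 <= w.start <= 180  # transition at 150 ± 10% of the length

    def test_constant_series(self):
        w = equilibrium_window(np.ones(50))
        assert w == (0, True)

    def test_never_stationary_flagged(self):
        w = equilibrium_window(np.arange(200.0))
        assert not w.stationary
        assert w.start == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_window([1.0] * 5)


class TestEnsembleAverage:
    def _trajectory(self, n_snapshots):
        topo = build_topology(2)
        conf = build_ideal_helix(2)
        return Trajectory(topo, [conf] * n_snapshots, 5.0 * np.arange(n_snapshots))

    def test_constant_metric(self):
        stats = ensemble_average(self._trajectory(5), [4.0] * 5)
        assert stats == (4.0, 0.0, 0.0)

    def test_two_value_hand_arithmetic(self):
        stats = ensemble_average(self._trajectory(2), [3.0, 5.0])
        assert stats.mean == pytest.approx(4.0)
        assert stats.sd == pytest.approx(np.sqrt(2.0))

    def test_callable_metric_on_jitter_free_helix(self, crystal):
        from pegconf.builder import dihedral_angle

        traj = self._trajectory(3)

        def mean_cc(conf):
            return float(
                np.mean([dihedral_angle(conf.coords, *q) for q in conf.topology.cc_torsion_quads])
            )

        stats = ensemble_average(traj, mean_cc)
        assert stats.mean == pytest.approx(crystal.cc_dihedral_gauche, abs=1e-9)
        assert stats.sd == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average(self._trajectory(3), [1.0, 2.0, 3.0], slice(3, 3))


def test_window_slicing_changes_the_average(self=None):
    topo = build_topology(2)
    conf = build_ideal_helix(2)
    traj = Trajectory(topo, [conf] * 4, 5.0 * np.arange(4))
    stats = ensemble_average(traj, [10.0, 10.0, 2.0, 2.0], slice(2, None))
    assert stats.mean == 2.0
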