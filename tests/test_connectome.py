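"""Sliding windows, group-mean correlation, eigenvector centrality and the
assembled dynamic connectome."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from mhnet import (GroupingScheme, WindowSpec, correlation_network,
                   dynamic_connectome, eigenvector_centrality,
                   group_mean_centrality, group_mean_correlation,
                   sliding_windows)
from mhnet.errors import GroupingError, ValidationError
from mhnet.synthetic import SyntheticSpec, generate_panel

from conftest import (block_matrix, network_from_matrix, planted_assignment,
                      random_network, random_panel)


def _grouping(units, n_groups=2):
    return GroupingScheme("test", {u: f"g{i % n_groups}"
                                   for i, u in enumerate(sorted(units))})


class TestSlidingWindows:
    @pytest.mark.parametrize("n_days, width, step, expected", [
        (315, 30, 1, 286),
        (30, 30, 1, 1),
        (31, 30, 2, 1),
        (100, 10, 7, 13),
    ])
    def test_window_count(self, rng, n_days, width, step, expected):
        panel = random_panel(rng, 3, n_days)
        wins = sliding_windows(panel, WindowSpec(width, step))
        assert len(wins) == expected

    @given(n_days=st.integers(2, 400), width=st.integers(2, 60),
           step=st.integers(1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_window_count_formula(self, n_days, width, step):
        spec = WindowSpec(width, step)
        if n_days < width:
            with pytest.raises(ValidationError):
                spec.n_windows(n_days)
        else:
            assert spec.n_windows(n_days) == (n_days - width) // step + 1

    def test_single_window_equals_panel(self, rng):
        panel = random_panel(rng, 3, 30)
        (win,) = sliding_windows(panel, WindowSpec(30, 1))
        np.testing.assert_array_equal(win.values, panel.values)

    def test_windows_are_contiguous_slices(self, rng):
        panel = random_panel(rng, 2, 40)
        wins = sliding_windows(panel, WindowSpec(10, 3))
        for k, win in enumerate(wins):
            assert win.dates[0] == panel.dates[3 * k]
            assert win.n_days == 10
            np.testing.assert_array_equal(win.values,
                                          panel.values[:, 3 * k:3 * k + 10])

    def test_too_short_panel_rejected(self, rng):
        with pytest.raises(ValidationError, match="shorter"):
            sliding_windows(random_panel(rng, 2, 10), WindowSpec(30, 1))


class TestGroupMeanCorrelation:
    def test_pair_group_returns_their_coefficient(self):
        P = np.array([[1.0, 0.37], [0.37, 1.0]])
        net = network_from_matrix(P)
        # restrict() drops grouping entries absent from the network
        grouping = GroupingScheme("g", {net.unit_ids[0]: "a",
                                        net.unit_ids[1]: "a",
                                        "XX": "b", "YY": "b"})
        got = group_mean_correlation(net, grouping)
        assert got == {"a": pytest.approx(0.37)}

    def test_triple_group_arithmetic_mean(self):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = 0.2
        P[0, 2] = P[2, 0] = 0.4
        P[1, 2] = P[2, 1] = 0.6
        net = network_from_matrix(P)
        grouping = GroupingScheme("g", {u: "a" for u in net.unit_ids}
                                  | {"pad1": "b", "pad2": "b"})
        got = group_mean_correlation(net, grouping)
        assert got["a"] == pytest.approx(0.4)

    def test_matches_brute_force_pair_enumeration(self, rng):
        net = random_network(rng, 10)
        grouping = _grouping(net.unit_ids, 2)
        got = group_mean_correlation(net, grouping)
        for g in grouping.groups:
            members = grouping.members(g)
            pairs = [net.P[net.unit_ids.index(x), net.unit_ids.index(y)]
                     for i, x in enumerate(members)
                     for y in members[i + 1:]]
            assert got[g] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_singleton_group_rejected(self, rng):
        net = random_network(rng, 3)
        grouping = GroupingScheme("g", {net.unit_ids[0]: "a",
                                        net.unit_ids[1]: "a",
                                        net.unit_ids[2]: "b"})
        with pytest.raises(GroupingError, match="'b'"):
            group_mean_correlation(net, grouping)


class TestEigenvectorCentrality:
    def test_complete_uniform_network_uniform_centrality(self):
        P = block_matrix([6], within=0.5, between=0)
        cent = eigenvector_centrality(network_from_matrix(P))
        np.testing.assert_allclose(list(cent.values()), 1 / np.sqrt(6),
                                   atol=1e-10)

    def test_two_unit_network(self):
        P = np.array([[1.0, -0.3], [-0.3, 1.0]])
        cent = eigenvector_centrality(network_from_matrix(P))
        np.testing.assert_allclose(list(cent.values()), 1 / np.sqrt(2),
                                   atol=1e-10)

    def test_matches_networkx_oracle(self, rng):
        for n in (5, 9, 14):
            net = random_network(rng, n)
            cent = eigenvector_centrality(net)
            W = np.abs(net.P)
            np.fill_diagonal(W, 0.0)
            g = nx.from_numpy_array(W)
            oracle = nx.eigenvector_centrality(g, max_iter=5000, tol=1e-12,
                                               weight="weight")
            got = np.array(list(cent.values()))
            exp = np.array([oracle[i] for i in range(n)])
            exp /= np.linalg.norm(exp)
            np.testing.assert_allclose(got, exp, atol=1e-8)

    def test_entries_nonnegative_unit_norm(self, rng):
        cent = eigenvector_centrality(random_network(rng, 12))
        v = np.array(list(cent.values()))
        assert (v >= 0).all()
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_positive_mode_uses_positive_part_only(self, rng):
        net = random_network(rng, 8)
        c_abs = eigenvector_centrality(net, mode="abs")
        c_pos = eigenvector_centrality(net, mode="positive")
        assert set(c_abs) == set(c_pos)
        if (net.P < 0).any():
            assert not np.allclose(list(c_abs.values()),
                                   list(c_pos.values()))

    def test_all_zero_network_rejected(self):
        P = np.eye(4)
        with pytest.raises(ValidationError, match="all-zero"):
            eigenvector_centrality(network_from_matrix(P))


class TestGroupMeanCentrality:
    def test_uniform_centrality_every_group_equal(self):
        cent = {f"u{i}": 0.25 for i in range(8)}
        got = group_mean_centrality(cent, _grouping(cent, 2))
        assert all(v == pytest.approx(0.25) for v in got.values())

    def test_single_member_group_passthrough(self):
        cent = {"a": 0.9, "b": 0.1, "c": 0.3}
        grouping = GroupingScheme("g", {"a": "solo", "b": "rest", "c": "rest"})
        got = group_mean_centrality(cent, grouping)
        assert got["solo"] == pytest.approx(0.9)
        assert got["rest"] == pytest.approx(0.2)

    def test_matches_brute_force_mean(self, rng):
        cent = {f"u{i}": float(v) for i, v in enumerate(rng.random(9))}
        grouping = _grouping(cent, 3)
        got = group_mean_centrality(cent, grouping)
        for g in grouping.groups:
            assert got[g] == pytest.approx(
                np.mean([cent[u] for u in grouping.members(g)]), abs=1e-12)


class TestDynamicConnectome:
    def _planted_panel(self, seed, snr_by_group):
        assignment = planted_assignment(2, 5)
        spec = SyntheticSpec(group_assignment=assignment, n_days=120,
                             snr=snr_by_group, baseline=50.0, wave_profile=(),
                             noise_sd=2.0, seed=seed)
        grouping = GroupingScheme("planted", assignment)
        return generate_panel(spec), grouping

    def test_high_snr_group_dominates_mean_correlation(self):
        wins_higher = []
        for seed in range(5):
            panel, grouping = self._planted_panel(seed, {"g0": 0.9, "g1": 0.0})
            series = dynamic_connectome(panel, grouping, WindowSpec(30, 5))
            hi = series.mean_correlation[series.groups.index("g0")]
            lo = series.mean_correlation[series.groups.index("g1")]
            wins_higher.append((hi > lo).mean())
        assert np.median(wins_higher) >= 0.9

    def test_single_full_window_matches_static_computation(self, rng):
        panel = random_panel(rng, 8, 45)
        grouping = _grouping(panel.unit_ids, 2)
        series = dynamic_connectome(panel, grouping, WindowSpec(45, 1))
        assert series.n_windows == 1
        net = correlation_network(panel)
        static_corr = group_mean_correlation(net, grouping)
        static_cent = group_mean_centrality(eigenvector_centrality(net),
                                            grouping)
        for gi, g in enumerate(series.groups):
            assert series.mean_correlation[gi, 0] == pytest.approx(
                static_corr[g], abs=1e-12)
            assert series.mean_centrality[gi, 0] == pytest.approx(
                static_cent[g], abs=1e-12)

    def test_invariant_under_unit_shuffle(self, rng):
        panel = random_panel(rng, 8, 60)
        grouping = _grouping(panel.unit_ids, 2)
        series = dynamic_connectome(panel, grouping, WindowSpec(20, 10))
        shuffled = panel.reorder_units(list(rng.permutation(panel.unit_ids)))
        series_s = dynamic_connectome(shuffled, grouping, WindowSpec(20, 10))
        assert series.groups == series_s.groups
        np.testing.assert_allclose(series.mean_correlation,
                                   series_s.mean_correlation, atol=1e-12)
        np.testing.assert_allclose(series.mean_centrality,
                                   series_s.mean_centrality, atol=1e-12)

    def test_degenerate_window_zeroed_with_warning(self, rng):
        panel = random_panel(rng, 4, 40)
        panel.values[0, :15] = 7.0  # constant inside early windows only
        grouping = _grouping(panel.unit_ids, 2)
        with pytest.warns(UserWarning, match="constant series"):
            series = dynamic_connectome(panel, grouping, WindowSpec(10, 10))
        assert np.isfinite(series.mean_correlation).all()

    def test_degenerate_window_strict_mode_raises(self, rng):
        panel = random_panel(rng, 4, 40)
        panel.values[0, :15] = 7.0
        grouping = _grouping(panel.unit_ids, 2)
        with pytest.raises(ValidationError):
            dynamic_connectome(panel, grouping, WindowSpec(10, 10),
                               strict=True)

    def test_series_round_trips_through_csv(self, rng, tmp_path):
        from mhnet import ConnectomeSeries
        import pandas as pd
        panel = random_panel(rng, 6, 50)
        series = dynamic_connectome(panel, _grouping(panel.unit_ids, 2),
                                    WindowSpec(20, 5))
        path = tmp_path / "series.csv"
        series.write_csv(path)
        back = ConnectomeSeries.from_long(pd.read_csv(path))
        assert back.groups == series.groups
        np.testing.assert_allclose(back.mean_correlation,
                                   series.mean_correlation, atol=1e-12)
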