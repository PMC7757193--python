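"""Connectivity, turnover events, patch states, cover classes, and file IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaspom import landscape as lsc


def brute_force_connectivity(xy, areas, occ, alpha):
    """Independent double-loop oracle for the kernel-weighted sum."""
    n = len(areas)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            d = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
            out[i] += np.exp(-alpha * d) * areas[j] * occ[j]
    return out


def _history_from_matrix(mat, patch_ids, years, species="M"):
    """Single-species occupancy embedded into the 3-species array."""
    n, t = mat.shape
    values = np.zeros((n, t, 3))
    values[:, :, lsc.SPECIES.index(species)] = mat
    return lsc.OccupancyHistory(values, years, patch_ids)


class TestConnectivity:
    def test_no_occupied_neighbours_gives_zero(self, square_landscape):
        hist = _history_from_matrix(np.zeros((4, 2)), square_landscape.patch_ids,
                                    [2000, 2001])
        s = lsc.compute_connectivity(hist, square_landscape, lsc.KernelParams(),
                                     "M", 2001)
        assert np.all(s == 0.0)

    def test_three_patch_hand_sum(self):
        # patches at (0,0), (1,0), (3,0); areas 10, 20, 40; occ (1,1,0)
        table = pd.DataFrame({
            "patch_id": list("xyz"), "x_km": [0.0, 1.0, 3.0], "y_km": 0.0,
            "area_m2": [10.0, 20.0, 40.0], "road": 0, "vs_score": 0,
            "cover_pl_2000": 1.0,
        })
        land = lsc.Landscape(table)
        hist = _history_from_matrix(np.array([[1, 0], [1, 0], [0, 0]]),
                                    land.patch_ids, [2000, 2001])
        s = lsc.compute_connectivity(hist, land, lsc.KernelParams(alpha=1.0),
                                     "M", 2001)
        expected = brute_force_connectivity(
            table[["x_km", "y_km"]].to_numpy(), table["area_m2"].to_numpy(),
            np.array([1.0, 1.0, 0.0]), 1.0)
        assert s[0] == pytest.approx(20.0 * np.exp(-1.0), rel=1e-12)
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 11)
            xy = rng.uniform(0, 10, (n, 2))
            areas = rng.lognormal(2, 1, n)
            occ = rng.integers(0, 2, n).astype(float)
            alpha = rng.uniform(0.2, 3.0)
            table = pd.DataFrame({
                "patch_id": [f"p{i}" for i in range(n)],
                "x_km": xy[:, 0], "y_km": xy[:, 1], "area_m2": areas,
                "road": 0, "vs_score": 0, "cover_pl_2000": 1.0,
            })
            land = lsc.Landscape(table)
            s = lsc.connectivity_from_occupancy(occ, land, lsc.KernelParams(alpha))
            np.testing.assert_allclose(
                s, brute_force_connectivity(xy, areas, occ, alpha), rtol=1e-12)

    def test_default_kernel_is_one_km_mean_dispersal(self):
        params = lsc.KernelParams()
        assert params.alpha == 1.0
        assert params.mean_dispersal == 1.0

    def test_missing_previous_year_raises(self, square_landscape):
        hist = _history_from_matrix(np.ones((4, 2)), square_landscape.patch_ids,
                                    [2000, 2001])
        with pytest.raises(KeyError):
            lsc.compute_connectivity(hist, square_landscape, lsc.KernelParams(),
                                     "M", 2000)
        with pytest.raises(KeyError):
            hist.species_index("X")

    def test_na_occupancy_contributes_zero(self, square_landscape):
        mat = np.array([[1.0, 0], [np.nan, 0], [0, 0], [0, 0]])
        hist = _history_from_matrix(mat, square_landscape.patch_ids, [2000, 2001])
        s = lsc.compute_connectivity(hist, square_landscape, lsc.KernelParams(),
                                     "M", 2001)
        occ = np.array([1.0, 0, 0, 0])
        expected = lsc.connectivity_from_occupancy(occ, square_landscape,
                                                   lsc.KernelParams())
        np.testing.assert_allclose(s, expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotonicity(self, seed):
        """More occupancy never lowers S; larger alpha never raises it."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        table = pd.DataFrame({
            "patch_id": [f"p{i}" for i in range(n)],
            "x_km": rng.uniform(0, 5, n), "y_km": rng.uniform(0, 5, n),
            "area_m2": rng.lognormal(2, 1, n), "road": 0, "vs_score": 0,
            "cover_pl_2000": 1.0,
        })
        land = lsc.Landscape(table)
        occ = rng.integers(0, 2, n).astype(float)
        empty = np.flatnonzero(occ == 0)
        s0 = lsc.connectivity_from_occupancy(occ, land, lsc.KernelParams(1.0))
        if empty.size:
            occ2 = occ.copy()
            occ2[rng.choice(empty)] = 1.0
            s1 = lsc.connectivity_from_occupancy(occ2, land, lsc.KernelParams(1.0))
            assert np.all(s1 >= s0 - 1e-12)
        s_steep = lsc.connectivity_from_occupancy(occ, land, lsc.KernelParams(2.0))
        assert np.all(s_steep <= s0 + 1e-12)


class TestHostConnectivity:
    def test_two_patch_hand_sum(self):
        table = pd.DataFrame({
            "patch_id": ["u", "v"], "x_km": [0.0, 1.0], "y_km": 0.0,
            "area_m2": 1.0, "road": 0, "vs_score": 0,
            "cover_pl_2000": [5.0, 8.0],
        })
        s = lsc.compute_host_connectivity(lsc.Landscape(table), lsc.KernelParams())
        assert s[0] == pytest.approx(8 * np.exp(-1.0), rel=1e-12)
        assert s[1] == pytest.approx(5 * np.exp(-1.0), rel=1e-12)

    def test_partial_cover_years_averaged_over_recorded(self, square_landscape):
        mean = square_landscape.mean_cover()
        # patch c has cover 3.0 in 2000 and NA in 2001 -> mean 3.0
        assert mean[2] == pytest.approx(3.0)
        assert mean[0] == pytest.approx(2.0)  # (1 + 3) / 2

    def test_zero_cover_gives_zero(self):
        table = pd.DataFrame({
            "patch_id": ["u", "v"], "x_km": [0.0, 1.0], "y_km": 0.0,
            "area_m2": 1.0, "road": 0, "vs_score": 0, "cover_pl_2000": 0.0,
        })
        s = lsc.compute_host_connectivity(lsc.Landscape(table), lsc.KernelParams())
        assert np.all(s == 0.0)

    def test_all_na_cover_names_patch(self):
        table = pd.DataFrame({
            "patch_id": ["u", "v"], "x_km": [0.0, 1.0], "y_km": 0.0,
            "area_m2": 1.0, "road": 0, "vs_score": 0,
            "cover_pl_2000": [np.nan, 1.0],
        })
        with pytest.raises(ValueError, match="u"):
            lsc.compute_host_connectivity(lsc.Landscape(table), lsc.KernelParams())

    def test_cover_year_imputed_with_patch_mean(self, square_landscape):
        c = square_landscape.cover(2001)
        assert c[2] == pytest.approx(3.0)  # NA year -> patch mean


class TestTurnoverEvents:
    def test_constant_occupancy_no_events(self):
        hist = _history_from_matrix(np.ones((3, 4)), list("abc"),
                                    [2000, 2001, 2002, 2003])
        ev = lsc.assign_turnover_events(hist, "M")
        assert not ev.colonizations and not ev.extinctions
        assert ev.n_possible_ext == 9 and ev.n_possible_col == 0

    def test_two_patch_example_enumeration(self):
        mat = np.array([[0, 1, 1, 0], [1, 1, 0, 1]], dtype=float)
        years = [2001, 2002, 2003, 2004]
        hist = _history_from_matrix(mat, ["p1", "p2"], years)
        ev = lsc.assign_turnover_events(hist, "M")
        assert set(ev.colonizations) == {("p1", 2002), ("p2", 2004)}
        assert set(ev.extinctions) == {("p1", 2004), ("p2", 2003)}
        # exhaustive: p1 transitions 0->1,1->1,1->0 ; p2 1->1,1->0,0->1
        assert ev.n_possible_col == 2
        assert ev.n_possible_ext == 4

    def test_joint_parasitoid_colonization_flagged(self):
        values = np.zeros((1, 2, 3))
        values[0, 1, lsc.SPECIES.index("M")] = 1
        values[0, 1, lsc.SPECIES.index("C")] = 1
        hist = lsc.OccupancyHistory(values, [2000, 2001], ["p1"])
        ev = lsc.assign_turnover_events(hist, "C")
        assert ev.colonizations == [("p1", 2001)]
        assert ev.joint_col == [("p1", 2001)]
        assert ev.n_possible_col == 1

    def test_parasitoid_denominator_excludes_hostless_patches(self):
        # host never present -> no possible parasitoid colonization
        values = np.zeros((2, 3, 3))
        hist = lsc.OccupancyHistory(values, [2000, 2001, 2002], ["p1", "p2"])
        ev = lsc.assign_turnover_events(hist, "C")
        assert ev.n_possible_col == 0

    def test_na_transitions_excluded(self):
        mat = np.array([[0, np.nan, 1], [0, 1, 1]])
        hist = _history_from_matrix(mat, ["p1", "p2"], [2000, 2001, 2002])
        ev = lsc.assign_turnover_events(hist, "M")
        assert set(ev.colonizations) == {("p2", 2001)}
        # p1's transitions both touch the NA survey; p2 has one 0->1 (possible
        # colonization) and one 1->1 (possible extinction)
        assert ev.n_possible_col == 1
        assert ev.n_possible_ext == 1

    def test_event_conservation(self, default_bundle):
        """col(t) - ext(t) = occ(t) - occ(t-1) summed over years, per species."""
        _, hist, _, _ = default_bundle
        for sp in lsc.SPECIES:
            ev = lsc.assign_turnover_events(hist, sp)
            delta = hist.occupied_count(sp, hist.years[-1]) - \
                hist.occupied_count(sp, hist.years[0])
            assert len(ev.colonizations) - len(ev.extinctions) == delta


class TestPatchState:
    def test_bijection_over_valid_triples(self):
        seen = set()
        for m in (0, 1):
            for c in (0, 1):
                for p in (0, 1):
                    if c == 1 and m == 0:
                        with pytest.raises(lsc.InvalidStateError):
                            lsc.encode_patch_state(m, c, p)
                    else:
                        st_ = lsc.encode_patch_state(m, c, p)
                        assert st_.flags == (m, c, p)
                        assert lsc.decode_patch_state(st_.label).flags == (m, c, p)
                        seen.add(st_.label)
        assert seen == set(lsc.STATE_LABELS)
        assert len(seen) == 6

    def test_all_present_is_mcp(self):
        assert lsc.encode_patch_state(1, 1, 1).label == "MCP"
        assert lsc.encode_patch_state(0, 0, 0).label == "0"

    def test_history_rejects_parasitoid_without_host(self):
        values = np.zeros((1, 2, 3))
        values[0, 0, lsc.SPECIES.index("C")] = 1
        with pytest.raises(lsc.InvalidStateError):
            lsc.OccupancyHistory(values, [2000, 2001], ["p1"])


class TestCoverClasses:
    def test_single_class(self):
        assert np.all(lsc.bin_cover_classes(np.arange(7.0), k=1) == 0)

    def test_thirty_values_fifteen_classes(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(30).astype(float)
        classes = lsc.bin_cover_classes(values, k=15)
        counts = np.bincount(classes, minlength=15)
        assert np.all(counts == 2)
        # sorting oracle: class index must be non-decreasing in cover
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(classes[order]) >= 0)

    def test_default_is_fifteen(self):
        import inspect
        assert inspect.signature(lsc.bin_cover_classes).parameters["k"].default == 15

    def test_k_exceeding_patches_raises(self):
        with pytest.raises(ValueError):
            lsc.bin_cover_classes(np.arange(3.0), k=4)


class TestIO:
    def test_round_trip(self, tmp_path, tiny_bundle):
        land, hist, precip, _ = tiny_bundle
        lsc.write_patches(land, tmp_path / "patches.csv")
        lsc.write_occupancy(hist, tmp_path / "occupancy.csv")
        lsc.write_precipitation(precip, tmp_path / "precipitation.csv")
        land2 = lsc.read_patches(tmp_path / "patches.csv")
        hist2 = lsc.read_occupancy(tmp_path / "occupancy.csv",
                                   patch_ids=land2.patch_ids)
        precip2 = lsc.read_precipitation(tmp_path / "precipitation.csv")
        pd.testing.assert_frame_equal(land.table, land2.table[land.table.columns])
        np.testing.assert_array_equal(hist.values, hist2.values)
        assert hist.years == hist2.years
        np.testing.assert_allclose(precip[lsc.PRECIP_COLUMNS].to_numpy(),
                                   precip2.to_numpy())

    def test_writers_are_stable(self, tmp_path, tiny_bundle):
        land, *_ = tiny_bundle
        lsc.write_patches(land, tmp_path / "a.csv")
        lsc.write_patches(land, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestLandscapeValidation:
    @pytest.mark.parametrize("column,bad", [
        ("area_m2", 0.0), ("area_m2", -1.0), ("x_km", np.inf), ("vs_score", 5),
    ])
    def test_invalid_attributes_rejected(self, square_landscape, column, bad):
        table = square_landscape.table.copy()
        table.loc[0, column] = bad
        with pytest.raises(ValueError):
            lsc.Landscape(table)

    def test_noncontiguous_years_rejected(self):
        with pytest.raises(ValueError):
            lsc.OccupancyHistory(np.zeros((1, 2, 3)), [2000, 2002], ["p1"])
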