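"""Nest labelling, filtering, areas, summaries, and the flood-fill oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import flood_fill_components, labels_to_components
from melnest import (
    LatticeGeometry,
    filter_nests,
    find_nests,
    label_nests,
    nest_area,
    nest_table,
    split_touching_nests,
    summarize,
)
from melnest.fixtures import make_fixture


def snapshot_of(melanoma_sites, geom=None, skin_sites=()):
    rows = []
    for n, (i, j, k) in enumerate(list(skin_sites) + list(melanoma_sites)):
        rows.append((0, 0.0, n, "skin" if n < len(skin_sites) else "melanoma", i, j, k))
    return pd.DataFrame(
        rows, columns=["step", "t_hours", "agent_id", "species", "i", "j", "k"]
    )


class TestLabelNests:
    def test_two_separated_blocks(self):
        fx = make_fixture("two_blocks")
        labels = label_nests(fx.snapshot, fx.geometry)
        table = nest_table(labels, fx.geometry)
        assert sorted(table["n_agents"]) == [8, 8]

    def test_empty_snapshot_has_no_components(self):
        g = LatticeGeometry(10, 10, 10)
        assert nest_table(label_nests(snapshot_of([], g), g), g).empty

    def test_diagonal_pair_connectivity(self):
        fx = make_fixture("diagonal_pair")
        t26 = nest_table(label_nests(fx.snapshot, fx.geometry, connectivity=26),
                         fx.geometry)
        t6 = nest_table(label_nests(fx.snapshot, fx.geometry, connectivity=6),
                        fx.geometry)
        assert len(t26) == 1 and len(t6) == 2

    def test_skin_agents_ignored(self):
        g = LatticeGeometry(10, 10, 10)
        snap = snapshot_of([(2, 2, 2)], g, skin_sites=[(3, 2, 2), (2, 3, 2)])
        table = nest_table(label_nests(snap, g), g)
        assert list(table["n_agents"]) == [1]

    def test_unknown_species_label_rejected(self):
        g = LatticeGeometry(10, 10, 10)
        snap = snapshot_of([(2, 2, 2)], g)
        snap.loc[0, "species"] = "fibroblast"
        with pytest.raises(ValueError, match="unknown species"):
            label_nests(snap, g)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_component_spanning_lateral_seam_is_one_nest(self, connectivity):
        g = LatticeGeometry(12, 12, 8)
        sites = [(11, 5, 3), (0, 5, 3)]  # face-adjacent across the i seam
        snap = snapshot_of(sites, g)
        periodic = nest_table(label_nests(snap, g, connectivity, periodic=True), g)
        clipped = nest_table(label_nests(snap, g, connectivity, periodic=False), g)
        assert len(periodic) == 1 and len(clipped) == 2

    def test_diagonal_seam_contact_merges_only_under_26(self):
        g = LatticeGeometry(12, 12, 8)
        snap = snapshot_of([(11, 5, 3), (0, 6, 4)])
        t26 = nest_table(label_nests(snap, g, 26), g)
        t6 = nest_table(label_nests(snap, g, 6), g)
        assert len(t26) == 1 and len(t6) == 2

    def test_labelling_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        g = LatticeGeometry(9, 9, 9)
        sites = {tuple(s) for s in rng.integers(0, 9, size=(60, 3))}
        snap = snapshot_of(sorted(sites), g)
        shuffled = snap.sample(frac=1.0, random_state=1).reset_index(drop=True)
        c1 = labels_to_components(label_nests(snap, g))
        c2 = labels_to_components(label_nests(shuffled, g))
        assert c1 == c2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_lattices(self, connectivity):
        rng = np.random.default_rng(12)
        for _ in range(20):
            shape = tuple(rng.integers(3, 11, size=3))
            g = LatticeGeometry(*shape)
            occ = {
                tuple(s)
                for s in np.argwhere(rng.random(shape) < 0.2)
            }
            snap = snapshot_of(sorted(occ), g)
            got = labels_to_components(label_nests(snap, g, connectivity))
            want = flood_fill_components(occ, shape, connectivity)
            assert got == want


class TestFilterAndArea:
    def test_small_nest_filter_keeps_components_of_four_or_more(self):
        fx = make_fixture("triplet_and_quad")
        table = nest_table(label_nests(fx.snapshot, fx.geometry), fx.geometry)
        assert sorted(table["n_agents"]) == [3, 4]
        kept = filter_nests(table, min_agents=4)
        assert list(kept["n_agents"]) == [4]

    def test_filter_threshold_examples(self):
        t = pd.DataFrame({"n_agents": [3, 4, 17]})
        assert sorted(filter_nests(t)["n_agents"]) == [4, 17]
        assert len(filter_nests(t, min_agents=1)) == 3
        singles = pd.DataFrame({"n_agents": [1, 1, 1]})
        assert filter_nests(singles).empty

    def test_filter_parameter_error(self):
        with pytest.raises(ValueError):
            filter_nests(pd.DataFrame({"n_agents": [5]}), min_agents=0)

    def test_filtered_and_unfiltered_sizes_partition_total_count(self):
        rng = np.random.default_rng(5)
        g = LatticeGeometry(10, 10, 10)
        occ = {tuple(s) for s in rng.integers(0, 10, size=(150, 3))}
        snap = snapshot_of(sorted(occ), g)
        table = nest_table(label_nests(snap, g), g)
        assert table["n_agents"].sum() == len(occ)
        kept = filter_nests(table)
        dropped = table[table["n_agents"] < 4]
        assert kept["n_agents"].sum() + dropped["n_agents"].sum() == len(occ)

    @pytest.mark.parametrize(
        "n_agents,expected_um2", [(1, 400.0), (4, 1600.0), (375, 150000.0)]
    )
    def test_area_per_agent_convention(self, n_agents, expected_um2):
        assert nest_area(n_agents, delta=20.0) == expected_um2

    def test_projected_area_counts_distinct_columns(self):
        g = LatticeGeometry(10, 10, 10)
        stack = [(4, 4, k) for k in range(5)]  # 5 agents in one column
        labels = label_nests(snapshot_of(stack, g), g)
        by_count = nest_table(labels, g, area_convention="agent_count")
        by_proj = nest_table(labels, g, area_convention="projected")
        assert by_count["area_um2"].iloc[0] == 2000.0
        assert by_proj["area_um2"].iloc[0] == 400.0


class TestSummarize:
    def test_single_nest(self):
        s = summarize([1234.0])
        assert s.n_nests == 1 and s.median == 1234.0 and s.outliers == []

    def test_outlier_flagging_against_direct_evaluation(self):
        # quartiles by linear interpolation: q1 = 2, q3 = 4, IQR = 2,
        # fences at -1 and 7 -> 100 is the only outlier
        s = summarize([1, 2, 3, 4, 100])
        assert s.median == 3.0 and (s.q1, s.q3) == (2.0, 4.0)
        assert (s.whisker_low, s.whisker_high) == (1.0, 4.0)
        assert s.outliers == [100.0]

    def test_empty_input(self):
        s = summarize([])
        assert s.n_nests == 0 and np.isnan(s.median)

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(2)
        areas = rng.lognormal(8, 1, size=200)
        s = summarize(areas)
        assert s.q1 <= s.median <= s.q3
        assert all(a < s.q1 - 1.5 * (s.q3 - s.q1)
                   or a > s.q3 + 1.5 * (s.q3 - s.q1) for a in s.outliers)


class TestSplitTouchingNests:
    def test_two_mounds_joined_by_thin_bridge_are_separated(self):
        # two 3x3 mounds three agents tall, linked by a one-agent-high
        # bridge: connected-component labelling sees one nest, the
        # height-map watershed restores two
        g = LatticeGeometry(20, 20, 10)
        sites = []
        for ci in (4, 14):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for k in range(3):
                        sites.append((ci + di, 5 + dj, k))
        bridge = [(i, 5, 0) for i in range(6, 13)]
        snap = snapshot_of(sites + bridge, g)
        merged = find_nests(snap, g)
        assert len(merged) == 1
        unfiltered = split_touching_nests(snap, g, min_agents=1)
        # watershed conserves agent mass over all basins
        assert unfiltered["n_agents"].sum() == len(sites) + len(bridge)
        split = split_touching_nests(snap, g)
        assert len(split) == 2
        assert (split["n_agents"] >= 27).all()  # one mound each (+ bridge share)

    def test_empty_and_isolated_inputs(self):
        g = LatticeGeometry(10, 10, 5)
        assert split_touching_nests(snapshot_of([], g), g).empty
        lone = snapshot_of([(3, 3, 0), (3, 4, 0), (4, 3, 0), (4, 4, 0)], g)
        t = split_touching_nests(lone, g)
        assert list(t["n_agents"]) == [4]
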