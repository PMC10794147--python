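import io

import pytest
from hypothesis import given, settings, strategies as st

import multinuc as mn
from multinuc.tileset import ShapeLayout, Tile, TilesetError


def test_glue_complement_involution():
    assert mn.complement("708") == "708*"
    assert mn.complement("708*") == "708"
    assert mn.complement(mn.complement("9")) == "9"
    assert mn.complement(None) is None


def test_glue_matching():
    assert mn.Glue("708").matches(mn.Glue("708*"))
    assert not mn.Glue("708").matches(mn.Glue("708"))
    assert not mn.Glue(None).matches(mn.Glue("708"))
    assert not mn.Glue(None).matches(mn.Glue(None))


def test_tile_requires_four_sides():
    with pytest.raises(TilesetError):
        Tile("t", {"N": None, "E": None, "S": None})


def test_layout_rejects_duplicate_tiles():
    with pytest.raises(TilesetError, match="at both"):
        ShapeLayout("s", 2, 2, {(0, 0): "t", (0, 1): "t"})


def test_sst_strand_length():
    """The SST motif has two 10-nt and two 11-nt domains: 42 nt total."""
    assert mn.sst_strand_length() == 42
    assert mn.sst_strand_length((10, 11, 10, 11)) == 42


class TestBuildUniqueDesign:
    def test_single_cell(self):
        system = mn.build_unique_design({"dot": [[True]]})
        assert len(system.tiles) == 1
        assert system.n_glue_pairs() == 0
        (tile,) = system.tiles.values()
        assert tile.null_sides() == frozenset("NESW")

    def test_two_by_two_square(self):
        system = mn.build_unique_design({"sq": [[True, True], [True, True]]})
        assert len(system.tiles) == 4
        assert system.n_glue_pairs() == 4  # four internal edges

    def test_validates_by_construction(self, mini_unique):
        for layout in mini_unique.layouts:
            assert mn.validate_layout(mini_unique, layout) == []

    def test_counts_match_mask_geometry(self, mini_unique):
        n_cells = sum(len(lay) for lay in mini_unique.layouts)
        n_edges = sum(len(lay.internal_edges()) for lay in mini_unique.layouts)
        assert len(mini_unique.tiles) == n_cells == 42
        assert mini_unique.n_glue_pairs() == n_edges

    def test_empty_mask_rejected(self):
        with pytest.raises(TilesetError, match="empty"):
            mn.build_unique_design({"x": [[False]]})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_masks_always_validate(self, seed):
        """Unique designs of random connected masks always pass validation,
        and their glue-pair count equals the number of internal adjacencies."""
        import numpy as np

        rng = np.random.default_rng(seed)
        rows, cols = rng.integers(1, 5, size=2)
        # grow a random connected mask
        cells = {(0, 0)}
        for _ in range(int(rng.integers(0, rows * cols))):
            frontier = [
                (r + dr, c + dc)
                for r, c in cells
                for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0))
                if 0 <= r + dr < rows and 0 <= c + dc < cols
                and (r + dr, c + dc) not in cells
            ]
            if frontier:
                cells.add(frontier[int(rng.integers(len(frontier)))])
        mask = [[(r, c) in cells for c in range(cols)] for r in range(rows)]
        system = mn.build_unique_design({"m": mask})
        (layout,) = system.layouts
        assert mn.validate_layout(system, layout) == []
        assert system.n_glue_pairs() == len(layout.internal_edges())


class TestValidateLayout:
    def test_flipped_internal_glue_gives_one_violation(self, mini_unique):
        system = mini_unique.copy()
        layout = system.layouts[0]
        loc, nb = layout.internal_edges()[0]
        side = "E" if nb == (loc[0], loc[1] + 1) else "S"
        name = layout.occupancy[loc]
        tile = system.tiles[name]
        glues = dict(tile.glues)
        glues[side] = "999999"
        system.glue_alphabet.add("999999")
        system.tiles[name] = Tile(name, glues)
        violations = mn.validate_layout(system, layout)
        assert len(violations) == 1
        assert violations[0].rule == "internal-mismatch"
        assert violations[0].location == loc

    def test_non_null_boundary_glue_reported(self, mini_unique):
        system = mini_unique.copy()
        layout = system.layouts[0]
        loc = next(
            l for l in layout.locations()
            if any(
                layout.neighbor(l, s) not in layout.occupancy for s in mn.SIDES
            )
        )
        side = next(
            s for s in mn.SIDES if layout.neighbor(loc, s) not in layout.occupancy
        )
        name = layout.occupancy[loc]
        glues = dict(system.tiles[name].glues)
        glues[side] = "999999"
        system.glue_alphabet.add("999999")
        system.tiles[name] = Tile(name, glues)
        violations = mn.validate_layout(system, layout)
        assert any(v.rule == "boundary-not-null" and v.location == loc
                   for v in violations)

    def test_unknown_tile_raises(self, mini_unique):
        bad = ShapeLayout("x", 1, 1, {(0, 0): "nope"})
        with pytest.raises(TilesetError, match="unknown tile"):
            mn.validate_layout(mini_unique, bad)


class TestSharingStats:
    def test_unique_design_all_singletons(self, mini_unique):
        stats = mn.sharing_stats(mini_unique)
        assert stats.unique == stats.total_tiles == 42
        assert stats.shared == 0
        assert sum(stats.by_multiplicity) == stats.total_tiles

    def test_merged_stats_match_direct_scan(self, mini_merged):
        """Sharing stats equal an independent set-intersection count."""
        stats = mn.sharing_stats(mini_merged)
        names = [lay.tile_names() for lay in mini_merged.layouts]
        direct = {1: 0, 2: 0, 3: 0}
        for t in mini_merged.tiles:
            m = sum(t in s for s in names)
            direct[m] += 1
        assert stats.unique == direct[1]
        assert stats.in_two == direct[2]
        assert stats.in_all == direct[3]
        assert stats.shared == direct[2] + direct[3]


class TestFixture:
    def test_deterministic(self):
        a = mn.make_fixture_system(seed=1, merged=True)
        b = mn.make_fixture_system(seed=1, merged=True)
        assert {t.name: t.signature for t in a.tiles.values()} == {
            t.name: t.signature for t in b.tiles.values()
        }

    def test_merged_strictly_smaller(self, mini_unique, mini_merged):
        assert len(mini_merged.tiles) < len(mini_unique.tiles)

    def test_merged_layouts_validate(self, mini_merged):
        for layout in mini_merged.layouts:
            assert mn.validate_layout(mini_merged, layout) == []


class TestIO:
    def test_tileset_round_trip_single_tile(self):
        system = mn.build_unique_design({"dot": [[True]]})
        buf = io.StringIO()
        mn.write_tileset(system, buf)
        buf.seek(0)
        back = mn.read_tileset(buf)
        assert set(back.tiles) == set(system.tiles)
        assert back.tiles["dot_r0c0"].signature == system.tiles["dot_r0c0"].signature

    def test_tileset_round_trip_preserves_stats(self, mini_merged, tmp_path):
        path = str(tmp_path / "sys.json")
        mn.write_tileset(mini_merged, path)
        back = mn.read_tileset(path)
        assert mn.sharing_stats(back) == mn.sharing_stats(mini_merged)

    def test_undeclared_glue_rejected_in_strict_mode(self):
        doc = """{"format": "multinuc-tileset", "version": 1,
                  "glues": ["9"],
                  "tiles": [{"name": "t", "edges":
                             {"N": "9*", "E": null, "S": null, "W": null}}],
                  "layouts": []}"""
        with pytest.raises(TilesetError, match="undeclared glue"):
            mn.read_tileset(io.StringIO(doc))
        lax = mn.read_tileset(io.StringIO(doc), strict=False)
        assert "9*" in lax.glue_alphabet

    def test_unknown_field_rejected_only_when_strict(self):
        doc = """{"format": "multinuc-tileset", "version": 1, "surprise": 1,
                  "glues": [], "tiles": [], "layouts": []}"""
        with pytest.raises(TilesetError, match="unknown document fields"):
            mn.read_tileset(io.StringIO(doc))
        mn.read_tileset(io.StringIO(doc), strict=False)

    def test_layout_text_round_trip(self, mini_unique):
        layout = mini_unique.layouts[0]
        buf = io.StringIO()
        mn.write_layout(layout, buf)
        buf.seek(0)
        back = mn.read_layout(buf, name=layout.name)
        assert back.occupancy == layout.occupancy
        assert (back.rows, back.cols) == (layout.rows, layout.cols)

    def test_layout_text_basics(self):
        one = mn.read_layout(io.StringIO("t0\n"))
        assert one.occupancy == {(0, 0): "t0"}
        three = mn.read_layout(io.StringIO("a b\n. c\n"))
        assert len(three) == 3
        with pytest.raises(TilesetError, match="ragged"):
            mn.read_layout(io.StringIO("a b\nc\n"))

    def test_xgrow_export_mentions_every_tile(self, mini_unique):
        buf = io.StringIO()
        mn.export_xgrow(mini_unique, buf)
        text = buf.getvalue()
        assert f"num tile types={len(mini_unique.tiles)}" in text
        assert f"num binding types={mini_unique.n_glue_pairs()}" in text
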