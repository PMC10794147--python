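import numpy as np
import pytest

import multinuc as mn
from multinuc.merge import MergeError, MergeProposal, apply_merge, propose_merge
from multinuc.tileset import SIDES, ShapeLayout, Tile, TileSystem

from oracles import brute_second_order, brute_self_healing


def two_dominoes(second_glues=("2", "2*")):
    """Two 1x2 shapes: A-B glued by '1', C-D glued by the given pair."""
    g_cd, g_dc = second_glues
    tiles = {
        "A": Tile("A", {"N": None, "E": "1", "S": None, "W": None}),
        "B": Tile("B", {"N": None, "E": None, "S": None, "W": "1*"}),
        "C": Tile("C", {"N": None, "E": g_cd, "S": None, "W": None}),
        "D": Tile("D", {"N": None, "E": None, "S": None, "W": g_dc}),
    }
    alphabet = {"1", "1*", g_cd, g_dc}
    layouts = [
        ShapeLayout("s1", 1, 2, {(0, 0): "A", (0, 1): "B"}),
        ShapeLayout("s2", 1, 2, {(0, 0): "C", (0, 1): "D"}),
    ]
    return TileSystem(tiles=tiles, glue_alphabet=alphabet, layouts=layouts)


class TestPropose:
    def test_null_side_mismatch_never_proposed(self, mini_unique, rng):
        """Edge tiles with null glues on different sides are ineligible."""
        seen = set()
        tried: set = set()
        while True:
            prop = propose_merge(mini_unique, rng, phase="global", exclude=tried)
            if prop is None:
                break
            tried.add(prop.key)
            seen.add(prop.key)
            a = mini_unique.tiles[prop.tile_a]
            b = mini_unique.tiles[prop.tile_b]
            assert a.null_sides() == b.null_sides()

    def test_same_shape_pairs_excluded(self, mini_unique, rng):
        tried: set = set()
        shape_of = {
            t: lay.name
            for lay in mini_unique.layouts
            for t in lay.tile_names()
        }
        for _ in range(50):
            prop = propose_merge(mini_unique, rng, phase="global", exclude=tried)
            if prop is None:
                break
            tried.add(prop.key)
            assert shape_of[prop.tile_a] != shape_of[prop.tile_b]

    def test_chequerboard_phase_respects_parity(self, mini_unique, rng):
        loc_of = {
            t: loc
            for lay in mini_unique.layouts
            for loc, t in lay.occupancy.items()
        }
        prop = propose_merge(mini_unique, rng, phase="chequerboard", parity=0)
        assert prop is not None
        for t in (prop.tile_a, prop.tile_b):
            r, c = loc_of[t]
            assert (r + c) % 2 == 0

    def test_deterministic_stream_for_fixed_seed(self, mini_unique):
        def stream(seed):
            rng = np.random.default_rng(seed)
            out = []
            tried: set = set()
            for _ in range(10):
                p = propose_merge(mini_unique, rng, phase="global", exclude=tried)
                if p is None:
                    break
                tried.add(p.key)
                out.append((p.tile_a, p.tile_b))
            return out

        assert stream(3) == stream(3)


class TestApply:
    def test_basic_merge_unifies_glues_and_validates(self):
        system = two_dominoes()
        ta, tc = system.tiles["A"], system.tiles["C"]
        prop = MergeProposal("A", "C", (("1", "2"),))
        merged = apply_merge(system, prop)
        assert len(merged.tiles) < len(system.tiles)
        for lay in merged.layouts:
            assert mn.validate_layout(merged, lay) == []
        # both dominoes now share the same tile pair
        assert merged.layouts[0].tile_names() == merged.layouts[1].tile_names()

    def test_self_complement_unification_rejected(self):
        system = two_dominoes(second_glues=("1*", "1"))
        prop = MergeProposal("A", "C", (("1", "1*"),))
        with pytest.raises(MergeError, match="own complement"):
            apply_merge(system, prop)

    def test_merging_identical_glue_sets_is_identity(self):
        system = two_dominoes()
        prop = MergeProposal("A", "A", (("1", "1"),))
        merged = apply_merge(system, prop)
        assert {t.name: t.signature for t in merged.tiles.values()} == {
            t.name: t.signature for t in system.tiles.values()
        }

    def test_fixture_merge_reduces_tiles_and_validates(self, mini_unique, rng):
        tried: set = set()
        while True:
            prop = propose_merge(mini_unique, rng, phase="global", exclude=tried)
            assert prop is not None
            tried.add(prop.key)
            try:
                merged = apply_merge(mini_unique, prop)
            except MergeError:
                continue
            break
        assert len(merged.tiles) <= len(mini_unique.tiles) - 1
        for lay in merged.layouts:
            assert mn.validate_layout(merged, lay) == []


class TestCriteria:
    def test_unique_design_passes_both_trivially(self, mini_unique):
        assert mn.check_self_healing(mini_unique).ok
        assert mn.check_second_order(mini_unique).ok

    def test_self_healing_failure_detected_with_witness(self):
        """A wrong tile carrying both glues around a location is a
        self-healing violation, found by check and by brute force."""
        system = mn.build_unique_design({"bar": [[True, True, True]]})
        mid = system.layouts[0].occupancy[(0, 1)]
        glues = dict(system.tiles[mid].glues)
        bad = Tile("intruder", glues)
        system.tiles["intruder"] = bad
        # a second shape so the intruder is a pooled tile
        report = mn.check_self_healing(system)
        assert not report.ok
        assert any(w.tile == "intruder" and len(w.matched_sides) == 2
                   for w in report.witnesses)
        assert brute_self_healing(system) != []

    def test_second_order_failure_detected_with_witness_chain(self):
        """Hand-built error chain: tile e attaches by one bond at (0,1), then
        tile f attaches by two bonds at (1,1), one of them to e."""
        system = mn.build_unique_design({"sq": [[True, True], [True, True]]})
        lay = system.layouts[0]
        a = system.tiles[lay.occupancy[(0, 0)]]
        c = system.tiles[lay.occupancy[(1, 0)]]
        # e: bonds a on its W side only; presents fresh glue "x" southwards
        e = Tile("e", {"N": None, "E": None, "S": "x",
                       "W": mn.complement(a.glues["E"])})
        # f: bonds e's "x" on its N side and c's E glue on its W side
        f = Tile("f", {"N": "x*", "E": None, "S": None,
                       "W": mn.complement(c.glues["E"])})
        system.tiles["e"] = e
        system.tiles["f"] = f
        system.glue_alphabet.update({"x", "x*"})
        assert mn.check_self_healing(system).ok  # e and f bond <= 1 correct side
        report = mn.check_second_order(system)
        assert not report.ok
        assert any(
            w.tile == "e" and w.tile2 == "f" and w.location == (0, 1)
            and w.location2 == (1, 1)
            for w in report.witnesses
        )
        chains = brute_second_order(system)
        assert any(ch[2] == "e" and ch[4] == "f" for ch in chains)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_checks_equal_brute_force_on_randomized_merges(self, seed):
        """After random merge attempts (accepted or not), both criteria agree
        with independent exhaustive error-attachment enumeration."""
        system = mn.make_fixture_system(seed=1)
        rng = np.random.default_rng(seed)
        tried: set = set()
        candidates = [system]
        for _ in range(6):
            prop = propose_merge(candidates[-1], rng, phase="global",
                                 exclude=tried)
            if prop is None:
                break
            tried.add(prop.key)
            try:
                candidates.append(apply_merge(candidates[-1], prop))
                tried = set()
            except MergeError:
                continue
        for cand in candidates:
            sh = mn.check_self_healing(cand)
            so = mn.check_second_order(cand)
            brute_sh = brute_self_healing(cand)
            brute_so = brute_second_order(cand)
            assert sh.ok == (not brute_sh)
            assert so.ok == (not brute_so)
            assert {(w.layout, w.location, w.tile) for w in sh.witnesses} == set(
                brute_sh
            )
            assert {
                (w.layout, w.location, w.tile, w.location2, w.tile2)
                for w in so.witnesses
            } == set(brute_so)


class TestRunMerging:
    def test_fixed_point_input_unchanged(self):
        """A system with no eligible pairs is returned as-is."""
        system = mn.build_unique_design({"solo": [[True, True]]})
        merged, log = mn.run_merging(system, 0)
        assert log.accepted == []
        assert set(merged.tiles) == set(system.tiles)

    def test_mini_ham_merges_and_keeps_criteria(self, mini_unique):
        merged, log = mn.run_merging(mini_unique, 1, restarts=2)
        assert len(merged.tiles) < len(mini_unique.tiles)
        assert mn.check_self_healing(merged).ok
        assert mn.check_second_order(merged).ok
        for lay in merged.layouts:
            assert mn.validate_layout(merged, lay) == []

    def test_tile_count_non_increasing(self, mini_unique):
        _, log = mn.run_merging(mini_unique, 2)
        counts = log.tile_counts
        assert counts == sorted(counts, reverse=True)

    def test_reproducible_per_seed(self, mini_unique):
        a, loga = mn.run_merging(mini_unique, 5)
        b, logb = mn.run_merging(mini_unique, 5)
        assert loga.accepted == logb.accepted
        assert set(a.tiles) == set(b.tiles)
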