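import math

import numpy as np
import pytest

import multinuc as mn
from multinuc.tileset import ShapeLayout

from conftest import uniform_gmc_pattern
from oracles import minimax_barrier


def square_layout(n, name="sq"):
    return ShapeLayout(
        name, n, n, {(r, c): f"{name}{r}{c}" for r in range(n) for c in range(n)}
    )


def line_layout(n):
    return ShapeLayout("line", 1, n, {(0, i): f"L{i}" for i in range(n)})


class TestSgmPath:
    def test_single_tile_layout(self, rng):
        layout = ShapeLayout("one", 1, 1, {(0, 0): "t"})
        pattern = uniform_gmc_pattern(["t"], 5.0)
        path = mn.sgm_sample_path(layout, pattern, mn.EnergyParams(g_se=3.0), (0, 0), rng)
        assert len(path) == 1
        assert path.barrier == pytest.approx(5.0)

    def test_2x2_barrier_is_nine_from_every_start_and_seed(self):
        """Uniform G_mc = 5, G_se = 3: every growth order passes through a
        trimer at G = 9, the worked-example barrier."""
        layout = square_layout(2)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        params = mn.EnergyParams(g_se=3.0)
        for seed in range(5):
            for start in layout.locations():
                path = mn.sgm_sample_path(
                    layout, pattern, params, start, np.random.default_rng(seed)
                )
                assert path.barrier == pytest.approx(9.0)
                assert len(path.barrier_state) == 3

    def test_1x4_line_monotone_increase(self, rng):
        """No 2-bond sites exist in 1-D: G rises all the way to the full line."""
        layout = line_layout(4)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        path = mn.sgm_sample_path(layout, pattern, mn.EnergyParams(g_se=3.0), (0, 0), rng)
        assert list(path.energies) == pytest.approx([5.0, 7.0, 9.0, 11.0])
        assert path.barrier == pytest.approx(11.0)

    def test_empty_start_rejected(self, rng):
        layout = line_layout(2)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        with pytest.raises(ValueError, match="empty"):
            mn.sgm_sample_path(layout, pattern, mn.EnergyParams(g_se=3.0), (0, 1000), rng)


class TestSgmRate:
    def test_doubling_concentrations_multiplies_rate_by_16(self):
        """2x2 worked case: the trimer barrier gains e^{3 ln 2} and the
        forward kinetics gain a factor 2: rate ratio exactly 16."""
        layout = square_layout(2)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        params = mn.EnergyParams(g_se=3.0)
        est1 = mn.sgm_estimate_rate(
            layout, pattern, params, n_paths=50, rng=np.random.default_rng(1)
        )
        est2 = mn.sgm_estimate_rate(
            layout, pattern.scaled(2.0), params, n_paths=50,
            rng=np.random.default_rng(2),
        )
        assert math.exp(est2.log_rate - est1.log_rate) == pytest.approx(16.0, rel=1e-9)

    def test_identical_disjoint_layouts_equal_rates(self):
        layout_a = square_layout(3, "a")
        layout_b = square_layout(3, "b")
        params = mn.EnergyParams(g_se=3.0)
        pa = uniform_gmc_pattern(layout_a.tile_names(), 5.0)
        pb = uniform_gmc_pattern(layout_b.tile_names(), 5.0)
        ra = mn.sgm_estimate_rate(layout_a, pa, params, n_paths=20,
                                  rng=np.random.default_rng(7))
        rb = mn.sgm_estimate_rate(layout_b, pb, params, n_paths=20,
                                  rng=np.random.default_rng(7))
        assert ra.log_rate == pytest.approx(rb.log_rate)

    def test_participation_frequencies_in_unit_interval(self, rng):
        layout = square_layout(3)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        est = mn.sgm_estimate_rate(layout, pattern, mn.EnergyParams(g_se=3.0),
                                   n_paths=10, rng=rng)
        assert all(0.0 <= f <= 1.0 for f in est.participation.values())
        assert est.k_median >= 1

    def test_colocalized_concentration_raises_rate(self):
        """High-concentration tiles contiguous in shape 1 but scattered in
        shape 2 give shape 1 the higher nucleation rate."""
        system, pattern = mn.make_wta_inputs(shared=True, enhanced_nm=500.0)
        params = mn.EnergyParams(g_se=10.5)
        rates = {}
        for layout in system.layouts:
            est = mn.sgm_estimate_rate(layout, pattern, params, n_paths=25,
                                       rng=np.random.default_rng(3))
            rates[layout.name] = est.log_rate
        assert rates["H"] > rates["B"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", ["2x2", "3x3", "1x4", "L", "T"])
    @pytest.mark.parametrize("conc", ["uniform", "random"])
    def test_sgm_reaches_exhaustive_minimax_barrier(self, case, conc):
        """On layouts of <= 9 tiles the minimum SGM barrier over many paths
        equals the exhaustive minimax barrier, and never undercuts it."""
        layouts = {
            "2x2": square_layout(2),
            "3x3": square_layout(3),
            "1x4": line_layout(4),
            "L": ShapeLayout("L", 3, 3, {(0, 0): "a", (1, 0): "b",
                                         (2, 0): "c", (2, 1): "d", (2, 2): "e"}),
            "T": ShapeLayout("T", 2, 3, {(0, 0): "a", (0, 1): "b",
                                         (0, 2): "c", (1, 1): "d"}),
        }
        layout = layouts[case]
        rng = np.random.default_rng(11)
        if conc == "uniform":
            conc_nm = {t: math.exp(-5.0) * 1e9 for t in layout.tile_names()}
        else:
            conc_nm = {t: float(rng.uniform(5.0, 2000.0))
                       for t in layout.tile_names()}
        pattern = mn.ConcentrationPattern(conc_nm)
        params = mn.EnergyParams(g_se=3.0)
        oracle = minimax_barrier(layout, conc_nm, params.g_se)
        est = mn.sgm_estimate_rate(
            layout, pattern, params, n_paths=200, rng=rng,
            commit_margin=math.inf,
        )
        assert est.min_barrier >= oracle - 1e-9
        assert est.min_barrier == pytest.approx(oracle, rel=1e-9)


class TestWnm:
    def test_k1_score_is_concentration_sum(self):
        layout = square_layout(2)
        pattern = mn.ConcentrationPattern({t: 100.0 for t in layout.tile_names()})
        params = mn.EnergyParams(g_se=3.0)
        assert mn.wnm_score(layout, pattern, params, k=1) == pytest.approx(
            4 * 100e-9, rel=1e-9
        )

    def test_3x3_uniform_k2_closed_form(self):
        """Four 2x2 windows, four bonds each: score = 4 (c/u0)^4 e^{4 G_se}."""
        layout = square_layout(3)
        c_nm = 60.0
        pattern = mn.ConcentrationPattern({t: c_nm for t in layout.tile_names()})
        params = mn.EnergyParams(g_se=3.0)
        expected = 4.0 * (c_nm * 1e-9) ** 4 * math.exp(4 * 3.0)
        assert mn.wnm_score(layout, pattern, params, k=2) == pytest.approx(
            expected, rel=1e-9
        )

    def test_permuting_within_window_preserves_weight(self):
        layout = square_layout(2)
        params = mn.EnergyParams(g_se=3.0)
        p1 = mn.ConcentrationPattern(
            dict(zip(sorted(layout.tile_names()), [10.0, 20.0, 30.0, 40.0]))
        )
        p2 = mn.ConcentrationPattern(
            dict(zip(sorted(layout.tile_names()), [40.0, 30.0, 20.0, 10.0]))
        )
        assert mn.wnm_score(layout, p1, params, k=2) == pytest.approx(
            mn.wnm_score(layout, p2, params, k=2)
        )

    def test_monotone_in_every_concentration(self):
        layout = square_layout(3)
        params = mn.EnergyParams(g_se=3.0)
        base = mn.ConcentrationPattern({t: 60.0 for t in layout.tile_names()})
        s0 = mn.wnm_log_score(layout, base, params, k=2)
        for t in layout.tile_names():
            up = base.updated({t: 120.0})
            assert mn.wnm_log_score(layout, up, params, k=2) > s0

    def test_no_complete_window_raises(self):
        layout = line_layout(4)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        with pytest.raises(ValueError, match="no fully occupied"):
            mn.wnm_log_score(layout, pattern, mn.EnergyParams(g_se=3.0), k=2)


class TestProfile:
    def test_2x2_profile_matches_enumeration(self, rng):
        layout = square_layout(2)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        params = mn.EnergyParams(g_se=3.0)
        paths = [
            mn.sgm_sample_path(layout, pattern, params, start, rng)
            for start in layout.locations()
            for _ in range(10)
        ]
        profile = mn.free_energy_profile(paths, layout, pattern, params)
        assert list(profile["g_min"]) == pytest.approx([5.0, 7.0, 9.0, 8.0])
        assert profile["g_min"].max() == pytest.approx(9.0)

    def test_line_profile_monotone(self, rng):
        layout = line_layout(4)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        params = mn.EnergyParams(g_se=3.0)
        paths = [mn.sgm_sample_path(layout, pattern, params, (0, i), rng)
                 for i in range(4)]
        profile = mn.free_energy_profile(paths, layout, pattern, params)
        g = list(profile["g_min"])
        assert g == sorted(g)

    def test_min_le_macro_aggregate_bound(self, rng):
        layout = square_layout(3)
        pattern = uniform_gmc_pattern(layout.tile_names(), 5.0)
        params = mn.EnergyParams(g_se=3.0)
        paths = [mn.sgm_sample_path(layout, pattern, params, s, rng)
                 for s in layout.locations()]
        profile = mn.free_energy_profile(paths, layout, pattern, params)
        # the macrostate (log-sum-exp) free energy lies at or below the
        # single-state minimum
        assert (profile["g_macro"] <= profile["g_min"] + 1e-9).all()


class TestClassify:
    def test_symmetric_system_declares_tie(self):
        system = mn.make_shared_block_fixture(seed=1, n=4, shared=False)
        pattern = mn.ConcentrationPattern.uniform(system.tiles, 60.0)
        res = mn.classify_pattern(pattern, system, mn.EnergyParams(g_se=10.5),
                                  method="wnm", k=2)
        assert res.is_tie
        assert res.predicted is None

    def test_colocalized_pattern_classified_with_positive_margin(self):
        system, pattern = mn.make_wta_inputs(shared=True)
        res = mn.classify_pattern(pattern, system, mn.EnergyParams(g_se=10.5),
                                  method="wnm", k=3)
        assert res.predicted == "H"
        assert res.margin > 0

    def test_temperature_reduces_seed_size(self):
        """Raising G_se (lower temperature) shrinks the typical critical
        seed size K."""
        system, pattern = mn.make_wta_inputs(shared=True)
        layout = system.layout("H")
        ks = []
        for g_se in (9.0, 12.0):
            est = mn.sgm_estimate_rate(
                layout, pattern, mn.EnergyParams(g_se=g_se), n_paths=10,
                rng=np.random.default_rng(5),
            )
            ks.append(est.k_median)
        assert ks[1] <= ks[0]
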