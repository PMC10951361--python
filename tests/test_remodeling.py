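"""BMU lifecycle: scheduling, initiation, fusion, resorption, formation."""

import numpy as np
import pytest

from marrowsim import remodeling as rem
from marrowsim.grid import CellKind, GridSpec, bone_perimeter_mask, init_world
from marrowsim.remodeling import (
    BmuPhase,
    RemodelingParams,
    initiate_bmu,
    msc_division_rate,
    place_msc_near_oc,
    schedule_bmu_initiations,
    update_mscs,
    update_osteoblasts,
    update_preosteoblasts,
    update_preosteoclasts,
)


@pytest.fixture
def params():
    return RemodelingParams()


class TestScheduling:
    def test_zero_horizon_empty(self, params):
        assert len(schedule_bmu_initiations(params, 0.0, 1000.0, seed=0)) == 0

    def test_same_seed_identical(self, params):
        a = schedule_bmu_initiations(params, 365.0, 1000.0, seed=42)
        b = schedule_bmu_initiations(params, 365.0, 1000.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_turnover_calibration_closed_form(self, params):
        """Expected events x (resorb_rate x oc_lifespan) equals the bone pool
        over four years, verified against a Monte-Carlo mean within 2 SE."""
        pool = 3096.0
        rate = params.calibrated_event_rate(pool)
        horizon = 4 * 365.0
        assert rate * horizon * params.resorb_rate * params.oc_lifespan == pytest.approx(pool)
        counts = [len(schedule_bmu_initiations(params, horizon, pool, seed=s))
                  for s in range(300)]
        expect = rate * horizon
        se = np.sqrt(expect / len(counts))  # Poisson SE of the mean
        assert abs(np.mean(counts) - expect) < 2 * se + 1e-9

    def test_times_sorted_within_horizon(self, params):
        t = schedule_bmu_initiations(params, 500.0, 3096.0, seed=1)
        assert (np.diff(t) >= 0).all()
        assert t.min() >= 0 and t.max() <= 500.0


class TestInitiateBmu:
    def test_activates_five_lining_cells(self, small_world):
        perim = np.argwhere(bone_perimeter_mask(small_world.bone.density))
        site = tuple(perim[len(perim) // 2])
        ev = initiate_bmu(small_world, site, RemodelingParams())
        assert len(ev.lining_sites) == 5
        assert all(small_world.rankl_active[s] for s in ev.lining_sites)
        assert ev.phase == BmuPhase.INITIATION

    def test_short_perimeter_activates_what_exists(self):
        """An isolated 3-cell sliver of bone can only activate 3 lining
        cells; the event still proceeds."""
        spec = GridSpec(nx=20, ny=20)
        mask = np.zeros(spec.shape)
        mask[9, 8:11] = 1.0
        w = init_world(spec, target_bone_fraction=3 / 400, mask=mask)
        # lining forms on all 3 perimeter bone sites; restrict to 3 cells
        ev = initiate_bmu(w, (9, 9), RemodelingParams())
        assert len(ev.lining_sites) == 3

    def test_interior_site_rejected(self, block_world):
        with pytest.raises(ValueError, match="marrow neighbor"):
            initiate_bmu(block_world, (10, 10), RemodelingParams())

    def test_marrow_site_rejected(self, block_world):
        with pytest.raises(ValueError, match="not bone"):
            initiate_bmu(block_world, (0, 0), RemodelingParams())

    def test_spawns_preosteoclasts_nearby(self, small_world, params):
        perim = np.argwhere(bone_perimeter_mask(small_world.bone.density))
        initiate_bmu(small_world, tuple(perim[0]), params)
        assert small_world.count(CellKind.PRE_OC) == params.preoc_spawn_count


class TestFusion:
    def _cluster(self, world, center, n):
        """Place n preosteoclasts packed around a site."""
        placed = 0
        for r in range(5):
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if placed >= n:
                        return
                    s = world.grid.wrap(center[0] + di, center[1] + dj)
                    if world.free_marrow(*s):
                        world.add_agent(CellKind.PRE_OC, s, lifespan=30.0)
                        placed += 1

    def _setup(self, world, n_preoc, p_fuse):
        params = RemodelingParams(p_fuse=p_fuse, preoc_spawn_count=0)
        perim = np.argwhere(bone_perimeter_mask(world.bone.density))
        site = tuple(perim[0])
        ev = initiate_bmu(world, site, params)
        world.fields.R_L[:] = 5.0  # established plateau: cluster holds still
        self._cluster(world, site, n_preoc)
        return params, ev

    def test_four_precursors_never_fuse(self, small_world):
        params, ev = self._setup(small_world, 4, p_fuse=1.0)
        for _ in range(50):
            update_preosteoclasts(small_world, params, [ev], 0.5)
        assert small_world.count(CellKind.OC) == 0

    def test_five_precursors_forced_fusion(self, small_world):
        params, ev = self._setup(small_world, 5, p_fuse=1.0)
        for _ in range(20):
            update_preosteoclasts(small_world, params, [ev], 0.5)
            if small_world.count(CellKind.OC):
                break
        assert small_world.count(CellKind.OC) == 1
        assert small_world.count(CellKind.PRE_OC) == 0
        assert ev.phase == BmuPhase.RESORPTION
        # RANKL expression stops at fusion
        assert not any(small_world.rankl_active[s] for s in ev.lining_sites)

    def test_fusion_probability_binomial(self, small_world):
        """Across many independent single-step trials of an eligible cluster,
        the fusion frequency matches p_fuse within 3 binomial SE."""
        n, p = 400, 0.3
        fused = 0
        for k in range(n):
            w = small_world.copy()
            w.rng = np.random.default_rng(k)
            params, ev = self._setup(w, 6, p_fuse=p)
            update_preosteoclasts(w, params, [ev], 0.5)
            fused += w.count(CellKind.OC)
        se = np.sqrt(n * p * (1 - p))
        assert abs(fused - n * p) < 3 * se

    def test_btz_fusion_block_vetoes(self, small_world):
        params, ev = self._setup(small_world, 6, p_fuse=1.0)
        for _ in range(30):
            update_preosteoclasts(small_world, params, [ev], 0.5, fusion_block_p=1.0)
        assert small_world.count(CellKind.OC) == 0

    def test_oc_budget_is_lifespan_times_rate(self, small_world):
        params, ev = self._setup(small_world, 5, p_fuse=1.0)
        for _ in range(20):
            update_preosteoclasts(small_world, params, [ev], 0.5)
            if small_world.count(CellKind.OC):
                break
        oc = tuple(small_world.sites_of(CellKind.OC)[0])
        assert small_world.budget[oc] == pytest.approx(
            params.resorb_rate * params.oc_lifespan)


class TestOsteoclasts:
    def _world_with_oc(self, block_world, budget=14.0, lifespan=14.0):
        # place OC beside the bone block, in marrow
        site = (7, 10)
        block_world.add_agent(CellKind.OC, site, lifespan=lifespan, budget=budget)
        return site

    def test_full_lifespan_resorbs_budget(self, block_world):
        """An osteoclast living its full lifespan at full activity removes
        resorb_rate x lifespan density in total (budget exactly spent)."""
        params = RemodelingParams(oc_bdf_floor=1.0)  # activity identically 1
        self._world_with_oc(block_world)
        total0 = block_world.bone.density.sum()
        for _ in range(2 * 16):  # 16 days at dt=0.5
            rem.update_osteoclasts(block_world, params, [], 0.5)
        removed = total0 - block_world.bone.density.sum()
        assert removed == pytest.approx(params.resorb_rate * params.oc_lifespan, rel=1e-6)
        assert block_world.count(CellKind.OC) == 0  # died at lifespan end

    def test_oc_without_adjacent_bone_idles_and_ages(self, empty_world, params):
        empty_world.add_agent(CellKind.OC, (12, 12), lifespan=14.0, budget=14.0)
        for _ in range(4):
            rem.update_osteoclasts(empty_world, params, [], 0.5)
        assert empty_world.bone.density.sum() == pytest.approx(4.0)  # untouched corner
        assert empty_world.age[12, 12] == pytest.approx(2.0)

    def test_zoledronate_scales_resorption(self, block_world, params):
        """With a 50% resorption block, cumulative resorption per OC halves
        against the unblocked twin at matched seeds."""
        twin = block_world.copy()
        twin.rng = np.random.default_rng(0)
        block_world.rng = np.random.default_rng(0)
        for w in (block_world, twin):
            w.add_agent(CellKind.OC, (7, 10), lifespan=4.0, budget=100.0)
            w.fields.T_beta[:] = 100.0
        for _ in range(8):
            rem.update_osteoclasts(block_world, params, [], 0.5, zol_effect=0.0)
            rem.update_osteoclasts(twin, params, [], 0.5, zol_effect=0.5)
        removed = 25.0 - block_world.bone.density.sum()
        removed_zol = 25.0 - twin.bone.density.sum()
        assert removed_zol == pytest.approx(0.5 * removed, rel=1e-6)

    def test_full_block_resorbs_nothing(self, block_world, params):
        self._world_with_oc(block_world)
        for _ in range(10):
            rem.update_osteoclasts(block_world, params, [], 0.5, zol_effect=1.0)
        assert block_world.bone.density.sum() == pytest.approx(25.0)
        assert block_world.resorbed_this_step.sum() == 0.0


class TestMscPlacement:
    def test_placed_within_40um(self, block_world, params):
        assert place_msc_near_oc(block_world, (7, 10), params)
        msc = block_world.sites_of(CellKind.MSC)
        assert len(msc) == 1
        d = np.hypot(*(msc[0] - np.array([7, 10]))) * block_world.grid.h
        assert d <= params.msc_radius_um

    def test_existing_msc_blocks_placement(self, block_world, params):
        block_world.add_agent(CellKind.MSC, (7, 13))  # 30 um away
        assert not place_msc_near_oc(block_world, (7, 10), params)
        assert block_world.count(CellKind.MSC) == 1

    def test_two_adjacent_fusions_place_one_msc(self, block_world, params):
        """Two osteoclasts fusing 10 um apart in one step share a
        neighborhood: the second placement sees the first MSC."""
        placed = [place_msc_near_oc(block_world, (7, 10), params),
                  place_msc_near_oc(block_world, (7, 11), params)]
        assert placed == [True, False]
        assert block_world.count(CellKind.MSC) == 1


class TestMscDivision:
    def test_rate_zero_below_floor(self, params):
        assert msc_division_rate(params.msc_floor * 0.5, params) == 0.0
        assert msc_division_rate(0.0, params) == 0.0

    def test_rate_monotone_saturating(self, params):
        ts = np.linspace(params.msc_floor, 3.0, 40)
        rates = [msc_division_rate(t, params) for t in ts]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] <= params.msc_div_max

    def test_no_divisions_in_bdf_free_world(self, empty_world, params):
        empty_world.add_agent(CellKind.MSC, (10, 10), lifespan=1e6,
                              budget=params.msc_max_divisions)
        for _ in range(200):
            update_mscs(empty_world, params, 0.5)
        assert empty_world.count(CellKind.PRE_OB) == 0

    def test_asymmetric_division_preserves_msc(self, empty_world, params):
        empty_world.add_agent(CellKind.MSC, (10, 10), lifespan=1e6,
                              budget=params.msc_max_divisions)
        empty_world.fields.T_beta[:] = 1.0
        for _ in range(40):
            update_mscs(empty_world, params, 0.5)
        assert empty_world.count(CellKind.MSC) == 1
        assert 0 < empty_world.count(CellKind.PRE_OB) <= params.msc_max_divisions

    def test_crowded_msc_defers_division(self, empty_world, params):
        empty_world.add_agent(CellKind.MSC, (10, 10), lifespan=1e6, budget=16.0)
        for di, dj in [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]:
            empty_world.add_agent(CellKind.MM, (10 + di, 10 + dj), clone_id=0)
        empty_world.fields.T_beta[:] = 1.0
        before = empty_world.kind.copy()
        for _ in range(20):
            update_mscs(empty_world, params, 0.5)
        assert empty_world.count(CellKind.PRE_OB) == 0
        np.testing.assert_array_equal(empty_world.kind, before)


class TestPreosteoblasts:
    def test_high_bdf_proliferates_never_differentiates(self, empty_world, params):
        empty_world.fields.T_beta[:] = 10 * params.preob_threshold
        empty_world.bone.resorbed_depth[10, 11] = 1.0
        empty_world.add_agent(CellKind.PRE_OB, (10, 10))
        p = rem.RemodelingParams(preob_death_rate=0.0, preob_div_rate=0.4)
        counts = []
        for _ in range(60):
            update_preosteoblasts(empty_world, p, [], 0.5)
            counts.append(empty_world.count(CellKind.PRE_OB))
        assert empty_world.count(CellKind.OB) == 0
        assert all(b >= a for a, b in zip(counts, counts[1:]))  # nondecreasing

    def test_low_bdf_differentiates_with_depth_proportional_lifespan(
            self, empty_world, params):
        empty_world.bone.resorbed_depth[10, 10] = 0.6
        empty_world.add_agent(CellKind.PRE_OB, (10, 10))
        p = rem.RemodelingParams(preob_death_rate=0.0)
        update_preosteoblasts(empty_world, p, [], 0.5)
        assert empty_world.kind[10, 10] == CellKind.OB
        assert empty_world.lifespan[10, 10] == pytest.approx(0.6 * p.ob_lifespan_per_depth)
        assert empty_world.budget[10, 10] == pytest.approx(0.6)

    def test_typical_cavity_gives_three_month_osteoblast(self, empty_world):
        """A fully excavated site (depth 1) yields an osteoblast living
        ~90 days, the typical formation-phase duration."""
        empty_world.bone.resorbed_depth[5, 5] = 1.0
        empty_world.add_agent(CellKind.PRE_OB, (5, 5))
        p = rem.RemodelingParams(preob_death_rate=0.0)
        update_preosteoblasts(empty_world, p, [], 0.5)
        assert empty_world.lifespan[5, 5] == pytest.approx(90.0)

    def test_blockade_map_vetoes_differentiation(self, empty_world):
        empty_world.bone.resorbed_depth[10, 10] = 1.0
        empty_world.add_agent(CellKind.PRE_OB, (10, 10))
        blocked = np.ones(empty_world.grid.shape, dtype=bool)
        p = rem.RemodelingParams(preob_death_rate=0.0)
        for _ in range(20):
            update_preosteoblasts(empty_world, p, [], 0.5, blocked=blocked)
        assert empty_world.count(CellKind.OB) == 0


class TestOsteoblasts:
    def test_full_life_deposits_exact_budget(self, empty_world):
        """budget b at rate b/L over lifespan L deposits exactly b."""
        p = rem.RemodelingParams(p_burial=0.0)
        b = 0.8
        empty_world.bone.resorbed_depth[6, 6] = b
        empty_world.add_agent(
            CellKind.OB, (6, 6), lifespan=b * p.ob_lifespan_per_depth,
            budget=b, ob_rate=1.0 / p.ob_lifespan_per_depth)
        for _ in range(2 * int(b * p.ob_lifespan_per_depth) + 4):
            update_osteoblasts(empty_world, p, [], 0.5)
        assert empty_world.bone.density[6, 6] == pytest.approx(b, abs=1e-9)
        assert empty_world.bone.resorbed_depth[6, 6] == pytest.approx(0.0)

    def test_burial_conserves_total_deposition(self, empty_world):
        """A buried osteoblast's unbuilt remainder transfers to the nearest
        survivor, leaving the eventually-deposited total unchanged."""
        p = rem.RemodelingParams(p_burial=1.0, ob_lining_fraction=0.0)
        for site, depth in [((6, 6), 0.5), ((12, 12), 1.0)]:
            empty_world.bone.resorbed_depth[site] = depth
            empty_world.add_agent(
                CellKind.OB, site, lifespan=depth * p.ob_lifespan_per_depth,
                budget=depth, ob_rate=1.0 / p.ob_lifespan_per_depth)
        for _ in range(2 * 200):
            update_osteoblasts(empty_world, p, [], 0.5)
        total = empty_world.bone.density.sum() + empty_world.budget[
            empty_world.kind == CellKind.OB].sum() + empty_world.unassigned_budget
        # corner block fixture contributes 4.0 background density
        assert total - 4.0 == pytest.approx(1.5, abs=1e-6)

    def test_no_burial_closes_budget_loop(self, empty_world):
        p = rem.RemodelingParams(p_burial=0.0)
        empty_world.bone.resorbed_depth[6, 6] = 1.0
        empty_world.add_agent(CellKind.OB, (6, 6), lifespan=90.0, budget=1.0,
                              ob_rate=1.0 / 90.0)
        for _ in range(2 * 95):
            update_osteoblasts(empty_world, p, [], 0.5)
        assert empty_world.bone.density[6, 6] == pytest.approx(1.0, abs=1e-9)

    def test_anabolic_boost_speeds_deposition(self, empty_world):
        p = rem.RemodelingParams(p_burial=0.0)
        for site in [(4, 4), (14, 14)]:
            empty_world.bone.resorbed_depth[site] = 1.0
            empty_world.add_agent(CellKind.OB, site, lifespan=90.0, budget=1.0,
                                  ob_rate=1.0 / 90.0)
        update_osteoblasts(empty_world, p, [], 0.5, anabolic_boost=0.0)
        d0 = empty_world.bone.density[4, 4]
        # fresh twin with boost
        assert d0 == pytest.approx(0.5 / 90.0)
        empty2 = empty_world
        empty2.bone.density[14, 14] = 0.0
        rem.update_osteoblasts(empty2, p, [], 0.5, anabolic_boost=0.3)
        assert empty2.bone.density[14, 14] >= d0  # boosted twin deposits more
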