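import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastdol import (CellBlock, ColonyGrid, choose_division_site,
                      dark_metabolic_update, eligible_to_divide,
                      light_metabolic_update, perform_division,
                      try_switch_dark_to_light, try_switch_light_to_dark,
                      update_block)
from yeastdol.core_types import DARK, LIGHT, SimulationConfig

from _reference import reference_block_update


class TestSwitching:
    @pytest.mark.parametrize("local, draw, expect", [
        (1.6, 0.3, True),    # above threshold, draw under P_DL
        (1.4, 0.3, False),   # below threshold regardless of draw
        (1.6, 0.9, False),   # draw at or above P_DL
        (1.5, 0.0, False),   # threshold is strict
    ])
    def test_dark_to_light(self, cfg, queued_rng, local, draw, expect):
        block = CellBlock(DARK, 5, 5, C=0.4, N=0.2)
        switched = try_switch_dark_to_light(block, local, cfg,
                                            queued_rng([draw]))
        assert switched is expect
        assert block.state == (LIGHT if expect else DARK)
        # pools are retained unchanged across a switch
        assert block.C == 0.4 and block.N == 0.2

    @pytest.mark.parametrize("local, draw, expect", [
        (0.0, 5e-5, True),
        (0.01, 5e-5, False),
        (0.0, 0.5, False),
    ])
    def test_light_to_dark(self, cfg, queued_rng, local, draw, expect):
        block = CellBlock(LIGHT, 5, 5)
        assert try_switch_light_to_dark(block, local, cfg,
                                        queued_rng([draw])) is expect


class TestDarkMetabolism:
    def test_default_budgeting_arithmetic(self, cfg):
        block = CellBlock(DARK, 0, 0)
        secreted = dark_metabolic_update(block, cfg)
        # f*AspU*Cmax = 0.125*0.2 to N; (1-f)*AspU*Cmax*Y = 0.875*0.2*0.31
        assert block.N == pytest.approx(0.025, rel=1e-12)
        c_tmp = 0.875 * 0.2 * 0.31
        assert secreted == pytest.approx(0.049 * c_tmp, rel=1e-12)
        assert block.C == pytest.approx(c_tmp * (1 - 0.049), rel=1e-12)
        assert block.C == pytest.approx(0.05159175, rel=1e-9)

    def test_secretion_cap_binds_for_large_pool(self, cfg):
        block = CellBlock(DARK, 0, 0, C=10.0)
        assert dark_metabolic_update(block, cfg) == cfg.secretion_cap == 0.12

    def test_all_flux_to_nitrogen_adds_no_carbon(self, cfg):
        cfg1 = cfg.replace(f=1.0)
        block = CellBlock(DARK, 0, 0)
        assert dark_metabolic_update(block, cfg1) == 0.0
        assert block.C == 0.0
        assert block.N == pytest.approx(cfg.AspU * cfg.Cmax)
        # with a pre-existing pool, secretion scales only with that pool
        block2 = CellBlock(DARK, 0, 0, C=1.0)
        assert dark_metabolic_update(block2, cfg1) == pytest.approx(cfg.Pf)

    def test_carbon_conserved_between_pool_and_secretion(self, cfg, rng):
        for _ in range(100):
            c0 = float(rng.uniform(0, 5))
            block = CellBlock(DARK, 0, 0, C=c0)
            secreted = dark_metabolic_update(block, cfg)
            gain = (1 - cfg.f) * cfg.AspU * cfg.Cmax * cfg.Y
            assert block.C + secreted == pytest.approx(c0 + gain, rel=1e-12)
            assert 0.0 <= secreted <= cfg.secretion_cap


class TestLightMetabolism:
    @pytest.mark.parametrize("local, expect_consumed", [
        (0.03, 0.03),  # below Cmax: site emptied
        (0.2, 0.05),   # Cmax binds
        (0.0, 0.0),    # nothing available
    ])
    def test_consumption(self, cfg, local, expect_consumed):
        block = CellBlock(LIGHT, 0, 0)
        consumed = light_metabolic_update(block, local, cfg)
        assert consumed == pytest.approx(expect_consumed)
        assert block.C == pytest.approx(expect_consumed)
        # aspartate is non-limiting: N always gains AspU*Cmax = 0.2
        assert block.N == pytest.approx(0.2)


class TestDivisionEligibility:
    @pytest.mark.parametrize("state, C, N, expect", [
        (DARK, 1.0, 1.0, True),
        (DARK, 0.99, 1.0, False),
        (DARK, 1.0, 0.99, False),
        (LIGHT, 1.0, 3.9, False),
        (LIGHT, 2.0, 4.0, True),
        (LIGHT, 0.99, 8.0, False),
    ])
    def test_reserve_thresholds(self, cfg, state, C, N, expect):
        assert eligible_to_divide(CellBlock(state, 0, 0, C, N), cfg) is expect

    def test_literal_rule_variant_swaps_thresholds(self, cfg):
        swapped = cfg.replace(light_rule="exn_on_c")
        assert eligible_to_divide(CellBlock(LIGHT, 0, 0, 4.0, 1.0), swapped)
        assert not eligible_to_divide(CellBlock(LIGHT, 0, 0, 1.0, 4.0),
                                      swapped)

    @given(C=st.floats(0, 10), N=st.floats(0, 10),
           dC=st.floats(0, 5), dN=st.floats(0, 5),
           state=st.sampled_from([DARK, LIGHT]))
    @settings(max_examples=200, deadline=None)
    def test_eligibility_is_monotone_in_reserves(self, C, N, dC, dN, state):
        cfg = SimulationConfig()
        if eligible_to_divide(CellBlock(state, 0, 0, C, N), cfg):
            assert eligible_to_divide(CellBlock(state, 0, 0, C + dC, N + dN),
                                      cfg)


def _grid_with(occupied, shape=(11, 11)):
    grid = ColonyGrid(shape)
    for (x, y) in occupied:
        grid.place(CellBlock(DARK, x, y))
    return grid


class TestChooseDivisionSite:
    def test_unique_empty_neighbor_is_chosen(self, rng):
        grid = _grid_with([(5, 5), (4, 5), (6, 5), (5, 4)])
        assert choose_division_site((5, 5), grid, rng) == (5, 6)

    def test_prefers_site_with_more_occupied_neighbors(self, rng):
        # (5,6) has 3 occupied neighbors, (5,4) has 1 (the mother)
        grid = _grid_with([(5, 5), (4, 6), (6, 6), (5, 7)])
        for _ in range(20):
            assert choose_division_site((5, 5), grid, rng) == (5, 6)

    def test_returns_none_when_surrounded(self, rng):
        grid = _grid_with([(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)])
        assert choose_division_site((5, 5), grid, rng) is None

    def test_ties_are_broken_at_random(self):
        grid = _grid_with([(5, 5)])  # all 4 neighbors empty, all count 1
        rng = np.random.default_rng(0)
        chosen = {choose_division_site((5, 5), grid, rng)
                  for _ in range(200)}
        assert chosen == {(4, 5), (6, 5), (5, 4), (5, 6)}

    def test_off_grid_neighbors_are_not_candidates(self, rng):
        grid = _grid_with([(0, 0), (1, 0)], shape=(3, 3))
        assert choose_division_site((0, 0), grid, rng) == (0, 1)


class TestPerformDivision:
    def test_pools_halved_and_conserved(self):
        mother = CellBlock(DARK, 5, 5, C=1.2, N=1.0)
        daughter = perform_division(mother, (5, 6), step=17)
        assert mother.C == daughter.C == 0.6
        assert mother.N == daughter.N == 0.5
        assert mother.C + daughter.C == 1.2
        assert daughter.position == (5, 6)
        assert mother.last_division_step == daughter.last_division_step == 17

    @pytest.mark.parametrize("state", [DARK, LIGHT])
    def test_state_inherited(self, state):
        mother = CellBlock(state, 5, 5, C=2.0, N=8.0)
        assert perform_division(mother, (5, 6), 0).state == state


class TestAgainstReferenceOracle:
    def test_update_block_matches_straight_line_oracle_bitwise(self, cfg):
        """10^4 randomized (state, pools, local field) tuples, with twin
        RNG streams, must agree bit-for-bit with the reference rules."""
        master = np.random.default_rng(2024)
        for case in range(10_000):
            state = DARK if master.random() < 0.5 else LIGHT
            C = float(master.uniform(0, 3))
            N = float(master.uniform(0, 6))
            local = float(10 ** master.uniform(-6, 1)) \
                if master.random() < 0.8 else 0.0
            block = CellBlock(state, 0, 0, C, N)
            out = update_block(block, local, cfg,
                               np.random.default_rng(case))
            ref = reference_block_update(state, C, N, local, cfg,
                                         np.random.default_rng(case))
            assert (block.state, block.C, block.N, out.secreted,
                    out.consumed_trehalose, out.switched) == ref
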