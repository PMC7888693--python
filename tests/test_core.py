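import math

import numpy as np
import pandas as pd
import pytest

from conftest import uniform_distance_system
from fcaccess.core import (
    DemandSet,
    InteractionTable,
    SupplySet,
    accessibility_index,
    build_interactions,
    mh3sfca,
    supply_demand_ratio,
)
from fcaccess.decay import DecayParams, derive_beta
from fcaccess.network import TravelTimeMatrix
from oracles import mh3sfca_dense, random_instance


def ttm(rows, d_max=30.0):
    return TravelTimeMatrix(
        pd.DataFrame(rows, columns=["demand_id", "supply_id", "minutes"]), d_max=d_max
    )


def supply(caps):
    return SupplySet(
        pd.DataFrame(
            {"id": list(caps), "x": 0.0, "y": 0.0, "capacity": list(caps.values())}
        )
    )


def demand(pops):
    return DemandSet(
        pd.DataFrame({"id": list(pops), "x": 0.0, "y": 0.0, "pop": list(pops.values())})
    )


class TestDomainTypes:
    def test_zero_capacity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            supply({"j": 0.0})

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            demand({"i": -1.0})

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DemandSet(
                pd.DataFrame({"id": ["a", "a"], "x": [0.0, 1.0], "y": [0.0, 1.0], "pop": [1.0, 2.0]})
            )


class TestBuildInteractions:
    def test_single_reachable_site_gets_probability_one(self, params30):
        I = build_interactions(ttm([("i", "j", 29.0)]), supply({"j": 3.0}), params30)
        assert I.table["huff"].tolist() == [1.0]

    def test_hand_computed_huff_split(self):
        # capacities (2, 1) and weights (0.5, 0.25) → Huff (0.8, 0.2)
        params = DecayParams(d_max=30.0, beta=1.0, w_min=0.01)
        d1 = math.sqrt(math.log(2.0))  # weight 0.5
        d2 = math.sqrt(math.log(4.0))  # weight 0.25
        I = build_interactions(
            ttm([("i", "j1", d1), ("i", "j2", d2)]),
            supply({"j1": 2.0, "j2": 1.0}),
            params,
        )
        got = I.table.set_index("supply_id")["huff"]
        assert got["j1"] == pytest.approx(0.8, abs=1e-12)
        assert got["j2"] == pytest.approx(0.2, abs=1e-12)

    def test_equal_distances_reduce_to_capacity_shares(self, params30):
        caps = {"j1": 2.0, "j2": 5.0, "j3": 3.0}
        I = build_interactions(
            ttm([("i", j, 12.0) for j in caps]), supply(caps), params30
        )
        got = I.table.set_index("supply_id")["huff"]
        for j, c in caps.items():
            assert got[j] == pytest.approx(c / 10.0, abs=1e-12)

    def test_unknown_supply_id_rejected(self, params30):
        with pytest.raises(ValueError, match="unknown supply"):
            build_interactions(ttm([("i", "ghost", 1.0)]), supply({"j": 1.0}), params30)

    def test_rows_normalize_per_demand_location(self, params30):
        rng = np.random.default_rng(0)
        _, _, _, S, _, T = random_instance(rng)
        I = build_interactions(T, S, params30)
        sums = I.table.groupby("demand_id")["huff"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestSupplyDemandRatio:
    def test_hand_computed_ratio(self, params30):
        # R_j = 2 / (0.8*100 + 0.5*300) = 2/230
        I = InteractionTable(
            pd.DataFrame(
                {
                    "demand_id": ["i1", "i2"],
                    "supply_id": ["j", "j"],
                    "minutes": [1.0, 2.0],
                    "weight": [0.9, 0.8],
                    "huff": [0.8, 0.5],
                }
            ),
            params30,
        )
        R = supply_demand_ratio(I, supply({"j": 2.0}), demand({"i1": 100.0, "i2": 300.0}))
        assert R.set_index("supply_id").loc["j", "R"] == pytest.approx(2.0 / 230.0, rel=1e-12)

    def test_simple_ratio(self, params30):
        I = InteractionTable(
            pd.DataFrame(
                {"demand_id": ["i"], "supply_id": ["j"], "minutes": [0.0], "weight": [1.0], "huff": [1.0]}
            ),
            params30,
        )
        R = supply_demand_ratio(I, supply({"j": 1.0}), demand({"i": 500.0}))
        assert R["R"].iloc[0] == pytest.approx(0.002, rel=1e-12)

    def test_island_site_flagged_as_zero(self, params30, caplog):
        I = InteractionTable(
            pd.DataFrame(
                {"demand_id": ["i"], "supply_id": ["j1"], "minutes": [1.0], "weight": [0.9], "huff": [1.0]}
            ),
            params30,
        )
        with caplog.at_level("WARNING"):
            R = supply_demand_ratio(
                I, supply({"j1": 1.0, "j2": 4.0}), demand({"i": 10.0})
            )
        assert R.set_index("supply_id").loc["j2", "R"] == 0.0
        assert "no demand" in caplog.text


class TestAccessibilityIndex:
    def test_hand_computed_index(self, params30):
        I = InteractionTable(
            pd.DataFrame(
                {
                    "demand_id": ["i", "i"],
                    "supply_id": ["j1", "j2"],
                    "minutes": [1.0, 2.0],
                    "weight": [0.5, 0.25],
                    "huff": [0.8, 0.2],
                }
            ),
            params30,
        )
        R = pd.DataFrame({"supply_id": ["j1", "j2"], "R": [0.01, 0.02]})
        A = accessibility_index(I, R)
        assert A["i"] == pytest.approx(0.8 * 0.01 * 0.5 + 0.2 * 0.02 * 0.25, rel=1e-12)


class TestMh3sfca:
    def test_colocated_single_pair_collapses_to_supply_ratio(self, params30):
        res = mh3sfca(ttm([("i", "j", 0.0)]), supply({"j": 3.0}), demand({"i": 600.0}), params30)
        assert res.demand["A"].iloc[0] == pytest.approx(3.0 / 600.0, abs=1e-12)

    @pytest.mark.parametrize("d", [0.0, 5.0, 15.0, 30.0])
    def test_uniform_distance_closed_form(self, d):
        beta = derive_beta(30.0, 0.01)
        params = DecayParams(30.0, beta, 0.01)
        T, S, D = uniform_distance_system(6, 4, d, 30.0)
        res = mh3sfca(T, S, D, params)
        expected = math.exp(-(d**2) / beta) * S.total_capacity / D.total_population
        assert np.allclose(res.demand["A"], expected, atol=1e-12)

    def test_uncovered_demand_gets_zero_and_is_counted(self, params30):
        res = mh3sfca(
            ttm([("i1", "j", 5.0)]),
            supply({"j": 1.0}),
            demand({"i1": 10.0, "i2": 20.0}),
            params30,
        )
        a = res.demand.set_index("id")["A"]
        assert a["i2"] == 0.0
        assert res.metadata["n_uncovered_demand"] == 1

    def test_zero_population_cell_has_access_but_no_demand_weight(self, params30):
        res = mh3sfca(
            ttm([("i1", "j", 5.0), ("i0", "j", 5.0)]),
            supply({"j": 1.0}),
            demand({"i1": 100.0, "i0": 0.0}),
            params30,
        )
        a = res.demand.set_index("id")["A"]
        assert a["i0"] > 0  # the empty cell still has access
        # allocated demand comes from i1 alone: R = S / (1.0 * 100)
        assert res.ratios["R"].iloc[0] == pytest.approx(1.0 / 100.0, rel=1e-12)

    def test_id_mismatch_reported(self, params30):
        with pytest.raises(ValueError, match="unknown demand"):
            mh3sfca(ttm([("ghost", "j", 1.0)]), supply({"j": 1.0}), demand({"i": 1.0}), params30)

    def test_matches_dense_oracle(self, params30):
        rng = np.random.default_rng(123)
        for _ in range(30):
            dmat, S_arr, D_arr, S, D, T = random_instance(rng)
            res = mh3sfca(T, S, D, params30)
            want = mh3sfca_dense(dmat, S_arr, D_arr, params30)
            got = res.demand["A"].to_numpy()
            assert np.max(np.abs(got - want)) < 1e-10

    def test_scale_equivariance(self, params30):
        rng = np.random.default_rng(5)
        _, _, _, S, D, T = random_instance(rng, allow_zero_pop=False)
        base = mh3sfca(T, S, D, params30).demand["A"].to_numpy()
        S2 = SupplySet(S.table.assign(capacity=S.table["capacity"] * 3.0))
        up = mh3sfca(T, S2, D, params30).demand["A"].to_numpy()
        assert np.allclose(up, 3.0 * base, rtol=1e-12)
        D2 = DemandSet(D.table.assign(pop=D.table["pop"] * 4.0))
        down = mh3sfca(T, S, D2, params30).demand["A"].to_numpy()
        assert np.allclose(down, base / 4.0, rtol=1e-12)

    def test_constant_total_demand(self, params30):
        rng = np.random.default_rng(9)
        for _ in range(20):
            _, _, _, S, D, T = random_instance(rng)
            I = build_interactions(T, S, params30)
            pop = D.table.set_index("id")["pop"]
            allocated = (
                I.table["huff"].to_numpy()
                * pop[I.table["demand_id"]].to_numpy(dtype=float)
            ).sum()
            covered = pop[pop.index.isin(I.table["demand_id"].unique())].sum()
            if covered > 0:
                assert allocated == pytest.approx(covered, rel=1e-9)

    def test_subzone_mode_with_degenerate_zones_matches_continuous(self):
        # one zone per observed distance, each distance its own midpoint
        beta = derive_beta(30.0, 0.01)
        distances = [1.5, 4.5, 7.5, 10.5, 13.5]
        n = len(distances)
        width = 3.0
        sub = DecayParams(n * width, beta, 0.01, mode="subzones", n_zones=n)
        cont = DecayParams(n * width, beta, 0.01, mode="continuous")
        rows = [(f"i{k}", "j", d) for k, d in enumerate(distances)]
        S = supply({"j": 2.0})
        D = demand({f"i{k}": 50.0 + k for k in range(n)})
        a_sub = mh3sfca(ttm(rows, d_max=n * width), S, D, sub).demand["A"].to_numpy()
        a_cont = mh3sfca(ttm(rows, d_max=n * width), S, D, cont).demand["A"].to_numpy()
        assert np.allclose(a_sub, a_cont, atol=1e-12)
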