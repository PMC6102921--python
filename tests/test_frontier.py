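import itertools
import math

import numpy as np
import pytest

from molarcea.engine import StrategyResult
from molarcea.frontier import (
    DOMINATED,
    EXTENDED_DOMINATED,
    UNDOMINATED,
    build_frontier,
    net_monetary_benefit,
)


def R(name, cost, eff):
    return StrategyResult(name, cost, eff)


class TestNetMonetaryBenefit:
    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(R("x", 420.0, 17.8), 0.0) == -420.0

    def test_direct_arithmetic(self):
        assert net_monetary_benefit(R("IFDP", 6611.2, 17.8), 1000.0) == (
            pytest.approx(11188.8)
        )

    def test_equal_nmb_at_the_pairwise_icer(self):
        a, b = R("a", 6611.2, 17.8), R("b", 8461.1, 19.1)
        icer = (b.cost - a.cost) / (b.effectiveness - a.effectiveness)
        assert net_monetary_benefit(a, icer) == pytest.approx(
            net_monetary_benefit(b, icer)
        )

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            net_monetary_benefit(R("x", 1.0, 1.0), -5.0)


class TestBuildFrontier:
    def test_two_strategy_increments(self):
        rep = build_frontier([R("IFDP", 6611.2, 17.8), R("Implant", 8461.1, 19.1)])
        inc = rep.increments[0]
        assert inc["incr_cost"] == pytest.approx(1849.9)
        assert inc["incr_effectiveness"] == pytest.approx(1.3)
        assert inc["icer"] == pytest.approx(1423.0, rel=1e-3)
        assert rep.frontier == ("IFDP", "Implant")

    def test_extended_dominance_middle_point(self):
        rep = build_frontier([R("A", 0, 0), R("B", 10, 1), R("C", 15, 3)])
        assert rep.classification == {
            "A": UNDOMINATED,
            "B": EXTENDED_DOMINATED,
            "C": UNDOMINATED,
        }
        assert rep.frontier == ("A", "C")
        assert rep.icer("C", "A") == pytest.approx(5.0)

    def test_strict_dominance(self):
        rep = build_frontier([R("A", 5, 1), R("B", 4, 2)])
        assert rep.classification["A"] == DOMINATED
        assert rep.classification["B"] == UNDOMINATED

    def test_equal_effectiveness_cheaper_survives(self):
        rep = build_frontier([R("A", 5, 2), R("B", 4, 2)])
        assert rep.classification == {"B": UNDOMINATED, "A": DOMINATED}

    def test_exact_ties_flagged_equivalent(self):
        rep = build_frontier([R("A", 5, 2), R("B", 5, 2)])
        assert rep.classification["A"] == UNDOMINATED
        assert rep.classification["B"] == UNDOMINATED
        assert rep.equivalent == (("A", "B"),)

    def test_icers_strictly_increase_along_frontier(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(2, 7)
            res = [
                R(f"s{i}", float(rng.uniform(0, 100)), float(rng.uniform(0, 10)))
                for i in range(n)
            ]
            icers = [d["icer"] for d in build_frontier(res).increments]
            assert all(b > a for a, b in zip(icers, icers[1:]))

    def test_invariant_to_input_order(self):
        res = [R("A", 0, 0), R("B", 10, 1), R("C", 15, 3), R("D", 30, 2)]
        reports = [
            build_frontier(perm) for perm in itertools.permutations(res)
        ]
        first = reports[0]
        for rep in reports[1:]:
            assert rep.classification == first.classification
            assert rep.frontier == first.frontier

    def test_nonfinite_totals_rejected(self):
        with pytest.raises(ValueError):
            build_frontier([R("A", math.inf, 1.0)])

    def test_export_mirrors_incremental_table(self):
        df = build_frontier(
            [R("IFDP", 6611.2, 17.8), R("Implant", 8461.1, 19.1)]
        ).to_frame()
        assert list(df.columns) == [
            "strategy", "cost", "incr_cost", "effectiveness",
            "incr_effectiveness", "icer", "classification",
        ]
        row = df.set_index("strategy").loc["Implant"]
        assert row["icer"] == pytest.approx(1423.0, rel=1e-3)


def brute_force_classification(results):
    """Oracle: a strategy is on the frontier iff it attains the maximum net
    monetary benefit for some non-negative willingness to pay."""

    def dominated(r):
        return any(
            o.cost <= r.cost
            and o.effectiveness >= r.effectiveness
            and (o.cost < r.cost or o.effectiveness > r.effectiveness)
            for o in results
            if o is not r
        )

    # candidate thresholds: all pairwise ICERs plus extremes
    lambdas = {0.0, 1e12}
    for a, b in itertools.combinations(results, 2):
        de = a.effectiveness - b.effectiveness
        if de != 0:
            lam = (a.cost - b.cost) / de
            if lam >= 0:
                lambdas.add(lam)
    optimal = set()
    for lam in lambdas:
        nmbs = [lam * r.effectiveness - r.cost for r in results]
        best = max(nmbs)
        for r, v in zip(results, nmbs):
            # a vertex threshold can tie two frontier points; both count
            if v == best:
                optimal.add(r.strategy)
    out = {}
    for r in results:
        if dominated(r):
            out[r.strategy] = DOMINATED
        elif r.strategy in optimal:
            out[r.strategy] = UNDOMINATED
        else:
            out[r.strategy] = EXTENDED_DOMINATED
    return out


class TestAgainstBruteForce:
    def test_random_strategy_sets(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            n = int(rng.integers(1, 7))
            res = [
                R(
                    f"s{i}",
                    float(rng.integers(0, 40)),  # integer grids exercise ties
                    float(rng.integers(0, 12)),
                )
                for i in range(n)
            ]
            # skip exact (cost, eff) duplicates: the oracle cannot tell
            # equivalent twins apart
            key = {(r.cost, r.effectiveness) for r in res}
            if len(key) != len(res):
                continue
            got = build_frontier(res).classification
            expected = brute_force_classification(res)
            assert got == expected, (res, got, expected)

    def test_reference_model_frontier(self, reference_traces):
        rep = build_frontier([t.result for t in reference_traces.values()])
        expected = brute_force_classification(
            [t.result for t in reference_traces.values()]
        )
        assert rep.classification == expected
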