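import numpy as np
import pytest

from molarcea.config import HealthState, ModelSpec, load_model_spec
from molarcea.engine import (
    base_case,
    discount_factor,
    run_cohort,
    transition_matrix,
)
from molarcea.lifetable import LifeTable, LifeTableError


def flat_life_table(q, lo=50, hi=400):
    return LifeTable({a: q for a in range(lo, hi + 1)})


def two_state_spec(f, q, r, horizon, uA=0.9, uB=0.6, cA=1000.0, cB=300.0,
                   mA=50.0, mB=80.0):
    """A -> B -> (absorbing), plus death; used against a closed form."""
    states = {
        "A": HealthState("A", entry_cost=cA, maintenance_cost=mA, qol=uA,
                         annual_failure_rate=f,
                         failure_allocation=(("B", 1.0),)),
        "B": HealthState("B", entry_cost=cB, maintenance_cost=mB, qol=uB),
        "dead": HealthState("dead"),
    }
    return ModelSpec(
        states=states,
        strategies={"A": "A"},
        start_age=50,
        horizon=horizon,
        cycle_length=1.0,
        discount_rate=r,
        life_table=flat_life_table(q),
    )


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,cycle,expected",
        [(0.02, 0, 1.0), (0.0, 7, 1.0), (0.02, 1, 1 / 1.02)],
    )
    def test_values(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.02, -1)


class TestTransitionMatrix:
    def test_identity_without_death_or_failure(self):
        spec = two_state_spec(f=0.0, q=1e-300, r=0.0, horizon=5)
        M = transition_matrix(spec, 50)
        assert np.allclose(M, np.eye(3), atol=1e-12)

    def test_ifdp_row_hand_computed(self, reference_spec):
        # q(50)=0.0016, f=0.11, split 0.998/0.002 applied to survivors
        M = transition_matrix(reference_spec, 50)
        rm = reference_spec.resolve()
        i = rm.index("IFDP")
        assert M[i, rm.index("dead")] == pytest.approx(0.0016)
        assert M[i, rm.index("secondIFDP")] == pytest.approx(
            0.9984 * 0.11 * 0.998
        )
        assert M[i, rm.index("RPD")] == pytest.approx(0.9984 * 0.11 * 0.002)
        assert M[i, i] == pytest.approx(0.9984 * 0.89)

    def test_rows_stochastic_all_ages(self, reference_spec):
        for age in range(50, 80):
            M = transition_matrix(reference_spec, age)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(M >= 0)

    def test_dead_row_identity(self, reference_spec):
        rm = reference_spec.resolve()
        M = transition_matrix(reference_spec, 60)
        d = rm.dead_index
        assert M[d, d] == 1.0 and M[d].sum() == 1.0

    def test_age_outside_table_errors(self, reference_spec):
        with pytest.raises(LifeTableError):
            transition_matrix(reference_spec, 120)


def closed_form_two_state(f, q, r, T, uA, uB, cA, cB, mA, mB):
    """Geometric-series totals for the A -> B chain with constant mortality."""
    v = 1.0 / (1.0 + r)
    p = 1.0 - q
    s = p * (1.0 - f)

    def G(x):  # sum_{t=0}^{T-1} x^t
        return T if x == 1.0 else (1.0 - x**T) / (1.0 - x)

    eff = uA * G(s * v) + uB * (G(p * v) - G(s * v))
    cost = (
        cA
        + mB * (G(p * v) - G(s * v))
        + mA * G(s * v)
        + cB * p * f * v * G(s * v)
    )
    return cost, eff


class TestRunCohort:
    def test_conservation_and_dead_monotone(self, reference_traces):
        for tr in reference_traces.values():
            sums = tr.occupancy.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)
            assert np.all((tr.occupancy >= -1e-15) & (tr.occupancy <= 1 + 1e-15))
            dead = tr.occupancy[:, tr.state_names.index("dead")]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_totals_within_domain(self, reference_spec, reference_traces):
        for tr in reference_traces.values():
            assert tr.total_cost >= 0
            assert 0 <= tr.total_effect <= reference_spec.horizon

    def test_degenerate_closed_form(self, reference_spec):
        # no failures, (almost) no deaths, no discounting: totals collapse
        # to horizon * per-cycle accrual plus the initial treatment
        doc = reference_spec.to_dict()
        for st in doc["states"].values():
            st["annual_failure_rate"] = 0.0
            st["failure_allocation"] = {}
        doc["settings"]["discount_rate"] = 0.0
        doc["life_table"] = {
            "kind": "table",
            "q": {a: 1e-15 for a in range(50, 81)},
        }
        spec = load_model_spec(doc)
        tr = run_cohort(spec, "IFDP")
        assert tr.total_effect == pytest.approx(30 * 0.83, abs=1e-9)
        assert tr.total_cost == pytest.approx(420 + 30 * 261.8, abs=1e-6)

    @pytest.mark.parametrize("f,q,r", [(0.11, 0.01, 0.02), (0.3, 0.05, 0.0),
                                       (0.0, 0.002, 0.05)])
    def test_two_state_oracle(self, f, q, r):
        args = dict(uA=0.9, uB=0.6, cA=1000.0, cB=300.0, mA=50.0, mB=80.0)
        spec = two_state_spec(f, q, r, horizon=30, **args)
        tr = run_cohort(spec, "A")
        cost, eff = closed_form_two_state(f, q, r, 30, **args)
        assert tr.total_cost == pytest.approx(cost, abs=1e-10 * max(1, cost))
        assert tr.total_effect == pytest.approx(eff, abs=1e-10 * max(1, eff))

    def test_higher_failure_rate_lowers_effectiveness(self, reference_spec):
        base = run_cohort(reference_spec, "IFDP").total_effect
        doc = reference_spec.to_dict()
        doc["states"]["IFDP"]["annual_failure_rate"] = 0.25
        worse = run_cohort(load_model_spec(doc), "IFDP").total_effect
        assert worse < base

    def test_zero_discount_raises_totals(self, reference_spec):
        undiscounted = reference_spec.with_settings(discount_rate=0.0)
        for name in reference_spec.strategies:
            a = run_cohort(reference_spec, name)
            b = run_cohort(undiscounted, name)
            assert b.total_cost >= a.total_cost
            assert b.total_effect >= a.total_effect

    def test_death_absorbs_in_the_long_run(self):
        spec = two_state_spec(f=0.1, q=0.05, r=0.0, horizon=300)
        tr = run_cohort(spec, "A")
        assert tr.occupancy[-1, tr.state_names.index("dead")] > 0.999

    def test_unknown_strategy_rejected(self, reference_spec):
        with pytest.raises(ValueError, match="unknown strategy"):
            run_cohort(reference_spec, "Dentures")

    def test_half_cycle_correction_reweights_boundary_cycles(
        self, reference_spec
    ):
        std = run_cohort(reference_spec, "IFDP")
        hcc = run_cohort(
            reference_spec.with_settings(half_cycle_correction=True), "IFDP"
        )
        rm = reference_spec.resolve()
        v_T = (1 + reference_spec.discount_rate) ** (-reference_spec.horizon)
        eff0 = std.occupancy[0] @ rm.qol
        effT = std.occupancy[-1] @ rm.qol * v_T
        expected = std.total_effect - 0.5 * eff0 + 0.5 * effT
        assert hcc.total_effect == pytest.approx(expected, rel=1e-12)

    def test_failure_cycle_utility_mode_lowers_effect(self, reference_spec):
        on = reference_spec.with_settings(use_failure_qol=True)
        for name in ("Implant", "IFDP"):
            assert (
                run_cohort(on, name).total_effect
                < run_cohort(reference_spec, name).total_effect
            )

    def test_trace_export_schema(self, reference_traces):
        df = reference_traces["IFDP"].to_frame()
        assert list(df.columns) == [
            "cycle", "age", "state", "occupancy", "disc_cost", "disc_effect",
        ]
        assert df["cycle"].max() == 30
        assert df["age"].min() == 50
        # occupancy shares per cycle sum to one
        assert np.allclose(df.groupby("cycle")["occupancy"].sum(), 1.0)


class TestBaseCase:
    def test_runs_all_strategies(self, reference_spec, reference_traces):
        assert set(reference_traces) == set(reference_spec.strategies)
        for name, tr in reference_traces.items():
            assert tr.result.strategy == name
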