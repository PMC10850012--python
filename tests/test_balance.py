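"""Flow accounting, the mass-balance solver and the audit."""

import numpy as np
import pytest

from pondweb import (
    BalanceError, CONSUMER, DETRITUS, PRODUCER, EcopathModel, Group,
    WebSpec, blank_ee, compute_flows, generate_web, solve_missing,
)


def chain_model(prey_ee=None, catch=0.0):
    """Producer fully eaten by one consumer; detritus closes the loop."""
    groups = [
        Group(name="algae", category=PRODUCER, biomass=10.0, pb=5.0,
              qb=0.0, ee=prey_ee, detritus_fate={"pool": 1.0}),
        Group(name="snail", category=CONSUMER, biomass=5.0, pb=2.0,
              qb=10.0, ee=0.4, gs=0.3, catch=4.0,
              detritus_fate={"pool": 1.0}),
        Group(name="pool", category=DETRITUS, biomass=1.0, pb=0.0, qb=0.0),
    ]
    diet = np.zeros((3, 3))
    diet[1, 0] = 1.0
    groups[0].catch = catch
    return EcopathModel(groups, diet, 300, "chain")


class TestComputeFlows:
    def test_chain_accounts(self):
        flows = compute_flows(chain_model(prey_ee=1.0))
        # snail: Q = 50, U = 15, P = 10, R = 25
        assert flows.Q[1] == pytest.approx(50.0)
        assert flows.U[1] == pytest.approx(15.0)
        assert flows.P[1] == pytest.approx(10.0)
        assert flows.R[1] == pytest.approx(25.0)
        assert flows.M2[0] == pytest.approx(50.0)
        # snail FD = U + P(1-EE) = 15 + 6
        assert flows.FD[1] == pytest.approx(21.0)

    def test_zero_respiration_limit(self):
        # gs = 0 and P = Q leaves nothing to respire
        model = chain_model(prey_ee=1.0)
        g = model.group("snail")
        g.gs, g.pb = 0.0, 10.0
        flows = compute_flows(model)
        assert flows.R[1] == pytest.approx(0.0)

    def test_consumption_conservation(self, mono_balanced, poly_balanced):
        for b in (mono_balanced, poly_balanced):
            f = b.flows
            total = (f.P + f.R + f.U)[b.model.mask(CONSUMER)].sum()
            assert f.Q.sum() == pytest.approx(total, rel=1e-9)

    def test_flow_matrix_columns_equal_consumption(self, mono_balanced):
        f = mono_balanced.flows
        np.testing.assert_allclose(f.flow_matrix.sum(axis=0), f.Q,
                                   rtol=1e-12)

    def test_published_detritus_flows(self, mono_balanced):
        f = mono_balanced.flows
        model = mono_balanced.model
        assert f.FD[model.index("C. idellus")] == pytest.approx(
            640.6955, rel=0.005)
        assert f.FD[model.index("Precipitation")] == pytest.approx(
            2.9792, rel=0.01)

    def test_unknowns_rejected(self, mono_model):
        with pytest.raises(BalanceError, match="unknown"):
            compute_flows(blank_ee(mono_model))


class TestSolveMissing:
    def test_full_utilization_gives_unit_ee(self):
        model = chain_model(prey_ee=None)
        balanced = solve_missing(model)
        assert balanced.model.group("algae").ee == pytest.approx(1.0)

    def test_published_consumer_and_import_ees(self, mono_balanced):
        ee = {g.name: g.ee for g in mono_balanced.model.groups}
        assert ee["Rotifera"] == pytest.approx(0.947, rel=0.01)
        assert ee["Feed"] == pytest.approx(0.941, rel=0.01)
        assert ee["Precipitation"] == pytest.approx(0.523, rel=0.01)

    def test_planted_ee_recovery(self):
        model, truth = generate_web(WebSpec(n_producers=2, n_consumers=5,
                                            n_detritus=2, seed=1))
        balanced = solve_missing(blank_ee(model))
        got = np.array([g.ee for g in balanced.model.groups
                        if g.is_living])
        want = truth.ee[[i for i, g in enumerate(model.groups)
                         if g.is_living]]
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_brute_force_oracle_small_webs(self):
        """EE from the linear solve equals explicit-loop flow summation."""
        for seed in range(8):
            model, _ = generate_web(WebSpec(n_producers=1, n_consumers=3,
                                            n_detritus=1, import_groups=1,
                                            seed=seed))
            balanced = solve_missing(blank_ee(model))
            for i, g in enumerate(model.groups):
                if not g.is_living:
                    continue
                m2 = 0.0
                for j, pred in enumerate(model.groups):
                    if pred.category == CONSUMER:
                        m2 += pred.biomass * pred.qb * model.diet[j, i]
                expected = (m2 + g.catch + g.migration + g.ba) / (
                    g.biomass * g.pb)
                assert balanced.model.groups[i].ee == pytest.approx(
                    expected, rel=1e-9), g.name

    def test_self_consistency_on_balanced_web(self):
        model, _ = generate_web(WebSpec(seed=5))
        first = solve_missing(blank_ee(model))
        again = solve_missing(blank_ee(first.model))
        for g1, g2 in zip(first.model.groups, again.model.groups):
            assert g1.ee == pytest.approx(g2.ee, rel=1e-9)

    def test_unknown_biomass_coupling(self):
        """A blanked prey biomass propagates through predator equations."""
        model, _ = generate_web(WebSpec(n_producers=2, n_consumers=4,
                                        n_detritus=2, seed=11))
        target = next(g for g in model.groups
                      if g.category == CONSUMER)
        truth_b = target.biomass
        unknown = blank_ee(model)
        g = unknown.group(target.name)
        g.ee = target.ee          # known EE instead ...
        g.biomass = None          # ... of known biomass
        balanced = solve_missing(unknown)
        assert balanced.model.group(target.name).biomass == pytest.approx(
            truth_b, rel=1e-9)

    def test_unknown_pb_recovered(self):
        model, _ = generate_web(WebSpec(seed=3))
        target = next(g for g in model.groups if g.category == CONSUMER)
        truth = target.pb
        unknown = model.copy()
        unknown.group(target.name).pb = None
        balanced = solve_missing(unknown)
        assert balanced.model.group(target.name).pb == pytest.approx(
            truth, rel=1e-9)

    def test_unknown_qb_needs_cannibalism(self):
        """Q/B never enters its own master equation, so without a loop the
        system is singular; with cannibalism it is identified."""
        groups = [
            Group(name="algae", category=PRODUCER, biomass=10.0, pb=2.0,
                  qb=0.0, ee=None, detritus_fate={"pool": 1.0}),
            Group(name="crab", category=CONSUMER, biomass=2.0, pb=4.0,
                  qb=None, ee=0.75, gs=0.2, catch=2.0,
                  detritus_fate={"pool": 1.0}),
            Group(name="pool", category=DETRITUS, biomass=1.0, pb=0.0,
                  qb=0.0),
        ]
        diet = np.zeros((3, 3))
        diet[1, 0], diet[1, 1] = 0.8, 0.2
        balanced = solve_missing(EcopathModel(groups, diet, 300, "loop"))
        assert balanced.model.group("crab").qb == pytest.approx(10.0)
        assert balanced.model.group("algae").ee == pytest.approx(0.8)

        diet2 = np.zeros((3, 3))
        diet2[1, 0] = 1.0
        with pytest.raises(BalanceError, match="singular"):
            solve_missing(EcopathModel(groups, diet2, 300, "noloop"))

    def test_zero_production_with_demand_is_singular(self):
        model = chain_model(prey_ee=None)
        model.group("algae").pb = 0.0
        with pytest.raises(BalanceError, match="singular"):
            solve_missing(model)

    def test_monotonicity_in_predator_pressure(self, mono_model):
        """Raising a predator's Q/B weakly raises every prey EE."""
        base = solve_missing(blank_ee(mono_model))
        bumped_model = blank_ee(mono_model)
        bumped_model.group("C. idellus").qb *= 1.1
        bumped = solve_missing(bumped_model)
        for g0, g1 in zip(base.model.groups, bumped.model.groups):
            if g0.is_living:
                assert g1.ee >= g0.ee - 1e-12, g0.name


class TestDetritusBudget:
    def test_published_pool_budgets(self, mono_balanced):
        budgets = mono_balanced.detritus_budget
        assert budgets["Precipitation"].ee == pytest.approx(0.523, rel=0.01)
        assert budgets["Feed"].surplus == pytest.approx(94.851, rel=0.01)

    def test_unconsumed_pool(self):
        model = chain_model(prey_ee=1.0)
        budget = compute_flows(model).budgets["pool"]
        assert budget.ee == 0.0
        assert budget.surplus == pytest.approx(budget.inflow)

    def test_sediment_surplus_accumulates(self, mono_balanced):
        ds = mono_balanced.detritus_budget["Detritus (sediment)"]
        assert ds.accumulation == pytest.approx(ds.surplus)
        assert ds.export == 0.0


class TestAudit:
    def test_fixtures_pass_hard_checks(self, mono_balanced, poly_balanced):
        for b in (mono_balanced, poly_balanced):
            hard = [d for d in b.audit if d.rule in
                    ("ee-above-one", "negative-respiration",
                     "detritus-overdrawn")]
            assert hard == []

    def test_inflated_production_flags_negative_respiration(self, mono_model):
        model = blank_ee(mono_model)
        model.group("C. idellus").pb *= 3.0
        diags = solve_missing(model).audit
        assert any(d.rule == "negative-respiration"
                   and d.group == "C. idellus" for d in diags)

    def test_halved_prey_biomass_flags_ee(self, mono_model):
        model = blank_ee(mono_model)
        model.group("Rotifera").biomass *= 0.5
        diags = solve_missing(model).audit
        assert any(d.rule == "ee-above-one" and d.group == "Rotifera"
                   for d in diags)

    def test_synthetic_webs_balance_to_tolerance(self):
        for seed in range(5):
            model, _ = generate_web(WebSpec(seed=seed))
            balanced = solve_missing(blank_ee(model))
            residuals = [d for d in balanced.audit if d.rule == "residual"]
            assert residuals == []
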