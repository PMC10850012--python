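"""Mass-balance computation: flow accounting, the per-group master
equation, detritus budgets and balance auditing.

Every living group *i* obeys, over the modelling period,

    B_i (P/B)_i EE_i = sum_j B_j (Q/B)_j DC_ji + Y_i + E_i + BA_i

i.e. production used in the system equals predation on the group plus
catches, net migration and biomass accumulation.  Consumption splits as
Q = P + R + U with respiration R >= 0 and egestion U = GS * Q.  Egestion
plus non-predation mortality P (1 - EE) flow to the detritus pools
according to each group's fate vector; detritus pools in turn pass any
surplus downstream, export it, or let it accumulate in the sediment.

:func:`solve_missing` assembles the master equations of all groups that
carry one unknown parameter into a single linear system and solves it
in one shot, which handles the coupling that arises when the unknown
biomass of a prey appears inside another group's predation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CONSUMER, DETRITUS, PRODUCER, SURPLUS_ACCUMULATION,
    EcopathModel, ModelError, validate,
)

RESIDUAL_RTOL = 1e-6  # |residual| <= RESIDUAL_RTOL * max(P_i, 1) counts as balanced


class BalanceError(ModelError):
    """Raised when the mass-balance system cannot be solved."""


@dataclass
class DetritusBudget:
    """Inflow/outflow accounting of one detritus pool (g m^-2 per period)."""

    inflow: float           # imports + routed flows to detritus + upstream surplus
    consumption_outflow: float
    surplus: float          # inflow - consumption
    routed: float           # surplus passed to downstream detritus pools
    export: float           # unrouted surplus leaving the system
    accumulation: float     # unrouted surplus retained (e.g. sediment build-up)
    ee: float               # consumption_outflow / inflow


@dataclass
class FlowAccounts:
    """Per-group flows plus the prey-to-predator flow matrix.

    ``FD`` holds, for living groups, egestion plus other mortality
    (Q*GS + P*(1-EE)); for a detritus group it holds the part of its
    surplus actually passed on to other detritus pools, so that
    ``FD.sum()`` is the total flow into detritus excluding raw imports.
    """

    Q: np.ndarray
    P: np.ndarray
    R: np.ndarray
    U: np.ndarray
    FD: np.ndarray
    M2: np.ndarray
    flow_matrix: np.ndarray          # [prey, predator] consumption flows
    detritus_flow: np.ndarray        # [source, detritus pool] routed flows
    export: np.ndarray               # per-group unrouted detritus/surplus export
    accumulation: np.ndarray         # per-group retained surplus
    budgets: dict[str, DetritusBudget] = field(default_factory=dict)


@dataclass
class Diagnostic:
    group: str
    rule: str
    value: float
    message: str


@dataclass
class BalancedModel:
    """A fully resolved model together with its flows and audit trail."""

    model: EcopathModel
    flows: FlowAccounts
    audit: list[Diagnostic] = field(default_factory=list)

    @property
    def detritus_budget(self) -> dict[str, DetritusBudget]:
        return self.flows.budgets


def _detritus_order(model: EcopathModel) -> list[int]:
    """Topological order of detritus pools along surplus-routing links."""
    det = [i for i, g in enumerate(model.groups) if g.category == DETRITUS]
    names = model.names
    succ = {i: [model.index(d) for d in model.groups[i].detritus_fate
                if model.groups[i].detritus_fate[d] > 0] for i in det}
    order: list[int] = []
    state: dict[int, int] = {}

    def visit(i: int) -> None:
        if state.get(i) == 2:
            return
        if state.get(i) == 1:
            raise BalanceError(
                f"cyclic surplus routing among detritus groups near "
                f"{names[i]!r}")
        state[i] = 1
        for j in succ[i]:
            visit(j)
        state[i] = 2
        order.append(i)

    for i in det:
        visit(i)
    order.reverse()  # sources first
    return order


def compute_flows(model: EcopathModel) -> FlowAccounts:
    """Flow accounting for a model with all parameters known.

    Computes consumption, production, respiration, egestion, predation
    mortality and flows to detritus, then settles the detritus budgets
    in routing order.  A negative respiration is recorded in the
    accounts (the audit flags it) rather than raised.
    """
    n = model.n
    B = model.param("biomass")
    pb = model.param("pb")
    qb = model.param("qb")
    ee = model.param("ee")
    gs = model.param("gs")
    consumer = model.mask(CONSUMER)
    living = model.living
    if (np.isnan(B[living]).any() or np.isnan(pb[living]).any()
            or np.isnan(qb[consumer]).any() or np.isnan(ee[living]).any()):
        raise BalanceError("model still contains unknown parameters; "
                           "run solve_missing first")
    B = np.nan_to_num(B)
    pb = np.nan_to_num(pb)
    qb = np.nan_to_num(qb)

    Q = np.where(consumer, B * qb, 0.0)
    P = np.where(living, B * pb, 0.0)
    U = Q * gs
    R = np.where(consumer, Q - P - U, 0.0)
    flow_matrix = (model.diet * Q[:, None]).T  # [prey, pred]
    M2 = flow_matrix.sum(axis=1)

    FD = np.zeros(n)
    FD[living] = U[living] + P[living] * (1.0 - ee[living])

    fate = model.fate_matrix()
    detritus_flow = np.zeros((n, n))
    export = np.zeros(n)
    accumulation = np.zeros(n)
    detritus_flow[living] = FD[living, None] * fate[living]
    export[living] = FD[living] * np.clip(1.0 - fate[living].sum(axis=1), 0.0, None)

    budgets: dict[str, DetritusBudget] = {}
    imports = model.param("imports", fill=0.0)
    for d in _detritus_order(model):
        g = model.groups[d]
        inflow = imports[d] + detritus_flow[:, d].sum()
        consumption = M2[d]
        surplus = inflow - consumption
        routed = 0.0
        if surplus > 0:
            detritus_flow[d] = surplus * fate[d]
            routed = detritus_flow[d].sum()
            rest = surplus - routed
            if g.surplus_disposition == SURPLUS_ACCUMULATION:
                accumulation[d] = rest
            else:
                export[d] = rest
        FD[d] = routed
        budgets[g.name] = DetritusBudget(
            inflow=inflow, consumption_outflow=consumption,
            surplus=surplus, routed=routed, export=export[d],
            accumulation=accumulation[d],
            ee=consumption / inflow if inflow > 0 else 0.0)

    return FlowAccounts(Q=Q, P=P, R=R, U=U, FD=FD, M2=M2,
                        flow_matrix=flow_matrix,
                        detritus_flow=detritus_flow, export=export,
                        accumulation=accumulation, budgets=budgets)


def solve_missing(model: EcopathModel) -> BalancedModel:
    """Resolve the unknown parameters and return a balanced model.

    Each living group may leave one of {B, P/B, Q/B, EE} unknown.  The
    master equations of those groups are linear in the unknowns (every
    product B*(P/B)*EE or B*(Q/B)*DC contains at most one), so they are
    assembled into a single linear system and solved simultaneously.
    Detritus-group EE values are always recomputed from the pool
    budgets.
    """
    validate(model).raise_if_failed()
    resolved = model.copy()
    groups = resolved.groups
    diet = resolved.diet
    unknown_of = {i: g.unknowns()[0]
                  for i, g in enumerate(groups)
                  if g.is_living and g.unknowns()}

    if unknown_of:
        idx = {i: k for k, i in enumerate(sorted(unknown_of))}
        m = len(idx)
        A = np.zeros((m, m))
        b = np.zeros(m)
        for i, row in idx.items():
            gi = groups[i]
            drive = (gi.catch + gi.migration + gi.ba)
            # production term  B_i * pb_i * ee_i
            parts = {"biomass": gi.biomass, "pb": gi.pb, "ee": gi.ee}
            if unknown_of[i] in parts:
                coeff = 1.0
                for p, v in parts.items():
                    if p != unknown_of[i]:
                        coeff *= v
                A[row, idx[i]] += coeff
            else:  # qb unknown: production fully known
                b[row] -= gi.biomass * gi.pb * gi.ee
            # predation term  sum_j B_j qb_j DC_ji
            for j, gj in enumerate(groups):
                if gj.category != CONSUMER or diet[j, i] == 0.0:
                    continue
                if j in unknown_of and unknown_of[j] == "biomass":
                    A[row, idx[j]] -= gj.qb * diet[j, i]
                elif j in unknown_of and unknown_of[j] == "qb":
                    A[row, idx[j]] -= gj.biomass * diet[j, i]
                else:
                    drive += gj.biomass * gj.qb * diet[j, i]
            b[row] += drive
        if np.linalg.matrix_rank(A) < m:
            dependent = [groups[i].name for i, row in idx.items()
                         if not A[row].any() or not A[:, idx[i]].any()]
            detail = (f" (zero pivot for {dependent}; e.g. zero production "
                      f"facing nonzero demand)" if dependent else "")
            raise BalanceError(
                "singular mass-balance system for unknowns of groups "
                f"{[groups[i].name for i in idx]}{detail}")
        x = np.linalg.solve(A, b)
        for i, row in idx.items():
            setattr(groups[i], unknown_of[i], float(x[row]))

    flows = compute_flows(resolved)
    for name, budget in flows.budgets.items():
        resolved.group(name).ee = budget.ee
    balanced = BalancedModel(model=resolved, flows=flows)
    balanced.audit = audit(balanced)
    return balanced


def audit(balanced: BalancedModel) -> list[Diagnostic]:
    """List every EE > 1, negative respiration, overdrawn detritus pool
    and per-group master-equation residual.  Report-only."""
    model, flows = balanced.model, balanced.flows
    out: list[Diagnostic] = []
    for i, g in enumerate(model.groups):
        if g.is_living and g.ee is not None and g.ee > 1.0 + 1e-9:
            out.append(Diagnostic(g.name, "ee-above-one", g.ee,
                                  f"EE = {g.ee:.4f} exceeds 1"))
        if g.category == CONSUMER and flows.R[i] < -1e-9:
            out.append(Diagnostic(g.name, "negative-respiration", flows.R[i],
                                  f"R = {flows.R[i]:.4f} < 0"))
        if g.is_living:
            residual = (flows.P[i] * g.ee - flows.M2[i]
                        - g.catch - g.migration - g.ba)
            if abs(residual) > RESIDUAL_RTOL * max(flows.P[i], 1.0):
                out.append(Diagnostic(
                    g.name, "residual", residual,
                    f"balance residual {residual:.6g} "
                    f"({residual / max(flows.P[i], 1e-300):.3%} of P)"))
    for name, budget in flows.budgets.items():
        if budget.surplus < -1e-9:
            out.append(Diagnostic(name, "detritus-overdrawn", budget.surplus,
                                  "detritus consumption exceeds inflow"))
    return out
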