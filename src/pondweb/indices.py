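"""Whole-system network statistics: throughput totals, the Lindeman
spine with per-level transfer efficiencies, Finn's cycling index and
the information-theoretic indices (ascendency, overhead, capacity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .balance import BalancedModel, BalanceError
from .model import DETRITUS, PRODUCER
from .trophic import level_fractions, trophic_levels


@dataclass
class SummaryStatistics:
    """System totals in g m^-2 per period plus dimensionless ratios."""

    tc: float   # sum of all consumption
    tae: float  # sum of all exports (catches, net migration, unrouted surplus)
    tr: float   # sum of all respiratory flows
    td: float   # sum of all flows into detritus, imports included
    tst: float  # total system throughput = tc + tae + tr + td
    tp: float   # total production of living groups
    tpp: float  # total net primary production
    nsp: float  # net system production, tpp - tr
    tb: float   # total biomass excluding detritus
    accumulation: float  # retained detritus surplus (outside the throughput)
    tpp_tr: float
    tpp_tb: float
    tb_tst: float
    detritus_origin_fraction: float
    producer_origin_fraction: float


def summary_statistics(balanced: BalancedModel) -> SummaryStatistics:
    model, flows = balanced.model, balanced.flows
    producers = model.mask(PRODUCER)
    living = model.living
    imports = model.param("imports", fill=0.0)
    Y = model.param("catch", fill=0.0)
    E = model.param("migration", fill=0.0)

    tc = float(flows.Q.sum())
    tr = float(flows.R.sum())
    # flows actually reaching a pool; unrouted shares count as export below
    td = float(flows.detritus_flow.sum() + imports.sum())
    tae = float(Y.sum() + E.sum() + flows.export.sum())
    tst = tc + tae + tr + td
    tp = float(flows.P[living].sum())
    tpp = float(flows.P[producers].sum())
    tb = float(np.nan_to_num(model.param("biomass"))[living].sum())

    det_inflow = sum(b.inflow for b in flows.budgets.values())
    base = tpp + det_inflow
    det_frac = det_inflow / base if base > 0 else 0.0
    return SummaryStatistics(
        tc=tc, tae=tae, tr=tr, td=td, tst=tst, tp=tp, tpp=tpp,
        nsp=tpp - tr, tb=tb, accumulation=float(flows.accumulation.sum()),
        tpp_tr=tpp / tr if tr else math.inf,
        tpp_tb=tpp / tb if tb else math.inf,
        tb_tst=tb / tst if tst else 0.0,
        detritus_origin_fraction=det_frac,
        producer_origin_fraction=1.0 - det_frac,
    )


@dataclass
class SpineLevel:
    level: int
    throughput: float
    flow_up: float       # consumption taken from this level by the next
    export: float        # catches + net migration (+ detritus export at I)
    respiration: float
    to_detritus: float
    accumulation: float
    te: float | None     # (flow_up + export) / throughput


@dataclass
class TrophicSpine:
    """Flows aggregated onto integer trophic levels.

    Detritus pools are pooled with the producers into level I for
    reporting; ``producer_throughput`` and ``detritus_throughput`` give
    the split of that box.  ``te`` per level is the fraction of the
    level's throughput passed upward or exported/caught; ``mean_te`` is
    the geometric mean over levels II-IV.
    """

    levels: list[SpineLevel] = field(default_factory=list)
    producer_throughput: float = 0.0
    detritus_throughput: float = 0.0
    mean_te: float = 0.0

    def te_by_level(self) -> dict[int, float]:
        return {lv.level: lv.te for lv in self.levels if lv.te is not None}


def lindeman_spine(balanced: BalancedModel,
                   tls: np.ndarray | None = None,
                   max_level: int = 8) -> TrophicSpine:
    """Apportion every group's flows over integer trophic levels.

    Each consumer's activity is split across levels by the fractional
    composition implied by its diet (computed recursively down to the
    level-1 groups), so its consumption, respiration, exports and flows
    to detritus are distributed with the same weights.  Level I holds
    net primary production together with the detritus-pool inflows.
    """
    model, flows = balanced.model, balanced.flows
    F = level_fractions(model, max_level=max_level)
    Y = model.param("catch", fill=0.0)
    E = model.param("migration", fill=0.0)
    det = model.mask(DETRITUS)
    producers = model.mask(PRODUCER)

    tpp = float(flows.P[producers].sum())
    det_inflow = sum(b.inflow for b in flows.budgets.values())

    levels: list[SpineLevel] = []
    for k in range(max_level):
        w = F[:, k]
        BA = model.param("ba", fill=0.0)
        if k == 0:
            throughput = tpp + det_inflow
            flow_up = float((flows.M2 * w).sum())
            export = float(((Y + E) * w)[producers].sum()
                           + flows.export[det].sum())
            respiration = 0.0
            # producer FD plus detritus surplus routed between pools
            to_det = float((flows.FD * w)[producers].sum()
                           + flows.FD[det].sum())
            accum = float(flows.accumulation[det].sum())
        else:
            throughput = float((flows.Q * w).sum())
            flow_up = float((flows.M2 * w).sum())
            export = float(((Y + E) * w)[model.living].sum())
            respiration = float((flows.R * w).sum())
            to_det = float((flows.FD * w)[model.living].sum())
            accum = float((BA * w)[model.living].sum())
        if throughput <= 0 and k > 0:
            continue
        te = (flow_up + export) / throughput if throughput > 0 else None
        levels.append(SpineLevel(level=k + 1, throughput=throughput,
                                 flow_up=flow_up, export=export,
                                 respiration=respiration,
                                 to_detritus=to_det, accumulation=accum,
                                 te=te))
    tes = [lv.te for lv in levels if lv.level in (2, 3, 4) and lv.te]
    mean_te = float(np.exp(np.mean(np.log(tes)))) if tes else 0.0
    return TrophicSpine(levels=levels, producer_throughput=tpp,
                        detritus_throughput=det_inflow, mean_te=mean_te)


# ---------------------------------------------------------------------------
# cycling

def _network_arrays(balanced: BalancedModel) -> tuple[np.ndarray, np.ndarray]:
    """Internal flow matrix (consumption + detritus routing) and the
    per-compartment throughflow (total inflow including outside input)."""
    model, flows = balanced.model, balanced.flows
    internal = flows.flow_matrix + flows.detritus_flow
    inflow = np.array([
        flows.budgets[g.name].inflow if g.category == DETRITUS
        else (flows.P[i] if g.category == PRODUCER else flows.Q[i])
        for i, g in enumerate(model.groups)])
    return internal, inflow


def cycled_throughflow(flow_matrix: np.ndarray,
                       throughflow: np.ndarray) -> float:
    """Finn's cycled throughflow for an arbitrary flow network.

    ``flow_matrix[i, j]`` is the flow from compartment i to j and
    ``throughflow[j]`` each compartment's total inflow (internal flows
    plus boundary inputs).  Uses the diagonal of the inverse structure
    matrix: Tc = sum_j T_j (N_jj - 1) / N_jj.
    """
    T = np.asarray(throughflow, dtype=float)
    n = T.size
    G = np.zeros((n, n))
    nz = T > 0
    G[:, nz] = flow_matrix[:, nz] / T[nz]
    try:
        N = np.linalg.inv(np.eye(n) - G)
    except np.linalg.LinAlgError as exc:
        raise BalanceError("absorbing cycle: the flow-fraction matrix has a "
                           "unit eigenvalue") from exc
    diag = np.diag(N)
    if np.any(diag <= 0):
        raise BalanceError("absorbing cycle: non-positive structure diagonal")
    return float((T * (diag - 1.0) / diag).sum())


def finn_cycling_index(balanced: BalancedModel) -> float:
    """Percentage of the total system throughput that is recycled."""
    internal, inflow = _network_arrays(balanced)
    tc = cycled_throughflow(internal, inflow)
    tst = summary_statistics(balanced).tst
    return 100.0 * tc / tst if tst > 0 else 0.0


# ---------------------------------------------------------------------------
# information indices

@dataclass
class CyclingAndInformation:
    ascendency: float
    overhead: float
    capacity: float

    @property
    def a_tdc(self) -> float:
        return self.ascendency / self.capacity if self.capacity else 0.0

    @property
    def o_tdc(self) -> float:
        return self.overhead / self.capacity if self.capacity else 0.0


def extended_flow_matrix(balanced: BalancedModel) -> np.ndarray:
    """``(n+3, n+3)`` flow matrix with boundary compartments: row ``n``
    imports, column ``n+1`` exports (catches, migration, unrouted
    surplus and accumulation), column ``n+2`` respiration."""
    model, flows = balanced.model, balanced.flows
    n = model.n
    internal, _ = _network_arrays(balanced)
    T = np.zeros((n + 3, n + 3))
    T[:n, :n] = internal
    T[n, :n] = model.param("imports", fill=0.0)
    Y = model.param("catch", fill=0.0)
    E = model.param("migration", fill=0.0)
    T[:n, n + 1] = Y + E + flows.export + flows.accumulation
    T[:n, n + 2] = flows.R
    return T


def information_indices(balanced: BalancedModel) -> CyclingAndInformation:
    """Ascendency, overhead and development capacity (flowbits).

    Computed on the boundary-extended flow matrix with base-2
    logarithms:  A = sum T_ij log2(T_ij T.. / (T_i. T._j)),
    C = -sum T_ij log2(T_ij / T..), O = C - A.  Zero flows contribute
    zero; all flows scale the three indices linearly.
    """
    return information_from_flows(extended_flow_matrix(balanced))


def information_from_flows(T: np.ndarray) -> CyclingAndInformation:
    """The information indices of an arbitrary flow matrix (see
    :func:`information_indices` for the formulas)."""
    T = np.asarray(T, dtype=float)
    total = T.sum()
    if total <= 0:
        return CyclingAndInformation(0.0, 0.0, 0.0)
    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    nz = T > 0
    i, j = np.nonzero(nz)
    t = T[nz]
    a = float((t * np.log2(t * total / (rows[i] * cols[j]))).sum())
    c = float(-(t * np.log2(t / total)).sum())
    return CyclingAndInformation(ascendency=a, overhead=c - a, capacity=c)


def spine_level_balance(balanced: BalancedModel,
                        spine: TrophicSpine) -> list[float]:
    """Relative imbalance per consumer level: inflow minus all outflows
    (flow up, exports, respiration, detritus flow) over inflow."""
    out = []
    for lv in spine.levels:
        if lv.level == 1 or lv.throughput <= 0:
            continue
        res = lv.throughput - (lv.flow_up + lv.export + lv.respiration
                               + lv.to_detritus + lv.accumulation)
        out.append(res / lv.throughput)
    return out
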