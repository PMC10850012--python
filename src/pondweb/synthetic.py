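"""Random, exactly balanced synthetic food webs with known ground truth.

The generator mirrors the structure of small aquaculture-pond webs:
import-fed detritus groups (feed-like pools), one or more internal
detritus pools, optional bacterial loops feeding ~95 % on a detritus
pool, producers, and a consumer guild.  Construction goes flows-first:
diets and consumption are fixed, then biomasses, rates, catches and
imports are back-derived so that every living group's ecotrophic
efficiency equals a planted value in [0.05, 0.95] and respiration is
strictly positive — no rejection sampling, exact ground truth, fully
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CONSUMER, DETRITUS, PRODUCER, SURPLUS_EXPORT,
    EcopathModel, Group, ModelError,
)

_DEFAULT_GS = {CONSUMER: (0.2, 0.65), PRODUCER: (0.0, 0.0)}


@dataclass
class WebSpec:
    """Shape parameters of a synthetic web.

    ``import_groups`` feed-like pools (detritus category, nonzero
    import) are appended after ``n_detritus`` internal pools.
    ``diet_concentration`` is the Dirichlet shape for diet draws
    (small values give concentrated diets).  ``bacterial_loops``
    dedicates the first consumers to a 95 % detritus diet, one per
    internal pool, emulating the water/sediment bacteria of pond webs.
    """

    n_producers: int = 2
    n_consumers: int = 6
    n_detritus: int = 2
    import_groups: int = 1
    diet_concentration: float = 1.0
    bacterial_loops: bool = True
    gs_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GS))
    seed: int = 0


@dataclass
class GroundTruth:
    """Quantities known exactly from the construction."""

    ee: np.ndarray             # planted EE per group (detritus: implied)
    flow_matrix: np.ndarray    # [prey, predator] consumption flows
    trophic_levels: np.ndarray


def generate_web(spec: WebSpec) -> tuple[EcopathModel, GroundTruth]:
    """Build a balanced web and its ground truth; deterministic per seed."""
    if spec.n_producers < 1 or spec.n_detritus < 1:
        raise ModelError("a web needs at least one producer and one "
                         "internal detritus pool")
    if spec.n_consumers < 0 or spec.import_groups < 0:
        raise ModelError("negative group counts are not meaningful")
    rng = np.random.default_rng(spec.seed)

    producers = [f"producer_{k + 1}" for k in range(spec.n_producers)]
    consumers = [f"consumer_{k + 1}" for k in range(spec.n_consumers)]
    pools = [f"detritus_{k + 1}" for k in range(spec.n_detritus)]
    feeds = [f"import_{k + 1}" for k in range(spec.import_groups)]
    names = producers + consumers + pools + feeds
    n = len(names)
    idx = {name: i for i, name in enumerate(names)}
    P_idx = [idx[x] for x in producers]
    C_idx = [idx[x] for x in consumers]
    D_idx = [idx[x] for x in pools]
    F_idx = [idx[x] for x in feeds]
    base_idx = P_idx + D_idx + F_idx

    n_bact = min(spec.n_detritus, spec.n_consumers) if spec.bacterial_loops else 0
    gs_lo, gs_hi = spec.gs_ranges.get(CONSUMER, _DEFAULT_GS[CONSUMER])

    # --- diets -------------------------------------------------------------
    diet = np.zeros((n, n))
    for c_pos, j in enumerate(C_idx):
        if c_pos < n_bact:
            pool = D_idx[c_pos]
            diet[j, pool] = 0.95
            other = F_idx[0] if F_idx else P_idx[0]
            diet[j, other] = 0.05
            continue
        candidates = base_idx + C_idx[:c_pos]
        take = rng.random(len(candidates)) < 0.6
        take[rng.integers(len(base_idx))] = True  # ensure a level-1 prey
        chosen = [g for g, t in zip(candidates, take) if t]
        w = rng.dirichlet(np.full(len(chosen), spec.diet_concentration))
        diet[j, chosen] = w / w.sum()

    # --- consumption and production, top predators first -------------------
    Q = np.zeros(n)
    Pr = np.zeros(n)
    Y = np.zeros(n)
    gs = np.zeros(n)
    ee = np.zeros(n)
    for c_pos in reversed(range(len(C_idx))):
        j = C_idx[c_pos]
        gs[j] = 0.4 if c_pos < n_bact else rng.uniform(gs_lo, gs_hi)
        ee[j] = rng.uniform(0.05, 0.95)
        u = rng.uniform(0.3, 0.8)          # P as a share of assimilation
        preds = C_idx[c_pos + 1:]  # only later consumers can prey on j
        m2 = float((Q[preds] * diet[preds, j]).sum())
        if m2 > 0:
            Pr[j] = m2 / ee[j]
            Q[j] = Pr[j] / ((1.0 - gs[j]) * u)
        else:
            Q[j] = float(rng.lognormal(2.0, 0.8))
            Pr[j] = (1.0 - gs[j]) * Q[j] * u
            Y[j] = ee[j] * Pr[j]
    for i in P_idx:
        ee[i] = rng.uniform(0.05, 0.95)
        m2 = float((Q * diet[:, i]).sum())
        if m2 > 0:
            Pr[i] = m2 / ee[i]
        else:
            Pr[i] = float(rng.lognormal(2.0, 0.8))
            Y[i] = ee[i] * Pr[i]

    # --- detritus routing and imports --------------------------------------
    fate = {}
    for i in P_idx + C_idx + F_idx:
        w = rng.dirichlet(np.full(len(D_idx), 1.0))
        fate[i] = {pools[k]: float(w[k]) for k in range(len(D_idx))}
    imports = np.zeros(n)
    FD = np.zeros(n)
    for i in P_idx + C_idx:
        FD[i] = Q[i] * gs[i] + Pr[i] * (1.0 - ee[i])
    feed_surplus = np.zeros(n)
    for f in F_idx:
        cons = float((Q * diet[:, f]).sum())
        target = rng.uniform(0.3, 0.9)
        imports[f] = max(cons / target, cons + 1.0)
        feed_surplus[f] = imports[f] - cons
    for d in D_idx:
        inflow = sum(FD[i] * fate[i][names[d]] for i in P_idx + C_idx)
        inflow += sum(feed_surplus[f] * fate[f][names[d]] for f in F_idx)
        cons = float((Q * diet[:, d]).sum())
        if cons > 0.95 * inflow:
            imports[d] = cons / 0.95 - inflow  # allochthonous top-up

    # --- assemble groups ----------------------------------------------------
    B = rng.lognormal(1.0, 0.7, size=n)
    groups = []
    for i, name in enumerate(names):
        if i in P_idx:
            groups.append(Group(name=name, category=PRODUCER,
                                biomass=float(B[i]), pb=float(Pr[i] / B[i]),
                                qb=0.0, ee=float(ee[i]), gs=0.0,
                                catch=float(Y[i]),
                                detritus_fate=fate[i]))
        elif i in C_idx:
            groups.append(Group(name=name, category=CONSUMER,
                                biomass=float(B[i]), pb=float(Pr[i] / B[i]),
                                qb=float(Q[i] / B[i]), ee=float(ee[i]),
                                gs=float(gs[i]), catch=float(Y[i]),
                                detritus_fate=fate[i]))
        else:
            groups.append(Group(name=name, category=DETRITUS,
                                biomass=float(B[i]), pb=0.0, qb=0.0,
                                gs=0.0, imports=float(imports[i]),
                                detritus_fate=fate.get(i, {}),
                                surplus_disposition=SURPLUS_EXPORT))
    model = EcopathModel(groups, diet, period_days=300,
                         label=f"synthetic(seed={spec.seed})")

    # --- ground truth -------------------------------------------------------
    tl = np.ones(n)
    for j in C_idx:  # prey always precede their predators
        tl[j] = 1.0 + float((diet[j] * tl).sum())
    flow_matrix = (diet * Q[:, None]).T
    return model, GroundTruth(ee=ee.copy(), flow_matrix=flow_matrix,
                              trophic_levels=tl)


def blank_ee(model: EcopathModel) -> EcopathModel:
    """Copy of a model with every living group's EE marked unknown —
    the natural input for exercising the balance solver."""
    out = model.copy()
    for g in out.groups:
        if g.is_living:
            g.ee = None
    return out


def perturb(model: EcopathModel, seed: int, scale: float) -> EcopathModel:
    """Multiply biomasses and rates by lognormal noise of the given scale
    and re-normalize the jittered consumer diets; deterministic per seed,
    identity at ``scale=0``."""
    out = model.copy()
    if scale == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for g in out.groups:
        if not g.is_living:
            continue
        for attr in ("biomass", "pb", "qb"):
            v = getattr(g, attr)
            if v:
                setattr(g, attr, float(v * rng.lognormal(0.0, scale)))
    for j, g in enumerate(out.groups):
        row = out.diet[j]
        if g.category == CONSUMER and row.any():
            noisy = row * rng.lognormal(0.0, scale, size=row.size)
            noisy[row == 0] = 0.0
            out.diet[j] = noisy / noisy.sum()
    return out
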