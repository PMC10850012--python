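"""Mixed trophic impacts and prey/predator niche overlap.

The mixed trophic impact (MTI) matrix gives the net direct-plus-
indirect effect of a small biomass increase of one group on every
other, obtained by inverting the matrix of net direct impacts
(positive as prey contribution, negative as predation share).  Niche
overlap uses Pianka's symmetric index on either diet-composition
vectors (prey overlap) or predation-composition vectors (predator
overlap).
"""

from __future__ import annotations

import numpy as np

from .balance import BalancedModel, BalanceError
from .model import EcopathModel


def _net_impact_matrix(balanced: BalancedModel) -> np.ndarray:
    """``q[i, j]``: direct impact of group i on group j — the share of i
    in j's diet minus the share of j's predation mortality exerted by i.

    Detritus groups have zero diet rows but active predation columns
    (donor control): consumption of a pool counts as predation on it.
    Harvest fleets are not modelled as compartments, so the predation
    shares are taken over biological consumption only.
    """
    model, flows = balanced.model, balanced.flows
    M2 = flows.M2
    share = np.zeros_like(flows.flow_matrix)  # share[j, i]: predation on j by i
    nz = M2 > 0
    share[nz] = flows.flow_matrix[nz] / M2[nz, None]
    # q[i, j] = diet[j, i] - share[j, i]
    return model.diet.T - share.T


def mixed_trophic_impact(balanced: BalancedModel) -> np.ndarray:
    """MTI matrix ``m[i, j]``: net impact of group i on group j.

    Solves ``M = (I - q)^-1 - I``, the closed form of the infinite sum
    of impact paths of every length.
    """
    q = _net_impact_matrix(balanced)
    n = q.shape[0]
    A = np.eye(n) - q
    if abs(np.linalg.det(A)) < 1e-12:
        raise BalanceError("net-impact matrix is singular; impacts diverge")
    return np.linalg.inv(A) - np.eye(n)


def _pianka(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Pianka index of the rows of ``vectors``; all-zero rows
    yield zero everywhere including the diagonal."""
    norms = np.sqrt((vectors ** 2).sum(axis=1))
    out = vectors @ vectors.T
    nz = norms > 0
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, out / np.where(denom > 0, denom, 1.0), 0.0)
    out[~nz, :] = 0.0
    out[:, ~nz] = 0.0
    # clip rounding spill so entries stay inside [0, 1]
    return np.clip(out, 0.0, 1.0)


def prey_overlap(model: EcopathModel) -> np.ndarray:
    """Similarity of diet composition between every pair of groups.

    ``O_jk = sum_i p_ji p_ki / sqrt(sum_i p_ji^2 sum_i p_ki^2)`` over
    diet fractions; groups without a diet get a zero row (flagged by
    their zero diagonal).
    """
    return _pianka(model.diet)


def predator_overlap(balanced: BalancedModel) -> np.ndarray:
    """Similarity of the predator fields of every pair of groups, using
    each group's predation-composition vector (the fraction of its
    predation mortality taken by each consumer)."""
    flows = balanced.flows
    M2 = flows.M2
    comp = np.zeros_like(flows.flow_matrix)
    nz = M2 > 0
    comp[nz] = flows.flow_matrix[nz] / M2[nz, None]
    return _pianka(comp)
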