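"""Effective trophic levels, omnivory, connectance and catch statistics.

The effective trophic level (ETL) of a consumer is one plus the
diet-weighted mean level of its prey; producers and detritus-type
groups (including import-fed pools such as feed) are fixed at level 1.
Cannibalism and loops among consumers are handled by solving the fixed
point as one linear system rather than by iteration.
"""

from __future__ import annotations

import numpy as np

from .model import CONSUMER, EcopathModel, ModelError


def trophic_levels(model: EcopathModel) -> np.ndarray:
    """Solve ``tl = 1 + DC @ tl`` with producer/detritus levels pinned at 1.

    Raises :class:`ModelError` for a consumer with an all-zero diet or a
    singular system (a consumer loop with no route down to level 1).
    """
    cons = model.mask(CONSUMER)
    diet = model.diet
    for i in np.flatnonzero(cons):
        if not diet[i].any():
            raise ModelError(
                f"consumer {model.names[i]!r} has an all-zero diet; "
                "trophic level undefined")
    tl = np.ones(model.n)
    ci = np.flatnonzero(cons)
    if ci.size:
        A = np.eye(ci.size) - diet[np.ix_(ci, ci)]
        b = 1.0 + diet[ci][:, ~cons].sum(axis=1)  # level-1 prey contribute 1
        if abs(np.linalg.det(A)) < 1e-12:
            raise ModelError("trophic-level system is singular: a consumer "
                             "loop never reaches level-1 prey")
        tl[ci] = np.linalg.solve(A, b)
    return tl


def level_fractions(model: EcopathModel, max_level: int = 10) -> np.ndarray:
    """``(n, max_level)`` matrix of each group's activity share per integer
    trophic level: producers/detritus sit entirely at level 1, a consumer's
    share at level k+1 equals its diet share taken from level-k prey.

    Rows sum to 1 up to the mass beyond ``max_level`` (renormalized, and
    negligible for webs whose diets concentrate near the base).
    """
    cons = model.mask(CONSUMER)
    F = np.zeros((model.n, max_level))
    F[~cons, 0] = 1.0
    for k in range(1, max_level):
        F[cons, k] = model.diet[cons] @ F[:, k - 1]
    # strong consumer loops can push a little activity past max_level;
    # renormalizing keeps the apportioning exact
    F /= F.sum(axis=1, keepdims=True)
    return F


def omnivory(model: EcopathModel, tls: np.ndarray,
             consumption: np.ndarray | None = None
             ) -> tuple[np.ndarray, float]:
    """Per-consumer omnivory index and the system omnivory index.

    ``oi_j`` is the diet-weighted variance of prey trophic levels about
    the predator's own feeding level ``tl_j - 1``.  The system index
    averages ``oi`` over consumers weighted by the logarithm of each
    one's total consumption (the customary convention; weights below 1
    are clipped to zero so tiny groups cannot carry negative weight).
    """
    cons = model.mask(CONSUMER)
    oi = np.zeros(model.n)
    dev = tls[None, :] - (tls[:, None] - 1.0)
    oi[cons] = (model.diet[cons] * dev[cons] ** 2).sum(axis=1)
    if consumption is None:
        B = model.param("biomass")
        qb = model.param("qb")
        consumption = np.where(cons, B * qb, 0.0)
    w = np.where(cons, np.log(np.clip(consumption, 1.0, None)), 0.0)
    soi = float((oi * w).sum() / w.sum()) if w.sum() > 0 else 0.0
    return oi, soi


def connectance(model: EcopathModel, denominator: str = "squared") -> float:
    """Connectance index: realized feeding links over possible links.

    ``denominator='squared'`` divides the link count by N_living^2 (the
    default; detritus-feeding links count, only living groups enter the
    denominator), ``'pairs'`` by N_living * (N_living - 1).
    """
    living = model.living
    L = int(np.count_nonzero(model.diet[living]))
    N = int(living.sum())
    if N <= 1:
        return 0.0
    if denominator == "squared":
        return L / (N * N)
    if denominator == "pairs":
        return L / (N * (N - 1))
    raise ModelError(f"unknown connectance denominator {denominator!r}")


def feeding_links(model: EcopathModel) -> int:
    """Number of nonzero diet entries of living consumers."""
    return int(np.count_nonzero(model.diet[model.living]))


def mean_trophic_level_of_catch(model: EcopathModel,
                                tls: np.ndarray) -> float:
    """Catch-weighted mean trophic level, ``sum(Y_i tl_i) / sum(Y_i)``."""
    Y = model.param("catch", fill=0.0)
    total = Y.sum()
    if total <= 0:
        raise ModelError("no catches in the model; "
                         "mean trophic level of the catch is undefined")
    return float((Y * tls).sum() / total)


def flow_origin(model: EcopathModel) -> np.ndarray:
    """Fraction of each group's consumption that traces back to detritus.

    Solves ``d = DC @ d`` with detritus-type groups (including feed and
    precipitation pools) pinned at 1 and producers at 0; the complement
    is the fraction originating from primary producers.
    """
    cons = model.mask(CONSUMER)
    det = model.mask("detritus")
    d = np.where(det, 1.0, 0.0)
    ci = np.flatnonzero(cons)
    if ci.size:
        A = np.eye(ci.size) - model.diet[np.ix_(ci, ci)]
        b = model.diet[ci][:, det].sum(axis=1)
        d[ci] = np.linalg.solve(A, b)
    return d
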