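"""Trophic levels, omnivory, mixed trophic impacts and keystoneness.

Trophic level (TL) is 1 for producers and detritus and one plus the
diet-weighted mean prey TL for consumers; the fixed point of that
definition is obtained by a single linear solve. The omnivory index (OI)
is the diet-weighted variance of prey trophic levels around TL − 1. The
mixed-trophic-impact (MTI) matrix propagates direct diet and predation
effects through all indirect pathways via a Leontief-type inverse, and
keystoneness combines a group's overall MTI effect with its (low) share of
system biomass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BalancedModel, DietMatrix


class TrophicError(ValueError):
    pass


def trophic_levels(diet: DietMatrix, categories: list[str],
                   import_tl: str = "producer") -> np.ndarray:
    """Solve the trophic-level linear system.

    ``import_tl`` controls the diet fraction taken outside the system:
    ``"producer"`` treats it as trophic-level-1 food, ``"exclude"`` drops it
    and renormalizes the internal diet.
    """
    n = len(categories)
    DC = diet.values.copy()
    imp = diet.import_row.copy()
    if import_tl == "exclude":
        internal = DC.sum(axis=0)
        scale = np.where(internal > 0, internal, 1.0)
        DC = DC / scale[np.newaxis, :]
        imp = np.zeros(n)
    elif import_tl != "producer":
        raise ValueError(f"unknown import_tl mode {import_tl!r}")

    A = np.eye(n)
    b = np.ones(n)
    for j, cat in enumerate(categories):
        if cat == "consumer":
            A[j, :] -= DC[:, j]
            b[j] = 1.0 + (imp[j] if import_tl == "producer" else 0.0)
        # producers and detritus: TL = 1 exactly
    try:
        tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise TrophicError(
            "trophic-level system is singular (degenerate diet loops)"
        ) from exc
    if not np.all(np.isfinite(tl)):
        raise TrophicError("non-finite trophic levels")
    return tl


def trophic_levels_fixed_point(diet: DietMatrix, categories: list[str],
                               iterations: int = 200) -> np.ndarray:
    """Reference fixed-point iteration TL ← 1 + DCᵀ·TL (independent check)."""
    n = len(categories)
    consumer = np.array([c == "consumer" for c in categories])
    tl = np.ones(n)
    for _ in range(iterations):
        new = 1.0 + diet.values.T @ tl + diet.import_row
        tl = np.where(consumer, new, 1.0)
    return tl


def omnivory_index(diet: DietMatrix, tl: np.ndarray,
                   categories: list[str]) -> np.ndarray:
    """Diet-weighted variance of prey TL around TL − 1; zero for
    non-consumers and single-prey diets."""
    n = len(categories)
    oi = np.zeros(n)
    for j, cat in enumerate(categories):
        if cat != "consumer":
            continue
        center = tl[j] - 1.0
        dev = (tl - center) ** 2
        oi[j] = float(diet.values[:, j] @ dev)
        if diet.import_row[j] > 0:
            oi[j] += diet.import_row[j] * (1.0 - center) ** 2
    return oi


def mixed_trophic_impact(model: BalancedModel) -> np.ndarray:
    """Net direct + indirect impact of a marginal biomass increase of each
    row group on each column group.

    The direct net impact of i on j is the benefit of i as food
    (DC[i, j]) minus the loss to i as a predator (i's share of the total
    predation on j); the full matrix is (I − q)⁻¹ − I.
    """
    DC = model.diet.values
    n = DC.shape[0]
    B = np.array([g.biomass or 0.0 for g in model.groups])
    QB = np.array([g.qb if g.qb is not None else 0.0 for g in model.groups])
    Q = B * QB

    predation = DC @ Q  # total consumption of each prey
    F = np.zeros((n, n))  # F[j, i]: share of predation on j due to i
    for j in range(n):
        if predation[j] > 0:
            F[j, :] = DC[j, :] * Q / predation[j]

    q = DC - F.T
    try:
        m = np.linalg.inv(np.eye(n) - q) - np.eye(n)
    except np.linalg.LinAlgError as exc:
        raise TrophicError("(I − q) is singular; MTI undefined") from exc
    return m


def keystoneness(m: np.ndarray, biomasses: np.ndarray,
                 living: np.ndarray,
                 names: list[str] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Keystone index and descending ranks over living groups.

    KS_i = log10(ε_i · (1 − p_i)) with ε_i the root-sum-square of group i's
    impacts on all other groups and p_i its share of living biomass: a group
    ranks as keystone when it has large overall impact despite small
    biomass. Non-living compartments get NaN/0.
    """
    n = m.shape[0]
    eps = np.sqrt((m ** 2).sum(axis=1) - np.diag(m) ** 2)
    btot = biomasses[living].sum()
    p = np.where(living, biomasses / btot, 0.0)
    with np.errstate(divide="ignore"):
        ks = np.where(eps > 0, np.log10(np.maximum(eps, 1e-300) * (1 - p)),
                      -np.inf)
    ks = np.where(living, ks, np.nan)

    ranks = np.zeros(n, dtype=int)
    live_idx = np.flatnonzero(living)
    # descending KS; −inf (no trophic links) sorts last; ties by name
    tie = (lambda i: names[i]) if names is not None else (lambda i: i)
    order = sorted(live_idx, key=lambda i: (-ks[i], tie(i)))
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ks, ranks


def mean_tl_of_catch(landings: np.ndarray, tl: np.ndarray) -> float:
    """Landings-weighted mean trophic level of the catch."""
    landings = np.asarray(landings, dtype=float)
    total = landings.sum()
    if total <= 0:
        raise TrophicError("mean TL of catch undefined: no landings")
    return float(landings @ tl / total)


@dataclass
class TrophicReport:
    """Per-group trophic statistics of a balanced model."""

    names: list[str]
    tl: np.ndarray
    oi: np.ndarray
    ks: np.ndarray
    keystone_rank: np.ndarray
    mean_tl_catch: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trophic_level": self.tl, "omnivory_index": self.oi,
             "keystoneness": self.ks, "keystone_rank": self.keystone_rank},
            index=pd.Index(self.names, name="group"),
        )


def trophic_report(model: BalancedModel,
                   import_tl: str = "producer") -> TrophicReport:
    """Compute TL, OI, MTI-based keystoneness and mean catch TL in one pass."""
    cats = [g.category for g in model.groups]
    tl = trophic_levels(model.diet, cats, import_tl=import_tl)
    oi = omnivory_index(model.diet, tl, cats)
    m = mixed_trophic_impact(model)
    living = np.array([g.is_living for g in model.groups])
    B = np.array([g.biomass or 0.0 for g in model.groups])
    ks, ranks = keystoneness(m, B, living, names=model.names)
    landings = np.array([g.landings for g in model.groups])
    mtlc = mean_tl_of_catch(landings, tl) if landings.sum() > 0 else None
    return TrophicReport(model.names, tl, oi, ks, ranks, mtlc)
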