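"""Whole-system network attributes of a balanced food web.

Covers the standard comparison battery for mass-balance models: totals
(production, throughput, net primary production), dimensionless ratios,
connectance, system omnivory, the information-theoretic
ascendency/overhead/capacity partition, and Finn's cycling statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .balance import FlowNetwork
from .core import BalancedModel, DietMatrix
from .trophic import mean_tl_of_catch, omnivory_index, trophic_levels

INF_SENTINEL = float("inf")


class NetworkError(ValueError):
    pass


@dataclass
class AttributeReport:
    """System-level attribute block (units in field comments)."""

    sum_of_production: float          # t·km⁻²·yr⁻¹
    total_system_throughput: float    # t·km⁻²·yr⁻¹
    total_net_pp: float               # t·km⁻²·yr⁻¹
    pp_over_respiration: float
    pp_over_biomass: float
    biomass_over_throughput: float    # yr⁻¹
    total_biomass_excl_detritus: float  # t·km⁻²
    total_catch: float                # t·km⁻²·yr⁻¹
    mean_tl_catch: float | None = None
    connectance: float | None = None
    system_omnivory: float | None = None
    ascendency_pct: float | None = None
    overhead_pct: float | None = None
    throughput_cycled: float | None = None  # t·km⁻²·yr⁻¹, excl. detritus
    finn_cycling_pct: float | None = None   # % of total throughput
    finn_mean_path_length: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def summary_statistics(model: BalancedModel,
                       flows: FlowNetwork) -> AttributeReport:
    """Production, biomass and ratio block of the attribute table.

    Sum of production is Σ B·(P/B) over living groups; net primary
    production is the producer part of that sum. Throughput follows the
    flow-network convention (consumption + exports + respiration + flow
    into detritus).
    """
    living = [g for g in model.groups if g.is_living]
    prod = sum(g.biomass * g.pb for g in living)
    pp = sum(g.biomass * g.pb for g in living if g.is_producer)
    resp = float(flows.respiration.sum())
    biomass = sum(g.biomass for g in living if g.biomass is not None)
    tst = flows.tst()
    catch = sum(g.landings for g in model.groups)
    return AttributeReport(
        sum_of_production=float(prod),
        total_system_throughput=tst,
        total_net_pp=float(pp),
        pp_over_respiration=pp / resp if resp > 0 else INF_SENTINEL,
        pp_over_biomass=pp / biomass if biomass > 0 else INF_SENTINEL,
        biomass_over_throughput=biomass / tst if tst > 0 else INF_SENTINEL,
        total_biomass_excl_detritus=float(biomass),
        total_catch=float(catch),
    )


def connectance(diet: DietMatrix, categories: list[str],
                include_cannibalism: bool = False) -> float:
    """Realized fraction of possible trophic links among living groups.

    Possible links are N(N−1) directed prey→predator pairs; self links
    (cannibalism) are excluded from the count by default.
    """
    living = np.array([c != "detritus" for c in categories])
    n_living = int(living.sum())
    if n_living < 2:
        raise NetworkError("connectance needs at least two living groups")
    sub = diet.values[np.ix_(living, living)]
    links = sub > 0
    if not include_cannibalism:
        np.fill_diagonal(links, False)
    return float(links.sum() / (n_living * (n_living - 1)))


def system_omnivory(oi: np.ndarray, model: BalancedModel,
                    weight_floor: float = np.log(1.01)) -> float:
    """Consumer omnivory averaged with log-consumption weights.

    Each consumer's weight is log(B·Q/B), floored at log(1.01) so that tiny
    intakes never contribute zero or negative weight, then renormalized.
    """
    weights = []
    values = []
    for i, g in enumerate(model.groups):
        if not g.is_consumer:
            continue
        intake = (g.biomass or 0.0) * (g.qb or 0.0)
        w = max(np.log(intake) if intake > 0 else weight_floor, weight_floor)
        weights.append(w)
        values.append(oi[i])
    if not weights:
        return 0.0
    w = np.asarray(weights)
    return float(np.asarray(values) @ (w / w.sum()))


def _extended_flow_matrix(flows: FlowNetwork) -> np.ndarray:
    """Internal flows bordered by virtual import row and export/respiration
    columns, the substrate for the information indices."""
    n = flows.n
    ext = np.zeros((n + 1, n + 2))
    ext[:n, :n] = flows.flows
    ext[n, :n] = flows.imports          # virtual import compartment → i
    ext[:n, n] = flows.exports          # i → virtual export
    ext[:n, n + 1] = flows.respiration  # i → virtual respiration sink
    return ext


def ascendency(flows: FlowNetwork) -> dict[str, float]:
    """Ascendency A, development capacity C and overhead O = C − A.

    A = Σ T_ij·log(T_ij·T·· / (T_i·+ · T·+j)) over the extended flow matrix
    (virtual import/export/respiration compartments included);
    C = −Σ T_ij·log(T_ij / T··). Percentages are log-base invariant.
    """
    T = _extended_flow_matrix(flows)
    total = T.sum()
    if total <= 0:
        raise NetworkError("ascendency undefined: zero total flow")
    rows = T.sum(axis=1, keepdims=True)
    cols = T.sum(axis=0, keepdims=True)
    mask = T > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        a_terms = np.where(mask, T * np.log(T * total / (rows * cols)), 0.0)
        c_terms = np.where(mask, -T * np.log(T / total), 0.0)
    A = float(a_terms.sum())
    C = float(c_terms.sum())
    O = C - A
    return {
        "ascendency": A,
        "capacity": C,
        "overhead": O,
        "ascendency_pct": 100.0 * A / C if C > 0 else 0.0,
        "overhead_pct": 100.0 * O / C if C > 0 else 0.0,
    }


@dataclass
class FinnResult:
    throughput_cycled: float           # over all compartments
    throughput_cycled_excl_detritus: float
    finn_cycling_pct: float            # % of total system throughput
    mean_path_length: float


def finn_indices(flows: FlowNetwork) -> FinnResult:
    """Cycled throughput, Finn's cycling index and mean path length.

    The input-oriented fractional-flow matrix G[i, j] = T[i→j] / inflow_j
    generates the Leontief-type structure matrix L = (I − Gᵀ)⁻¹; the
    diagonal excess (L_ii − 1)/L_ii is the fraction of compartment i's
    inflow that returns to i through cycles. Mean path length is total
    throughput per unit of outflow (exports + respiration).
    """
    n = flows.n
    inflow = flows.inflows()
    G = np.zeros((n, n))
    nz = inflow > 0
    G[:, nz] = flows.flows[:, nz] / inflow[nz]
    try:
        L = np.linalg.inv(np.eye(n) - G.T)
    except np.linalg.LinAlgError as exc:
        raise NetworkError("(I − Gᵀ) singular; cycling undefined") from exc
    diag = np.diag(L)
    cycled_frac = np.where(diag != 0, (diag - 1.0) / diag, 0.0)
    cycled = cycled_frac * inflow
    tst = flows.tst()
    living = np.array([c != "detritus" for c in flows.categories])
    outflow = flows.exports.sum() + flows.respiration.sum()
    return FinnResult(
        throughput_cycled=float(cycled.sum()),
        throughput_cycled_excl_detritus=float(cycled[living].sum()),
        finn_cycling_pct=100.0 * float(cycled.sum()) / tst if tst > 0 else 0.0,
        mean_path_length=tst / outflow if outflow > 0 else INF_SENTINEL,
    )


def attribute_report(model: BalancedModel, flows: FlowNetwork,
                     import_tl: str = "producer") -> AttributeReport:
    """Full system-attribute table for one balanced model."""
    report = summary_statistics(model, flows)
    cats = [g.category for g in model.groups]
    tl = trophic_levels(model.diet, cats, import_tl=import_tl)
    oi = omnivory_index(model.diet, tl, cats)
    landings = np.array([g.landings for g in model.groups])
    if landings.sum() > 0:
        report.mean_tl_catch = mean_tl_of_catch(landings, tl)
    report.connectance = connectance(model.diet, cats)
    report.system_omnivory = system_omnivory(oi, model)
    asc = ascendency(flows)
    report.ascendency_pct = asc["ascendency_pct"]
    report.overhead_pct = asc["overhead_pct"]
    finn = finn_indices(flows)
    report.throughput_cycled = finn.throughput_cycled_excl_detritus
    report.finn_cycling_pct = finn.finn_cycling_pct
    report.finn_mean_path_length = finn.mean_path_length
    return report
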