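"""Mass-balance solver and flow-network construction.

The solver fills in the one missing basic parameter per living group. The
only genuinely simultaneous unknowns are biomasses (an unknown predator
biomass appears in the balance equations of all of its prey), so the solver
assembles a square linear system over the unknown biomasses and afterwards
resolves unknown P/B and EE by direct substitution. Q/B is never estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    DEFAULT_GS,
    BalancedModel,
    Diagnostic,
    EcopathInputs,
    has_errors,
    validate_inputs,
)

EE_TOL = 1e-9


class BalanceError(ValueError):
    """Raised when a model cannot be solved (singular or infeasible)."""


def _demand(inputs_like, B, QB, DC) -> np.ndarray:
    """Predation pressure on each group: sum_j B_j (Q/B)_j DC[i, j]."""
    Q = np.where(np.isnan(QB), 0.0, np.nan_to_num(B) * np.nan_to_num(QB))
    return DC @ Q


def solve_balance(inputs: EcopathInputs, gs_default: float = DEFAULT_GS,
                  check: bool = True) -> BalancedModel:
    """Solve the balance identity for the missing parameter of every group.

    Parameters
    ----------
    inputs
        Validated model inputs (three of four basic parameters per living
        group).
    gs_default
        Unassimilated fraction used for consumers that do not set one.
    check
        Run :func:`~shelfweb.core.validate_inputs` first and refuse to solve
        on errors.

    Returns
    -------
    BalancedModel
        All of B, P/B, Q/B, EE filled for living groups; detritus EE as a
        derived output; residuals and warnings attached. Ecotrophic
        efficiencies outside [0, 1] are flagged as warnings, not clipped:
        the model is returned "unbalanced" for inspection, mirroring how
        practitioners iterate on diets and biomasses.
    """
    if check:
        diags = validate_inputs(inputs)
        if has_errors(diags):
            msgs = "; ".join(str(d) for d in diags if d.severity == "error")
            raise BalanceError(f"invalid inputs: {msgs}")

    n = inputs.n
    groups = [replace(g) for g in inputs.groups]
    DC = inputs.diet.values
    living = inputs.living_mask()

    B = np.array([np.nan if g.biomass is None else g.biomass for g in groups])
    PB = np.array([np.nan if g.pb is None else g.pb for g in groups])
    QB = np.array([np.nan if g.qb is None else g.qb for g in groups])
    EE = np.array([np.nan if g.ee is None else g.ee for g in groups])
    Y = np.array([g.landings + g.migration + g.ba for g in groups])

    unknown_b = [i for i in range(n) if living[i] and np.isnan(B[i])]
    unknown_pb = [i for i in range(n) if living[i] and np.isnan(PB[i])]
    unknown_ee = [i for i in range(n) if living[i] and np.isnan(EE[i])]

    # --- linear system over unknown biomasses ----------------------------
    if unknown_b:
        pos = {g: k for k, g in enumerate(unknown_b)}
        m = len(unknown_b)
        A = np.zeros((m, m))
        rhs = np.zeros(m)
        qb0 = np.nan_to_num(QB)
        for row, i in enumerate(unknown_b):
            # B_i PB_i EE_i - sum_j B_j QB_j DC[i,j] = Y_i
            A[row, pos[i]] += PB[i] * EE[i]
            rhs[row] = Y[i]
            for j in range(n):
                coef = qb0[j] * DC[i, j]
                if coef == 0.0:
                    continue
                if j in pos:
                    A[row, pos[j]] -= coef
                else:
                    rhs[row] += coef * B[j]
        rank = np.linalg.matrix_rank(A)
        if rank < m:
            names = ", ".join(inputs.names[i] for i in unknown_b)
            raise BalanceError(
                f"singular biomass system over groups [{names}]: "
                "their balance equations are linearly dependent")
        B[unknown_b] = np.linalg.solve(A, rhs)

    demand = _demand(inputs, B, QB, DC) + Y

    # --- direct substitution for P/B and EE ------------------------------
    for i in unknown_pb:
        if B[i] * EE[i] == 0 and demand[i] > 0:
            raise BalanceError(
                f"group {inputs.names[i]!r}: zero B·EE but nonzero demand; "
                "P/B cannot be recovered")
        PB[i] = demand[i] / (B[i] * EE[i]) if B[i] * EE[i] != 0 else 0.0
    for i in unknown_ee:
        prod = B[i] * PB[i]
        if prod == 0:
            if demand[i] > EE_TOL:
                raise BalanceError(
                    f"group {inputs.names[i]!r}: zero production "
                    f"(B·P/B = 0) but nonzero demand {demand[i]:.3g}")
            EE[i] = 0.0
        else:
            EE[i] = demand[i] / prod

    warnings: list[Diagnostic] = []
    for i in range(n):
        if not living[i]:
            continue
        if EE[i] > 1 + EE_TOL or EE[i] < -EE_TOL:
            warnings.append(Diagnostic(
                "warning", inputs.names[i],
                f"EE = {EE[i]:.4f} outside [0, 1]; model unbalanced"))
        if B[i] < 0:
            warnings.append(Diagnostic(
                "warning", inputs.names[i],
                f"estimated biomass negative ({B[i]:.4g})"))

    for i, g in enumerate(groups):
        if not living[i]:
            continue
        g.biomass, g.pb, g.ee = float(B[i]), float(PB[i]), float(EE[i])
        if g.is_consumer:
            g.qb = float(QB[i])

    residuals = _residuals(groups, DC, living)
    model = BalancedModel(groups, inputs.diet, residuals, warnings)
    model.detritus_ee = _detritus_ee(model, gs_default)
    return model


def _residuals(groups, DC, living) -> np.ndarray:
    n = len(groups)
    B = np.array([g.biomass if g.biomass is not None else 0.0 for g in groups])
    QB = np.array([g.qb if g.qb is not None else 0.0 for g in groups])
    PB = np.array([g.pb if g.pb is not None else 0.0 for g in groups])
    EE = np.array([g.ee if g.ee is not None else 0.0 for g in groups])
    Y = np.array([g.landings + g.migration + g.ba for g in groups])
    demand = DC @ (B * QB) + Y
    res = B * PB * EE - demand
    res[~living] = 0.0
    return res


def balance_residuals(model: BalancedModel) -> np.ndarray:
    """Per-group balance residual B·(P/B)·EE − (predation + Y + E + BA)."""
    living = np.array([g.is_living for g in model.groups])
    return _residuals(model.groups, model.diet.values, living)


def _detritus_ee(model: BalancedModel, gs_default: float) -> dict[str, float]:
    """Detrital "EE": fraction of total detritus inflow that is consumed."""
    net = build_flow_network(model, gs_default=gs_default, strict=False)
    out: dict[str, float] = {}
    for i, g in enumerate(model.groups):
        if not g.is_detritus:
            continue
        inflow = net.flows[:, i].sum() + net.imports[i]
        consumed = net.flows[i, :].sum()
        out[g.name] = consumed / inflow if inflow > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Flow network
# ---------------------------------------------------------------------------

@dataclass
class FlowNetwork:
    """Compartment-level flows (t·km⁻²·yr⁻¹) of a solved model.

    ``flows[i, j]`` is the flow from compartment i to compartment j:
    consumption of i by j, or (for detrital columns) egestion plus
    non-predation mortality routed to detritus. ``imports`` collects all
    exogenous inflows — primary production for producers, the diet import
    fraction for consumers, external input for detritus. ``exports`` are
    fishery landings plus detrital surplus; ``respiration`` is metabolic
    loss of consumers.
    """

    names: list[str]
    categories: list[str]
    flows: np.ndarray
    imports: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray

    @property
    def n(self) -> int:
        return len(self.names)

    def inflows(self) -> np.ndarray:
        """Total inflow per compartment (internal flows + imports)."""
        return self.flows.sum(axis=0) + self.imports

    def total_consumption(self) -> float:
        cons = np.array([c == "consumer" for c in self.categories])
        return float(self.inflows()[cons].sum())

    def flow_to_detritus(self) -> float:
        det = np.array([c == "detritus" for c in self.categories])
        return float(self.inflows()[det].sum())

    def tst(self) -> float:
        """Total system throughput: consumption + exports + respiration +
        flow into detritus."""
        return (self.total_consumption() + self.exports.sum()
                + self.respiration.sum() + self.flow_to_detritus())

    def balance_check(self) -> np.ndarray:
        """Relative inflow−outflow mismatch per compartment."""
        inflow = self.inflows()
        outflow = self.flows.sum(axis=1) + self.exports + self.respiration
        scale = np.maximum(1.0, inflow)
        return (inflow - outflow) / scale


def build_flow_network(model: BalancedModel, gs_default: float = DEFAULT_GS,
                       strict: bool = True) -> FlowNetwork:
    """Expand a balanced model into explicit compartment-to-compartment flows.

    Consumption flows are B_j·(Q/B)_j·DC[i, j]. A consumer's respiration is
    assimilated intake minus production, (1−GS)·Q − P; producers respire
    nothing in this energy-currency convention (gross = net primary
    production). Flow to detritus from group j is egestion GS_j·Q_j plus
    unexploited production (1−EE_j)·P_j. Detrital surplus (inflow minus
    consumption) leaves the system as export rather than accumulating.

    With ``strict`` a consumer whose production exceeds assimilated intake
    (P/Q > 1−GS, negative respiration) raises :class:`BalanceError`.
    """
    n = len(model.groups)
    names = model.names
    cats = [g.category for g in model.groups]
    B = np.array([g.biomass if g.biomass is not None else 0.0
                  for g in model.groups])
    QB = np.array([g.qb if g.qb is not None else 0.0 for g in model.groups])
    PB = np.array([g.pb if g.pb is not None else 0.0 for g in model.groups])
    EE = np.array([g.ee if g.ee is not None else 0.0 for g in model.groups])
    GS = np.array([g.gs_or_default(gs_default) for g in model.groups])
    Q = B * QB
    P = B * PB

    T = model.diet.values * Q[np.newaxis, :]
    imports = model.diet.import_row * Q
    exports = np.array([g.landings for g in model.groups], dtype=float)
    respiration = np.zeros(n)

    det_idx = [i for i, g in enumerate(model.groups) if g.is_detritus]
    if not det_idx:
        raise BalanceError("flow network requires a detritus compartment")

    for j, g in enumerate(model.groups):
        if g.is_consumer:
            resp = Q[j] * (1 - GS[j]) - P[j]
            if resp < -1e-9:
                if strict:
                    raise BalanceError(
                        f"group {g.name!r}: negative respiration "
                        f"({resp:.4g}); production exceeds assimilated "
                        "intake (P/Q > 1−GS)")
                resp = 0.0
            respiration[j] = max(resp, 0.0)
            to_det = GS[j] * Q[j] + (1 - EE[j]) * P[j]
        elif g.is_producer:
            imports[j] = P[j]  # primary production enters as exogenous input
            to_det = (1 - EE[j]) * P[j]
        else:
            imports[j] += g.detritus_import
            continue
        # route to the (first) detritus pool; multi-detritus splits would
        # need an explicit detritus-fate matrix, out of scope here
        T[j, det_idx[0]] += max(to_det, 0.0)

    # detrital surplus leaves the system (steady state, no accumulation)
    for d in det_idx:
        inflow = T[:, d].sum() + imports[d]
        consumed = T[d, :].sum()
        exports[d] += max(inflow - consumed, 0.0)

    return FlowNetwork(list(names), cats, T, imports, exports, respiration)
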