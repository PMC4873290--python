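"""Core domain types for static mass-balance food-web models.

A model is a set of functional groups (consumers, producers, one or more
detritus pools) plus a diet-composition matrix. For every living group the
balance identity

    B_i * (P/B)_i * EE_i = sum_j B_j * (Q/B)_j * DC[i, j] + Y_i + E_i + BA_i

partitions production into predation, fishery landings, net migration and
biomass accumulation. Three of the four basic parameters (B, P/B, Q/B, EE)
must be supplied per group; the solver estimates the fourth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

CONSUMER = "consumer"
PRODUCER = "producer"
DETRITUS = "detritus"
CATEGORIES = (CONSUMER, PRODUCER, DETRITUS)

#: Canonical default for the unassimilated fraction of consumption.
DEFAULT_GS = 0.2

DIET_TOL = 1e-6


@dataclass
class GroupInput:
    """Basic parameters of one functional group.

    Units: biomass t·km⁻²; pb and qb yr⁻¹; landings, ba, migration and
    detritus_import t·km⁻²·yr⁻¹; ee and gs dimensionless. ``None`` marks an
    unknown to be estimated by the solver (at most one of biomass/pb/ee per
    living group).
    """

    name: str
    category: str = CONSUMER
    biomass: float | None = None
    pb: float | None = None
    qb: float | None = None
    ee: float | None = None
    landings: float = 0.0
    gs: float | None = None
    ba: float = 0.0
    migration: float = 0.0
    detritus_import: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"group {self.name!r}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )

    # -- convenience predicates -------------------------------------------
    @property
    def is_consumer(self) -> bool:
        return self.category == CONSUMER

    @property
    def is_producer(self) -> bool:
        return self.category == PRODUCER

    @property
    def is_detritus(self) -> bool:
        return self.category == DETRITUS

    @property
    def is_living(self) -> bool:
        return self.category != DETRITUS

    def gs_or_default(self, default: float = DEFAULT_GS) -> float:
        """Unassimilated fraction, falling back to the global default."""
        if not self.is_consumer:
            return 0.0
        return default if self.gs is None else self.gs


class DietMatrix:
    """Prey × predator diet-fraction matrix.

    ``values[i, j]`` is the fraction of prey ``i`` (by wet weight) in the
    diet of predator ``j``; every consumer column sums to one together with
    the optional import fraction (food taken from outside the system,
    ``import_row[j]``). Producer and detritus columns are all-zero.
    """

    def __init__(
        self,
        names: Sequence[str],
        values: np.ndarray,
        import_row: np.ndarray | None = None,
    ) -> None:
        self.names = list(names)
        values = np.asarray(values, dtype=float)
        n = len(self.names)
        if values.shape != (n, n):
            raise ValueError(
                f"diet matrix shape {values.shape} does not match "
                f"{n} group names"
            )
        self.values = values
        if import_row is None:
            import_row = np.zeros(n)
        self.import_row = np.asarray(import_row, dtype=float)
        if self.import_row.shape != (n,):
            raise ValueError("import row length does not match group count")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DietMatrix):
            return NotImplemented
        return (
            self.names == other.names
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.import_row, other.import_row)
        )

    def column_sums(self) -> np.ndarray:
        """Diet column totals including the import fraction."""
        return self.values.sum(axis=0) + self.import_row

    def reorder(self, names: Sequence[str]) -> "DietMatrix":
        idx = [self.names.index(n) for n in names]
        return DietMatrix(
            [self.names[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.import_row[idx],
        )


@dataclass
class EcopathInputs:
    """A complete model specification: ordered groups plus an aligned diet."""

    groups: list[GroupInput]
    diet: DietMatrix

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if names != self.diet.names:
            raise ValueError("diet matrix group order does not match groups")

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def n(self) -> int:
        return len(self.groups)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def categories(self) -> list[str]:
        return [g.category for g in self.groups]

    def living_mask(self) -> np.ndarray:
        return np.array([g.is_living for g in self.groups])

    def consumer_mask(self) -> np.ndarray:
        return np.array([g.is_consumer for g in self.groups])

    def producer_mask(self) -> np.ndarray:
        return np.array([g.is_producer for g in self.groups])

    def permuted(self, order: Sequence[int]) -> "EcopathInputs":
        """Same model with groups listed in a different order."""
        groups = [replace(self.groups[i]) for i in order]
        return EcopathInputs(groups, self.diet.reorder([g.name for g in groups]))


@dataclass
class Diagnostic:
    severity: str  # "error" | "warning"
    where: str     # group or column name, or "" for model-level issues
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.where}: {self.message}"


@dataclass
class BalancedModel:
    """A solved model: every living group carries all four basic parameters.

    ``residuals`` holds the per-group balance residual (t·km⁻²·yr⁻¹) and
    ``warnings`` lists diagnostics such as out-of-range ecotrophic
    efficiencies. EE > 1 is reported, never clipped: it flags an unbalanced
    model in which predation plus catch exceeds production.
    """

    groups: list[GroupInput]
    diet: DietMatrix
    residuals: np.ndarray
    warnings: list[Diagnostic] = field(default_factory=list)
    detritus_ee: dict[str, float] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def balanced(self) -> bool:
        return not any(w.severity == "warning" and "EE" in w.message
                       for w in self.warnings)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group(self, name: str) -> GroupInput:
        return self.groups[self.index(name)]

    def categories(self) -> list[str]:
        return [g.category for g in self.groups]

    def biomasses(self) -> np.ndarray:
        return np.array([g.biomass if g.biomass is not None else np.nan
                         for g in self.groups])

    def as_inputs(self) -> EcopathInputs:
        return EcopathInputs([replace(g) for g in self.groups], self.diet)


def validate_inputs(inputs: EcopathInputs) -> list[Diagnostic]:
    """Check an input model against the type invariants.

    Returns a list of diagnostics (empty iff the inputs are solvable); never
    raises on content. Errors mark conditions that make the balance
    unsolvable (two unknowns in one group, diet columns not summing to one,
    missing Q/B on a consumer); warnings mark suspicious but solvable input.
    """
    diags: list[Diagnostic] = []
    names = [g.name for g in inputs.groups]

    seen: set[str] = set()
    for name in names:
        if name in seen:
            diags.append(Diagnostic("error", name, "duplicate group name"))
        seen.add(name)

    n_producers = sum(g.is_producer for g in inputs.groups)
    n_detritus = sum(g.is_detritus for g in inputs.groups)
    if n_producers < 1:
        diags.append(Diagnostic("error", "", "model needs at least one producer"))
    if n_detritus < 1:
        diags.append(Diagnostic("error", "", "model needs a detritus group"))

    for g in inputs.groups:
        for label, value in (("biomass", g.biomass), ("pb", g.pb),
                             ("qb", g.qb), ("ee", g.ee),
                             ("landings", g.landings),
                             ("detritus_import", g.detritus_import)):
            if value is not None and value < 0:
                diags.append(Diagnostic("error", g.name,
                                        f"{label} must be non-negative"))
        if g.gs is not None and not (0 <= g.gs < 1):
            diags.append(Diagnostic("error", g.name, "gs must be in [0, 1)"))

        if g.is_consumer:
            if g.qb is None:
                diags.append(Diagnostic("error", g.name,
                                        "consumer requires qb"))
            unknowns = [lbl for lbl, v in
                        (("biomass", g.biomass), ("pb", g.pb), ("ee", g.ee))
                        if v is None]
            if len(unknowns) > 1:
                diags.append(Diagnostic(
                    "error", g.name,
                    f"two unknowns in one group ({', '.join(unknowns)}); "
                    "at most one of biomass/pb/ee may be missing"))
        elif g.is_producer:
            if g.qb is not None:
                diags.append(Diagnostic("error", g.name,
                                        "producer must not have qb"))
            if g.gs is not None:
                diags.append(Diagnostic("error", g.name,
                                        "producer must not have gs"))
            unknowns = [lbl for lbl, v in
                        (("biomass", g.biomass), ("pb", g.pb), ("ee", g.ee))
                        if v is None]
            if len(unknowns) > 1:
                diags.append(Diagnostic(
                    "error", g.name,
                    f"two unknowns in one group ({', '.join(unknowns)})"))
        else:  # detritus
            for lbl, v in (("pb", g.pb), ("qb", g.qb), ("ee", g.ee)):
                if v is not None:
                    diags.append(Diagnostic(
                        "error", g.name,
                        f"detritus must not have {lbl} as input"))
            if g.biomass is None:
                diags.append(Diagnostic("warning", g.name,
                                        "detritus biomass unset"))

    # diet matrix checks
    dm = inputs.diet
    if (dm.values < -DIET_TOL).any() or (dm.values > 1 + DIET_TOL).any():
        diags.append(Diagnostic("error", "", "diet fractions outside [0, 1]"))
    if (dm.import_row < -DIET_TOL).any() or (dm.import_row > 1 + DIET_TOL).any():
        diags.append(Diagnostic("error", "", "import fractions outside [0, 1]"))
    sums = dm.column_sums()
    for j, g in enumerate(inputs.groups):
        if g.is_consumer:
            if abs(sums[j] - 1.0) > DIET_TOL:
                diags.append(Diagnostic(
                    "error", g.name,
                    f"diet column ≠ 1 (sums to {sums[j]:.6f})"))
        else:
            if sums[j] > DIET_TOL:
                diags.append(Diagnostic(
                    "error", g.name,
                    "non-consumer diet column must be all-zero"))
    return diags


def has_errors(diags: Iterable[Diagnostic]) -> bool:
    return any(d.severity == "error" for d in diags)
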