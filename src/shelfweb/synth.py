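"""Synthetic inputs with the statistical structure the pipeline assumes.

The food-web generator emulates a tropical-shelf model of ~25 functional
groups: a couple of producer groups, one detritus pool, and consumers
arranged in trophic bands that only feed on strictly lower bands plus
detritus. Gross efficiencies P/Q are drawn in a physiologically plausible
band, diet columns sum to one by construction, and biomasses are adjusted
bottom-up so every ecotrophic efficiency lands at or below a configurable
cap (0.98 by default, leaving margin so floating-point noise in tests never
tips a fixture into "unbalanced"). The interview generator produces noisy
lognormal observations of true parameters over two Delphi rounds, with
round-2 answers shrunk toward the round-1 median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DietMatrix, EcopathInputs, GroupInput
from .elicitation import InterviewRecord


@dataclass
class WebGenConfig:
    n_groups: int = 25
    n_producers: int = 2
    n_detritus: int = 1
    n_bands: int = 4                    # consumer trophic bands
    link_density: float = 0.5           # chance of a feasible prey link
    diet_concentration: float = 1.0     # Dirichlet concentration
    pq_band: tuple[float, float] = (0.1, 0.3)
    producer_pb: tuple[float, float] = (10.0, 80.0)
    producer_biomass: tuple[float, float] = (20.0, 100.0)
    detritus_biomass: tuple[float, float] = (50.0, 300.0)
    consumer_biomass: tuple[float, float] = (2.0, 20.0)
    biomass_decay: float = 0.3          # per-band biomass shrink factor
    qb_base: tuple[float, float] = (10.0, 50.0)
    qb_decay: float = 0.5               # per-band Q/B shrink factor
    landings_fraction: float = 0.1      # share of production caught, top bands
    detritus_diet: float = 0.3          # max detritus share for band-1 diets
    ee_cap: float = 0.98
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_groups < self.n_producers + self.n_detritus + 2:
            raise ValueError("n_groups too small for the requested structure")
        lo, hi = self.pq_band
        if not (0 < lo <= hi < 1):
            raise ValueError("pq_band must lie inside (0, 1)")
        if not (0 < self.ee_cap < 1):
            raise ValueError("ee_cap must be in (0, 1)")


@dataclass
class SyntheticWeb:
    """A generated model plus its construction-time ground truth."""

    inputs: EcopathInputs
    true_ee: dict[str, float]
    bands: dict[str, int] = field(default_factory=dict)


def generate_foodweb(config: WebGenConfig) -> SyntheticWeb:
    """Draw a mass-balanced food web; deterministic for a fixed seed.

    The returned inputs leave EE unset for every living group (the standard
    one-unknown pattern), so running the solver on them must recover the
    ground-truth EE stored alongside.
    """
    rng = np.random.default_rng(config.seed)
    n_cons = config.n_groups - config.n_producers - config.n_detritus

    names, cats, bands = [], [], []
    for p in range(config.n_producers):
        names.append(f"producer_{p + 1}")
        cats.append("producer")
        bands.append(0)
    for d in range(config.n_detritus):
        names.append(f"detritus_{d + 1}")
        cats.append("detritus")
        bands.append(0)
    per_band = np.array_split(np.arange(n_cons), config.n_bands)
    for b, chunk in enumerate(per_band, start=1):
        for c in chunk:
            names.append(f"consumer_b{b}_{c + 1}")
            cats.append("consumer")
            bands.append(b)
    n = len(names)
    bands_arr = np.array(bands)
    is_cons = np.array([c == "consumer" for c in cats])
    is_prod = np.array([c == "producer" for c in cats])
    is_det = np.array([c == "detritus" for c in cats])

    PB = np.zeros(n)
    QB = np.zeros(n)
    B = np.zeros(n)
    B[is_prod] = rng.uniform(*config.producer_biomass, is_prod.sum())
    B[is_det] = rng.uniform(*config.detritus_biomass, is_det.sum())
    PB[is_prod] = rng.uniform(*config.producer_pb, is_prod.sum())
    for i in range(n):
        if not is_cons[i]:
            continue
        band = bands_arr[i]
        QB[i] = rng.uniform(*config.qb_base) * config.qb_decay ** (band - 1)
        PB[i] = rng.uniform(*config.pq_band) * QB[i]
        lo, hi = config.consumer_biomass
        decay = config.biomass_decay ** (band - 1)
        B[i] = rng.uniform(lo, hi) * decay

    # diets: strictly lower bands plus detritus
    DC = np.zeros((n, n))
    for j in range(n):
        if not is_cons[j]:
            continue
        feasible = np.flatnonzero((bands_arr < bands_arr[j]) & ~is_det)
        chosen = feasible[rng.random(feasible.size) < config.link_density]
        if chosen.size == 0:
            chosen = rng.choice(feasible, size=1)
        frac = rng.dirichlet(np.full(chosen.size, config.diet_concentration))
        det_share = rng.uniform(0, config.detritus_diet) \
            if bands_arr[j] == 1 else 0.0
        DC[chosen, j] = (1 - det_share) * frac
        if det_share > 0:
            d = int(np.flatnonzero(is_det)[0])
            DC[d, j] = det_share

    # harvest the top two bands
    top = bands_arr >= config.n_bands - 1
    harvested = is_cons & top

    # bottom-up biomass fix: predators of a group sit in strictly higher
    # bands, so one descending pass settles every EE at or below the cap
    f = config.landings_fraction
    for band in range(config.n_bands, -1, -1):
        for i in np.flatnonzero(bands_arr == band):
            if is_det[i] or PB[i] == 0:
                continue
            pred = float(DC[i, :] @ (B * QB))
            min_b = pred / ((config.ee_cap - (f if harvested[i] else 0.0))
                            * PB[i]) if pred > 0 else 0.0
            if B[i] < min_b:
                B[i] = min_b * 1.0000001

    Y = np.where(harvested, f * B * PB, 0.0)
    demand = DC @ (B * QB) + Y
    with np.errstate(divide="ignore", invalid="ignore"):
        EE = np.where(B * PB > 0, demand / (B * PB), 0.0)
    EE[is_det] = 0.0
    if (EE > config.ee_cap + 1e-9).any():
        raise RuntimeError("generator failed to cap ecotrophic efficiency")

    groups = []
    for i in range(n):
        if is_det[i]:
            groups.append(GroupInput(names[i], "detritus", biomass=B[i]))
        elif is_prod[i]:
            groups.append(GroupInput(names[i], "producer", biomass=B[i],
                                     pb=PB[i]))
        else:
            groups.append(GroupInput(names[i], "consumer", biomass=B[i],
                                     pb=PB[i], qb=QB[i], landings=float(Y[i])))
    inputs = EcopathInputs(groups, DietMatrix(names, DC))
    return SyntheticWeb(inputs, dict(zip(names, EE)),
                        dict(zip(names, bands)))


def generate_interviews(true_params: dict[tuple[str, str], float],
                        n_fishers: int, cv: float,
                        seed: int | None = None,
                        round2_shrink: float = 0.5) -> list[InterviewRecord]:
    """Two-round Delphi interviews as noisy observations of true values.

    Round-1 responses are truth × lognormal(mean 1, coefficient of
    variation ``cv``); round-2 responses move toward the round-1 median by
    ``round2_shrink`` (Delphi convergence), so round-2 dispersion never
    exceeds round-1 dispersion.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[InterviewRecord] = []
    sig = np.sqrt(np.log(1 + cv ** 2)) if cv > 0 else 0.0
    for (species, parameter), truth in sorted(true_params.items()):
        noise = (rng.lognormal(-0.5 * sig ** 2, sig, n_fishers)
                 if cv > 0 else np.ones(n_fishers))
        r1 = truth * noise
        med = float(np.median(r1))
        r2 = med + round2_shrink * (r1 - med)
        for fid in range(n_fishers):
            records.append(InterviewRecord(
                f"fisher_{fid + 1:02d}", 1, species, parameter,
                float(r1[fid])))
            records.append(InterviewRecord(
                f"fisher_{fid + 1:02d}", 2, species, parameter,
                float(r2[fid])))
    return records
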