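"""Bundled example data.

``baia_formosa_groups`` carries the basic inputs of a 25-compartment
mass-balance model of the small-scale fishery on the tropical Brazilian
northeast shelf (Baía Formosa region), in two parameterizations of the same
web: one from fishers' expert knowledge ("fk") and one from literature data
("sc"). Only the basic parameter table is bundled; the corresponding
diet-composition matrices are not available in a transcribable form, so
pipeline demonstrations pair these groups with a clearly labelled synthetic
diet from :func:`synthetic_shelf_diet`.
"""

from __future__ import annotations

import numpy as np

from .core import DietMatrix, EcopathInputs, GroupInput

# name, category, B (t·km⁻²), P/B sc, P/B fk, Q/B sc, Q/B fk, EE sc, EE fk
# (EE columns are the published model outputs, kept for plausibility
# checks; they are not inputs)
_BAIA_FORMOSA = [
    ("Dogfish", "consumer", 0.055, 0.84, 0.61, 5.70, 6.46, 0.43, 0.37),
    ("Thunnus atlanticus", "consumer", 1.200, 0.54, 0.53, 7.22, 9.50, 0.45, 0.66),
    ("Grouper", "consumer", 0.478, 0.74, 0.35, 3.20, 3.92, 0.59, 0.16),
    ("Scomberomorus brasiliensis", "consumer", 1.243, 1.11, 0.32, 5.70, 9.22, 0.60, 0.82),
    ("Lutjanus spp", "consumer", 2.291, 0.87, 0.44, 4.90, 6.32, 0.11, 0.65),
    ("Seriola fasciata", "consumer", 0.430, 0.52, 0.42, 3.81, 4.51, 0.98, 0.91),
    ("Coryphaena hippurus", "consumer", 0.672, 1.78, 1.66, 3.80, 5.07, 0.46, 0.66),
    ("Euthynnus alletteratus", "consumer", 0.397, 0.77, 0.43, 7.10, 11.25, 0.92, 1.00),
    ("Cynoscion jamaicensis", "consumer", 0.195, 0.56, 0.64, 7.30, 4.48, 0.68, 0.18),
    ("Scomberomorus cavalla", "consumer", 0.250, 0.81, 0.29, 4.50, 12.67, 0.67, 0.92),
    ("Dolphins", "consumer", 0.014, 0.68, 0.68, 35.50, 35.50, 0.13, 0.00),
    ("Sharks", "consumer", 0.064, 0.26, 0.26, 3.57, 3.57, 0.32, 0.00),
    ("Large pelagics", "consumer", 0.510, 0.39, 0.39, 7.30, 7.30, 0.58, 0.06),
    ("Medium pelagics", "consumer", 1.600, 0.63, 0.63, 5.06, 5.06, 0.98, 0.96),
    ("Small pelagics", "consumer", 4.475, 4.41, 4.41, 12.71, 12.71, 0.72, 0.96),
    ("Carnivorous reef fishes", "consumer", 4.630, 0.63, 0.63, 6.37, 6.37, 0.78, 0.93),
    ("Omnivorous reef fishes", "consumer", 4.670, 1.44, 1.44, 8.52, 8.52, 0.88, 0.69),
    ("Demersal fishes", "consumer", 2.500, 0.68, 0.68, 7.50, 7.50, 0.75, 0.15),
    ("Cephalopods", "consumer", 3.800, 1.88, 1.88, 10.70, 10.70, 0.83, 0.98),
    ("Carnivorous zoobenthos", "consumer", 5.700, 2.50, 2.50, 10.00, 10.00, 0.96, 0.91),
    ("Detritivorous zoobenthos", "consumer", 13.430, 2.61, 2.61, 13.02, 13.02, 0.75, 0.75),
    ("Zooplankton", "consumer", 14.078, 40.00, 40.00, 165.00, 165.00, 0.16, 0.25),
    ("Macroalgae", "producer", 98.450, 13.25, 13.25, None, None, 0.05, 0.02),
    ("Phytoplankton", "producer", 35.000, 70.00, 70.00, None, None, 0.97, 0.97),
    ("Detritus", "detritus", 201.910, None, None, None, None, 0.06, 0.29),
]


def baia_formosa_groups(model: str = "sc") -> list[GroupInput]:
    """Basic inputs (B, P/B, Q/B) of the shelf-fishery web; EE left unset
    so the solver estimates it. ``model`` selects the "sc" (science-based)
    or "fk" (fishers'-knowledge) parameterization."""
    if model not in ("sc", "fk"):
        raise ValueError("model must be 'sc' or 'fk'")
    col = 0 if model == "sc" else 1
    groups = []
    for name, cat, b, pb_sc, pb_fk, qb_sc, qb_fk, _, _ in _BAIA_FORMOSA:
        pb = (pb_sc, pb_fk)[col]
        qb = (qb_sc, qb_fk)[col]
        groups.append(GroupInput(name, cat, biomass=b, pb=pb, qb=qb))
    return groups


def baia_formosa_published_ee(model: str = "sc") -> dict[str, float]:
    """Published ecotrophic efficiencies (model outputs, for plausibility
    comparison only)."""
    col = 7 if model == "sc" else 8
    return {row[0]: row[col] for row in _BAIA_FORMOSA}


def synthetic_shelf_diet(groups: list[GroupInput],
                         seed: int = 0) -> DietMatrix:
    """SYNTHETIC diet matrix for the shelf-fishery group list.

    The real diet-composition matrices of this fishery are not bundled;
    this stand-in only reproduces coarse qualitative structure (piscivores
    eat smaller fish and cephalopods, zoobenthos and zooplankton feed low,
    detritivores use detritus) so that full-pipeline examples can run. Any
    trophic statistic computed from it is illustrative, not a reproduction
    of the published models.
    """
    rng = np.random.default_rng(seed)
    names = [g.name for g in groups]
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    dc = np.zeros((n, n))

    low = ["Small pelagics", "Omnivorous reef fishes", "Demersal fishes",
           "Cephalopods", "Carnivorous zoobenthos",
           "Detritivorous zoobenthos", "Zooplankton"]
    piscivores = ["Dogfish", "Thunnus atlanticus", "Grouper",
                  "Scomberomorus brasiliensis", "Lutjanus spp",
                  "Seriola fasciata", "Coryphaena hippurus",
                  "Euthynnus alletteratus", "Cynoscion jamaicensis",
                  "Scomberomorus cavalla", "Dolphins", "Sharks",
                  "Large pelagics", "Medium pelagics",
                  "Carnivorous reef fishes"]
    prey_of = {p: low for p in piscivores}
    prey_of.update({
        "Small pelagics": ["Zooplankton", "Phytoplankton"],
        "Omnivorous reef fishes": ["Macroalgae", "Detritivorous zoobenthos",
                                   "Detritus"],
        "Demersal fishes": ["Detritivorous zoobenthos",
                            "Carnivorous zoobenthos", "Detritus"],
        "Cephalopods": ["Small pelagics", "Detritivorous zoobenthos",
                        "Carnivorous zoobenthos"],
        "Carnivorous zoobenthos": ["Detritivorous zoobenthos", "Zooplankton",
                                   "Detritus"],
        "Detritivorous zoobenthos": ["Detritus", "Macroalgae"],
        "Zooplankton": ["Phytoplankton", "Detritus"],
    })
    for pred, prey in prey_of.items():
        cols = [idx[p] for p in prey if p != pred]
        frac = rng.dirichlet(np.ones(len(cols)) * 2.0)
        dc[cols, idx[pred]] = frac
    return DietMatrix(names, dc)


def baia_formosa_inputs(model: str = "sc", seed: int = 0) -> EcopathInputs:
    """Shelf-fishery groups paired with the synthetic diet stand-in."""
    groups = baia_formosa_groups(model)
    return EcopathInputs(groups, synthetic_shelf_diet(groups, seed=seed))
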