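"""Empirical life-history estimators for P/B and Q/B inputs.

Standard fisheries shortcuts for data-poor parameterization: asymptotic
length from maximum observed length, length–weight conversion, natural
mortality from growth and temperature (used as P/B at equilibrium), and
consumption rate from asymptotic weight, temperature, caudal-fin aspect
ratio and feeding habit. All estimators are log-linear; every published
coefficient set ships as an overridable preset because different editions
of these regressions circulate in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: log10 L∞ = a + b·log10 Lmax  (asymptotic length from max length)
LINF_COEFFS = {"froese_binohlan": (0.044, 0.9841)}

#: log10 M = c0 + cL·log10 L∞ + cK·log10 K + cT·log10 T
M_COEFFS = {"pauly": (-0.0066, -0.279, 0.6543, 0.4634)}

#: log10 Q/B = c0 + cW·log10 W∞ + cT·(1000/(T+273.15)) + cA·A + ch·h + cd·d
QB_COEFFS = {"palomares_pauly": (7.964, -0.204, -1.965, 0.083, 0.532, 0.398)}


@dataclass
class LifeHistory:
    """Per-species life-history inputs (lengths cm, weights g, K yr⁻¹,
    temperature °C)."""

    name: str = ""
    lmax: float | None = None
    linf: float | None = None
    winf: float | None = None
    k: float | None = None
    temperature: float = 27.0  # tropical shelf default; override in config
    lw_a: float = 0.01
    lw_b: float = 3.0
    aspect_ratio: float = 1.5
    herbivore: bool = False
    detritivore: bool = False


def _require_positive(**values: float) -> None:
    for label, v in values.items():
        if v is None or v <= 0:
            raise ValueError(f"{label} must be positive, got {v!r}")


def linf_from_lmax(lmax: float, preset: str = "froese_binohlan",
                   coeffs: tuple[float, float] | None = None) -> float:
    """Asymptotic length (cm) from maximum observed length (cm)."""
    _require_positive(lmax=lmax)
    a, b = coeffs if coeffs is not None else LINF_COEFFS[preset]
    return 10.0 ** (a + b * math.log10(lmax))


def length_weight(length: float, lw_a: float, lw_b: float) -> float:
    """Weight (g) from length (cm): W = a·L^b."""
    _require_positive(length=length, lw_a=lw_a, lw_b=lw_b)
    return lw_a * length ** lw_b


def weight_to_length(weight: float, lw_a: float, lw_b: float) -> float:
    """Inverse length–weight conversion (exact round trip)."""
    _require_positive(weight=weight, lw_a=lw_a, lw_b=lw_b)
    return (weight / lw_a) ** (1.0 / lw_b)


def pauly_m(linf: float, k: float, temperature: float,
            preset: str = "pauly",
            coeffs: tuple[float, float, float, float] | None = None) -> float:
    """Natural mortality M (yr⁻¹) from L∞ (cm), von Bertalanffy K (yr⁻¹) and
    mean habitat temperature (°C); used as P/B at equilibrium."""
    _require_positive(linf=linf, k=k, temperature=temperature)
    c0, cl, ck, ct = coeffs if coeffs is not None else M_COEFFS[preset]
    return 10.0 ** (c0 + cl * math.log10(linf) + ck * math.log10(k)
                    + ct * math.log10(temperature))


def palomares_pauly_qb(winf: float, temperature: float,
                       aspect_ratio: float = 1.5,
                       herbivore: bool = False, detritivore: bool = False,
                       preset: str = "palomares_pauly",
                       coeffs: tuple[float, ...] | None = None) -> float:
    """Consumption rate Q/B (yr⁻¹) from asymptotic weight (g), temperature
    (°C), caudal-fin aspect ratio and feeding-habit flags."""
    _require_positive(winf=winf, temperature=temperature)
    if aspect_ratio <= 0:
        raise ValueError(f"aspect_ratio must be positive, got {aspect_ratio}")
    c0, cw, ct, ca, ch, cd = (coeffs if coeffs is not None
                              else QB_COEFFS[preset])
    t_prime = 1000.0 / (temperature + 273.15)
    return 10.0 ** (c0 + cw * math.log10(winf) + ct * t_prime
                    + ca * aspect_ratio + ch * float(herbivore)
                    + cd * float(detritivore))


def estimate_pb_qb(lh: LifeHistory) -> tuple[float, float]:
    """Run the full estimator chain for one species.

    Fills L∞ from Lmax if needed, W∞ from L∞ via the length–weight
    coefficients, then returns (P/B, Q/B).
    """
    linf = lh.linf
    if linf is None:
        if lh.lmax is None:
            raise ValueError(f"{lh.name}: need lmax or linf")
        linf = linf_from_lmax(lh.lmax)
    winf = lh.winf
    if winf is None:
        winf = length_weight(linf, lh.lw_a, lh.lw_b)
    if lh.k is None:
        raise ValueError(f"{lh.name}: need von Bertalanffy K for P/B")
    pb = pauly_m(linf, lh.k, lh.temperature)
    qb = palomares_pauly_qb(winf, lh.temperature, lh.aspect_ratio,
                            lh.herbivore, lh.detritivore)
    return pb, qb
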