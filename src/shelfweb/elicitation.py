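"""Delphi-style expert elicitation: records, consensus, aggregation, and
the small statistical utilities used to compare expert-derived and
literature-derived model inputs.

The protocol is a two-round Delphi: experts answer individually, see the
pooled first-round answers, and may revise. A later-round answer from the
same expert supersedes the earlier one for the same item. Consensus is
declared when at least a threshold fraction (default 50%) of experts give
the same answer — verbatim for categorical items, within a relative band
of the median for numeric ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy import stats

#: answers ingested but excluded from parameter export by default because
#: experts systematically cannot observe them (daily ration, longevity,
#: absolute stock size, absolute annual catch)
UNRELIABLE_PARAMETERS = frozenset(
    {"food_per_day", "longevity", "stock_qualitative", "catch_qualitative"})


@dataclass
class InterviewRecord:
    fisher_id: str
    round: int
    species: str
    parameter: str
    value: float | str
    units: str = ""

    def __post_init__(self) -> None:
        if self.round < 1:
            raise ValueError("round must be ≥ 1")
        if isinstance(self.value, (int, float)) and self.value < 0:
            raise ValueError("numeric responses must be non-negative")


@dataclass
class ConsensusResult:
    species: str
    parameter: str
    n_respondents: int
    agreeing_fraction: float
    consensual: bool
    consensus_value: float | str | None


def latest_round(records: list[InterviewRecord]) -> list[InterviewRecord]:
    """Keep each expert's most recent answer per species × parameter."""
    best: dict[tuple[str, str, str], InterviewRecord] = {}
    for rec in records:
        key = (rec.fisher_id, rec.species, rec.parameter)
        if key not in best or rec.round > best[key].round:
            best[key] = rec
    return list(best.values())


def _by_item(records: list[InterviewRecord]):
    items: dict[tuple[str, str], list[InterviewRecord]] = {}
    for rec in latest_round(records):
        items.setdefault((rec.species, rec.parameter), []).append(rec)
    return items


def consensus(records: list[InterviewRecord], threshold: float = 0.5,
              numeric_band: float = 0.2) -> list[ConsensusResult]:
    """Consensus state per species × parameter.

    Categorical items agree when identical; numeric items agree when within
    ``numeric_band`` (relative) of the respondent median. Consensual iff
    the agreeing share reaches ``threshold`` (≥, so 12 of 23 passes a 50%
    threshold and 11 of 23 does not).
    """
    results = []
    for (species, parameter), recs in sorted(_by_item(records).items()):
        values = [r.value for r in recs]
        n = len(values)
        if all(isinstance(v, (int, float)) for v in values):
            med = median(values)
            if med == 0:
                agree = [v for v in values if v == 0]
            else:
                agree = [v for v in values
                         if abs(v - med) <= numeric_band * abs(med)]
            frac = len(agree) / n
            value = float(np.mean(agree)) if agree else None
        else:
            counts = Counter(str(v) for v in values)
            value, top = counts.most_common(1)[0]
            frac = top / n
        results.append(ConsensusResult(species, parameter, n, frac,
                                       frac >= threshold, value))
    return results


def aggregate_responses(records: list[InterviewRecord]) -> list[dict]:
    """Mean, sample SD (n−1) and n per numeric species × parameter item."""
    rows = []
    for (species, parameter), recs in sorted(_by_item(records).items()):
        values = [r.value for r in recs
                  if isinstance(r.value, (int, float))]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        rows.append({
            "species": species, "parameter": parameter,
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
            "n": len(arr),
        })
    return rows


def export_parameters(records: list[InterviewRecord],
                      include_unreliable: bool = False) -> list[dict]:
    """Aggregated numeric answers suitable as model inputs, dropping the
    known-unreliable parameters unless asked to keep them."""
    rows = aggregate_responses(records)
    if include_unreliable:
        return rows
    return [r for r in rows if r["parameter"] not in UNRELIABLE_PARAMETERS]


def mention_frequency(records: list[InterviewRecord],
                      species_list: list[str]) -> dict[str, float]:
    """Share of species-choice mentions per species, in percent (1 dp)."""
    mentions = [r.species for r in records]
    total = len(mentions)
    if total == 0:
        raise ValueError("no species-choice records")
    counts = Counter(mentions)
    return {s: round(100.0 * counts.get(s, 0) / total, 1)
            for s in species_list}


def spearman_rank(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def paired_t(x, y) -> tuple[float, int]:
    """Paired t statistic and degrees of freedom n − 1.

    Zero-variance nonzero differences return a signed infinity sentinel;
    identical vectors return t = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length ≥ 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
    return t, n - 1
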