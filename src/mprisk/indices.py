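"""Three-tier ecological risk assessment for microplastic surveys.

Per sample i with abundance C_i and reference minimum C_oi (the smallest
abundance observed in the same compartment):

    PLI_i = C_i / C_oi                     pollution load index
    H_i   = sum_n P_n * S_n                polymer hazard index
    PRI_i = H_i * PLI_i                    pollution risk index

where P_n is the fraction of polymer n among the sample's identified
particles and S_n its hazard score.  Zone-level values are geometric means
of the per-sample values over each compartment's sampling points, so
PRI_zone = H_zone * PLI_zone holds identically.

Risk categories: PLI > 1 is "polluted"; H falls in bands I-V at thresholds
(10, 100, 1000, 10000); PRI falls in minor/medium/considerable/high/danger
bands at thresholds (150, 300, 600, 1200).  Bands are half-open [lo, hi) so
they partition (0, inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .concentration import Abundance, campaign_abundances
from .distributions import polymer_fractions
from .field_data import Campaign, Compartment, Polymer

__all__ = [
    "DEFAULT_HAZARD_SCORES",
    "TABLE_SCHEME",
    "RiskCategoryScheme",
    "IndexResult",
    "ZoneSummary",
    "Assessment",
    "load_hazard_scores",
    "pli",
    "geometric_mean",
    "hazard_index",
    "pri",
    "categorize",
    "zone_summary",
    "assess",
]

#: Polymer hazard scores established for this survey's scoring scheme.
#: Only polypropylene and polyvinyl chloride ship as defaults; scores for
#: other polymers must be supplied via configuration (they differ between
#: published hazard rankings and are not hard-coded as authoritative).
DEFAULT_HAZARD_SCORES: dict[Polymer, float] = {
    Polymer.PP: 1.0,
    Polymer.PVC: 10001.0,
}


@dataclass(frozen=True)
class RiskCategoryScheme:
    """Banded risk categories for the three indices.

    ``h_thresholds`` separate hazard bands I-V and ``pri_thresholds``
    separate the PRI bands; both are strictly increasing and the bands are
    half-open ``[lo, hi)``, partitioning (0, inf).
    """

    h_thresholds: tuple[float, ...] = (10.0, 100.0, 1000.0, 10000.0)
    h_labels: tuple[str, ...] = ("I", "II", "III", "IV", "V")
    pri_thresholds: tuple[float, ...] = (150.0, 300.0, 600.0, 1200.0)
    pri_labels: tuple[str, ...] = ("minor", "medium", "considerable", "high", "danger")
    pli_polluted_above: float = 1.0

    def __post_init__(self) -> None:
        for name, thresholds, labels in (("h", self.h_thresholds, self.h_labels),
                                         ("pri", self.pri_thresholds, self.pri_labels)):
            if list(thresholds) != sorted(set(thresholds)):
                raise ValueError(f"{name}_thresholds must be strictly increasing")
            if len(labels) != len(thresholds) + 1:
                raise ValueError(f"{name}_labels must have one more entry than thresholds")


#: The survey's published categorization table.
TABLE_SCHEME = RiskCategoryScheme()


@dataclass(frozen=True)
class IndexResult:
    """Per-sample indices and risk categories."""

    sample_id: str
    compartment: Compartment
    c_i: float
    c_oi: float
    pli: float
    h: float
    pri: float
    pli_category: str
    h_category: str
    pri_category: str


@dataclass(frozen=True)
class ZoneSummary:
    """Geometric-mean aggregates over one compartment's sampling points."""

    compartment: Compartment
    n: int
    pli_zone: float
    h_zone: float
    pri_zone: float
    pli_category: str
    h_category: str
    pri_category: str


@dataclass(frozen=True)
class Assessment:
    """Full per-sample and zone-level risk assessment of a campaign."""

    results: list[IndexResult]
    zones: dict[Compartment, ZoneSummary]
    c_oi: dict[Compartment, float]
    notes: list[str] = field(default_factory=list)


def load_hazard_scores(path: str | Path) -> dict[Polymer, float]:
    """Read a polymer -> hazard score table from a YAML mapping."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping of polymer to score")
    scores: dict[Polymer, float] = {}
    for key, value in raw.items():
        polymer = Polymer(str(key))
        score = float(value)
        if score <= 0:
            raise ValueError(f"hazard score for {polymer.value} must be positive, got {score}")
        scores[polymer] = score
    return scores


def pli(c_i: float, c_oi: float) -> float:
    """Pollution load index: the abundance ratio C_i / C_oi, unrounded."""
    if c_oi <= 0:
        raise ValueError(f"reference abundance C_oi must be positive, got {c_oi}")
    if c_i < 0:
        raise ValueError(f"abundance C_i must be non-negative, got {c_i}")
    return c_i / c_oi


def geometric_mean(values: Sequence[float]) -> float:
    """n-th root of the product of n positive values, as exp(mean(log))."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty sequence is undefined")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def hazard_index(fractions: Mapping[Polymer, float],
                 scores: Mapping[Polymer, float]) -> float:
    """Polymer hazard index H = sum_n P_n * S_n.

    ``fractions`` must sum to 1 and every polymer present must have a score.
    """
    if not fractions:
        raise ValueError("no polymer fractions supplied")
    total = math.fsum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"polymer fractions must sum to 1, got {total!r}")
    missing = [p.value for p in fractions if p not in scores]
    if missing:
        raise ValueError(f"no hazard score for polymer(s) {missing}")
    return math.fsum(frac * scores[p] for p, frac in fractions.items())


def pri(h_i: float, pli_i: float) -> float:
    """Pollution risk index: the product H_i * PLI_i."""
    if h_i <= 0 or pli_i <= 0:
        raise ValueError(f"PRI requires positive H and PLI, got H={h_i}, PLI={pli_i}")
    return h_i * pli_i


def _band(value: float, thresholds: Sequence[float], labels: Sequence[str]) -> str:
    for threshold, label in zip(thresholds, labels):
        if value < threshold:
            return label
    return labels[-1]


def categorize(value: float, index_kind: str,
               scheme: RiskCategoryScheme = TABLE_SCHEME) -> str:
    """Risk category of an index value under half-open [lo, hi) bands."""
    if value <= 0:
        raise ValueError(f"index value must be positive, got {value}")
    kind = index_kind.upper()
    if kind == "PLI":
        return "polluted" if value > scheme.pli_polluted_above else "not polluted"
    if kind == "H":
        return _band(value, scheme.h_thresholds, scheme.h_labels)
    if kind == "PRI":
        return _band(value, scheme.pri_thresholds, scheme.pri_labels)
    raise ValueError(f"unknown index kind {index_kind!r}")


def zone_summary(results: Sequence[IndexResult],
                 scheme: RiskCategoryScheme = TABLE_SCHEME) -> ZoneSummary:
    """Geometric-mean zone aggregate of per-sample results for one compartment."""
    if not results:
        raise ValueError("no per-sample results to aggregate")
    compartments = {r.compartment for r in results}
    if len(compartments) > 1:
        raise ValueError("zone aggregation never mixes compartments")
    (compartment,) = compartments
    pli_zone = geometric_mean([r.pli for r in results])
    h_zone = geometric_mean([r.h for r in results])
    pri_zone = geometric_mean([r.pri for r in results])
    return ZoneSummary(
        compartment=compartment, n=len(results),
        pli_zone=pli_zone, h_zone=h_zone, pri_zone=pri_zone,
        pli_category=categorize(pli_zone, "PLI", scheme),
        h_category=categorize(h_zone, "H", scheme),
        pri_category=categorize(pri_zone, "PRI", scheme),
    )


def assess(campaign: Campaign,
           scores: Mapping[Polymer, float] | None = None,
           scheme: RiskCategoryScheme = TABLE_SCHEME,
           hazard_indices: Optional[Mapping[str, float]] = None) -> Assessment:
    """Per-sample PLI/H/PRI and per-compartment zone summaries for a campaign.

    The reference abundance C_oi is the minimum observed abundance within
    each compartment, so min PLI = 1 there.  H comes from each sample's
    particle polymer fractions weighted by ``scores``; where particle-level
    composition is unavailable, per-sample hazard indices may be supplied
    directly via ``hazard_indices`` (sample_id -> H), which take precedence.
    """
    if scores is None:
        scores = DEFAULT_HAZARD_SCORES
    abundances = campaign_abundances(campaign)
    by_compartment: dict[Compartment, list[Abundance]] = {}
    for a in abundances:
        by_compartment.setdefault(a.compartment, []).append(a)

    c_oi: dict[Compartment, float] = {}
    for compartment, members in by_compartment.items():
        minimum = min(a.value for a in members)
        if minimum <= 0:
            raise ValueError(f"compartment {compartment.value} has a zero-abundance sample; "
                             "C_oi would be zero")
        c_oi[compartment] = minimum

    notes: list[str] = []
    results: list[IndexResult] = []
    for a in abundances:
        if hazard_indices is not None and a.sample_id in hazard_indices:
            h_i = float(hazard_indices[a.sample_id])
            if h_i <= 0:
                raise ValueError(f"supplied hazard index for sample {a.sample_id!r} "
                                 f"must be positive, got {h_i}")
        else:
            particles = campaign.particles_of(a.sample_id)
            if not particles:
                raise ValueError(
                    f"sample {a.sample_id!r} has no particle records and no supplied "
                    "hazard index; H cannot be computed")
            h_i = hazard_index(polymer_fractions(particles), scores)
        pli_i = pli(a.value, c_oi[a.compartment])
        pri_i = pri(h_i, pli_i)
        results.append(IndexResult(
            sample_id=a.sample_id, compartment=a.compartment,
            c_i=a.value, c_oi=c_oi[a.compartment],
            pli=pli_i, h=h_i, pri=pri_i,
            pli_category=categorize(pli_i, "PLI", scheme) if pli_i > 0 else "not polluted",
            h_category=categorize(h_i, "H", scheme),
            pri_category=categorize(pri_i, "PRI", scheme),
        ))

    zones = {
        compartment: zone_summary([r for r in results if r.compartment is compartment],
                                  scheme)
        for compartment in by_compartment
    }
    for compartment, zone in zones.items():
        # The source categorization table places values below 150 in "minor"
        # and H in [10, 100) in band II; surveys sometimes label borderline
        # zone values one band up.  Record the banding actually applied.
        notes.append(f"{compartment.value}: C_oi={c_oi[compartment]:g}, "
                     f"PLI_zone={zone.pli_zone:.4f} ({zone.pli_category}), "
                     f"H_zone={zone.h_zone:.4f} (category {zone.h_category}), "
                     f"PRI_zone={zone.pri_zone:.4f} ({zone.pri_category})")
    return Assessment(results=results, zones=zones, c_oi=c_oi, notes=notes)
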