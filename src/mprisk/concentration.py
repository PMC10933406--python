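"""Abundance normalization and group statistics.

Particle counts are normalized to items/L for water samples (grab volume, or
plankton-net filtered volume from the continuity equation Q = A*V) and to
items/kg dry weight for sediment samples.  Group summaries report arithmetic
mean and sample (n-1) standard deviation; between-group differences use the
classical one-way ANOVA F test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .field_data import Campaign, Compartment, Method, NetSamplingGeometry, SampleRecord

__all__ = [
    "Abundance",
    "GroupSummary",
    "net_sample_volume",
    "abundance",
    "campaign_abundances",
    "group_summary",
    "recovery_rate",
    "one_way_anova",
]

M3_TO_L = 1000.0

UNITS = {Compartment.WATER: "items/L", Compartment.SEDIMENT: "items/kg"}


@dataclass(frozen=True)
class Abundance:
    """Normalized microplastic concentration of one sample.

    ``value`` is items/L for water and items/kg dry weight for sediment.
    ``site_id`` and ``location_group`` are carried for grouping and are
    filled in by :func:`campaign_abundances`.
    """

    sample_id: str
    compartment: Compartment
    method: Method
    value: float
    units: str
    site_id: Optional[str] = None
    location_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"abundance must be non-negative, got {self.value}")
        if self.units != UNITS[self.compartment]:
            raise ValueError(f"units {self.units!r} inconsistent with "
                             f"compartment {self.compartment.value}")


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample standard deviation of abundances within one group.

    ``sd`` is ``None`` (undefined) for singleton groups.
    """

    group: str
    n: int
    mean: float
    sd: Optional[float]


def net_sample_volume(geometry: NetSamplingGeometry) -> float:
    """Water volume (L) filtered by a plankton net: A * V * t, m^3 -> L."""
    return geometry.aperture_area * geometry.mean_velocity * geometry.duration * M3_TO_L


def abundance(sample: SampleRecord, site_id: Optional[str] = None,
              location_group: Optional[str] = None) -> Abundance:
    """Normalize a sample's particle count by its denominator.

    Water: count / grab volume (WC) or count / net filtered volume (PN),
    items/L.  Sediment: count / dry mass, items/kg dry weight.
    """
    if sample.method is Method.WC:
        denom = sample.grab_volume
    elif sample.method is Method.PN:
        denom = net_sample_volume(sample.net_geometry)
    else:
        denom = sample.dry_mass
    if denom is None:
        raise ValueError(f"sample {sample.sample_id!r} has no normalization denominator")
    if denom <= 0:
        raise ValueError(f"sample {sample.sample_id!r} has non-positive denominator {denom}")
    return Abundance(
        sample_id=sample.sample_id,
        compartment=sample.compartment,
        method=sample.method,
        value=sample.particle_count / denom,
        units=UNITS[sample.compartment],
        site_id=site_id if site_id is not None else sample.site_id,
        location_group=location_group,
    )


def campaign_abundances(campaign: Campaign) -> list[Abundance]:
    """Abundance for every sample, with site and location labels attached."""
    sites = campaign.site_by_id
    return [
        abundance(s, site_id=s.site_id,
                  location_group=sites[s.site_id].location_group.value)
        for s in campaign.samples
    ]


Grouping = Literal["site", "location", "method", "compartment"]


def _group_key(a: Abundance, grouping: Grouping) -> str:
    if grouping == "site":
        return a.site_id or ""
    if grouping == "location":
        return a.location_group or ""
    if grouping == "method":
        return a.method.value
    if grouping == "compartment":
        return a.compartment.value
    raise ValueError(f"unknown grouping {grouping!r}")


def group_summary(abundances: Sequence[Abundance],
                  grouping: Grouping = "compartment") -> list[GroupSummary]:
    """Per-group arithmetic mean and (n-1) standard deviation.

    Mixing compartments within a group is rejected except for the
    ``compartment`` grouping itself: items/L and items/kg do not average.
    """
    if not abundances:
        raise ValueError("no abundances to summarize")
    groups: dict[str, list[Abundance]] = {}
    for a in abundances:
        groups.setdefault(_group_key(a, grouping), []).append(a)
    out = []
    for label in sorted(groups):
        members = groups[label]
        if grouping != "compartment" and len({m.compartment for m in members}) > 1:
            raise ValueError(f"group {label!r} mixes water and sediment abundances; "
                             "summarize compartments separately")
        values = np.array([m.value for m in members], dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
        out.append(GroupSummary(group=label, n=len(values),
                                mean=float(values.mean()), sd=sd))
    return out


def recovery_rate(spiked_count: int, recovered_count: int) -> float:
    """QA recovery percentage: 100 * recovered / spiked."""
    if spiked_count <= 0:
        raise ValueError(f"spiked_count must be positive, got {spiked_count}")
    if not 0 <= recovered_count <= spiked_count:
        raise ValueError(f"recovered_count {recovered_count} outside [0, {spiked_count}]")
    return 100.0 * recovered_count / spiked_count


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within and its
    upper-tail p value.

    Requires at least two groups of at least two observations each.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than two observations")
    total_n = sum(g.size for g in arrays)
    if total_n <= len(arrays):
        raise ValueError("total observations must exceed the number of groups")
    result = stats.f_oneway(*arrays)
    return float(result.statistic), float(result.pvalue)
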