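"""Synthetic sampling campaigns and the packaged Raquette River fixture.

The generator draws a campaign with the statistical structure the analysis
assumes: per-sample particle counts around an expected abundance times the
sample's denominator (fixed or Poisson), and particle attributes drawn
independently from per-compartment categorical distributions (polymer,
shape, color, size class; dimension uniform within the drawn size class).

:func:`raquette_fixture` reproduces the published field survey of the
Raquette River (NY): 6 sites across a wastewater treatment plant, a
hydro-dam and the Raquette-St. Lawrence confluence; 11 water and 10
sediment samples with the printed per-sample abundances.  Per-sample hazard
indices are supplied alongside the campaign because per-sample polymer
compositions were published only as pie-chart percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .field_data import (
    Campaign,
    Color,
    Compartment,
    Method,
    NetSamplingGeometry,
    ParticleRecord,
    Polymer,
    PositionTag,
    LocationGroup,
    SampleRecord,
    SiteRecord,
)
from .distributions import SizeClass

__all__ = [
    "CategoricalSpec",
    "CompositionSpec",
    "SampleSpec",
    "CampaignConfig",
    "generate",
    "raquette_fixture",
    "raquette_config",
    "RaquetteFixture",
    "config_from_yaml",
    "config_to_yaml",
]

#: (lower, upper) µm bounds of each size class for uniform within-class draws.
_SIZE_BOUNDS: dict[SizeClass, tuple[float, float]] = {
    SizeClass.LT_50: (0.0, 50.0),
    SizeClass.FROM_50_TO_100: (50.0, 100.0),
    SizeClass.FROM_100_TO_200: (100.0, 200.0),
    SizeClass.FROM_200_TO_500: (200.0, 500.0),
    SizeClass.FROM_500_TO_5000: (500.0, 5000.0),
}


def _validate_distribution(dist: dict[str, float], name: str) -> dict[str, float]:
    if not dist:
        raise ValueError(f"{name} distribution is empty")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} distribution has negative probabilities")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} distribution sums to {total!r}, expected 1")
    return dist


class CompositionSpec(BaseModel):
    """Categorical particle-attribute distributions for one compartment."""

    model_config = ConfigDict(frozen=True)

    polymer: dict[str, float]
    shape: dict[str, float]
    color: dict[str, float]
    size_class: dict[str, float]

    @field_validator("polymer", "shape", "color", "size_class")
    @classmethod
    def _is_distribution(cls, v: dict[str, float], info) -> dict[str, float]:
        return _validate_distribution(v, info.field_name)

    @model_validator(mode="after")
    def _known_categories(self) -> "CompositionSpec":
        for value_set, dist in ((Polymer, self.polymer), (Color, self.color)):
            for key in dist:
                value_set(key)  # raises on unknown label
        for key in self.shape:
            from .field_data import Shape
            Shape(key)
        for key in self.size_class:
            SizeClass(key)
        return self


CategoricalSpec = dict[str, float]


class SiteSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    site_id: str
    location_group: LocationGroup
    position_tag: PositionTag
    latitude: float
    longitude: float
    sampled_at: datetime


class SampleSpec(BaseModel):
    """Expected abundance and denominator for one sample to generate."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    site_id: str
    compartment: Compartment
    method: Method
    expected_abundance: float  # items/L (water) or items/kg (sediment)
    grab_volume_L: Optional[float] = None
    net_area_m2: Optional[float] = None
    net_velocity_m_s: Optional[float] = None
    net_duration_s: Optional[float] = None
    dry_mass_kg: Optional[float] = None

    @field_validator("expected_abundance")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"expected_abundance must be non-negative, got {v}")
        return v

    def denominator(self) -> float:
        """Volume (L) or dry mass (kg) the count is normalized by."""
        if self.method is Method.WC:
            if self.grab_volume_L is None:
                raise ValueError(f"sample {self.sample_id!r}: grab method needs grab_volume_L")
            return self.grab_volume_L
        if self.method is Method.PN:
            if None in (self.net_area_m2, self.net_velocity_m_s, self.net_duration_s):
                raise ValueError(f"sample {self.sample_id!r}: net method needs full geometry")
            return self.net_area_m2 * self.net_velocity_m_s * self.net_duration_s * 1000.0
        if self.dry_mass_kg is None:
            raise ValueError(f"sample {self.sample_id!r}: sediment method needs dry_mass_kg")
        return self.dry_mass_kg


class CampaignConfig(BaseModel):
    """Full specification of a synthetic campaign.

    ``count_model`` "fixed" rounds expected_abundance x denominator to the
    nearest integer count (exact, reproducible abundances); "poisson" draws
    the count from Poisson with that mean.  A fixed ``seed`` makes the
    generated campaign byte-identical across runs.
    """

    model_config = ConfigDict(frozen=True)

    sites: list[SiteSpec]
    samples: list[SampleSpec]
    composition: dict[Compartment, CompositionSpec]
    count_model: Literal["fixed", "poisson"] = "fixed"
    seed: int = 0
    generate_particles: bool = True


def _draw_particles(rng: np.random.Generator, spec: SampleSpec, count: int,
                    comp: CompositionSpec) -> list[ParticleRecord]:
    polymer_labels = list(comp.polymer)
    polymer_probs = list(comp.polymer.values())
    shape_labels = list(comp.shape)
    shape_probs = list(comp.shape.values())
    color_labels = list(comp.color)
    color_probs = list(comp.color.values())
    size_labels = list(comp.size_class)
    size_probs = list(comp.size_class.values())
    particles = []
    for i in range(count):
        polymer = polymer_labels[rng.choice(len(polymer_labels), p=polymer_probs)]
        shape = shape_labels[rng.choice(len(shape_labels), p=shape_probs)]
        color = color_labels[rng.choice(len(color_labels), p=color_probs)]
        size_bin = SizeClass(size_labels[rng.choice(len(size_labels), p=size_probs)])
        lo, hi = _SIZE_BOUNDS[size_bin]
        dimension = 0.0
        while dimension <= 0.0:  # uniform on (lo, hi); guard the open lower end at 0
            dimension = lo + (hi - lo) * rng.random()
        particles.append(ParticleRecord(
            particle_id=f"{spec.sample_id}-P{i + 1:05d}",
            sample_id=spec.sample_id,
            max_dimension=dimension,
            shape=shape, color=color, polymer=polymer))
    return particles


def generate(config: CampaignConfig, seed: Optional[int] = None) -> Campaign:
    """Draw a campaign from ``config``.

    Stream order is documented and stable: samples in listed order; within a
    sample, the count first, then per particle polymer, shape, color, size
    class, dimension.  ``seed`` overrides ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sites = [SiteRecord(**s.model_dump()) for s in config.sites]
    samples: list[SampleRecord] = []
    particles: list[ParticleRecord] = []
    for spec in config.samples:
        denom = spec.denominator()
        mean_count = spec.expected_abundance * denom
        if config.count_model == "fixed":
            count = int(round(mean_count))
        else:
            count = int(rng.poisson(mean_count))
        geometry = None
        if spec.method is Method.PN:
            geometry = NetSamplingGeometry(aperture_area=spec.net_area_m2,
                                           mean_velocity=spec.net_velocity_m_s,
                                           duration=spec.net_duration_s)
        samples.append(SampleRecord(
            sample_id=spec.sample_id, site_id=spec.site_id,
            compartment=spec.compartment, method=spec.method,
            grab_volume=spec.grab_volume_L, net_geometry=geometry,
            dry_mass=spec.dry_mass_kg, particle_count=count))
        if config.generate_particles:
            particles.extend(_draw_particles(rng, spec, count,
                                             config.composition[spec.compartment]))
    return Campaign(sites=sites, samples=samples, particles=particles)


def config_from_yaml(path: str | Path) -> CampaignConfig:
    with open(path, encoding="utf-8") as fh:
        return CampaignConfig.model_validate(yaml.safe_load(fh))


def config_to_yaml(config: CampaignConfig, path: str | Path) -> None:
    data = config.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# The Raquette River survey fixture
# ---------------------------------------------------------------------------

_SITES = [
    # site_id, location_group, position_tag, latitude, longitude, sampled_at
    ("WWTP-US", "WWTP", "US", 44.680314, -74.994967, "2022-10-26T09:25:00"),
    ("WWTP-EF", "WWTP", "EF", 44.680769, -74.995053, "2022-10-26T09:30:00"),
    ("WWTP-DS", "WWTP", "DS", 44.683436, -74.997056, "2022-10-26T11:05:00"),
    ("NHD-US", "NHD", "US", 44.743161, -75.005625, "2023-09-14T09:45:00"),
    ("NHD-DS", "NHD", "DS", 44.744433, -75.004181, "2023-09-14T10:30:00"),
    ("R-STL-Con", "CONFLUENCE", "CON", 44.981056, -74.712922, "2022-09-11T10:30:00"),
]

# Published water abundances, items/L.  The effluent sample is encoded as a
# single grab sample (the survey does not say whether it was grab or net).
_WATER_ABUNDANCES = {
    ("WWTP-US", "WC"): 23, ("WWTP-US", "PN"): 26,
    ("WWTP-EF", "WC"): 25,
    ("WWTP-DS", "WC"): 13, ("WWTP-DS", "PN"): 10,
    ("NHD-US", "WC"): 27, ("NHD-US", "PN"): 23,
    ("NHD-DS", "WC"): 14, ("NHD-DS", "PN"): 17,
    ("R-STL-Con", "WC"): 10, ("R-STL-Con", "PN"): 34,
}

# Sediment abundances, items/kg dry weight.  The WWTP-DS bed-load value
# (300, the survey maximum) is published; the NHD-DS and confluence values
# follow from the published per-sample hazard and risk indices; the bed/
# suspended splits at WWTP-US and NHD-US were not published and are
# SYNTHETIC placeholders that preserve the published site means (205, 235)
# and the bed-load > suspended-load ordering.
_SEDIMENT_ABUNDANCES = {
    ("WWTP-US", "BL"): 250, ("WWTP-US", "SSL"): 160,    # synthetic split, mean 205
    ("WWTP-DS", "BL"): 300, ("WWTP-DS", "SSL"): 120,
    ("NHD-US", "BL"): 270, ("NHD-US", "SSL"): 200,      # synthetic split, mean 235
    ("NHD-DS", "BL"): 190, ("NHD-DS", "SSL"): 110,
    ("R-STL-Con", "BL"): 230, ("R-STL-Con", "SSL"): 120,
}

# Published per-sample hazard indices.  Supplied directly because per-sample
# polymer compositions were published only as figure percentages.
_HAZARD_INDICES = {
    "WWTP-US-WC": 20.50, "WWTP-US-PN": 30.0, "WWTP-EF-WC": 20.50,
    "WWTP-DS-WC": 14.85, "WWTP-DS-PN": 5290.0,
    "NHD-US-WC": 14.85, "NHD-US-PN": 7.50,
    "NHD-DS-WC": 8.20, "NHD-DS-PN": 16.50,
    "R-STL-Con-WC": 3493.0, "R-STL-Con-PN": 5277.0,
    "WWTP-US-BL": 4.0, "WWTP-US-SSL": 4.0,
    "WWTP-DS-BL": 4.0, "WWTP-DS-SSL": 5277.0,
    "NHD-US-BL": 5.50, "NHD-US-SSL": 8.10,
    "NHD-DS-BL": 10.40, "NHD-DS-SSL": 1069.0,
    "R-STL-Con-BL": 3483.0, "R-STL-Con-SSL": 5277.0,
}

# Denominators chosen so integer particle counts reproduce the published
# abundances exactly: three pooled 1-L grabs, a 0.01 m^2 net at 0.1 m/s for
# 300 s (300 L filtered), 0.1 kg dry sediment.
_GRAB_VOLUME_L = 3.0
_NET = {"net_area_m2": 0.01, "net_velocity_m_s": 0.1, "net_duration_s": 300.0}
_NET_VOLUME_L = 300.0
_DRY_MASS_KG = 0.1

# Published compartment-level categorical distributions (percent / 100).
_WATER_COMPOSITION = CompositionSpec(
    polymer={"PE": 0.35, "PP": 0.28, "PS": 0.25, "PET": 0.12},
    shape={"fragment": 0.57, "fiber": 0.36, "foam": 0.07},
    # no dominant color was reported; uniform over the six observed colors
    color={c.value: 1 / 6 for c in Color},
    size_class={"<50": 0.07, "50-100": 0.25, "100-200": 0.21,
                "200-500": 0.24, "500-5000": 0.23},
)
_SEDIMENT_COMPOSITION = CompositionSpec(
    polymer={"PET": 0.56, "PVC": 0.14, "PE": 0.13, "PP": 0.11, "PS": 0.06},
    shape={"fragment": 0.70, "fiber": 0.19, "foam": 0.11},
    color={c.value: 1 / 6 for c in Color},
    size_class={"<50": 0.11, "50-100": 0.33, "100-200": 0.25,
                "200-500": 0.18, "500-5000": 0.13},
)


def _fixture_sample_specs() -> list[SampleSpec]:
    specs = []
    for (site_id, method), value in _WATER_ABUNDANCES.items():
        kwargs = {"grab_volume_L": _GRAB_VOLUME_L} if method == "WC" else dict(_NET)
        specs.append(SampleSpec(
            sample_id=f"{site_id}-{method}", site_id=site_id,
            compartment=Compartment.WATER, method=Method(method),
            expected_abundance=float(value), **kwargs))
    for (site_id, method), value in _SEDIMENT_ABUNDANCES.items():
        specs.append(SampleSpec(
            sample_id=f"{site_id}-{method}", site_id=site_id,
            compartment=Compartment.SEDIMENT, method=Method(method),
            expected_abundance=float(value), dry_mass_kg=_DRY_MASS_KG))
    return specs


def raquette_config(count_model: Literal["fixed", "poisson"] = "fixed",
                    seed: int = 0, generate_particles: bool = True) -> CampaignConfig:
    """Generator configuration emulating the Raquette River survey design."""
    return CampaignConfig(
        sites=[SiteSpec(site_id=s, location_group=g, position_tag=p,
                        latitude=lat, longitude=lon,
                        sampled_at=datetime.fromisoformat(ts))
               for s, g, p, lat, lon, ts in _SITES],
        samples=_fixture_sample_specs(),
        composition={Compartment.WATER: _WATER_COMPOSITION,
                     Compartment.SEDIMENT: _SEDIMENT_COMPOSITION},
        count_model=count_model, seed=seed,
        generate_particles=generate_particles)


@dataclass(frozen=True)
class RaquetteFixture:
    """The packaged survey campaign plus its per-sample hazard indices."""

    campaign: Campaign
    hazard_indices: dict[str, float]


def raquette_fixture() -> RaquetteFixture:
    """The deterministic Raquette River campaign: 6 sites, 11 water and 10
    sediment samples at the published abundances, abundance-only (no particle
    rows), with the 21 published per-sample hazard indices attached."""
    campaign = generate(raquette_config(generate_particles=False))
    return RaquetteFixture(campaign=campaign, hazard_indices=dict(_HAZARD_INDICES))
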