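"""Size binning and categorical composition tables.

Particles are classified into five size classes spanning (0, 5000] µm and
tabulated by size, shape, color, or polymer as percentages of classified
particles per reporting group.  Polymer fractions are *number* fractions of
identified (non-UNKNOWN) particles; particles without a confident polymer
assignment are excluded from polymer tables and reported separately.
"""

from __future__ import annotations

import enum
import warnings
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .field_data import MAX_PARTICLE_DIMENSION_UM, ParticleRecord, Polymer

__all__ = ["SizeClass", "size_class", "composition", "polymer_fractions"]


class SizeClass(str, enum.Enum):
    """Five size bins partitioning (0, 5000] µm.

    Interior boundaries are left-closed ([50, 100) etc.); the last bin is
    closed at the 5000 µm definitional bound.
    """

    LT_50 = "<50"
    FROM_50_TO_100 = "50-100"
    FROM_100_TO_200 = "100-200"
    FROM_200_TO_500 = "200-500"
    FROM_500_TO_5000 = "500-5000"


#: Lower edges of each bin, in bin order; first bin is (0, 50).
SIZE_BIN_EDGES: list[tuple[float, SizeClass]] = [
    (500.0, SizeClass.FROM_500_TO_5000),
    (200.0, SizeClass.FROM_200_TO_500),
    (100.0, SizeClass.FROM_100_TO_200),
    (50.0, SizeClass.FROM_50_TO_100),
    (0.0, SizeClass.LT_50),
]

SIZE_CLASS_ORDER = [SizeClass.LT_50, SizeClass.FROM_50_TO_100, SizeClass.FROM_100_TO_200,
                    SizeClass.FROM_200_TO_500, SizeClass.FROM_500_TO_5000]


def size_class(max_dimension: float) -> SizeClass:
    """Map a particle's maximum dimension (µm) to its size bin."""
    if not 0 < max_dimension <= MAX_PARTICLE_DIMENSION_UM:
        raise ValueError(f"max_dimension {max_dimension} µm outside "
                         f"(0, {MAX_PARTICLE_DIMENSION_UM:g}] µm")
    for lower, label in SIZE_BIN_EDGES:
        if max_dimension >= lower and lower > 0:
            return label
    return SizeClass.LT_50


Attribute = Literal["size", "shape", "color", "polymer"]


def _category(p: ParticleRecord, attribute: Attribute) -> Optional[str]:
    if attribute == "size":
        return size_class(p.max_dimension).value
    if attribute == "shape":
        return p.shape.value
    if attribute == "color":
        return p.color.value
    if attribute == "polymer":
        # sub-threshold spectral matches do not enter polymer tables
        return None if p.polymer is Polymer.UNKNOWN else p.polymer.value
    raise ValueError(f"unknown attribute {attribute!r}")


def composition(particles: Sequence[ParticleRecord], attribute: Attribute,
                groups: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Per-group category counts and percentages for one attribute.

    ``groups`` maps sample_id to a reporting group label (site, compartment,
    ...); omitted, all particles form a single group ``"all"``.  Percentages
    are computed per group from raw counts over that group's classified
    particles.  Returns a tidy frame with columns
    ``group, attribute, category, count, percent``.  Groups whose particles
    are all unclassifiable (e.g. all-UNKNOWN polymer) are omitted with a
    warning.
    """
    if not particles:
        raise ValueError("no particles to tabulate")
    rows = []
    for p in particles:
        group = groups.get(p.sample_id, None) if groups is not None else "all"
        if group is None:
            continue
        rows.append({"group": group, "category": _category(p, attribute)})
    df = pd.DataFrame(rows, columns=["group", "category"])
    out = []
    for group, sub in df.groupby("group", sort=True):
        classified = sub.dropna(subset=["category"])
        if classified.empty:
            warnings.warn(f"group {group!r} has no classifiable particles for "
                          f"attribute {attribute!r}; omitted", stacklevel=2)
            continue
        counts = classified["category"].value_counts().sort_index()
        total = int(counts.sum())
        for category, count in counts.items():
            out.append({"group": group, "attribute": attribute, "category": category,
                        "count": int(count), "percent": 100.0 * count / total})
    return pd.DataFrame(out, columns=["group", "attribute", "category", "count", "percent"])


def polymer_fractions(particles: Sequence[ParticleRecord]) -> dict[Polymer, float]:
    """Number fraction of each identified polymer among a sample's particles.

    UNKNOWN particles are excluded; the returned fractions sum to 1 over
    identified particles.  Raises if no particle has an identified polymer.
    """
    counts: dict[Polymer, int] = {}
    for p in particles:
        if p.polymer is Polymer.UNKNOWN:
            continue
        counts[p.polymer] = counts.get(p.polymer, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no particles with an identified polymer")
    return {polymer: n / total for polymer, n in sorted(counts.items(),
                                                        key=lambda kv: kv[0].value)}
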