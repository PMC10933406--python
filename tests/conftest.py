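from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from mprisk import Polymer
from mprisk.synthetic import raquette_fixture

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def raquette():
    """The packaged Raquette River campaign with per-sample hazard indices."""
    return raquette_fixture()


@pytest.fixture(scope="session")
def full_scores():
    """A complete polymer hazard-score table (user-configured scheme)."""
    return {Polymer.PE: 11.0, Polymer.PP: 1.0, Polymer.PS: 30.0,
            Polymer.PET: 4.0, Polymer.PVC: 10001.0}


# ---------------------------------------------------------------------------
# Hypothesis strategies for random valid campaigns
# ---------------------------------------------------------------------------

from hypothesis import strategies as st  # noqa: E402

from mprisk import (  # noqa: E402
    Campaign,
    Color,
    Compartment,
    LocationGroup,
    Method,
    NetSamplingGeometry,
    ParticleRecord,
    PositionTag,
    SampleRecord,
    Shape,
    SiteRecord,
)

_ident = st.text(
    alphabet=st.characters(categories=("Lu", "Ll", "Nd"), include_characters="-_"),
    min_size=1, max_size=12)

_finite_pos = st.floats(min_value=1e-3, max_value=1e4,
                        allow_nan=False, allow_infinity=False)

_datetimes = st.datetimes(min_value=datetime(2000, 1, 1),
                          max_value=datetime(2030, 12, 31)).map(
    lambda d: d.replace(microsecond=0))


@st.composite
def site_records(draw, site_id=None):
    location = draw(st.sampled_from(list(LocationGroup)))
    positions = [p for p in PositionTag
                 if p is not PositionTag.EF or location is LocationGroup.WWTP]
    return SiteRecord(
        site_id=site_id or draw(_ident),
        location_group=location,
        position_tag=draw(st.sampled_from(positions)),
        latitude=draw(st.floats(min_value=-90, max_value=90,
                                allow_nan=False, allow_infinity=False)),
        longitude=draw(st.floats(min_value=-180, max_value=180,
                                 allow_nan=False, allow_infinity=False)),
        sampled_at=draw(_datetimes))


@st.composite
def sample_records(draw, sample_id, site_id, particle_count=None):
    method = draw(st.sampled_from(list(Method)))
    compartment = (Compartment.WATER if method in (Method.WC, Method.PN)
                   else Compartment.SEDIMENT)
    kwargs = {}
    if method is Method.WC:
        kwargs["grab_volume"] = draw(_finite_pos)
    elif method is Method.PN:
        kwargs["net_geometry"] = NetSamplingGeometry(
            aperture_area=draw(_finite_pos), mean_velocity=draw(_finite_pos),
            duration=draw(_finite_pos))
    else:
        kwargs["dry_mass"] = draw(_finite_pos)
    return SampleRecord(
        sample_id=sample_id, site_id=site_id, compartment=compartment,
        method=method,
        particle_count=(particle_count if particle_count is not None
                        else draw(st.integers(min_value=0, max_value=50))),
        **kwargs)


@st.composite
def particle_records(draw, particle_id, sample_id):
    return ParticleRecord(
        particle_id=particle_id, sample_id=sample_id,
        max_dimension=draw(st.floats(min_value=0.5, max_value=5000,
                                     allow_nan=False, allow_infinity=False)),
        shape=draw(st.sampled_from(list(Shape))),
        color=draw(st.sampled_from(list(Color))),
        polymer=draw(st.sampled_from(list(Polymer))))


@st.composite
def campaigns(draw, with_particles=True, max_sites=3, max_samples=5):
    n_sites = draw(st.integers(1, max_sites))
    sites = [draw(site_records(site_id=f"S{i}")) for i in range(n_sites)]
    n_samples = draw(st.integers(1, max_samples))
    samples = []
    particles = []
    for j in range(n_samples):
        site = draw(st.sampled_from(sites))
        if with_particles:
            count = draw(st.integers(0, 8))
            sample = draw(sample_records(f"M{j}", site.site_id, particle_count=count))
            particles.extend(
                draw(particle_records(f"M{j}-P{k}", sample.sample_id))
                for k in range(count))
        else:
            sample = draw(sample_records(f"M{j}", site.site_id))
        samples.append(sample)
    return Campaign(sites=sites, samples=samples, particles=particles)
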