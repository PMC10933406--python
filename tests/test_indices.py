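"""PLI / hazard index / PRI arithmetic, categorization, zone aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mprisk import (
    Compartment,
    Polymer,
    assess,
    categorize,
    geometric_mean,
    hazard_index,
    pli,
    pri,
    zone_summary,
)
from mprisk.indices import DEFAULT_HAZARD_SCORES, IndexResult, RiskCategoryScheme

WATER_PLIS = [2.3, 2.6, 1.3, 1.0, 2.7, 2.3, 1.4, 1.7, 2.5, 3.4, 1.0]
WATER_H = [7.50, 8.20, 14.85, 14.85, 16.50, 20.50, 20.50, 30, 3493, 5277, 5290]
SEDIMENT_H = [4, 4, 4, 5.50, 8.10, 10.40, 1069, 3483, 5277, 5277]

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


# -- pli ----------------------------------------------------------------------

def test_pli_worked_examples():
    assert pli(34, 10) == pytest.approx(3.40)
    assert pli(10, 10) == pytest.approx(1.0)
    assert pli(300, 110) == pytest.approx(2.7272727272727)


def test_pli_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        pli(34, 0)


@settings(max_examples=50)
@given(positive, positive, st.floats(0.1, 10))
def test_pli_scale_invariance(c_i, c_oi, k):
    assert pli(k * c_i, k * c_oi) == pytest.approx(pli(c_i, c_oi), rel=1e-12)


# -- geometric mean ------------------------------------------------------------

def test_geometric_mean_closed_forms():
    assert geometric_mean([7.0, 7.0, 7.0]) == pytest.approx(7.0)
    assert geometric_mean([1.0, 4.0]) == pytest.approx(2.0)


def test_geometric_mean_of_fixture_water_plis_is_printed_zone_value():
    assert round(geometric_mean(WATER_PLIS), 2) == 1.87


@pytest.mark.parametrize("values", [[], [0.0], [-1.0, 2.0]])
def test_geometric_mean_domain(values):
    with pytest.raises(ValueError):
        geometric_mean(values)


@settings(max_examples=100)
@given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=10))
def test_geometric_mean_against_brute_force_root_of_product(values):
    brute = math.prod(values) ** (1.0 / len(values))
    gm = geometric_mean(values)
    assert gm == pytest.approx(brute, rel=1e-9)
    assert gm == pytest.approx(stats.gmean(values), rel=1e-9)  # library cross-check


@settings(max_examples=100)
@given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=10))
def test_geometric_mean_bounds_and_am_gm(values):
    gm = geometric_mean(values)
    assert min(values) <= gm * (1 + 1e-12)
    assert gm <= max(values) * (1 + 1e-12)
    assert gm <= np.mean(values) * (1 + 1e-12)


@settings(max_examples=50)
@given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=8), st.randoms())
def test_geometric_mean_permutation_invariant(values, rnd):
    shuffled = list(values)
    rnd.shuffle(shuffled)
    assert geometric_mean(shuffled) == pytest.approx(geometric_mean(values), rel=1e-12)


# -- hazard index ----------------------------------------------------------------

def test_hazard_index_worked_examples():
    assert hazard_index({Polymer.PP: 1.0}, DEFAULT_HAZARD_SCORES) == pytest.approx(1.0)
    assert hazard_index({Polymer.PVC: 1.0}, DEFAULT_HAZARD_SCORES) == pytest.approx(10001.0)
    assert hazard_index({Polymer.PP: 0.5, Polymer.PVC: 0.5},
                        DEFAULT_HAZARD_SCORES) == pytest.approx(5001.0)


def test_hazard_index_missing_score_names_polymer(full_scores):
    with pytest.raises(ValueError, match="PE"):
        hazard_index({Polymer.PE: 1.0}, DEFAULT_HAZARD_SCORES)


def test_hazard_index_requires_normalized_fractions(full_scores):
    with pytest.raises(ValueError, match="sum to 1"):
        hazard_index({Polymer.PE: 0.4, Polymer.PP: 0.4}, full_scores)


@settings(max_examples=100)
@given(st.dictionaries(st.sampled_from([p for p in Polymer if p is not Polymer.UNKNOWN]),
                       st.floats(0.01, 1.0), min_size=1, max_size=5))
def test_hazard_index_bounded_by_present_scores(full_scores, weights):
    total = sum(weights.values())
    fractions = {p: w / total for p, w in weights.items()}
    h = hazard_index(fractions, full_scores)
    present = [full_scores[p] for p in fractions]
    assert min(present) - 1e-9 <= h <= max(present) + 1e-9


def test_hazard_index_monotone_under_shift_to_higher_scored_polymer(full_scores):
    base = {Polymer.PP: 0.6, Polymer.PVC: 0.4}
    shifted = {Polymer.PP: 0.5, Polymer.PVC: 0.5}
    assert hazard_index(shifted, full_scores) > hazard_index(base, full_scores)


# -- pri ------------------------------------------------------------------------

def test_pri_worked_examples():
    assert pri(3493, 1.0) == pytest.approx(3493)
    assert pri(5290, 1.0) == pytest.approx(5290)
    assert pri(5277, 3.4) == pytest.approx(17941.8)


def test_pri_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        pri(0, 1.0)
    with pytest.raises(ValueError):
        pri(10.0, -1.0)


# -- categorization ---------------------------------------------------------------

@pytest.mark.parametrize("value, expected", [
    (7.50, "I"), (8.20, "I"),
    (10.0, "II"), (14.85, "II"), (20.50, "II"), (30, "II"), (10.40, "II"),
    (100.0, "III"), (72.13, "II"), (999.99, "III"),
    (1069, "IV"), (3493, "IV"), (5290, "IV"),
    (10000, "V"), (20000, "V"),
])
def test_hazard_band_membership(value, expected):
    assert categorize(value, "H") == expected


@pytest.mark.parametrize("value, expected", [
    (10.9, "minor"), (134.87, "minor"), (149.999, "minor"),
    (150, "medium"), (299, "medium"),
    (300, "considerable"), (599, "considerable"),
    (600, "high"), (1069, "high"), (1199.9, "high"),
    (1200, "danger"), (3493, "danger"), (5290, "danger"), (17943, "danger"),
])
def test_pri_band_membership(value, expected):
    assert categorize(value, "PRI") == expected


def test_pli_categorization():
    assert categorize(3.4, "PLI") == "polluted"
    assert categorize(1.0, "PLI") == "not polluted"


def test_scheme_thresholds_must_increase():
    with pytest.raises(ValueError):
        RiskCategoryScheme(h_thresholds=(10, 10, 1000, 10000))


# -- zone aggregation --------------------------------------------------------------

def make_result(i, compartment=Compartment.WATER, pli_i=1.0, h_i=10.0):
    return IndexResult(sample_id=f"s{i}", compartment=compartment,
                       c_i=pli_i * 10, c_oi=10.0, pli=pli_i, h=h_i,
                       pri=pli_i * h_i,
                       pli_category="polluted", h_category="II", pri_category="minor")


def test_zone_hazard_indices_match_printed_values():
    water = [make_result(i, h_i=h) for i, h in enumerate(WATER_H)]
    sediment = [make_result(i, Compartment.SEDIMENT, h_i=h)
                for i, h in enumerate(SEDIMENT_H)]
    assert round(zone_summary(water).h_zone, 2) == 72.13
    assert round(zone_summary(sediment).h_zone, 2) == 70.60


def test_single_sample_zone_equals_sample():
    zone = zone_summary([make_result(0, pli_i=2.0, h_i=42.0)])
    assert zone.n == 1
    assert zone.pli_zone == pytest.approx(2.0)
    assert zone.h_zone == pytest.approx(42.0)
    assert zone.pri_zone == pytest.approx(84.0)


def test_zone_never_mixes_compartments():
    with pytest.raises(ValueError, match="compartment"):
        zone_summary([make_result(0), make_result(1, Compartment.SEDIMENT)])


@settings(max_examples=100)
@given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(0.1, 1e4)),
                min_size=1, max_size=12))
def test_zone_pri_is_product_of_zone_pli_and_zone_h(pairs):
    results = [make_result(i, pli_i=p, h_i=h) for i, (p, h) in enumerate(pairs)]
    zone = zone_summary(results)
    assert zone.pri_zone == pytest.approx(zone.h_zone * zone.pli_zone, rel=1e-9)
    plis = [p for p, _ in pairs]
    assert min(plis) - 1e-12 <= zone.pli_zone <= max(plis) + 1e-12


# -- full assessment ---------------------------------------------------------------

def test_fixture_assessment_reproduces_printed_zone_values(raquette):
    result = assess(raquette.campaign, hazard_indices=raquette.hazard_indices)
    water = result.zones[Compartment.WATER]
    sediment = result.zones[Compartment.SEDIMENT]
    assert (water.n, sediment.n) == (11, 10)
    assert result.c_oi[Compartment.WATER] == pytest.approx(10.0)
    assert result.c_oi[Compartment.SEDIMENT] == pytest.approx(110.0)
    assert round(water.pli_zone, 2) == 1.87
    assert round(water.h_zone, 2) == 72.13
    assert round(sediment.h_zone, 2) == 70.60
    assert water.pri_zone == pytest.approx(water.h_zone * water.pli_zone, rel=1e-12)
    # minimum per-sample PLI is exactly 1 with C_oi the in-compartment minimum
    for compartment in Compartment:
        plis = [r.pli for r in result.results if r.compartment is compartment]
        assert min(plis) == pytest.approx(1.0)


def test_fixture_per_sample_categories_match_survey(raquette):
    result = assess(raquette.campaign, hazard_indices=raquette.hazard_indices)
    by_id = {r.sample_id: r for r in result.results}
    assert by_id["NHD-US-PN"].h_category == "I"
    assert by_id["WWTP-US-PN"].h_category == "II"
    assert by_id["WWTP-DS-PN"].h_category == "IV"
    assert by_id["NHD-DS-SSL"].pri_category == "high"
    assert by_id["R-STL-Con-PN"].pri_category == "danger"
    assert by_id["R-STL-Con-PN"].pri == pytest.approx(17941.8)


def test_assess_from_particle_compositions(full_scores):
    from mprisk.synthetic import raquette_config
    from mprisk.synthetic import generate
    campaign = generate(raquette_config(seed=11))
    result = assess(campaign, scores=full_scores)
    for compartment, zone in result.zones.items():
        assert zone.pri_zone == pytest.approx(zone.h_zone * zone.pli_zone, rel=1e-9)
    plis = [r.pli for r in result.results]
    assert min(plis) >= 1.0


def test_assess_scale_invariance_of_pli(raquette):
    from mprisk.field_data import Campaign
    base = assess(raquette.campaign, hazard_indices=raquette.hazard_indices)
    # triple every water grab volume and count: same abundance ratios
    scaled_samples = []
    for s in raquette.campaign.samples:
        if s.grab_volume is not None:
            scaled_samples.append(s.model_copy(update={
                "grab_volume": s.grab_volume * 3,
                "particle_count": s.particle_count * 3}))
        else:
            scaled_samples.append(s)
    scaled = Campaign(sites=raquette.campaign.sites, samples=scaled_samples)
    result = assess(scaled, hazard_indices=raquette.hazard_indices)
    for r0, r1 in zip(base.results, result.results):
        assert r1.pli == pytest.approx(r0.pli, rel=1e-12)


def test_assess_requires_hazard_information(raquette):
    with pytest.raises(ValueError, match="hazard index"):
        assess(raquette.campaign)  # fixture has no particle rows
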