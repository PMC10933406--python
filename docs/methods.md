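# Methods

## Sampling model and normalization

A campaign is six kinds of records across three tables: sites (a location
group — wastewater treatment plant, hydro-dam, or river confluence — plus an
upstream/effluent/downstream/confluence position), physical samples, and
individual identified particles. Water samples are either instantaneous
grabs (denominator: grab volume, L) or timed plankton-net deployments, whose
filtered volume follows from the continuity equation: Q = A·V with A the net
aperture area (m²) and V the time-averaged flow velocity (m/s), and
Volume = Q·t with t the deployment duration (default 300 s). Sediment
samples are bed load (top ~5 cm of the riverbed, long-term accumulation) or
suspended sediment load (recent deposits resuspended behind an obstruction);
their denominator is oven-dry mass (kg). Abundance is count/denominator —
items/L for water, items/kg dry weight for sediment — and the two
compartments are never mixed in any summary or index.

Particles carry a maximum dimension (0 < d ≤ 5000 µm, the definitional
microplastic bound), a shape (fiber/fragment/foam), a color, and a polymer
label from upstream spectroscopy. A polymer of `UNKNOWN` stands for a
spectral match below the identification threshold: such particles count in
size/shape/color tables but are excluded from polymer tables and from hazard
scoring.

## Risk indices

Per sample i: PLI_i = C_i / C_oi, where C_oi is the **minimum abundance
observed in the same compartment** — so min PLI = 1 by construction and PLI
is invariant under rescaling all abundances. H_i = Σ P_n·S_n with P_n the
polymer fractions and S_n configured hazard scores; PRI_i = H_i·PLI_i.
Zone values are geometric means over a compartment's sampling points
(implemented as exp(mean(log x)) for numerical stability), and the package
treats each physical sample — not each site — as a sampling point. Because
the geometric mean is multiplicative, PRI_zone = H_zone·PLI_zone holds to
floating-point accuracy; the tests verify it against a brute-force n-th root
of the product.

P_n is implemented as the **number fraction** of identified particles, not a
mass fraction: the survey workflow measures counts only and no particle
masses exist. This is stated prominently because hazard-index conventions in
the literature sometimes read "mass fraction".

Only two hazard scores ship as defaults (PP = 1, PVC = 10001); scores for
other polymers vary between published GHS-based rankings and must be
supplied via configuration (`examples/hazard_scores_full.yaml` shows a
complete table). Where per-sample polymer composition is unavailable,
per-sample hazard indices can be supplied directly to `assess` (this is how
the packaged campaign is evaluated).

### Categorization

Categories use half-open bands so that they partition (0, ∞):
H — I [0,10), II [10,100), III [100,1000), IV [1000,10000), V [10000,∞);
PRI — minor [0,150), medium [150,300), considerable [300,600),
high [600,1200), danger [1200,∞); PLI > 1 is "polluted". Published
presentations of this table print overlapping or gapped bounds
("10–100, 100–1000, 1001–10,000"); the half-open convention reproduces every
per-sample category in the source survey. Note a known discrepancy in that
survey's own prose: zone H values of ~72/71 are called "category III" and
zone PRI values of ~134/118 "considerable", although the table places them
in II and minor respectively. The package follows the table; the run log
records the banding actually applied.

## The packaged Raquette River campaign

`raquette_fixture()` reconstructs the published pilot survey: 6 sites, 11
water and 10 sediment samples. Water abundances are the published per-sample
values (23, 26, 13, 10, 27, 23, 14, 17, 25, 34, 10 items/L; minimum 10, so
C_oi(water) = 10). The effluent sample is encoded as a single grab at
25 items/L — the survey does not say whether it was grab, net, or an average
of both. Sediment abundances: the WWTP downstream bed-load value (300
items/kg, the maximum) is published; four more follow algebraically from
published (H, PRI) pairs via PLI = PRI/H and C = PLI·110; the bed/suspended
splits at the two remaining sites were never published and are **synthetic
placeholders** (250/160 and 270/200 items/kg) that preserve the published
site means (205, 235) and the bed-load > suspended-load ordering. Per-sample
hazard indices are injected as given rather than reconstructed from polymer
fractions, because per-sample compositions exist only as chart percentages.

Denominators are not published either; the fixture uses three pooled 1-L
grabs (3 L), a 0.01 m² net at 0.1 m/s for 300 s (300 L filtered), and 0.1 kg
dry sediment, chosen so integer particle counts reproduce the published
abundances exactly.

## Synthetic-data generator

`generate(config)` draws campaigns with the structure the analysis assumes:
per-sample counts either fixed (round(expected abundance × denominator)) or
Poisson with that mean, and particle attributes drawn independently from
per-compartment categorical distributions over polymer, shape, color, and
size class, with the dimension uniform within the drawn size class (only
class frequencies are ever reported for real surveys, so no within-class
shape is assumed). A single campaign-level seed with a documented stream
order (samples in listed order; per particle: polymer, shape, color, size
class, dimension) makes output byte-identical across runs.

The packaged configuration (`raquette_config()`) uses the published
compartment-level composition: water polymers PE/PP/PS/PET at
35/28/25/12 %, sediment PET/PVC/PE/PP/PS at 56/14/13/11/6 %, shapes
57/36/7 % (water) and 70/19/11 % (sediment) for fragment/fiber/foam, and the
five size classes at 7/25/21/24/23 % (water) and 11/33/25/18/13 %
(sediment). No dominant color was reported, so colors are uniform over the
six observed ones — a package choice.

What the generator does **not** emulate: spatial correlation between
sites, within-sample correlation of attributes (a fiber is no more likely to
be PET than a fragment is), transport dynamics between source, dam, and
confluence, seasonal variation, or measurement error in dimensions. Passing
tests therefore demonstrate the pipeline's arithmetic and invariances, not
that real rivers behave like the generator.

## Numerical conventions

* Sample standard deviation uses the n−1 denominator (matches the published
  20.2 ± 7.86 items/L on the 11 water values).
* All index arithmetic is carried at full precision; rounding (1 dp
  abundances, 2 dp zone indices, integers for per-sample PRI ≥ 1000 and for
  percentages) is applied only by the report writer. Half-up decimal
  rounding is used so that printed values match hand-rounded ones.
* Size bins are left-closed: (0,50), [50,100), [100,200), [200,500),
  [500,5000]. Boundary membership is never stated in survey reports; the
  left-closed convention makes the bins a partition of (0, 5000].
* Geometric means reject zero or negative inputs rather than silently
  returning 0; a zero-abundance sample makes C_oi, and thus every PLI,
  undefined, and `assess` says so.
* One-way ANOVA is the classical F = MS_between/MS_within with the
  upper-tail p from the F distribution (scipy's implementation behind the
  module surface, verified against an explicit sums-of-squares oracle).
  Published F/p values for this survey are not reproduced because the exact
  sample groupings entering each test are not recoverable from the text.

## Problem sizes

The packaged campaign is the survey's own size (21 samples). Property
checks run on 10⁴ randomly drawn campaigns of 2–12 sampling points for the
zone-product identity and bounds, and generator parameter recovery uses
~10⁴ particles (three standard errors of a binomial/Poisson draw). The full
suite completes in well under a minute on one core.

## Known limitations

* The hazard index inherits whatever hazard-score ranking the user supplies;
  results are only comparable across studies using the same ranking.
* PLI is a within-campaign relative measure (C_oi is the campaign minimum),
  so a uniformly contaminated campaign reports PLI = 1 everywhere.
* Abundance-only campaigns cannot produce composition tables or
  particle-derived hazard indices; per-sample H must then be supplied.
* No uncertainty propagation: indices are point values, as in the source
  methodology.
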