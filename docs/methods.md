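# Methods

`potlipid` interprets organic residues absorbed in archaeological ceramics.
Its inputs are the quantities an organic-residue laboratory reports per
sherd after extraction and GC/GC-MS/GC-C-IRMS work: a total lipid
concentration, compound-specific carbon-isotope values of the two major
fatty acids, a triacylglycerol carbon-number envelope, an identified-compound
peak table, and small-organic-acid quantities from a butylation extract.
The package does not touch raw chromatograms; it starts where peak
integration and compound identification end.

## Interpretability screen

Absorbed lipid below about 5 µg per g of ceramic cannot be reliably
distinguished from burial-environment background, so vessels under the
threshold receive no compositional calls at all — an all-absent profile
with an explanatory note, never a set of negative calls.  The threshold is
configurable (`PipelineConfig.lipid_threshold`); the boundary is inclusive
(a vessel at exactly 5 µg/g is interpretable).

## Animal-fat classification from fatty-acid δ¹³C

Two classifiers run on the (δ¹³C₁₆:₀, δ¹³C₁₈:₀) pair, both standard in the
field:

**Δ¹³C windows.**  Δ¹³C = δ¹³C₁₈:₀ − δ¹³C₁₆:₀ removes most of the
environmental baseline and isolates the biosynthetic offset between the two
fatty acids.  Ruminant dairy fats fall below −3.3 ‰, ruminant adipose fats
between −3.3 ‰ and −1.0 ‰, non-ruminant fats above −1.0 ‰.  Both window
endpoints are assigned to the middle (ruminant adipose) class; dairy is
strictly `< −3.3` and non-ruminant strictly `> −1.0`, so the three windows
partition the line exactly.

**Reference ellipses.**  Each modern reference-fat class is modelled as a
bivariate normal; the coverage-q region is the ellipse of squared
Mahalanobis radius χ²₂(q).  A query point belongs to every class whose
ellipse contains it.  `fit_reference_ellipse` uses the sample mean and
sample covariance (ddof = 1) — the simplest reproducible estimator; its
coverage calibration is verified by Monte Carlo in the test suite.
Tentative porcine calls operationalize "on the edge of the porcine range":
inside the 95 % porcine ellipse but outside the nominal 68 % one, with a
non-ruminant Δ¹³C.  Both quantiles are configurable.

The shipped reference table (`data/reference_classes_synthetic.yaml`) is a
**synthetic approximation** of the published reference-fat geometry: the
authentic compilations of modern reference values are not redistributable
here, so the file reproduces only their qualitative layout (dairy depleted
in 18:0, porcine and marine enriched, freshwater depleted and dispersed).
It is clearly labelled non-authoritative; real studies must supply their own
table in the same YAML schema.

**Δ¹³C density.**  `kde_delta` summarises assemblage structure with a
Gaussian kernel density whose bandwidth is the kernel standard deviation
itself (default 0.5 ‰), not a rule-of-thumb multiplier.  The evaluation
grid (512 points) pads the data range by four bandwidths so the trapezoid
integral is 1 within 10⁻³ even for a single observation.

## Triacylglycerol envelope statistics

The TAG envelope is the relative-abundance distribution over total acyl
carbon number T40–T56 (acyl dialect: the glycerol backbone is not counted).
Two statistics are computed after normalization:

- **M** — abundance-weighted mean carbon number;
- **DF** — dispersion factor, implemented as the abundance-weighted
  standard deviation of carbon number.  The originating literature defers
  the exact dispersion equation to its own citation chain without printing
  it; the weighted SD is adopted because it reproduces the published dairy
  window (DF 2.0–2.6 with M 48–49 on broad T42–T54 envelopes) and the
  DF = 0 degeneracy at a single carbon number.  `tag_dispersion` accepts a
  replacement function should a different published index be preferred.

Calls: *dairy-like* requires M ∈ [48, 49], DF ∈ [2.0, 2.6] **and** nonzero
abundance at T44 or below — the low-mass tail is the actual dairy
signature; *adipose-like* requires support confined to T46–T54, a mode at
T52 (50/54 accepted within a 5 % relative-abundance tie tolerance) and DF
below the dairy window; everything else is *indeterminate*.  Because burial
preferentially strips low-molecular-weight TAGs, degraded dairy drifts
toward the adipose field — the generator's degradation model reproduces
this bias, and the tests assert that low-mass loss strictly raises M and
lowers DF.

## Biomarker rules

Rules are pure functions of the peak table; "presence" means abundance
strictly above a configurable floor (default 0, appropriate for tables that
have already passed detection-limit filtering).  Numeric parameters live in
`data/rules.yaml` and can be overridden per run.  The main rules:

| call | criterion |
|---|---|
| plant wax | odd C25–C33 alkanes with C29 or C31 strictly dominant; positive with n-alkanols or W40–W48 wax esters, else tentative |
| Brassica | nonacosan-15-one; positive when nonacosan-15-ol co-occurs |
| leek | hentriacontan-16-one together with the C31 n-alkane |
| fennel / sermountain | nonacosan-10-one; always tentative |
| plant oil | C18:1/C18:0 strictly > 2 with C18:2 present; undefined ratio abstains with a note |
| beeswax | quorum over 4 families (C27-dominant alkanes; C24:0-dominant even C20–C28 FAs; C30-dominant alkanols; W40–W50 esters): ≥3 positive, 2 tentative |
| pine resin | DHA plus another Pinaceae diterpenoid/oxidation product; DHA alone tentative |
| pitch | fired resin plus retene or methyl-DHA |
| aquatic | APAAs of acyl chain ≥ 20 plus ≥ 2 distinct isoprenoid acids (phytanic, pristanic, TMTD) |
| heating | symmetric condensation ketones K33/K35 or any C16–C22 APAA |
| grape wax | odd alkanes with C25 strictly dominant (tentative, supporting acid evidence) |
| cereal / millet | any alkylresorcinol / miliacin |

Dominance is strict — a tied maximum never counts.  One structural
subtlety: hentriacontan-16-one is simultaneously the K31 condensation
ketone of the heating series and the leek taxon marker, so it never fires
heating on its own; it is recorded as supporting evidence when K33/K35 are
present.  Taxon ketones at oxidation positions 10/15/16 likewise never
trigger heating.  Phytanic-acid %SRR is computed with window classification
against configurable aquatic/ruminant ranges; the shipped window defaults
overlap deliberately and are placeholders, not reference values.

Peak-table rows are unique per (compound, class, chain, position,
unsaturation); the compound name participates in the key because distinct
named sterols (β-sitosterol, α-spinasterol) share identical structural
coordinates.

## Fruit acids

%TA = 100 · tartaric/(tartaric + malic) discriminates grape products
(strictly > 35 %) from low-tartaric orchard fruits.  Because trace tartaric
acid can be burial contamination, grape calls additionally require the
absolute tartaric quantity to pass a screen (default 0.1 µg/g, inclusive;
a placeholder for laboratory-specific recommendations, configurable).  The
malic quantification floor mirrors it.  Samples whose tartaric fails the
screen remain eligible for a generic fruit call through malic acid.
Succinic and the other minor acids alone are never a fruit call (succinic
also forms by fatty-acid degradation); they yield a non-specific plant
note.  Every grape call carries the tamarind/pomegranate ambiguity as a
note rather than a separate label.

## Evidence fusion

`build_commodity_profile` combines the four proxies into one profile of 18
commodity flags at three evidence levels (absent / tentative / positive)
plus a heating boolean and an audit trail naming every fired rule.
Precedence: molecular evidence upgrades but never deletes an isotope call —
a dairy-like TAG envelope upgrades dairy to positive even under an adipose
Δ¹³C, with the conflict noted.  A pitch call certifies its resin base.
Taxon markers imply at least tentative plant wax.  "Unidentified plant" is
the fallback for plant sterols or tentative wax without a taxon.  Missing
blocks (no isotopes, no butylation extract) produce notes, never negative
calls.  Three structural invariants are validated on every output:
pitch ⇒ pine resin, grape ⇒ fruit, taxon ⇒ plant wax ≥ tentative.

## Synthetic assemblage generator

The generator exists so the whole pipeline is testable without restricted
laboratory data.  Each commodity has a generative spec: an isotope mean
(per-commodity sampling covariance 0.3 ‰ SD per axis, mildly correlated), a
TAG template (dairy: broad T42–T54, M 48.5, DF 2.5; adipose: narrow,
T52-centred, DF 1.9), an exact marker set, and, for fruit commodities, a
log-normal acid model (grape anchored at 2 µg/g tartaric with %TA ≈ 75 ± 8;
orchard fruit at 4 µg/g malic with %TA ≈ 10 ± 5).  Vessel mixtures combine
sources by mass fraction: isotope mixing is a linear mass balance with each
fraction re-weighted by the commodity's relative C16:0/C18:0 contribution;
TAG envelopes and marker abundances blend linearly; tentative-porcine truth
vessels are placed midway through the porcine confidence annulus.
Degradation is deliberately kinetic-free: a fractional loss of T≤46 TAGs
and a fractional oxidation of C18:1, enough to exercise the documented
biases (dairy drifting toward adipose; plant oils vanishing).

Lipid concentrations are log-normal (median 60 µg/g, log-SD 1) with a 9 %
poor-preservation fraction drawn uniformly below 5 µg/g, so default
assemblages show study-like site means (tens to ~150 µg/g) and a ~91 %
interpretability rate.  The default site composition mixes animal-fat
vessels (adipose, non-ruminant, occasional dairy and edge-porcine) with
vegetable, fruit/grape, beeswax and pine vessels and realistic two-source
mixtures, some heated.

Ground truth per vessel is the profile of its **noise-free twin**: the same
contents run through the forward model without sampling noise and then
through the interpretation pipeline.  Closure therefore means a pure,
noise-free vessel classifies back to exactly its commodity's declared
flags (asserted for all 18 labels), and recovery under noise measures only
the effect of sampling noise — at the default noise level, per-(vessel,
label) flag agreement over 500 vessels is ≈ 99 %, with the residual
disagreement concentrated at the Δ¹³C window boundaries as expected from
the isotope overlap.  Everything is driven by one `numpy` `Generator`
seed; identical seeds produce byte-identical sample sheets.

## Problem sizes and numerical choices

The test suite and the acceptance script use assemblages of 120–500
vessels, 10⁵ Monte-Carlo draws for ellipse coverage, and 1,000 random
profiles/pairs for the statistic-vs-oracle checks; these sizes make every
stochastic check stable at the asserted tolerances while keeping a full run
in seconds.  Ties in dominance tests lose deliberately; TAG normalization
tolerates 10⁻⁹; ellipse fitting refuses collinear point sets rather than
regularizing.

## Limitations

- The shipped reference ellipses and the plant %TA table are synthetic
  stand-ins; all quantitative isotope conclusions depend on user-supplied
  reference data.
- The generator injects markers exactly; it does not simulate co-elution,
  detection-limit censoring, or soil-derived contamination beyond the
  tartaric screen's rationale, so perfect rule sensitivity on synthetic
  data says nothing about chromatographic identification in real extracts.
- The DF statistic is a reconstruction (weighted SD); comparisons against
  publications using a different dispersion index should swap the function.
- Mixing is qualitative: the pipeline flags co-occurring commodities but
  does not estimate source proportions.
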