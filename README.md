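# potlipid

Multi-proxy interpretation of lipid residues absorbed in archaeological
pottery.  Given the measurements an organic-residue analysis (ORA)
laboratory reports per ceramic sherd — total lipid concentration,
compound-specific fatty-acid δ¹³C values, triacylglycerol (TAG)
distributions, identified GC-MS compound tables and small-organic-acid
quantities — `potlipid` produces per-vessel *commodity profiles*: which
foodstuffs and technical substances (ruminant dairy and adipose fats,
non-ruminant/porcine fats, vegetables by taxon, plant oils and waxes,
beeswax, pine resin and pitch, fruit and grape products, aquatic oils,
cereals, millet) the chemistry supports, at what evidence level, with a
full audit trail of which rule fired.  It is aimed at archaeometrists and
biomolecular archaeologists who already have integrated peak tables and
want reproducible, configurable interpretation on top of them.

## The science in brief

- **Animal fats** are classified from the carbon-isotope offset
  Δ¹³C = δ¹³C₁₈:₀ − δ¹³C₁₆:₀ (dairy < −3.3 ‰, ruminant adipose −3.3 to
  −1.0 ‰, non-ruminant > −1.0 ‰) and, in (δ¹³C₁₆:₀, δ¹³C₁₈:₀) space, by
  membership in bivariate-normal reference ellipses with χ²₂-quantile
  radii — including an "edge of the porcine range" tentative call
  (inside the 95 % porcine ellipse, outside the 68 % one).
- **TAG envelopes** are summarised by M (abundance-weighted mean acyl
  carbon number) and DF (abundance-weighted SD).  Broad T42–T54 envelopes
  with M ∈ [48, 49], DF ∈ [2.0, 2.6] and a preserved low-mass tail are
  dairy-like; narrow T52-centred envelopes are adipose-like.
- **Molecular biomarkers** are called by a rule engine over the peak
  table: leaf-wax alkane/alkanol/ester suites, taxon-specific mid-chain
  ketones (Brassica, leek, fennel/sermountain), the C18:1/C18:0 > 2 plant
  oil criterion, the four-family beeswax quorum, Pinaceae diterpenoids with
  retene/methyl-DHA pitch markers, APAA + isoprenoid aquatic criteria, and
  thermal markers.
- **Fruit acids** use %TA = 100·tartaric/(tartaric + malic): > 35 % with a
  quantifiable tartaric amount indicates grape products; malic-dominated
  extracts indicate orchard fruits.

A seeded synthetic-assemblage generator (`potlipid.simulate`) forward-models
all of the above — isotope mass-balance mixing, TAG blending and
degradation, exact marker injection, class-conditional acid quantities —
with per-vessel ground truth, so the entire pipeline is testable without
restricted laboratory data.  See `docs/methods.md` for the full model
description and its limitations.

## Worked example

Simulate a small assemblage and interpret it:

```sh
potlipid simulate --n 6 --seed 42 --out demo/sim
potlipid interpret --sample-sheet demo/sim/sample_sheet.csv \
                   --peak-table demo/sim/peak_table.csv \
                   --out demo/interp
```

The fired flags per vessel (from `demo/interp/report.json`):

```
SYN_0001  olla         127.1 µg/g  {fruit: positive}
SYN_0002  cooking pot   43.7 µg/g  {beeswax: positive, pine_resin: positive}
SYN_0003  lid          144.6 µg/g  {ruminant_adipose: positive}
SYN_0004  pan           25.4 µg/g  {non_ruminant: positive, porcine_tentative: tentative}
SYN_0005  olla          49.9 µg/g  {non_ruminant: positive, porcine_tentative: tentative}
SYN_0006  cooking pot   42.2 µg/g  {plant_unidentified: tentative}
```

Vessel 1 carried a malic-dominated acid extract (%TA below 35), so a
generic fruit product is called without a grape attribution; vessel 2
combines the four beeswax compound families with dehydroabietic acid and
its oxidation products; vessels 4–5 sit in the porcine confidence annulus
with non-ruminant Δ¹³C, hence the tentative porcine qualifier.  The TAG
table (`mdf_table.csv`) reports vessel 3's envelope as

```
sample_id,site,M,DF,tag_class
SYN_0003,SYN,51.38,1.93277003288027,adipose_like
```

— a T52-centred envelope (M 51.4, DF 1.9), consistent with its ruminant
adipose isotope call.  `demo/interp/` also contains the flat TSV report, a
per-site summary (counts and fractions per commodity flag), the Δ¹³C
kernel-density export and an isotope window/ellipse summary.  Real sample
sheets in foreign layouts are adapted with a column map
(`read_sample_sheet(..., column_map=...)`); reference ellipses and rule
parameters are YAML files you can replace per run (`--refs`, `--rules`).

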