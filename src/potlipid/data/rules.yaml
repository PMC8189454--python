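# Numeric parameters of the biomarker rule engine.  Override any key with a
# user rules file passed to the CLI / PipelineConfig.
presence_floor: 0.0

# Plant (leaf) wax: odd n-alkanes in this range with C29 or C31 dominant,
# plus n-alkanols or wax esters W40-W48 for a positive call.
plant_wax_alkane_range: [25, 33]
plant_wax_dominants: [29, 31]
wax_ester_range: [40, 48]

# Beeswax quorum over its four component families (alkanes/C27, even long
# FAs/C24:0, alkanols/C30, wax esters W40-W50).
beeswax_quorum_positive: 3
beeswax_quorum_tentative: 2

# Plant oil: oleic/stearic ratio threshold (strict >), with linoleic present.
plant_oil_ratio: 2.0

# Aquatic: APAAs of at least this acyl chain length together with at least
# this many distinct isoprenoid acids (phytanic, pristanic, TMTD).
aquatic_min_apaa_chain: 20
aquatic_isoprenoid_quorum: 2

# Heating: symmetric condensation ketones of these chain lengths, or any
# APAA in the chain range below.  K31 (hentriacontan-16-one) is excluded
# because it is indistinguishable from the leek taxon marker.
heating_ketone_chains: [33, 35]
apaa_chain_range: [16, 22]

# Phytanic-acid %SRR windows (non-authoritative placeholders; configure from
# your own reference data).  Overlapping windows are expected.
srr_aquatic_window: [50.0, 100.0]
srr_ruminant_window: [0.0, 75.0]
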