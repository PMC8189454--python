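# SYNTHETIC reference-fat geometry for (delta13C16:0, delta13C18:0), per mil VPDB.
#
# These ellipse parameters are a constructed approximation of the geometry of
# modern authentic reference fats (dairy depleted in 18:0 relative to 16:0;
# porcine enriched in both; marine most enriched; freshwater depleted and
# dispersed).  They are NOT the published compilation of modern reference
# values and must not be treated as authoritative: supply your own reference
# table (same schema) for real studies.
classes:
  ruminant_dairy:
    mean: [-29.5, -33.5]
    covariance: [[1.2, 0.6], [0.6, 1.5]]
    n: 50
    coverage: 0.68
  ruminant_adipose:
    mean: [-28.5, -30.5]
    covariance: [[1.2, 0.7], [0.7, 1.2]]
    n: 80
    coverage: 0.68
  porcine:
    mean: [-25.5, -25.0]
    covariance: [[1.0, 0.5], [0.5, 1.0]]
    n: 60
    coverage: 0.68
  marine:
    mean: [-22.0, -20.5]
    covariance: [[1.5, 0.8], [0.8, 1.5]]
    n: 40
    coverage: 0.68
  freshwater:
    mean: [-32.0, -29.5]
    covariance: [[2.0, 1.0], [1.0, 2.0]]
    n: 39
    coverage: 0.68
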