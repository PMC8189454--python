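"""Synthetic assemblage generator with full ground-truth bookkeeping.

Generates sherd-level records with the statistical structure the
interpretation pipeline assumes: commodity-specific bivariate isotope
distributions, linear isotope mass-balance mixing across commodities, TAG
envelope templates for dairy vs adipose fats, exact biomarker injection,
class-conditional fruit-acid quantities, and a deliberately simple
degradation model (fractional low-molecular-weight TAG loss and fractional
oleic-acid oxidation).  Every vessel carries a :class:`VesselTruth` whose
expected commodity flags are derived from the noise-free forward model, so
recovery against ground truth is always measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import compounds as cmp
from .aggregate import build_commodity_profile
from .config import PipelineConfig, load_reference_classes
from .isotopes import ReferenceClass
from .types import (
    AcidQuant,
    IsotopeMeasurement,
    Peak,
    PeakTable,
    SampleRecord,
    TagProfile,
    ValidationError,
)

#: Broad dairy TAG envelope: M ~ 48.5, DF ~ 2.5, low-mass tail at T42/T44.
DAIRY_TAG_TEMPLATE = TagProfile(
    {42: 0.01, 44: 0.05, 46: 0.22, 48: 0.30, 50: 0.26, 52: 0.12, 54: 0.04}
)
#: Narrow ruminant-adipose envelope centred on T52.
ADIPOSE_TAG_TEMPLATE = TagProfile(
    {46: 0.03, 48: 0.08, 50: 0.25, 52: 0.45, 54: 0.19}
)

_ISOTOPE_NOISE_COV = ((0.09, 0.02), (0.02, 0.09))  # per-commodity sampling noise, per mil^2


@dataclass
class Degradation:
    """Post-depositional alteration parameters (fractions in [0, 1])."""

    low_mw_tag_loss: float = 0.0
    c18_1_oxidation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("low_mw_tag_loss", "c18_1_oxidation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class AcidModel:
    """Class-conditional small-acid quantities.

    The anchoring acid is drawn log-normally around ``anchor_median`` (ug/g)
    and %TA normally around ``percent_ta_mean``; the partner acid follows
    from the ratio.  Noise-free draws return the medians exactly.
    """

    anchor: str  # "tartaric" or "malic"
    anchor_median: float
    percent_ta_mean: float
    percent_ta_sd: float = 5.0
    log_sigma: float = 0.4

    def sample(self, rng: Optional[np.random.Generator]) -> Tuple[float, float]:
        if rng is None:
            anchor_amount, pct = self.anchor_median, self.percent_ta_mean
        else:
            anchor_amount = float(
                self.anchor_median * math.exp(rng.normal(0.0, self.log_sigma))
            )
            pct = float(np.clip(rng.normal(self.percent_ta_mean, self.percent_ta_sd), 1.0, 99.0))
        if self.anchor == "tartaric":
            tartaric = anchor_amount
            malic = tartaric * (100.0 - pct) / pct
        else:
            malic = anchor_amount
            tartaric = malic * pct / (100.0 - pct)
        return tartaric, malic


@dataclass
class CommoditySpec:
    """Ground-truth generative parameters for one commodity."""

    label: str
    isotope_mean: Optional[Tuple[float, float]] = None
    isotope_cov: Tuple[Tuple[float, float], Tuple[float, float]] = _ISOTOPE_NOISE_COV
    fa_mass: Tuple[float, float] = (1.0, 1.0)  # relative C16:0, C18:0 contributions
    tag_template: Optional[TagProfile] = None
    markers: Tuple[Peak, ...] = ()
    acid_model: Optional[AcidModel] = None
    expected_flags: Dict[str, str] = field(default_factory=dict)
    expected_heating: bool = False


@dataclass
class VesselTruth:
    """What one synthetic vessel actually contains."""

    sample_id: str
    mixture: Dict[str, float]
    heated: bool = False
    degradation: Degradation = field(default_factory=Degradation)
    expected_flags: Dict[str, str] = field(default_factory=dict)
    expected_heating: bool = False

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.mixture.values()):
            raise ValidationError("mixture mass fractions must be >= 0")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValidationError("mixture mass fractions must sum to 1")


@dataclass
class VesselBlueprint:
    """One vessel archetype within an assemblage composition."""

    weight: float
    mixture: Dict[str, float]
    heated: bool = False
    degradation: Degradation = field(default_factory=Degradation)


@dataclass
class AssemblageSpec:
    """Site-level composition: vessel archetypes and concentration model."""

    site: str = "SYN"
    blueprints: Sequence[VesselBlueprint] = ()
    vessel_forms: Sequence[str] = ("olla", "cooking pot", "lid", "pan")
    conc_median: float = 60.0  # ug/g, log-normal median
    conc_log_sigma: float = 1.0
    #: Fraction of sherds with failed lipid preservation (< 5 ug/g yields).
    poor_preservation_rate: float = 0.09

    def __post_init__(self) -> None:
        if not self.blueprints:
            return
        total = sum(b.weight for b in self.blueprints)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("blueprint weights must sum to 1")


def porcine_edge_point(
    porcine: ReferenceClass,
    inner_coverage: float = 0.68,
    outer_coverage: float = 0.95,
) -> Tuple[float, float]:
    """A point midway through the porcine confidence annulus (enriched side)."""
    target = 0.5 * (
        stats.chi2.ppf(inner_coverage, df=2) + stats.chi2.ppf(outer_coverage, df=2)
    )
    u = np.array([1.0, 1.0])
    cov = porcine.cov_matrix
    scale = math.sqrt(target / float(u @ np.linalg.solve(cov, u)))
    point = np.asarray(porcine.mean) + scale * u
    return (float(point[0]), float(point[1]))


def _animal_markers(ruminant: bool) -> Tuple[Peak, ...]:
    markers = [
        cmp.fatty_acid(16, 10.0),
        cmp.fatty_acid(18, 10.0),
        cmp.sterol(cmp.CHOLESTEROL, 3.0),
    ]
    if ruminant:
        markers += [
            cmp.branched_fatty_acid(15, 0.5),
            cmp.branched_fatty_acid(17, 0.5),
            cmp.fatty_acid(15, 0.5),
            cmp.fatty_acid(17, 0.5),
        ]
    return tuple(markers)


def default_specs(
    refs: Optional[Mapping[str, ReferenceClass]] = None,
) -> Dict[str, CommoditySpec]:
    """Generative specs for all commodity labels the pipeline can call."""
    refs = dict(refs) if refs is not None else load_reference_classes()
    specs: Dict[str, CommoditySpec] = {}

    specs["ruminant_dairy"] = CommoditySpec(
        "ruminant_dairy",
        isotope_mean=refs["ruminant_dairy"].mean,
        tag_template=DAIRY_TAG_TEMPLATE,
        markers=_animal_markers(ruminant=True),
        expected_flags={"ruminant_dairy": "positive"},
    )
    specs["ruminant_adipose"] = CommoditySpec(
        "ruminant_adipose",
        isotope_mean=refs["ruminant_adipose"].mean,
        tag_template=ADIPOSE_TAG_TEMPLATE,
        markers=_animal_markers(ruminant=True),
        expected_flags={"ruminant_adipose": "positive"},
    )
    specs["non_ruminant"] = CommoditySpec(
        "non_ruminant",
        isotope_mean=(-30.0, -30.4),
        markers=_animal_markers(ruminant=False),
        expected_flags={"non_ruminant": "positive"},
    )
    specs["porcine_tentative"] = CommoditySpec(
        "porcine_tentative",
        isotope_mean=porcine_edge_point(refs["porcine"]),
        markers=_animal_markers(ruminant=False),
        expected_flags={"non_ruminant": "positive", "porcine_tentative": "tentative"},
    )
    specs["plant_unidentified"] = CommoditySpec(
        "plant_unidentified",
        markers=(cmp.sterol(cmp.B_SITOSTEROL, 2.0),),
        expected_flags={"plant_unidentified": "tentative"},
    )
    specs["plant_oil"] = CommoditySpec(
        "plant_oil",
        markers=(
            cmp.fatty_acid(16, 8.0),
            cmp.fatty_acid(18, 2.0),
            cmp.fatty_acid(18, 6.0, unsaturation=1),
            cmp.fatty_acid(18, 1.0, unsaturation=2),
        ),
        expected_flags={"plant_oil": "positive"},
    )
    specs["plant_wax"] = CommoditySpec(
        "plant_wax",
        markers=(
            cmp.alkane(25, 2.0),
            cmp.alkane(27, 4.0),
            cmp.alkane(29, 10.0),
            cmp.alkane(31, 6.0),
            cmp.alkane(33, 1.0),
            cmp.alkanol(26, 3.0),
            cmp.alkanol(28, 4.0),
            cmp.wax_ester(44, 2.0),
        ),
        expected_flags={"plant_wax": "positive"},
    )
    specs["brassica"] = CommoditySpec(
        "brassica",
        markers=(
            cmp.ketone(29, 15, 5.0),
            cmp.alkanol(29, 2.0, position=15),
            cmp.alkane(27, 3.0),
            cmp.alkane(29, 8.0),
            cmp.alkane(31, 4.0),
            cmp.alkanol(26, 2.0),
        ),
        expected_flags={"brassica": "positive", "plant_wax": "positive"},
    )
    specs["leek"] = CommoditySpec(
        "leek",
        markers=(
            cmp.ketone(31, 16, 5.0),
            cmp.alkane(27, 2.0),
            cmp.alkane(29, 3.0),
            cmp.alkane(31, 9.0),
        ),
        expected_flags={"leek": "positive", "plant_wax": "tentative"},
    )
    specs["fennel_or_sermountain"] = CommoditySpec(
        "fennel_or_sermountain",
        markers=(
            cmp.ketone(29, 10, 4.0),
            cmp.alkane(27, 2.0),
            cmp.alkane(29, 6.0),
            cmp.alkane(31, 3.0),
        ),
        expected_flags={"fennel_or_sermountain": "tentative", "plant_wax": "tentative"},
    )
    specs["beeswax"] = CommoditySpec(
        "beeswax",
        markers=(
            cmp.alkane(25, 2.0),
            cmp.alkane(27, 10.0),
            cmp.alkane(29, 4.0),
            cmp.alkane(31, 3.0),
            cmp.alkane(33, 1.0),
            cmp.fatty_acid(20, 1.0),
            cmp.fatty_acid(22, 2.0),
            cmp.fatty_acid(24, 6.0),
            cmp.fatty_acid(26, 3.0),
            cmp.fatty_acid(28, 2.0),
            cmp.alkanol(24, 2.0),
            cmp.alkanol(26, 3.0),
            cmp.alkanol(28, 4.0),
            cmp.alkanol(30, 8.0),
            cmp.alkanol(32, 2.0),
            cmp.wax_ester(40, 3.0),
            cmp.wax_ester(42, 4.0),
            cmp.wax_ester(44, 5.0),
            cmp.wax_ester(46, 4.0),
            cmp.wax_ester(48, 2.0),
            cmp.wax_ester(50, 1.0),
        ),
        expected_flags={"beeswax": "positive"},
    )
    specs["pine_resin"] = CommoditySpec(
        "pine_resin",
        markers=(
            cmp.diterpenoid(cmp.DHA, 8.0),
            cmp.diterpenoid(cmp.OXO_DHA, 3.0),
            cmp.diterpenoid(cmp.ABIETIC, 2.0),
        ),
        expected_flags={"pine_resin": "positive"},
    )
    specs["pitch"] = CommoditySpec(
        "pitch",
        markers=(
            cmp.diterpenoid(cmp.DHA, 8.0),
            cmp.diterpenoid(cmp.OXO_DHA, 3.0),
            cmp.diterpenoid(cmp.RETENE, 4.0),
            cmp.diterpenoid(cmp.METHYL_DHA, 3.0),
        ),
        expected_flags={"pine_resin": "positive", "pitch": "positive"},
    )
    specs["fruit"] = CommoditySpec(
        "fruit",
        acid_model=AcidModel(anchor="malic", anchor_median=4.0, percent_ta_mean=10.0),
        expected_flags={"fruit": "positive"},
    )
    specs["grape"] = CommoditySpec(
        "grape",
        markers=(
            cmp.alkane(25, 8.0),
            cmp.alkane(27, 3.0),
            cmp.alkane(29, 2.0),
        ),
        acid_model=AcidModel(anchor="tartaric", anchor_median=2.0, percent_ta_mean=75.0, percent_ta_sd=8.0),
        expected_flags={"grape": "positive", "fruit": "positive"},
    )
    specs["aquatic"] = CommoditySpec(
        "aquatic",
        markers=(
            cmp.fatty_acid(16, 8.0),
            cmp.fatty_acid(18, 6.0),
            cmp.apaa(18, 1.0),
            cmp.apaa(20, 2.0),
            cmp.apaa(22, 1.0),
            cmp.isoprenoid(cmp.PHYTANIC, 3.0),
            cmp.isoprenoid(cmp.TMTD, 2.0),
            cmp.isoprenoid(cmp.PRISTANIC, 1.0),
        ),
        expected_flags={"aquatic": "positive"},
        expected_heating=True,
    )
    specs["cereal"] = CommoditySpec(
        "cereal",
        markers=(cmp.alkylresorcinol(19, 2.0), cmp.alkylresorcinol(21, 3.0)),
        expected_flags={"cereal": "positive"},
    )
    specs["millet"] = CommoditySpec(
        "millet",
        markers=(cmp.miliacin(4.0),),
        expected_flags={"millet": "positive"},
    )
    return specs


def _weights(truth: VesselTruth, specs: Mapping[str, CommoditySpec]) -> Dict[str, float]:
    for label in truth.mixture:
        if label not in specs:
            raise ValidationError(f"mixture references unknown commodity {label!r}")
    return {label: w for label, w in truth.mixture.items() if w > 0}


def mix_isotopes(
    truth: VesselTruth,
    specs: Mapping[str, CommoditySpec],
    rng: Optional[np.random.Generator] = None,
) -> Optional[IsotopeMeasurement]:
    """Linear isotope mass balance over the mixture, per fatty acid.

    Each commodity's delta value is weighted by its mass fraction re-weighted
    by its relative contribution of that fatty acid.  With ``rng`` supplied,
    sampling noise is drawn from the mixture of per-commodity covariances
    (scaled by squared mixture weights); with ``rng=None`` the noise-free
    mass-balance means are returned.
    """
    weights = _weights(truth, specs)
    iso = {l: w for l, w in weights.items() if specs[l].isotope_mean is not None}
    if not iso:
        return None
    total = sum(iso.values())
    norm = {l: w / total for l, w in iso.items()}

    deltas = []
    for fa_idx in (0, 1):
        fa_w = {l: norm[l] * specs[l].fa_mass[fa_idx] for l in norm}
        fa_total = sum(fa_w.values())
        deltas.append(
            sum(fa_w[l] / fa_total * specs[l].isotope_mean[fa_idx] for l in fa_w)
        )
    point = np.array(deltas)
    if rng is not None:
        cov = sum(
            (w**2) * np.asarray(specs[l].isotope_cov, dtype=float)
            for l, w in norm.items()
        )
        point = rng.multivariate_normal(point, cov)
    return IsotopeMeasurement(float(point[0]), float(point[1]))


def mix_tags(
    truth: VesselTruth, specs: Mapping[str, CommoditySpec]
) -> Optional[TagProfile]:
    """Mass-weighted blend of TAG templates, then preferential low-mass loss."""
    weights = _weights(truth, specs)
    tagged = {l: w for l, w in weights.items() if specs[l].tag_template is not None}
    if not tagged:
        return None
    blend: Dict[int, float] = {}
    for label, w in tagged.items():
        template = specs[label].tag_template
        total = template.total
        for c, a in template.abundances.items():
            blend[c] = blend.get(c, 0.0) + w * a / total
    loss = truth.degradation.low_mw_tag_loss
    if loss > 0:
        blend = {c: (a * (1 - loss) if c <= 46 else a) for c, a in blend.items()}
    if not any(a > 0 for a in blend.values()):
        return None
    total = sum(blend.values())
    return TagProfile({c: a / total for c, a in blend.items()})


def emit_peaks(truth: VesselTruth, specs: Mapping[str, CommoditySpec]) -> PeakTable:
    """Union of commodity marker sets, heating ketones, and C18:1 oxidation."""
    weights = _weights(truth, specs)
    merged: Dict[Tuple, Peak] = {}

    def add(peak: Peak, scale: float) -> None:
        key = peak.key
        if key in merged:
            merged[key] = replace(merged[key], abundance=merged[key].abundance + peak.abundance * scale)
        else:
            merged[key] = replace(peak, abundance=peak.abundance * scale)

    for label, w in weights.items():
        for p in specs[label].markers:
            add(p, w)
    if truth.heated:
        for p in cmp.heating_ketones(2.0):
            add(p, 1.0)
    ox = truth.degradation.c18_1_oxidation
    if ox > 0:
        out = {}
        for key, p in merged.items():
            if p.compound_class == "fatty_acid" and p.chain_length == 18 and p.unsaturation == 1:
                p = replace(p, abundance=p.abundance * (1 - ox))
            if p.abundance > 0:
                out[key] = p
        merged = out
    return PeakTable(merged.values())


def mix_acids(
    truth: VesselTruth,
    specs: Mapping[str, CommoditySpec],
    rng: Optional[np.random.Generator] = None,
) -> Optional[AcidQuant]:
    """Mass-weighted sum of class-conditional acid draws (None when no source)."""
    weights = _weights(truth, specs)
    sourced = {l: w for l, w in weights.items() if specs[l].acid_model is not None}
    if not sourced:
        return None
    tartaric = malic = 0.0
    for label, w in sourced.items():
        t, m = specs[label].acid_model.sample(rng)
        tartaric += w * t
        malic += w * m
    return AcidQuant(tartaric=tartaric, malic=malic)


def build_vessel(
    truth: VesselTruth,
    specs: Mapping[str, CommoditySpec],
    site: str,
    vessel_form: str,
    concentration: float,
    rng: Optional[np.random.Generator] = None,
) -> SampleRecord:
    """Forward-model one vessel (noise-free when ``rng`` is None)."""
    isotopes = mix_isotopes(truth, specs, rng)
    tag_profile = mix_tags(truth, specs)
    peaks = emit_peaks(truth, specs)
    acids = mix_acids(truth, specs, rng)
    flags = {"acid_methanol"}
    if tag_profile is not None:
        flags.add("solvent")
    if acids is not None:
        flags.add("butylation")
    return SampleRecord(
        sample_id=truth.sample_id,
        site=site,
        vessel_form=vessel_form,
        lipid_concentration=concentration,
        isotopes=isotopes,
        tag_profile=tag_profile,
        peaks=peaks,
        acids=acids,
        extraction_flags=frozenset(flags),
    )


def generate_assemblage(
    spec: AssemblageSpec,
    n: int,
    seed: int,
    specs: Optional[Mapping[str, CommoditySpec]] = None,
    refs: Optional[Mapping[str, ReferenceClass]] = None,
    config: Optional[PipelineConfig] = None,
    noise: bool = True,
) -> Tuple[List[SampleRecord], List[VesselTruth]]:
    """Generate ``n`` vessels from the site composition, with ground truth.

    Expected flags in each :class:`VesselTruth` come from running the full
    interpretation pipeline on the vessel's noise-free twin, so the declared
    truth is exactly what the vessel's contents imply under the forward
    model without sampling noise.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not spec.blueprints:
        raise ValidationError("assemblage spec has no blueprints")
    rng = np.random.default_rng(seed)
    specs = dict(specs) if specs is not None else default_specs(refs)
    refs = dict(refs) if refs is not None else load_reference_classes()
    cfg = config or PipelineConfig()

    weights = np.array([b.weight for b in spec.blueprints], dtype=float)
    records: List[SampleRecord] = []
    truths: List[VesselTruth] = []
    for i in range(n):
        bp = spec.blueprints[int(rng.choice(len(spec.blueprints), p=weights))]
        truth = VesselTruth(
            sample_id=f"{spec.site}_{i + 1:04d}",
            mixture=dict(bp.mixture),
            heated=bp.heated,
            degradation=bp.degradation,
        )
        form = spec.vessel_forms[i % len(spec.vessel_forms)]
        if noise:
            if rng.uniform() < spec.poor_preservation_rate:
                conc = float(rng.uniform(0.2, 5.0))
            else:
                conc = float(
                    spec.conc_median * math.exp(rng.normal(0.0, spec.conc_log_sigma))
                )
        else:
            conc = spec.conc_median
        clean = build_vessel(truth, specs, spec.site, form, conc, rng=None)
        expected = build_commodity_profile(clean, refs, cfg)
        truth.expected_flags = {
            label: level.value for label, level in expected.fired().items()
        }
        truth.expected_heating = expected.heating
        record = (
            build_vessel(truth, specs, spec.site, form, conc, rng=rng)
            if noise
            else clean
        )
        records.append(record)
        truths.append(truth)
    return records, truths


def default_assemblage_spec(site: str = "SYN") -> AssemblageSpec:
    """A study-like site composition: mostly animal fats, frequent plant and
    fruit admixtures, occasional dairy, grape, beeswax and pine vessels."""
    b = VesselBlueprint
    return AssemblageSpec(
        site=site,
        blueprints=(
            b(0.18, {"ruminant_adipose": 1.0}),
            b(0.14, {"non_ruminant": 1.0}),
            b(0.08, {"ruminant_dairy": 1.0}, heated=True),
            b(0.10, {"ruminant_adipose": 0.6, "brassica": 0.4}, heated=True),
            b(0.10, {"non_ruminant": 0.7, "fruit": 0.3}),
            b(0.08, {"ruminant_adipose": 0.5, "non_ruminant": 0.5}),
            b(0.06, {"grape": 1.0}),
            b(0.06, {"fruit": 1.0}),
            b(0.05, {"porcine_tentative": 1.0}),
            b(0.05, {"plant_unidentified": 1.0}),
            b(0.04, {"leek": 0.5, "non_ruminant": 0.5}, heated=True),
            b(0.03, {"fennel_or_sermountain": 1.0}),
            b(0.02, {"beeswax": 0.5, "pine_resin": 0.5}),
            b(0.01, {"pitch": 1.0}),
        ),
    )


def flag_recovery(
    truths: Sequence[VesselTruth],
    profiles: Sequence,
    labels: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of (vessel, label) decisions matching the declared truth.

    A decision matches when the label fires (any strength) in both truth
    and profile, or in neither; heating is scored as one extra decision.
    """
    from .types import COMMODITY_LABELS, EvidenceLevel

    labels = list(labels) if labels is not None else list(COMMODITY_LABELS)
    if len(truths) != len(profiles):
        raise ValidationError("truths and profiles must align")
    hits = total = 0
    for truth, prof in zip(truths, profiles):
        for label in labels:
            want = label in truth.expected_flags
            got = prof.flags[label] is not EvidenceLevel.ABSENT
            hits += want == got
            total += 1
        hits += truth.expected_heating == prof.heating
        total += 1
    return hits / total
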