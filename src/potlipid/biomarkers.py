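"""Molecular-biomarker rules over GC-MS peak tables.

Each rule is a pure function ``(PeakTable, RuleConfig) -> RuleResult`` that
pattern-matches identified compounds: plant (leaf) waxes and their taxon
markers (mid-chain ketones of Brassica, leek, fennel/sermountain), seed
oils, beeswax, Pinaceae resin and pitch, heating markers, aquatic markers,
sterols, cereal alkylresorcinols and miliacin.  "Presence" means abundance
strictly above the configured floor (default 0); rules are monotone in
evidence — adding peaks never un-fires a fired rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from . import compounds as cmp
from .config import RuleConfig
from .types import Peak, PeakTable, ValidationError


@dataclass
class RuleResult:
    """Outcome of one biomarker rule, with the peaks that satisfied it."""

    rule_id: str
    fired: bool = False
    evidence: List[Tuple[str, float]] = field(default_factory=list)
    strength: str = "positive"
    notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fired and self.evidence:
            raise ValidationError(f"{self.rule_id}: evidence on an unfired rule")


def _ev(peaks: Sequence[Peak]) -> List[Tuple[str, float]]:
    return [(p.compound, p.abundance) for p in sorted(peaks, key=lambda p: p.key)]


def _present(peaks: PeakTable, floor: float, **coords) -> List[Peak]:
    return [
        p
        for p in peaks.rows()
        if p.abundance > floor
        and all(getattr(p, k) == v for k, v in coords.items())
    ]


def dominance(
    peaks: PeakTable,
    compound_class: str,
    chain: int,
    floor: float = 0.0,
) -> bool:
    """True iff ``chain`` has strictly the greatest abundance in its class.

    Ties lose: a shared maximum is not dominance.
    """
    per_chain = peaks.chain_abundances(compound_class, floor=floor)
    if chain not in per_chain:
        return False
    target = per_chain[chain]
    return all(a < target for c, a in per_chain.items() if c != chain)


def _odd_alkanes(peaks: PeakTable, rng: Tuple[int, int], floor: float) -> Dict[int, float]:
    lo, hi = rng
    return peaks.chain_abundances("n_alkane", chains=range(lo, hi + 1), parity=1, floor=floor)


def detect_plant_wax(peaks: PeakTable, config: RuleConfig = RuleConfig()) -> RuleResult:
    """Leaf-wax suite: odd C25-C33 alkanes dominated by C29 or C31,
    supported by n-alkanols or W40-W48 wax esters for a positive call."""
    floor = config.presence_floor
    odd = _odd_alkanes(peaks, config.plant_wax_alkane_range, floor)
    alkane_ok = bool(odd) and any(
        dominance(peaks, "n_alkane", c, floor) for c in config.plant_wax_dominants
    )
    if not alkane_ok:
        return RuleResult("plant_wax", fired=False)
    alkanols = [p for p in peaks.class_rows("n_alkanol") if p.abundance > floor]
    lo, hi = config.wax_ester_range
    wes = [
        p
        for p in peaks.class_rows("wax_ester")
        if p.abundance > floor and lo <= p.chain_length <= hi
    ]
    alkane_peaks = _present(peaks, floor, compound_class="n_alkane")
    evidence_peaks = [p for p in alkane_peaks if p.chain_length in odd]
    if alkanols or wes:
        return RuleResult(
            "plant_wax", True, _ev(evidence_peaks + alkanols + wes), "positive"
        )
    return RuleResult("plant_wax", True, _ev(evidence_peaks), "tentative")


def detect_taxon_ketones(
    peaks: PeakTable, config: RuleConfig = RuleConfig()
) -> Dict[str, RuleResult]:
    """Taxon-specific mid-chain ketones.

    * Brassica — nonacosan-15-one; positive when nonacosan-15-ol co-occurs.
    * Leek — hentriacontan-16-one together with the C31 n-alkane.
    * Fennel / broad-leaved sermountain — nonacosan-10-one; always
      tentative (no second marker can firmly identify these taxa).
    """
    floor = config.presence_floor
    out: Dict[str, RuleResult] = {}

    k29_15 = _present(peaks, floor, compound_class="mid_chain_ketone", chain_length=29, substituent_position=15)
    ol29_15 = _present(peaks, floor, compound_class="n_alkanol", chain_length=29, substituent_position=15)
    if k29_15:
        strength = "positive" if ol29_15 else "tentative"
        out["brassica"] = RuleResult("brassica", True, _ev(k29_15 + ol29_15), strength)
    else:
        out["brassica"] = RuleResult("brassica", fired=False)

    k31_16 = _present(peaks, floor, compound_class="mid_chain_ketone", chain_length=31, substituent_position=16)
    a31 = _present(peaks, floor, compound_class="n_alkane", chain_length=31)
    if k31_16 and a31:
        out["leek"] = RuleResult("leek", True, _ev(k31_16 + a31), "positive")
    else:
        out["leek"] = RuleResult("leek", fired=False)

    k29_10 = _present(peaks, floor, compound_class="mid_chain_ketone", chain_length=29, substituent_position=10)
    if k29_10:
        out["fennel_or_sermountain"] = RuleResult(
            "fennel_or_sermountain", True, _ev(k29_10), "tentative"
        )
    else:
        out["fennel_or_sermountain"] = RuleResult("fennel_or_sermountain", fired=False)
    return out


def detect_heating(peaks: PeakTable, config: RuleConfig = RuleConfig()) -> RuleResult:
    """Thermal markers: symmetric long-chain ketones or APAAs.

    Ketone evidence counts chains in ``heating_ketone_chains`` (default K33,
    K35) at their symmetric mid-chain position; taxon ketones at positions
    10/15/16 never trigger heating, which also excludes the ambiguous
    K31/leek compound hentriacontan-16-one from firing on its own (it is
    still recorded as supporting evidence when the series fires).
    """
    floor = config.presence_floor
    kets: List[Peak] = []
    for chain in config.heating_ketone_chains:
        pos = cmp.symmetric_position(chain)
        if pos in (10, 15, 16):
            continue
        kets.extend(
            _present(
                peaks,
                floor,
                compound_class="mid_chain_ketone",
                chain_length=chain,
                substituent_position=pos,
            )
        )
    lo, hi = config.apaa_chain_range
    apaas = [
        p
        for p in peaks.class_rows("apaa")
        if p.abundance > floor and lo <= p.chain_length <= hi
    ]
    if not kets and not apaas:
        return RuleResult("heating", fired=False)
    support = kets + apaas
    if kets:
        support += _present(
            peaks, floor, compound_class="mid_chain_ketone", chain_length=31, substituent_position=16
        )
    return RuleResult("heating", True, _ev(support), "positive")


def detect_plant_oil(peaks: PeakTable, config: RuleConfig = RuleConfig()) -> RuleResult:
    """Seed-oil signature: oleic/stearic ratio strictly above threshold with
    linoleic acid present.  An undefined ratio (no stearic acid) never fires."""
    floor = config.presence_floor
    oleic = peaks.abundance_of("fatty_acid", chain_length=18, unsaturation=1)
    stearic = peaks.abundance_of("fatty_acid", chain_length=18, unsaturation=0)
    linoleic = _present(peaks, floor, compound_class="fatty_acid", chain_length=18, unsaturation=2)
    if stearic <= floor:
        res = RuleResult("plant_oil", fired=False)
        if oleic > floor:
            res.notes.append("oleic/stearic ratio undefined (no C18:0); no call")
        return res
    if oleic / stearic > config.plant_oil_ratio and linoleic:
        ev = _present(peaks, floor, compound_class="fatty_acid", chain_length=18)
        return RuleResult("plant_oil", True, _ev(ev), "positive")
    return RuleResult("plant_oil", fired=False)


def _beeswax_conditions(
    peaks: PeakTable, config: RuleConfig
) -> List[Tuple[str, List[Peak]]]:
    floor = config.presence_floor
    met: List[Tuple[str, List[Peak]]] = []
    odd = _odd_alkanes(peaks, (25, 33), floor)
    if odd and dominance(peaks, "n_alkane", 27, floor):
        met.append(("alkanes C25-C33 dominated by C27",
                    [p for p in _present(peaks, floor, compound_class="n_alkane") if p.chain_length in odd]))
    evens = peaks.chain_abundances(
        "fatty_acid", chains=range(20, 29), parity=0, unsaturation=0, floor=floor
    )
    if evens and 24 in evens and all(a < evens[24] for c, a in evens.items() if c != 24):
        met.append(("even FAs C20:0-C28:0 dominated by C24:0",
                    [p for p in _present(peaks, floor, compound_class="fatty_acid", unsaturation=0) if p.chain_length in evens]))
    ols = peaks.chain_abundances(
        "n_alkanol", chains=range(24, 33), parity=0, floor=floor
    )
    if ols and 30 in ols and all(a < ols[30] for c, a in ols.items() if c != 30):
        met.append(("alkanols C24-C32 dominated by C30",
                    [p for p in _present(peaks, floor, compound_class="n_alkanol") if p.chain_length in ols]))
    wes = [
        p
        for p in peaks.class_rows("wax_ester")
        if p.abundance > floor and 40 <= p.chain_length <= 50
    ]
    if wes:
        met.append(("wax esters W40-W50", wes))
    return met


def detect_beeswax(peaks: PeakTable, config: RuleConfig = RuleConfig()) -> RuleResult:
    """Beeswax suite: quorum over four component families (odd alkanes with
    C27 dominant; even long-chain FAs with C24:0 dominant; alkanols with C30
    dominant; W40-W50 palmitate wax esters).  Three of four families give a
    positive call, exactly two a tentative one."""
    met = _beeswax_conditions(peaks, config)
    n = len(met)
    if n >= config.beeswax_quorum_positive:
        strength = "positive"
    elif n >= config.beeswax_quorum_tentative:
        strength = "tentative"
    else:
        return RuleResult("beeswax", fired=False)
    ev: List[Peak] = []
    for _, ps in met:
        ev.extend(ps)
    res = RuleResult("beeswax", True, _ev(ev), strength)
    res.notes = [name for name, _ in met]
    return res


def detect_pine(
    peaks: PeakTable, config: RuleConfig = RuleConfig()
) -> Dict[str, RuleResult]:
    """Pinaceae resin and pitch.

    Resin fires positive on dehydroabietic acid (DHA) plus at least one
    other Pinaceae diterpenoid or oxidation product; DHA alone is tentative.
    Pitch requires a fired resin call plus retene or methyl-DHA (markers of
    resin heated with wood)."""
    floor = config.presence_floor
    dha = [p for p in peaks.class_rows("diterpenoid") if p.compound == cmp.DHA and p.abundance > floor]
    companions = [
        p
        for p in peaks.class_rows("diterpenoid")
        if p.compound in cmp.PINE_COMPANIONS and p.abundance > floor
    ]
    out: Dict[str, RuleResult] = {}
    if dha and companions:
        out["pine_resin"] = RuleResult("pine_resin", True, _ev(dha + companions), "positive")
    elif dha:
        out["pine_resin"] = RuleResult("pine_resin", True, _ev(dha), "tentative")
    else:
        out["pine_resin"] = RuleResult("pine_resin", fired=False)

    pitch_markers = [
        p
        for p in peaks.rows()
        if p.compound in cmp.PITCH_MARKERS and p.abundance > floor
    ]
    if out["pine_resin"].fired and pitch_markers:
        out["pitch"] = RuleResult("pitch", True, _ev(pitch_markers), "positive")
    else:
        out["pitch"] = RuleResult("pitch", fired=False)
    return out


def detect_aquatic(peaks: PeakTable, config: RuleConfig = RuleConfig()) -> RuleResult:
    """Aquatic-oil criterion: long-chain APAAs (acyl chain >= 20) together
    with at least two distinct isoprenoid acids (phytanic, pristanic, TMTD).

    Isoprenoids alone never fire — they also occur in terrestrial animal
    fats, at lower abundance."""
    floor = config.presence_floor
    long_apaas = [
        p
        for p in peaks.class_rows("apaa")
        if p.abundance > floor and p.chain_length >= config.aquatic_min_apaa_chain
    ]
    isos = [
        p
        for p in peaks.class_rows("isoprenoid_acid")
        if p.compound in cmp.ISOPRENOID_ACIDS and p.abundance > floor
    ]
    if long_apaas and len({p.compound for p in isos}) >= config.aquatic_isoprenoid_quorum:
        return RuleResult("aquatic", True, _ev(long_apaas + isos), "positive")
    res = RuleResult("aquatic", fired=False)
    if isos and not long_apaas:
        res.notes.append(
            "isoprenoid acids present without long-chain APAAs; "
            "these also occur in some terrestrial animal fats"
        )
    return res


def phytanic_srr(
    srr_abundance: float,
    rrr_abundance: float,
    config: RuleConfig = RuleConfig(),
) -> Tuple[float, str]:
    """%SRR = 100 * SRR / (SRR + RRR) of phytanic-acid stereoisomers, with a
    window call against configurable aquatic/ruminant reference ranges:
    ``aquatic_range``, ``ruminant_range``, ``overlap`` or ``neither``."""
    if srr_abundance < 0 or rrr_abundance < 0:
        raise ValidationError("stereoisomer abundances must be >= 0")
    total = srr_abundance + rrr_abundance
    if total == 0:
        raise ValidationError("%SRR undefined: both stereoisomer abundances are zero")
    pct = 100.0 * srr_abundance / total
    a_lo, a_hi = config.srr_aquatic_window
    r_lo, r_hi = config.srr_ruminant_window
    in_aq = a_lo <= pct <= a_hi
    in_rum = r_lo <= pct <= r_hi
    if in_aq and in_rum:
        call = "overlap"
    elif in_aq:
        call = "aquatic_range"
    elif in_rum:
        call = "ruminant_range"
    else:
        call = "neither"
    return pct, call


def detect_sterols(
    peaks: PeakTable, config: RuleConfig = RuleConfig()
) -> Dict[str, RuleResult]:
    """Sterol calls: cholesterol (animal), beta-sitosterol/campesterol/
    stigmasterol (plant), with a note when spinach-specific sterols appear."""
    floor = config.presence_floor
    chol = [p for p in peaks.class_rows("sterol") if p.compound == cmp.CHOLESTEROL and p.abundance > floor]
    plant = [p for p in peaks.class_rows("sterol") if p.compound in cmp.PLANT_STEROLS and p.abundance > floor]
    spinach = [p for p in peaks.class_rows("sterol") if p.compound in cmp.SPINACH_STEROLS and p.abundance > floor]
    out = {
        "animal_sterol": RuleResult("animal_sterol", bool(chol), _ev(chol), "positive"),
        "plant_sterol": RuleResult("plant_sterol", bool(plant), _ev(plant), "positive"),
    }
    if spinach:
        out["plant_sterol"].notes.append(
            "spinach-specific sterols present: " + ", ".join(p.compound for p in spinach)
        )
        if not out["plant_sterol"].fired:
            out["plant_sterol"] = RuleResult(
                "plant_sterol", True, _ev(spinach), "tentative", out["plant_sterol"].notes
            )
    return out


def detect_cereal_markers(
    peaks: PeakTable, config: RuleConfig = RuleConfig()
) -> Dict[str, RuleResult]:
    """Cereal alkylresorcinols (wheat/barley/rye) and miliacin (broomcorn millet)."""
    floor = config.presence_floor
    ars = [p for p in peaks.class_rows("alkylresorcinol") if p.abundance > floor]
    mil = [p for p in peaks.class_rows("triterpenoid_ether") if p.compound == cmp.MILIACIN and p.abundance > floor]
    return {
        "cereal": RuleResult("cereal", bool(ars), _ev(ars), "positive"),
        "millet": RuleResult("millet", bool(mil), _ev(mil), "positive"),
    }


def detect_ruminant_bacterial(
    peaks: PeakTable, config: RuleConfig = RuleConfig()
) -> RuleResult:
    """Rumen-bacterial fingerprint: a branched C15:0/C17:0 fatty acid
    together with a linear C15:0/C17:0 fatty acid."""
    floor = config.presence_floor
    branched = [
        p
        for p in peaks.class_rows("branched_fatty_acid")
        if p.abundance > floor and p.chain_length in (15, 17)
    ]
    linear = [
        p
        for p in peaks.class_rows("fatty_acid")
        if p.abundance > floor and p.chain_length in (15, 17) and p.unsaturation == 0
    ]
    if branched and linear:
        return RuleResult("ruminant_bacterial", True, _ev(branched + linear), "positive")
    return RuleResult("ruminant_bacterial", fired=False)


def detect_grape_wax(peaks: PeakTable, config: RuleConfig = RuleConfig()) -> RuleResult:
    """Grape-berry epicuticular wax: odd n-alkanes with C25 strictly dominant."""
    floor = config.presence_floor
    odd = _odd_alkanes(peaks, (23, 33), floor)
    if odd and dominance(peaks, "n_alkane", 25, floor):
        ev = [p for p in _present(peaks, floor, compound_class="n_alkane") if p.chain_length in odd]
        return RuleResult("grape_wax", True, _ev(ev), "tentative")
    return RuleResult("grape_wax", fired=False)


_SINGLE_RULES: Dict[str, Callable[[PeakTable, RuleConfig], RuleResult]] = {
    "plant_wax": detect_plant_wax,
    "heating": detect_heating,
    "plant_oil": detect_plant_oil,
    "beeswax": detect_beeswax,
    "aquatic": detect_aquatic,
    "ruminant_bacterial": detect_ruminant_bacterial,
    "grape_wax": detect_grape_wax,
}

_MULTI_RULES = (detect_taxon_ketones, detect_pine, detect_sterols, detect_cereal_markers)


def run_all_rules(
    peaks: PeakTable, config: Optional[RuleConfig] = None
) -> Dict[str, RuleResult]:
    """Run the whole rule registry over one peak table."""
    cfg = config or RuleConfig()
    results: Dict[str, RuleResult] = {}
    for rule_id, fn in _SINGLE_RULES.items():
        results[rule_id] = fn(peaks, cfg)
    for fn in _MULTI_RULES:
        results.update(fn(peaks, cfg))
    return results
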