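"""Fuse isotope, TAG, biomarker and acid evidence into per-vessel profiles.

Fusion precedence: molecular evidence (TAG envelopes, biomarkers) can
*upgrade* but never delete an isotope-based call; conflicts between proxies
are recorded in the profile notes rather than silently resolved.  Samples
below the lipid-interpretability threshold receive an all-absent profile
with an explanatory note; measurement blocks that were not analysed degrade
to absent flags plus a not-analysed note, never to negative calls.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from . import biomarkers, fruit_acids, tags
from .config import PipelineConfig
from .isotopes import ReferenceClass, classify_by_ellipse, classify_delta
from .types import (
    COMMODITY_LABELS,
    CommodityProfile,
    EvidenceLevel,
    SampleRecord,
    ValidationError,
)

POSITIVE = EvidenceLevel.POSITIVE
TENTATIVE = EvidenceLevel.TENTATIVE


def is_interpretable(concentration: float, threshold: float = 5.0) -> bool:
    """True iff the lipid concentration (ug/g) is reliably endogenous."""
    if concentration < 0:
        raise ValidationError(f"lipid concentration negative: {concentration}")
    return concentration >= threshold


def build_commodity_profile(
    record: SampleRecord,
    refs: Optional[Mapping[str, ReferenceClass]] = None,
    config: Optional[PipelineConfig] = None,
) -> CommodityProfile:
    """Derive the full commodity-evidence profile for one vessel."""
    cfg = config or PipelineConfig()
    profile = CommodityProfile()

    if not is_interpretable(record.lipid_concentration, cfg.lipid_threshold):
        profile.note(
            f"below interpretability threshold "
            f"({record.lipid_concentration:g} < {cfg.lipid_threshold:g} ug/g); no calls"
        )
        return profile

    _apply_isotopes(record, profile, refs, cfg)
    tag_class = _apply_tags(record, profile)
    rules = biomarkers.run_all_rules(record.peaks, cfg.rules)
    _apply_rules(rules, profile)
    _apply_acids(record, profile, cfg)

    # Dairy TAG envelope upgrades the animal call even under a non-dairy
    # Delta13C (mixing of fats dilutes the isotope signal first).
    if tag_class == "dairy_like":
        if record.isotopes is not None and profile.flags["ruminant_dairy"] is not POSITIVE:
            profile.note(
                "TAG envelope dairy_like under non-dairy Delta13C: dairy upgraded, "
                "isotope call retained (proxy conflict)"
            )
        profile.set_at_least("ruminant_dairy", POSITIVE)

    profile.validate()
    return profile


def _apply_isotopes(
    record: SampleRecord,
    profile: CommodityProfile,
    refs: Optional[Mapping[str, ReferenceClass]],
    cfg: PipelineConfig,
) -> None:
    m = record.isotopes
    if m is None:
        profile.note("no isotope data; no animal-fat call")
        return
    window = classify_delta(m.delta13c)
    profile.set_at_least(window, POSITIVE)
    profile.note(f"delta_window:{window} (Delta13C={m.delta13c:+.2f})")
    if refs:
        ec = classify_by_ellipse(
            m, refs.values(), edge_class="porcine", edge_coverage=cfg.porcine_edge_coverage
        )
        if ec.members:
            profile.note("ellipse_members:" + ",".join(sorted(ec.members)))
        if ec.porcine_tentative or (
            "porcine" in ec.members and window == "non_ruminant"
        ):
            profile.set_at_least("porcine_tentative", TENTATIVE)
            profile.note("rule:porcine_edge")


def _apply_tags(record: SampleRecord, profile: CommodityProfile) -> Optional[str]:
    if record.tag_profile is None:
        return None
    tag_class = tags.classify_tag_profile(record.tag_profile)
    m = tags.tag_mean_carbon(record.tag_profile)
    df = tags.tag_dispersion(record.tag_profile)
    profile.note(f"tag:{tag_class} (M={m:.2f}, DF={df:.2f})")
    if tag_class == "adipose_like" and record.isotopes is None:
        profile.set_at_least("ruminant_adipose", TENTATIVE)
    return tag_class


_RULE_TO_FLAG = {
    "plant_wax": "plant_wax",
    "plant_oil": "plant_oil",
    "beeswax": "beeswax",
    "pine_resin": "pine_resin",
    "pitch": "pitch",
    "aquatic": "aquatic",
    "cereal": "cereal",
    "millet": "millet",
    "brassica": "brassica",
    "leek": "leek",
    "fennel_or_sermountain": "fennel_or_sermountain",
}

_TAXON_RULES = ("brassica", "leek", "fennel_or_sermountain")


def _apply_rules(rules: Dict[str, biomarkers.RuleResult], profile: CommodityProfile) -> None:
    for rule_id, flag in _RULE_TO_FLAG.items():
        res = rules.get(rule_id)
        if res is not None and res.fired:
            profile.set_at_least(flag, EvidenceLevel(res.strength))
            profile.note(f"rule:{rule_id}:{res.strength}")
    # Pitch is heat-transformed resin, so a pitch call certifies the resin.
    if profile.flags["pitch"] is POSITIVE:
        profile.set_at_least("pine_resin", POSITIVE)
    # Taxon-specific leaf-wax markers imply a plant wax was present even when
    # the generic alkane suite is too degraded to fire on its own.
    if any(rules[t].fired for t in _TAXON_RULES if t in rules):
        profile.set_at_least("plant_wax", TENTATIVE)

    taxon_fired = any(rules[t].fired for t in _TAXON_RULES if t in rules)
    plant_sterol = rules.get("plant_sterol")
    if not taxon_fired and (
        (plant_sterol is not None and plant_sterol.fired)
        or profile.flags["plant_wax"] is TENTATIVE
    ):
        profile.set_at_least("plant_unidentified", TENTATIVE)
        profile.note("rule:plant_unidentified")

    for aux in ("animal_sterol", "ruminant_bacterial", "grape_wax", "heating"):
        res = rules.get(aux)
        if res is not None and res.fired:
            profile.note(f"rule:{aux}:{res.strength}")
    for res in rules.values():
        for n in res.notes:
            profile.note(f"{res.rule_id}: {n}")

    heating = rules.get("heating")
    profile.heating = bool(heating is not None and heating.fired)


def _apply_acids(record: SampleRecord, profile: CommodityProfile, cfg: PipelineConfig) -> None:
    if record.acids is None or "butylation" not in record.extraction_flags:
        profile.note("not analysed for fruit acids")
        return
    call = fruit_acids.classify_fruit_signal(
        record.acids, ta_threshold=cfg.ta_threshold, malic_floor=cfg.malic_floor
    )
    if call.percent_ta is not None:
        profile.note(f"percent_ta:{call.percent_ta:.1f}")
    if call.label == "grape_product":
        profile.set_at_least("grape", POSITIVE)
        profile.set_at_least("fruit", POSITIVE)
        profile.note("rule:grape_product")
    elif call.label == "other_fruit":
        profile.set_at_least("fruit", POSITIVE)
        profile.note("rule:other_fruit")
    elif call.label == "plant_nonspecific":
        profile.note("acids:plant_nonspecific")
    for n in call.notes:
        profile.note(f"acids: {n}")


def summarize_assemblage(
    profiles: Iterable[Tuple[SampleRecord, CommodityProfile]],
    group_by: str = "site",
) -> pd.DataFrame:
    """Group-level summary: n, mean lipid concentration, per-flag counts and
    fractions at each evidence level, and heating counts.

    ``group_by`` is one of ``site``, ``vessel_form`` or ``site_form``.
    """
    pairs = list(profiles)
    if not pairs:
        raise ValidationError("summarize_assemblage needs at least one profile")

    def key(rec: SampleRecord) -> Tuple[str, ...]:
        if group_by == "site":
            return (rec.site,)
        if group_by == "vessel_form":
            return (rec.vessel_form,)
        if group_by == "site_form":
            return (rec.site, rec.vessel_form)
        raise ValidationError(f"unknown group_by {group_by!r}")

    groups: Dict[Tuple[str, ...], List[Tuple[SampleRecord, CommodityProfile]]] = {}
    for rec, prof in pairs:
        groups.setdefault(key(rec), []).append((rec, prof))

    rows = []
    for gkey in sorted(groups):
        members = groups[gkey]
        n = len(members)
        row: Dict[str, object] = {}
        if group_by == "site_form":
            row["site"], row["vessel_form"] = gkey
        else:
            row[group_by] = gkey[0]
        row["n"] = n
        row["mean_lipid_concentration"] = (
            sum(rec.lipid_concentration for rec, _ in members) / n
        )
        row["n_heating"] = sum(1 for _, p in members if p.heating)
        for label in COMMODITY_LABELS:
            for level in EvidenceLevel:
                count = sum(1 for _, p in members if p.flags[label] is level)
                row[f"{label}_{level.value}"] = count
            fired = sum(
                1 for _, p in members if p.flags[label] is not EvidenceLevel.ABSENT
            )
            row[f"{label}_fraction"] = fired / n
        rows.append(row)
    return pd.DataFrame(rows)
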