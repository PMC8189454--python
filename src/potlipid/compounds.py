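"""Canonical compound vocabulary and peak constructors.

Compound names follow common usage in archaeological lipid work (e.g.
"dehydroabietic acid", "miliacin", "nonacosan-15-one").  Helper constructors
build :class:`~potlipid.types.Peak` rows with consistent naming so peak
tables written by hand, by the simulator and by readers all agree.
"""

from __future__ import annotations

from typing import Optional

from .types import Peak

# Named sterols (structural coordinates overlap, names disambiguate).
CHOLESTEROL = "cholesterol"
B_SITOSTEROL = "beta-sitosterol"
CAMPESTEROL = "campesterol"
STIGMASTEROL = "stigmasterol"
A_SPINASTEROL = "alpha-spinasterol"
STIGMASTENOL_7 = "7-stigmastenol"

PLANT_STEROLS = (B_SITOSTEROL, CAMPESTEROL, STIGMASTEROL)
SPINACH_STEROLS = (A_SPINASTEROL, STIGMASTENOL_7)

# Pinaceae diterpenoids and their oxidation / pyrolysis products.
ABIETIC = "abietic acid"
PIMARIC = "pimaric acid"
ISOPIMARIC = "isopimaric acid"
DHA = "dehydroabietic acid"
OXO_DHA = "7-oxo-dehydroabietic acid"
HYDROXY_DHA = "15-hydroxy-dehydroabietic acid"
METHYL_DHA = "methyl dehydroabietic acid"
RETENE = "retene"

PINE_COMPANIONS = (ABIETIC, PIMARIC, ISOPIMARIC, OXO_DHA, HYDROXY_DHA, METHYL_DHA)
PITCH_MARKERS = (RETENE, METHYL_DHA)

# Isoprenoid fatty acids (aquatic / ruminant markers).
PHYTANIC = "phytanic acid"
PRISTANIC = "pristanic acid"
TMTD = "4,8,12-trimethyltridecanoic acid"
ISOPRENOID_ACIDS = (PHYTANIC, PRISTANIC, TMTD)
_ISOPRENOID_CHAINS = {PHYTANIC: 20, PRISTANIC: 19, TMTD: 16}

# Millet triterpenoid ether.
MILIACIN = "miliacin"

_STEROL_CHAINS = {
    CHOLESTEROL: 27,
    CAMPESTEROL: 28,
    B_SITOSTEROL: 29,
    STIGMASTEROL: 29,
    A_SPINASTEROL: 29,
    STIGMASTENOL_7: 29,
}


def alkane(chain: int, abundance: float) -> Peak:
    return Peak(f"n-alkane C{chain}", "n_alkane", chain, 0, 0, abundance)


def alkanol(chain: int, abundance: float, position: int = 0) -> Peak:
    name = f"n-alkanol C{chain}" if position == 0 else _mid_chain_name(chain, position, "ol")
    return Peak(name, "n_alkanol", chain, position, 0, abundance)


def ketone(chain: int, position: int, abundance: float) -> Peak:
    return Peak(_mid_chain_name(chain, position, "one"), "mid_chain_ketone", chain, position, 0, abundance)


def fatty_acid(chain: int, abundance: float, unsaturation: int = 0) -> Peak:
    return Peak(f"C{chain}:{unsaturation} fatty acid", "fatty_acid", chain, 0, unsaturation, abundance)


def branched_fatty_acid(chain: int, abundance: float) -> Peak:
    return Peak(f"branched C{chain}:0 fatty acid", "branched_fatty_acid", chain, 0, 0, abundance)


def wax_ester(total_carbons: int, abundance: float) -> Peak:
    return Peak(f"wax ester W{total_carbons}", "wax_ester", total_carbons, 0, 0, abundance)


def apaa(chain: int, abundance: float) -> Peak:
    """omega-(o-alkylphenyl)alkanoic acid of the given acyl chain length."""
    return Peak(f"APAA C{chain}", "apaa", chain, 0, 0, abundance)


def alkylresorcinol(chain: int, abundance: float) -> Peak:
    return Peak(f"alkylresorcinol C{chain}", "alkylresorcinol", chain, 0, 0, abundance)


def sterol(name: str, abundance: float) -> Peak:
    return Peak(name, "sterol", _STEROL_CHAINS.get(name, 0), 0, 0, abundance)


def diterpenoid(name: str, abundance: float) -> Peak:
    return Peak(name, "diterpenoid", 0, 0, 0, abundance)


def isoprenoid(name: str, abundance: float) -> Peak:
    return Peak(name, "isoprenoid_acid", _ISOPRENOID_CHAINS.get(name, 0), 0, 0, abundance)


def miliacin(abundance: float) -> Peak:
    return Peak(MILIACIN, "triterpenoid_ether", 0, 0, 0, abundance)


_GREEK = {29: "nonacosan", 31: "hentriacontan", 33: "tritriacontan", 35: "pentatriacontan"}


def _mid_chain_name(chain: int, position: int, suffix: str) -> str:
    stem = _GREEK.get(chain, f"C{chain}-alkan")
    return f"{stem}-{position}-{suffix}"


def heating_ketones(abundance: float) -> list[Peak]:
    """The K31/K33/K35 symmetric-ketone series formed by fatty-acid condensation."""
    return [ketone(31, 16, abundance), ketone(33, 17, abundance), ketone(35, 18, abundance)]


def symmetric_position(chain: int) -> Optional[int]:
    """Mid-chain carbonyl position of the symmetric condensation ketone."""
    return (chain + 1) // 2 if chain % 2 == 1 else None
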