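"""Domain types for pottery organic-residue interpretation.

A *sample* is one ceramic sherd with the full set of measurements an
organic-residue study produces: total lipid concentration, compound-specific
fatty-acid carbon-isotope values, a triacylglycerol (TAG) carbon-number
envelope, an integrated GC-MS peak table, and small-organic-acid quantities
from a butylation extract.  Every measurement block is optional except the
lipid concentration — a block that was not measured is ``None``, never zero,
so that downstream rules can distinguish "not analysed" from "not detected".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple


class SchemaError(ValueError):
    """A tabular input is missing mandatory structure (columns, headers)."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


#: Isotope plausibility window for fatty-acid delta13C values (per mil VPDB).
DELTA13C_PLAUSIBLE = (-45.0, -10.0)

#: Even acyl carbon numbers a TAG envelope may contain.
TAG_CARBONS = tuple(range(40, 58, 2))

#: Compound classes understood by the biomarker rule engine.
COMPOUND_CLASSES = frozenset(
    {
        "n_alkane",
        "n_alkanol",
        "mid_chain_ketone",
        "fatty_acid",
        "branched_fatty_acid",
        "wax_ester",
        "sterol",
        "diterpenoid",
        "triterpenoid_ether",
        "isoprenoid_acid",
        "apaa",
        "alkylresorcinol",
    }
)

#: Commodity labels a vessel profile can carry (the summary-figure vocabulary).
COMMODITY_LABELS = (
    "ruminant_dairy",
    "ruminant_adipose",
    "non_ruminant",
    "porcine_tentative",
    "plant_unidentified",
    "plant_oil",
    "plant_wax",
    "brassica",
    "leek",
    "fennel_or_sermountain",
    "beeswax",
    "pine_resin",
    "pitch",
    "fruit",
    "grape",
    "aquatic",
    "cereal",
    "millet",
)

EXTRACTION_FLAGS = frozenset({"acid_methanol", "solvent", "butylation"})


class EvidenceLevel(str, enum.Enum):
    """Strength of evidence for a commodity in one vessel."""

    ABSENT = "absent"
    TENTATIVE = "tentative"
    POSITIVE = "positive"

    @property
    def rank(self) -> int:
        return ("absent", "tentative", "positive").index(self.value)

    def at_least(self, other: "EvidenceLevel") -> bool:
        return self.rank >= other.rank


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """Paired delta13C values of palmitic (C16:0) and stearic (C18:0) acid.

    Both values are per mil versus VPDB.  ``delta13c`` is the big-Delta
    discriminant delta13C18:0 - delta13C16:0 used to separate ruminant dairy,
    ruminant adipose and non-ruminant fats.
    """

    d13c_16_0: float
    d13c_18_0: float

    def __post_init__(self) -> None:
        for name, v in (("d13c_16_0", self.d13c_16_0), ("d13c_18_0", self.d13c_18_0)):
            _require_finite(name, v)
            lo, hi = DELTA13C_PLAUSIBLE
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"{name}={v} outside plausible window [{lo}, {hi}] per mil"
                )

    @property
    def delta13c(self) -> float:
        return self.d13c_18_0 - self.d13c_16_0

    def as_point(self) -> Tuple[float, float]:
        return (self.d13c_16_0, self.d13c_18_0)


@dataclass(frozen=True)
class TagProfile:
    """Relative TAG abundance by even total acyl carbon number (T40..T56)."""

    abundances: Mapping[int, float]

    def __post_init__(self) -> None:
        abunds = dict(self.abundances)
        if not abunds:
            raise ValidationError("TagProfile needs at least one entry")
        for c, a in abunds.items():
            if c not in TAG_CARBONS:
                raise ValidationError(f"TAG carbon number {c} not an even number in 40..56")
            _require_finite(f"abundance T{c}", a)
            if a < 0:
                raise ValidationError(f"abundance T{c} negative: {a}")
        if not any(a > 0 for a in abunds.values()):
            raise ValidationError("TagProfile is all-zero")
        object.__setattr__(self, "abundances", abunds)

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))

    @property
    def is_normalized(self) -> bool:
        return abs(self.total - 1.0) <= 1e-9

    def support(self) -> Tuple[int, ...]:
        return tuple(sorted(c for c, a in self.abundances.items() if a > 0))

    def items(self) -> Iterator[Tuple[int, float]]:
        return iter(sorted(self.abundances.items()))


@dataclass(frozen=True)
class Peak:
    """One integrated, identified compound in a sample's GC-MS peak table.

    ``chain_length`` is carbon count (0 when not applicable, e.g. named
    terpenoids); ``substituent_position`` is the oxidation position of
    mid-chain ketones/alkanols (0 otherwise); ``unsaturation`` counts double
    bonds.
    """

    compound: str
    compound_class: str
    chain_length: int = 0
    substituent_position: int = 0
    unsaturation: int = 0
    abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(f"unknown compound_class {self.compound_class!r}")
        if self.chain_length < 0 or self.substituent_position < 0 or self.unsaturation < 0:
            raise ValidationError("chain/position/unsaturation must be >= 0")
        _require_finite("abundance", self.abundance)
        if self.abundance < 0:
            raise ValidationError(f"abundance negative: {self.abundance}")

    @property
    def key(self) -> Tuple[str, str, int, int, int]:
        return (
            self.compound,
            self.compound_class,
            self.chain_length,
            self.substituent_position,
            self.unsaturation,
        )


class PeakTable:
    """A sample's identified-compound list with structural lookups.

    Rows are unique per (compound, class, chain, position, unsaturation);
    the compound name participates in the key because distinct named sterols
    and diterpenoids share identical structural coordinates.
    """

    def __init__(self, peaks: Iterable[Peak] = ()):
        rows: Dict[Tuple, Peak] = {}
        for p in peaks:
            if p.key in rows:
                raise ValidationError(f"duplicate peak row {p.key}")
            rows[p.key] = p
        self._rows = rows

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self) -> Iterator[Peak]:
        return iter(sorted(self._rows.values(), key=lambda p: p.key))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return self._rows == other._rows

    def rows(self) -> List[Peak]:
        return list(self)

    def class_rows(self, compound_class: str) -> List[Peak]:
        return [p for p in self if p.compound_class == compound_class]

    def abundance_of(
        self,
        compound_class: str,
        chain_length: Optional[int] = None,
        substituent_position: Optional[int] = None,
        unsaturation: Optional[int] = None,
    ) -> float:
        """Summed abundance over rows matching the given coordinates."""
        total = 0.0
        for p in self.class_rows(compound_class):
            if chain_length is not None and p.chain_length != chain_length:
                continue
            if substituent_position is not None and p.substituent_position != substituent_position:
                continue
            if unsaturation is not None and p.unsaturation != unsaturation:
                continue
            total += p.abundance
        return total

    def named(self, compound: str) -> Optional[Peak]:
        for p in self._rows.values():
            if p.compound == compound:
                return p
        return None

    def has_compound(self, compound: str, floor: float = 0.0) -> bool:
        p = self.named(compound)
        return p is not None and p.abundance > floor

    def chain_abundances(
        self,
        compound_class: str,
        chains: Optional[Sequence[int]] = None,
        parity: Optional[int] = None,
        unsaturation: Optional[int] = None,
        floor: float = 0.0,
    ) -> Dict[int, float]:
        """Per-chain-length summed abundances within one compound class.

        ``parity`` 0/1 restricts to even/odd chains; ``chains`` restricts to
        an explicit set; entries at or below ``floor`` are dropped.
        """
        out: Dict[int, float] = {}
        for p in self.class_rows(compound_class):
            if chains is not None and p.chain_length not in chains:
                continue
            if parity is not None and p.chain_length % 2 != parity:
                continue
            if unsaturation is not None and p.unsaturation != unsaturation:
                continue
            out[p.chain_length] = out.get(p.chain_length, 0.0) + p.abundance
        return {c: a for c, a in out.items() if a > floor}


@dataclass(frozen=True)
class AcidQuant:
    """Small-organic-acid quantities from the butylation extract (ug/g sherd)."""

    tartaric: float = 0.0
    malic: float = 0.0
    succinic: float = 0.0
    fumaric: float = 0.0
    maleic: float = 0.0
    malonic: float = 0.0
    oxalic: float = 0.0

    ACID_NAMES = ("tartaric", "malic", "succinic", "fumaric", "maleic", "malonic", "oxalic")

    def __post_init__(self) -> None:
        for name in self.ACID_NAMES:
            v = getattr(self, name)
            _require_finite(f"acid {name}", v)
            if v < 0:
                raise ValidationError(f"acid {name} negative: {v}")

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in self.ACID_NAMES}

    @property
    def minor_total(self) -> float:
        return self.succinic + self.fumaric + self.maleic + self.malonic + self.oxalic


@dataclass
class CommodityProfile:
    """Per-vessel commodity evidence flags plus a heating call and audit notes."""

    flags: Dict[str, EvidenceLevel] = field(
        default_factory=lambda: {label: EvidenceLevel.ABSENT for label in COMMODITY_LABELS}
    )
    heating: bool = False
    notes: List[str] = field(default_factory=list)

    def set_at_least(self, label: str, level: EvidenceLevel) -> None:
        if label not in self.flags:
            raise ValidationError(f"unknown commodity label {label!r}")
        if level.rank > self.flags[label].rank:
            self.flags[label] = level

    def fired(self) -> Dict[str, EvidenceLevel]:
        return {k: v for k, v in self.flags.items() if v is not EvidenceLevel.ABSENT}

    def note(self, text: str) -> None:
        self.notes.append(text)

    def validate(self) -> None:
        f = self.flags
        if f["pitch"] is EvidenceLevel.POSITIVE and f["pine_resin"] is not EvidenceLevel.POSITIVE:
            raise ValidationError("pitch positive requires pine_resin positive")
        for taxon in ("brassica", "leek", "fennel_or_sermountain"):
            if f[taxon] is EvidenceLevel.POSITIVE and not f["plant_wax"].at_least(
                EvidenceLevel.TENTATIVE
            ):
                raise ValidationError(f"{taxon} positive requires plant_wax >= tentative")
        if f["grape"] is EvidenceLevel.POSITIVE and f["fruit"] is not EvidenceLevel.POSITIVE:
            raise ValidationError("grape positive requires fruit positive")


@dataclass
class SampleRecord:
    """One sherd's full measurement bundle."""

    sample_id: str
    site: str
    vessel_form: str = "other"
    lipid_concentration: float = 0.0
    isotopes: Optional[IsotopeMeasurement] = None
    tag_profile: Optional[TagProfile] = None
    peaks: PeakTable = field(default_factory=PeakTable)
    acids: Optional[AcidQuant] = None
    extraction_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        _require_finite("lipid_concentration", self.lipid_concentration)
        if self.lipid_concentration < 0:
            raise ValidationError(
                f"lipid_concentration negative: {self.lipid_concentration}"
            )
        bad = set(self.extraction_flags) - EXTRACTION_FLAGS
        if bad:
            raise ValidationError(f"unknown extraction flags: {sorted(bad)}")
        self.extraction_flags = frozenset(self.extraction_flags)
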