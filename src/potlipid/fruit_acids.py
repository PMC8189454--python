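"""Small-organic-acid interpretation: %TA and grape/other-fruit calls.

The discriminant is %TA = 100 * tartaric / (tartaric + malic).  Values
strictly above 35% are characteristic of ripe grapes and grape products
(wine, juice, vinegar — also tamarind and some pomegranate cultivars, which
is why every grape call carries that caveat as a note); values at or below
35% with quantifiable malic acid point to low-tartaric fruits (apple, plum,
cherry, peach).  Because small tartaric amounts can be burial-environment
contamination, grape calls additionally require the absolute tartaric
quantity to pass a contamination screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import pandas as pd

from .types import AcidQuant, SampleRecord, ValidationError

#: %TA above which a grape product is indicated (strict inequality).
GRAPE_PERCENT_TA = 35.0

GRAPE_AMBIGUITY_NOTE = (
    "%TA > 35 is also produced by tamarind and some pomegranate cultivars"
)


@dataclass(frozen=True)
class FruitCall:
    label: str  # grape_product | other_fruit | plant_nonspecific | none
    percent_ta: Optional[float]
    ta_screen: Optional[str]  # quantified | below_threshold | None
    notes: tuple = ()


def percent_ta(tartaric: float, malic: float) -> float:
    """%TA = 100 * tartaric / (tartaric + malic)."""
    if tartaric < 0 or malic < 0:
        raise ValidationError("acid quantities must be >= 0")
    total = tartaric + malic
    if total == 0:
        raise ValidationError("%TA undefined: tartaric + malic = 0")
    return 100.0 * tartaric / total


def screen_ta_quantity(tartaric: float, threshold: float = 0.1) -> str:
    """Contamination screen: 'quantified' iff tartaric >= threshold (ug/g)."""
    if tartaric < 0:
        raise ValidationError("tartaric must be >= 0")
    if not (threshold > 0):
        raise ValidationError("threshold must be positive")
    return "quantified" if tartaric >= threshold else "below_threshold"


def classify_fruit_signal(
    acids: AcidQuant,
    ta_threshold: float = 0.1,
    malic_floor: float = 0.1,
) -> FruitCall:
    """Classify one butylation extract.

    grape_product: %TA strictly above 35 and tartaric passes the screen.
    other_fruit: %TA at or below 35 with malic above its quantification
    floor (and, as a fallback, samples whose tartaric fails the screen but
    whose malic is quantifiable).  plant_nonspecific: only minor acids
    (succinic etc.) detected — succinic alone is never a fruit call since it
    also forms by fatty-acid degradation.  none: nothing quantifiable.
    """
    notes = []
    pct: Optional[float] = None
    screen: Optional[str] = None
    if acids.tartaric + acids.malic > 0:
        pct = percent_ta(acids.tartaric, acids.malic)
        screen = screen_ta_quantity(acids.tartaric, ta_threshold)

    if pct is not None and pct > GRAPE_PERCENT_TA and screen == "quantified":
        notes.append(GRAPE_AMBIGUITY_NOTE)
        return FruitCall("grape_product", pct, screen, tuple(notes))
    if pct is not None and acids.malic >= malic_floor:
        # covers %TA <= 35 and grape-range %TA whose tartaric failed the screen
        return FruitCall("other_fruit", pct, screen, tuple(notes))
    if acids.minor_total > 0:
        notes.append(
            "only minor acids detected; succinic can form by fatty-acid degradation"
        )
        return FruitCall("plant_nonspecific", pct, screen, tuple(notes))
    return FruitCall("none", pct, screen, tuple(notes))


def acid_prevalence(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Per-acid detection fractions among butylation-extracted samples.

    Detection means quantity > 0.  Samples without the butylation extraction
    flag are excluded from the denominator; with no extracted samples at all
    the table is empty rather than a division by zero.
    """
    extracted = [
        r
        for r in records
        if "butylation" in r.extraction_flags and r.acids is not None
    ]
    if not extracted:
        return pd.DataFrame(columns=["acid", "n_detected", "n_extracted", "fraction"])
    rows = []
    for acid in AcidQuant.ACID_NAMES:
        detected = sum(1 for r in extracted if getattr(r.acids, acid) > 0)
        rows.append(
            {
                "acid": acid,
                "n_detected": detected,
                "n_extracted": len(extracted),
                "fraction": detected / len(extracted),
            }
        )
    return pd.DataFrame(rows)
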