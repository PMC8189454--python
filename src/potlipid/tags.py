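"""Triacylglycerol (TAG) envelope statistics and dairy/adipose calls.

A TAG envelope is the relative-abundance distribution over total acyl carbon
number (T40..T56).  Two summary statistics drive interpretation:

* ``M`` — abundance-weighted mean carbon number.
* ``DF`` — dispersion factor, implemented as the abundance-weighted standard
  deviation of carbon number (a reconstruction of the published dispersion
  index; the function is pluggable via ``dispersion_fn``).

Degraded dairy fats show a broad envelope (T42-T54) with low M (48-49) and
high DF (2.0-2.6); ruminant adipose fats a narrow envelope (T46-T54) centred
on T52 with lower DF.  Preferential loss of low-molecular-weight TAGs during
burial pushes dairy envelopes toward the adipose region, so dairy calls
require the low-mass tail to still be present.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

from .types import TagProfile, ValidationError

#: Dairy call windows: M in [48, 49], DF in [2.0, 2.6], support at C <= 44.
DAIRY_M_WINDOW = (48.0, 49.0)
DAIRY_DF_WINDOW = (2.0, 2.6)
DAIRY_LOW_MASS_CARBON = 44

#: Adipose support window and expected mode.
ADIPOSE_SUPPORT = (46, 54)
ADIPOSE_MODE = 52
#: Relative-abundance tolerance for mode ties (fraction of total).
MODE_TIE_TOLERANCE = 0.05


def normalize_profile(p: TagProfile) -> TagProfile:
    """Rescale abundances to sum to one; zero entries are preserved."""
    total = p.total
    if total <= 0:
        raise ValidationError("cannot normalize an all-zero profile")
    return TagProfile({c: a / total for c, a in p.abundances.items()})


def tag_mean_carbon(p: TagProfile) -> float:
    """M: abundance-weighted mean total acyl carbon number."""
    q = normalize_profile(p)
    return sum(c * a for c, a in q.items())


def weighted_sd_dispersion(p: TagProfile) -> float:
    """DF as the abundance-weighted standard deviation of carbon number."""
    q = normalize_profile(p)
    m = sum(c * a for c, a in q.items())
    var = sum(a * (c - m) ** 2 for c, a in q.items())
    return math.sqrt(var)


def tag_dispersion(
    p: TagProfile,
    dispersion_fn: Optional[Callable[[TagProfile], float]] = None,
) -> float:
    """DF: dispersion factor of the TAG envelope (default: weighted SD)."""
    fn = dispersion_fn or weighted_sd_dispersion
    return fn(p)


def classify_tag_profile(p: TagProfile) -> str:
    """Call a TAG envelope dairy-like, adipose-like or indeterminate.

    dairy_like: M in [48, 49], DF in [2.0, 2.6], and nonzero abundance at
    some carbon number <= 44 (the low-mass tail that distinguishes dairy).
    adipose_like: support confined to T46-T54, modal carbon 52 (50 or 54
    accepted within a 5% relative-abundance tie tolerance), DF below the
    dairy window.  Anything else: indeterminate.
    """
    q = normalize_profile(p)
    m = tag_mean_carbon(q)
    df = tag_dispersion(q)
    support = q.support()

    has_low_tail = any(c <= DAIRY_LOW_MASS_CARBON for c in support)
    if (
        DAIRY_M_WINDOW[0] <= m <= DAIRY_M_WINDOW[1]
        and DAIRY_DF_WINDOW[0] <= df <= DAIRY_DF_WINDOW[1]
        and has_low_tail
    ):
        return "dairy_like"

    lo, hi = ADIPOSE_SUPPORT
    if support and lo <= support[0] and support[-1] <= hi:
        mode_c, mode_a = max(q.items(), key=lambda item: item[1])
        near_52 = q.abundances.get(ADIPOSE_MODE, 0.0)
        mode_ok = mode_c == ADIPOSE_MODE or (
            mode_c in (50, 54) and mode_a - near_52 <= MODE_TIE_TOLERANCE
        )
        if mode_ok and df < DAIRY_DF_WINDOW[0]:
            return "adipose_like"

    return "indeterminate"
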