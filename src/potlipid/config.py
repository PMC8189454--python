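"""Configuration objects and loaders for packaged and user-supplied configs.

Two shipped resources matter:

* ``data/reference_classes_synthetic.yaml`` — bivariate-normal reference
  geometry for modern fat classes.  These are **synthetic approximations**
  of the published reference-fat geometry (the authentic compilation of
  modern reference values is not reproduced here); studies should supply
  their own reference table for authoritative work.
* ``data/rules.yaml`` — numeric parameters of the biomarker rule engine
  (presence floor, dominance targets, quorums, windows), overridable per run.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import pandas as pd
import yaml

from .isotopes import ReferenceClass
from .types import ValidationError

PathLike = Union[str, Path]

_DATA = importlib.resources.files("potlipid") / "data"
DEFAULT_REFERENCE_PATH = _DATA / "reference_classes_synthetic.yaml"
DEFAULT_RULES_PATH = _DATA / "rules.yaml"
DEFAULT_PLANT_TA_PATH = _DATA / "plant_ta_reference_synthetic.csv"


@dataclass(frozen=True)
class RuleConfig:
    """Tunable parameters of the biomarker rule engine."""

    presence_floor: float = 0.0
    plant_wax_alkane_range: Tuple[int, int] = (25, 33)
    plant_wax_dominants: Tuple[int, ...] = (29, 31)
    wax_ester_range: Tuple[int, int] = (40, 48)
    beeswax_quorum_positive: int = 3
    beeswax_quorum_tentative: int = 2
    plant_oil_ratio: float = 2.0
    aquatic_min_apaa_chain: int = 20
    aquatic_isoprenoid_quorum: int = 2
    heating_ketone_chains: Tuple[int, ...] = (33, 35)
    apaa_chain_range: Tuple[int, int] = (16, 22)
    srr_aquatic_window: Tuple[float, float] = (50.0, 100.0)
    srr_ruminant_window: Tuple[float, float] = (0.0, 75.0)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RuleConfig":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in data:
                v = data[f]
                kwargs[f] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "RuleConfig":
        return replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end interpretation settings."""

    #: Lowest lipid concentration (ug/g) reliably attributable as endogenous.
    lipid_threshold: float = 5.0
    #: Tartaric-acid quantity (ug/g) below which grape calls are withheld.
    ta_threshold: float = 0.1
    #: Matching quantification floor for malic acid (ug/g).
    malic_floor: float = 0.1
    #: Gaussian kernel standard deviation for Delta13C densities (per mil).
    kde_bandwidth: float = 0.5
    #: Nominal coverage of reference ellipses.
    ellipse_coverage: float = 0.68
    #: Outer coverage defining the tentative porcine annulus.
    porcine_edge_coverage: float = 0.95
    rules: RuleConfig = field(default_factory=RuleConfig)


def load_reference_classes(
    path: Optional[PathLike] = None,
    coverage: Optional[float] = None,
) -> Dict[str, ReferenceClass]:
    """Read reference fat classes from YAML (defaults to the shipped synthetic set)."""
    source = Path(path) if path is not None else DEFAULT_REFERENCE_PATH
    data = yaml.safe_load(source.read_text())
    if not isinstance(data, Mapping) or "classes" not in data:
        raise ValidationError("reference config must contain a 'classes' mapping")
    refs: Dict[str, ReferenceClass] = {}
    for label, entry in data["classes"].items():
        refs[label] = ReferenceClass(
            label=label,
            mean=tuple(entry["mean"]),
            covariance=tuple(tuple(row) for row in entry["covariance"]),
            n=int(entry.get("n", 0)),
            coverage=float(coverage if coverage is not None else entry.get("coverage", 0.68)),
        )
    return refs


def load_rule_config(path: Optional[PathLike] = None) -> RuleConfig:
    source = Path(path) if path is not None else DEFAULT_RULES_PATH
    data = yaml.safe_load(source.read_text()) or {}
    return RuleConfig.from_mapping(data)


def load_plant_ta_reference(path: Optional[PathLike] = None) -> pd.DataFrame:
    """Typical %TA values for plants/plant products (synthetic stand-in table)."""
    source = Path(path) if path is not None else DEFAULT_PLANT_TA_PATH
    return pd.read_csv(source, comment="#")
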