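"""Study configuration: the knobs of the synthetic study population.

The defaults encode the surveyed Wuhan-style study frame: 20 communities,
172 residential areas (13 work-unit, 148 commercial, 11 demolished),
commercial housing prices in three tiers split near 39,000 and 62,000 RMB,
community aging rates between 0.11 and 0.16, and 447 questionnaire
respondents with the marginal demographics of the published survey table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .scales import DEFAULT_SCALES, ALL_ITEMS, ScaleDefinition

RESIDENTIAL_TYPES = ("unit", "commercial", "demolished")

# Marginal shares of the valid questionnaires (proportions, not percents).
DEFAULT_MARGINS: dict[str, dict[int, float]] = {
    # 1: aged 60-70, 2: over 70
    "age_group": {1: 0.4855, 2: 0.5145},
    # 1: male, 2: female
    "gender": {1: 0.4832, 2: 0.5168},
    # 1: elementary or below, 2: middle school, 3: university and above
    "education": {1: 0.5212, 2: 0.3781, 3: 0.1007},
    # 1: <3k RMB, 2: 3-5k, 3: 5-8k, 4: >8k
    "income": {1: 0.1790, 2: 0.6018, 3: 0.1678, 4: 0.0514},
    # 1: self-care, 2: self-help (aids needed), 3: caregiver-dependent
    "self_care": {1: 0.60, 2: 0.30, 3: 0.10},
}

# Per-item standardized loading on the scale's latent factor.  Calibrated so
# the five-category discretized items reproduce scale reliabilities close to
# the published ones (alpha about 0.77 / 0.82 / 0.75).
DEFAULT_LOADINGS: dict[str, float] = {
    "bathing_assistance": 0.72,
    "daytime_care": 0.72,
    "canteen": 0.72,
    "night_care": 0.72,
    "rehabilitation_nursing": 0.81,
    "healthcare": 0.81,
    "spiritual_consolation": 0.81,
    "chess_cards": 0.70,
    "sports_activities": 0.70,
    "art_activities": 0.70,
    "university": 0.70,
}

# Latent location of each item (0 maps to a mean score of 3); chosen so the
# expected item means sit near the published descriptive profile.
DEFAULT_ITEM_LOCATIONS: dict[str, float] = {
    "bathing_assistance": -0.75,
    "daytime_care": -0.37,
    "canteen": 0.50,
    "night_care": -0.50,
    "rehabilitation_nursing": -0.20,
    "healthcare": 0.06,
    "spiritual_consolation": -0.28,
    "chess_cards": 0.72,
    "sports_activities": 0.50,
    "art_activities": 0.40,
    "university": 0.22,
}

# Log-odds of each attribute on each binary demand outcome (per unit of the
# ordinal code).  Moderate values a community survey could plausibly detect.
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "life_care": {"income": 0.90, "self_care": 0.70, "education": 0.40},
    "medical_security": {"income": 0.60, "self_care": 0.80, "education": 0.55},
    "cultural_entertainment": {"income": 0.70, "self_care": 0.35, "education": 0.25},
}

# Walking-time category probabilities (<=5 min, 5-10 min, 10-15 min).
# Healthcare and night care match the two published marginal values; the
# rest are plausible defaults.
DEFAULT_WALK_PROBS: dict[str, tuple[float, float, float]] = {
    "bathing_assistance": (0.30, 0.45, 0.25),
    "daytime_care": (0.25, 0.45, 0.30),
    "canteen": (0.35, 0.45, 0.20),
    "night_care": (0.0398, 0.3302, 0.63),
    "rehabilitation_nursing": (0.30, 0.40, 0.30),
    "healthcare": (0.4827, 0.3373, 0.18),
    "spiritual_consolation": (0.20, 0.45, 0.35),
    "chess_cards": (0.30, 0.45, 0.25),
    "sports_activities": (0.25, 0.45, 0.30),
    "art_activities": (0.20, 0.45, 0.35),
    "university": (0.15, 0.40, 0.45),
}

# Three-component commercial-price mixture (center RMB, spread RMB, weight).
# Component midpoints bracket the published tier cuts at 39,000 and 62,000.
DEFAULT_PRICE_PARAMS: tuple[tuple[float, float, float], ...] = (
    (28_000.0, 4_000.0, 0.40),
    (50_000.0, 4_500.0, 0.40),
    (74_000.0, 5_000.0, 0.20),
)


@dataclass
class StudyConfig:
    """Parameters of one synthetic study population."""

    n_communities: int = 20
    n_residential_areas: int = 172
    type_counts: dict[str, int] = field(
        default_factory=lambda: {"unit": 13, "commercial": 148, "demolished": 11}
    )
    price_params: tuple[tuple[float, float, float], ...] = DEFAULT_PRICE_PARAMS
    aging_rate_range: tuple[float, float] = (0.11, 0.16)
    n_respondents: int = 447
    demographic_margins: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINS.items()}
    )
    factor_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    item_locations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_LOCATIONS)
    )
    factor_correlation: float = 0.3
    effect_sizes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()}
    )
    outcome_intercepts: dict[str, float] = field(
        default_factory=lambda: {s.scale_name: 0.0 for s in DEFAULT_SCALES}
    )
    outcome_factor_shift: float = 1.2
    walking_time_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_WALK_PROBS.items()}
    )
    facility_spatial_mode: str = "clustered"
    n_facilities: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in ("n_communities", "n_residential_areas", "n_respondents",
                     "n_facilities"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if set(self.type_counts) != set(RESIDENTIAL_TYPES):
            raise ConfigurationError(
                f"type_counts must have exactly the keys {RESIDENTIAL_TYPES}"
            )
        if any(c < 0 for c in self.type_counts.values()):
            raise ConfigurationError("type counts must be nonnegative")
        if sum(self.type_counts.values()) != self.n_residential_areas:
            raise ConfigurationError(
                "type_counts must sum to n_residential_areas "
                f"({sum(self.type_counts.values())} != {self.n_residential_areas})"
            )
        lo, hi = self.aging_rate_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                "aging_rate_range must be an ordered pair inside (0, 1)"
            )
        for var, margin in self.demographic_margins.items():
            total = sum(margin.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ConfigurationError(
                    f"margins for {var!r} sum to {total}, expected 1"
                )
            if any(p < 0 for p in margin.values()):
                raise ConfigurationError(f"negative margin in {var!r}")
        missing = [i for i in ALL_ITEMS if i not in self.factor_loadings]
        if missing:
            raise ConfigurationError(f"factor_loadings missing items: {missing}")
        for item, lam in self.factor_loadings.items():
            if not (0.0 <= lam <= 1.0):
                raise ConfigurationError(
                    f"loading for {item!r} must lie in [0, 1], got {lam}"
                )
        if not (0.0 <= self.factor_correlation < 1.0):
            raise ConfigurationError("factor_correlation must lie in [0, 1)")
        for item, probs in self.walking_time_probs.items():
            if len(probs) != 3 or not math.isclose(sum(probs), 1.0, abs_tol=1e-6):
                raise ConfigurationError(
                    f"walking-time probabilities for {item!r} must be 3 values summing to 1"
                )
        if self.facility_spatial_mode not in ("clustered", "random", "uniform"):
            raise ConfigurationError(
                "facility_spatial_mode must be clustered, random or uniform"
            )
        weights = [w for _, _, w in self.price_params]
        if len(self.price_params) != 3 or not math.isclose(sum(weights), 1.0,
                                                           abs_tol=1e-6):
            raise ConfigurationError(
                "price_params must be 3 (center, spread, weight) tuples with weights summing to 1"
            )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "StudyConfig":
        kwargs: dict[str, Any] = dict(data)
        if "demographic_margins" in kwargs:
            kwargs["demographic_margins"] = {
                var: {int(k): float(v) for k, v in margin.items()}
                for var, margin in kwargs["demographic_margins"].items()
            }
        if "price_params" in kwargs:
            kwargs["price_params"] = tuple(
                tuple(p) for p in kwargs["price_params"]
            )
        if "aging_rate_range" in kwargs:
            kwargs["aging_rate_range"] = tuple(kwargs["aging_rate_range"])
        if "walking_time_probs" in kwargs:
            kwargs["walking_time_probs"] = {
                k: tuple(v) for k, v in kwargs["walking_time_probs"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "study" in data:  # allow a full pipeline config file
            data = data["study"]
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
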