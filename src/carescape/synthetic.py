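"""Seeded synthetic study populations.

Generates the four layers of a community elder-care study on a unit-square
planar region: communities with populations and aging rates, residential
areas typed as work-unit / commercial / demolished housing (commercial areas
carry a price drawn from a three-component mixture), care facilities with
capacities, and a questionnaire table of respondents.

Respondent demographics are sampled independently from configured marginal
proportions.  Each respondent carries one binary demand indicator per
primary scale, drawn from a logistic model in the ordinal attribute codes
with configured log-odds; the scale's latent factor is shifted by that
indicator, items load on their factor and are discretized to the 1-5 Likert
codes by fixed thresholds.  This makes the logistic model on the stored
indicators exactly well-specified (so configured odds ratios are
recoverable) while the Likert scores still carry the demand signal.
Walking-time items are independent categorical draws.

Everything is driven by a single integer seed through
``numpy.random.SeedSequence``: identical configs yield bit-identical
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import RESIDENTIAL_TYPES, StudyConfig
from .errors import ConfigurationError
from .layout import PointPattern
from .scales import (
    ALL_ITEMS,
    DEFAULT_SCALES,
    need_column,
    walk_column,
)

_LIKERT_THRESHOLDS = np.array([-1.5, -0.5, 0.5, 1.5])


@dataclass
class SyntheticStudy:
    communities: pd.DataFrame
    residential_areas: pd.DataFrame
    facilities: PointPattern
    facility_capacities: np.ndarray
    survey: pd.DataFrame
    config: StudyConfig


def _rngs(config: StudyConfig, n: int) -> list[np.random.Generator]:
    """Independent child streams so each layer is reproducible in isolation."""
    seq = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in seq.spawn(n)]


def generate_communities(config: StudyConfig) -> pd.DataFrame:
    """Communities with locations, populations and aging rates.

    Aging rates are uniform over the configured range; the stored rate is
    recomputed as older/total after rounding the older count so the
    rate-consistency invariant holds exactly.
    """
    rng = _rngs(config, 5)[0]
    n = config.n_communities
    lo, hi = config.aging_rate_range
    locations = rng.uniform(0.0, 1.0, size=(n, 2))
    # populations in hundreds so two-decimal rate bounds are realizable exactly
    population = rng.integers(20, 81, size=n) * 100
    rates = rng.uniform(lo, hi, size=n)
    older = np.rint(rates * population)
    # rounding can nudge the realized rate just past the range ends
    lower = np.ceil(lo * population - 1e-9)
    upper = np.floor(hi * population + 1e-9)
    older = np.minimum(np.maximum(older, lower), np.maximum(lower, upper))
    older = older.astype(int)
    return pd.DataFrame(
        {
            "community_id": [f"C{i + 1:02d}" for i in range(n)],
            "x": locations[:, 0],
            "y": locations[:, 1],
            "population": population,
            "older_population": older,
            "aging_rate": older / population,
        }
    )


def generate_residential_areas(
    config: StudyConfig, communities: pd.DataFrame
) -> pd.DataFrame:
    """Residential areas with exact type counts and mixture-drawn prices.

    Only commercial housing has a market price; work-unit and demolished
    areas get a missing price.  Each area is attached to a uniformly chosen
    community.
    """
    rng = _rngs(config, 5)[1]
    counts = config.type_counts
    if sum(counts.values()) != config.n_residential_areas:
        raise ConfigurationError("type counts must sum to n_residential_areas")
    types = np.concatenate(
        [np.full(counts[t], t, dtype=object) for t in RESIDENTIAL_TYPES]
    )
    rng.shuffle(types)
    community_ids = rng.choice(
        communities["community_id"].to_numpy(), size=len(types)
    )
    prices = np.full(len(types), np.nan)
    commercial = np.flatnonzero(types == "commercial")
    centers, spreads, weights = zip(*config.price_params)
    comp = rng.choice(len(centers), size=len(commercial), p=np.asarray(weights))
    prices[commercial] = rng.normal(
        np.asarray(centers)[comp], np.asarray(spreads)[comp]
    )
    return pd.DataFrame(
        {
            "area_id": [f"R{i + 1:03d}" for i in range(len(types))],
            "community_id": community_ids,
            "type": types,
            "price_rmb": prices,
        }
    )


def generate_facilities(config: StudyConfig) -> tuple[PointPattern, np.ndarray]:
    """Facility point pattern plus per-facility capacities.

    ``clustered`` scatters facilities as Gaussian offsets around a few
    parent centers (the empirically observed agglomeration of urban care
    facilities), ``random`` is uniform, ``uniform`` is a jittered grid.
    """
    rng = _rngs(config, 5)[2]
    n = config.n_facilities
    mode = config.facility_spatial_mode
    if mode == "random":
        pts = rng.uniform(0.0, 1.0, size=(n, 2))
    elif mode == "clustered":
        n_parents = max(2, n // 10)
        parents = rng.uniform(0.15, 0.85, size=(n_parents, 2))
        which = rng.integers(0, n_parents, size=n)
        pts = parents[which] + rng.normal(0.0, 0.04, size=(n, 2))
        pts = np.clip(pts, 0.0, 1.0)
    else:  # uniform: jittered grid
        side = int(np.ceil(np.sqrt(n)))
        gx, gy = np.meshgrid(
            (np.arange(side) + 0.5) / side, (np.arange(side) + 0.5) / side
        )
        grid = np.column_stack([gx.ravel(), gy.ravel()])[:n]
        pts = np.clip(grid + rng.normal(0.0, 0.01, size=grid.shape), 0.0, 1.0)
    capacities = rng.integers(20, 121, size=n).astype(float)
    labels = [f"F{i + 1:02d}" for i in range(n)]
    return PointPattern(points=pts, region_area=1.0, labels=labels), capacities


def _sample_margin(rng: np.random.Generator, margin: dict[int, float],
                   n: int) -> np.ndarray:
    """Quota allocation: exact largest-remainder counts, independently shuffled.

    Mirrors proportional quota sampling; empirical margins deviate from the
    configured ones by at most the integer-rounding residue, and variables
    remain independent because each gets its own permutation.
    """
    codes = np.array(sorted(margin))
    probs = np.array([margin[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    counts = np.floor(probs * n).astype(int)
    remainder = probs * n - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    out = np.repeat(codes, counts)
    rng.shuffle(out)
    return out


def _margin_mean(margin: dict[int, float]) -> float:
    return sum(c * p for c, p in margin.items()) / sum(margin.values())


def generate_survey(
    config: StudyConfig, residential_areas: pd.DataFrame
) -> pd.DataFrame:
    """Questionnaire table: demographics, demand indicators, Likert items,
    walking-time items.

    Demographics are independent draws from the configured margins.  For
    each primary scale the binary demand indicator is Bernoulli with
    logit = intercept + sum_a beta_a (x_a - E[x_a]) (attribute codes
    centered at their configured means, so the intercept sets baseline
    prevalence).  Latent factors are exchangeably correlated standard
    normals shifted by the indicator and restandardized; item scores
    discretize loading*factor + noise + item location by thresholds at
    -1.5, -0.5, 0.5, 1.5.
    """
    rng = _rngs(config, 5)[3]
    n = config.n_respondents
    margins = config.demographic_margins

    data: dict[str, np.ndarray] = {
        "respondent_id": np.array([f"P{i + 1:05d}" for i in range(n)]),
        "area_id": rng.choice(residential_areas["area_id"].to_numpy(), size=n),
    }
    for var in ("age_group", "gender", "education", "income", "self_care"):
        if var not in margins:
            raise ConfigurationError(f"demographic margins missing {var!r}")
        data[var] = _sample_margin(rng, margins[var], n)

    # binary demand indicators from the configured logistic model
    scale_names = [s.scale_name for s in DEFAULT_SCALES]
    outcomes = np.empty((n, len(scale_names)), dtype=int)
    for j, name in enumerate(scale_names):
        betas = config.effect_sizes[name]
        eta = np.full(n, config.outcome_intercepts.get(name, 0.0))
        for attr, beta in betas.items():
            eta += beta * (data[attr] - _margin_mean(margins[attr]))
        outcomes[:, j] = rng.random(n) < expit(eta)
        data[need_column(name)] = outcomes[:, j]

    # latent factors: exchangeable correlation, shifted by the indicator
    rho = config.factor_correlation
    k = len(scale_names)
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    shift = config.outcome_factor_shift
    factors = (z + shift * (outcomes - 0.5)) / np.sqrt(1.0 + 0.25 * shift**2)

    for j, scale in enumerate(DEFAULT_SCALES):
        for item in scale.item_ids:
            lam = config.factor_loadings[item]
            latent = (
                lam * factors[:, j]
                + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
                + config.item_locations.get(item, 0.0)
            )
            data[item] = np.digitize(latent, _LIKERT_THRESHOLDS) + 1

    for item in ALL_ITEMS:
        probs = np.asarray(config.walking_time_probs[item], dtype=float)
        data[walk_column(item)] = rng.choice([1, 2, 3], size=n,
                                             p=probs / probs.sum())
    return pd.DataFrame(data)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate all four layers of a study from one config."""
    communities = generate_communities(config)
    areas = generate_residential_areas(config, communities)
    facilities, capacities = generate_facilities(config)
    survey = generate_survey(config, areas)
    return SyntheticStudy(
        communities=communities,
        residential_areas=areas,
        facilities=facilities,
        facility_capacities=capacities,
        survey=survey,
        config=config,
    )
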