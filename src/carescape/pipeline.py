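"""End-to-end orchestration: simulate -> layout -> access -> psych -> demand.

Each stage persists its tabular outputs under the configured output
directory and contributes a section to a consolidated JSON study report.
Runs are deterministic given the seeds in the study config; the report
records a hash of the configuration so outputs can be traced back to it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .access import ODAccess, SupplyPoint, DemandPoint, basic_2sfca, improved_2sfca
from .config import StudyConfig
from .demand import (
    aging_rates,
    attribute_logistic,
    cluster_prices,
    demand_summary,
    group_anova,
)
from .errors import CarescapeError, ValidationError
from .io import (
    write_communities,
    write_facilities,
    write_table,
)
from .layout import kernel_density, nearest_neighbor_index, silverman_bandwidth
from .psych import reliability_table, scale_report
from .scales import ALL_ITEMS, DEFAULT_SCALES, walk_column
from .synthetic import SyntheticStudy, generate_study

log = logging.getLogger("carescape")


@dataclass
class PipelineConfig:
    study: StudyConfig = field(default_factory=StudyConfig)
    kernel: str = "gaussian"
    bandwidth: float | None = None  # None -> rule-of-thumb
    kde_cell_size: float = 0.02
    d0: float = 0.25  # catchment radius in region units
    access_method: str = "improved"
    walking_speed_kmh: float = 4.5
    logistic_threshold: float = 3.0
    anova_alpha: float = 0.05
    welch: bool = False
    run_spatial: bool = True
    run_survey: bool = True
    output_dir: str = "carescape_out"

    def config_hash(self) -> str:
        blob = json.dumps(
            {"study": self.study.to_dict(),
             **{k: v for k, v in self.__dict__.items() if k != "study"}},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    provenance: dict
    layout: dict | str
    accessibility: dict | str
    reliability: list | str
    demand: dict | str
    effects: dict | str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def minutes_to_distance(minutes: float, walking_speed_kmh: float = 4.5) -> float:
    """Walking-time catchment converted to kilometres."""
    return walking_speed_kmh * minutes / 60.0


def run_pipeline(config: PipelineConfig) -> StudyReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    study = generate_study(config.study)
    _persist_study(out, study)
    log.info("simulate: %d communities, %d areas, %d facilities, %d respondents",
             len(study.communities), len(study.residential_areas),
             study.facilities.n, len(study.survey))

    layout_section: dict | str = "skipped"
    access_section: dict | str = "skipped"
    if config.run_spatial:
        layout_section = _stage("layout", _run_layout, out, config, study)
        access_section = _stage("access", _run_access, out, config, study)

    reliability_section: list | str = "skipped"
    demand_section: dict | str = "skipped"
    effects_section: dict | str = "skipped"
    if config.run_survey:
        reliability_section = _stage("psych", _run_psych, out, config, study)
        demand_section = _stage("demand", _run_demand, out, config, study)
        effects_section = _stage("effects", _run_effects, out, config, study)

    report = StudyReport(
        provenance={
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.study.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "runtime_s": round(time.time() - t0, 3),
        },
        layout=layout_section,
        accessibility=access_section,
        reliability=reliability_section,
        demand=demand_section,
        effects=effects_section,
    )
    report.to_json(out / "study_report.json")
    return report


def _stage(name, fn, out, config, study):
    try:
        result = fn(out, config, study)
    except CarescapeError as exc:
        raise CarescapeError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s complete", name)
    return result


def _persist_study(out: Path, study: SyntheticStudy) -> None:
    write_communities(out / "communities.geojson", study.communities)
    write_facilities(out / "facilities.geojson", study.facilities,
                     study.facility_capacities)
    write_table(out / "residential_areas.csv", study.residential_areas)
    write_table(out / "survey.csv", study.survey)


def _run_layout(out: Path, config: PipelineConfig, study: SyntheticStudy) -> dict:
    pattern = study.facilities
    nni = nearest_neighbor_index(pattern)
    nni.to_json(out / "nni.json")
    h = config.bandwidth or silverman_bandwidth(pattern)
    surface = kernel_density(
        pattern, h, cell_size=config.kde_cell_size,
        n_rows=int(round(1.0 / config.kde_cell_size)),
        n_cols=int(round(1.0 / config.kde_cell_size)),
        kernel=config.kernel,
    )
    surface.write_ascii_grid(out / "facility_density.asc")
    return {
        "nni": nni.nni,
        "z_score": nni.z_score,
        "classification": nni.classification,
        "kde_bandwidth": h,
        "kde_peak": float(surface.values.max()),
        "kde_mass_on_grid": surface.total_mass(),
    }


def _run_access(out: Path, config: PipelineConfig, study: SyntheticStudy) -> dict:
    labels = study.facilities.labels or [
        f"F{i + 1:02d}" for i in range(study.facilities.n)
    ]
    supplies = [
        SupplyPoint(id=lab, location=tuple(pt), capacity=float(cap))
        for lab, pt, cap in zip(labels, study.facilities.points,
                                study.facility_capacities)
    ]
    demands = [
        DemandPoint(id=row.community_id, location=(row.x, row.y),
                    demand=float(row.older_population))
        for row in study.communities.itertuples()
    ]
    od = ODAccess(supplies=supplies, demands=demands,
                  catchment_radius=config.d0)
    if config.access_method == "improved":
        od = improved_2sfca(od)
    elif config.access_method == "basic":
        od = basic_2sfca(od)
    else:
        raise ValidationError("access_method must be 'improved' or 'basic'")
    acc = pd.DataFrame(
        {"community_id": [d.id for d in demands],
         "accessibility": od.accessibility}
    )
    ratios = pd.DataFrame(
        {"facility_id": [s.id for s in supplies], "ratio": od.ratios}
    )
    write_table(out / "accessibility.csv", acc)
    write_table(out / "supply_ratios.csv", ratios)
    A, D = np.asarray(od.accessibility), np.asarray(od.populations)
    return {
        "method": config.access_method,
        "d0": config.d0,
        "mean_accessibility": float(A.mean()),
        "min_accessibility": float(A.min()),
        "max_accessibility": float(A.max()),
        "served_demand_weighted_total": float((A * D).sum()),
        "total_capacity": float(np.asarray(od.capacities).sum()),
    }


def _run_psych(out: Path, config: PipelineConfig, study: SyntheticStudy) -> list:
    reports = [scale_report(study.survey, s) for s in DEFAULT_SCALES]
    table = reliability_table(reports)
    write_table(out / "reliability_report.csv", table)
    with open(out / "reliability_report.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
    return [r.to_dict() for r in reports]


def _run_demand(out: Path, config: PipelineConfig, study: SyntheticStudy) -> dict:
    summary = demand_summary(study.survey)
    rows = [{"item": i, "mean": round(m, 2)} for i, m in summary.item_means.items()]
    write_table(out / "demand_summary.csv", pd.DataFrame(rows))
    prices = study.residential_areas["price_rmb"].dropna()
    clustering = cluster_prices(prices, seed=config.study.seed)
    write_table(
        out / "price_clusters.csv",
        pd.DataFrame({"price_rmb": prices.to_numpy(),
                      "tier": clustering.assignments}),
    )
    rates = aging_rates(study.communities)
    write_table(out / "aging_rates.csv", rates)
    return {
        "item_means": {k: round(v, 2) for k, v in summary.item_means.items()},
        "indicator_means": {k: round(v, 2) for k, v in summary.indicator_means.items()},
        "overall_mean": round(summary.overall_mean, 2),
        "walk_within_5min": {k: round(v[0], 4) for k, v in summary.walk_proportions.items()},
        "price_tier_centers_rmb": [round(c) for c in clustering.centers],
        "price_tier_boundaries_rmb": [round(b) for b in clustering.boundaries],
        "aging_rate_min": float(rates["aging_rate"].min()),
        "aging_rate_max": float(rates["aging_rate"].max()),
    }


def _run_effects(out: Path, config: PipelineConfig, study: SyntheticStudy) -> dict:
    survey = study.residential_areas.merge(
        study.survey, on="area_id", how="right"
    )
    anova = group_anova(survey, "type", alpha=config.anova_alpha,
                        welch=config.welch)
    write_table(out / "anova_report.csv", anova.table)
    logistic_tables = {}
    for scale in DEFAULT_SCALES:
        rep = attribute_logistic(
            study.survey, scale.scale_name,
            threshold=config.logistic_threshold,
        )
        logistic_tables[scale.scale_name] = rep.table
    combined = pd.concat(
        [t.assign(outcome=name) for name, t in logistic_tables.items()],
        ignore_index=True,
    )
    write_table(out / "logistic_report.csv", combined)
    return {
        "anova_significant_items": anova.table.loc[
            anova.table["significant"], "item"
        ].tolist(),
        "odds_ratios": {
            name: {r.attribute: round(r.OR, 3) for r in t.itertuples()}
            for name, t in logistic_tables.items()
        },
    }


# ---------------------------------------------------------------------------
# survey validation

_DEMOGRAPHIC_RANGES = {
    "age_group": (1, 2),
    "gender": (1, 2),
    "education": (1, 3),
    "income": (1, 4),
    "self_care": (1, 3),
}


def validate_survey(path) -> list[dict]:
    """Structural checks on a survey CSV; returns a row-level issue list."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise ValidationError(f"cannot read survey file {path}: {exc}") from exc
    issues: list[dict] = []
    expected = list(_DEMOGRAPHIC_RANGES) + list(ALL_ITEMS) + [
        walk_column(i) for i in ALL_ITEMS
    ]
    for col in expected:
        if col not in df.columns:
            issues.append({"row": None, "column": col, "issue": "missing column"})
    for col, (lo, hi) in _DEMOGRAPHIC_RANGES.items():
        if col in df.columns:
            bad = df.index[~df[col].isin(range(lo, hi + 1))]
            issues.extend(
                {"row": int(r), "column": col, "issue": f"code outside {lo}-{hi}"}
                for r in bad
            )
    for col in ALL_ITEMS:
        if col in df.columns:
            bad = df.index[~df[col].isin([1, 2, 3, 4, 5])]
            issues.extend(
                {"row": int(r), "column": col, "issue": "Likert code outside 1-5"}
                for r in bad
            )
        wcol = walk_column(col)
        if wcol in df.columns:
            bad = df.index[~df[wcol].isin([1, 2, 3])]
            issues.extend(
                {"row": int(r), "column": wcol, "issue": "walking code outside 1-3"}
                for r in bad
            )
    return issues
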