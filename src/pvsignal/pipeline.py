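"""End-to-end pipeline: generate/load -> clean -> screen -> describe -> correlate.

Stages are pure library calls stitched together with stderr logging and
a run manifest; all randomness flows from the single generator seed, so
a rerun with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .ingest import deduplicate, load_reports, load_synonym_table, normalize_drug_names
from .meddra import SEIZURE_HLGT, load_hierarchy, pts_under_hlgt, seizure_hierarchy
from .receptors import (correlate_panel, load_affinity_table,
                        load_reference_panel, panel_to_frame)
from .reports import ReportSet
from .stats import ScreenOutput, Thresholds, results_to_frame, screen
from .synthetic import DrugSpec, EventSpec, GeneratorConfig, SignalSpec, generate_reports, write_tables

log = logging.getLogger("pvsignal")


@dataclass
class PipelineConfig:
    """Declarative run description (usually loaded from YAML)."""

    screen_drugs: list[str]
    generator: GeneratorConfig | None = None
    tables: dict[str, str] | None = None  # demo/drug/reac paths, if not generating
    hlgt: str = SEIZURE_HLGT
    thresholds: Thresholds = field(default_factory=Thresholds)
    synonyms_path: str | None = None      # None -> packaged dictionary
    hierarchy_path: str | None = None     # None -> packaged seizure hierarchy
    affinity_path: str | None = None      # None -> packaged Ki fixture
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.screen_drugs:
            raise ConfigurationError("screen_drugs must be non-empty")
        if self.generator is None and self.tables is None:
            raise ConfigurationError("either a generator section or input tables are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        gen = None
        if "generator" in raw:
            g = raw["generator"]
            gen = GeneratorConfig(
                n_reports=g["n_reports"],
                drugs=tuple(DrugSpec(d["name"], d["probability"], tuple(d.get("synonyms", ())))
                            for d in g["drugs"]),
                events=tuple(EventSpec(e["pt"], e["probability"]) for e in g["events"]),
                signals=tuple(SignalSpec(s["drug"], s["event_pt"], s["rate_multiplier"])
                              for s in g.get("signals", ())),
                duplicate_rate=g.get("duplicate_rate", 0.0),
                concomitant_rate=g.get("concomitant_rate", 0.0),
                missing_age_rate=g.get("missing_age_rate", 0.0),
                missing_sex_rate=g.get("missing_sex_rate", 0.0),
                missing_country_rate=g.get("missing_country_rate", 0.0),
                seed=g.get("seed", 0),
            )
        th = Thresholds(**raw.get("thresholds", {}))
        return cls(
            screen_drugs=list(raw["screen_drugs"]),
            generator=gen,
            tables=raw.get("tables"),
            hlgt=raw.get("hlgt", SEIZURE_HLGT),
            thresholds=th,
            synonyms_path=raw.get("synonyms_path"),
            hierarchy_path=raw.get("hierarchy_path"),
            affinity_path=raw.get("affinity_path"),
            log_level=raw.get("log_level", "INFO"),
        )


def demo_config_path() -> Path:
    """Path of the packaged demonstration configuration."""
    return Path(str(resources.files("pvsignal.data") / "demo_config.yaml"))


@dataclass
class DemographicSummary:
    """Counts by age group, sex, and reporting region for one drug's
    signal-positive cases, plus mean/SD age over non-missing."""

    drug: str
    n: int
    age_mean: float
    age_sd: float
    age_le18: int
    age_19_59: int
    age_ge60: int
    age_unknown: int
    male: int
    female: int
    sex_unknown: int
    us: int
    non_us: int
    country_unknown: int

    def as_row(self) -> dict:
        row = dict(vars(self))
        total = max(self.n, 1)
        for k in ("age_le18", "age_19_59", "age_ge60", "age_unknown",
                  "male", "female", "sex_unknown", "us", "non_us", "country_unknown"):
            row[k + "_pct"] = 100.0 * row[k] / total
        return row


def summarize_demographics(rs: ReportSet, drug: str = "") -> DemographicSummary:
    """Bin ages inclusively (<=18, 19-59, >=60, unknown), split sex and
    US / non-US / unknown reporting country."""
    age = rs.demo["age"]
    sex = rs.demo["sex"]
    country = rs.demo["country"]
    known_age = age.dropna()
    return DemographicSummary(
        drug=drug,
        n=len(rs),
        age_mean=float(known_age.mean()) if len(known_age) else math.nan,
        age_sd=float(known_age.std(ddof=1)) if len(known_age) > 1 else math.nan,
        age_le18=int((age <= 18).sum()),
        age_19_59=int(((age >= 19) & (age <= 59)).sum()),
        age_ge60=int((age >= 60).sum()),
        age_unknown=int(age.isna().sum()),
        male=int((sex == "M").sum()),
        female=int((sex == "F").sum()),
        sex_unknown=int(sex.isna().sum()),
        us=int((country == "US").sum()),
        non_us=int(((country != "US") & country.notna()).sum()),
        country_unknown=int(country.isna().sum()),
    )


@dataclass
class PipelineResult:
    universe: ReportSet
    screen_output: ScreenOutput
    demographics: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict


def _packaged_synonyms() -> dict[str, str]:
    with resources.as_file(resources.files("pvsignal.data") / "drug_synonyms.tsv") as p:
        return load_synonym_table(p)


def _json_safe(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _json_safe(float(obj))
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage and write the result bundle to ``out_dir``.

    Outputs: raw generated tables (when generating), ``signals.tsv`` /
    ``signals.json``, ``screen_counts.tsv``, ``demographics.tsv``,
    ``correlations.tsv`` and ``manifest.json``.  Deterministic given the
    generator seed.
    """
    logging.basicConfig(level=cfg.log_level, format="%(name)s: %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.generator is not None:
        log.info("[generate] n_reports=%d seed=%d", cfg.generator.n_reports, cfg.generator.seed)
        raw = generate_reports(cfg.generator)
        paths = write_tables(raw, out / "raw")
        demo_p, drug_p, reac_p = paths["demo"], paths["drug"], paths["reac"]
    else:
        demo_p, drug_p, reac_p = (cfg.tables[k] for k in ("demo", "drug", "reac"))
        for p in (demo_p, drug_p, reac_p):
            if not Path(p).exists():
                raise ConfigurationError(f"input table does not exist: {p}")

    log.info("[ingest] loading %s", demo_p)
    rs = load_reports(demo_p, drug_p, reac_p)
    synonyms = (load_synonym_table(cfg.synonyms_path) if cfg.synonyms_path
                else _packaged_synonyms())
    rs = normalize_drug_names(rs, synonyms)
    rs = deduplicate(rs)
    log.info("[ingest] %d reports after dedup (%d duplicates removed)",
             len(rs), rs.provenance.duplicates_removed)

    hierarchy = (load_hierarchy(cfg.hierarchy_path) if cfg.hierarchy_path
                 else seizure_hierarchy())
    pts = pts_under_hlgt(hierarchy, cfg.hlgt)

    log.info("[screen] %d drugs x %d PTs", len(cfg.screen_drugs), len(pts))
    screened = screen(rs, cfg.screen_drugs, pts, cfg.thresholds, event_set_name=cfg.hlgt)
    signals = screened.to_frame()
    signals.to_csv(out / "signals.tsv", sep="\t", index=False)
    with open(out / "signals.json", "w", encoding="utf-8") as fh:
        json.dump(_json_safe(signals.to_dict(orient="records")), fh, indent=1, sort_keys=True)
    screened.counts_frame().to_csv(out / "screen_counts.tsv", sep="\t", index=False)

    # demographics of each drug's signal-positive cases (ROR criterion at PT level)
    demo_rows = []
    for drug in cfg.screen_drugs:
        flagged_pts = {r.event for r in screened.results
                       if r.drug == drug and r.level == "PT" and r.ror_flag}
        ps_ids = set(rs.ps_primaryids(drug))
        case_ids = ps_ids & set(rs.event_primaryids(flagged_pts)) if flagged_pts else set()
        demo_rows.append(summarize_demographics(rs.subset(case_ids), drug=drug).as_row())
    demographics = pd.DataFrame(demo_rows)
    demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)

    # correlate group-level ROR025 against the receptor panel
    hlgt_rows = {r.drug: r.ror025 for r in screened.results if r.level == "HLGT"}
    if cfg.affinity_path:
        affinity = load_affinity_table(cfg.affinity_path)
    else:
        affinity, _ = load_reference_panel()
    panel = correlate_panel(hlgt_rows, affinity)
    correlations = panel_to_frame(panel)
    correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)

    manifest = _json_safe({
        "package_version": __version__,
        "seed": cfg.generator.seed if cfg.generator else None,
        "provenance": rs.provenance.as_dict(),
        "n_reports_after_dedup": len(rs),
        "screen_drugs": list(cfg.screen_drugs),
        "hlgt": cfg.hlgt,
        "n_hlgt_pts": len(pts),
        "outputs": ["signals.tsv", "signals.json", "screen_counts.tsv",
                    "demographics.tsv", "correlations.tsv"],
    })
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("[done] outputs in %s", out)

    return PipelineResult(universe=rs, screen_output=screened,
                          demographics=demographics, correlations=correlations,
                          manifest=manifest)
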