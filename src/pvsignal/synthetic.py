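"""Synthetic spontaneous-report generator with known association structure.

Emulates the three tables of a spontaneous-reporting database (DEMO,
DRUG, REAC): each report carries one primary-suspect (PS) drug drawn
from a marginal distribution, a set of adverse-event preferred terms
drawn as independent per-PT Bernoullis, demographics with configurable
missingness, and optional duplicate case versions.  Planted drug–event
signals multiply the event's per-report probability for reports whose
PS drug is the signal drug, so every 2x2 contingency cell has a closed
form (``expected_contingency``) that downstream estimators can be
checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CatalogLookupError, ConfigurationError
from .reports import DEMO_COLUMNS, DRUG_COLUMNS, REAC_COLUMNS, Provenance, ReportSet
from .stats import ContingencyTable

_COUNTRIES = np.array(["US", "GB", "DE", "FR", "CA", "JP"])
_COUNTRY_P = np.array([0.50, 0.12, 0.12, 0.10, 0.08, 0.08])


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: canonical name, marginal PS probability, synonyms."""

    name: str
    probability: float
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class EventSpec:
    """One catalog preferred term with its background per-report probability."""

    pt: str
    probability: float


@dataclass(frozen=True)
class SignalSpec:
    """A planted drug–event association.

    ``rate_multiplier`` (lambda) multiplies the event's per-report
    probability in reports whose PS drug is ``drug``; lambda = 1 means
    no association.
    """

    drug: str
    event_pt: str
    rate_multiplier: float


@dataclass
class GeneratorConfig:
    n_reports: int
    drugs: Sequence[DrugSpec]
    events: Sequence[EventSpec]
    signals: Sequence[SignalSpec] = ()
    duplicate_rate: float = 0.0
    concomitant_rate: float = 0.0
    missing_age_rate: float = 0.0
    missing_sex_rate: float = 0.0
    missing_country_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ConfigurationError("n_reports must be positive")
        if not self.drugs:
            raise ConfigurationError("drugs catalog is empty")
        if not self.events:
            raise ConfigurationError("events catalog is empty")
        total = sum(d.probability for d in self.drugs)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ConfigurationError(f"drugs: marginal probabilities sum to {total}, expected 1")
        for ev in self.events:
            if not 0.0 < ev.probability < 1.0:
                raise ConfigurationError(f"events: probability for {ev.pt!r} must be in (0,1)")
        for rate_name in ("duplicate_rate", "concomitant_rate", "missing_age_rate",
                          "missing_sex_rate", "missing_country_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"{rate_name} must be in [0,1)")
        drug_names = {d.name for d in self.drugs}
        event_pts = {e.pt: e.probability for e in self.events}
        for s in self.signals:
            if s.rate_multiplier <= 0:
                raise ConfigurationError(f"signals: rate_multiplier for ({s.drug}, {s.event_pt}) must be > 0")
            if s.drug not in drug_names:
                raise ConfigurationError(f"signals: unknown drug {s.drug!r}")
            if s.event_pt not in event_pts:
                raise ConfigurationError(f"signals: unknown event {s.event_pt!r}")
            if s.rate_multiplier * event_pts[s.event_pt] >= 1.0:
                raise ConfigurationError(
                    f"signals: rate_multiplier * probability >= 1 for ({s.drug}, {s.event_pt})")


def multiplier_for_odds_ratio(target_or: float, p_event: float) -> float:
    """Rate multiplier lambda such that the analytic 2x2 odds ratio equals
    ``target_or`` when the target event has background probability
    ``p_event`` and all other drugs stay at baseline.

    Because lambda scales the probability (not the odds), lambda itself
    is slightly below the odds ratio it induces.
    """
    if not 0 < p_event < 1:
        raise ConfigurationError("p_event must be in (0,1)")
    if target_or <= 0:
        raise ConfigurationError("target_or must be positive")
    odds = target_or * p_event / (1.0 - p_event)
    return odds / (1.0 + odds) / p_event


def _multiplier_matrix(config: GeneratorConfig) -> np.ndarray:
    k, m = len(config.drugs), len(config.events)
    drug_index = {d.name: i for i, d in enumerate(config.drugs)}
    event_index = {e.pt: j for j, e in enumerate(config.events)}
    mult = np.ones((k, m))
    for s in config.signals:
        mult[drug_index[s.drug], event_index[s.event_pt]] = s.rate_multiplier
    return mult


def generate_reports(config: GeneratorConfig) -> ReportSet:
    """Draw a synthetic ReportSet; deterministic given ``config.seed``.

    Reports with zero events are redrawn (every emitted report mentions
    at least one PT, matching REAC semantics).  Duplicate versions share
    the original's caseid, get a strictly larger primaryid, are emitted
    after all originals, and have their missing demographics completed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_p = np.array([d.probability for d in config.drugs])
    event_p = np.array([e.probability for e in config.events])
    mult = _multiplier_matrix(config)

    drug_idx = rng.choice(len(config.drugs), size=n, p=drug_p)
    probs = event_p[None, :] * mult[drug_idx, :]
    event_mat = rng.random((n, len(config.events))) < probs
    # condition every report on >=1 event
    empty = ~event_mat.any(axis=1)
    while empty.any():
        idx = np.flatnonzero(empty)
        event_mat[idx] = rng.random((len(idx), len(config.events))) < probs[idx]
        empty = ~event_mat.any(axis=1)

    age = np.round(np.clip(rng.normal(42.0, 18.0, size=n), 1.0, 95.0))
    sex = np.where(rng.random(n) < 0.5, "M", "F").astype(object)
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P).astype(object)
    age_missing = rng.random(n) < config.missing_age_rate
    sex_missing = rng.random(n) < config.missing_sex_rate
    country_missing = rng.random(n) < config.missing_country_rate

    # as-reported spelling: uniform over canonical + synonyms per drug
    raw_names = np.empty(n, dtype=object)
    for i, spec in enumerate(config.drugs):
        pool = [spec.name, *spec.synonyms]
        rows = np.flatnonzero(drug_idx == i)
        raw_names[rows] = np.array(pool, dtype=object)[rng.integers(0, len(pool), size=len(rows))]

    primaryid = np.arange(1, n + 1)
    caseid = primaryid.copy()

    demo = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": caseid,
        "age": np.where(age_missing, np.nan, age),
        "sex": np.where(sex_missing, None, sex),
        "country": np.where(country_missing, None, country),
    })

    drug_rows = [pd.DataFrame({
        "primaryid": primaryid,
        "drugname": raw_names,
        "canonical": pd.array([None] * n, dtype=object),
        "role": "PS",
    })]
    if config.concomitant_rate > 0:
        has_con = rng.random(n) < config.concomitant_rate
        con_idx = rng.choice(len(config.drugs), size=int(has_con.sum()), p=drug_p)
        con_names = np.array([config.drugs[i].name for i in con_idx], dtype=object)
        drug_rows.append(pd.DataFrame({
            "primaryid": primaryid[has_con],
            "drugname": con_names,
            "canonical": pd.array([None] * len(con_names), dtype=object),
            "role": "C",
        }))

    rep_rows, pt_cols = np.nonzero(event_mat)
    pt_names = np.array([e.pt for e in config.events], dtype=object)
    reac = pd.DataFrame({"primaryid": primaryid[rep_rows], "pt": pt_names[pt_cols]})

    # duplicate case versions, appended after all originals
    is_dup = rng.random(n) < config.duplicate_rate
    dup_src = np.flatnonzero(is_dup)
    if len(dup_src):
        dup_pid = np.arange(n + 1, n + 1 + len(dup_src))
        fill_age = np.round(np.clip(rng.normal(42.0, 18.0, size=len(dup_src)), 1.0, 95.0))
        fill_sex = np.where(rng.random(len(dup_src)) < 0.5, "M", "F").astype(object)
        fill_country = rng.choice(_COUNTRIES, size=len(dup_src), p=_COUNTRY_P).astype(object)
        dup_demo = pd.DataFrame({
            "primaryid": dup_pid,
            "caseid": caseid[dup_src],
            "age": np.where(age_missing[dup_src], fill_age, age[dup_src]),
            "sex": np.where(sex_missing[dup_src], fill_sex, sex[dup_src]),
            "country": np.where(country_missing[dup_src], fill_country, country[dup_src]),
        })
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        pid_map = dict(zip(primaryid[dup_src], dup_pid))
        drug_all = pd.concat(drug_rows, ignore_index=True)
        dup_drug = drug_all[drug_all["primaryid"].isin(pid_map)].copy()
        dup_drug["primaryid"] = dup_drug["primaryid"].map(pid_map)
        drug_rows.append(dup_drug)
        dup_reac = reac[reac["primaryid"].isin(pid_map)].copy()
        dup_reac["primaryid"] = dup_reac["primaryid"].map(pid_map)
        reac = pd.concat([reac, dup_reac], ignore_index=True)

    drug = pd.concat(drug_rows, ignore_index=True).sort_values(
        ["primaryid", "role"], kind="stable").reset_index(drop=True)
    reac = reac.sort_values(["primaryid", "pt"], kind="stable").reset_index(drop=True)

    return ReportSet(
        demo=demo[DEMO_COLUMNS],
        drugs=drug[DRUG_COLUMNS],
        events=reac[REAC_COLUMNS],
        provenance=Provenance(raw_reports=len(demo)),
    )


def expected_contingency(config: GeneratorConfig, drug_id: str, event_pt: str) -> ContingencyTable:
    """Expected 2x2 cell counts under the generative model, ignoring
    duplicates and the zero-event redraw.

    The redraw conditions each report on having >=1 event, which
    inflates every per-PT probability by a factor close to
    1/P(>=1 event); for small background probabilities and several
    catalog PTs the factor is near 1 and these closed forms are a good
    approximation (the generator's Monte-Carlo tests quantify it).
    """
    drug_index = {d.name: i for i, d in enumerate(config.drugs)}
    event_index = {e.pt: j for j, e in enumerate(config.events)}
    if drug_id not in drug_index:
        raise CatalogLookupError(f"unknown drug {drug_id!r}")
    if event_pt not in event_index:
        raise CatalogLookupError(f"unknown event {event_pt!r}")
    n = config.n_reports
    p_drug = config.drugs[drug_index[drug_id]].probability
    p_event = config.events[event_index[event_pt]].probability
    mult = _multiplier_matrix(config)
    j = event_index[event_pt]
    lam = mult[drug_index[drug_id], j]

    a = n * p_drug * p_event * lam
    b = n * p_drug * (1.0 - p_event * lam)
    c = n * sum(
        d.probability * p_event * mult[i, j]
        for i, d in enumerate(config.drugs) if d.name != drug_id
    )
    d = n - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def write_tables(rs: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Write demo/drug/reac as tab-separated UTF-8 tables with a header
    row; missing values as empty strings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    demo = rs.demo.copy()
    demo["age"] = demo["age"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    specs = {
        "demo": (demo, ["primaryid", "caseid", "age", "sex", "country"]),
        "drug": (rs.drugs, ["primaryid", "drugname", "role"]),
        "reac": (rs.events, ["primaryid", "pt"]),
    }
    for name, (frame, cols) in specs.items():
        path = out / f"{name}.tsv"
        frame[cols].to_csv(path, sep="\t", index=False, na_rep="", encoding="utf-8")
        paths[name] = path
    return paths
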