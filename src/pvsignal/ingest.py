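"""Loading, drug-name normalization, and case deduplication.

Desk-scale analogue of the standard spontaneous-report preprocessing
workflow: join the three report tables on primaryid, map as-reported
drug spellings to canonical names via a synonym dictionary, keep one
version per case, and restrict to primary-suspect mentions.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .reports import DEMO_COLUMNS, DRUG_COLUMNS, Provenance, ReportSet


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"primaryid": "int64"},
                        keep_default_na=False, na_values=[""])
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{Path(path).name}: missing required column {col!r}")
    return frame


def load_reports(demo_path, drug_path, reac_path) -> ReportSet:
    """Join demo/drug/reac tables into a (pre-deduplication) ReportSet.

    Reports without any event row are dropped and counted in
    provenance; drug or event rows whose primaryid has no demo row are
    orphans, likewise counted and discarded.
    """
    demo = _read_table(demo_path, ["primaryid", "caseid", "age", "sex", "country"])
    drug = _read_table(drug_path, ["primaryid", "drugname", "role"])
    reac = _read_table(reac_path, ["primaryid", "pt"])

    demo = demo.copy()
    demo["age"] = pd.to_numeric(demo["age"], errors="coerce")  # non-numeric age -> missing
    demo["caseid"] = pd.to_numeric(demo["caseid"], errors="raise").astype("int64")

    known = set(demo["primaryid"])
    orphan_drug = int((~drug["primaryid"].isin(known)).sum())
    orphan_reac = int((~reac["primaryid"].isin(known)).sum())
    drug = drug[drug["primaryid"].isin(known)]
    reac = reac[reac["primaryid"].isin(known)]

    with_event = set(reac["primaryid"])
    dropped = int((~demo["primaryid"].isin(with_event)).sum())
    demo = demo[demo["primaryid"].isin(with_event)].reset_index(drop=True)
    drug = drug[drug["primaryid"].isin(with_event)].reset_index(drop=True)

    drug = drug.copy()
    if "canonical" not in drug.columns:
        drug["canonical"] = pd.array([None] * len(drug), dtype=object)

    prov = Provenance(
        raw_reports=len(demo) + dropped,
        dropped_no_event=dropped,
        orphan_drug_rows=orphan_drug,
        orphan_reac_rows=orphan_reac,
    )
    return ReportSet(demo=demo[DEMO_COLUMNS], drugs=drug[DRUG_COLUMNS],
                     events=reac.reset_index(drop=True), provenance=prov)


def load_synonym_table(path: str | Path) -> dict[str, str]:
    """Two-column delimited file (raw, canonical) -> lookup dict keyed by
    trimmed, lower-cased raw spelling."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise FormatError("synonym table needs two columns (raw, canonical)")
    raw_col, canon_col = frame.columns[:2]
    return {
        str(raw).strip().lower(): str(canon)
        for raw, canon in zip(frame[raw_col], frame[canon_col])
    }


def normalize_drug_names(rs: ReportSet, synonym_table: dict[str, str]) -> ReportSet:
    """Fill canonical drug names via case-insensitive, whitespace-trimmed
    lookup; unmapped spellings stay raw and are counted, never an error.

    Canonical names map to themselves even without an explicit synonym
    entry.
    """
    table = {k.strip().lower(): v for k, v in synonym_table.items()}
    for canon in set(table.values()):
        table.setdefault(canon.strip().lower(), canon)

    drugs = rs.drugs.copy()
    keys = drugs["drugname"].astype(str).str.strip().str.lower()
    mapped = keys.map(table)
    drugs["canonical"] = mapped.where(mapped.notna(), None)
    unmapped = int(mapped.isna().sum())
    prov = replace(rs.provenance, unmapped_drug_names=rs.provenance.unmapped_drug_names + unmapped)
    return ReportSet(demo=rs.demo, drugs=drugs, events=rs.events, provenance=prov)


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep exactly one report per caseid: the numerically greatest
    primaryid (latest version).  Idempotent."""
    keep = rs.demo.groupby("caseid")["primaryid"].max()
    keep_ids = set(keep)
    removed = len(rs.demo) - len(keep_ids)
    out = rs.subset(keep_ids)
    out.provenance = replace(
        rs.provenance,
        duplicates_removed=rs.provenance.duplicates_removed + removed,
    )
    return out


def ps_reports_for(rs: ReportSet, canonical_drug: str) -> ReportSet:
    """Reports where ``canonical_drug`` appears with role PS; SS/I/C
    mentions never qualify."""
    return rs.subset(rs.ps_primaryids(canonical_drug))
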