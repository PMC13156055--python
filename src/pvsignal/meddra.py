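"""Minimal MedDRA-style term hierarchy (PT -> HLT -> HLGT -> SOC).

Supports the one query the seizure screen needs — the set of preferred
terms under a high-level group term — against a packaged seizure
hierarchy.  PT matching is exact-string and case-sensitive after a
single canonical-casing pass at load time: PTs are controlled
vocabulary, and fuzzy matching invites silent misclassification.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import CatalogLookupError, FormatError
from .reports import ReportSet

SEIZURE_HLGT = "Seizures (incl subtypes)"

#: Spelling variants kept as distinct hierarchy entries (both valid PTs in
#: incoming data); maps the variant to its preferred spelling.
PT_ALIASES = {"Hyponatremic seizure": "Hyponatraemic seizure"}


@dataclass(frozen=True)
class TermHierarchy:
    """A set of (pt, hlt, hlgt, soc) quadruples; a PT may carry several
    parents."""

    entries: frozenset[tuple[str, str, str, str]]

    def hlgts(self) -> set[str]:
        return {e[2] for e in self.entries}

    def pts(self) -> set[str]:
        return {e[0] for e in self.entries}

    def parents_of(self, pt: str) -> set[tuple[str, str, str]]:
        """All (hlt, hlgt, soc) parent paths of a PT."""
        return {(h, g, s) for p, h, g, s in self.entries if p == pt}


def load_hierarchy(path: str | Path) -> TermHierarchy:
    """Read a four-column tab-separated hierarchy file (pt, hlt, hlgt, soc)."""
    frame = pd.read_csv(path, sep="\t")
    required = ["pt", "hlt", "hlgt", "soc"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"hierarchy file missing columns: {missing}")
    entries = frozenset(
        (str(r.pt).strip(), str(r.hlt).strip(), str(r.hlgt).strip(), str(r.soc).strip())
        for r in frame.itertuples(index=False)
    )
    return TermHierarchy(entries=entries)


def seizure_hierarchy() -> TermHierarchy:
    """The packaged seizure HLGT fixture."""
    with resources.as_file(resources.files("pvsignal.data") / "seizure_hierarchy.tsv") as p:
        return load_hierarchy(p)


def pts_under_hlgt(h: TermHierarchy, hlgt_name: str) -> set[str]:
    """Exact, case-sensitive member PT set of one HLGT."""
    known = h.hlgts()
    if hlgt_name not in known:
        raise CatalogLookupError(
            f"unknown HLGT {hlgt_name!r}; known HLGTs: {sorted(known)}")
    return {pt for pt, _, hlgt, _ in h.entries if hlgt == hlgt_name}


def filter_reports_by_pts(rs: ReportSet, pts) -> ReportSet:
    """Reports retaining at least one event in ``pts``.

    Event sets are NOT truncated: downstream per-PT counting needs the
    full REAC row set of every retained report.
    """
    keep = rs.event_primaryids(pts)
    return rs.subset(keep)
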