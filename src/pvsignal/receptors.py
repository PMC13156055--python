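"""Rank correlation of signal strength against receptor binding profiles.

Each antipsychotic's affinity for six monoamine receptors is summarised
as the arithmetic mean of published Ki values (nM; smaller = stronger
binding).  Three serotonin/dopamine ratios, Ki(5-HT1A)/Ki(D2),
Ki(5-HT2A)/Ki(D2) and Ki(5-HT2C)/Ki(D2), index the balance between
serotonergic and D2 antagonism.  Signal strength (the lower 95% bound
of the group-level reporting odds ratio) is then rank-correlated
against each receptor column and each ratio, pairwise-complete per
column so that a drug missing one receptor still contributes to the
others.

Two affinity scales are exposed.  The default correlates the raw Ki
scale (and raw Ki ratios) exactly as such tables are printed; setting
``use_inverse_affinity=True`` correlates the reciprocal 1/Ki ("affinity
index", larger = stronger binding), which for a rank statistic simply
flips every correlation's sign.  See the methods note for why the
printed-scale mode is the default.

Small-sample p-values come from exact enumeration of all n! rank
permutations (n <= 9); larger panels fall back on the t approximation
t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.  Note the
two can differ noticeably at n = 7-8: the t approximation is what
mainstream statistics packages print by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .errors import DomainError, FormatError, InsufficientDataError

RECEPTORS = ["D1", "D2", "D3", "5-HT1A", "5-HT2A", "5-HT2C"]
RATIOS = ["5-HT1A/D2", "5-HT2A/D2", "5-HT2C/D2"]

#: exact enumeration is n! permutations; 9! = 362,880 is the practical cap
EXACT_N_MAX = 9


def mean_ki(measurements) -> float:
    """Arithmetic mean of available Ki measurements; empty -> NaN
    (a missing table entry, not an error)."""
    vals = [float(v) for v in measurements]
    if not vals:
        return math.nan
    if any(v <= 0 for v in vals):
        raise DomainError("Ki measurements must be positive")
    return sum(vals) / len(vals)


def affinity_index(ki: float) -> float:
    """Reciprocal mean Ki: larger index = stronger binding."""
    if not ki > 0:
        raise DomainError(f"Ki must be positive, got {ki}")
    return 1.0 / ki


@dataclass(frozen=True)
class ReceptorAffinityTable:
    """Per-drug mean Ki (nM) for the six receptors; NaN marks a receptor
    with no curated measurement."""

    ki: pd.DataFrame  # index: drug, columns: RECEPTORS

    def __post_init__(self) -> None:
        missing = [c for c in RECEPTORS if c not in self.ki.columns]
        if missing:
            raise FormatError(f"affinity table missing receptor columns: {missing}")
        if (self.ki[RECEPTORS] <= 0).any().any():
            raise DomainError("Ki values must be positive where present")

    @property
    def drugs(self) -> list[str]:
        return list(self.ki.index)

    def ratios(self) -> pd.DataFrame:
        """Ki(5-HTx)/Ki(D2) per drug; NaN when either parent is missing."""
        out = pd.DataFrame(index=self.ki.index)
        for ratio in RATIOS:
            num = ratio.split("/")[0]
            out[ratio] = self.ki[num] / self.ki["D2"]
        return out

    def panel(self) -> pd.DataFrame:
        """Six receptor columns followed by the three ratio columns."""
        return pd.concat([self.ki[RECEPTORS], self.ratios()], axis=1)


def load_affinity_table(path: str | Path) -> ReceptorAffinityTable:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "drug" not in frame.columns:
        raise FormatError("affinity file needs a 'drug' column")
    return ReceptorAffinityTable(ki=frame.set_index("drug")[RECEPTORS].astype(float))


def load_reference_panel() -> tuple[ReceptorAffinityTable, pd.Series]:
    """Packaged fixture: curated mean Ki values for the eight atypical
    antipsychotics plus each drug's group-level ROR025 signal value.

    Returns (affinity table, ror025 series indexed by drug).
    """
    with resources.as_file(resources.files("pvsignal.data") / "receptor_ki.tsv") as p:
        frame = pd.read_csv(p, sep="\t", na_values=["NA"]).set_index("drug")
    return (ReceptorAffinityTable(ki=frame[RECEPTORS].astype(float)),
            frame["ror025"].astype(float))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n_effective: int
    p_two_sided: float
    method: str  # exact_permutation | t_approximation | insufficient_data
    d_squared_sum: float

    @property
    def defined(self) -> bool:
        return self.method != "insufficient_data"


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: fraction of the n! permutations of one rank
    vector with |rho| >= |rho_obs| - 1e-12 (tolerance guards float
    equality at the observed statistic)."""
    n = len(rx)
    rx_c = rx - rx.mean()
    rx_norm = np.linalg.norm(rx_c)
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    pc = perms - perms.mean(axis=1, keepdims=True)
    rhos = (pc @ rx_c) / (np.linalg.norm(pc, axis=1) * rx_norm)
    return float(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12) / len(perms))


def spearman(x, y, p_method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete missing handling.

    Ties get mid-ranks; rho uses the classical 1 - 6*sum(d^2)/(n(n^2-1))
    formula when tie-free and Pearson-on-ranks otherwise.  ``p_method``:
    ``"auto"`` (exact enumeration for n <= 9, else t approximation),
    ``"exact"``, or ``"t"``.
    """
    if p_method not in ("auto", "exact", "t"):
        raise ValueError(f"unknown p_method {p_method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, have {n}")
    rx = rankdata(x[mask])
    ry = rankdata(y[mask])
    d2 = float(np.sum((rx - ry) ** 2))
    tie_free = len(set(rx)) == n and len(set(ry)) == n
    if tie_free:
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])

    use_exact = p_method == "exact" or (p_method == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        if n > EXACT_N_MAX:
            raise InsufficientDataError(f"exact enumeration capped at n={EXACT_N_MAX}")
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact_permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(t_dist.sf(abs(t_stat), df=n - 2))
        method = "t_approximation"
    return CorrelationResult(rho=rho, n_effective=n, p_two_sided=p,
                             method=method, d_squared_sum=d2)


def correlate_panel(ror_by_drug, affinity: ReceptorAffinityTable,
                    use_inverse_affinity: bool = False,
                    p_method: str = "auto") -> dict[str, CorrelationResult]:
    """Spearman correlation of per-drug signal strength against every
    receptor column and ratio column, pairwise-complete per column.

    ``ror_by_drug`` maps drug -> signal value (e.g. group-level ROR025).
    Columns with fewer than three complete pairs are reported with
    method ``"insufficient_data"`` rather than raised.
    """
    ror = pd.Series(ror_by_drug, dtype=float)
    shared = [d for d in affinity.drugs if d in ror.index]
    if len(shared) < 3:
        raise InsufficientDataError("need >=3 drugs shared between tables")
    panel = affinity.panel().loc[shared]
    if use_inverse_affinity:
        panel = 1.0 / panel
    x = ror.loc[shared].to_numpy()
    out: dict[str, CorrelationResult] = {}
    for col in panel.columns:
        y = panel[col].to_numpy()
        try:
            out[col] = spearman(x, y, p_method=p_method)
        except InsufficientDataError:
            n = int((~(np.isnan(x) | np.isnan(y))).sum())
            out[col] = CorrelationResult(rho=math.nan, n_effective=n,
                                         p_two_sided=math.nan,
                                         method="insufficient_data",
                                         d_squared_sum=math.nan)
    return out


def panel_to_frame(panel: dict[str, CorrelationResult]) -> pd.DataFrame:
    rows = [{"column": k, "n": v.n_effective, "rho": v.rho,
             "p_two_sided": v.p_two_sided, "method": v.method}
            for k, v in panel.items()]
    return pd.DataFrame(rows, columns=["column", "n", "rho", "p_two_sided", "method"])
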