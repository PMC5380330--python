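"""Gene-set over-representation analysis.

For a selected gene list against each term of a collection: build the 2×2
contingency table over a background universe, compute a one-sided Fisher
exact (hypergeometric upper tail) p-value and a Pearson χ² p-value,
Benjamini–Hochberg-adjust the Fisher p-values over the whole tested
family, and flag terms significant when p < 0.05 and q < 0.05 (strict).
The χ² value is reported alongside but does not govern significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_contingency",
    "fisher_exact_enrichment",
    "chi_square_enrichment",
    "bh_fdr",
    "significant_terms",
    "enrich",
    "membership_matrix",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: a = selected∩set, b = selected∖set, c = unselected∩set,
    d = unselected∖set."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    table: ContingencyTable
    p_fisher: float
    p_chi2: float
    q_bh: float = float("nan")
    significant: bool = False


def build_contingency(
    selected: Iterable[str], term_set: Iterable[str], background: Iterable[str]
) -> ContingencyTable:
    """Count the 2×2 table of selected × term membership over the
    background universe.  Term members outside the background are ignored;
    selected genes outside the background are an error."""
    sel = set(selected)
    bg = set(background)
    if not bg:
        raise ValueError("background universe is empty")
    stray = sel - bg
    if stray:
        raise ValueError(f"selected genes not in background: {sorted(stray)}")
    term = set(term_set) & bg
    a = len(sel & term)
    b = len(sel - term)
    c = len(term - sel)
    d = len(bg) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_exact_enrichment(table: ContingencyTable) -> float:
    """One-sided over-representation p: P(X >= a) for
    X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b)."""
    N = table.n
    K = table.a + table.c
    n = table.a + table.b
    return float(stats.hypergeom.sf(table.a - 1, N, K, n))


def chi_square_enrichment(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson χ² with 1 df, two-sided; Yates continuity correction
    optional.  Any zero marginal makes the statistic undefined: returns
    (0, 1)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.n
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0 or N == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - N / 2.0)
    chi2 = N * diff**2 / (row1 * row2 * col1 * col2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, aligned to the input
    order and clipped to [0, 1]: q(i) = min_{j>=i} p(j)·m/j on sorted p."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def significant_terms(
    results: Sequence[EnrichmentResult], alpha: float = 0.05, fdr: float = 0.05
) -> list[EnrichmentResult]:
    """Terms passing the dual rule p_fisher < alpha and q_bh < fdr (strict)."""
    return [r for r in results if r.p_fisher < alpha and r.q_bh < fdr]


def enrich(
    selected: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
    fdr: float = 0.05,
    yates: bool = False,
) -> list[EnrichmentResult]:
    """Run the full over-representation analysis for every term.

    The background defaults to the collection's declared universe, else the
    union of all term members plus the selected genes.
    """
    sel = set(selected)
    if background is not None:
        bg = set(background)
    elif collection.background is not None:
        bg = set(collection.background)
    else:
        bg = set(collection.all_genes()) | sel
    results: list[EnrichmentResult] = []
    for term_id, (term_name, members) in collection.sets.items():
        table = build_contingency(sel, members, bg)
        p_fisher = fisher_exact_enrichment(table)
        _, p_chi2 = chi_square_enrichment(table, yates=yates)
        results.append(
            EnrichmentResult(
                term_id=term_id, term_name=term_name, table=table,
                p_fisher=p_fisher, p_chi2=p_chi2,
            )
        )
    qs = bh_fdr([r.p_fisher for r in results])
    for r, q in zip(results, qs):
        r.q_bh = float(q)
        r.significant = r.p_fisher < alpha and r.q_bh < fdr
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "p_fisher": r.p_fisher,
            "p_chi2": r.p_chi2,
            "q_bh": r.q_bh,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "a", "b", "c", "d",
                 "p_fisher", "p_chi2", "q_bh", "significant"],
    )


def membership_matrix(
    results: Sequence[EnrichmentResult],
    collection: GeneSetCollection,
    genes: Iterable[str],
) -> pd.DataFrame:
    """Binary term × gene matrix: entry (t, g) = 1 iff g belongs to term t
    and to the supplied gene list.  Rows and columns are ordered by
    descending marginal sums, ties broken lexicographically."""
    gene_list = sorted(set(genes))
    terms = [r.term_id for r in results]
    mat = pd.DataFrame(0, index=terms, columns=gene_list, dtype=int)
    for r in results:
        members = collection.members(r.term_id)
        for g in gene_list:
            if g in members:
                mat.loc[r.term_id, g] = 1
    row_order = sorted(mat.index, key=lambda t: (-mat.loc[t].sum(), t))
    col_order = sorted(mat.columns, key=lambda g: (-mat[g].sum(), g))
    return mat.loc[row_order, col_order]
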