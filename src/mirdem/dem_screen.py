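"""Differentially expressed miRNA (DEM) screening and contrast comparison.

A probe is called a DEM in a two-group contrast when all three criteria
hold simultaneously: linear fold change > 2.0 (up) or < 0.5 (down), raw
two-sided pooled-variance t-test p < 0.05, and consistent detection flags
(within each compared group all replicate flags identical, with at least
one group commonly Present).  All inequalities are strict.  No multiple
testing correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionDataset

__all__ = [
    "ContrastResult",
    "ContrastComparison",
    "flag_consistency_filter",
    "student_t_test",
    "fold_change",
    "call_dems",
    "run_contrast",
    "truncate_percent",
    "compare_contrasts",
    "hierarchical_order",
]


@dataclass
class ContrastResult:
    """Per-probe statistics and calls for one test-vs-reference contrast.

    ``table`` is indexed by probe id with columns fc_linear, log2fc,
    t_stat, p_value, flag_ok, degenerate, call ∈ {up, down, none}.
    """

    test: str
    reference: str
    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def up_probes(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down_probes(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    @classmethod
    def from_calls(cls, test: str, reference: str, calls: Mapping[str, str]) -> "ContrastResult":
        """Build a minimal result from probe→call labels (for set analyses)."""
        df = pd.DataFrame({"call": pd.Series(dict(calls), dtype=object)})
        df.index.name = "probe_id"
        return cls(test=test, reference=reference, table=df)


def flag_consistency_filter(
    dataset: ExpressionDataset, test: str, reference: str
) -> pd.Series:
    """Per-probe flag criterion: within each of the two compared groups all
    replicate flags must be identical, and at least one group's common flag
    must be Present.  Probes Absent across both groups are unmeasured and
    fail."""
    for group in (test, reference):
        if len(dataset.sample_indices(group)) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 replicates")
    idx_t = dataset.sample_indices(test)
    idx_r = dataset.sample_indices(reference)
    flags_t = dataset.present[:, idx_t]
    flags_r = dataset.present[:, idx_r]
    same_t = (flags_t == flags_t[:, [0]]).all(axis=1)
    same_r = (flags_r == flags_r[:, [0]]).all(axis=1)
    any_present = flags_t[:, 0] | flags_r[:, 0]
    ok = same_t & same_r & any_present
    return pd.Series(ok, index=dataset.probe_ids, name="flag_ok")


def student_t_test(
    log2_values: np.ndarray,
    idx_a: Sequence[int],
    idx_b: Sequence[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise unpaired two-sample t-test with pooled variance.

    Returns ``(t, p, degenerate)``.  With zero pooled variance the test is
    undefined: equal means give (t=0, p=1); unequal means give p=0 with the
    degenerate flag set so callers can log the probe.
    """
    a = np.asarray(log2_values, dtype=float)[:, list(idx_a)]
    b = np.asarray(log2_values, dtype=float)[:, list(idx_b)]
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >=2 replicates")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled_var = (ss_a + ss_b) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))

    diff = mean_a - mean_b
    degenerate = (se == 0) & (diff != 0)
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    regular = se > 0
    t[regular] = diff[regular] / se[regular]
    p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df)
    t[degenerate] = np.where(diff[degenerate] > 0, np.inf, -np.inf)
    p[degenerate] = 0.0
    return t, p, degenerate


def fold_change(
    linear_values: np.ndarray,
    idx_test: Sequence[int],
    idx_reference: Sequence[int],
) -> np.ndarray:
    """Per-probe fold change = mean(test) / mean(reference) on the linear
    normalized scale.  Zero reference mean yields NaN (probe excluded)."""
    v = np.asarray(linear_values, dtype=float)
    mean_t = v[:, list(idx_test)].mean(axis=1)
    mean_r = v[:, list(idx_reference)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_r > 0, mean_t / mean_r, np.nan)
    return fc


def call_dems(
    result: ContrastResult,
    alpha: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> ContrastResult:
    """Assign up/down/none calls using strict thresholds on fold change,
    p-value and the flag criterion; all three must hold."""
    t = result.table
    usable = t["flag_ok"] & t["fc_linear"].notna() & (t["p_value"] < alpha)
    call = np.where(
        usable & (t["fc_linear"] > fc_up),
        "up",
        np.where(usable & (t["fc_linear"] < fc_down), "down", "none"),
    )
    t = t.copy()
    t["call"] = call
    return ContrastResult(
        test=result.test,
        reference=result.reference,
        table=t,
        thresholds={"alpha": alpha, "fc_up": fc_up, "fc_down": fc_down},
    )


def run_contrast(
    dataset: ExpressionDataset,
    log2_values: np.ndarray,
    test: str,
    reference: str,
    alpha: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> ContrastResult:
    """Full screen for one contrast: t-test on log2 values, fold change on
    linear values, flag filter, then DEM calling."""
    idx_t = dataset.sample_indices(test)
    idx_r = dataset.sample_indices(reference)
    t_stat, p, degenerate = student_t_test(log2_values, idx_t, idx_r)
    fc = fold_change(dataset.intensities, idx_t, idx_r)
    flag_ok = flag_consistency_filter(dataset, test, reference)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    table = pd.DataFrame(
        {
            "fc_linear": fc,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p,
            "flag_ok": flag_ok.to_numpy(),
            "degenerate": degenerate,
        },
        index=pd.Index(dataset.probe_ids, name="probe_id"),
    )
    result = ContrastResult(test=test, reference=reference, table=table)
    return call_dems(result, alpha=alpha, fc_up=fc_up, fc_down=fc_down)


def truncate_percent(count: int, total: int) -> float:
    """100·count/total truncated (floored) to two decimals, computed with
    exact rational arithmetic so e.g. 130/150 gives 86.66, not 86.67."""
    if total <= 0:
        raise ValueError("total must be positive")
    hundredths = Fraction(10000 * count, total)
    return (hundredths.numerator // hundredths.denominator) / 100.0


@dataclass
class ContrastComparison:
    """Shared/specific DEM sets between two contrasts and shared-percentage
    summaries (floor-truncated to two decimals)."""

    shared_up: set[str]
    shared_down: set[str]
    specific_up_a: set[str]
    specific_up_b: set[str]
    specific_down_a: set[str]
    specific_down_b: set[str]
    pct_shared_up_a: float
    pct_shared_up_b: float
    pct_shared_down_a: float
    pct_shared_down_b: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("shared_up", len(self.shared_up), self.pct_shared_up_a, self.pct_shared_up_b),
                ("shared_down", len(self.shared_down), self.pct_shared_down_a, self.pct_shared_down_b),
                ("specific_up_a", len(self.specific_up_a), np.nan, np.nan),
                ("specific_up_b", len(self.specific_up_b), np.nan, np.nan),
                ("specific_down_a", len(self.specific_down_a), np.nan, np.nan),
                ("specific_down_b", len(self.specific_down_b), np.nan, np.nan),
            ],
            columns=["category", "count", "pct_of_a", "pct_of_b"],
        )


def compare_contrasts(a: ContrastResult, b: ContrastResult) -> ContrastComparison:
    """Set intersections/differences of the up/down calls of two contrasts
    over the same probe universe, with shared counts expressed as truncated
    two-decimal percentages of each contrast's totals."""
    if set(a.table.index) != set(b.table.index):
        raise ValueError("contrasts cover different probe universes")
    up_a, up_b = a.up_probes, b.up_probes
    down_a, down_b = a.down_probes, b.down_probes
    shared_up = up_a & up_b
    shared_down = down_a & down_b

    def pct(shared: set[str], total: set[str]) -> float:
        return truncate_percent(len(shared), len(total)) if total else 0.0

    return ContrastComparison(
        shared_up=shared_up,
        shared_down=shared_down,
        specific_up_a=up_a - up_b,
        specific_up_b=up_b - up_a,
        specific_down_a=down_a - down_b,
        specific_down_b=down_b - down_a,
        pct_shared_up_a=pct(shared_up, up_a),
        pct_shared_up_b=pct(shared_up, up_b),
        pct_shared_down_a=pct(shared_down, down_a),
        pct_shared_down_b=pct(shared_down, down_b),
    )


# ---------------------------------------------------------------------------
# Hierarchical ordering of DEM profiles


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between rows; rows with zero variance are at
    distance 1 from everything else (and 0 from themselves)."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    centered = v - v.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    d = np.ones((n, n))
    nz = norms > 0
    if nz.any():
        u = centered[nz] / norms[nz, None]
        corr = np.clip(u @ u.T, -1.0, 1.0)
        d[np.ix_(nz, nz)] = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_order(
    log2_values: np.ndarray, probe_ids: Sequence[str]
) -> tuple[list[str], list[tuple[str, str, float, int]]]:
    """Agglomerative average-linkage ordering of probe profiles.

    Distance is 1 − Pearson correlation.  At every step the pair of
    clusters at minimal average distance is merged; exact ties break on the
    lexicographically smallest (representative, representative) pair, and a
    merged cluster lists the lexicographically smaller side first, so the
    leaf order is deterministic for any input permutation.

    Returns ``(leaf_order, merges)`` where each merge is
    (repr_left, repr_right, height, merged_size).
    """
    ids = list(probe_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate probe ids")
    if len(ids) < 2:
        raise ValueError("need >=2 probes to order")
    v = np.asarray(log2_values, dtype=float)
    order = np.argsort(np.array(ids, dtype=object))
    # canonical input order: sort rows by probe id so permutations are moot
    ids = [ids[i] for i in order]
    v = v[order]

    d = _correlation_distance(v)
    clusters: dict[str, list[str]] = {pid: [pid] for pid in ids}
    dist: dict[frozenset[str], float] = {}
    for i, pi in enumerate(ids):
        for j in range(i + 1, len(ids)):
            dist[frozenset((pi, ids[j]))] = d[i, j]

    merges: list[tuple[str, str, float, int]] = []
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        pair, height = best
        left, right = sorted(pair)
        size_l, size_r = len(clusters[left]), len(clusters[right])
        merged = clusters[left] + clusters[right]
        merges.append((left, right, height, len(merged)))
        del clusters[left], clusters[right]
        new_rep = left  # lexicographically smaller representative
        for key in list(dist):
            if left in key or right in key:
                del dist[key]
        clusters[new_rep] = merged
        idx = {pid: k for k, pid in enumerate(ids)}
        for other, members in clusters.items():
            if other == new_rep:
                continue
            total = sum(d[idx[p1], idx[p2]] for p1 in merged for p2 in members)
            dist[frozenset((new_rep, other))] = total / (len(merged) * len(members))

    leaf_order = clusters[next(iter(clusters))]
    return leaf_order, merges
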