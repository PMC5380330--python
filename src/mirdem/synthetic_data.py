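"""Seeded generators for datasets with the statistical structure the
pipeline assumes, plus packaged text fixtures.

Every generator takes an explicit integer seed and is byte-deterministic.
Planted ground truth is returned as a first-class object so recovery tests
never re-derive it from the generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genomic_clustering import GenomicFeature
from .io_formats import ExpressionDataset, GeneSetCollection, MTITable, read_coordinates, read_mti

__all__ = [
    "DESpec",
    "ClusterSpec",
    "GeneSetSpec",
    "EnrichmentSpec",
    "AnnotationResult",
    "TargetDB",
    "generate_expression_dataset",
    "generate_annotation",
    "generate_target_db",
    "codown_cluster_fixture",
    "mti_fixture",
    "MTI_FIXTURE_DOWN",
    "MTI_FIXTURE_UP",
]


# ---------------------------------------------------------------------------
# Expression matrices with planted differential expression


@dataclass
class DESpec:
    """Parameters of a planted-DE expression simulation.

    The first group is the reference condition; every other group defines
    one test-vs-reference contrast.  ``shared_fraction`` of each planted
    direction is common to all test groups (co-regulation), the rest is
    contrast-specific.  Baseline log2 intensities are N(baseline_mean,
    baseline_sd); planted probes shift the test-group mean by
    ±``effect_log2``; replicates add N(0, noise_sd_log2).  Intensities are
    exported on the linear scale (2**log2).  Measurements falling below the
    ``low_intensity_quantile`` of the whole matrix are flagged Absent with
    probability ``flag_dropout``.
    """

    n_probes: int = 2006
    groups: dict[str, int] = field(
        default_factory=lambda: {"PBMC": 3, "CIK_IL2": 3, "CIK_IL15": 3}
    )
    de_fraction_up: float = 0.05
    de_fraction_down: float = 0.05
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.25
    flag_dropout: float = 0.1
    shared_fraction: float = 0.9
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    low_intensity_quantile: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        for name in ("de_fraction_up", "de_fraction_down", "shared_fraction", "flag_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if len(self.groups) < 2:
            raise ValueError("need a reference group and >=1 test group")
        for g, reps in self.groups.items():
            if reps < 2:
                raise ValueError(f"group {g!r} has {reps} replicate(s); need >=2")

    @property
    def reference_group(self) -> str:
        return next(iter(self.groups))

    @property
    def test_groups(self) -> list[str]:
        return list(self.groups)[1:]

    def contrast_name(self, test: str) -> str:
        return f"{test}_vs_{self.reference_group}"


def generate_expression_dataset(spec: DESpec) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate a flagged expression dataset with planted DEMs.

    Returns ``(dataset, truth)`` where truth is a probe × contrast frame
    with entries in {"up", "down", "none"} recording the planted status.
    """
    rng = np.random.default_rng(spec.seed)
    probe_ids = [f"probe{i:05d}" for i in range(spec.n_probes)]
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for g, reps in spec.groups.items():
        for r in range(1, reps + 1):
            sid = f"{g}_r{r}"
            sample_ids.append(sid)
            groups[sid] = g

    n_up = round(spec.de_fraction_up * spec.n_probes)
    n_down = round(spec.de_fraction_down * spec.n_probes)
    n_shared_up = round(spec.shared_fraction * n_up)
    n_shared_down = round(spec.shared_fraction * n_down)
    tests = spec.test_groups
    needed = (
        n_shared_up
        + n_shared_down
        + len(tests) * ((n_up - n_shared_up) + (n_down - n_shared_down))
    )
    if needed > spec.n_probes:
        raise ValueError(f"planted design needs {needed} probes but only {spec.n_probes} exist")

    pool = list(rng.permutation(spec.n_probes))

    def take(k: int) -> list[int]:
        out = [pool.pop() for _ in range(k)]
        return out

    shared_up = take(n_shared_up)
    shared_down = take(n_shared_down)
    planted: dict[str, dict[int, str]] = {}
    for g in tests:
        status = {p: "up" for p in shared_up}
        status.update({p: "down" for p in shared_down})
        for p in take(n_up - n_shared_up):
            status[p] = "up"
        for p in take(n_down - n_shared_down):
            status[p] = "down"
        planted[g] = status

    baseline = rng.normal(spec.baseline_mean_log2, spec.baseline_sd_log2, size=spec.n_probes)
    log2 = np.empty((spec.n_probes, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        g = groups[sid]
        shift = np.zeros(spec.n_probes)
        if g in planted:
            for p, direction in planted[g].items():
                shift[p] = spec.effect_log2 if direction == "up" else -spec.effect_log2
        noise = rng.normal(0.0, spec.noise_sd_log2, size=spec.n_probes)
        log2[:, j] = baseline + shift + noise

    linear = np.exp2(log2)
    threshold = np.quantile(linear, spec.low_intensity_quantile)
    dropout = rng.random(linear.shape) < spec.flag_dropout
    present = ~((linear < threshold) & dropout)

    dataset = ExpressionDataset(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        intensities=linear,
        present=present,
        groups=groups,
    )
    truth = pd.DataFrame(
        "none",
        index=pd.Index(probe_ids, name="probe_id"),
        columns=[spec.contrast_name(g) for g in tests],
    )
    for g in tests:
        col = spec.contrast_name(g)
        for p, direction in planted[g].items():
            truth.loc[probe_ids[p], col] = direction
    return dataset, truth


# ---------------------------------------------------------------------------
# Genomic annotations with planted clusters


@dataclass
class ClusterSpec:
    """Parameters of a planted-cluster genomic annotation.

    Consecutive members of a planted cluster are separated by gaps of at
    most ``intra_gap_bp``; distinct planted units (clusters and singletons)
    are separated by at least ``min_inter_cluster_gap_bp``.
    """

    n_clusters: int = 5
    sizes: Sequence[int] | int = 2
    intra_gap_bp: int = 3000
    n_singletons: int = 0
    min_inter_cluster_gap_bp: int = 1_000_000
    chromosomes: Sequence[str] = ("chr1", "chr2", "chr3", "chr4", "chr5")
    feature_length: tuple[int, int] = (18, 23)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sizes, int):
            self.sizes = [self.sizes] * self.n_clusters
        if len(self.sizes) != self.n_clusters:
            raise ValueError("sizes must list one count per cluster")
        if any(s < 2 for s in self.sizes):
            raise ValueError("planted clusters need >=2 members")
        if self.intra_gap_bp >= self.min_inter_cluster_gap_bp:
            raise ValueError("intra_gap_bp must be < min_inter_cluster_gap_bp")


class AnnotationResult(NamedTuple):
    features: list[GenomicFeature]
    planted_clusters: list[frozenset[str]]


def generate_annotation(spec: ClusterSpec) -> AnnotationResult:
    """Place planted clusters and isolated singletons on chromosomes.

    Roughly half the features are put on the minus strand so that writing
    them in the start>end coordinate dialect exercises normalization.
    """
    rng = np.random.default_rng(spec.seed)
    cursors = {c: int(rng.integers(1_000_000, 2_000_000)) for c in spec.chromosomes}
    chrom_cycle = list(spec.chromosomes)
    features: list[GenomicFeature] = []
    planted: list[frozenset[str]] = []

    units: list[tuple[str, int]] = [("cluster", s) for s in spec.sizes]
    units += [("singleton", 1)] * spec.n_singletons

    for u, (kind, size) in enumerate(units):
        chrom = chrom_cycle[u % len(chrom_cycle)]
        pos = cursors[chrom]
        names: list[str] = []
        for i in range(size):
            length = int(rng.integers(spec.feature_length[0], spec.feature_length[1] + 1))
            low, high = pos, pos + length - 1
            strand = "-" if rng.random() < 0.5 else "+"
            name = f"mir-{kind[0].upper()}{u}-{i}"
            features.append(
                GenomicFeature(name=name, chromosome=chrom, low=low, high=high, strand=strand)
            )
            names.append(name)
            gap = int(rng.integers(1, spec.intra_gap_bp + 1))
            pos = high + gap
        if kind == "cluster":
            planted.append(frozenset(names))
        jitter = int(rng.integers(0, spec.min_inter_cluster_gap_bp))
        cursors[chrom] = features[-1].high + spec.min_inter_cluster_gap_bp + jitter
    return AnnotationResult(features=features, planted_clusters=planted)


# ---------------------------------------------------------------------------
# Target databases with planted gene-set enrichment


@dataclass
class GeneSetSpec:
    n_terms: int = 20
    set_size: int = 50

    def __post_init__(self) -> None:
        if self.n_terms < 1 or self.set_size < 1:
            raise ValueError("n_terms and set_size must be >= 1")


@dataclass
class EnrichmentSpec:
    """How to wire the planted enrichment: a designated miRNA subset is
    connected to genes of ``n_enriched`` designated terms with the base
    edge probability multiplied by ``multiplier`` (1 = null)."""

    n_enriched: int = 2
    multiplier: float = 1.0
    base_prob: float = 0.05
    selected_mirnas: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        if not 0.0 < self.base_prob < 1.0:
            raise ValueError("base_prob must lie in (0, 1)")


class TargetDB(NamedTuple):
    mti: MTITable
    gene_sets: GeneSetCollection
    enriched_terms: frozenset[str]
    selected_mirnas: tuple[str, ...]


def generate_target_db(
    mirnas: Sequence[str],
    n_genes: int,
    geneset_spec: GeneSetSpec,
    enrichment_spec: EnrichmentSpec,
    seed: int = 0,
) -> TargetDB:
    """Simulate a miRNA→gene interaction table plus gene sets with planted
    over-representation.

    Truth = ``enriched_terms`` × ``selected_mirnas``: target lists of the
    selected miRNAs are over-wired into the enriched terms' genes at
    ``base_prob × multiplier``.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    if geneset_spec.set_size > n_genes:
        raise ValueError("set_size exceeds the gene universe")
    term_ids = [f"TERM{i:04d}" for i in range(geneset_spec.n_terms)]
    for term in term_ids:
        members = rng.choice(genes, size=geneset_spec.set_size, replace=False)
        sets[term] = (f"simulated set {term}", frozenset(members.tolist()))
    gene_sets = GeneSetCollection(sets=sets, background=frozenset(genes.tolist()))

    if not mirnas:
        return TargetDB(MTITable(edges=[]), gene_sets, frozenset(), tuple())

    n_enriched = min(enrichment_spec.n_enriched, len(term_ids))
    enriched = frozenset(rng.choice(term_ids, size=n_enriched, replace=False).tolist())
    if enrichment_spec.selected_mirnas is not None:
        selected = tuple(enrichment_spec.selected_mirnas)
    else:
        selected = tuple(mirnas[: max(1, len(mirnas) // 2)])

    enriched_genes = frozenset().union(*(sets[t][1] for t in enriched)) if enriched else frozenset()
    gene_is_enriched = np.isin(genes, sorted(enriched_genes))
    base = enrichment_spec.base_prob
    boosted = min(0.95, base * enrichment_spec.multiplier)

    edges: list[tuple[str, str, str]] = []
    for mirna in mirnas:
        p = np.where(
            gene_is_enriched & (mirna in selected), boosted, base
        )
        hits = rng.random(n_genes) < p
        for gene in genes[hits]:
            edges.append((mirna, str(gene), "simulated"))
    return TargetDB(MTITable(edges=edges), gene_sets, enriched, selected)


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str):
    return resources.files("mirdem").joinpath("data", name)


def codown_cluster_fixture() -> list[GenomicFeature]:
    """The packaged 37-record coordinate table of co-downregulated human
    miRNA loci (1-based inclusive, minus strand printed start > end) used
    as the exact-recovery fixture for genomic clustering."""
    with resources.as_file(_data_path("codown_mirna_loci.tsv")) as path:
        return read_coordinates(path, dialect="mircoord")


MTI_FIXTURE_DOWN = frozenset(
    {"hsa-let-7c", "hsa-miR-199a-5p", "hsa-miR-199b-5p", "hsa-miR-30e-5p"}
)
MTI_FIXTURE_UP = frozenset({"hsa-miR-155-5p"})


def mti_fixture() -> tuple[MTITable, frozenset[str], frozenset[str]]:
    """Small curated miRNA→gene interaction fixture for network contract
    tests.  Returns ``(table, down_mirnas, up_mirnas)``."""
    with resources.as_file(_data_path("mti_fixture.tsv")) as path:
        table = read_mti(path)
    return table, MTI_FIXTURE_DOWN, MTI_FIXTURE_UP
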