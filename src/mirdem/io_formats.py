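"""Readers and writers for every external representation the pipeline touches.

All on-disk formats are plain text: TSV expression/flag matrices with a
two-column sample→group map, coordinate tables (BED or the 1-based start>end minus-strand dialect), GMT gene-set collections, TSV miRNA→gene edge lists
and TSV result tables.  Round-trips are value-exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_clustering import GenomicFeature, normalize_coordinates

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionDataset",
    "GeneSetCollection",
    "MTITable",
    "normalize_gene_symbol",
    "read_expression_table",
    "write_expression_dataset",
    "read_coordinates",
    "write_coordinates",
    "read_gmt",
    "write_gmt",
    "read_mti",
    "write_mti",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# Protein-style names that appear in interaction tables mapped to the
# corresponding HGNC gene symbol.  Lookup happens after uppercasing.
GENE_ALIASES: dict[str, str] = {
    "FASL": "FASLG",
    "TRAIL": "TNFSF10",
    "CD94": "KLRD1",
    "TNF-A": "TNF",
    "TNF-ALPHA": "TNF",
    "TNFA": "TNF",
}


def normalize_gene_symbol(symbol: str) -> str:
    """Uppercase a gene symbol and resolve known protein-name aliases."""
    s = symbol.strip().upper().replace("Α", "A")
    return GENE_ALIASES.get(s, s)


# ---------------------------------------------------------------------------
# Expression datasets


@dataclass
class ExpressionDataset:
    """Probe × sample intensity matrix with detection flags and group map.

    ``intensities`` are linear-scale non-negative reals; ``present`` is a
    boolean matrix of the same shape (True = the Present detection flag,
    any other flag token collapses to Absent).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    present: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        n_probes, n_samples = len(self.probe_ids), len(self.sample_ids)
        if len(set(self.probe_ids)) != n_probes:
            raise FormatError("duplicate probe ids")
        if len(set(self.sample_ids)) != n_samples:
            raise FormatError("duplicate sample ids")
        if self.intensities.shape != (n_probes, n_samples):
            raise FormatError(
                f"intensity shape {self.intensities.shape} != ({n_probes}, {n_samples})"
            )
        if self.present.shape != self.intensities.shape:
            raise FormatError(
                f"flag shape {self.present.shape} != intensity shape {self.intensities.shape}"
            )
        if (self.intensities < 0).any():
            raise FormatError("negative intensities")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group assignment: {missing}")

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def sample_indices(self, group: str) -> list[int]:
        idx = [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    def with_intensities(self, values: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            probe_ids=list(self.probe_ids),
            sample_ids=list(self.sample_ids),
            intensities=np.asarray(values, dtype=float),
            present=self.present.copy(),
            groups=dict(self.groups),
        )


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe id(s) in {path}: {dups}")
    return df


def read_expression_table(
    path: str | Path,
    flag_path: str | Path | None = None,
    group_path: str | Path | None = None,
    groups: Mapping[str, str] | None = None,
    flag_suffix: str = "_flag",
) -> ExpressionDataset:
    """Read a TSV intensity table plus flags and a sample→group map.

    Flags come either from a parallel file of identical layout
    (``flag_path``) or from interleaved columns named ``<sample><flag_suffix>``
    in the main table.  The group map is a headerless two-column TSV
    (sample, group) or an explicit mapping.
    """
    path = Path(path)
    raw = _read_matrix(path)

    if flag_path is not None:
        flags = _read_matrix(Path(flag_path))
        intens = raw
    else:
        flag_cols = [c for c in raw.columns if c.endswith(flag_suffix)]
        if not flag_cols:
            raise FormatError(f"no flag columns (*{flag_suffix}) and no flag file given")
        intens = raw[[c for c in raw.columns if not c.endswith(flag_suffix)]]
        flags = raw[flag_cols].rename(columns=lambda c: c[: -len(flag_suffix)])

    if list(flags.index) != list(intens.index) or list(flags.columns) != list(intens.columns):
        raise FormatError(
            f"flag matrix layout does not match intensities "
            f"({flags.shape} vs {intens.shape})"
        )

    if groups is None:
        if group_path is None:
            raise FormatError("either group_path or groups mapping is required")
        gdf = pd.read_csv(group_path, sep="\t", header=None, dtype=str, comment="#")
        if gdf.shape[1] < 2:
            raise FormatError("group map must have two columns: sample, group")
        groups = dict(zip(gdf[0], gdf[1]))

    try:
        values = intens.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity in {path}: {exc}") from exc
    present = flags.apply(lambda col: col.str.strip().str.upper().isin(["P", "PRESENT"]))
    return ExpressionDataset(
        probe_ids=list(intens.index),
        sample_ids=list(intens.columns),
        intensities=values,
        present=present.to_numpy(),
        groups=dict(groups),
    )


def write_expression_dataset(
    dataset: ExpressionDataset,
    expression_path: str | Path,
    flag_path: str | Path,
    group_path: str | Path,
) -> None:
    """Write a dataset in the three-file layout read_expression_table reads.

    Intensities use repr-exact float formatting so write→read round-trips
    bit-stably.
    """
    intens = pd.DataFrame(
        dataset.intensities, index=dataset.probe_ids, columns=dataset.sample_ids
    )
    intens.index.name = "probe_id"
    intens.to_csv(expression_path, sep="\t", float_format=None)
    flags = pd.DataFrame(
        np.where(dataset.present, "Present", "Absent"),
        index=dataset.probe_ids,
        columns=dataset.sample_ids,
    )
    flags.index.name = "probe_id"
    flags.to_csv(flag_path, sep="\t")
    with open(group_path, "w") as fh:
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{dataset.groups[s]}\n")


# ---------------------------------------------------------------------------
# Coordinate tables


def read_coordinates(path: str | Path, dialect: str = "mircoord") -> list[GenomicFeature]:
    """Read miRNA genomic coordinates.

    ``mircoord`` dialect: whitespace/tab-separated columns (name, accession,
    chromosome, start, end), 1-based inclusive, minus strand encoded as
    start > end.  Single-token section labels and a header line are
    skipped.  ``bed`` dialect: standard 0-based half-open BED (chrom,
    start, end, name[, score, strand]); converted to the internal 1-based
    inclusive convention.
    """
    path = Path(path)
    features: list[GenomicFeature] = []
    if dialect == "mircoord":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            fields = line.split()
            if len(fields) < 5:
                continue  # blank lines, cluster labels, short rows
            name, accession, chrom, start_s, end_s = fields[:5]
            if not (start_s.lstrip("-").isdigit() and end_s.lstrip("-").isdigit()):
                if lineno == 1:
                    continue  # header row
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate {start_s!r}/{end_s!r}")
            low, high, strand = normalize_coordinates(int(start_s), int(end_s))
            features.append(
                GenomicFeature(
                    name=name, accession=accession, chromosome=chrom,
                    low=low, high=high, strand=strand,
                )
            )
    elif dialect == "bed":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >=3 fields")
            chrom, start_s, end_s = fields[:3]
            if not (start_s.isdigit() and end_s.isdigit()):
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate")
            start0, end0 = int(start_s), int(end_s)
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "unknown"
            features.append(
                GenomicFeature(
                    name=name, chromosome=chrom,
                    low=start0 + 1, high=end0, strand=strand,
                )
            )
    else:
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    return features


def write_coordinates(features: Iterable[GenomicFeature], path: str | Path) -> None:
    """Write features in the mircoord dialect (minus strand as start > end)."""
    with open(path, "w") as fh:
        fh.write("name\taccession\tchromosome\tstart\tend\n")
        for f in features:
            if f.strand == "-":
                start, end = f.high, f.low
            else:
                start, end = f.low, f.high
            fh.write(f"{f.name}\t{f.accession}\t{f.chromosome}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Gene sets and interaction tables


@dataclass
class GeneSetCollection:
    """Named gene sets (term_id → (term_name, members)) with an optional
    explicit background universe.  Members are normalized symbols."""

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} is empty")

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class MTITable:
    """miRNA→gene interaction edge list, deduplicated on (miRNA, gene)."""

    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, str, str]] = []
        dropped = 0
        for mirna, gene, *rest in self.edges:
            gene = normalize_gene_symbol(gene)
            evidence = rest[0] if rest else ""
            key = (mirna, gene)
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
            unique.append((mirna, gene, evidence))
        if dropped:
            logger.info("deduplicated %d repeated MTI edge(s)", dropped)
        self.edges = unique

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _, _ in self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g, _ in self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
        term, desc = fields[0], fields[1]
        members = frozenset(normalize_gene_symbol(g) for g in fields[2:] if g.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: empty gene set {term!r}")
        sets[term] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_mti(path: str | Path) -> MTITable:
    edges: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0].strip().lower() in {"mirna", "mirna_id", "mir"}:
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: edge line needs miRNA and gene columns")
        edges.append((fields[0].strip(), fields[1].strip(), fields[2].strip() if len(fields) > 2 else ""))
    return MTITable(edges=edges)


def write_mti(table: MTITable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tevidence\n")
        for mirna, gene, evidence in table.edges:
            fh.write(f"{mirna}\t{gene}\t{evidence}\n")


# ---------------------------------------------------------------------------
# Result tables

_PVALUE_COLUMNS = {"p_value", "p_fisher", "p_chi2", "q_bh", "fc_linear", "log2fc", "t_stat"}


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write result tables as TSV with stable column order and 6 significant
    digits on statistics columns.  Empty tables produce headers-only files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        out = df.copy()
        for col in out.columns:
            if col in _PVALUE_COLUMNS:
                out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
        out.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
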