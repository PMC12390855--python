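"""Readers and writers for the on-disk formats the pipeline touches.

Counts travel as 10x-style Matrix Market triplet directories (``matrix.mtx``
plus ``features.tsv`` and ``barcodes.tsv``, optionally gzipped), gene-set
collections as GMT files in the MSigDB dialect, and gene panels as plain
one-symbol-per-line text. Matrix Market indices are 1-based on disk and
0-based in memory. Gene identity is by symbol string, case-sensitive; no
alias resolution is attempted.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as spio

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_gmt",
    "write_gmt",
    "read_gene_panel",
    "write_gene_panel",
    "read_samples_manifest",
]


class FormatError(ValueError):
    """A file exists but does not conform to its declared format."""


def _open_text(path: Path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_variant(directory: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {list(stems)} (or .gz variants) found in {directory}"
    )


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer gene x cell UMI count matrix.

    ``values`` is CSR with genes on rows and cells on columns; zeros are
    implicit (no explicitly stored zero entries).
    """

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix
    sample_id: str = "sample"
    group: str = "control"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.values.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def validate(self) -> "CountMatrix":
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate cell barcodes")
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match axis lengths "
                f"({len(self.genes)}, {len(self.barcodes)})"
            )
        data = self.values.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("count matrix must contain nonnegative integers")
        return self

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def read_10x_mtx(directory_path: str | Path, sample_id: str | None = None,
                 group: str = "control") -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, each optionally gzipped. Genes and barcodes keep file
    order; the 1-based triplet ``(i, j, v)`` maps to gene ``i-1``, cell
    ``j-1``, value ``v``.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    mtx_path = _find_variant(directory, ["matrix.mtx"])
    feat_path = _find_variant(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_variant(directory, ["barcodes.tsv"])

    with _open_text(mtx_path) as fh:
        try:
            mat = spio.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"{mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
        raise FormatError(f"{mtx_path}: negative or non-integer count value")

    with _open_text(feat_path) as fh:
        feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    genes = [row[1] if len(row) > 1 else row[0] for row in feats]
    with _open_text(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: declared shape {mat.shape} does not match "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    cm = CountMatrix(
        genes=genes,
        barcodes=barcodes,
        values=mat.astype(np.int64).tocsr(),
        sample_id=sample_id if sample_id is not None else directory.name,
        group=group,
    )
    return cm.validate()


def write_10x_mtx(matrix: CountMatrix, directory_path: str | Path) -> None:
    """Write a :class:`CountMatrix` as a 10x-style triplet directory.

    Emits ``matrix.mtx`` (Matrix Market coordinate, integer field, 1-based),
    ``features.tsv`` (id TAB symbol) and ``barcodes.tsv``. The result
    round-trips through :func:`read_10x_mtx`.
    """
    matrix.validate()
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.values.tocoo().astype(np.int64)
    spio.mmwrite(str(directory / "matrix.mtx"), coo)
    with open(directory / "features.tsv", "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in matrix.barcodes:
            fh.write(b + "\n")


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Ordered mapping of gene-set name to (description, unique gene list)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene-set name: {gene_set.name}")
        if not gene_set.genes:
            raise FormatError(f"empty gene set: {gene_set.name}")
        self.sets[gene_set.name] = gene_set


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene TAB gene ...).

    One set per line, line order preserved; duplicate genes within a line are
    dropped keeping the first occurrence. Lines with fewer than three fields
    and duplicate set names raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    collection = GeneSetCollection()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            collection.add(GeneSet(name, description, genes))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gene_panel(path: str | Path) -> list[str]:
    """Read a plain-text gene panel (one symbol per line, blanks ignored).

    Order is preserved; duplicates are removed with a logged warning. An
    empty panel is an error — it cannot drive clustering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with _open_text(path) as fh:
        raw = [line.strip() for line in fh]
    raw = [g for g in raw if g]
    panel = list(dict.fromkeys(raw))
    if len(panel) < len(raw):
        log.warning(
            "gene panel %s contained %d duplicate entries; deduplicated",
            path, len(raw) - len(panel),
        )
    if not panel:
        raise FormatError(f"{path}: empty gene panel")
    return panel


def write_gene_panel(panel: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in panel:
            fh.write(g + "\n")


def read_samples_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV with columns sample_id, group, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "path"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: manifest must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise FormatError(f"{path}: unknown group labels {sorted(bad)}")
    return df
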