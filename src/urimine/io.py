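"""Readers and writers for every table the pipeline touches.

All gene identity in this package is by *normalized official symbol*:
uppercased, whitespace-stripped tokens compared case-insensitively.
Parsers validate strictly and raise :class:`FormatError` rather than
silently coercing malformed values.

Accepted dialects
-----------------
* gene lists — CSV/TSV, one symbol column (by name or index)
* expression tables — TSV, first column ``gene``, header row of sample
  ids, second row ``label`` carrying ``tumor``/``normal`` per sample
* marker tables — CSV/TSV with columns symbol, name, location, family,
  urine, blood, fold_change, p_value; presence flags accept
  ``1/true/yes/y/x/•`` (bullet) for present and blank/``0/false/no`` for absent
* edge lists — three-column delimited text, either ``a<TAB>b<TAB>kind``
  or the SIF order ``a<TAB>kind<TAB>b``
* gene sets — GMT (name, description, members, tab-separated)
* annotations — two-column TSV (gene, term)
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "normalize_symbol",
    "ExpressionTable",
    "MarkerRecord",
    "EdgeRecord",
    "AnnotationRecord",
    "GeneSet",
    "EDGE_KINDS",
    "LOCATIONS",
    "read_gene_list",
    "write_gene_list",
    "read_expression_table",
    "write_expression_table",
    "read_marker_table",
    "write_marker_table",
    "read_edges",
    "write_edges",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotations",
    "write_annotations",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip, uppercase, reject internal whitespace."""
    s = str(symbol).strip()
    if not s:
        raise FormatError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise FormatError(f"gene symbol contains whitespace: {symbol!r}")
    return s.upper()


EDGE_KINDS = ("coexpression", "shared_domain", "colocalization", "physical")

#: Canonical subcellular locations distinguished by the marker table; anything
#: else collapses to "other".
LOCATIONS = ("Extracellular Space", "Plasma Membrane", "Cytoplasm", "other")

_TRUE_FLAGS = {"1", "true", "yes", "y", "x", "•", "present"}
_FALSE_FLAGS = {"", "0", "false", "no", "n", "absent"}


def _parse_flag(cell: object, row: int, column: str) -> bool:
    token = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip().lower()
    if token in _TRUE_FLAGS:
        return True
    if token in _FALSE_FLAGS:
        return False
    raise FormatError(f"row {row}: unrecognized presence flag {cell!r} in column {column!r}")


def _canonical_location(text: str) -> str:
    token = str(text).strip().lower()
    for loc in LOCATIONS[:3]:
        if token == loc.lower():
            return loc
    return "other"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionTable:
    """A genes x samples log2 expression matrix with tumor/normal labels."""

    genes: list[str]
    samples: list[str]
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [normalize_symbol(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise FormatError(f"duplicate genes after normalization: {dupes}")
        if len(self.labels) != len(self.samples):
            raise FormatError("every sample needs a label")
        bad = sorted(set(self.labels) - {"tumor", "normal"})
        if bad:
            raise FormatError(f"labels must be 'tumor' or 'normal', got {bad}")
        counts = pd.Series(self.labels).value_counts()
        for grp in ("tumor", "normal"):
            if counts.get(grp, 0) < 2:
                raise FormatError(f"need >=2 '{grp}' samples, got {counts.get(grp, 0)}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )

    def group_values(self, label: str) -> np.ndarray:
        mask = np.array([lab == label for lab in self.labels])
        return self.values[:, mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class MarkerRecord:
    """One candidate marker: fluid presence flags plus DE statistics."""

    gene: str
    name: str = ""
    location: str = "other"
    family: str = ""
    in_urine: bool = False
    in_blood: bool = False
    fold_change: float = 1.0
    p_value: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        object.__setattr__(self, "location", _canonical_location(self.location))
        if not self.fold_change > 0:
            raise FormatError(f"{self.gene}: fold_change must be positive, got {self.fold_change}")
        if not 0 < self.p_value <= 1:
            raise FormatError(f"{self.gene}: p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True, order=True)
class EdgeRecord:
    """Undirected typed interaction, endpoints stored in canonical order."""

    a: str
    b: str
    kind: str

    def __post_init__(self) -> None:
        a, b = normalize_symbol(self.a), normalize_symbol(self.b)
        if a == b:
            raise FormatError(f"self-loop on {a}")
        if self.kind not in EDGE_KINDS:
            raise FormatError(f"unknown edge kind {self.kind!r}; allowed: {', '.join(EDGE_KINDS)}")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class AnnotationRecord:
    """gene -> ontology term assignment."""

    gene: str
    term: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        term = str(self.term).strip()
        if not term:
            raise FormatError(f"{self.gene}: empty term")
        object.__setattr__(self, "term", term)


@dataclass
class GeneSet:
    name: str
    description: str = ""
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not str(self.name).strip():
            raise FormatError("gene set needs a non-empty name")
        self.members = {normalize_symbol(m) for m in self.members}
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# delimiter sniffing (comma and tab only, per config contract)


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()
    for line in head:
        if "\t" in line:
            return "\t"
        if "," in line:
            return ","
    return ","


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path: str | Path, column: str | int = 0) -> set[str]:
    """Read one symbol column from a CSV/TSV into a normalized gene set.

    ``column`` may be a header name or a 0-based index. Blank cells are
    skipped; duplicates (after case folding) collapse.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    header = 0 if isinstance(column, str) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: gene list is empty", stacklevel=2)
        return set()
    if isinstance(column, str):
        if column not in df.columns:
            raise FormatError(
                f"column {column!r} not found; available: {list(df.columns)}"
            )
        series = df[column]
    else:
        if column >= df.shape[1]:
            raise FormatError(f"column index {column} out of range; file has {df.shape[1]} columns")
        series = df.iloc[:, column]
        # drop a header-looking first cell only when it repeats nowhere: a
        # single-column file of symbols has no header by convention
    genes = {normalize_symbol(v) for v in series if str(v).strip()}
    if not genes:
        warnings.warn(f"{path}: gene list is empty", stacklevel=2)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(normalize_symbol(g) for g in genes)) + "\n")


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV expression table (header = sample ids, 2nd row = labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index[0].strip().lower() != "label":
        raise FormatError(f"{path}: second row must carry the 'label' marker in column 1")
    labels = [str(v).strip() for v in df.iloc[0]]
    body = df.iloc[1:]
    try:
        values = body.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionTable(
        genes=list(body.index),
        samples=list(df.columns),
        labels=labels,
        values=values,
    )


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(table.samples) + "\n")
        fh.write("label\t" + "\t".join(table.labels) + "\n")
        for gene, row in zip(table.genes, table.values):
            fh.write(gene + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# marker tables

_MARKER_COLUMNS = ["symbol", "name", "location", "family", "urine", "blood", "fold_change", "p_value"]


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    """Read a candidate-marker table into :class:`MarkerRecord` rows.

    Presence columns encode the detected-in-fluid flag; accepted spellings
    for "present" are ``1``, ``true``, ``yes``, ``y``, ``x`` and the bullet
    ``•``; blank, ``0``, ``false``, ``no`` mean absent.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower().replace("-", "_").replace(" ", "_") for c in df.columns]
    aliases = {"gene": "symbol", "gene_name": "name", "fold_change": "fold_change",
               "foldchange": "fold_change", "fc": "fold_change", "p": "p_value",
               "pvalue": "p_value", "p_val": "p_value"}
    df = df.rename(columns=aliases)
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    records: list[MarkerRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        d = dict(zip(df.columns, row))
        try:
            fc = float(d["fold_change"])
            p = float(d["p_value"])
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: non-numeric fold change or p-value ({exc})") from exc
        records.append(
            MarkerRecord(
                gene=d["symbol"],
                name=d["name"].strip(),
                location=d["location"],
                family=d["family"].strip(),
                in_urine=_parse_flag(d["urine"], i, "urine"),
                in_blood=_parse_flag(d["blood"], i, "blood"),
                fold_change=fc,
                p_value=p,
            )
        )
    return records


def write_marker_table(records: Sequence[MarkerRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_MARKER_COLUMNS)
        for r in records:
            writer.writerow(
                [r.gene, r.name, r.location, r.family,
                 "1" if r.in_urine else "0", "1" if r.in_blood else "0",
                 format(r.fold_change, "g"), format(r.p_value, "g")]
            )


# ---------------------------------------------------------------------------
# edge lists


def read_edges(path: str | Path) -> list[EdgeRecord]:
    """Read a typed edge list; accepts (a, b, kind) and SIF (a, kind, b)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    edges: list[EdgeRecord] = []
    seen: set[EdgeRecord] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) != 3:
            raise FormatError(f"{path} line {lineno}: expected 3 fields, got {len(parts)}")
        if parts[2] in EDGE_KINDS:
            a, b, kind = parts
        elif parts[1] in EDGE_KINDS:  # SIF order
            a, kind, b = parts
        else:
            raise FormatError(
                f"{path} line {lineno}: unknown edge kind in {parts!r}; "
                f"allowed kinds: {', '.join(EDGE_KINDS)}"
            )
        try:
            edge = EdgeRecord(a, b, kind)
        except FormatError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from exc
        if edge not in seen:
            seen.add(edge)
            edges.append(edge)
    return edges


def write_edges(edges: Iterable[EdgeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.kind}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then members, tab-separated."""
    sets: list[GeneSet] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path} line {lineno}: GMT needs >=3 tab-separated fields")
        members = [p for p in parts[2:] if p.strip()]
        if not members:
            raise FormatError(f"{path} line {lineno}: gene set {parts[0]!r} has no members")
        sets.append(GeneSet(name=parts[0], description=parts[1], members=set(members)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a two-column TSV (gene, term) annotation table."""
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path} line {lineno}: expected 2 tab-separated fields")
        records.append(AnnotationRecord(gene=parts[0], term=parts[1]))
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.gene, r.term)):
            fh.write(f"{r.gene}\t{r.term}\n")
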