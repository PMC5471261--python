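"""Readers, writers and in-memory containers for expression-analysis formats.

The pipeline works on post-normalisation (RMA-style) log2 intensity matrices
and the small flat-file formats that surround them in microarray work:

* tab-separated expression matrices with a header row, or GCT 1.2;
* CLS phenotype files or two-column ``sample<TAB>group`` TSVs;
* GMT gene-set collections;
* probeset annotation tables (probeset -> gene, cross-reactivity, coding);
* NCBI Homologene flat files (homology groups across taxa).

All readers validate and raise :class:`FormatError` on malformed input rather
than silently coercing.  Gene and probeset identifiers are handled as strings
throughout; joins across species always go through gene *IDs*, never symbols.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GroupLabels",
    "ProbesetAnnotation",
    "HomologyTable",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_class_labels",
    "write_class_labels",
    "read_gmt",
    "write_gmt",
    "read_probeset_annotation",
    "write_probeset_annotation",
    "read_homologene",
    "write_homologene",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix: rows are features, columns are samples.

    Parameters
    ----------
    values:
        DataFrame of finite log2 intensities; the index holds feature ids
        (probeset ids or gene ids), the columns hold sample ids.
    level:
        ``"probeset"`` or ``"gene"`` — the granularity of the rows.
    species:
        Free-form taxon tag (e.g. ``"9606"``); carried through the pipeline.
    """

    values: pd.DataFrame
    level: str = "probeset"
    species: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("probeset", "gene"):
            raise ValueError(f"level must be 'probeset' or 'gene', got {self.level!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if arr.size and not np.all(np.isfinite(arr)):
            raise FormatError("non-finite expression values")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupLabels:
    """Sample -> phenotype-group assignment.

    ``group_order`` preserves the order in which groups were declared (the
    CLS header order, or first appearance in a TSV); differential operations
    interpret the first group as "group 1".
    """

    assignments: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        if not self.group_order:
            self.group_order = seen
        missing = [g for g in seen if g not in self.group_order]
        if missing:
            raise FormatError(f"groups present but not declared: {missing}")
        empty = [g for g in self.group_order if g not in seen]
        if empty:
            raise FormatError(f"declared groups with no samples: {empty}")

    @property
    def groups(self) -> list[str]:
        return list(self.group_order)

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def two_groups(self) -> tuple[str, str]:
        """The (group1, group2) pair, erroring unless exactly two groups exist."""
        if len(self.group_order) != 2:
            raise ValueError(
                f"differential operations need exactly two groups, got {self.group_order}"
            )
        return self.group_order[0], self.group_order[1]

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        unlabeled = [s for s in matrix.sample_ids if s not in self.assignments]
        if unlabeled:
            raise FormatError(f"unlabeled samples: {unlabeled}")


@dataclass
class ProbesetAnnotation:
    """Probeset-level annotation used by the collapse step.

    ``table`` is indexed by probeset id and has columns ``gene_id``,
    ``gene_symbol``, ``cross_reactive`` and ``coding``.  The two flags are
    three-valued: ``True``, ``False`` or ``None`` ("unknown") — criteria are
    applied only where the information was annotated.
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "gene_symbol", "cross_reactive", "coding")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"annotation missing column {col!r}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate probeset ids in annotation")
        bad = self.table["gene_id"].astype(str).str.len() == 0
        if bad.any():
            raise FormatError("annotation rows with empty gene_id")

    @property
    def probeset_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.table["gene_id"].astype(str).unique())


@dataclass
class HomologyTable:
    """Homologene-style table: rows of (group_id, taxon_id, gene_id, gene_symbol)."""

    table: pd.DataFrame

    REQUIRED = ("group_id", "taxon_id", "gene_id", "gene_symbol")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"homology table missing column {col!r}")
        key = self.table[["group_id", "taxon_id", "gene_id"]].astype(str)
        if key.duplicated().any():
            raise FormatError("duplicate (group_id, taxon_id, gene_id) rows")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon_id"].astype(str).unique())

    def n_groups(self) -> int:
        return self.table["group_id"].astype(str).nunique()


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"empty gene set {name!r}")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _as_numeric(df: pd.DataFrame, context: str) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {context}: {exc}") from exc


def read_expression(
    path: str | Path,
    format: str = "tsv",
    level: str = "probeset",
    species: str = "",
    linear: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV (header row) or GCT 1.2.

    With ``linear=True`` the values on disk are linear intensities and log2
    is applied on load; by contract the in-memory matrix is always log2.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        df = _as_numeric(df, str(path))
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version not in ("#1.2",):
                raise FormatError(f"unsupported GCT version line {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError("malformed GCT dimensions line")
            nrow, ncol = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", dtype={0: str})
        if body.shape[0] != nrow or body.shape[1] - 2 != ncol:
            raise FormatError(
                f"GCT declares {nrow}x{ncol} but file has "
                f"{body.shape[0]}x{body.shape[1] - 2}"
            )
        df = body.set_index(body.columns[0]).drop(columns=[body.columns[1]])
        df.index = df.index.astype(str)
        df = _as_numeric(df, str(path))
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if linear:
        if (df.to_numpy() <= 0).any():
            raise FormatError("non-positive intensities cannot be log2-transformed")
        df = np.log2(df)
    return ExpressionMatrix(values=df, level=level, species=species)


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = matrix.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_features}\t{matrix.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for fid, row in matrix.values.iterrows():
                fh.write(str(fid) + "\tna\t" + "\t".join(repr(v) for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# phenotype labels
# ---------------------------------------------------------------------------


def read_class_labels(
    path: str | Path,
    format: str = "tsv",
    sample_ids: Sequence[str] | None = None,
) -> GroupLabels:
    """Read group labels from a two-column TSV or a Broad CLS file.

    CLS carries no sample names, only an ordered label line, so
    ``sample_ids`` (the matrix column order) must be supplied for CLS input;
    for TSV it is ignored.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
        if df.shape[1] != 2:
            raise FormatError("label TSV must have exactly two columns (sample, group)")
        if df.isna().any().any():
            raise FormatError("label TSV contains missing fields")
        # tolerate an optional header row
        if list(df.iloc[0]) == ["sample_id", "group"]:
            df = df.iloc[1:]
        if df[0].duplicated().any():
            raise FormatError("duplicate sample ids in label TSV")
        assignments = dict(zip(df[0].astype(str), df[1].astype(str)))
        return GroupLabels(assignments=assignments)
    if format == "cls":
        lines = [ln.strip() for ln in open(path) if ln.strip()]
        if len(lines) < 3:
            raise FormatError("CLS file needs 3 lines")
        head = lines[0].split()
        if len(head) != 3:
            raise FormatError("malformed CLS header line")
        n_samples, n_groups = int(head[0]), int(head[1])
        names_line = lines[1].split()
        if names_line[0] != "#":
            raise FormatError("second CLS line must start with '#'")
        group_names = names_line[1:]
        if len(group_names) != n_groups:
            raise FormatError(
                f"CLS declares {n_groups} groups but names {len(group_names)}"
            )
        tokens = lines[2].split()
        if len(tokens) != n_samples:
            raise FormatError(
                f"CLS declares {n_samples} samples but labels {len(tokens)}"
            )
        if all(t.isdigit() for t in tokens):
            idx = [int(t) for t in tokens]
            if max(idx) >= n_groups:
                raise FormatError("CLS label index out of range")
            labels = [group_names[i] for i in idx]
        else:
            unknown = sorted(set(tokens) - set(group_names))
            if unknown:
                raise FormatError(f"CLS labels not in declared groups: {unknown}")
            labels = tokens
        if sample_ids is None:
            sample_ids = [f"sample_{i + 1}" for i in range(n_samples)]
        if len(sample_ids) != n_samples:
            raise FormatError(
                f"matrix has {len(sample_ids)} samples but CLS declares {n_samples}"
            )
        return GroupLabels(
            assignments=dict(zip([str(s) for s in sample_ids], labels)),
            group_order=group_names,
        )
    raise ValueError(f"unknown label format {format!r}")


def write_class_labels(labels: GroupLabels, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for sample, group in labels.assignments.items():
                fh.write(f"{sample}\t{group}\n")
    elif format == "cls":
        samples = list(labels.assignments)
        with open(path, "w") as fh:
            fh.write(f"{len(samples)} {len(labels.group_order)} 1\n")
            fh.write("# " + " ".join(labels.group_order) + "\n")
            fh.write(" ".join(labels.assignments[s] for s in samples) + "\n")
    else:
        raise ValueError(f"unknown label format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


# ---------------------------------------------------------------------------
# probeset annotation
# ---------------------------------------------------------------------------

_FLAG_TO_STR = {True: "true", False: "false", None: "unknown"}
_STR_TO_FLAG = {"true": True, "false": False, "unknown": None, "": None}


def read_probeset_annotation(path: str | Path) -> ProbesetAnnotation:
    """Read a probeset annotation TSV.

    Columns: ``probeset_id``, ``gene_id``, ``gene_symbol``, ``cross_reactive``,
    ``coding``.  Flag cells hold ``true``/``false``/``unknown`` (empty reads
    as unknown — absence of annotation is not evidence).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["probeset_id", "gene_id", "gene_symbol", "cross_reactive", "coding"]
    if list(df.columns) != expected:
        raise FormatError(f"annotation columns must be {expected}, got {list(df.columns)}")

    def to_flag(cell: str, col: str) -> bool | None:
        key = cell.strip().lower()
        if key not in _STR_TO_FLAG:
            raise FormatError(f"bad {col} value {cell!r} (expect true/false/unknown)")
        return _STR_TO_FLAG[key]

    table = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str).to_numpy(),
            "gene_symbol": df["gene_symbol"].astype(str).to_numpy(),
            "cross_reactive": [to_flag(c, "cross_reactive") for c in df["cross_reactive"]],
            "coding": [to_flag(c, "coding") for c in df["coding"]],
        },
        index=pd.Index(df["probeset_id"].astype(str), name="probeset_id"),
    )
    return ProbesetAnnotation(table=table)


def write_probeset_annotation(annotation: ProbesetAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probeset_id\tgene_id\tgene_symbol\tcross_reactive\tcoding\n")
        for pid, row in annotation.table.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(pid),
                        str(row["gene_id"]),
                        str(row["gene_symbol"]),
                        _FLAG_TO_STR[row["cross_reactive"]],
                        _FLAG_TO_STR[row["coding"]],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Homologene
# ---------------------------------------------------------------------------


def read_homologene(path: str | Path) -> HomologyTable:
    """Read an NCBI Homologene flat file (no header).

    The release-68 layout has six tab-separated columns — homology group id,
    taxon id, gene id, gene symbol, protein gi, protein accession; the last
    two are ignored.  A four-column variant (the first four) is accepted.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 6):
                raise FormatError(
                    f"homologene line {lineno}: expected 4 or 6 columns, got {len(fields)}"
                )
            group_id, taxon_id, gene_id, symbol = fields[:4]
            if not group_id.strip() or not taxon_id.strip() or not gene_id.strip():
                raise FormatError(f"homologene line {lineno}: missing required field")
            rows.append((group_id.strip(), taxon_id.strip(), gene_id.strip(), symbol))
    table = pd.DataFrame(rows, columns=["group_id", "taxon_id", "gene_id", "gene_symbol"])
    return HomologyTable(table=table)


def write_homologene(table: HomologyTable, path: str | Path) -> None:
    """Write the real six-column Homologene layout (protein fields left empty)."""
    with open(path, "w") as fh:
        for _, row in table.table.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(row["group_id"]),
                        str(row["taxon_id"]),
                        str(row["gene_id"]),
                        str(row["gene_symbol"]),
                        "",
                        "",
                    ]
                )
                + "\n"
            )
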