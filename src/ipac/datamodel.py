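"""Shared data model and readers/writers for all external formats.

All downstream stages operate on the in-memory containers defined here
(:class:`GenomicMatrix`, :class:`GeneSetCollection`, :class:`GeneTable`);
no stage re-reads raw files.  Values are log2-scale throughout; missing
cells are carried as NaN and handled pairwise-complete downstream.
Coordinates are 1-based inclusive and chromosome labels are free text
compared verbatim.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ipac")

#: Default minimum pairwise-complete observations for correlations / fits.
DEFAULT_MIN_PAIRS = 10

#: Significant digits used when writing result tables.
FLOAT_DIGITS = 6

_META_COLS_CN = ["probe_id", "chromosome", "position"]
_META_COLS_EXPR = ["probe_id", "gene_symbol", "chromosome", "position"]


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the ``ipac`` logger hierarchy."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


class FormatError(ValueError):
    """Malformed input file (header, field counts, duplicated ids)."""


class ParseError(ValueError):
    """A cell could not be parsed; reports row and column."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic annotation of one probe.

    position is a 1-based basepair coordinate; gene_symbol is present only
    on expression probes.
    """

    probe_id: str
    chromosome: str
    position: int
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        if not self.chromosome:
            raise ValueError(f"probe {self.probe_id}: empty chromosome")


@dataclass
class GenomicMatrix:
    """Features x samples real matrix with per-feature genome coordinates.

    Carrier for raw or segmented (PCF) copy number and for expression.
    ``values`` is indexed by probe id with one column per sample;
    ``annotations`` is aligned row-for-row to ``values``.
    """

    values: pd.DataFrame          # index: probe_id, columns: samples, float
    annotations: pd.DataFrame     # index: probe_id; chromosome, position[, gene_symbol]
    kind: str = "copy_number"     # {copy_number, expression}

    def __post_init__(self) -> None:
        if self.kind not in ("copy_number", "expression"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not self.values.index.equals(self.annotations.index):
            raise ValueError("values and annotations are not aligned")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated probe id {dup!r}")
        if (self.annotations["position"] < 1).any():
            bad = self.annotations.index[self.annotations["position"] < 1][0]
            raise ValueError(f"probe {bad!r}: position must be >= 1")
        if (self.annotations["chromosome"].astype(str) == "").any():
            raise ValueError("empty chromosome label")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def check_aligned(self, other: "GenomicMatrix") -> None:
        """Matrices analyzed together must share the sample list (and order)."""
        if self.samples != other.samples:
            raise ValueError("sample lists differ between matrices")


@dataclass
class GeneSetCollection:
    """Gene sets keyed by set id; membership is a set of gene symbols.

    Membership is intersected with the analysis gene universe at use time,
    not at load time.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def name(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def add(self, set_id: str, name: str, members) -> None:
        if set_id in self.sets:
            raise FormatError(f"duplicated set id {set_id!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {set_id!r} has no members")
        self.sets[set_id] = (name, members)


@dataclass
class GeneTable:
    """Gene-level matched copy-number and expression matrices.

    One row per gene symbol; ``cn`` and ``expr`` share index (gene symbols)
    and columns (samples).  ``annotations`` has chromosome and position
    (mean of the contributing expression-probe positions, hence real-valued).
    """

    cn: pd.DataFrame
    expr: pd.DataFrame
    annotations: pd.DataFrame     # index: gene_symbol; chromosome, position

    def __post_init__(self) -> None:
        if not (self.cn.index.equals(self.expr.index)
                and self.cn.index.equals(self.annotations.index)):
            raise ValueError("gene-level tables are not aligned")
        if list(self.cn.columns) != list(self.expr.columns):
            raise ValueError("sample lists differ between cn and expr")

    @property
    def genes(self) -> list[str]:
        return list(self.cn.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cn.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, kind: str, log2_transform: bool = False,
                log2_offset: float = 1.0) -> GenomicMatrix:
    """Read a probe-level TSV matrix.

    Layout: header row with sample names after the metadata columns
    (``probe_id, chromosome, position`` for copy number, plus ``gene_symbol``
    for expression).  Values are assumed log2 already unless
    ``log2_transform`` is set, in which case log2(x + offset) is applied.
    Empty cells and ``NA`` are recorded as missing.
    """
    meta_cols = _META_COLS_EXPR if kind == "expression" else _META_COLS_CN
    try:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str,
                                                "gene_symbol": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: malformed header, missing columns {missing}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: duplicated probe id {dup!r}")

    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    values = df[sample_cols].copy()
    for col in sample_cols:
        if values[col].dtype == object:
            coerced = pd.to_numeric(values[col].replace({"NA": np.nan, "": np.nan}),
                                    errors="coerce")
            bad = coerced.isna() & values[col].notna() & ~values[col].isin(["NA", ""])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: non-numeric cell at row {row + 2}, column {col!r}: "
                    f"{values[col].iloc[row]!r}")
            values[col] = coerced
    values = values.astype(float)
    if log2_transform:
        values = np.log2(values + log2_offset)
    values.index = pd.Index(df["probe_id"], name="probe_id")

    ann = df[[c for c in meta_cols if c != "probe_id"]].copy()
    ann.index = values.index
    ann["position"] = ann["position"].astype(int)
    return GenomicMatrix(values=values, annotations=ann, kind=kind)


def write_matrix(gm: GenomicMatrix, path) -> None:
    """Write a GenomicMatrix as TSV (inverse of :func:`read_matrix`)."""
    meta_cols = _META_COLS_EXPR if gm.kind == "expression" else _META_COLS_CN
    out = gm.annotations.reset_index()[meta_cols[:1] + meta_cols[1:]]
    out = pd.concat([out, gm.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: set_id TAB description TAB member1 ...

    Duplicate members within a line are collapsed; a line with fewer than
    three fields is a format error reported with its line number.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has "
                                  f"{len(fields)} fields, need >= 3")
            set_id, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} empty")
            coll.add(set_id, desc, members)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    """Write a GeneSetCollection as GMT with sorted members (deterministic)."""
    with open(path, "w") as fh:
        for set_id in sorted(coll.sets):
            name, members = coll.sets[set_id]
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def write_results(records: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Write a result table as TSV with stable column order.

    Floats are formatted at 6 significant digits, NaN as literal ``NA``;
    rows are sorted by ``sort_by`` (default: all columns, left to right) so
    the same table always produces byte-identical output.
    """
    df = records.copy()
    if len(df):
        keys = sort_by if sort_by is not None else list(df.columns)
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=f"%.{FLOAT_DIGITS}g")
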