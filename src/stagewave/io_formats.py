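"""Tabular I/O for the pipeline: count matrices, BLAST tabular output, GO maps,
and the packaged worked-example tables.

All readers validate rather than coerce: malformed counts, duplicate contig
ids, or unparseable library labels raise ``ValueError`` with enough context
(row/column or line number) to locate the offending field. All writers emit a
stable column order so that write -> read -> write is byte-stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Sentinel used in the printed tables for a query without any BLAST hit.
NO_HIT_SENTINEL = "No hits found"

_LIB_LABEL = re.compile(r"^(\d+)dpp(?:[._-][A-Za-z0-9]+)?$")

_FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2_04": "table2_04.tsv",
    "table2_8": "table2_8.tsv",
    "table2_1216": "table2_1216.tsv",
}


def parse_age(label: str) -> int:
    """Return the fruit age (days post pollination) encoded in a library label.

    Labels are ``"<age>dpp"`` with an optional replicate suffix, e.g. ``"8dpp"``
    or ``"8dpp.b"``.
    """
    m = _LIB_LABEL.match(str(label))
    if m is None:
        raise ValueError(f"unparseable library label {label!r}; expected '<age>dpp'")
    return int(m.group(1))


class CountMatrix:
    """Contig x library read-count matrix, the pipeline's root object.

    Wraps a :class:`pandas.DataFrame` whose index holds contig ids (strings)
    and whose columns are library labels encoding fruit age (``"0dpp"`` ...).
    Counts must be non-negative integers; library columns must be ordered by
    non-decreasing age. Multiple libraries per age are permitted, in which
    case age-level quantities aggregate within age.
    """

    def __init__(self, counts: pd.DataFrame):
        df = counts.copy()
        df.index = df.index.astype(str)
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate contig ids: {dup}")
        ages = [parse_age(c) for c in df.columns]
        if any(b < a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"library ages not sorted ascending: {ages}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            r, c = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise ValueError(
                f"invalid count {arr[r, c]!r} at contig {df.index[r]!r}, "
                f"library {df.columns[c]!r}: counts must be non-negative integers"
            )
        self.df = df.astype(np.int64)
        self.ages = ages

    # -- basic accessors -------------------------------------------------
    @property
    def contig_ids(self) -> pd.Index:
        return self.df.index

    @property
    def libraries(self) -> list[str]:
        return list(self.df.columns)

    @property
    def depths(self) -> pd.Series:
        """Total reads per library (column sums)."""
        return self.df.sum(axis=0)

    @property
    def totals(self) -> pd.Series:
        """Total reads per contig across all libraries."""
        return self.df.sum(axis=1)

    def subset(self, contig_ids: Iterable[str]) -> "CountMatrix":
        ids = [str(i) for i in contig_ids]
        missing = [i for i in ids if i not in self.df.index]
        if missing:
            raise KeyError(f"contigs not in matrix: {missing}")
        return CountMatrix(self.df.loc[ids])

    def age_columns(self) -> dict[int, list[str]]:
        """Library labels grouped by age, in age order."""
        out: dict[int, list[str]] = {}
        for lab, age in zip(self.df.columns, self.ages):
            out.setdefault(age, []).append(lab)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.df.shape[0]} contigs x {self.df.shape[1]} libraries)"


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV count matrix (first column contig id, header = library labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "contig_id"
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path) -> None:
    df = cm.df.copy()
    df.index.name = "contig_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


@dataclass(frozen=True)
class BlastHitRecord:
    """One tabular BLAST hit (standard 12 columns plus optional extensions).

    ``subject_description`` and ``subject_taxon`` come from optional columns
    13 and 14; the taxon is required downstream for the homology-tier cascade
    on non-Arabidopsis hits.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    e_value: float
    bit_score: float
    subject_description: str | None = None
    subject_taxon: str | None = None


def read_blast_tab(path, max_evalue: float | None = None) -> list[BlastHitRecord]:
    """Parse tabular BLAST output keeping the single best hit per query.

    Best = minimum E-value; ties broken by higher bit score, then
    lexicographically smaller subject id. Records are returned in order of
    each query's first appearance. Hits with E-value above ``max_evalue``
    (when given) are dropped before best-hit selection.
    """
    best: dict[str, BlastHitRecord] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                pident = float(fields[2])
                bits = float(fields[11])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {err}") from None
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value {evalue}")
            if max_evalue is not None and evalue > max_evalue:
                continue
            rec = BlastHitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=pident,
                e_value=evalue,
                bit_score=bits,
                subject_description=fields[12] if len(fields) > 12 and fields[12] else None,
                subject_taxon=fields[13] if len(fields) > 13 and fields[13] else None,
            )
            prev = best.get(rec.query_id)
            if prev is None:
                best[rec.query_id] = rec
                order.append(rec.query_id)
            elif (rec.e_value, -rec.bit_score, rec.subject_id) < (
                prev.e_value,
                -prev.bit_score,
                prev.subject_id,
            ):
                best[rec.query_id] = rec
    return [best[q] for q in order]


def best_hits_by_query(hits: Iterable[BlastHitRecord]) -> dict[str, BlastHitRecord]:
    """Index best-hit-per-query records by query id."""
    out = {}
    for h in hits:
        if h.query_id in out:
            raise ValueError(f"multiple records for query {h.query_id!r}; expected best-hit lists")
        out[h.query_id] = h
    return out


def read_go_map(path) -> dict[str, set[str]]:
    """Read a two-column gene_id -> GO-category TSV into a multimap."""
    go: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (gene_id, category)")
            go.setdefault(fields[0], set()).add(fields[1])
    return go


def write_go_map(go_map: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for cat in sorted(go_map[gene]):
                fh.write(f"{gene}\t{cat}\n")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load a packaged worked-example table.

    ``table1`` holds the 19 highly expressed cucurbit-only contigs;
    ``table2_04`` / ``table2_8`` / ``table2_1216`` hold the 21/27/21 contigs
    very highly expressed (>0.1% of the transcript pool) in exactly one age
    group. Empty cells are empty strings; E-values of rows without a hit are
    NaN. The ``secondary_description`` column carries the tables' italic
    non-Arabidopsis annotations.
    """
    try:
        fname = _FIXTURE_FILES[table_id]
    except KeyError:
        raise KeyError(
            f"unknown table_id {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}"
        ) from None
    path = resources.files("stagewave.data").joinpath(fname)
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in ("reads", "length_bp", "total_reads", "group_reads"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    df["e_value"] = pd.to_numeric(df["e_value"].replace("", np.nan))
    df["contig_id"] = df["contig_id"].astype(str)
    return df
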