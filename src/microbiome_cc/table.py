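"""Composition tables with greengenes-style lineage strings.

The central object is :class:`TaxonTable`, a samples x taxa matrix of counts
or relative abundances together with a taxonomic lineage per taxon.  Tables
are read and written in the classic OTU-table TSV dialect (taxa as rows,
first header field ``#OTU ID``, last column ``taxonomy``) and can be
collapsed to any rank from phylum down to species by summing taxa that share
the truncated lineage prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lineage",
    "TaxonTable",
    "TableFormatError",
    "LEVELS",
    "read_taxon_table",
    "write_taxon_table",
    "to_relative",
    "collapse_to_level",
    "pool_levels",
]

# canonical rank order; kingdom is optional in input lineages
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")

#: taxonomic level name -> rank prefix
LEVELS = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}

#: the levels the analysis iterates over, coarse to fine
ANALYSIS_LEVELS = ("phylum", "class", "order", "family", "genus", "species")


class TableFormatError(ValueError):
    """Raised for malformed OTU tables (ragged rows, negatives, duplicates)."""


@dataclass(frozen=True)
class Lineage:
    """An ordered greengenes-style taxonomy path.

    ``ranks`` is a tuple of ``(prefix, name)`` pairs in canonical order, e.g.
    ``(("p", "Firmicutes"), ("c", "Clostridia"), ...)``.  Empty names (as in
    ``g__;s__``) are legal and meaningful: they denote an unnamed group that
    is kept distinct from its parent.
    """

    ranks: tuple[tuple[str, str], ...]

    @classmethod
    def parse(cls, s: str) -> "Lineage":
        """Parse ``k__Bacteria; p__Firmicutes; ...`` (separator ';' or '; ')."""
        ranks = []
        for token in s.split(";"):
            token = token.strip()
            if not token:
                continue
            if "__" not in token:
                raise TableFormatError(f"malformed lineage token {token!r} in {s!r}")
            prefix, name = token.split("__", 1)
            if prefix not in RANK_PREFIXES:
                raise TableFormatError(f"unknown rank prefix {prefix!r} in {s!r}")
            ranks.append((prefix, name))
        order = [RANK_PREFIXES.index(p) for p, _ in ranks]
        if order != sorted(order) or len(set(order)) != len(order):
            raise TableFormatError(f"ranks out of canonical order in {s!r}")
        return cls(tuple(ranks))

    def truncate(self, level: str) -> "Lineage":
        """Truncate to ``level``, padding intermediate missing ranks with ''.

        The truncated lineage always ends at the requested rank so that e.g.
        a genus-level cut of ``p__X`` is ``p__X;c__;o__;f__;g__``.
        """
        if level not in LEVELS:
            raise ValueError(f"unknown taxonomic level {level!r}; expected one of {sorted(LEVELS)}")
        cut = RANK_PREFIXES.index(LEVELS[level])
        have = dict(self.ranks)
        start = 0 if ("k" in have) else 1
        ranks = tuple((p, have.get(p, "")) for p in RANK_PREFIXES[start : cut + 1])
        return Lineage(ranks)

    def name_at(self, level: str) -> str:
        return dict(self.ranks).get(LEVELS[level], "")

    def __str__(self) -> str:
        return ";".join(f"{p}__{n}" for p, n in self.ranks)


@dataclass
class TaxonTable:
    """Samples x taxa abundance matrix with per-taxon lineages.

    Parameters
    ----------
    data : DataFrame
        Rows are samples, columns are taxa; non-negative.
    lineages : dict
        Maps taxon id -> :class:`Lineage`.  May be empty if the source table
        had no taxonomy column.
    mode : {"counts", "relative"}
        Relative tables must have rows summing to 1 (tolerance 1e-9).
    """

    data: pd.DataFrame
    lineages: dict[str, Lineage] = field(default_factory=dict)
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative", "pooled"):
            raise ValueError(f"mode must be 'counts', 'relative' or 'pooled', got {self.mode!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample IDs: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate taxon IDs: {dup}")
        values = self.data.to_numpy()
        if values.size and values.min() < 0:
            bad = self.data.index[(self.data < 0).any(axis=1)].tolist()
            raise TableFormatError(f"negative abundances in samples: {bad}")
        if self.mode == "relative" and len(self.data):
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-9
            if off.any():
                bad = self.data.index[off].tolist()
                raise TableFormatError(f"relative rows not summing to 1: {bad}")

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return TaxonTable(self.data.loc[list(sample_ids)].copy(), dict(self.lineages), self.mode)

    # -- transforms ----------------------------------------------------------

    def to_relative(self) -> "TaxonTable":
        return to_relative(self)

    def collapse_to_level(self, level: str) -> "TaxonTable":
        return collapse_to_level(self, level)


def to_relative(table: TaxonTable) -> TaxonTable:
    """Convert a counts table to per-sample proportions (rows sum to 1)."""
    if table.mode == "relative":
        return table
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total abundance: {zero.index.tolist()}")
    rel = table.data.div(totals, axis=0)
    return TaxonTable(rel, dict(table.lineages), mode="relative")


def collapse_to_level(table: TaxonTable, level: str) -> TaxonTable:
    """Sum taxa sharing the lineage prefix truncated at ``level``.

    Output taxon ids are the truncated lineage strings; per-sample totals are
    conserved.  Taxa with empty names at the target rank stay distinct groups
    keyed by their full truncated prefix (``...;g__;s__`` style labels).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown taxonomic level {level!r}; expected one of {sorted(LEVELS)}")
    if not table.lineages:
        raise ValueError("table has no lineages; cannot collapse")
    missing = [t for t in table.taxon_ids if t not in table.lineages]
    if missing:
        raise ValueError(f"taxa without lineage: {missing[:5]}")
    keys = [str(table.lineages[t].truncate(level)) for t in table.taxon_ids]
    grouped = table.data.T.groupby(pd.Index(keys, name="lineage"), sort=True).sum().T
    lineages = {k: Lineage.parse(k) for k in grouped.columns}
    return TaxonTable(grouped, lineages, table.mode)


def pool_levels(table: TaxonTable, levels: Iterable[str] = ANALYSIS_LEVELS) -> TaxonTable:
    """Concatenate the collapses of ``table`` at each level into one table.

    Each collapsed level contributes its taxa once, keyed by the truncated
    lineage string, so a family and its genera coexist as separate columns.
    This is the pooled multi-rank testing set used for taxon-wise screens;
    its mode is ``pooled`` (rows sum to one *per level*, not overall).
    """
    parts = [collapse_to_level(table, lvl) for lvl in levels]
    data = pd.concat([p.data for p in parts], axis=1)
    if data.columns.has_duplicates:
        raise ValueError("duplicate lineage keys across levels; levels must be distinct")
    lineages: dict[str, Lineage] = {}
    for p in parts:
        lineages.update(p.lineages)
    mode = "pooled" if table.mode == "relative" else table.mode
    return TaxonTable(data, lineages, mode)


# -- classic OTU-table TSV io ------------------------------------------------


def read_taxon_table(path: str | Path, mode: str = "infer") -> TaxonTable:
    """Read a classic OTU-table TSV (taxa as rows, samples as columns).

    Leading ``#`` comment lines are allowed; the header line starts with
    ``#OTU ID``.  A trailing ``taxonomy`` column, when present, is parsed
    into lineages.  ``mode`` may be ``counts``, ``relative`` or ``infer``
    (relative iff every sample column sums to 1 within 1e-6).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header_idx = i
            break
        if not line.startswith("#"):
            raise TableFormatError(f"{path}: line {i + 1}: expected '#OTU ID' header before data")
    if header_idx is None:
        raise TableFormatError(f"{path}: no '#OTU ID' header line found")
    header = lines[header_idx].split("\t")
    has_taxonomy = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_taxonomy else None]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise TableFormatError(f"{path}: duplicate sample IDs in header: {dup}")

    taxon_ids: list[str] = []
    rows: list[list[float]] = []
    lineages: dict[str, Lineage] = {}
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TableFormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        taxon = fields[0]
        values_str = fields[1 : -1 if has_taxonomy else None]
        try:
            values = [float(v) for v in values_str]
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {lineno}: non-numeric abundance: {exc}") from None
        if min(values, default=0.0) < 0:
            raise TableFormatError(f"{path}: line {lineno}: negative abundance for taxon {taxon!r}")
        taxon_ids.append(taxon)
        rows.append(values)
        if has_taxonomy:
            lineages[taxon] = Lineage.parse(fields[-1])
    if len(set(taxon_ids)) != len(taxon_ids):
        dup = sorted({t for t in taxon_ids if taxon_ids.count(t) > 1})
        raise TableFormatError(f"{path}: duplicate taxon IDs: {dup}")

    data = pd.DataFrame(rows, index=taxon_ids, columns=sample_ids).T
    if mode == "infer":
        sums = data.sum(axis=1).to_numpy()
        mode = "relative" if len(data) and np.allclose(sums, 1.0, atol=1e-6) else "counts"
    return TaxonTable(data, lineages, mode)


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    """Write ``table`` in the classic OTU-table TSV dialect."""
    path = Path(path)
    with_tax = bool(table.lineages)
    with path.open("w") as fh:
        cols = ["#OTU ID"] + table.sample_ids + (["taxonomy"] if with_tax else [])
        fh.write("\t".join(cols) + "\n")
        for taxon in table.taxon_ids:
            vals = [repr(float(v)) for v in table.data[taxon]]
            row = [taxon] + vals
            if with_tax:
                row.append(str(table.lineages[taxon]))
            fh.write("\t".join(row) + "\n")
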