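"""Readers and writers for count tables, designs and GMT gene-set files.

All formats are tab-separated UTF-8 text. Count tables follow the shape of
protein-level spectral-count exports (one row per protein with accession /
gene / description / length metadata, one integer column per LC-MS/MS run);
the column layout is configurable through :class:`CountTableDialect` because
upstream tools disagree on header names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import GroupDesign, SpectralCountTable, ValidationError

__all__ = [
    "CountTableDialect",
    "ParseError",
    "GeneSet",
    "GeneSetCollection",
    "read_count_table",
    "write_count_table",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending location."""


@dataclass(frozen=True)
class CountTableDialect:
    """Column layout of a count table.

    ``accession`` names the protein-identifier column; ``meta_columns`` maps
    canonical metadata names (gene, description, length_aa) to header names in
    the file; every remaining column is treated as a run unless
    ``run_columns`` lists them explicitly.
    """

    accession: str = "accession"
    gene: str | None = "gene"
    description: str | None = "description"
    length: str | None = "length_aa"
    run_columns: tuple[str, ...] | None = None

    def meta_columns(self) -> dict[str, str]:
        out = {}
        if self.gene:
            out["gene"] = self.gene
        if self.description:
            out["description"] = self.description
        if self.length:
            out["length_aa"] = self.length
        return out


DEFAULT_DIALECT = CountTableDialect()


def read_count_table(path: str | Path, dialect: CountTableDialect = DEFAULT_DIALECT) -> SpectralCountTable:
    """Read a tab-separated protein x run spectral-count table.

    Rows and run columns are preserved in input order. Malformed count cells
    raise :class:`ParseError` naming the protein row and run column; duplicate
    accessions raise :class:`~spcquant.model.ValidationError`.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect.accession not in raw.columns:
        raise ParseError(f"{path}: missing accession column {dialect.accession!r}")
    meta_map = {k: v for k, v in dialect.meta_columns().items() if v in raw.columns}
    non_run = {dialect.accession, *meta_map.values()}
    if dialect.run_columns is not None:
        runs = list(dialect.run_columns)
        missing = [r for r in runs if r not in raw.columns]
        if missing:
            raise ParseError(f"{path}: missing run columns {missing}")
    else:
        runs = [c for c in raw.columns if c not in non_run]
    if not runs:
        raise ParseError(f"{path}: no run columns found")

    accessions = raw[dialect.accession]
    counts = {}
    for run in runs:
        parsed = pd.to_numeric(raw[run], errors="coerce")
        for i in raw.index[parsed.isna()]:
            raise ParseError(
                f"{path}: count cell for protein {accessions[i]!r}, run {run!r} "
                f"is not an integer: {raw.at[i, run]!r}"
            )
        nonint = parsed[parsed % 1 != 0]
        if len(nonint):
            i = nonint.index[0]
            raise ParseError(
                f"{path}: count cell for protein {accessions[i]!r}, run {run!r} "
                f"is not an integer: {raw.at[i, run]!r}"
            )
        neg = parsed[parsed < 0]
        if len(neg):
            i = neg.index[0]
            raise ParseError(
                f"{path}: count cell for protein {accessions[i]!r}, run {run!r} "
                f"is negative: {raw.at[i, run]!r}"
            )
        counts[run] = parsed.astype("int64")

    counts_df = pd.DataFrame(counts, columns=runs)
    counts_df.index = pd.Index(accessions, name="accession")
    meta = pd.DataFrame(index=counts_df.index)
    for canonical, source in meta_map.items():
        meta[canonical] = raw[source].to_numpy()
    if "length_aa" in meta.columns:
        meta["length_aa"] = pd.to_numeric(meta["length_aa"], errors="coerce").fillna(1).astype(int)
    return SpectralCountTable(counts=counts_df, meta=meta)


def write_count_table(table: SpectralCountTable, path: str | Path,
                      dialect: CountTableDialect = DEFAULT_DIALECT) -> None:
    """Write a count table in the canonical layout (round-trips bit-exactly)."""
    out = pd.DataFrame({dialect.accession: table.counts.index})
    for canonical, source in dialect.meta_columns().items():
        if canonical in table.meta.columns:
            out[source] = table.meta[canonical].to_numpy()
    for run in table.runs:
        out[run] = table.counts[run].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, groups: Iterable[str] | None = None) -> GroupDesign:
    """Read a run/patient/group design table (tab-separated, header row)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("run", "patient", "group"):
        if col not in raw.columns:
            raise ParseError(f"{path}: design requires a {col!r} column")
    frame = raw.set_index("run")[["patient", "group"]]
    return GroupDesign(assignments=frame, groups=tuple(groups) if groups else ())


def write_design(design: GroupDesign, path: str | Path) -> None:
    design.assignments.rename_axis("run").reset_index().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents). Set names are unique; members deduplicated."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>member...``.

    Duplicate members within a set are dropped (first occurrence kept);
    duplicate set names raise :class:`~spcquant.model.ValidationError`;
    a line with fewer than three fields raises :class:`ParseError` with its
    line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and >=1 member, "
                    f"got {len(fields)} field(s)"
                )
            name, description, *members = fields
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            deduped = tuple(dict.fromkeys(m for m in members if m))
            sets[name] = GeneSet(name=name, description=description, members=deduped)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
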