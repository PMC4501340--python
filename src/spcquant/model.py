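"""Core domain types for spectral-count group comparisons.

The containers wrap :class:`pandas.DataFrame` objects and enforce the
invariants a spectral-counting analysis relies on: counts are non-negative
integers, run identifiers and protein accessions are unique, and every run
belongs to exactly one (patient, group) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinMeta",
    "SpectralCountTable",
    "GroupDesign",
    "PooledGroupCounts",
    "RscConfig",
    "SelectionCriteria",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass(frozen=True)
class ProteinMeta:
    """Identity of one protein row: accession, gene symbol, description, length.

    ``length_aa`` is the protein length in amino acids as reported by the
    upstream identification pipeline; it is carried through to reports but
    plays no role in the spectral-count statistics.
    """

    accession: str
    gene: str = ""
    description: str = ""
    length_aa: int = 1

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if self.length_aa < 1:
            raise ValidationError(
                f"{self.accession}: length_aa must be >= 1, got {self.length_aa}"
            )


@dataclass
class SpectralCountTable:
    """Proteins x runs matrix of raw spectral counts (PSMs per protein per run).

    Parameters
    ----------
    counts
        Integer DataFrame indexed by protein accession with one column per
        LC-MS/MS run. Entries are raw spectral counts (>= 0).
    meta
        Per-protein metadata indexed by accession with columns
        ``gene``, ``description`` and ``length_aa``. Optional columns are
        filled with defaults when absent.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein accessions: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate run identifiers: {dupes}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("spectral counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            raise ValidationError("spectral counts must be >= 0")
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.counts.index)
        self.meta = self.meta.reindex(self.counts.index)
        for col, default in (("gene", ""), ("description", ""), ("length_aa", 1)):
            if col not in self.meta.columns:
                self.meta[col] = default
        self.meta["gene"] = self.meta["gene"].fillna("")
        self.meta["description"] = self.meta["description"].fillna("")
        self.meta["length_aa"] = self.meta["length_aa"].fillna(1).astype(int)

    @property
    def accessions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def runs(self) -> list[str]:
        return list(self.counts.columns)

    def protein_meta(self, accession: str) -> ProteinMeta:
        row = self.meta.loc[accession]
        return ProteinMeta(
            accession=accession,
            gene=str(row["gene"]),
            description=str(row["description"]),
            length_aa=int(row["length_aa"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.meta.equals(other.meta)


@dataclass
class GroupDesign:
    """Run -> (patient, group) assignment with an ordered set of group labels."""

    assignments: pd.DataFrame
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"patient", "group"}
        missing = required - set(self.assignments.columns)
        if missing:
            raise ValidationError(f"design is missing columns: {sorted(missing)}")
        if self.assignments.index.has_duplicates:
            raise ValidationError("duplicate run identifiers in design")
        observed = list(dict.fromkeys(self.assignments["group"]))
        if not self.groups:
            self.groups = tuple(observed)
        else:
            unknown = set(observed) - set(self.groups)
            if unknown:
                raise ValidationError(f"design uses undeclared groups: {sorted(unknown)}")
        for g in self.groups:
            if (self.assignments["group"] == g).sum() < 1:
                raise ValidationError(f"group {g!r} has no runs")

    @property
    def runs(self) -> list[str]:
        return list(self.assignments.index)

    def runs_for(self, group: str) -> list[str]:
        if group not in self.groups:
            raise ValidationError(f"unknown group {group!r}")
        mask = self.assignments["group"] == group
        return list(self.assignments.index[mask])


@dataclass
class PooledGroupCounts:
    """Pooled counts n[i, g] over all runs of each group, plus group totals t[g].

    Pooling sums the raw spectral counts of every run of every patient in a
    group, the aggregation applied before fold changes and G-tests are
    computed. ``totals[g]`` is the column sum of ``counts`` over all proteins.
    """

    counts: pd.DataFrame
    totals: pd.Series = None  # type: ignore[assignment]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("pooled counts must be >= 0")
        sums = self.counts.sum(axis=0)
        if self.totals is None:
            self.totals = sums.astype(np.int64)
        else:
            if not np.allclose(self.totals.reindex(sums.index), sums):
                raise ValidationError("group totals must equal column sums of pooled counts")

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class RscConfig:
    """Parameters of the Rsc log2 fold change.

    ``pseudocount`` is the stabiliser f added to counts and to the remaining
    totals so zero-count proteins give finite fold changes (default 1.25,
    the value conventional in spectral-counting comparisons).
    ``focal_negative`` keeps the reporting convention in which enrichment in
    the focal group appears as a negative Rsc; set False to flip the sign.
    """

    pseudocount: float = 1.25
    focal_negative: bool = True

    def __post_init__(self) -> None:
        if not self.pseudocount > 0:
            raise ValidationError(f"pseudocount must be > 0, got {self.pseudocount}")


@dataclass(frozen=True)
class SelectionCriteria:
    """Marker-candidate thresholds.

    A protein is retained when, against *every* reference group, its G-test
    p-value is below ``p_max`` and its Rsc is below ``rsc_max`` (focal
    enrichment negative); additionally its relative abundance must be
    strictly highest in the focal group (if ``require_focal_percent_highest``)
    and its total spectral count over the compared disease groups must be
    strictly greater than ``min_total_spc``.
    """

    p_max: float = 0.05
    rsc_max: float = -1.0
    min_total_spc: int = 5
    require_focal_percent_highest: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max < 1.0):
            raise ValidationError(f"p_max must be in (0, 1), got {self.p_max}")
        if self.min_total_spc < 0:
            raise ValidationError("min_total_spc must be >= 0")
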