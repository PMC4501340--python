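"""Pairwise group comparisons and marker-candidate selection.

A marker candidate for the focal group must, against *every* reference
group, show a Yates-corrected G-test p-value below 0.05 and an Rsc below -1
(i.e. a fold change above 2 in the focal group), have its relative
abundance strictly highest in the focal group, and carry more than 5
spectral counts in total across the compared disease groups. Candidates are
reported in increasing order of Rsc against the first reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    GroupDesign,
    PooledGroupCounts,
    RscConfig,
    SelectionCriteria,
    SpectralCountTable,
    ValidationError,
)
from .semiquant import pool_counts, relative_percent, rsc
from .stats import g_test_yates

__all__ = [
    "compare_groups",
    "build_comparison_frame",
    "MarkerTable",
    "select_markers",
    "render_marker_report",
    "find_markers",
]


def compare_groups(
    pooled: PooledGroupCounts,
    focal: str,
    reference: str,
    config: RscConfig = RscConfig(),
    totals: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-protein Rsc and Yates G-test of the focal group against a reference.

    ``totals`` overrides the group totals (e.g. with calibrated effective
    totals); by default the observed pooled totals are used. Returns a frame
    indexed by accession with columns n_focal, n_reference, rsc, g_stat,
    p_value and degenerate.
    """
    for g in (focal, reference):
        if g not in pooled.groups:
            raise ValidationError(f"unknown group {g!r}")
    t = dict(pooled.totals)
    if totals is not None:
        t.update(totals)
    n_a = pooled.counts[focal].to_numpy(dtype=float)
    n_b = pooled.counts[reference].to_numpy(dtype=float)
    t_a, t_b = float(t[focal]), float(t[reference])
    values = rsc(
        n_a, n_b, t_a, t_b,
        f=config.pseudocount, focal_negative=config.focal_negative,
    )
    g_stat = np.empty(len(n_a))
    p_value = np.empty(len(n_a))
    degenerate = np.zeros(len(n_a), dtype=bool)
    for i, (a, b) in enumerate(zip(n_a, n_b)):
        res = g_test_yates([[a, b], [t_a - a, t_b - b]])
        g_stat[i], p_value[i], degenerate[i] = res
    return pd.DataFrame(
        {
            "n_focal": pooled.counts[focal].to_numpy(),
            "n_reference": pooled.counts[reference].to_numpy(),
            "rsc": values,
            "g_stat": g_stat,
            "p_value": p_value,
            "degenerate": degenerate,
        },
        index=pooled.counts.index,
    )


def build_comparison_frame(
    pooled: PooledGroupCounts,
    focal: str,
    references: Sequence[str],
    config: RscConfig = RscConfig(),
    totals: Mapping[str, float] | None = None,
    percent_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-protein frame the selection predicate consumes.

    Percentages are computed over ``percent_groups`` (default: focal plus
    references, the compared disease groups), totals over the same groups.
    """
    references = list(references)
    if not references:
        raise ValidationError("at least one reference group is required")
    groups = list(percent_groups) if percent_groups is not None else [focal, *references]
    pct = relative_percent(pooled, groups)
    frame = pd.DataFrame(index=pooled.counts.index)
    if pooled.meta is not None:
        for col in ("gene", "description", "length_aa"):
            if col in pooled.meta.columns:
                frame[col] = pooled.meta[col]
    for g in groups:
        frame[f"n_{g}"] = pooled.counts[g]
    frame["total_spc"] = pooled.counts[groups].sum(axis=1)
    for g in groups:
        frame[f"pct_{g}"] = pct[g]
    for ref in references:
        comp = compare_groups(pooled, focal, ref, config=config, totals=totals)
        frame[f"rsc_vs_{ref}"] = comp["rsc"]
        frame[f"g_vs_{ref}"] = comp["g_stat"]
        frame[f"p_vs_{ref}"] = comp["p_value"]
    frame.attrs["focal"] = focal
    frame.attrs["references"] = tuple(references)
    return frame


@dataclass
class MarkerTable:
    """Selected marker candidates plus per-protein criteria provenance.

    ``selected`` holds the retained rows sorted by increasing Rsc against
    the first reference group (ties: smaller total first, then reverse
    accession order, matching published marker-table convention).
    ``rejected`` carries a ``failed_criteria`` column naming every criterion
    each excluded protein failed.
    """

    selected: pd.DataFrame
    rejected: pd.DataFrame
    focal: str
    references: tuple[str, ...]
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)

    def __len__(self) -> int:
        return len(self.selected)

    @property
    def accessions(self) -> list[str]:
        return list(self.selected.index)


def select_markers(
    frame: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
    focal: str | None = None,
    references: Sequence[str] | None = None,
) -> MarkerTable:
    """Apply the marker-candidate criteria to a comparison frame.

    The frame must carry ``rsc_vs_<ref>`` and ``p_vs_<ref>`` for every
    reference, ``pct_<g>`` for the focal and reference groups, and
    ``total_spc`` (see :func:`build_comparison_frame`; the packaged panel's
    printed columns via :func:`spcquant.panel.panel_comparison_frame` work
    as well).
    """
    focal = focal if focal is not None else frame.attrs.get("focal")
    references = (
        tuple(references)
        if references is not None
        else tuple(frame.attrs.get("references", ()))
    )
    if focal is None or not references:
        raise ValidationError("focal group and reference groups must be specified")
    for ref in references:
        for col in (f"rsc_vs_{ref}", f"p_vs_{ref}"):
            if col not in frame.columns:
                raise ValidationError(f"missing comparison column {col!r}")

    failures = pd.Series([[] for _ in range(len(frame))], index=frame.index, dtype=object)
    failures = failures.apply(list)
    for ref in references:
        p = frame[f"p_vs_{ref}"]
        r = frame[f"rsc_vs_{ref}"]
        for acc in frame.index[~(p < criteria.p_max)]:
            failures[acc].append(f"p_vs_{ref}>={criteria.p_max}")
        for acc in frame.index[~(r < criteria.rsc_max)]:
            failures[acc].append(f"rsc_vs_{ref}>={criteria.rsc_max}")
    if criteria.require_focal_percent_highest:
        focal_pct = frame[f"pct_{focal}"]
        highest = pd.Series(True, index=frame.index)
        for ref in references:
            highest &= focal_pct > frame[f"pct_{ref}"]
        for acc in frame.index[~highest]:
            failures[acc].append(f"pct_{focal}_not_highest")
    low_total = ~(frame["total_spc"] > criteria.min_total_spc)
    for acc in frame.index[low_total]:
        failures[acc].append(f"total_spc<={criteria.min_total_spc}")

    n_failed = failures.apply(len)
    keep = n_failed == 0
    first_ref = references[0]
    selected = frame[keep].copy()
    # Published ordering: increasing Rsc vs the first reference; within ties,
    # smaller total first, then reverse-lexicographic accession.
    order = selected.assign(_acc=selected.index).sort_values(
        by=[f"rsc_vs_{first_ref}", "total_spc", "_acc"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    selected = order.drop(columns="_acc")
    rejected = frame[~keep].copy()
    rejected["failed_criteria"] = failures[~keep].apply(";".join)
    return MarkerTable(
        selected=selected,
        rejected=rejected,
        focal=focal,
        references=references,
        criteria=criteria,
    )


_REPORT_META = ("gene", "description", "length_aa")


def render_marker_report(table: MarkerTable, path: str | Path) -> pd.DataFrame:
    """Write the marker table as a tab-separated report in published layout.

    Columns: No, accession, metadata, per-group SpC, total, percentages,
    then Rsc (3 decimals) and p (scientific, 2 decimals) per comparison.
    Returns the formatted frame that was written.
    """
    focal = table.focal
    groups = [focal, *table.references]
    out = pd.DataFrame(index=table.selected.index)
    out["no"] = np.arange(1, len(table.selected) + 1)
    for col in _REPORT_META:
        if col in table.selected.columns:
            out[col] = table.selected[col]
    for g in groups:
        col = f"n_{g}"
        if col in table.selected.columns:
            out[f"spc_{g.lower()}"] = table.selected[col]
    out["total"] = table.selected["total_spc"]
    for g in groups:
        col = f"pct_{g}"
        if col in table.selected.columns:
            out[f"pct_{g.lower()}"] = table.selected[col].map(lambda v: f"{v:.1f}")
    for ref in table.references:
        out[f"rsc_vs_{ref.lower()}"] = table.selected[f"rsc_vs_{ref}"].map(
            lambda v: f"{v:.3f}"
        )
    for ref in table.references:
        out[f"p_vs_{ref.lower()}"] = table.selected[f"p_vs_{ref}"].map(
            lambda v: f"{v:.2E}"
        )
    out.rename_axis("accession").reset_index().set_index("no").reset_index().to_csv(
        path, sep="\t", index=False
    )
    return out


def find_markers(
    table: SpectralCountTable,
    design: GroupDesign,
    focal: str,
    references: Sequence[str] | None = None,
    criteria: SelectionCriteria = SelectionCriteria(),
    config: RscConfig = RscConfig(),
    totals: Mapping[str, float] | None = None,
    percent_groups: Sequence[str] | None = None,
) -> MarkerTable:
    """End-to-end pipeline: pool runs, compare the focal group against every
    reference, and apply the marker criteria.

    ``references`` defaults to every other disease group in the design
    except a pseudo-normal group labelled ``pN`` (computed comparisons
    against pN can be requested explicitly but are not part of the
    selection predicate).
    """
    pooled = pool_counts(table, design)
    if references is None:
        references = [g for g in design.groups if g not in (focal, "pN")]
    frame = build_comparison_frame(
        pooled, focal, references, config=config, totals=totals,
        percent_groups=percent_groups,
    )
    return select_markers(frame, criteria=criteria, focal=focal, references=references)
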