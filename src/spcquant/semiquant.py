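"""Semi-quantitative spectral-count comparison: pooling, relative abundances,
Rsc log2 fold changes, and calibration of effective group totals.

The Rsc fold change between a focal group *a* and a reference group *b* is

    Rsc(a vs b) = log2((n_b + f) / (n_a + f)) + log2((t_a - n_a + f) / (t_b - n_b + f))

with pooled counts n, group total counts t and pseudocount f (default 1.25).
Under this orientation a protein enriched in the focal group has a negative
Rsc; |Rsc| > 1 corresponds to a fold change above 2 (or below 0.5).

Published marker tables typically print Rsc and p-values but not the group
totals t_g. Because only the totals *ratio* enters the formula appreciably,
the ratio can be recovered from the printed values themselves; the
``calibrate_totals`` / ``calibrate_totals_from_pvalues`` fits do exactly
that and return effective totals at a documented absolute focal scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import (
    GroupDesign,
    PooledGroupCounts,
    SpectralCountTable,
    ValidationError,
)
from .stats import g_test_yates

__all__ = [
    "pool_counts",
    "relative_percent",
    "rsc",
    "TotalsCalibration",
    "calibrate_totals",
    "calibrate_totals_from_pvalues",
    "detection_filter",
]

DEFAULT_FOCAL_TOTAL = 18_000.0
"""Documented convention for the absolute scale of effective group totals.

Only totals ratios are identifiable from printed Rsc/p values; the focal
group's absolute total is fixed at a value consistent with pooling three
patients x three runs at typical exploratory LC-MS/MS depth."""


def pool_counts(table: SpectralCountTable, design: GroupDesign) -> PooledGroupCounts:
    """Sum raw spectral counts over all runs of all patients in each group."""
    missing = [r for r in table.runs if r not in design.runs]
    if missing:
        raise ValidationError(f"runs without group assignment: {missing}")
    pooled = {}
    for group in design.groups:
        runs = [r for r in design.runs_for(group) if r in table.counts.columns]
        if not runs:
            raise ValidationError(f"group {group!r} has no runs in the count table")
        pooled[group] = table.counts[runs].sum(axis=1)
    frame = pd.DataFrame(pooled, columns=list(design.groups))
    return PooledGroupCounts(counts=frame, meta=table.meta)


def relative_percent(
    pooled: PooledGroupCounts,
    groups: Sequence[str] | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Relative abundance 100 * n[i,g] / sum_g' n[i,g'] over the given groups.

    Proteins absent from every group (row sum zero) are reported as NaN.
    ``decimals`` applies half-even rounding for report-style output.
    """
    groups = list(groups) if groups is not None else pooled.groups
    sub = pooled.counts[groups].astype(float)
    totals = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = sub.div(totals, axis=0) * 100.0
    pct[totals == 0] = np.nan
    if decimals is not None:
        pct = pct.round(decimals)
    return pct


def rsc(
    n_a,
    n_b,
    t_a,
    t_b,
    f: float = 1.25,
    focal_negative: bool = True,
):
    """Rsc log2 fold change of the focal group *a* against reference *b*.

    Vectorised over ``n_a``/``n_b``. Antisymmetric under swapping the two
    groups; strictly decreasing in ``n_a`` under the focal-negative
    convention.
    """
    if not f > 0:
        raise ValidationError(f"pseudocount must be > 0, got {f}")
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a > t_a) or np.any(n_b > t_b):
        raise ValidationError("group totals must be >= pooled counts")
    value = np.log2((n_b + f) / (n_a + f)) + np.log2((t_a - n_a + f) / (t_b - n_b + f))
    if not focal_negative:
        value = -value
    return value if value.ndim else float(value)


@dataclass(frozen=True)
class TotalsCalibration:
    """Effective group totals for an ordered pair (focal, reference).

    ``delta`` is the fitted count-independent offset
    log2((t_a - n_a + f)/(t_b - n_b + f)) of the Rsc formula; ``focal_total``
    and ``reference_total`` are effective totals consistent with it at the
    documented absolute scale. ``residuals`` are (model - observed) for the
    rows used in the fit.
    """

    pair: tuple[str, str]
    pseudocount: float
    delta: float
    focal_total: float
    reference_total: float
    residuals: np.ndarray
    source: str = "rsc"

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else 0.0

    @property
    def totals(self) -> dict[str, float]:
        return {self.pair[0]: self.focal_total, self.pair[1]: self.reference_total}


def calibrate_totals(
    n_focal,
    n_reference,
    rsc_values,
    f: float = 1.25,
    focal_total: float = DEFAULT_FOCAL_TOTAL,
    pair: tuple[str, str] = ("focal", "reference"),
) -> TotalsCalibration:
    """Recover effective group totals from printed Rsc values.

    Fits the constant offset delta by least squares over the offset model
    ``rsc = log2((n_b+f)/(n_a+f)) + delta`` and then refines an effective
    reference total (focal total fixed at the documented scale) by least
    squares over the full Rsc formula, which also captures the slight
    count-dependence of the totals term.
    """
    n_a = np.asarray(n_focal, dtype=float)
    n_b = np.asarray(n_reference, dtype=float)
    observed = np.asarray(rsc_values, dtype=float)
    if n_a.size == 0:
        raise ValidationError("cannot calibrate totals from an empty table")
    count_term = np.log2((n_b + f) / (n_a + f))
    delta = float(np.mean(observed - count_term))

    def loss(t_b: float) -> float:
        model = count_term + np.log2((focal_total - n_a + f) / (t_b - n_b + f))
        return float(np.sum((model - observed) ** 2))

    fit = minimize_scalar(
        loss, bounds=(focal_total / 8.0, focal_total * 8.0), method="bounded",
        options={"xatol": 1e-6},
    )
    t_b = float(fit.x)
    residuals = (
        count_term + np.log2((focal_total - n_a + f) / (t_b - n_b + f)) - observed
    )
    return TotalsCalibration(
        pair=pair,
        pseudocount=f,
        delta=delta,
        focal_total=focal_total,
        reference_total=t_b,
        residuals=residuals,
        source="rsc",
    )


def calibrate_totals_from_pvalues(
    n_focal,
    n_reference,
    p_values,
    focal_total: float = DEFAULT_FOCAL_TOTAL,
    pair: tuple[str, str] = ("focal", "reference"),
    f: float = 1.25,
) -> TotalsCalibration:
    """Recover effective group totals from printed G-test p-values.

    Same one-parameter fit as :func:`calibrate_totals` but matching the
    Yates-corrected G-test p-values (least squares on log p). Published
    tables can carry Rsc and p columns computed at slightly different
    totals; calibrating each column family from its own values reproduces
    both. Residuals are log(p_model) - log(p_observed).
    """
    n_a = np.asarray(n_focal, dtype=float)
    n_b = np.asarray(n_reference, dtype=float)
    observed = np.asarray(p_values, dtype=float)
    if n_a.size == 0:
        raise ValidationError("cannot calibrate totals from an empty table")

    def logp(t_b: float) -> np.ndarray:
        out = np.empty_like(n_a)
        for i, (a, b) in enumerate(zip(n_a, n_b)):
            res = g_test_yates([[a, b], [focal_total - a, t_b - b]])
            out[i] = np.log(res.p_value)
        return out

    def loss(t_b: float) -> float:
        return float(np.sum((logp(t_b) - np.log(observed)) ** 2))

    fit = minimize_scalar(
        loss, bounds=(focal_total / 8.0, focal_total * 8.0), method="bounded",
        options={"xatol": 1e-4},
    )
    t_b = float(fit.x)
    residuals = logp(t_b) - np.log(observed)
    delta = float(np.log2((focal_total + f) / (t_b + f)))
    return TotalsCalibration(
        pair=pair,
        pseudocount=f,
        delta=delta,
        focal_total=focal_total,
        reference_total=t_b,
        residuals=residuals,
        source="pvalues",
    )


def detection_filter(
    pooled: PooledGroupCounts, group: str, min_spc: int = 2
) -> list[str]:
    """Accessions whose pooled count in ``group`` exceeds ``min_spc`` (strict),
    in input order."""
    if group not in pooled.groups:
        raise ValidationError(f"unknown group {group!r}")
    mask = pooled.counts[group] > min_spc
    return list(pooled.counts.index[mask])
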