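"""Packaged reference marker panel: 70 LPIA-enriched proteins.

The panel is a published table of marker candidates for lepidic predominant
invasive adenocarcinoma (LPIA), selected against the MIA and AIS groups by
pooled spectral counting (three patients x triplicate LC-MS/MS runs per
group). Each row carries protein metadata, pooled spectral counts for
LPIA/MIA/AIS, the row total, relative percentages across the three disease
stages, and printed Rsc / G-test p-values for LPIA vs MIA, vs AIS and vs
pseudo-normal (pN).

pN pooled counts were never published; the vs-pN Rsc and p columns are
stored as reference-only values that cannot be recomputed from the panel.
The table is a regression target: percentages reproduce exactly at
1-decimal rounding, and the Rsc / p columns reproduce under effective-totals
calibration (see :mod:`spcquant.semiquant`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import PooledGroupCounts, ValidationError
from .semiquant import TotalsCalibration, calibrate_totals, calibrate_totals_from_pvalues

__all__ = [
    "DISEASE_GROUPS",
    "REFERENCE_GROUPS",
    "load_reference_panel",
    "panel_pooled_counts",
    "panel_comparison_frame",
    "calibrate_panel",
]

DISEASE_GROUPS = ("LPIA", "MIA", "AIS")
REFERENCE_GROUPS = ("MIA", "AIS")
_PANEL_RESOURCE = "lpia_reference_panel.tsv"


def load_reference_panel() -> pd.DataFrame:
    """Load the 70-row reference panel as a DataFrame in published order.

    Columns: no, accession, gene, description, length_aa, spc_lpia, spc_mia,
    spc_ais, total, pct_lpia/mia/ais, rsc_lpia_vs_{mia,ais,pn},
    p_lpia_vs_{mia,ais,pn}.
    """
    source = resources.files("spcquant.data").joinpath(_PANEL_RESOURCE)
    with resources.as_file(source) as path:
        panel = pd.read_csv(path, sep="\t")
    if len(panel) != 70:
        raise ValidationError(f"reference panel must have 70 rows, found {len(panel)}")
    totals = panel["spc_lpia"] + panel["spc_mia"] + panel["spc_ais"]
    if not (totals == panel["total"]).all():
        raise ValidationError("reference panel totals are inconsistent with counts")
    return panel


def panel_pooled_counts(panel: pd.DataFrame | None = None) -> PooledGroupCounts:
    """Panel counts as a PooledGroupCounts over the three disease groups.

    The column sums here run over the 70 panel proteins only, not over the
    full identified proteome, so they are *not* the experiment's group
    totals; use :func:`calibrate_panel` for effective totals.
    """
    panel = load_reference_panel() if panel is None else panel
    counts = pd.DataFrame(
        {
            "LPIA": panel["spc_lpia"].to_numpy(),
            "MIA": panel["spc_mia"].to_numpy(),
            "AIS": panel["spc_ais"].to_numpy(),
        },
        index=pd.Index(panel["accession"], name="accession"),
    )
    meta = pd.DataFrame(
        {
            "gene": panel["gene"].to_numpy(),
            "description": panel["description"].to_numpy(),
            "length_aa": panel["length_aa"].to_numpy(),
        },
        index=counts.index,
    )
    return PooledGroupCounts(counts=counts, meta=meta)


def calibrate_panel(
    reference: str = "MIA",
    panel: pd.DataFrame | None = None,
    f: float = 1.25,
    focal_total: float = 18_000.0,
    source: str = "rsc",
) -> TotalsCalibration:
    """Calibrate effective (LPIA, reference) totals from the panel's printed
    Rsc column (``source='rsc'``) or G-test p column (``source='pvalues'``)."""
    if reference not in REFERENCE_GROUPS:
        raise ValidationError(f"reference must be one of {REFERENCE_GROUPS}")
    panel = load_reference_panel() if panel is None else panel
    key = reference.lower()
    if source == "rsc":
        return calibrate_totals(
            panel["spc_lpia"], panel[f"spc_{key}"], panel[f"rsc_lpia_vs_{key}"],
            f=f, focal_total=focal_total, pair=("LPIA", reference),
        )
    if source == "pvalues":
        return calibrate_totals_from_pvalues(
            panel["spc_lpia"], panel[f"spc_{key}"], panel[f"p_lpia_vs_{key}"],
            focal_total=focal_total, pair=("LPIA", reference), f=f,
        )
    raise ValidationError(f"unknown calibration source {source!r}")


def panel_comparison_frame(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Selection-ready frame built from the panel's *printed* columns.

    Used to check the marker-selection predicate against the published
    table itself: percentages, totals, Rsc and p are taken verbatim rather
    than recomputed.
    """
    panel = load_reference_panel() if panel is None else panel
    frame = pd.DataFrame(
        {
            "gene": panel["gene"].to_numpy(),
            "description": panel["description"].to_numpy(),
            "length_aa": panel["length_aa"].to_numpy(),
            "n_LPIA": panel["spc_lpia"].to_numpy(),
            "n_MIA": panel["spc_mia"].to_numpy(),
            "n_AIS": panel["spc_ais"].to_numpy(),
            "total_spc": panel["total"].to_numpy(),
            "pct_LPIA": panel["pct_lpia"].to_numpy(),
            "pct_MIA": panel["pct_mia"].to_numpy(),
            "pct_AIS": panel["pct_ais"].to_numpy(),
            "rsc_vs_MIA": panel["rsc_lpia_vs_mia"].to_numpy(),
            "rsc_vs_AIS": panel["rsc_lpia_vs_ais"].to_numpy(),
            "p_vs_MIA": panel["p_lpia_vs_mia"].to_numpy(),
            "p_vs_AIS": panel["p_lpia_vs_ais"].to_numpy(),
        },
        index=pd.Index(panel["accession"], name="accession"),
    )
    return frame
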