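"""Synthetic spectral-count datasets with known ground truth.

The generator emulates the pooled-group study design: a small number of
patients per disease group, each analysed in triplicate LC-MS/MS runs. Each
run's total spectral count is Poisson-distributed around a target depth and
allocated across proteins by multinomial sampling from the group's
normalised abundance weights — the simplest generative model under which
spectral counts behave as sampled peptide-spectrum matches.

Baseline protein abundances are long-tailed (log-normal); a chosen number
of marker proteins is spiked by a known log2 fold change in one group.
Marker proteins are drawn from the upper part of the baseline abundance
distribution (above the ``marker_weight_quantile`` quantile, default the
median): published marker panels consist of proteins detectable above a
total-count filter, and spiking undetectable proteins would conflate
identification sensitivity with statistical sensitivity. Optional
per-patient log-normal abundance multipliers support robustness
experiments; they are off by default since downstream analysis pools
across patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import GroupDesign, SpectralCountTable, ValidationError
from .selection import MarkerTable

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_counts",
    "RecoveryMetrics",
    "evaluate_recovery",
]

DEFAULT_GROUPS = ("LPIA", "MIA", "AIS", "pN")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic spectral-count experiment.

    Defaults reproduce the pooled study design scale: 4 groups x 3 patients
    x 3 replicate runs at an expected per-run depth of 1,800 counts, so each
    pooled group total lands near 16,000 — the regime in which the
    effective-totals calibration of the reference panel is meaningful.
    """

    n_proteins: int = 500
    groups: tuple[str, ...] = DEFAULT_GROUPS
    patients_per_group: int = 3
    replicates_per_patient: int = 3
    depth: float = 1_800.0
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.5
    n_markers: int = 20
    marker_log2_fold: float = 2.0
    marker_group: str = "LPIA"
    marker_direction: str = "up"
    marker_weight_quantile: float = 0.5
    patient_sdlog: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or not self.groups:
            raise ValidationError("need at least one protein and one group")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.marker_log2_fold < 0:
            raise ValidationError("marker_log2_fold must be >= 0")
        if self.n_markers < 0 or self.n_markers > self.n_proteins:
            raise ValidationError("n_markers must be in [0, n_proteins]")
        if self.n_markers and self.marker_group not in self.groups:
            raise ValidationError(f"marker group {self.marker_group!r} not in groups")
        if self.marker_direction not in ("up", "down"):
            raise ValidationError("marker_direction must be 'up' or 'down'")

    @property
    def runs_per_group(self) -> int:
        return self.patients_per_group * self.replicates_per_patient


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-protein group weights and marker flags."""

    weights: pd.DataFrame          # normalised abundance per group, rows sum to 1 per column
    is_marker: pd.Series
    marker_group: str
    marker_log2_fold: float

    def true_log2_fold(self, group_a: str, group_b: str) -> pd.Series:
        """log2 of the normalised abundance ratio of group_a over group_b."""
        return np.log2(self.weights[group_a] / self.weights[group_b])

    @property
    def markers(self) -> list[str]:
        return list(self.is_marker.index[self.is_marker])


def simulate_counts(cfg: SimulationConfig) -> tuple[SpectralCountTable, GroupDesign, TruthTable]:
    """Draw a run-level spectral-count dataset with known ground truth.

    Deterministic under ``cfg.seed``: the same configuration yields
    byte-identical count matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    accessions = [f"SIM{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    genes = [f"GENE{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    index = pd.Index(accessions, name="accession")

    base = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, cfg.n_proteins)
    marker_mask = np.zeros(cfg.n_proteins, dtype=bool)
    if cfg.n_markers:
        threshold = np.quantile(base, cfg.marker_weight_quantile)
        eligible = np.flatnonzero(base >= threshold)
        chosen = rng.choice(eligible, size=cfg.n_markers, replace=False)
        marker_mask[chosen] = True

    fold = 2.0 ** cfg.marker_log2_fold
    if cfg.marker_direction == "down":
        fold = 1.0 / fold
    group_weights: dict[str, np.ndarray] = {}
    for g in cfg.groups:
        w = base.copy()
        if g == cfg.marker_group:
            w[marker_mask] *= fold
        group_weights[g] = w / w.sum()

    rows = []
    counts: dict[str, np.ndarray] = {}
    for g in cfg.groups:
        probs = group_weights[g]
        for p in range(1, cfg.patients_per_group + 1):
            patient = f"{g}_P{p}"
            if cfg.patient_sdlog > 0:
                effect = rng.lognormal(0.0, cfg.patient_sdlog, cfg.n_proteins)
                pw = probs * effect
                pw = pw / pw.sum()
            else:
                pw = probs
            for r in range(1, cfg.replicates_per_patient + 1):
                run = f"{patient}_R{r}"
                depth = rng.poisson(cfg.depth)
                counts[run] = rng.multinomial(depth, pw)
                rows.append({"run": run, "patient": patient, "group": g})

    counts_df = pd.DataFrame(counts, index=index)
    meta = pd.DataFrame(
        {
            "gene": genes,
            "description": ["simulated protein"] * cfg.n_proteins,
            "length_aa": rng.integers(80, 1200, cfg.n_proteins),
        },
        index=index,
    )
    table = SpectralCountTable(counts=counts_df, meta=meta)
    design = GroupDesign(
        assignments=pd.DataFrame(rows).set_index("run")[["patient", "group"]],
        groups=cfg.groups,
    )
    truth = TruthTable(
        weights=pd.DataFrame(group_weights, index=index),
        is_marker=pd.Series(marker_mask, index=index, name="is_marker"),
        marker_group=cfg.marker_group,
        marker_log2_fold=cfg.marker_log2_fold,
    )
    return table, design, truth


class RecoveryMetrics(NamedTuple):
    sensitivity: float
    fdp: float
    n_selected: int
    n_true: int
    labels: pd.Series  # per-protein TP/FP/FN/TN


def evaluate_recovery(markers: MarkerTable | Sequence[str], truth: TruthTable) -> RecoveryMetrics:
    """Score a selection against the simulation ground truth.

    Sensitivity is the fraction of true markers selected; FDP (false
    discovery proportion) is the fraction of selected proteins that are not
    true markers (0 when nothing is selected).
    """
    selected = list(markers.accessions) if isinstance(markers, MarkerTable) else list(markers)
    unknown = set(selected) - set(truth.is_marker.index)
    if unknown:
        raise ValidationError(
            f"selected proteins not in the simulation namespace: {sorted(unknown)}"
        )
    sel = pd.Series(False, index=truth.is_marker.index)
    sel[selected] = True
    true = truth.is_marker.astype(bool)
    labels = pd.Series("TN", index=true.index)
    labels[true & sel] = "TP"
    labels[true & ~sel] = "FN"
    labels[~true & sel] = "FP"
    n_true = int(true.sum())
    n_sel = int(sel.sum())
    tp = int((true & sel).sum())
    sensitivity = tp / n_true if n_true else 0.0
    fdp = (n_sel - tp) / n_sel if n_sel else 0.0
    return RecoveryMetrics(sensitivity, fdp, n_sel, n_true, labels)
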