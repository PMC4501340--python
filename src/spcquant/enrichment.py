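"""Gene-set over-representation analysis (ORA) on selected marker lists.

For each gene set the overlap with the selected list is scored by the
hypergeometric upper tail against a user-supplied background universe
(by default the full list of proteins identified in the experiment, which
conditions the test on detectability), with Benjamini-Hochberg FDR across
all tested sets. Gene symbols are matched case-insensitively and exactly;
no alias resolution is attempted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .io import GeneSetCollection
from .model import ValidationError
from .stats import bh_fdr, hypergeom_tail

__all__ = ["run_ora"]


def _normalise(genes: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        key = str(g).strip().upper()
        if key:
            seen.setdefault(key, None)
    return list(seen)


def run_ora(
    selected: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` genes in each set.

    Every gene set is intersected with the universe before testing; sets
    with empty post-intersection membership are dropped. Results are sorted
    by (q, p, name) and filtered at ``q < q_max`` (pass ``q_max=1`` to keep
    all tested sets). Selected genes missing from the universe raise
    :class:`~spcquant.model.ValidationError` listing the offenders.
    """
    sel = _normalise(selected)
    uni = set(_normalise(universe))
    missing = sorted(set(sel) - uni)
    if missing:
        raise ValidationError(
            f"selected genes absent from the universe: {missing}"
        )
    sel_set = set(sel)
    n, N = len(sel_set), len(uni)

    records = []
    for gs in sets:
        members = set(_normalise(gs.members)) & uni
        if not members:
            continue
        overlap = sorted(sel_set & members)
        k, K = len(overlap), len(members)
        p = hypergeom_tail(k, n, K, N)
        records.append(
            {
                "set": gs.name,
                "description": gs.description,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "genes": ";".join(overlap),
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["set", "description", "k", "n", "K", "N", "p", "q", "genes"]
        )
    result = pd.DataFrame.from_records(records)
    result["q"] = bh_fdr(result["p"])
    result = result[["set", "description", "k", "n", "K", "N", "p", "q", "genes"]]
    result = result.sort_values(["q", "p", "set"], kind="mergesort").reset_index(drop=True)
    if q_max >= 1.0:  # q_max=1 disables filtering (q is capped at 1)
        return result
    return result[result["q"] < q_max].reset_index(drop=True)
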