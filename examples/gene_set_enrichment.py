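"""Gene-set over-representation of the reference panel's marker genes.

Builds a small GMT-style collection in memory, uses the panel's 70 genes as
the selected list against a synthetic 840-gene background universe (the
selected genes plus filler symbols, mimicking an identified proteome), and
reports hypergeometric p-values with BH-FDR q-values.
"""

import spcquant as sq
from spcquant.io import GeneSet, GeneSetCollection

panel = sq.load_reference_panel()
selected = list(panel["gene"])
universe = selected + [f"BG{i:04d}" for i in range(840 - len(selected))]

sets = GeneSetCollection(sets={
    "trna_ligases": GeneSet("trna_ligases", "aminoacyl-tRNA ligases",
                            ("AARS", "NARS", "MARS", "QARS", "DARS", "BG0001", "BG0002")),
    "adhesion_invasion": GeneSet("adhesion_invasion", "junction/invasion proteins",
                                 ("CDH1", "CTNNA1", "CTTN", "EGFR", "MUC1",
                                  "BG0010", "BG0011", "BG0012")),
    "background_only": GeneSet("background_only", "unrelated set",
                               tuple(f"BG{i:04d}" for i in range(100, 130))),
})

result = sq.run_ora(selected, universe, sets, q_max=1.0)
print(result[["set", "k", "K", "p", "q", "genes"]].to_string(index=False))
print(
    "\nk of K set members overlap the 70 selected genes out of N=840; "
    "q is the BH-FDR-corrected hypergeometric tail p."
)
print("sets significant at q < 0.05:", list(result[result["q"] < 0.05]["set"]))
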