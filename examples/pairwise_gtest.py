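"""The statistical kernel on a single protein: Rsc and the Yates-corrected G-test.

A protein with 9 pooled counts in the focal group and 0 in the reference
(at group totals 18,000 vs 16,150) — the situation the continuity
correction exists for.
"""

import spcquant as sq

n_focal, n_ref = 9, 0
t_focal, t_ref = 18_000, 16_150

value = sq.rsc(n_focal, n_ref, t_focal, t_ref, f=1.25)
print(f"Rsc = {value:.3f}  (negative: enriched in the focal group; |Rsc|>1 ~ fold>2)")

g, p, degenerate = sq.g_test_yates(
    [[n_focal, n_ref], [t_focal - n_focal, t_ref - n_ref]]
)
print(f"Yates-corrected G = {g:.3f}, p = {p:.2E}")

g0, p0, _ = sq.g_test_uncorrected(
    [[n_focal, n_ref], [t_focal - n_focal, t_ref - n_ref]]
)
print(f"uncorrected      G = {g0:.3f}, p = {p0:.2E}  (correction is conservative)")
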