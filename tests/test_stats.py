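"""Statistical kernel: Yates-corrected G-test, chi-square tail, BH-FDR,
hypergeometric tail."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spcquant as sq


def g_yates_reference(o11, o12, o21, o22):
    """Independent pure-python evaluation of the capped Yates-corrected G.

    Deliberately written cell by cell (no arrays) as a brute-force oracle
    for the vectorised implementation.
    """
    total = o11 + o12 + o21 + o22
    r1, r2 = o11 + o12, o21 + o22
    c1, c2 = o11 + o21, o12 + o22
    if 0 in (r1, r2, c1, c2):
        return 0.0, 1.0, True
    g = 0.0
    for obs, e in ((o11, r1 * c1 / total), (o12, r1 * c2 / total),
                   (o21, r2 * c1 / total), (o22, r2 * c2 / total)):
        if e > obs:
            adj = obs + min(0.5, e - obs)
        else:
            adj = obs - min(0.5, obs - e)
        if adj > 0:
            g += adj * math.log(adj / e)
    g = max(2.0 * g, 0.0)
    # chi-square df=1 upper tail via the normal tail of sqrt(G)
    p = math.erfc(math.sqrt(g / 2.0))
    return g, p, False


class TestGTestYates:
    def test_balanced_table_gives_null_result(self):
        g, p, degenerate = sq.g_test_yates([[5, 5], [50, 50]])
        assert g == 0.0 and p == 1.0 and not degenerate

    def test_hand_worked_example(self):
        g, p, _ = sq.g_test_yates([[10, 0], [90, 100]])
        g_ref, p_ref, _ = g_yates_reference(10, 0, 90, 100)
        assert g == pytest.approx(g_ref, abs=1e-12)
        assert g == pytest.approx(10.31, abs=0.02)
        assert p == pytest.approx(1.3e-3, rel=0.05)

    def test_symmetry_under_row_and_column_swap(self):
        base = sq.g_test_yates([[12, 3], [88, 97]])
        assert sq.g_test_yates([[3, 12], [97, 88]]) == pytest.approx(base)
        assert sq.g_test_yates([[88, 97], [12, 3]]) == pytest.approx(base)

    def test_degenerate_margins_flagged_not_raised(self):
        g, p, degenerate = sq.g_test_yates([[0, 0], [10, 20]])
        assert (g, p, degenerate) == (0.0, 1.0, True)
        g, p, degenerate = sq.g_test_yates([[0, 5], [0, 20]])
        assert degenerate

    def test_invalid_tables_raise(self):
        with pytest.raises(ValueError):
            sq.g_test_yates([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            sq.g_test_yates([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            sq.g_test_yates([[0, 0], [0, 0]])

    def test_matches_brute_force_on_small_tables(self):
        """Exhaustive oracle equivalence on 2x2 tables with entries 0..5."""
        for o11 in range(6):
            for o12 in range(6):
                for o21 in range(6):
                    for o22 in range(6):
                        if o11 + o12 + o21 + o22 == 0:
                            continue
                        got = sq.g_test_yates([[o11, o12], [o21, o22]])
                        g_ref, p_ref, deg_ref = g_yates_reference(o11, o12, o21, o22)
                        assert got.degenerate == deg_ref
                        assert got.g_stat == pytest.approx(g_ref, abs=1e-10)
                        assert got.p_value == pytest.approx(p_ref, abs=1e-10)

    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=200)
    def test_correction_never_exceeds_uncorrected_g(self, cells):
        o11, o12, o21, o22 = cells
        if min(o11 + o12, o21 + o22, o11 + o21, o12 + o22) == 0:
            return
        yates = sq.g_test_yates([[o11, o12], [o21, o22]])
        plain = sq.g_test_uncorrected([[o11, o12], [o21, o22]])
        assert yates.g_stat <= plain.g_stat + 1e-9

    def test_type_one_error_is_controlled_under_the_null(self, panel):
        """Null 2x2 tables at published margins: empirical rate <= nominal."""
        rng = np.random.default_rng(2024)
        t1, t2 = 18_000.0, 16_000.0
        row_totals = panel["total"].to_numpy()
        n_sim = 2_000
        hits = 0
        for total in rng.choice(row_totals, n_sim):
            share = total / (t1 + t2)
            n1 = rng.binomial(int(t1), share)
            n2 = rng.binomial(int(t2), share)
            _, p, _ = sq.g_test_yates([[n1, n2], [t1 - n1, t2 - n2]])
            hits += p < 0.05
        rate = hits / n_sim
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)


class TestChisqTail:
    def test_anchor_values(self):
        assert sq.chisq_tail_df1(0.0) == 1.0
        assert sq.chisq_tail_df1(3.841459) == pytest.approx(0.05, abs=1e-4)

    def test_strictly_decreasing(self):
        xs = np.linspace(0, 20, 50)
        ps = [sq.chisq_tail_df1(x) for x in xs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            sq.chisq_tail_df1(-0.1)


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = sq.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_its_own_q(self):
        assert sq.bh_fdr([0.037]) == pytest.approx([0.037])

    def test_all_ones_stay_ones(self):
        assert sq.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_order_preserved_and_monotone_in_rank(self):
        p = [0.2, 0.001, 0.05, 0.9]
        q = sq.bh_fdr(p)
        assert q[1] == min(q)
        # q never smaller than p
        assert (np.asarray(q) >= np.asarray(p) - 1e-12).all()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sq.bh_fdr([])
        with pytest.raises(ValueError):
            sq.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            sq.bh_fdr([1.5])


class TestHypergeomTail:
    def test_exact_combinatorial_value(self):
        # C(5,4)*C(15,0)/C(20,4) = 5/4845
        assert sq.hypergeom_tail(4, 4, 5, 20) == pytest.approx(5 / 4845, rel=1e-12)

    def test_certain_events(self):
        assert sq.hypergeom_tail(0, 4, 5, 20) == 1.0
        assert sq.hypergeom_tail(3, 3, 3, 3) == 1.0

    def test_monotone_in_overlap(self):
        ps = [sq.hypergeom_tail(k, 10, 20, 100) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_arguments_raise(self):
        with pytest.raises(ValueError):
            sq.hypergeom_tail(5, 4, 5, 20)
        with pytest.raises(ValueError):
            sq.hypergeom_tail(1, 30, 5, 20)
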