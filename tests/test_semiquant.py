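"""Pooling, relative abundances, Rsc fold changes and totals calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spcquant as sq
from spcquant.semiquant import calibrate_totals


class TestPooling:
    def test_pooling_sums_runs_within_group(self):
        counts = pd.DataFrame(
            {"r1": [3], "r2": [2], "r3": [4]},
            index=pd.Index(["P1"], name="accession"),
        )
        design = sq.GroupDesign(
            assignments=pd.DataFrame(
                {"patient": ["A", "A", "B"], "group": ["g", "g", "g"]},
                index=pd.Index(["r1", "r2", "r3"], name="run"),
            )
        )
        pooled = sq.pool_counts(sq.SpectralCountTable(counts=counts), design)
        assert pooled.counts.loc["P1", "g"] == 9
        assert pooled.totals["g"] == 9

    def test_all_zero_table_pools_to_zero(self, tiny_design):
        counts = pd.DataFrame(
            {"run1": [0, 0], "run2": [0, 0]},
            index=pd.Index(["P1", "P2"], name="accession"),
        )
        pooled = sq.pool_counts(sq.SpectralCountTable(counts=counts), tiny_design)
        assert (pooled.counts == 0).all().all()
        assert pooled.totals["grp"] == 0

    def test_run_order_does_not_matter(self, tiny_table, tiny_design):
        permuted = sq.SpectralCountTable(
            counts=tiny_table.counts[["run2", "run1"]], meta=tiny_table.meta
        )
        a = sq.pool_counts(tiny_table, tiny_design)
        b = sq.pool_counts(permuted, tiny_design)
        assert a.counts.equals(b.counts)

    def test_unassigned_run_is_an_error(self, tiny_table):
        design = sq.GroupDesign(
            assignments=pd.DataFrame(
                {"patient": ["A"], "group": ["g"]},
                index=pd.Index(["run1"], name="run"),
            )
        )
        with pytest.raises(sq.ValidationError, match="run2"):
            sq.pool_counts(tiny_table, design)


class TestRelativePercent:
    @pytest.mark.parametrize(
        "counts,expected",
        [((29, 4, 9), (69.0, 9.5, 21.4)),   # ALDH6A1
         ((32, 0, 6), (84.2, 0.0, 15.8))],  # NONO
    )
    def test_published_rows(self, counts, expected):
        pooled = sq.PooledGroupCounts(
            counts=pd.DataFrame(
                {"LPIA": [counts[0]], "MIA": [counts[1]], "AIS": [counts[2]]},
                index=pd.Index(["P"], name="accession"),
            )
        )
        pct = sq.relative_percent(pooled, decimals=1)
        assert tuple(pct.loc["P"]) == expected

    def test_even_split(self):
        pooled = sq.PooledGroupCounts(
            counts=pd.DataFrame({"a": [5], "b": [5]}, index=pd.Index(["P"]))
        )
        assert tuple(sq.relative_percent(pooled, decimals=1).loc["P"]) == (50.0, 50.0)

    def test_all_zero_protein_is_missing(self):
        pooled = sq.PooledGroupCounts(
            counts=pd.DataFrame({"a": [0, 1], "b": [0, 1]}, index=pd.Index(["P0", "P1"]))
        )
        pct = sq.relative_percent(pooled)
        assert pct.loc["P0"].isna().all()
        assert not pct.loc["P1"].isna().any()


class TestRsc:
    def test_spot_values_at_calibrated_totals(self):
        # zero-count reference: HPX-like row
        assert sq.rsc(9, 0, 18_000, 16_150, f=1.25) == pytest.approx(-2.880, abs=0.005)
        assert sq.rsc(16, 5, 18_000, 16_150, f=1.25) == pytest.approx(-1.309, abs=0.005)

    def test_equal_counts_equal_totals_give_zero(self):
        assert sq.rsc(7, 7, 10_000, 10_000) == pytest.approx(0.0, abs=1e-12)

    @given(
        n_a=st.integers(0, 200), n_b=st.integers(0, 200),
        t_a=st.integers(1_000, 30_000), t_b=st.integers(1_000, 30_000),
    )
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetry(self, n_a, n_b, t_a, t_b):
        forward = sq.rsc(n_a, n_b, t_a, t_b)
        backward = sq.rsc(n_b, n_a, t_b, t_a)
        assert forward == pytest.approx(-backward, abs=1e-9)

    def test_strictly_decreasing_in_focal_count(self):
        values = [sq.rsc(n, 10, 18_000, 16_000) for n in range(0, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_sign_flip_convention(self):
        assert sq.rsc(9, 0, 18_000, 16_000, focal_negative=False) == pytest.approx(
            -sq.rsc(9, 0, 18_000, 16_000)
        )

    def test_counts_above_totals_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.rsc(11, 0, 10, 100)


class TestTotalsCalibration:
    def test_panel_offsets_match_zero_count_spot_checks(self, panel):
        cal_mia = sq.calibrate_panel("MIA", panel=panel)
        cal_ais = sq.calibrate_panel("AIS", panel=panel)
        # spot-checkable on zero-count rows, e.g. HPX: log2(10.25/1.25) - 2.880
        assert cal_mia.delta == pytest.approx(0.155, abs=0.01)
        assert cal_ais.delta == pytest.approx(0.213, abs=0.01)
        assert cal_mia.max_abs_residual < 0.01
        assert cal_ais.max_abs_residual < 0.01

    def test_generate_then_fit_round_trip(self):
        rng = np.random.default_rng(7)
        n_a = rng.integers(0, 80, 50)
        n_b = rng.integers(0, 80, 50)
        t_a, t_b = 18_000.0, 15_200.0
        observed = sq.rsc(n_a, n_b, t_a, t_b)
        cal = calibrate_totals(n_a, n_b, observed, focal_total=t_a)
        assert cal.reference_total == pytest.approx(t_b, abs=0.5)
        assert cal.max_abs_residual < 1e-6
        true_delta = np.log2((t_a + 1.25) / (t_b + 1.25))
        assert cal.delta == pytest.approx(true_delta, abs=5e-3)

    def test_pvalue_calibration_reproduces_printed_pvalues(self, panel, panel_pooled):
        cal = sq.calibrate_panel("MIA", source="pvalues")
        comp = sq.compare_groups(panel_pooled, "LPIA", "MIA", totals=cal.totals)
        printed = panel["p_lpia_vs_mia"].to_numpy()
        rel = np.abs(comp["p_value"].to_numpy() - printed) / printed
        assert rel.max() < 0.05

    def test_empty_fixture_is_an_error(self):
        with pytest.raises(sq.ValidationError):
            calibrate_totals([], [], [])


class TestDetectionFilter:
    def test_panel_mia_detection_count(self, panel_pooled):
        assert len(sq.detection_filter(panel_pooled, "MIA", min_spc=2)) == 11

    def test_zero_threshold_keeps_all_positive(self):
        pooled = sq.PooledGroupCounts(
            counts=pd.DataFrame({"g": [1, 2, 3]}, index=pd.Index(["a", "b", "c"]))
        )
        assert sq.detection_filter(pooled, "g", min_spc=0) == ["a", "b", "c"]

    def test_empty_table_gives_empty_result(self):
        pooled = sq.PooledGroupCounts(
            counts=pd.DataFrame({"g": []}, index=pd.Index([], name="accession"))
        )
        assert sq.detection_filter(pooled, "g") == []

    def test_order_preserved(self, panel_pooled):
        kept = sq.detection_filter(panel_pooled, "LPIA", min_spc=20)
        order = list(panel_pooled.counts.index)
        assert kept == [a for a in order if a in set(kept)]
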