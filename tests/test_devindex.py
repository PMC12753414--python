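"""Segment classification, index arithmetic, slopes, and the ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cqindex import (
    NonEvaluableSegmentError,
    PanelConfig,
    Segment,
    classify_segment_genes,
    compare_slopes_ancova,
    compute_index,
    fit_segment_slopes,
    run_devindex_pipeline,
)
from tests import oracles
from tests.conftest import make_expr_table

SEG = Segment(26, 55)


def fc_rows(gene, values_by_day, arm="DMSO"):
    rows = []
    for day, values in values_by_day.items():
        for rep, v in enumerate(values, start=1):
            rows.append((arm, day, rep, gene, v))
    return rows


class TestClassification:
    def test_rising_gene_called_up(self):
        # log2FC (0.9, 1.0, 1.1) at day 26 and (1.9, 2.0, 2.1) at day 55;
        # expected r/p frozen from the raw-sum oracle
        fc = make_expr_table(
            fc_rows("A", {26: 2.0 ** np.array([0.9, 1.0, 1.1]),
                          55: 2.0 ** np.array([1.9, 2.0, 2.1])})
        )
        cls = classify_segment_genes(fc, SEG).set_index("gene")
        assert cls.loc["A", "direction"] == "up"
        assert cls.loc["A", "r"] == pytest.approx(0.9869275424, abs=1e-9)
        assert cls.loc["A", "p"] == pytest.approx(2.552167e-4, rel=1e-5)

    def test_falling_gene_called_down_by_sign_symmetry(self):
        fc = make_expr_table(
            fc_rows("A", {26: 2.0 ** np.array([2.1, 2.0, 1.9]),
                          55: 2.0 ** np.array([1.1, 1.0, 0.9])})
        )
        cls = classify_segment_genes(fc, SEG).set_index("gene")
        assert cls.loc["A", "direction"] == "down"
        assert cls.loc["A", "r"] == pytest.approx(-0.9869275424, abs=1e-9)

    def test_zero_variance_gene_is_ns_with_undefined_r(self):
        fc = make_expr_table(fc_rows("A", {26: [2.0, 2.0, 2.0], 55: [2.0, 2.0, 2.0]}))
        cls = classify_segment_genes(fc, SEG).set_index("gene")
        assert cls.loc["A", "direction"] == "ns"
        assert np.isnan(cls.loc["A", "r"])

    def test_too_few_observations_is_ns(self):
        fc = make_expr_table(fc_rows("A", {26: [1.0], 55: [2.0]}))
        cls = classify_segment_genes(fc, SEG).set_index("gene")
        assert cls.loc["A", "direction"] == "ns"
        assert cls.loc["A", "n_obs"] == 2

    def test_segment_without_data_rejected(self):
        fc = make_expr_table(fc_rows("A", {26: [1.0] * 3}))
        with pytest.raises(ValueError, match="no control-arm data"):
            classify_segment_genes(fc, Segment(95, 138))

    def test_direction_always_matches_sign_rule(self, noisy_fc, panel_config):
        for seg in panel_config.segments:
            cls = classify_segment_genes(noisy_fc, seg, alpha=0.05)
            for _, row in cls.dropna(subset=["r"]).iterrows():
                expected = (
                    "up" if row["p"] < 0.05 and row["r"] > 0
                    else "down" if row["p"] < 0.05 and row["r"] < 0
                    else "ns"
                )
                assert row["direction"] == expected

    def test_matches_oracle_on_noisy_panel(self, noisy_fc, panel_config):
        for seg in panel_config.segments:
            cls = classify_segment_genes(noisy_fc, seg).set_index("gene")
            sub = noisy_fc[
                (noisy_fc["treatment"] == "DMSO") & seg.contains(noisy_fc["div"])
            ]
            for gene, g in sub.groupby("gene"):
                r, p = oracles.pearson_r_p(g["div"], np.log2(g["value"]))
                assert cls.loc[gene, "r"] == pytest.approx(r, abs=1e-10)
                assert cls.loc[gene, "p"] == pytest.approx(p, abs=1e-10)


def classification_frame(up=(), down=(), ns=()):
    rows = [(g, "up", 0.9, 0.01) for g in up]
    rows += [(g, "down", -0.9, 0.01) for g in down]
    rows += [(g, "ns", 0.1, 0.9) for g in ns]
    return pd.DataFrame(rows, columns=["gene", "direction", "r", "p"])


class TestIndex:
    def test_ratio_of_rescaled_means(self):
        # control means: up genes 1.0, down genes 0.5; the treated sample has
        # rescaled up values {2.0, 2.0} and down values {0.5, 0.5} -> index 4
        rows = []
        for gene, (a, b) in [("U1", (0.5, 1.5)), ("U2", (0.5, 1.5)),
                             ("D1", (0.25, 0.75)), ("D2", (0.25, 0.75))]:
            rows += [("DMSO", 26, 1, gene, a), ("DMSO", 26, 2, gene, b)]
        rows += [("ALLO", 26, 1, g, v)
                 for g, v in [("U1", 2.0), ("U2", 2.0), ("D1", 0.25), ("D2", 0.25)]]
        expr = make_expr_table(rows)
        cls = classification_frame(up=("U1", "U2"), down=("D1", "D2"))
        out = compute_index(expr, cls, SEG)
        treated = out[out["treatment"] == "ALLO"]
        assert treated["index"].iloc[0] == pytest.approx(4.0, rel=1e-12)

    def test_index_is_one_at_the_control_segment_mean(self):
        # a sample whose fold changes all sit at the gene-wise control-arm
        # segment mean has rescaled values of exactly 1 -> index 1
        rows = []
        for gene, vals in [("U", (1.0, 2.0, 3.0)), ("D", (3.0, 2.0, 1.0))]:
            for day, v in zip((26, 40, 55), vals):
                rows.append(("DMSO", day, 1, gene, v))
        expr = make_expr_table(rows)
        cls = classification_frame(up=("U",), down=("D",))
        out = compute_index(expr, cls, SEG).set_index("div")
        assert out.loc[40, "index"] == pytest.approx(1.0, rel=1e-12)

    def test_explicit_arithmetic(self):
        # control day 26 all genes at 1, day 55: up genes x4, down genes /4
        rows = []
        for gene in ("U", "D"):
            rows += fc_rows(gene, {26: [1.0, 1.0]})
        rows += fc_rows("U", {55: [4.0, 4.0]})
        rows += fc_rows("D", {55: [0.25, 0.25]})
        expr = make_expr_table(rows)
        cls = classification_frame(up=("U",), down=("D",))
        out = compute_index(expr, cls, SEG).set_index("div")
        # rescale constants: mean U = 2.5, mean D = 0.625
        assert out.loc[26, "index"].iloc[0] == pytest.approx((1 / 2.5) / (1 / 0.625))
        assert out.loc[55, "index"].iloc[0] == pytest.approx((4 / 2.5) / (0.25 / 0.625))

    def test_label_swap_inverts_index(self, noisy_fc, panel_config):
        seg = panel_config.segments[0]
        cls = classify_segment_genes(noisy_fc, seg)
        swapped = cls.copy()
        swapped["direction"] = cls["direction"].map(
            {"up": "down", "down": "up", "ns": "ns"}
        )
        fwd = compute_index(noisy_fc, cls, seg)
        rev = compute_index(noisy_fc, swapped, seg)
        np.testing.assert_allclose(fwd["index"], 1.0 / rev["index"], rtol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(factor=st.floats(0.01, 100.0))
    def test_per_gene_rescaling_leaves_index_invariant(self, factor, noisy_fc,
                                                       panel_config):
        seg = panel_config.segments[0]
        cls = classify_segment_genes(noisy_fc, seg)
        base = compute_index(noisy_fc, cls, seg)
        gene = cls.loc[cls["direction"] == "up", "gene"].iloc[0]
        scaled = noisy_fc.copy()
        scaled.loc[scaled["gene"] == gene, "value"] *= factor
        out = compute_index(scaled, cls, seg)
        np.testing.assert_allclose(base["index"], out["index"], rtol=1e-9)

    def test_empty_direction_set_flags_segment(self):
        expr = make_expr_table(
            [("DMSO", 26, 1, "A", 2.0), ("DMSO", 26, 1, "B", 0.5)]
        )
        with pytest.raises(NonEvaluableSegmentError, match="down"):
            compute_index(expr, classification_frame(up=("A", "B")), SEG)


class TestSlopes:
    def test_two_point_slope(self):
        series = pd.DataFrame(
            {"treatment": "DMSO", "div": [26] * 3 + [55] * 3,
             "replicate": [1, 2, 3] * 2, "index": [1.0] * 3 + [2.0] * 3}
        )
        assert fit_segment_slopes(series, "DMSO") == pytest.approx(1 / 29)

    def test_constant_index_zero_slope(self):
        series = pd.DataFrame(
            {"treatment": "DMSO", "div": [26, 26, 55, 55],
             "replicate": [1, 2, 1, 2], "index": [1.5] * 4}
        )
        assert fit_segment_slopes(series, "DMSO") == pytest.approx(0.0, abs=1e-15)

    def test_replicate_spread_matches_normal_equations(self):
        x = [26, 26, 55, 55]
        y = [1.0, 1.2, 1.9, 2.1]
        series = pd.DataFrame(
            {"treatment": "DMSO", "div": x, "replicate": [1, 2, 1, 2], "index": y}
        )
        assert fit_segment_slopes(series, "DMSO") == pytest.approx(0.9 / 29)
        assert fit_segment_slopes(series, "DMSO") == pytest.approx(
            oracles.ols_slope(x, y), abs=1e-12
        )

    def test_single_day_rejected(self):
        series = pd.DataFrame(
            {"treatment": "DMSO", "div": [26, 26], "replicate": [1, 2],
             "index": [1.0, 1.1]}
        )
        with pytest.raises(ValueError, match="2 distinct days"):
            fit_segment_slopes(series, "DMSO")


def index_series(control, treated, days=(55, 78), label="DIV55-DIV78"):
    rows = []
    for arm, per_day in (("DMSO", control), ("ALLO", treated)):
        for day, values in zip(days, per_day):
            for rep, v in enumerate(values, start=1):
                rows.append({"treatment": arm, "segment": label, "div": day,
                             "replicate": rep, "index": v})
    return pd.DataFrame(rows)


class TestAncova:
    def test_identical_arms_no_interaction(self):
        vals = ([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        comp = compare_slopes_ancova(index_series(vals, vals), Segment(55, 78))
        assert comp.evaluable and not comp.degenerate
        assert comp.interaction_F == pytest.approx(0.0, abs=1e-8)
        assert comp.interaction_p == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_slope_separation_flags_degenerate(self):
        control = ([1.0, 1.0], [2.0, 2.0])          # slope 1/23
        treated = ([1.0, 1.0], [1.5, 1.5])          # slope 0.5/23
        comp = compare_slopes_ancova(index_series(control, treated), Segment(55, 78))
        assert comp.degenerate
        assert comp.interaction_p == 0.0
        assert comp.slope_control == pytest.approx(1 / 23)
        assert comp.slope_treated == pytest.approx(0.5 / 23)

    def test_noiseless_equal_slopes_not_a_detection(self):
        control = ([1.0, 1.0], [2.0, 2.0])
        treated = ([1.2, 1.2], [2.2, 2.2])          # offset, same slope
        comp = compare_slopes_ancova(index_series(control, treated), Segment(55, 78))
        assert comp.degenerate
        assert comp.interaction_F == 0.0
        assert comp.interaction_p == 1.0

    @pytest.mark.parametrize("scale", ["linear", "log"])
    def test_matches_oracle_on_pipeline_instance(self, scale, noisy_fc, panel_config):
        """The 12-row segment instances produced by the pipeline at seed 0
        give the same interaction F as brute-force design-matrix least
        squares, on both index scales."""
        res = run_devindex_pipeline(noisy_fc, panel_config, index_scale=scale)
        checked = 0
        for comp in res.slope_comparisons:
            if not comp.evaluable or comp.degenerate:
                continue
            sub = res.index_series[res.index_series["segment"] == comp.segment.label]
            y = np.log2(sub["index"]) if scale == "log" else sub["index"]
            F, p = oracles.ancova_interaction_F(sub["div"], sub["treatment"], y)
            assert comp.interaction_F == pytest.approx(F, abs=1e-8)
            assert comp.interaction_p == pytest.approx(p, abs=1e-8)
            checked += 1
        assert checked >= 3

    def test_missing_arm_days_not_evaluable(self):
        series = index_series(([1.0], [2.0]), ([1.0], [2.0]))
        series = series[~((series["treatment"] == "ALLO") & (series["div"] == 78))]
        comp = compare_slopes_ancova(series, Segment(55, 78))
        assert not comp.evaluable
        assert "ALLO" in comp.error


class TestPipeline:
    def test_null_preset_yields_four_evaluable_segments(self, noisy_fc, panel_config):
        res = run_devindex_pipeline(noisy_fc, panel_config)
        assert len(res.slope_comparisons) == 4
        assert all(c.evaluable for c in res.slope_comparisons)
        assert set(res.gene_sets) == {s.label for s in panel_config.segments}

    def test_noiseless_delay_detected_exactly_in_delay_window(
        self, noiseless_fc, panel_config
    ):
        """With σ=0 the log-scale index is linear in the maturation clock,
        so the interaction is real exactly where the clock rate differs:
        the two segments overlapping the delay window DIV67-95."""
        res = run_devindex_pipeline(noiseless_fc, panel_config, index_scale="log")
        detected = {
            c.segment.label: c.interaction_p < 0.05 for c in res.slope_comparisons
        }
        assert detected == {
            "DIV26-DIV55": False,
            "DIV55-DIV78": True,
            "DIV78-DIV95": True,
            "DIV95-DIV138": False,
        }

    def test_classification_recovers_latent_trends_noiseless(
        self, delay_truth_noiseless, noiseless_fc, panel_config
    ):
        expected = delay_truth_noiseless.expected_direction()
        res = run_devindex_pipeline(noiseless_fc, panel_config)
        for label, cls in res.classifications.items():
            for _, row in cls.iterrows():
                assert row["direction"] == expected[row["gene"]], (label, row["gene"])

    def test_segment_errors_do_not_stop_other_segments(self, noisy_fc):
        config = PanelConfig(
            genes=tuple(sorted(set(noisy_fc["gene"]))),
            segments=(Segment(26, 55), Segment(55, 78), Segment(78, 95),
                      Segment(95, 120)),  # no day inside (95, 120] but 95
        )
        res = run_devindex_pipeline(noisy_fc, config)
        assert len(res.slope_comparisons) == 4
        assert any(not c.evaluable for c in res.slope_comparisons)
        assert sum(c.evaluable for c in res.slope_comparisons) >= 3

    def test_per_day_mean_option_runs(self, noisy_fc, panel_config):
        res = run_devindex_pipeline(noisy_fc, panel_config, per_day_mean=True)
        assert len(res.slope_comparisons) == 4
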