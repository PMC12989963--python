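"""Flow tallies, the conditional contamination decomposition, mean
concentrations, stream summaries, and the diversity regression."""
import numpy as np
import pandas as pd
import pytest

import aquarisk as aq
from aquarisk import flows
from aquarisk.io import SAMPLING_COLUMNS


def _frame(rows):
    return pd.DataFrame(rows, columns=SAMPLING_COLUMNS)


def _sample(sid, result, monitor="J", source="I", year=2020,
            hazard=None, cls="antibiotic", conc=None, limit=0.0):
    return (sid, year, monitor, source, "fish", result, hazard, cls, conc, limit)


class TestTally:
    def test_counting_rule_multi_hazard(self):
        # 10 samples I->J, 2 failed, one failure carries 2 antibiotics:
        # NST=10, NSC=2, per-hazard occurrences sum to 3.
        rows = [_sample(f"p{i}", "pass") for i in range(8)]
        rows += [_sample("f1", "fail", hazard="A", conc=5.0),
                 _sample("f2", "fail", hazard="A", conc=5.0),
                 _sample("f2", "fail", hazard="B", conc=7.0)]
        counts = aq.tally_flow_counts(_frame(rows))
        cell = counts.table.loc[("I", "J")]
        assert (cell["NST"], cell["NSC"], cell["NSC_ant"]) == (10, 2, 2)
        assert counts.hazard_counts["count"].sum() == 3

    def test_all_passed_gives_zero_failures(self):
        counts = aq.tally_flow_counts(_frame([_sample(f"p{i}", "pass") for i in range(5)]))
        cell = counts.table.loc[("I", "J")]
        assert cell["NSC"] == 0 and counts.hazard_counts.empty

    def test_flows_are_additive_across_cells(self):
        rows = [_sample("a", "pass", source="I"), _sample("b", "pass", source="K"),
                _sample("c", "fail", source="K", hazard="A", conc=3.0)]
        counts = aq.tally_flow_counts(_frame(rows))
        assert counts.table["NST"].sum() == 3
        assert set(counts.table.index) == {("I", "J"), ("K", "J")}

    def test_empty_input_is_empty_not_error(self):
        counts = aq.tally_flow_counts(_frame([]))
        assert counts.table.empty

    def test_pooling_per_year_equals_pooled(self, small_dataset):
        """Tallying per year then summing equals pooled tallying, integer-exact."""
        df = small_dataset.records
        pooled = aq.tally_flow_counts(df)
        per_year = [aq.tally_flow_counts(df, years=(y, y))
                    for y in sorted(df["year"].unique())]
        summed = flows.sum_counts(per_year)
        pd.testing.assert_frame_equal(
            pooled.table.sort_index(), summed.table.sort_index())
        lhs = pooled.hazard_counts.sort_values(
            ["source_province", "monitoring_province", "hazard_name"]).reset_index(drop=True)
        rhs = summed.hazard_counts.sort_values(
            ["source_province", "monitoring_province", "hazard_name"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs, check_like=True)


class TestEstimateContamination:
    def test_conditional_decomposition_arithmetic(self):
        # NST=1000, NSC=20, NSC_k=10, occurrences=25 -> ProbC = 0.02*0.4 = 0.008
        table = pd.DataFrame(
            {"NST": [1000], "NSC": [20], "NSC_ant": [20]},
            index=pd.MultiIndex.from_tuples([("I", "J")],
                                            names=["source_province", "monitoring_province"]))
        hz = pd.DataFrame({"source_province": ["I", "I"], "monitoring_province": ["J", "J"],
                           "hazard_name": ["A", "B"], "hazard_class": ["antibiotic"] * 2,
                           "count": [10, 15]})
        matrix = aq.estimate_contamination(flows.FlowCounts(table, hz))
        assert matrix.get_probc("I", "J", "A") == pytest.approx(0.008, abs=1e-15)
        assert matrix.cells["a"].iloc[0] == pytest.approx(0.02)

    def test_single_hazard_probc_equals_rate(self):
        table = pd.DataFrame(
            {"NST": [500], "NSC": [5], "NSC_ant": [5]},
            index=pd.MultiIndex.from_tuples([("I", "J")],
                                            names=["source_province", "monitoring_province"]))
        hz = pd.DataFrame({"source_province": ["I"], "monitoring_province": ["J"],
                           "hazard_name": ["A"], "hazard_class": ["antibiotic"],
                           "count": [5]})
        matrix = aq.estimate_contamination(flows.FlowCounts(table, hz))
        assert matrix.get_probc("I", "J", "A") == pytest.approx(0.01)

    def test_zero_failures_gives_zero_everywhere(self):
        rows = [_sample(f"p{i}", "pass") for i in range(4)]
        matrix = aq.estimate_contamination(aq.tally_flow_counts(_frame(rows)))
        assert (matrix.cells["a"] == 0).all()
        assert matrix.get_probc("I", "J", "A") == 0.0

    def test_probc_partitions_the_contaminated_mass(self, small_pipeline):
        """sum_k ProbC(i,j,k) over all hazards equals a(i,j) exactly."""
        m = small_pipeline.matrix
        sums = m.probc.groupby(["source_province", "monitoring_province"])["probc"].sum()
        cells = m.cells.set_index(["source_province", "monitoring_province"])
        sub = cells.loc[cells["NSC"] > 0, "a"]
        assert np.allclose(sums.reindex(sub.index), sub, atol=1e-12)

    def test_probc_bounded_by_cell_rate(self, small_pipeline):
        m = small_pipeline.matrix
        merged = m.probc.merge(m.cells, on=["source_province", "monitoring_province"])
        assert (merged["probc"] <= merged["a"] + 1e-12).all()

    def test_source_categories(self, small_pipeline):
        cells = small_pipeline.matrix.cells
        internal = cells[cells["source_category"] == "internal"]
        assert (internal["source_province"] == internal["monitoring_province"]).all()
        unknown = cells[cells["source_category"] == "unknown"]
        assert (unknown["source_province"] == aq.UNKNOWN).all()

    def test_untested_flow_is_missing_not_zero(self, caplog):
        table = pd.DataFrame(
            {"NST": [10, 0], "NSC": [1, 0], "NSC_ant": [1, 0]},
            index=pd.MultiIndex.from_tuples([("I", "J"), ("K", "J")],
                                            names=["source_province", "monitoring_province"]))
        hz = pd.DataFrame(columns=["source_province", "monitoring_province",
                                   "hazard_name", "hazard_class", "count"])
        with caplog.at_level("WARNING"):
            matrix = aq.estimate_contamination(flows.FlowCounts(table, hz))
        assert len(matrix.cells) == 1
        assert "no samples" in caplog.text


class TestConcentration:
    def test_mean_over_contaminated_samples(self):
        rows = [_sample(f"f{i}", "fail", hazard="A", conc=c)
                for i, c in enumerate([100.0, 200.0, 300.0])]
        cl = aq.estimate_concentration(_frame(rows))
        assert cl.get_cl("J", "A") == pytest.approx(200.0)
        assert cl.table["n_contributing"].iloc[0] == 3

    def test_absent_hazard_is_missing(self):
        rows = [_sample("f0", "fail", hazard="A", conc=80.0)]
        cl = aq.estimate_concentration(_frame(rows))
        assert cl.get_cl("J", "A") == pytest.approx(80.0)
        assert cl.get_cl("J", "B") is None

    def test_recovers_truncated_lognormal_mean(self):
        """Estimated means converge on the truncated-log-normal expectation."""
        truth = aq.make_ground_truth(
            2, 1, seed=5,
            overrides={"internal_mean": 0.4, "external_mean": 0.4, "unknown_mean": 0.4,
                       "internal_sd": 0.0, "external_sd": 0.0, "unknown_sd": 0.0})
        ds = aq.generate_dataset(truth, 2000, (2020, 2020))
        cl = aq.estimate_concentration(ds.records)
        ab = truth.antibiotics.iloc[0]
        expected = aq.truncated_lognormal_mean(ab["log_mu"], ab["log_sd"], ab["mrl"])
        sub = cl.table[(cl.table["hazard_name"] == ab["name"])
                       & (cl.table["n_contributing"] >= 200)]
        assert len(sub) >= 1
        rel_err = (sub["cl"] - expected).abs() / expected
        assert (rel_err < 0.10).all()


class TestDiversityRegression:
    def test_perfect_line(self):
        reg = flows.fit_diversity_line([1, 2, 3], [0.01, 0.02, 0.03])
        assert reg.slope == pytest.approx(0.01)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        reg = flows.fit_diversity_line([1, 2, 3], [0.02, 0.02, 0.02])
        assert reg.slope == 0.0 and reg.r_squared == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            flows.fit_diversity_line([1, 2], [0.1, 0.2])

    def test_slope_recovery_within_ci(self):
        """A diversity-dependent external rate built into the truth is
        recovered within the fit's own 95% CI in >= 18/20 seeds."""
        slope_true = -0.003
        hits = 0
        for seed in range(20):
            truth = aq.make_ground_truth(16, 3, seed=seed,
                                         overrides={"external_share": 0.5,
                                                    "external_decay": 1.0})
            fs = truth.flow_shares
            n_ext = (fs[fs["source_province"] != aq.UNKNOWN]
                     .groupby("monitoring_province")["source_province"].nunique() - 1)
            contamination = dict(truth.contamination_prob)
            for (i, j), a in contamination.items():
                if i not in (j, aq.UNKNOWN):
                    contamination[(i, j)] = 0.08 + slope_true * n_ext[j]
            truth = aq.GroundTruth(**{**truth.__dict__,
                                      "contamination_prob": contamination})
            ds = aq.generate_dataset(truth, 450, (2015, 2018))
            matrix = aq.estimate_contamination(aq.tally_flow_counts(ds.records))
            # rate is the all-hazard external rate here, matching the truth scale
            pts = flows.diversity_points(matrix, "external")
            sub = matrix.cells[matrix.cells["source_category"] == "external"]
            g = sub.groupby("monitoring_province")[["NSC", "NST"]].sum()
            pts = pts.set_index("monitoring_province")
            pts["rate"] = g["NSC"] / g["NST"]
            reg = flows.fit_diversity_line(pts["n_sources"], pts["rate"])
            lo, hi = reg.ci95_slope
            hits += lo <= slope_true <= hi
        assert hits >= 18

    def test_stream_summary_means(self):
        rows = [_sample(f"x{i}", "pass", source="E1") for i in range(99)]
        rows += [_sample("xf", "fail", source="E1", hazard="A", conc=5.0)]
        rows += [_sample(f"y{i}", "pass", source="E2") for i in range(97)]
        rows += [_sample(f"yf{i}", "fail", source="E2", hazard="A", conc=5.0)
                 for i in range(3)]
        matrix = aq.estimate_contamination(aq.tally_flow_counts(_frame(rows)))
        streams = aq.summarize_streams(matrix).set_index("stream")
        assert streams.loc["external", "mean_a_ant"] == pytest.approx(0.02)
        assert streams.loc["external", "n_cells"] == 2

    def test_stream_ordering_recovered_on_preset(self, preset_pipeline):
        """External > unknown > internal mean rates, as built into the truth."""
        streams = preset_pipeline.streams.set_index("stream")["mean_a_ant"]
        assert streams["external"] > streams["unknown"] > streams["internal"]
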