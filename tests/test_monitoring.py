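"""Detection probabilities, scheme evaluation, and the allocation solvers."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aquarisk as aq
from aquarisk.monitoring import (
    _greedy_budget,
    brute_force_province,
    detection_probability,
    joint_detection,
    solve_province,
)


class TestDetectionProbability:
    @pytest.mark.parametrize("a,x,s,expected", [
        (0.2, 3, 1.0, 1 - 0.8**3),   # 0.488
        (0.3, 0, 1.0, 0.0),          # no sampling, no detection
        (1.0, 1, 1.0, 1.0),
        (0.5, 2, 0.98, 1 - (1 - 0.49)**2),
    ])
    def test_values(self, a, x, s, expected):
        assert detection_probability(a, x, s) == pytest.approx(expected, abs=1e-12)

    def test_negative_batches_rejected(self):
        with pytest.raises(ValueError):
            detection_probability(0.2, -1)

    def test_joint_product_rule(self):
        assert joint_detection([0.5], [1]) == pytest.approx(0.5)
        assert joint_detection([0.5, 0.5], [1, 1]) == pytest.approx(0.25)
        # an unsampled positive source zeroes the joint probability
        assert joint_detection([0.5, 0.2], [3, 0]) == 0.0
        # zero-prevalence sources are skipped, not zeroing the product
        assert joint_detection([0.5, 0.0], [1, 0]) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.01, 0.99), st.integers(0, 30), st.integers(0, 30))
    def test_monotone_in_batches(self, a, x, dx):
        assert detection_probability(a, x + dx, a and 1.0) >= \
            detection_probability(a, x, 1.0) - 1e-15

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.01, 0.99), st.integers(1, 30),
           st.floats(0.5, 1.0), st.floats(0.5, 1.0))
    def test_lower_sensitivity_never_helps(self, a, x, s1, s2):
        lo, hi = sorted((s1, s2))
        assert detection_probability(a, x, lo) <= detection_probability(a, x, hi) + 1e-15


def _mini_setup():
    """Two-source single-monitor setup with hand-computable quantities."""
    cells = pd.DataFrame({
        "source_province": ["I1", "I2"], "monitoring_province": ["J", "J"],
        "NST": [100, 100], "NSC": [50, 50], "NSC_ant": [50, 50],
        "a": [0.5, 0.5], "a_ant": [0.5, 0.5],
        "source_category": ["internal", "external"]})
    probc = pd.DataFrame({
        "source_province": ["I1", "I2"], "monitoring_province": ["J", "J"],
        "hazard_name": ["A", "A"], "hazard_class": ["antibiotic"] * 2,
        "count": [50, 50], "probc": [0.5, 0.5]})
    marg = pd.DataFrame({"monitoring_province": ["J"], "NST": [200], "NSC": [100],
                         "NSC_ant": [100], "a": [0.5], "a_ant": [0.5]})
    matrix = aq.ContaminationMatrix(cells, probc, marg)
    chq = pd.DataFrame({"source_province": ["I1", "I2"],
                        "monitoring_province": ["J", "J"],
                        "hazard_name": ["A", "A"], "probc": [0.5, 0.5],
                        "hq": [1.2, 1.0], "chq": [0.6, 0.5]})
    hi_partial = pd.DataFrame({"source_province": ["I1", "I2"],
                               "monitoring_province": ["J", "J"],
                               "hi_partial": [0.6, 0.5]})
    hi = pd.DataFrame({"monitoring_province": ["J"], "HI": [1.1],
                       "exceeds_standard": [True]})
    risk = aq.RiskTable(chq, hi_partial, hi)
    vol = pd.DataFrame({"province": ["J", "J"], "year": [2021, 2022],
                        "TV": [100.0, 110.0], "rate_all": [0.5] * 2,
                        "rate_ant": [0.5] * 2, "CTV_all": [50.0, 55.0],
                        "CTV_ant": [50.0, 55.0]})
    loss = aq.TradeVolumeTable(vol, pd.DataFrame(
        columns=["province", "year", "hazard_name", "rate", "CTV"]))
    return matrix, risk, loss


def _alloc(batches, budget=None):
    table = pd.DataFrame({"monitoring_province": ["J"] * len(batches),
                          "source_province": [f"I{i+1}" for i in range(len(batches))],
                          "batches": batches})
    total = int(sum(batches))
    return aq.AllocationMatrix(table, {"J": budget if budget is not None else total})


class TestEvaluateScheme:
    def test_joint_detection_and_saved_risk(self, config):
        matrix, risk, loss = _mini_setup()
        ev = aq.evaluate_scheme(_alloc([1, 1]), matrix, risk, loss, config)
        row = ev.summary.iloc[0]
        assert row["h"] == pytest.approx(0.25)
        assert row["g_ant"] == pytest.approx(0.25)
        # SHI = d1*0.6 + d2*0.5 with d = 0.5 each
        assert row["SHI"] == pytest.approx(0.55)
        assert row["residual_HI"] == pytest.approx(1.1 - 0.55)
        # saved loss, as printed: mean CTV * (1 - a_ant * g)
        assert row["STV_as_printed"] == pytest.approx(52.5 * (1 - 0.5 * 0.25))
        assert row["STV_intercepted"] == pytest.approx(52.5 * 0.25)
        # TV_after from the latest year's volume and the scheme's own h
        assert row["TV_after"] == pytest.approx(110.0 * (1 - 0.5 * 0.25))

    def test_detected_source_saves_its_partial(self, config):
        matrix, risk, loss = _mini_setup()
        # x=(big, 0): d1 ~ 1, d2 = 0 -> SHI ~ 0.6, residual ~ 0.5
        ev = aq.evaluate_scheme(_alloc([60, 0]), matrix, risk, loss, config)
        row = ev.summary.iloc[0]
        assert row["SHI"] == pytest.approx(0.6, abs=1e-6)
        assert row["h"] == 0.0  # one positive source unsampled

    def test_unknown_flow_in_allocation_rejected(self, config):
        matrix, risk, loss = _mini_setup()
        table = pd.DataFrame({"monitoring_province": ["J"], "source_province": ["NOPE"],
                              "batches": [1]})
        with pytest.raises(ValueError, match="NOPE"):
            aq.evaluate_scheme(aq.AllocationMatrix(table, {"J": 1}), matrix, risk,
                               loss, config)

    def test_budget_violation_rejected(self):
        table = pd.DataFrame({"monitoring_province": ["J"], "source_province": ["I1"],
                              "batches": [5]})
        with pytest.raises(ValueError, match="exceeds budget"):
            aq.AllocationMatrix(table, {"J": 4})

    def test_compare_schemes_deltas(self, config):
        matrix, risk, loss = _mini_setup()
        e1 = aq.evaluate_scheme(_alloc([2, 2]), matrix, risk, loss, config)
        e0 = aq.evaluate_scheme(_alloc([1, 1], budget=4), matrix, risk, loss, config)
        comp = aq.compare_schemes(e1, e0)
        row = comp.table.iloc[0]
        assert row["delta_shi"] == pytest.approx(
            e1.summary["SHI"].iloc[0] - e0.summary["SHI"].iloc[0])
        same = aq.compare_schemes(e1, e1)
        assert (same.table[["delta_stv", "delta_shi"]] == 0).all().all()
        assert same.national["delta_shi"] == 0.0


class TestSolvers:
    def test_worked_instance_two_sources(self):
        """I=2, a=(0.5, 0.1), NS=4: optimum x=(2,2), h=0.75*0.19=0.1425."""
        sol = solve_province(np.array([0.5, 0.1]), 4)
        assert list(sol.x) == [2, 2]
        assert sol.h == pytest.approx(0.1425, abs=1e-12)
        oracle = brute_force_province(np.array([0.5, 0.1]), 4)
        assert list(oracle.x) == [2, 2]
        assert oracle.h == pytest.approx(sol.h, abs=1e-15)

    def test_single_source_takes_full_budget(self):
        sol = solve_province(np.array([0.3]), 5)
        assert list(sol.x) == [5]
        assert sol.h == pytest.approx(1 - 0.7**5)

    def test_zero_budget_zero_detection(self):
        sol = solve_province(np.array([0.3, 0.2]), 0)
        assert list(sol.x) == [0, 0] and sol.h == 0.0

    def test_budget_below_source_count_yields_empty_scheme(self):
        sol = solve_province(np.array([0.3, 0.2, 0.1]), 2)
        assert list(sol.x) == [0, 0, 0] and sol.h == 0.0
        oracle = brute_force_province(np.array([0.3, 0.2, 0.1]), 2)
        assert list(oracle.x) == [0, 0, 0]

    def test_oracle_guard(self):
        with pytest.raises(ValueError, match="guard"):
            brute_force_province(np.full(5, 0.1), 3)

    def test_inactive_constraint_matches_unconstrained(self):
        a = np.array([0.4, 0.2])
        free = solve_province(a, 6)
        # a residual-risk floor already satisfied at the unconstrained optimum
        constrained = solve_province(a, 6, a_ant=a, hi_partial=np.array([1.0, 1.0]),
                                     shi_min=0.5)
        assert list(free.x) == list(constrained.x)
        assert free.h == constrained.h

    def test_infeasible_risk_floor_returns_max_saved_risk(self):
        a = np.array([0.05, 0.02])
        hi = np.array([0.3, 0.2])
        sol = solve_province(a, 3, a_ant=a, hi_partial=hi, shi_min=0.45)
        assert not sol.feasible
        oracle = brute_force_province(a, 3, a_ant=a, hi_partial=hi, shi_min=0.45)
        assert not oracle.feasible
        assert sol.shi == pytest.approx(oracle.shi, abs=1e-12)

    def test_greedy_equals_oracle_budget_only(self):
        """Concavity: greedy marginal allocation is exact for the budget-only
        problem, verified against enumeration on a seeded sweep."""
        rng = np.random.default_rng(3)
        for _ in range(120):
            n = int(rng.integers(1, 5))
            budget = int(rng.integers(0, 13))
            a = rng.uniform(0.02, 0.95, n)
            q = 1.0 - a
            x = _greedy_budget(q, budget)
            got = joint_detection(a, x)
            want = brute_force_province(a, budget).h
            assert got == pytest.approx(want, abs=1e-12)

    def test_exact_dp_matches_oracle_with_constraints(self):
        """Exact DP equals enumeration on random instances with and without
        active volume/risk constraints (objective to machine precision)."""
        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(1, 5))
            budget = int(rng.integers(0, 13))
            a = rng.uniform(0.02, 0.9, n)
            a_ant = a * rng.uniform(0.5, 1.0, n)
            hi = rng.uniform(0.0, 1.5, n)
            s = 1.0 if trial % 3 else 0.98
            h_cap = shi_min = None
            kind = trial % 4
            if kind in (1, 3):
                h_cap = solve_province(a, budget, s).h * rng.uniform(0.3, 0.95)
            if kind in (2, 3):
                shi_min = rng.uniform(0.0, hi.sum() * 0.8)
            dp = solve_province(a, budget, s, a_ant, hi, h_cap, shi_min, "exact_dp")
            orc = brute_force_province(a, budget, s, a_ant, hi, h_cap, shi_min)
            assert dp.feasible == orc.feasible
            if dp.feasible:
                assert abs(dp.h - orc.h) <= 1e-12
            else:
                assert abs(dp.shi - orc.shi) <= 1e-9

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10),
           st.lists(st.floats(0.05, 0.9), min_size=1, max_size=4))
    def test_budget_monotonicity(self, budget, a):
        a = np.asarray(a)
        h1 = solve_province(a, budget).h
        h2 = solve_province(a, budget + 1).h
        assert h2 >= h1 - 1e-15

    def test_optimization_audit_recomputes_objective(self, small_pipeline, config):
        """The reported objective re-derives through evaluate_scheme exactly."""
        opt = small_pipeline.optimization
        ev = small_pipeline.optimized_eval
        h = ev.summary.set_index("monitoring_province")["h"]
        for j, obj in opt.objective.items():
            assert h[j] == pytest.approx(obj, abs=1e-12)

    def test_shi_bounded_by_hi(self, small_pipeline):
        ev = small_pipeline.optimized_eval.summary
        hi = small_pipeline.risk.hi.set_index("monitoring_province")["HI"]
        for row in ev.itertuples():
            assert -1e-12 <= row.SHI <= hi[row.monitoring_province] + 1e-12

    def test_optimizer_shifts_batches_away_from_unknown(self, preset_pipeline,
                                                        preset_dataset):
        """Where the external streams are riskier than the unknown stream, the
        optimizer cuts the unknown batch share and raises the external share
        relative to the baseline scheme."""
        base = aq.baseline_allocation(preset_dataset.truth, 1200)
        opt = preset_pipeline.optimization.allocation
        cells = preset_pipeline.matrix.cells.set_index(
            ["monitoring_province", "source_province"])

        def shares(alloc, j):
            sub = alloc.table[alloc.table["monitoring_province"] == j]
            total = sub["batches"].sum()
            by_cat = {}
            for row in sub.itertuples():
                cat = cells.loc[(j, row.source_province), "source_category"]
                by_cat[cat] = by_cat.get(cat, 0) + row.batches
            return {k: v / total for k, v in by_cat.items()}

        checked = 0
        for j in preset_dataset.truth.provinces:
            sub = cells.loc[j]
            ext_a = sub[sub["source_category"] == "external"]["a"].mean()
            unk_a = sub[sub["source_category"] == "unknown"]["a"].mean()
            if not ext_a > unk_a:
                continue
            s_base, s_opt = shares(base, j), shares(opt, j)
            assert s_opt.get("unknown", 0) < s_base.get("unknown", 0)
            assert s_opt.get("external", 0) > s_base.get("external", 0)
            checked += 1
        assert checked >= 15  # the regime holds in most provinces
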