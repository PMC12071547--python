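"""First-principles statistics tests: brute-force pair-counting oracle for
the Mann-Whitney U, enumeration cross-checks for the exact p-value,
closed-form chi-square values, and the Table-1-style report."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, mannwhitneyu, rankdata

from anometry import (
    build_group_report,
    chi_square_2x2,
    constipation_comparison,
    mann_whitney_u,
)
from anometry.metrics import AggregateTriple, PatientSummary
from anometry.stats import holm_adjust

samples = st.lists(
    st.integers(min_value=0, max_value=6).map(float), min_size=1, max_size=8
)


def brute_force_u1(a, b):
    """U1 as the discordant-pair count: sum [a > b] + 0.5 [a == b]."""
    return sum(
        1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
    )


def brute_force_exact_p(a, b):
    """Two-sided exact p over all C(n, n1) group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = min(brute_force_u1(a, b), brute_force_u1(b, a))
    u_max = len(a) * len(b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u1 = brute_force_u1(ga, gb)
        total += 1
        if u1 <= u_obs + 1e-9 or u1 >= u_max - u_obs - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_gives_zero(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic_value == 0.0
        assert res.extra["u1"] == 0.0
        assert res.extra["u2"] == 9.0

    def test_identical_fully_tied_samples(self):
        res = mann_whitney_u([5, 5, 5], [5, 5, 5], method="normal")
        assert res.extra["u1"] == 4.5
        assert res.extra["u2"] == 4.5
        assert res.p_value == 1.0
        assert res.z_value is None  # zero variance under full ties

    def test_u_matches_brute_force_pair_counting(self, rng):
        # 200 random small-sample pairs with ties
        for _ in range(200):
            n1, n2 = rng.integers(1, 9, size=2)
            a = rng.integers(0, 6, size=n1).astype(float)
            b = rng.integers(0, 6, size=n2).astype(float)
            res = mann_whitney_u(a, b, method="normal")
            u1 = brute_force_u1(a, b)
            assert res.extra["u1"] == pytest.approx(u1)
            assert res.statistic_value == pytest.approx(min(u1, n1 * n2 - u1))

    @given(a=samples, b=samples)
    def test_u1_plus_u2_identity(self, a, b):
        res = mann_whitney_u(a, b, method="normal")
        assert res.extra["u1"] + res.extra["u2"] == pytest.approx(len(a) * len(b))
        assert 0 <= res.statistic_value <= len(a) * len(b) / 2

    @given(a=samples, b=samples)
    def test_invariant_under_monotone_transform(self, a, b):
        base = mann_whitney_u(a, b, method="normal")
        transformed = mann_whitney_u(
            np.exp(0.5 * np.asarray(a)), np.exp(0.5 * np.asarray(b)), method="normal"
        )
        assert transformed.statistic_value == pytest.approx(base.statistic_value)
        assert transformed.p_value == pytest.approx(base.p_value)

    def test_exact_p_matches_assignment_enumeration(self, rng):
        # DP-based exact p against the brute-force enumeration of all
        # group assignments, on small samples with ties
        for _ in range(25):
            n1, n2 = rng.integers(2, 6, size=2)
            a = rng.integers(0, 4, size=n1).astype(float)
            b = rng.integers(0, 4, size=n2).astype(float)
            res = mann_whitney_u(a, b, method="exact")
            assert res.p_value == pytest.approx(brute_force_exact_p(a, b))

    def test_exact_p_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=7)
            res = mann_whitney_u(a, b, method="exact")
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_p_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        res = mann_whitney_u(a, b, method="normal")
        ref = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_close_to_exact_for_moderate_n(self, rng):
        # Without heavy ties the uncorrected normal approximation tracks
        # the exact enumeration for n1, n2 >= 8: within 0.05 everywhere
        # and within 0.01 in the decision-relevant tail (exact p <= 0.1).
        # Near the null center the discrete point mass makes the exact p
        # up to ~0.046 larger at n = 8 (verified by full enumeration of
        # the U distribution) -- a feature of the no-continuity-correction
        # convention, not an implementation gap.
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(loc=rng.uniform(-1, 1), size=8)
            res = mann_whitney_u(a, b, method="exact")
            gap = abs(res.extra["p_normal"] - res.p_value)
            assert gap < 0.05
            if res.p_value <= 0.1:
                assert gap < 0.01

    def test_auto_switches_on_problem_size(self):
        small = mann_whitney_u([1, 2], [3, 4])
        assert small.method == "exact"
        big = mann_whitney_u(np.arange(21), np.arange(21) + 0.5)
        assert big.method == "normal"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u1_definition_via_rank_sum(self, rng):
        # U1 = R1 - n1(n1+1)/2 with midranks
        a = rng.integers(0, 5, size=6).astype(float)
        b = rng.integers(0, 5, size=9).astype(float)
        ranks = rankdata(np.concatenate([a, b]))
        u1 = ranks[:6].sum() - 6 * 7 / 2
        assert mann_whitney_u(a, b).extra["u1"] == pytest.approx(u1)


class TestChiSquare:
    def test_perfect_association(self):
        res = chi_square_2x2([[10, 0], [0, 10]])
        assert res.statistic_value == pytest.approx(20.0)
        assert res.df == 1

    def test_independence(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic_value == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_inferred_constipation_table(self):
        # the only integer table consistent with 9 constipated in a 12/26
        # split: X^2 ~ 3.14 from the closed form
        res = chi_square_2x2([[5, 7], [4, 22]])
        assert res.statistic_value == pytest.approx(3.1377, abs=1e-4)

    @given(
        cells=st.lists(st.integers(min_value=1, max_value=40), min_size=4, max_size=4)
    )
    def test_invariant_under_transpose_and_swaps(self, cells):
        a, b, c, d = cells
        base = chi_square_2x2([[a, b], [c, d]]).statistic_value
        assert chi_square_2x2([[a, c], [b, d]]).statistic_value == pytest.approx(base)
        assert chi_square_2x2([[c, d], [a, b]]).statistic_value == pytest.approx(base)
        assert chi_square_2x2([[b, a], [d, c]]).statistic_value == pytest.approx(base)

    @given(
        cells=st.lists(st.integers(min_value=1, max_value=40), min_size=4, max_size=4)
    )
    def test_matches_scipy_contingency(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        mine = chi_square_2x2(table)
        ref = chi2_contingency(np.array(table), correction=False)
        assert mine.statistic_value == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)
        yates = chi_square_2x2(table, yates=True)
        ref_yates = chi2_contingency(np.array(table), correction=True)
        assert yates.statistic_value == pytest.approx(ref_yates.statistic)

    def test_zero_marginal_is_a_finding_not_a_crash(self):
        res = chi_square_2x2([[0, 0], [5, 7]])
        assert res.statistic_value is None
        assert res.p_value is None
        assert any(f.code == "zero-marginal" for f in res.findings)

    def test_small_expected_counts_warn(self):
        res = chi_square_2x2([[1, 11], [0, 26]])
        assert any(f.code == "small-counts" for f in res.findings)
        assert res.statistic_value is not None

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            chi_square_2x2([[-1, 2], [3, 4]])


def patient(pid, group, circ, ant, ratio, constipated=None):
    t = lambda v: AggregateTriple(0.9 * v, v, 1.1 * v)
    return PatientSummary(
        patient_id=pid,
        n_maneuvers_used=3,
        n_maneuvers_dropped=0,
        circumferential=t(circ),
        anterior=t(ant),
        ratio=t(ratio),
        group_label=group,
        constipated=constipated,
    )


class TestGroupReport:
    def cohort(self, rng, n_a=10, n_b=14, shift=0.0):
        out = []
        for i in range(n_a):
            out.append(
                patient(f"a{i}", "A", rng.normal(105, 20), rng.normal(60 + shift, 12), rng.normal(0.55, 0.1))
            )
        for i in range(n_b):
            out.append(
                patient(f"b{i}", "B", rng.normal(140, 25), rng.normal(135, 20), rng.normal(0.9, 0.1))
            )
        return out

    def test_nine_rows_and_group_means(self, rng):
        report = build_group_report(self.cohort(rng))
        t = report.table
        assert len(t) == 9
        assert set(t["metric"]) == {"circumferential", "anterior", "ratio"}
        assert set(t["aggregate"]) == {"min", "mean", "max"}
        row = t[(t["metric"] == "anterior") & (t["aggregate"] == "mean")].iloc[0]
        assert row["group_a_mean"] < row["group_b_mean"]
        assert row["n_a"] == 10 and row["n_b"] == 14

    def test_identical_groups_give_p_one(self):
        group_a = [patient(f"a{i}", "A", 100, 80, 0.8) for i in range(3)]
        group_b = [patient(f"b{i}", "B", 100, 80, 0.8) for i in range(3)]
        report = build_group_report(group_a + group_b)
        assert (report.table["p_value"] == 1.0).all()

    def test_single_patient_per_group_u_values(self):
        report = build_group_report(
            [patient("a", "A", 90, 55, 0.5), patient("b", "B", 150, 140, 0.95)]
        )
        assert set(report.table["u_statistic"]) <= {0.0, 0.5, 1.0}

    def test_holm_adjustment_monotone(self, rng):
        report = build_group_report(self.cohort(rng), holm=True)
        t = report.table
        assert (t["p_holm"] >= t["p_value"] - 1e-12).all()
        assert (t["p_holm"] <= 1.0).all()

    def test_maneuver_unit_produces_three_rows(self, rng):
        import pandas as pd

        maneuvers = pd.DataFrame(
            {
                "group": ["A"] * 20 + ["B"] * 30,
                "mean_circumferential": rng.normal(110, 20, 50),
                "mean_anterior": np.r_[rng.normal(60, 10, 20), rng.normal(135, 20, 30)],
                "ratio": rng.uniform(0.3, 1.1, 50),
            }
        )
        report = build_group_report(
            [], unit_of_analysis="maneuver", maneuver_table=maneuvers
        )
        assert len(report.table) == 3
        assert (report.table["aggregate"] == "per-maneuver").all()

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="per group"):
            build_group_report([patient("a", "A", 100, 60, 0.5)])

    def test_markdown_rendering_contains_all_rows(self, rng):
        md = build_group_report(self.cohort(rng)).to_markdown()
        assert md.count("anterior") == 3

    def test_holm_adjust_known_values(self):
        adj = holm_adjust(np.array([0.01, 0.04, 0.03]))
        assert adj == pytest.approx([0.03, 0.06, 0.06])


class TestConstipation:
    def test_table_and_rates(self):
        cohort = (
            [patient(f"a{i}", "A", 100, 60, 0.5, constipated=i < 5) for i in range(12)]
            + [patient(f"b{i}", "B", 140, 135, 0.9, constipated=i < 4) for i in range(26)]
        )
        res = constipation_comparison(cohort)
        assert res.extra["table"] == [[5, 7], [4, 22]]
        assert res.extra["rate_a"] == pytest.approx(5 / 12)
        assert res.extra["rate_b"] == pytest.approx(4 / 26)
        assert res.statistic_value == pytest.approx(3.1377, abs=1e-4)

    def test_all_false_flags_zero_marginal_finding(self):
        cohort = [patient(f"a{i}", "A", 100, 60, 0.5, constipated=False) for i in range(3)] + [
            patient(f"b{i}", "B", 140, 135, 0.9, constipated=False) for i in range(3)
        ]
        res = constipation_comparison(cohort)
        assert res.statistic_value is None
        assert any(f.code == "zero-marginal" for f in res.findings)

    def test_unknown_flags_excluded_and_counted(self):
        cohort = (
            [patient(f"a{i}", "A", 100, 60, 0.5, constipated=True) for i in range(4)]
            + [patient("a9", "A", 100, 60, 0.5, constipated=None)]
            + [patient(f"b{i}", "B", 140, 135, 0.9, constipated=(i == 0)) for i in range(6)]
        )
        res = constipation_comparison(cohort)
        assert res.extra["excluded"] == 1
        assert sum(sum(row) for row in res.extra["table"]) == 10
        assert any(f.code == "excluded-patients" for f in res.findings)

    def test_single_constipated_patient_warns_small_counts(self):
        cohort = [patient(f"a{i}", "A", 100, 60, 0.5, constipated=(i == 0)) for i in range(6)] + [
            patient(f"b{i}", "B", 140, 135, 0.9, constipated=False) for i in range(8)
        ]
        res = constipation_comparison(cohort)
        assert res.statistic_value is not None
        assert any(f.code == "small-counts" for f in res.findings)
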