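"""t-test, post-hoc power, gating, correlations, heat-map and volcano."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from plexquant.design import ValidationError
from plexquant.differential import (
    Thresholds,
    differential_table,
    heatmap_scale,
    posthoc_power,
    power_from_d,
    significant_set,
    student_ttest,
    treatment_correlation,
    volcano_table,
)
from plexquant.quantify import merge_common, relative_abundance
from plexquant.simulate import generate_truth, paper_design, simulate_plexes

from conftest import make_matrix

# 3-decimal grid keeps shift-invariance numerically exact to rounding noise
finite_floats = st.floats(
    min_value=0.1, max_value=10, allow_nan=False, allow_infinity=False
).map(lambda v: round(v, 3))


def mc_rejection_rate(d: float, n: int, n_sim: int, rng) -> tuple[float, float]:
    """Monte-Carlo oracle: empirical two-sided pooled-t rejection rate at
    level 0.05 for normal groups separated by d pooled-sd units.
    Returns (rate, binomial standard error)."""
    x = rng.normal(d, 1.0, (n_sim, n))
    y = rng.normal(0.0, 1.0, (n_sim, n))
    p = stats.ttest_ind(x, y, axis=1, equal_var=True).pvalue
    rate = float((p < 0.05).mean())
    se = float(np.sqrt(rate * (1 - rate) / n_sim)) or 1.0 / n_sim
    return rate, se


class TestStudentTTest:
    def test_identical_groups_give_p_one(self):
        assert student_ttest([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]) == 1.0

    def test_hand_computed_example(self):
        # x=(1,2,3), y=(2,3,4): pooled sd = 1, se = sqrt(2/3),
        # t = -1/sqrt(2/3) = -1.2247, df = 4 -> p = 0.2878
        p = student_ttest([1, 2, 3], [2, 3, 4])
        assert p == pytest.approx(0.28783, abs=2e-4)

    def test_zero_variance_edges(self):
        assert student_ttest([1.0, 1.0], [1.0, 1.0]) == 1.0
        assert student_ttest([1.0, 1.0], [2.0, 2.0]) == 0.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            student_ttest([1.0], [1.0, 2.0])

    @given(
        x=st.lists(finite_floats, min_size=2, max_size=5),
        y=st.lists(finite_floats, min_size=2, max_size=5),
        shift=st.floats(min_value=-5, max_value=5, allow_nan=False).map(
            lambda v: round(v, 3)
        ),
    )
    def test_symmetry_and_shift_invariance(self, x, y, shift):
        p_xy = student_ttest(x, y)
        assert student_ttest(y, x) == pytest.approx(p_xy, rel=1e-9)
        x2 = [v + shift for v in x]
        y2 = [v + shift for v in y]
        assert student_ttest(x2, y2) == pytest.approx(p_xy, rel=1e-6, abs=1e-9)

    def test_null_pvalues_are_calibrated(self):
        """On independent log-normal null groups (n = 3) the empirical
        rejection rate at α = 0.05 is 5% within Monte-Carlo error."""
        rng = np.random.default_rng(2024)
        x = np.exp(rng.normal(0, 0.02, (10_000, 3)))
        y = np.exp(rng.normal(0, 0.02, (10_000, 3)))
        p = stats.ttest_ind(x, y, axis=1, equal_var=True).pvalue
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 10_000))


class TestPosthocPower:
    def test_zero_effect_power_equals_alpha(self):
        assert power_from_d(0.0, 3, 3, alpha=0.05) == pytest.approx(0.05, abs=1e-10)
        assert posthoc_power([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(
            0.05, abs=1e-10
        )

    def test_huge_effect_saturates(self):
        assert power_from_d(10.0, 3, 3) > 0.999

    def test_large_noncentrality_stays_finite(self):
        # the opposite-tail term must not poison the result at extreme d
        p = power_from_d(np.array([0.0, 5.0, 25.0, 100.0]), 3, 3)
        assert np.all(np.isfinite(p))
        assert np.all((0 <= p) & (p <= 1))
        assert p[-1] > 0.9999

    def test_monte_carlo_oracle_at_observed_d(self):
        """Power at d = 2.5, n = 3 matches the simulated rejection rate."""
        rng = np.random.default_rng(11)
        rate, se = mc_rejection_rate(2.5, 3, 100_000, rng)
        assert power_from_d(2.5, 3, 3) == pytest.approx(rate, abs=max(3 * se, 0.005))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        solver = TTestIndPower()
        for d in (0.2, 0.5, 1.0, 2.0, 4.0):
            for n in (3, 5, 10):
                expected = solver.power(
                    effect_size=d, nobs1=n, ratio=1.0, alpha=0.05, alternative="two-sided"
                )
                assert power_from_d(d, n, n) == pytest.approx(expected, abs=1e-6)

    def test_monotonicity_grid(self):
        """Power rises with |effect| and replicate count, falls with sd."""
        ds = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        p = power_from_d(ds, 3, 3)
        assert np.all(np.diff(p) > 0)
        for d in (0.5, 1.0, 2.0):
            pn = [power_from_d(d, n, n) for n in (3, 5, 10, 20)]
            assert np.all(np.diff(pn) > 0)
        # widening the within-group spread at fixed mean difference
        # lowers the observed d, hence the power
        narrow = posthoc_power([1.0, 1.2, 1.4], [2.0, 2.2, 2.4])
        wide = posthoc_power([0.8, 1.2, 1.6], [1.8, 2.2, 2.6])
        assert wide < narrow

    def test_zero_sd_edges(self):
        assert posthoc_power([1.0, 1.0], [2.0, 2.0]) == 1.0
        assert posthoc_power([1.0, 1.0], [1.0, 1.0]) == 0.05


class TestDifferentialTable:
    def test_constant_protein_has_no_flags(self):
        m = make_matrix(
            {"P1": [1.0, 1.0, 1.0, 1.0], "P2": [2.0, 2.1, 1.0, 1.05]},
            {
                "t1": ("p1", "treat", 1),
                "t2": ("p1", "treat", 2),
                "c1": ("p1", "ctrl", 1),
                "c2": ("p1", "ctrl", 2),
            },
        )
        table = differential_table(m, "ctrl")
        row = table[table["protein"] == "P1"].iloc[0]
        assert row["degenerate"]
        assert not row[["pass_power", "pass_p", "pass_fc"]].any()
        row2 = table[table["protein"] == "P2"].iloc[0]
        assert row2["ratio"] == pytest.approx(2.0, abs=0.01)
        assert row2["pass_fc"]

    def test_single_replicate_group_is_an_error(self):
        m = make_matrix(
            {"P1": [1.0, 1.0, 1.0]},
            {"t1": ("p1", "treat", 1), "c1": ("p1", "ctrl", 1), "c2": ("p1", "ctrl", 2)},
        )
        with pytest.raises(ValidationError, match="treat"):
            differential_table(m, "ctrl")

    def test_missing_control_is_an_error(self, paper_merged):
        with pytest.raises(ValidationError, match="nothere"):
            differential_table(paper_merged, "nothere")

    def test_recovery_on_planted_effects(self):
        """1,000 proteins, 10% perturbed at ratio 1.5, σ = 0.05: the p+fc
        gate recovers ≥ 90% of true effects with ≤ 7% false positives."""
        truth = generate_truth(
            n_proteins=1000,
            n_pathways=5,
            frac_de=0.1,
            effect_range=(1.5, 1.5),
            sigma=0.05,
            dropout=0.0,
            seed=4242,
        )
        designs = paper_design()
        tables = simulate_plexes(truth, designs)
        merged = merge_common(
            [relative_abundance(t, d) for t, d in zip(tables, designs)]
        )
        table = differential_table(merged, "DMSO")
        for t in truth.treatments:
            sig = significant_set(table, t, "p_fc")
            de = truth.de_sets[t]
            recall = len(sig & de) / len(de)
            fpr = len(sig - de) / (len(merged.proteins) - len(de))
            assert recall >= 0.9, t
            assert fpr <= 0.07, t

    def test_both_gates_coexist(self, paper_diff):
        """Power-gate and p-gate run on the same table without
        interference and select different (non-nested) protein sets."""
        t = paper_diff["treatment"].iloc[0]
        by_p = significant_set(paper_diff, t, "p")
        by_power = significant_set(paper_diff, t, "power")
        assert by_p and by_power
        assert by_p != by_power

    def test_strong_hit_dominates_volcano(self):
        """A planted strong effect (ratio 3, tiny variance) has the
        largest −log10 p of its treatment."""
        rng = np.random.default_rng(3)
        values = {
            f"P{i}": list(1 + 0.02 * rng.standard_normal(4)) for i in range(50)
        }
        values["HIT"] = [3.0, 3.001, 1.0, 1.001]
        m = make_matrix(
            values,
            {
                "t1": ("p1", "treat", 1),
                "t2": ("p1", "treat", 2),
                "c1": ("p1", "ctrl", 1),
                "c2": ("p1", "ctrl", 2),
            },
        )
        table = differential_table(m, "ctrl")
        volc = volcano_table(table, fc_floor=0.15)
        top = volc.loc[volc["neg_log10_p"].idxmax(), "protein"]
        assert top == "HIT"


class TestCorrelation:
    def test_identical_profiles(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B", "C"] * 2,
                "treatment": ["t1"] * 3 + ["t2"] * 3,
                "ratio": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        assert treatment_correlation(table, {"A", "B", "C"}, "t1", "t2") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B", "C"] * 2,
                "treatment": ["t1"] * 3 + ["t2"] * 3,
                "ratio": [1.0, 2.0, 3.0, 3.0, 2.0, 1.0],
            }
        )
        assert treatment_correlation(table, {"A", "B", "C"}, "t1", "t2") == pytest.approx(-1.0)

    def test_small_subset_rejected(self):
        table = pd.DataFrame(
            {"protein": ["A", "B"], "treatment": ["t1", "t2"], "ratio": [1.0, 2.0]}
        )
        with pytest.raises(ValidationError, match="at least 3"):
            treatment_correlation(table, {"A"}, "t1", "t2")

    def test_zero_variance_is_nan(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B", "C"] * 2,
                "treatment": ["t1"] * 3 + ["t2"] * 3,
                "ratio": [1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
            }
        )
        assert np.isnan(treatment_correlation(table, {"A", "B", "C"}, "t1", "t2"))


class TestHeatmapAndVolcano:
    def test_row_scaling(self):
        m = make_matrix(
            {"P1": [2.0, 4.0, 8.0], "P2": [5.0, 5.0, 5.0]},
            {
                "s1": ("p1", "g", 1),
                "s2": ("p1", "g", 2),
                "s3": ("p1", "g", 3),
            },
        )
        scaled = heatmap_scale(m)
        assert list(scaled.loc["P1"]) == [0.25, 0.5, 1.0]
        assert list(scaled.loc["P2"]) == [1.0, 1.0, 1.0]

    def test_row_maxima_are_one(self, paper_merged):
        sub = set(list(paper_merged.proteins)[:100])
        scaled = heatmap_scale(paper_merged, sub)
        assert np.allclose(scaled.max(axis=1), 1.0)

    def test_unknown_protein_rejected(self, paper_merged):
        with pytest.raises(ValidationError, match="not in matrix"):
            heatmap_scale(paper_merged, {"NOPE"})

    def test_volcano_threshold_arithmetic(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B", "C"],
                "treatment": "t",
                "ratio": [1.5, 1.0, 0.7],
                "p_value": [0.049, 0.001, 0.2],
            }
        )
        v = volcano_table(table, fc_floor=0.15)
        # unchanged protein excluded at any positive floor; p >= 0.05 excluded
        assert list(v["protein"]) == ["A"]
        assert v["neg_log10_p"].iloc[0] == pytest.approx(-np.log10(0.049), abs=1e-9)
        assert -np.log10(0.05) == pytest.approx(1.301, abs=1e-3)

    def test_volcano_floor_05(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B"],
                "treatment": "t",
                "ratio": [1.4, 1.6],
                "p_value": [0.01, 0.01],
            }
        )
        v = volcano_table(table, fc_floor=0.5)
        assert list(v["protein"]) == ["B"]
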