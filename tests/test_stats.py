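"""Oracle and property tests for the statistical battery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from avatarlab.stats import (
    RCI_THRESHOLD,
    ComputationError,
    InsufficientDataError,
    epsilons,
    goldstein_healy_level,
    holm_adjust,
    icc_repeated,
    kappa_agreement,
    mendoza_test,
    mixed_anova,
    mixed_anova_arrays,
    planned_comparisons,
    rci,
    rci_table,
)


# ---------------------------------------------------------------------------
# epsilons

FIXED_COV_4 = np.array(
    [
        [2.0, 0.8, 0.5, 0.2],
        [0.8, 1.5, 0.6, 0.3],
        [0.5, 0.6, 1.8, 0.4],
        [0.2, 0.3, 0.4, 1.2],
    ]
)


class TestEpsilons:
    def test_gg_matches_eigenvalue_oracle(self):
        """GG epsilon equals (sum lambda)^2 / ((k-1) sum lambda^2) on the
        double-centered covariance — an independent eigen-decomposition route."""
        k = 4
        P = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(P @ FIXED_COV_4 @ P)
        oracle = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        gg, _ = epsilons(FIXED_COV_4, n=20, g=2)
        assert gg == pytest.approx(oracle, abs=1e-10)

    def test_compound_symmetry_gives_one(self):
        cs = 0.6 * np.ones((6, 6)) + 0.4 * np.eye(6)
        gg, hf = epsilons(cs, n=32, g=2)
        assert gg == pytest.approx(1.0, abs=1e-12)
        assert hf == 1.0

    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_ordering(self, seed):
        """1/(k-1) <= GG <= HF <= 1 for arbitrary PSD covariances."""
        rng = np.random.default_rng(seed)
        k = 6
        A = rng.normal(size=(k + 3, k))
        S = A.T @ A
        gg, hf = epsilons(S, n=32, g=2)
        assert 1.0 / (k - 1) - 1e-12 <= gg <= 1.0 + 1e-12
        assert gg <= hf <= 1.0

    def test_asymmetric_rejected(self):
        S = FIXED_COV_4.copy()
        S[0, 1] = 99.0
        with pytest.raises(ValueError, match="symmetric"):
            epsilons(S, n=20, g=2)


# ---------------------------------------------------------------------------
# multisample sphericity

class TestMendoza:
    def test_two_levels_is_vacuous(self):
        rng = np.random.default_rng(0)
        res = mendoza_test([rng.normal(size=(10, 2)), rng.normal(size=(12, 2))])
        assert res.p == 1.0

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InsufficientDataError):
            mendoza_test([rng.normal(size=(2, 6)), rng.normal(size=(16, 6))])

    def test_power_against_strong_violation(self):
        """AR(1) rho=0.9 with heterogeneous variances, n=200/group: near-certain rejection."""
        k = 6
        rho = 0.9
        sd = np.sqrt(np.linspace(1.0, 4.0, k))
        S = np.outer(sd, sd) * rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        L = np.linalg.cholesky(S)
        rng = np.random.default_rng(3)
        rejections = sum(
            mendoza_test([rng.normal(size=(200, k)) @ L.T, rng.normal(size=(200, k)) @ L.T]).p
            < 0.05
            for _ in range(100)
        )
        assert rejections > 90


# ---------------------------------------------------------------------------
# mixed ANOVA

def split_plot_oracle(groups):
    """Hand-decomposed expected-mean-squares computation with explicit loops."""
    g = len(groups)
    k = len(groups[0][0])
    ns = [len(m) for m in groups]
    N = sum(ns)
    flat = [x for m in groups for row in m for x in row]
    grand = sum(flat) / len(flat)
    ss_group = 0.0
    for m in groups:
        gm = sum(x for row in m for x in row) / (len(m) * k)
        ss_group += len(m) * k * (gm - grand) ** 2
    ss_subj = 0.0
    for m in groups:
        gm = sum(x for row in m for x in row) / (len(m) * k)
        for row in m:
            ss_subj += k * (sum(row) / k - gm) ** 2
    ss_time = 0.0
    for j in range(k):
        tm = sum(m[i][j] for m in groups for i in range(len(m))) / N
        ss_time += N * (tm - grand) ** 2
    ss_int = 0.0
    for m in groups:
        gm = sum(x for row in m for x in row) / (len(m) * k)
        for j in range(k):
            cm = sum(row[j] for row in m) / len(m)
            tm = sum(mm[i][j] for mm in groups for i in range(len(mm))) / N
            ss_int += len(m) * (cm - gm - tm + grand) ** 2
    ss_err = 0.0
    for m in groups:
        gm = sum(x for row in m for x in row) / (len(m) * k)
        for row in m:
            sm = sum(row) / k
            for j in range(k):
                cm = sum(r[j] for r in m) / len(m)
                ss_err += (row[j] - sm - cm + gm) ** 2
    F_group = (ss_group / (g - 1)) / (ss_subj / (N - g))
    F_time = (ss_time / (k - 1)) / (ss_err / ((N - g) * (k - 1)))
    F_int = (ss_int / ((g - 1) * (k - 1))) / (ss_err / ((N - g) * (k - 1)))
    return F_group, F_time, F_int


TOY_GROUPS = [
    [[3.0, 5.0, 6.0, 9.0], [2.0, 4.0, 7.0, 8.0]],
    [[4.0, 4.0, 5.0, 5.0], [6.0, 5.0, 6.0, 7.0]],
]


class TestMixedAnova:
    def test_toy_table_matches_hand_oracle(self):
        oracle = split_plot_oracle(TOY_GROUPS)
        res = mixed_anova_arrays([np.array(m) for m in TOY_GROUPS])
        assert res["group"].F == pytest.approx(oracle[0], abs=1e-8)
        assert res["time"].F == pytest.approx(oracle[1], abs=1e-8)
        assert res["interaction"].F == pytest.approx(oracle[2], abs=1e-8)

    def test_matches_pingouin_on_unbalanced_data(self):
        """Independent cross-check against an established implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        rows = []
        for gname, n in (("a", 7), ("b", 5)):
            for i in range(n):
                base = rng.normal()
                for j in range(1, 7):
                    rows.append(
                        {"participant_id": f"{gname}{i}", "group": gname,
                         "interview_index": j,
                         "y": base + 0.3 * j * (gname == "a") + rng.normal()}
                    )
        tab = pd.DataFrame(rows)
        mine = mixed_anova(tab, "y")
        ref = pg.mixed_anova(data=tab, dv="y", within="interview_index",
                             subject="participant_id", between="group")
        by_source = {row["Source"]: row for _, row in ref.iterrows()}
        assert mine["group"].F == pytest.approx(by_source["group"]["F"], rel=1e-9)
        assert mine["time"].F == pytest.approx(by_source["interview_index"]["F"], rel=1e-9)
        assert mine["interaction"].F == pytest.approx(by_source["Interaction"]["F"], rel=1e-9)
        assert mine["time"].partial_eta_sq == pytest.approx(
            by_source["interview_index"]["np2"], rel=1e-9
        )

    def test_constant_dv_is_computation_error(self):
        const = [np.full((4, 6), 3.0), np.full((5, 6), 3.0)]
        with pytest.raises(ComputationError):
            mixed_anova_arrays(const)

    def test_missing_cells_name_participants(self, metrics_table):
        broken = metrics_table.drop(index=metrics_table.index[0])
        with pytest.raises(ValueError, match="missing interview cells"):
            mixed_anova(broken, "prop_recommended")

    @pytest.mark.parametrize("target_eps,expected", [(0.55, "GG"), (0.95, "HF")])
    def test_epsilon_threshold_rule(self, target_eps, expected):
        """GG below 0.75, HF at or above it — the two-branch correction rule."""
        k = 6
        if target_eps < 0.75:
            sd = np.sqrt(np.linspace(1.0, 6.0, k))
            S = np.outer(sd, sd) * 0.85 ** np.abs(
                np.subtract.outer(np.arange(k), np.arange(k))
            )
        else:
            S = 0.4 * np.ones((k, k)) + 0.6 * np.eye(k)
        L = np.linalg.cholesky(S)
        rng = np.random.default_rng(17)
        groups = [rng.normal(size=(40, k)) @ L.T for _ in range(2)]
        res = mixed_anova_arrays(groups)
        assert (res["time"].epsilon_gg >= 0.75) == (expected == "HF")
        assert res["time"].correction_used == expected
        assert res["time"].df1_corrected < res["time"].df1 or res["time"].epsilon_hf == 1.0

    def test_observed_power_in_unit_interval(self, metrics_table):
        res = mixed_anova(metrics_table, "factor")
        for eff in res.values():
            assert 0.0 <= eff.observed_power <= 1.0
            assert 0.0 <= eff.partial_eta_sq <= 1.0


# ---------------------------------------------------------------------------
# planned comparisons + Holm

class TestPlannedComparisons:
    def test_identical_groups_yield_null_results(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(8, 6))
        rows = []
        for gname in ("feedback", "control"):
            for i in range(8):
                for j in range(6):
                    rows.append({"participant_id": f"{gname}{i}", "group": gname,
                                 "interview_index": j + 1, "y": m[i, j]})
        res = planned_comparisons(pd.DataFrame(rows), "y")
        assert len(res) == 6
        for c in res:
            assert c.F == pytest.approx(0.0, abs=1e-20)
            assert c.p_holm == pytest.approx(1.0)
            assert not c.significant

    def test_f_equals_t_squared(self, metrics_table):
        res = planned_comparisons(metrics_table, "prop_recommended")
        sub = metrics_table[metrics_table["interview_index"] == 4]
        x = sub.loc[sub["group"] == "control", "prop_recommended"]
        y = sub.loc[sub["group"] == "feedback", "prop_recommended"]
        t, p = sps.ttest_ind(x, y, equal_var=True)
        c4 = next(c for c in res if c.interview_index == 4)
        assert c4.F == pytest.approx(t ** 2, rel=1e-10)
        assert c4.p_raw == pytest.approx(p, rel=1e-9)

    def test_family_size_is_six(self, metrics_table):
        assert len(planned_comparisons(metrics_table, "factor")) == 6


class TestHolm:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([1.0, 1.0], [1.0, 1.0]),
            ([0.3, 0.01, 0.04, 0.002, 0.9, 0.04], None),  # checked vs statsmodels
        ],
    )
    def test_step_down_definition(self, pvals, expected):
        got = holm_adjust(pvals)
        if expected is not None:
            assert got == pytest.approx(expected)
        sm = pytest.importorskip("statsmodels.stats.multitest")
        assert got == pytest.approx(sm.multipletests(pvals, method="holm")[1].tolist())

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_dominates_raw_and_bonferroni(self, pvals):
        adj = holm_adjust(pvals)
        m = len(pvals)
        for raw, a in zip(pvals, adj):
            assert a >= raw - 1e-15
            assert a <= min(1.0, m * raw) + 1e-12  # never exceeds Bonferroni

    def test_fwer_controlled_under_null(self):
        """2,000 null families of 6: familywise error rate stays near/below alpha."""
        rng = np.random.default_rng(8)
        fwer = 0
        for _ in range(2000):
            adj = holm_adjust(rng.uniform(size=6))
            fwer += min(adj) < 0.05
        mc_se = math.sqrt(0.05 * 0.95 / 2000)
        assert fwer / 2000 <= 0.05 + 2 * mc_se


# ---------------------------------------------------------------------------
# RCI / ICC

class TestRCI:
    def test_no_change_is_zero(self):
        res = rci(44.0, 44.0, sd_baseline=23.6, icc=0.5)
        assert res.rci == 0.0
        assert not res.reliable
        assert res.direction == "none"

    def test_formula_evaluation(self):
        res = rci(44.1, 64.1, sd_baseline=23.6, icc=0.5)
        assert res.rci == pytest.approx(20.0 / 23.6, abs=1e-9)
        assert not res.reliable

    def test_threshold_is_90pct_two_sided(self):
        assert RCI_THRESHOLD == pytest.approx(sps.norm.isf(0.05), abs=5e-4)
        denom = 10.0 * math.sqrt(2 * (1 - 0.5))
        just_over = rci(0.0, 1.6500001 * denom, 10.0, 0.5)
        assert just_over.reliable and just_over.direction == "increase"
        just_under = rci(0.0, 1.63 * denom, 10.0, 0.5)
        assert not just_under.reliable

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rci(0.0, 1.0, sd_baseline=0.0, icc=0.5)
        with pytest.raises(ValueError):
            rci(0.0, 1.0, sd_baseline=1.0, icc=1.0)

    def test_rci_table_structure(self, metrics_table):
        tab = rci_table(metrics_table, "prop_recommended")
        assert len(tab) == 32
        assert set(tab["group"]) == {"feedback", "control"}
        assert (tab["reliable"] == (tab["rci"].abs() > RCI_THRESHOLD)).all()


class TestICC:
    def test_pure_between_variance_approaches_one(self):
        base = np.arange(10, dtype=float)
        m = np.tile(base[:, None], (1, 6)) + 1e-6 * np.random.default_rng(0).normal(size=(10, 6))
        assert icc_repeated(m) > 0.999

    def test_iid_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(5000, 6))
        assert icc_repeated(m) == pytest.approx(0.0, abs=0.02)

    def test_recovers_variance_ratio(self):
        """sigma_b = sigma_e = 1 gives ICC(1) = 0.5."""
        rng = np.random.default_rng(2)
        n = 10_000
        m = rng.normal(size=(n, 1)) + rng.normal(size=(n, 6))
        assert icc_repeated(m) == pytest.approx(0.5, abs=0.02)

    def test_consistency_variant_removes_occasion_effect(self):
        rng = np.random.default_rng(3)
        occasion = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        m = rng.normal(size=(2000, 1)) + occasion[None, :] + rng.normal(size=(2000, 6))
        assert icc_repeated(m, "consistency") == pytest.approx(0.5, abs=0.03)
        assert icc_repeated(m, "oneway") < icc_repeated(m, "consistency")

    def test_missing_cells_rejected(self):
        m = np.ones((5, 6))
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_repeated(m)


# ---------------------------------------------------------------------------
# kappa

class TestKappa:
    def test_perfect_agreement(self):
        pairs = [("a", "a"), ("b", "b"), ("a", "a"), ("c", "c")]
        assert kappa_agreement(pairs).kappa == pytest.approx(1.0)

    def test_chance_level_table(self):
        pairs = (
            [("x", "x")] * 25 + [("x", "y")] * 25 + [("y", "x")] * 25 + [("y", "y")] * 25
        )
        assert kappa_agreement(pairs).kappa == pytest.approx(0.0, abs=1e-12)

    def test_worked_2x2_table(self):
        """[[20,5],[10,15]] over n=50: po=0.70, pe=0.50, kappa=0.40."""
        pairs = (
            [("a", "a")] * 20 + [("a", "b")] * 5 + [("b", "a")] * 10 + [("b", "b")] * 15
        )
        res = kappa_agreement(pairs)
        assert res.percent_agreement == pytest.approx(70.0)
        assert res.kappa == pytest.approx(0.40, abs=1e-12)
        assert res.ci_low < 0.40 < res.ci_high

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, size=300)
        b = np.where(rng.random(300) < 0.6, a, rng.integers(0, 4, size=300))
        res = kappa_agreement(list(zip(a.tolist(), b.tolist())))
        assert res.kappa == pytest.approx(sk.cohen_kappa_score(a, b), rel=1e-12)

    def test_degenerate_single_category(self):
        res = kappa_agreement([("a", "a")] * 10)
        assert res.degenerate
        assert math.isnan(res.kappa)
        assert res.percent_agreement == pytest.approx(100.0)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            kappa_agreement([("a", "a")])


# ---------------------------------------------------------------------------
# Goldstein-Healy adjusted levels

class TestGoldsteinHealy:
    def test_closed_form_at_equal_ses(self):
        lvl = goldstein_healy_level(1.0, 1.0)
        closed = 100 * (2 * sps.norm.cdf(sps.norm.isf(0.025) / math.sqrt(2)) - 1)
        assert lvl.level == pytest.approx(closed, abs=1e-12)

    def test_strictly_increasing_in_ratio(self):
        levels = [goldstein_healy_level(1.0, r).level for r in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert all(a < b for a, b in zip(levels, levels[1:]))
        assert all(0 < lv < 100 for lv in levels)

    def test_symmetric_in_arguments(self):
        assert goldstein_healy_level(1.0, 3.0).level == pytest.approx(
            goldstein_healy_level(3.0, 1.0).level
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            goldstein_healy_level(0.0, 1.0)
        with pytest.raises(ValueError):
            goldstein_healy_level(1.0, 1.0, alpha=1.5)
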