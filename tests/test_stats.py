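"""t-tests, effect sizes, Bayes factors, FDR, map tests, ANOVA, tables."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sstats

from thetanet.containers import ConnectivityResult
from thetanet.stats import (
    asymmetry_table,
    bh_fdr,
    cohen_d_independent,
    cohen_d_paired,
    evidence_label,
    group_table,
    independent_t,
    jzs_bf,
    mixed_anova,
    paired_t,
    pointwise_map_test,
)
from ._oracles import brute_bh, mixed_anova_ss


class TestPairedT:
    def test_identical_samples_give_zero_t_unit_p(self):
        x = np.arange(5.0)
        assert paired_t(x, x) == (0.0, 4, 1.0)

    def test_hand_computed_example(self):
        # differences {1, 2, 3}: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        t, df, p = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert df == 2

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        t, df, p = paired_t(x, y)
        ref = sstats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(1)
        reps = 10_000
        d = rng.standard_normal((reps, 15))
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(15))
        p = 2 * sstats.t.sf(np.abs(t), 14)
        assert sstats.kstest(p, "uniform").pvalue > 0.01

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.array([1.0]), np.array([2.0]))


class TestIndependentT:
    def test_identical_groups_give_zero(self):
        x = np.arange(6.0)
        t, df, p = independent_t(x, x)
        assert t == 0.0 and p == 1.0

    def test_df_is_pooled_for_31_and_29_subjects(self):
        rng = np.random.default_rng(2)
        _, df, _ = independent_t(rng.standard_normal(31), rng.standard_normal(29))
        assert df == 58

    def test_agrees_with_hand_formula_on_six_values(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 9.0])
        t, df, p = independent_t(x, y)
        sp2 = (2 * x.var(ddof=1) + 2 * y.var(ddof=1)) / 4
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(t_hand, abs=1e-12)
        ref = sstats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "t, n, expected",
        [(-3.84, 31, 0.69), (6.18, 29, 1.15), (-5.12, 31, 0.92), (0.0, 10, 0.0)],
    )
    def test_paired_d_magnitudes(self, t, n, expected):
        assert round(abs(cohen_d_paired(t, n)), 2) == expected

    @pytest.mark.parametrize(
        "t, n1, n2, expected",
        [(-4.87, 31, 29, -1.26), (-2.09, 31, 29, -0.54), (0.0, 5, 5, 0.0)],
    )
    def test_independent_d_signed(self, t, n1, n2, expected):
        assert round(cohen_d_independent(t, n1, n2), 2) == expected

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            cohen_d_paired(1.0, 1)


class TestBayesFactor:
    def test_cross_checks_against_pingouin(self):
        for t, n in [(3.84, 31), (3.76, 29), (1.2, 12)]:
            ours = jzs_bf(t, n, design="paired")
            ref = float(pg.bayesfactor_ttest(t, n, paired=True))
            assert ours == pytest.approx(ref, rel=1e-4)
        ours = jzs_bf(-2.09, 31, 29, design="independent")
        ref = float(pg.bayesfactor_ttest(-2.09, 31, 29, paired=False))
        assert ours == pytest.approx(ref, rel=1e-4)

    def test_null_t_favors_h0_and_bf_grows_with_t(self):
        assert jzs_bf(0.0, 20) < 1.0
        bfs = [jzs_bf(t, 20) for t in (0.5, 1.0, 2.0, 3.0, 4.0)]
        assert np.all(np.diff(bfs) > 0)

    def test_symmetric_in_sign_of_t(self):
        assert jzs_bf(2.5, 25) == pytest.approx(jzs_bf(-2.5, 25), rel=1e-12)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            jzs_bf(1.0, 10, 12, design="paired")
        with pytest.raises(ValueError):
            jzs_bf(1.0, 10, design="independent")
        with pytest.raises(ValueError):
            jzs_bf(np.inf, 10)


class TestEvidenceLabels:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (51.96, "Very strong H1"),
            (0.21, "Moderate H0"),
            (1.0, "Anecdotal H0"),  # H1 labels require BF10 > 1
            (3.0, "Anecdotal H1"),  # boundaries go to the weaker band
            (150.0, "Extreme H1"),
            (0.005, "Extreme H0"),
            (0.05, "Strong H0"),
        ],
    )
    def test_band_assignment(self, bf, label):
        assert evidence_label(bf) == label

    def test_invalid_bf_rejected(self):
        with pytest.raises(ValueError):
            evidence_label(0.0)


class TestFDR:
    def test_single_p_passes_through(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_hand_computed_staircase(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04) and rej.all()

    def test_matches_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            adj, _ = bh_fdr(p)
            assert np.allclose(adj, brute_bh(p), atol=1e-12)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPointwiseMap:
    def test_equal_conditions_yield_no_discoveries(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((10, 3, 20))
        out = pointwise_map_test(a, a.copy())
        assert not out["sig"].any()

    def test_single_subject_rejected(self):
        a = np.zeros((1, 2, 5))
        with pytest.raises(ValueError, match="2 subjects"):
            pointwise_map_test(a, a)

    def test_injected_effect_found_with_controlled_false_discoveries(self):
        rng = np.random.default_rng(5)
        n_rep, n_subj, n_t = 100, 20, 60
        window = slice(20, 30)
        fdp, hit = [], 0
        for _ in range(n_rep):
            a = rng.standard_normal((n_subj, 1, n_t))
            b = rng.standard_normal((n_subj, 1, n_t))
            a[:, 0, window] += 1.5
            out = pointwise_map_test(a, b)
            sig = out["sig"][0]
            true = np.zeros(n_t, bool)
            true[window] = True
            n_disc = sig.sum()
            fdp.append((sig & ~true).sum() / max(n_disc, 1))
            hit += sig[window].mean() > 0.5
        assert np.mean(fdp) <= 0.05 + 0.02  # BH controls expected FDP at 5%
        assert hit >= 95  # the injected window is consistently detected


class TestMixedAnova:
    def _frame(self, values):
        # values: (n_groups, n_subjects, n_within)
        rows = []
        sid = 0
        for g in range(values.shape[0]):
            for s in range(values.shape[1]):
                for w, f in enumerate((4.5, 8.0)):
                    rows.append(
                        {"subject": sid, "group": f"g{g}", "flicker_freq": f,
                         "power": values[g, s, w]}
                    )
                sid += 1
        return pd.DataFrame(rows)

    def test_flat_data_gives_zero_f(self):
        df = self._frame(np.ones((2, 4, 2)))
        out = mixed_anova(df)
        assert np.allclose(out["F"], 0.0) and np.allclose(out["p"], 1.0)

    def test_df_for_31_plus_29_subjects(self):
        rng = np.random.default_rng(6)
        rows = []
        sid = 0
        for g, nsub in ((0, 31), (1, 29)):
            for s in range(nsub):
                for f in (4.5, 8.0):
                    rows.append({"subject": sid, "group": f"g{g}",
                                 "flicker_freq": f, "power": rng.standard_normal()})
                sid += 1
        out = mixed_anova(pd.DataFrame(rows)).set_index("effect")
        assert out.loc["group", "df1"] == 1 and out.loc["group", "df2"] == 58
        assert out.loc["flicker_freq", "df2"] == 58

    def test_matches_sums_of_squares_oracle_on_six_subjects(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((2, 3, 2))
        out = mixed_anova(self._frame(values)).set_index("effect")
        oracle = mixed_anova_ss(values)
        for key, row in (("group", "group"), ("within", "flicker_freq"),
                         ("interaction", "Interaction")):
            F, df1, df2, eta = oracle[key]
            assert out.loc[row, "F"] == pytest.approx(F, abs=1e-10)
            assert out.loc[row, "df1"] == df1 and out.loc[row, "df2"] == df2
            assert out.loc[row, "partial_eta_sq"] == pytest.approx(eta, abs=1e-10)

    def test_incomplete_within_layout_rejected(self):
        df = self._frame(np.ones((2, 3, 2)))
        with pytest.raises(ValueError, match="within-factor"):
            mixed_anova(df[df.flicker_freq == 4.5].iloc[:-1]._append(df.iloc[-1:]))


def _cr(matrix, rois=("A", "B"), nc=None):
    m = np.asarray(matrix, float)
    return ConnectivityResult(lC=m, NC=m if nc is None else np.asarray(nc, float),
                              roi_names=list(rois))


def _subjects_with_surplus(n, surplus, sd=0.2, seed=0, rois=("A", "B")):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        m = np.full((len(rois), len(rois)), 0.5)
        m[0, 1] = 0.5 + surplus + rng.normal(0, sd)
        m[1, 0] = 0.5 + rng.normal(0, sd)
        out.append(_cr(m, rois))
    return out


class TestAsymmetryTable:
    def test_large_surplus_is_flagged_after_fdr(self):
        subs = _subjects_with_surplus(31, surplus=0.4, seed=1)
        tab = asymmetry_table(subs, [("A", "B")], "action_planning")
        lin = tab[tab.measure == "linear"].iloc[0]
        assert lin.sig_fdr and lin.p_fdr >= lin.p
        assert lin.d == abs(cohen_d_paired(lin.t, 31))
        assert lin.evidence == evidence_label(lin.BF10)

    def test_row_contract_columns(self):
        subs = _subjects_with_surplus(5, 0.1)
        tab = asymmetry_table(subs, [("A", "B")], "standby")
        assert list(tab.columns) == [
            "phase", "measure", "connection", "mean_ab", "sem_ab", "mean_ba",
            "sem_ba", "t", "d", "p", "p_fdr", "sig_fdr", "BF10", "evidence",
        ]
        assert set(tab.measure) == {"linear", "nonlinear"}

    def test_missing_pair_names_subject_and_roi(self):
        subs = _subjects_with_surplus(4, 0.1)
        subs.append(_cr(np.full((2, 2), 0.5), rois=("A", "C")))
        with pytest.raises(KeyError, match="subject 4.*'B'"):
            asymmetry_table(subs, [("A", "B")], "perception")

    def test_single_subject_refused(self):
        with pytest.raises(ValueError, match="at least 2 subjects"):
            asymmetry_table(_subjects_with_surplus(1, 0.1), [("A", "B")], "standby")

    def test_symmetric_generator_controls_false_positives(self):
        uncorr = 0
        fdr_hits = 0
        reps = 200
        for rep in range(reps):
            subs = _subjects_with_surplus(15, surplus=0.0, seed=1000 + rep)
            tab = asymmetry_table(subs, [("A", "B")], "standby", measures=("linear",))
            uncorr += (tab.p < 0.05).sum()
            fdr_hits += tab.sig_fdr.sum()
        assert 0.02 <= uncorr / reps <= 0.09
        assert fdr_hits / reps <= 0.09


class TestGroupTable:
    def _group(self, n, level, rois=("A", "B", "C"), sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            m = level + rng.normal(0, sd, (len(rois), len(rois)))
            out.append(_cr(np.abs(m), rois))
        return out

    def test_connections_outside_shared_rois_absent(self):
        ga = self._group(6, 0.5, rois=("A", "B", "C"), seed=1)
        gb = self._group(6, 0.5, rois=("A", "B", "LG"), seed=2)
        tab = group_table(ga, gb, shared_rois=("A", "B"))
        assert set(tab.connection) == {"A -> B", "B -> A"}
        assert not tab.connection.str.contains("LG").any()

    def test_df_58_for_31_vs_29(self):
        ga = self._group(31, 0.5, seed=3)
        gb = self._group(29, 0.6, seed=4)
        tab = group_table(ga, gb, shared_rois=("A", "B", "C"))
        assert (tab.df == 58).all()

    def test_one_distribution_controls_fdr_false_positives(self):
        hits = 0
        reps = 100
        for rep in range(reps):
            ga = self._group(10, 0.5, seed=rep)
            gb = self._group(10, 0.5, seed=10_000 + rep)
            tab = group_table(ga, gb, ("A", "B", "C"), measures=("linear",))
            hits += tab.sig_fdr.any()
        assert hits / reps <= 0.1

    def test_signed_d_matches_conversion(self):
        ga = self._group(8, 0.4, seed=5)
        gb = self._group(9, 0.7, seed=6)
        tab = group_table(ga, gb, ("A", "B"))
        for _, row in tab.iterrows():
            assert row.d == pytest.approx(cohen_d_independent(row.t, 8, 9), abs=1e-12)

    def test_small_groups_refused(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_table(self._group(1, 0.5), self._group(5, 0.5), ("A",))
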