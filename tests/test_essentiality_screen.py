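"""Essentiality-screen filters, the moderated t-test and its oracle.

The oracle re-derives the moderated statistic from scratch: plain-loop
group means and variances, trigamma inversion by bracketed root finding
(scipy brentq, independent of the package's Newton iteration), and scalar
shrinkage — then the package output is required to agree to 1e-8.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from scipy.optimize import brentq

from neuro17q import SimulationConfig, simulate_dependency_screen
from neuro17q.essentiality_screen import (DependencyScreen, ScreenError,
                                          ScreenParams, bh_fdr,
                                          exclude_common_essential,
                                          filter_dependency,
                                          filter_expression,
                                          fit_variance_prior,
                                          moderated_t_test, run_screen)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_moderated_t(dep: pd.DataFrame, group: pd.Series):
    """Scalar re-implementation of the moderated two-group test."""
    a_cols = [c for c in dep.columns if group[c] == "MNA"]
    b_cols = [c for c in dep.columns if group[c] == "other"]
    n1, n2 = len(a_cols), len(b_cols)
    d = n1 + n2 - 2
    deltas, s2s = [], []
    for g in dep.index:
        a = [dep.at[g, c] for c in a_cols]
        b = [dep.at[g, c] for c in b_cols]
        ma, mb = sum(a) / n1, sum(b) / n2
        ss = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
        deltas.append(ma - mb)
        s2s.append(ss / d)
    e = [math.log(s2) - special.digamma(d / 2) + math.log(d / 2)
         for s2 in s2s]
    emean = sum(e) / len(e)
    evar = sum((x - emean) ** 2 for x in e) / (len(e) - 1)
    excess = evar - special.polygamma(1, d / 2)
    if excess > 0:
        d0 = 2 * brentq(lambda y: special.polygamma(1, y) - excess,
                        1e-8, 1e10)
        s0_2 = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
        t_out, p_out = [], []
        for delta, s2 in zip(deltas, s2s):
            st2 = (d0 * s0_2 + d * s2) / (d0 + d)
            t = delta / math.sqrt(st2 * (1 / n1 + 1 / n2))
            t_out.append(t)
            p_out.append(2 * stats.t.sf(abs(t), d0 + d))
    else:
        d0, s0_2 = math.inf, math.exp(emean)
        t_out = [delta / math.sqrt(s0_2 * (1 / n1 + 1 / n2))
                 for delta in deltas]
        p_out = [2 * stats.norm.sf(abs(t)) for t in t_out]
    return np.array(t_out), np.array(p_out), d0, s0_2


def _random_instance(rng, n_genes=20, n1=4, n2=6):
    genes = [f"G{i}" for i in range(n_genes)]
    lines = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    dep = pd.DataFrame(rng.normal(0, rng.uniform(0.05, 0.5),
                                  size=(n_genes, n1 + n2)),
                       index=genes, columns=lines)
    group = pd.Series(["MNA"] * n1 + ["other"] * n2, index=lines)
    return dep, group


class TestModeratedT:
    def test_matches_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            dep, group = _random_instance(rng)
            got, d0, s0_2 = moderated_t_test(dep, group)
            t_exp, p_exp, d0_exp, s0_exp = oracle_moderated_t(dep, group)
            np.testing.assert_allclose(got["t_mod"], t_exp, atol=1e-8)
            np.testing.assert_allclose(got["p"], p_exp, atol=1e-8)
            if math.isfinite(d0):
                assert d0 == pytest.approx(d0_exp, rel=1e-6)
            assert s0_2 == pytest.approx(s0_exp, rel=1e-6)

    def test_identical_group_means_give_t_zero_p_one(self):
        lines = ["A0", "A1", "B0", "B1"]
        dep = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0],     # equal means, nonzero variance
             [0.5, 0.2, 0.4, -0.1]],
            index=["G0", "G1"], columns=lines)
        group = pd.Series(["MNA", "MNA", "other", "other"], index=lines)
        res, *_ = moderated_t_test(dep, group)
        assert res.loc["G0", "t_mod"] == pytest.approx(0.0)
        assert res.loc["G0", "p"] == pytest.approx(1.0)

    def test_equal_variances_fully_shrink(self):
        """When every gene has the same s_g^2 the fitted prior has infinite
        d0 and all tests share one squeezed variance: t_mod is a common
        positive multiple of the ordinary pooled t (identical ordering),
        approaching equality as the residual df grows (the log-variance
        bias correction exp(log(d/2) - digamma(d/2)) -> 1)."""
        rng = np.random.default_rng(5)
        n1 = n2 = 40
        base = rng.normal(0, 1, size=n1 + n2)
        genes, rows = [], []
        for i in range(30):
            shift = rng.normal(0, 1)
            rows.append(np.concatenate([base[:n1] + shift, base[n1:]]))
            genes.append(f"G{i}")
        dep = pd.DataFrame(rows, index=genes,
                           columns=[f"A{i}" for i in range(n1)] +
                                   [f"B{i}" for i in range(n2)])
        group = pd.Series(["MNA"] * n1 + ["other"] * n2, index=dep.columns)
        res, d0, s0_2 = moderated_t_test(dep, group)
        assert math.isinf(d0)
        ratios = []
        for g in genes:
            a = dep.loc[g].iloc[:n1]
            b = dep.loc[g].iloc[n1:]
            t_ref = stats.ttest_ind(a, b, equal_var=True).statistic
            ratios.append(res.loc[g, "t_mod"] / t_ref)
            assert res.loc[g, "t_mod"] == pytest.approx(t_ref, rel=0.02)
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        """Forcing d0 = 0 disables shrinkage entirely: the moderated test
        must reproduce the ordinary pooled two-sample t exactly."""
        rng = np.random.default_rng(8)
        dep, group = _random_instance(rng, n_genes=15, n1=5, n2=7)
        res, *_ = moderated_t_test(dep, group, prior=(0.0, 1.0))
        for g in dep.index:
            a = dep.loc[g].iloc[:5]
            b = dep.loc[g].iloc[5:]
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert res.loc[g, "t_mod"] == pytest.approx(ref.statistic,
                                                        abs=1e-10)
            assert res.loc[g, "p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_prior_recovery_from_known_hyperparameters(self):
        """s_g^2 simulated under (d0, s0^2) = (4, 0.04): the moment-matched
        fit recovers both within 25% relative error."""
        rng = np.random.default_rng(17)
        d0_true, s0_true, d = 4.0, 0.04, 10
        n_genes = 200
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, n_genes)
        s2 = sigma2 * rng.chisquare(d, n_genes) / d
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert abs(d0_hat - d0_true) / d0_true < 0.25
        assert abs(s0_hat - s0_true) / s0_true < 0.25

    def test_all_zero_variance_is_degenerate(self):
        with pytest.raises(ScreenError, match="degenerate"):
            fit_variance_prior(np.zeros(10), 5)

    def test_single_gene_falls_back_with_warning(self):
        lines = ["A0", "A1", "B0", "B1"]
        dep = pd.DataFrame([[0.1, 0.3, -0.2, 0.0]], index=["G0"],
                           columns=lines)
        group = pd.Series(["MNA", "MNA", "other", "other"], index=lines)
        with pytest.warns(UserWarning, match="ordinary t"):
            res, *_ = moderated_t_test(dep, group)
        t_ref = stats.ttest_ind([0.1, 0.3], [-0.2, 0.0],
                                equal_var=True).statistic
        assert res.loc["G0", "t_mod"] == pytest.approx(t_ref)


class TestFilters:
    def _screen(self, expr_counts, n_mna=13, n_other=4):
        """Screen whose gene i is expressed (log2 TPM 3) in expr_counts[i]
        MNA lines."""
        genes = [f"G{i}" for i in range(len(expr_counts))]
        mna = [f"M{i}" for i in range(n_mna)]
        other = [f"O{i}" for i in range(n_other)]
        expr = pd.DataFrame(0.0, index=genes, columns=mna + other)
        for g, c in zip(genes, expr_counts):
            expr.loc[g, mna[:c]] = 3.0
        dep = pd.DataFrame(0.0, index=genes, columns=mna + other)
        group = pd.Series(["MNA"] * n_mna + ["other"] * n_other,
                          index=mna + other)
        return DependencyScreen(dep, expr, group, frozenset())

    def test_expression_filter_11_of_13_boundary(self):
        screen = self._screen([12, 11, 10])
        kept = filter_expression(screen)
        assert kept == {"G0", "G1"}

    def test_expression_exactly_at_threshold_dropped(self):
        screen = self._screen([13])
        screen.expr.loc[:, :] = 2.0  # strict > 2 required
        assert filter_expression(screen) == set()

    @pytest.mark.parametrize("med_mna,med_other,kept", [
        (-0.5, -0.1, True),
        (-0.1, -0.1, False),    # MNA median not < -0.2
        (-0.25, -0.35, False),  # other median not > -0.3
        (-0.2, -0.1, False),    # strict at the MNA boundary
    ])
    def test_dependency_median_rule(self, med_mna, med_other, kept):
        lines = ["M0", "M1", "M2", "O0", "O1", "O2"]
        dep = pd.DataFrame([[med_mna] * 3 + [med_other] * 3], index=["G0"],
                           columns=lines)
        expr = pd.DataFrame(3.0, index=["G0"], columns=lines)
        group = pd.Series(["MNA"] * 3 + ["other"] * 3, index=lines)
        screen = DependencyScreen(dep, expr, group, frozenset())
        result, _ = filter_dependency(screen)
        assert ("G0" in result) is kept

    def test_exclude_common_essential_set_difference(self):
        assert exclude_common_essential({"A", "B", "C"}, {"B"}) == {"A", "C"}
        assert exclude_common_essential({"A"}, {"X"}) == {"A"}
        assert exclude_common_essential({"A", "B"}, {"A", "B"}) == set()


class TestBhFdr:
    def test_hand_computed_example(self):
        # min over j >= i of p_(j) * m / j
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ScreenError):
            bh_fdr([0.5, 1.5])


class TestRunScreen:
    def test_recovers_planted_genes(self, dependency_screen):
        """2000 genes, 40 planted at effect -0.5 over 13 vs 607 lines:
        sensitivity >= 0.9 and false-discovery proportion <= 0.1."""
        _, screen, truth = dependency_screen
        result = run_screen(screen)
        hits = set(result.hits)
        planted = set(truth.planted_essential)
        assert len(hits & planted) / len(planted) >= 0.9
        assert len(hits - planted) / max(len(hits), 1) <= 0.1

    def test_null_hit_count_within_binomial_bound(self):
        config = SimulationConfig(seed=31, n_genes=2000,
                                  dependency_effect=0.0)
        screen, _ = simulate_dependency_screen(config)
        result = run_screen(screen)
        n_tested = int(result.table["p"].notna().sum())
        bound = stats.binom.ppf(0.99, max(n_tested, 1), 0.05)
        assert len(result.hits) <= bound

    def test_common_essential_never_hit(self, dependency_screen):
        """Genes essential in both groups are excluded outright."""
        _, screen, truth = dependency_screen
        result = run_screen(screen)
        assert not set(result.hits) & set(truth.common_essential)
        flagged = result.table.loc[truth.common_essential, "excluded_common"]
        assert flagged.all()

    def test_filter_cascade_order_insensitive(self, dependency_screen):
        """The filters are independent set predicates: intersecting them in
        any order yields the tested-gene set run_screen used."""
        _, screen, truth = dependency_screen
        params = ScreenParams()
        expressed = filter_expression(screen, params)
        dep_kept, _ = filter_dependency(screen, params)
        common = set(screen.common_essential)
        orders = [
            (set(screen.dep.index) & expressed & dep_kept) - common,
            (set(screen.dep.index) - common) & dep_kept & expressed,
            ((set(screen.dep.index) & dep_kept) - common) & expressed,
        ]
        assert orders[0] == orders[1] == orders[2]
        result = run_screen(screen, params)
        tested = set(result.table.index[result.table["p"].notna()])
        assert tested == orders[0]

    def test_empty_candidate_set_warns_not_raises(self):
        lines = ["M0", "M1", "O0", "O1"]
        dep = pd.DataFrame(0.0, index=["G0"], columns=lines)
        expr = pd.DataFrame(0.0, index=["G0"], columns=lines)  # unexpressed
        group = pd.Series(["MNA", "MNA", "other", "other"], index=lines)
        screen = DependencyScreen(dep, expr, group, frozenset())
        result = run_screen(screen)
        assert result.hits == []
        assert result.table["p"].isna().all()
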