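"""Univariate Cox screening, AACCV curves and transition comparison."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from metadeg.survival import (
    AACCVPoint,
    aaccv_curve,
    combine_bidirectional,
    compare_transitions,
    coef_density_summary,
    cox_per_gene,
    cox_univariate_batch,
)
from _oracles import cox_mle_grid, ranksum_exact_p


def _surv_frame(expr_values, time, event, group="confined"):
    n = len(time)
    cols = [f"s{i}" for i in range(n)]
    expr = pd.DataFrame(
        np.atleast_2d(expr_values),
        index=[f"g{i}" for i in range(np.atleast_2d(expr_values).shape[0])],
        columns=cols,
    )
    ann = pd.DataFrame(
        {"group": group, "os_time": time, "os_event": event}, index=cols
    )
    return expr, ann


class TestCoxUnivariateBatch:
    def test_toy_with_ties_matches_partial_likelihood_maximiser(self):
        # 6 subjects, binary covariate, one tied event time (Breslow)
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        time = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 9.0])
        event = np.array([1, 1, 1, 1, 0, 1])
        fit = cox_univariate_batch(x, time, event)
        oracle = cox_mle_grid(x, time, event)
        assert fit["converged"].iloc[0]
        assert fit["coef"].iloc[0] == pytest.approx(oracle, abs=1e-6)

    def test_matches_lifelines_without_ties(self):
        rng = np.random.default_rng(0)
        n = 120
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / np.exp(0.4 * x))
        event = (rng.random(n) > 0.25).astype(int)
        fit = cox_univariate_batch(x, time, event)
        df = pd.DataFrame({"x": x, "t": time, "e": event})
        cph = CoxPHFitter()
        cph.fit(df, "t", "e")
        assert fit["coef"].iloc[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit["se"].iloc[0] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_planted_beta_recovered_at_n500(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.01 * np.exp(0.5 * x)))
        censor = rng.uniform(0, 250, size=n)
        event = (time <= censor).astype(int)
        obs = np.minimum(time, censor)
        fit = cox_univariate_batch(x, obs, event)
        assert abs(fit["coef"].iloc[0] - 0.5) < 0.15

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate_batch(
                np.ones(4), np.arange(1.0, 5.0), np.zeros(4, dtype=int)
            )


class TestCoxPerGene:
    def test_null_genes_have_small_mean_coef(self):
        rng = np.random.default_rng(2)
        n = 200
        expr_values = rng.normal(8, 1, size=(300, n))
        time = rng.exponential(100, size=n)
        event = (rng.random(n) > 0.3).astype(int)
        expr, ann = _surv_frame(expr_values, time, event)
        out = cox_per_gene(expr, ann)
        good = out[out["converged"]]
        assert abs(good["coef"].mean()) < 0.02
        assert np.allclose(good["hr"], np.exp(good["coef"]))

    def test_zscore_invariance_under_affine_transform(self):
        rng = np.random.default_rng(3)
        n = 150
        gene = rng.normal(size=n)
        time = rng.exponential(1.0 / np.exp(0.3 * gene))
        event = np.ones(n, dtype=int)
        expr, ann = _surv_frame(np.vstack([gene, 10.0 + 5.0 * gene]), time, event)
        out = cox_per_gene(expr, ann)
        assert out["coef"].iloc[0] == pytest.approx(out["coef"].iloc[1], abs=1e-8)

    def test_constant_gene_flagged_degenerate(self):
        rng = np.random.default_rng(4)
        n = 50
        expr, ann = _surv_frame(
            np.vstack([np.full(n, 3.0), rng.normal(size=n)]),
            rng.exponential(1, n),
            np.ones(n, dtype=int),
        )
        out = cox_per_gene(expr, ann)
        assert bool(out["degenerate"].iloc[0])
        assert out["coef"].iloc[0] == 0.0
        assert not out["degenerate"].iloc[1]

    def test_normal_samples_excluded(self):
        rng = np.random.default_rng(5)
        n = 60
        expr, ann = _surv_frame(rng.normal(size=(5, n)), rng.exponential(1, n), np.ones(n, dtype=int))
        ann.loc[ann.index[:20], "group"] = "normal"
        out = cox_per_gene(expr, ann)
        assert (out["n_used"] == 40).all()


class TestAACCV:
    def _cox_frame(self, coefs):
        return pd.DataFrame(
            {
                "coef": coefs,
                "converged": True,
                "degenerate": False,
            },
            index=[f"g{i}" for i in range(len(coefs))],
        )

    def _diff_frame(self, scores):
        return pd.DataFrame({"d_score": scores}, index=[f"g{i}" for i in range(len(scores))])

    def test_equal_coefs_give_flat_curve(self):
        cox = self._cox_frame([0.7] * 10)
        diff = self._diff_frame(np.linspace(1, 2, 10))
        pts = aaccv_curve(cox, diff, [5, 10], "up")
        assert [p.aaccv for p in pts] == pytest.approx([0.7, 0.7])
        assert [p.top_n for p in pts] == [5, 10]

    def test_step_coefs_average_as_expected(self):
        # top 5 by score have |coef| 1, the next 5 have 0
        scores = np.concatenate([np.linspace(2, 3, 5), np.linspace(0.5, 1, 5)])
        coefs = np.concatenate([np.ones(5), np.zeros(5)])
        pts = aaccv_curve(self._cox_frame(coefs), self._diff_frame(scores), [5, 10], "up")
        assert pts[0].aaccv == pytest.approx(1.0)
        assert pts[1].aaccv == pytest.approx(0.5)

    def test_order_invariance_within_top_list(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0.1, 5, 40)
        coefs = rng.normal(size=40)
        pts = aaccv_curve(self._cox_frame(coefs), self._diff_frame(scores), [20], "up")
        perm = rng.permutation(40)
        pts_perm = aaccv_curve(
            self._cox_frame(coefs[perm]).set_axis([f"g{i}" for i in perm]),
            self._diff_frame(scores[perm]).set_axis([f"g{i}" for i in perm]),
            [20],
            "up",
        )
        assert pts[0].aaccv == pytest.approx(pts_perm[0].aaccv)

    def test_bidirectional_concatenation(self):
        up = AACCVPoint("t", "up", 2, 1.0, [1.0, 1.0])
        down = AACCVPoint("t", "down", 2, 0.0, [0.0, 0.0])
        both = combine_bidirectional(up, down)
        assert both.aaccv == pytest.approx(0.5)
        assert len(both.member_abs_coefs) == 4


class TestCompareTransitions:
    def test_identical_lists_give_p1(self):
        a = AACCVPoint("a", "up", 3, 1.0, [1.0, 1.0, 1.0])
        b = AACCVPoint("b", "up", 3, 1.0, [1.0, 1.0, 1.0])
        _, p = compare_transitions(a, b)
        assert p == 1.0

    def test_separated_lists_match_enumeration(self):
        a = AACCVPoint("a", "up", 3, 2.0, [1.0, 2.0, 3.0])
        b = AACCVPoint("b", "up", 3, 5.0, [4.0, 5.0, 6.0])
        _, p = compare_transitions(a, b)
        assert p == pytest.approx(ranksum_exact_p([1, 2, 3], [4, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        a = AACCVPoint("a", "up", 10, 0.0, list(rng.normal(size=10)))
        b = AACCVPoint("b", "up", 10, 0.0, list(rng.normal(size=10)))
        _, p_ab = compare_transitions(a, b)
        _, p_ba = compare_transitions(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_empty_members_rejected(self):
        a = AACCVPoint("a", "up", 0, 0.0, [])
        b = AACCVPoint("b", "up", 1, 1.0, [1.0])
        with pytest.raises(ValueError):
            compare_transitions(a, b)


class TestCoefDensitySummary:
    def test_single_gene_set_flags_undefined_sd(self):
        cox = pd.DataFrame(
            {"coef": [0.5, -0.2], "converged": True, "degenerate": False},
            index=["g0", "g1"],
        )
        out = coef_density_summary(cox, {"solo": ["g0"]})
        assert out["solo"]["mean"] == pytest.approx(0.5)
        assert out["solo"]["sd_undefined"]

    def test_unknown_gene_rejected(self):
        cox = pd.DataFrame(
            {"coef": [0.5], "converged": True, "degenerate": False}, index=["g0"]
        )
        with pytest.raises(KeyError):
            coef_density_summary(cox, {"bad": ["nope"]})

    def test_planted_up_set_has_positive_mean(self):
        """Genes whose expression raises the hazard show positive Cox
        coefficients on average."""
        rng = np.random.default_rng(8)
        n = 300
        risk = rng.normal(size=n)
        genes = risk + rng.normal(0, 0.7, size=(20, n))  # all load on the risk factor
        noise = rng.normal(size=(20, n))
        time = rng.exponential(1.0 / np.exp(0.6 * risk))
        expr, ann = _surv_frame(np.vstack([genes, noise]), time, np.ones(n, dtype=int))
        cox = cox_per_gene(expr, ann)
        out = coef_density_summary(
            cox,
            {"linked": [f"g{i}" for i in range(20)],
             "null": [f"g{i}" for i in range(20, 40)]},
        )
        assert out["linked"]["mean"] > 0.2
        assert abs(out["null"]["mean"]) < 0.1
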