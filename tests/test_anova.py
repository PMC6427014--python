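import math
import warnings

import numpy as np
import pytest
from scipy import stats

from bacaba import anova, synthetic
from bacaba.datatypes import DesignError, TraitTable, ValidityError
from tests.conftest import make_table


class TestGeneticParametersFromMeanSquares:
    @pytest.mark.parametrize(
        "GMS, RMS, mean, cvg, ratio",
        [
            (13.45, 1.20, 16.40, 5.70, None),   # fruit length row
            (15.16, 0.99, 14.76, 6.82, 1.01),   # fruit width row
        ],
    )
    def test_published_rows_recompute(self, GMS, RMS, mean, cvg, ratio):
        gp = anova.genetic_parameters_from_mean_squares(GMS, RMS, mean, 14)
        assert round(gp.CVg_pct, 2) == cvg
        if ratio is not None:
            assert round(gp.cvg_over_cve, 2) == ratio

    def test_published_heritabilities_lie_in_rounding_intervals(self, ref_params):
        # printed h2mp must be reachable from *some* mean squares that round
        # to the printed 2-decimal GMS and RMS
        for trait, row in ref_params.iterrows():
            lo = 100 * (1 - (row.RMS + 0.005) / max(row.GMS - 0.005, 1e-9))
            hi = 100 * (1 - (row.RMS - 0.005) / (row.GMS + 0.005))
            # the printed h2mp is itself rounded to 2 dp (half-ulp slack)
            assert lo - 0.005 <= row.h2mp_pct <= hi + 0.005, trait

    def test_negative_genetic_variance_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            gp = anova.genetic_parameters_from_mean_squares(1.0, 2.0, 10.0, 4)
        assert gp.sigma2_g == 0.0 and gp.CVg_pct == 0.0


class TestOneWayAnova:
    def test_matches_scipy_f_oneway(self, rng):
        blocks = [list(rng.normal(10 + i, 1.0, size=5)) for i in range(6)]
        table = make_table({"A": blocks})
        res = anova.one_way_anova(table, "A")
        F, p = stats.f_oneway(*[np.array(b) for b in blocks])
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)
        assert res.df_g == 5 and res.df_e == 24

    def test_sum_of_squares_identity(self, rng):
        for _ in range(20):
            blocks = [list(rng.normal(0, 2, size=7)) for _ in range(8)]
            table = make_table({"A": blocks})
            res = anova.one_way_anova(table, "A")
            y = np.concatenate(blocks)
            ss_total = ((y - y.mean()) ** 2).sum()
            recomposed = res.GMS * res.df_g + res.RMS * res.df_e
            assert recomposed == pytest.approx(ss_total, rel=1e-9)

    def test_noise_free_case(self):
        table = make_table({"A": [[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]]})
        with pytest.warns(UserWarning, match="zero residue"):
            res = anova.one_way_anova(table, "A")
        assert res.RMS == 0.0 and res.h2mp == 1.0
        assert math.isinf(res.F) and res.p_value == 0.0

    def test_unbalanced_requires_explicit_flag(self):
        table = make_table({"A": [[1.0, 2.0, 3.0], [4.0, 5.0]]})
        with pytest.raises(DesignError, match="unbalanced"):
            anova.one_way_anova(table, "A")
        res = anova.one_way_anova(table, "A", allow_unbalanced=True)
        assert res.sigma2_g >= 0

    def test_moderate_heritability_recovery(self):
        # Monte-Carlo oracle at 60 genotypes (small-sample bias ~ -2h2/df_g
        # is negligible there): mean estimate within +/-0.03 of 0.5
        vals = []
        for seed in range(500):
            cfg = synthetic.simulate_from_target_parameters(
                60, 4, np.array([10.0]), np.array([10.0]), np.array([0.5]),
                seed=seed,
            )
            table, _ = synthetic.simulate_population(cfg)
            vals.append(anova.one_way_anova(table, table.traits[0]).h2mp)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)


class TestGeneticParameterTable:
    def test_one_row_per_trait_in_order(self, study_table):
        table, _, _ = study_table
        rows = anova.genetic_parameter_table(table)
        assert [r.trait for r in rows] == table.traits

    def test_trait_permutation_equivariance(self, study_table):
        table, _, _ = study_table
        rows = {r.trait: r for r in anova.genetic_parameter_table(table)}
        permuted = table.subset(list(reversed(table.traits)))
        rows_p = {r.trait: r for r in anova.genetic_parameter_table(permuted)}
        for t in table.traits:
            assert rows[t] == rows_p[t]


class TestScottKnott:
    def test_identical_means_single_group(self):
        g = anova.scott_knott({"a": 5.0, "b": 5.0}, RMS=1.0, df_e=20, r=4)
        assert set(g.groups) == {"a"}

    def test_outlier_mean_splits_off(self):
        # brute-force oracle over both contiguous 2-partitions of the sorted
        # means {9.0, 1.1, 1.0} with the lambda statistic confirms a single
        # split isolating 9.0
        means = {"x": 1.0, "y": 1.1, "z": 9.0}
        r, RMS, df_e, alpha = 1, 0.01, 40, 0.05

        def lam(seg, cut):
            seg = np.array(seg)
            t1, t2 = seg[:cut].sum(), seg[cut:].sum()
            k1, k2, k = cut, len(seg) - cut, len(seg)
            b0 = t1**2 / k1 + t2**2 / k2 - (t1 + t2) ** 2 / k
            s0 = (((seg - seg.mean()) ** 2).sum() + df_e * RMS / r) / (k + df_e)
            return (math.pi / (2 * (math.pi - 2))) * b0 / s0

        crit = stats.chi2.ppf(1 - alpha, 3 / (math.pi - 2))
        lams = [lam([9.0, 1.1, 1.0], c) for c in (1, 2)]
        assert max(lams) > crit and np.argmax(lams) == 0  # split after 9.0

        g = anova.scott_knott(means, RMS=RMS, df_e=df_e, r=r, alpha=alpha)
        assert g.as_dict()["z"] != g.as_dict()["x"]
        assert g.as_dict()["x"] == g.as_dict()["y"]

    def test_huge_residual_variance_single_group(self):
        g = anova.scott_knott(
            {"x": 1.0, "y": 1.1, "z": 9.0}, RMS=1e9, df_e=40, r=1
        )
        assert len(set(g.groups)) == 1

    def test_input_order_invariance(self, rng):
        means = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 3, 12))}
        a = anova.scott_knott(means, RMS=0.5, df_e=33, r=3)
        shuffled = dict(reversed(list(means.items())))
        b = anova.scott_knott(shuffled, RMS=0.5, df_e=33, r=3)
        assert a.as_dict() == b.as_dict()

    def test_groups_are_contiguous_runs(self, rng):
        means = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 5, 15))}
        g = anova.scott_knott(means, RMS=1.0, df_e=42, r=3)
        seen = []
        for letter in g.groups:
            if letter not in seen:
                seen.append(letter)
        assert g.groups == tuple(
            sorted(g.groups, key=seen.index)
        )  # letters appear in contiguous blocks

    def test_non_finite_mean_rejected(self):
        with pytest.raises(ValidityError):
            anova.scott_knott({"a": float("nan")}, RMS=1.0, df_e=10, r=2)
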