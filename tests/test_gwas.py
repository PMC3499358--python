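import numpy as np
import pandas as pd
import pytest
from scipy import stats

import viroquant as vq
from viroquant.panel import LinePanel
from tests.conftest import make_line_values


def panel_from_codes(codes: dict[str, list[int]], lines=None) -> LinePanel:
    n = len(next(iter(codes.values())))
    lines = lines or [f"l{i}" for i in range(n)]
    return LinePanel(pd.DataFrame(codes, index=lines))


class TestCollapse:
    def test_fly_weighted_mean_survival(self):
        pheno = pd.DataFrame(
            {
                "line_id": "l0",
                "vial_id": ["v0"] * 10 + ["v1"] * 30,
                "value": [4.0] * 10 + [8.0] * 30,
            }
        )
        lv = vq.collapse_to_line_values(pheno, "survival")
        assert lv.loc[0, "value"] == pytest.approx(7.0)
        assert lv.loc[0, "weight"] == 40

    @pytest.mark.parametrize("prop,expected", [(0.0, 0.0), (0.5, np.pi / 4), (1.0, np.pi / 2)])
    def test_arcsine_transform(self, prop, expected):
        pheno = pd.DataFrame(
            {"line_id": "l0", "vial_id": "v0", "n_flies": 20, "n_infected": int(20 * prop)},
            index=[0],
        )
        lv = vq.collapse_to_line_values(pheno, "infection", arcsine=True)
        assert lv.loc[0, "value"] == pytest.approx(expected)

    def test_single_vial_value_is_that_vial(self):
        pheno = pd.DataFrame({"line_id": "l0", "vial_id": "v0", "value": [3.0, 5.0]})
        lv = vq.collapse_to_line_values(pheno, "survival")
        assert lv.loc[0, "value"] == pytest.approx(4.0)


class TestFilterSites:
    def test_minor_line_count_threshold(self):
        # minor allele in 3 lines vs 4 lines (out of 10)
        three = [2] * 3 + [0] * 7
        four = [2] * 4 + [0] * 6
        panel = panel_from_codes({"2L:1": three, "2L:2": four})
        assert vq.filter_sites(panel, min_minor_lines=4) == ["2L:2"]

    def test_monomorphic_dropped(self):
        panel = panel_from_codes({"2L:1": [0] * 8, "2L:2": [2] * 4 + [0] * 4})
        assert vq.filter_sites(panel) == ["2L:2"]

    def test_segregating_call_can_make_site_monomorphic(self):
        # the only minor-allele carriers are segregating -> site becomes monomorphic
        codes = [-2] * 4 + [0] * 6
        panel = panel_from_codes({"2L:1": codes})
        assert vq.filter_sites(panel, min_minor_lines=1) == []


class TestScan:
    def test_perfect_genotype_effect_recovered_exactly(self):
        x = [2] * 6 + [0] * 6
        panel = panel_from_codes({"2L:1": x})
        y = 3.0 + 1.7 * (np.array(x) - 1.0)
        res = vq.scan(panel, make_line_values(panel, y), min_minor_lines=1)
        row = res.table.iloc[0]
        assert row["a_hat"] == pytest.approx(1.7)
        assert row["p"] < 1e-50

    def test_six_line_toy_matches_closed_form(self):
        """Slope/SE/F from the normal equations on a hand-sized design."""
        x = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0, 1.0, -1.0])
        rng = np.random.default_rng(3)
        y = 0.5 * x + rng.normal(size=8)
        panel = panel_from_codes({"2L:1": ((x + 1).astype(int)).tolist()})
        res = vq.scan(panel, make_line_values(panel, y), min_minor_lines=1)
        # independent oracle: explicit least squares
        X = np.column_stack([np.ones(8), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / 6
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        F = (beta[1] / se) ** 2
        p = stats.f.sf(F, 1, 6)
        row = res.table.iloc[0]
        assert row["a_hat"] == pytest.approx(beta[1], rel=1e-10)
        assert row["se"] == pytest.approx(se, rel=1e-10)
        assert row["F"] == pytest.approx(F, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_equivariance_under_relabeling_and_allele_swap(self, small_panel):
        rng = np.random.default_rng(8)
        y = rng.normal(size=small_panel.n_lines)
        lv = make_line_values(small_panel, y)
        res = vq.scan(small_panel, lv)
        # permute line order in the phenotype table: same lines, same values
        perm = rng.permutation(small_panel.n_lines)
        lv2 = lv.iloc[perm].reset_index(drop=True)
        res2 = vq.scan(small_panel, lv2)
        pd.testing.assert_frame_equal(res.table, res2.table)
        # swap allele labels at one site: p unchanged, a_hat flips sign
        site = res.table["site"].iloc[0]
        geno = small_panel.genotypes.copy()
        col = geno[site].to_numpy().copy()
        col[col == 0], col[col == 2] = 5, 0  # placeholder swap
        col[col == 5] = 2
        geno[site] = col
        res3 = vq.scan(LinePanel(geno), lv)
        r_old = res.table.set_index("site").loc[site]
        r_new = res3.table.set_index("site").loc[site]
        assert r_new["p"] == pytest.approx(r_old["p"], rel=1e-9)
        assert r_new["a_hat"] == pytest.approx(-r_old["a_hat"], rel=1e-9)

    def test_missing_genotypes_dropped_casewise(self):
        panel = panel_from_codes({"2L:1": [2, 2, 2, 0, 0, 0, -1, -1]})
        y = np.array([2.0, 2.1, 1.9, 0.0, 0.1, -0.1, 50.0, -50.0])
        res = vq.scan(panel, make_line_values(panel, y), min_minor_lines=1)
        assert res.table.iloc[0]["n_lines"] == 6

    def test_covariate_collinear_site_flagged(self):
        x = [2] * 5 + [0] * 5
        panel = panel_from_codes({"2L:1": x, "2L:2": x, "2L:3": [2, 0] * 5})
        y = np.arange(10.0)
        res = vq.scan(panel, make_line_values(panel, y),
                      covariate_sites=("2L:1",), min_minor_lines=1)
        tab = res.table.set_index("site")
        assert tab.loc["2L:2", "note"] == "collinear with covariates"
        assert np.isnan(tab.loc["2L:2", "p"])
        assert np.isfinite(tab.loc["2L:3", "p"])


class TestPermutation:
    def test_single_site_threshold_matches_alpha(self):
        rng = np.random.default_rng(5)
        panel = panel_from_codes({"2L:1": ([2] * 30 + [0] * 30)})
        y = rng.normal(size=60)
        null = vq.permute_threshold(panel, make_line_values(panel, y), n_perm=400,
                                    seed=6, min_minor_lines=1)
        # with one independent test, the alpha-quantile of min-p is ~alpha
        assert null.threshold(0.05) == pytest.approx(0.05, abs=0.03)

    def test_threshold_monotone_in_alpha(self, small_panel):
        rng = np.random.default_rng(9)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        null = vq.permute_threshold(small_panel, lv, n_perm=50, seed=2)
        assert null.threshold(0.05) <= null.threshold(0.2)

    def test_reproducible_under_same_seed(self, small_panel):
        rng = np.random.default_rng(10)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        a = vq.permute_threshold(small_panel, lv, n_perm=30, seed=7)
        b = vq.permute_threshold(small_panel, lv, n_perm=30, seed=7)
        assert np.array_equal(a.min_p, b.min_p)

    def test_low_perm_count_warns(self, small_panel):
        rng = np.random.default_rng(11)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        with pytest.warns(UserWarning, match="unstable"):
            vq.permute_threshold(small_panel, lv, n_perm=10, seed=3)


class TestQQ:
    def test_null_trait_sits_on_diagonal(self, small_panel):
        rng = np.random.default_rng(12)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        est = vq.PermutationThreshold(n_perm=100, keep_full=True, seed=4)
        est.fit(small_panel, lv)
        qq = vq.qq_curve(est.scan_, est.null_)
        # a null observed scan is exchangeable with the permutation scans
        resid = qq["observed_nlog10p"] - qq["expected_nlog10p"]
        assert np.abs(np.median(resid)) < 0.2

    def test_planted_locus_lifts_top_of_curve(self, small_panel, gaussian_pheno):
        pheno, _, site = gaussian_pheno
        lv = vq.collapse_to_line_values(pheno, "survival")
        est = vq.PermutationThreshold(n_perm=50, keep_full=True, seed=5)
        est.fit(small_panel, lv)
        qq = vq.qq_curve(est.scan_, est.null_)
        top = qq.iloc[0]  # smallest p-value rank
        assert top["observed_nlog10p"] > top["expected_nlog10p"] + 1.0

    def test_curve_monotone_in_both_coordinates(self, small_panel):
        rng = np.random.default_rng(13)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        est = vq.PermutationThreshold(n_perm=30, keep_full=True, seed=6)
        est.fit(small_panel, lv)
        qq = vq.qq_curve(est.scan_, est.null_)
        # ranks run smallest p to largest, so both -log10 columns decrease
        assert (np.diff(qq["observed_nlog10p"]) <= 1e-12).all()
        assert (np.diff(qq["expected_nlog10p"]) <= 1e-12).all()


class TestJointAndSequential:
    def test_perfectly_correlated_pair_reports_aliasing(self):
        x = [2] * 5 + [0] * 5
        panel = panel_from_codes({"2L:1": x, "2L:2": x})
        rng = np.random.default_rng(14)
        y = np.array(x, dtype=float) + rng.normal(scale=0.1, size=10)
        jm = vq.joint_fit(panel, make_line_values(panel, y), ["2L:1", "2L:2"])
        assert (jm["note"].str.contains("aliased")).all()

    def test_single_site_marginal_equals_scan_p(self, small_panel):
        rng = np.random.default_rng(15)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        site = vq.filter_sites(small_panel)[0]
        jm = vq.joint_fit(small_panel, lv, [site])
        sc = vq.scan(small_panel, lv).table.set_index("site")
        assert jm.loc[0, "p"] == pytest.approx(sc.loc[site, "p"], rel=1e-9)

    def test_sequential_first_term_equals_marginal_alone(self, small_panel):
        rng = np.random.default_rng(16)
        lv = make_line_values(small_panel, rng.normal(size=small_panel.n_lines))
        sites = vq.filter_sites(small_panel)[:2]
        seq = vq.sequential_fit(small_panel, lv, sites)
        assert seq.shape[0] == 2 and np.isfinite(seq["p"]).all()

    def test_matches_statsmodels_joint_model(self, small_panel):
        """Independent cross-check of marginal F-tests against statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        y = rng.normal(size=small_panel.n_lines)
        lv = make_line_values(small_panel, y)
        sites = vq.filter_sites(small_panel)[:3]
        signed = small_panel.signed()[sites]
        keep = ~signed.isna().any(axis=1)
        X = sm.add_constant(signed.loc[keep].to_numpy())
        fit = sm.OLS(y[keep.to_numpy()], X).fit()
        jm = vq.joint_fit(small_panel, lv, sites).set_index("site")
        for k, s in enumerate(sites):
            if np.isnan(jm.loc[s, "p"]):
                continue
            assert jm.loc[s, "p"] == pytest.approx(fit.pvalues[k + 1], rel=1e-6)

    def test_too_many_sites_rejected(self):
        panel = panel_from_codes({f"2L:{i + 1}": [2, 2, 0, 0, 2] for i in range(5)})
        y = np.arange(5.0)
        with pytest.raises(ValueError, match="n-2"):
            vq.joint_fit(panel, make_line_values(panel, y), list(panel.site_ids)[:4])
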