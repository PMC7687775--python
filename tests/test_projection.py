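import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from gwasbasis.basis import Basis
from gwasbasis.harmonise import SummaryStats
from gwasbasis.projection import Projection, delta_covariance, fdr_adjust
from gwasbasis.projection import flag_significant, project, project_study
from gwasbasis.projection import test_components as component_tests
from gwasbasis.projection import test_overall as overall_test
from gwasbasis.simulate import simulate_null_betas, simulate_null_study

from conftest import make_panel


def _with_betas(ss, betas):
    from dataclasses import replace
    df = ss.data.copy()
    df["beta"] = betas
    return replace(ss, data=df)


class TestProject:
    def test_all_zero_study_projects_exactly_to_origin(self, small_system):
        basis = small_system["basis"]
        ss = _with_betas(small_system["studies"][0],
                         np.zeros(basis.n_variants))
        np.testing.assert_array_equal(project(basis, ss).delta, 0.0)

    def test_linear_in_effect_estimates(self, small_system):
        basis = small_system["basis"]
        s1 = small_system["studies"][0]
        s2 = small_system["studies"][1]
        both = _with_betas(s1, s1.beta.to_numpy() + s2.beta.to_numpy())
        np.testing.assert_allclose(
            project(basis, both).delta,
            project(basis, s1).delta + project(basis, s2).delta, atol=1e-12)

    def test_training_trait_close_to_full_rotation_oracle(self, small_system):
        """Sparse projection distorts training deltas only minimally."""
        basis = small_system["basis"]
        sparse = np.vstack([project(basis, ss).delta
                            for ss in small_system["studies"]])
        m = basis.scores[:-1] - basis.scores[-1]  # full-Q training deltas
        for k in range(basis.m):
            assert np.corrcoef(sparse[:, k], m[:, k])[0, 1] > 0.999

    def test_missing_variants_fall_back_to_zero(self, small_system, caplog):
        basis = small_system["basis"]
        ss = small_system["studies"][0]
        betas = ss.beta.to_numpy().copy()
        betas[: len(betas) // 2] = np.nan
        with caplog.at_level("WARNING"):
            pr = project(basis, _with_betas(ss, betas))
        assert pr.missing_fraction == pytest.approx(0.5)
        assert "missing" in caplog.text

    def test_unaligned_study_raises(self, small_system):
        from dataclasses import replace
        basis = small_system["basis"]
        ss = small_system["studies"][0]
        short = replace(ss, data=ss.data.iloc[:10])
        with pytest.raises(ValueError, match="aligned"):
            project(basis, short)


def _single_snp_basis(q, w, sigma):
    idx = pd.Index(["1:1:A:G"], name="variant")
    return Basis(traits=["t", "control"], variant_index=idx,
                 col_means=np.zeros(1), rotation=np.array([[1.0]]),
                 scores=np.zeros((2, 1)), singular_values=np.ones(1),
                 mode="continuous", sigma_maf=np.array([sigma]),
                 w=np.array([w]), alpha=np.zeros(1),
                 sparse_rotation=np.array([[q]]))


class TestDeltaCovariance:
    def test_zero_se_gives_zero_matrix(self, small_system):
        basis = small_system["basis"]
        ss = small_system["studies"][0]
        from dataclasses import replace
        df = ss.data.copy()
        df["se"] = 0.0
        v = delta_covariance(basis, replace(ss, data=df),
                             small_system["panel"])
        np.testing.assert_array_equal(v, 0.0)

    def test_single_snp_single_component(self):
        import numpy as _np
        basis = _single_snp_basis(q=0.8, w=0.5, sigma=2.0)
        panel = make_panel([("1", 1, "A", "G", 0.5, "b1")],
                           ld={"b1": _np.eye(1)})
        df = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
        df["beta"], df["se"] = 0.1, 0.3
        ss = SummaryStats(trait_id="t", data=df, aligned=True)
        v = delta_covariance(basis, ss, panel)
        a = 0.8 * 0.5 / 2.0
        assert v[0, 0] == pytest.approx(a**2 * 0.3**2, rel=1e-12)

    def test_monte_carlo_oracle_independent_snps(self, small_system):
        """Analytic Var(delta) matches resampling when LD is the identity."""
        rng = np.random.default_rng(42)
        from gwasbasis.simulate import SimulationScenario, simulate_panel
        sc = SimulationScenario(n_snps=60, n_blocks=3, within_block_ld=0.0,
                                n_traits=3, seed=7)
        panel = simulate_panel(sc)
        basis = small_system["basis"]
        # tiny ad-hoc basis over this panel
        q = rng.normal(size=(60, 2))
        q, _ = np.linalg.qr(q)
        w = rng.uniform(0.1, 1.0, 60)
        sigma = rng.uniform(1.0, 3.0, 60)
        b = Basis(traits=["t", "control"], variant_index=panel.index,
                  col_means=np.zeros(60), rotation=q, scores=np.zeros((2, 2)),
                  singular_values=np.ones(2), mode="continuous",
                  sigma_maf=sigma, w=w, alpha=np.zeros(2), sparse_rotation=q)
        df = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
        beta0 = rng.normal(0, 0.05, 60)
        se = rng.uniform(0.02, 0.08, 60)
        df["beta"], df["se"] = beta0, se
        ss = SummaryStats(trait_id="t", data=df, aligned=True)
        v = delta_covariance(b, ss, panel)
        n_draws = 100_000
        draws = beta0 + rng.standard_normal((n_draws, 60)) * se
        deltas = (draws * (w / sigma)) @ q
        emp = np.cov(deltas.T)
        mc_se = np.sqrt((np.outer(np.diag(emp), np.diag(emp)) + emp**2)
                        / n_draws)
        assert np.all(np.abs(emp - v) < 3 * mc_se)

    def test_diagonal_option_drops_ld_terms(self, small_system):
        basis = small_system["basis"]
        ss = small_system["studies"][0]
        v_full = delta_covariance(basis, ss, small_system["panel"])
        v_diag = delta_covariance(basis, ss, small_system["panel"],
                                  diagonal_ld=True)
        assert not np.allclose(v_full, v_diag)


class TestOverall:
    def test_null_delta_gives_unit_p(self):
        t, df, p = overall_test(np.zeros(5), np.eye(5))
        assert (t, p) == (0.0, 1.0)

    def test_chi_square_quantile_13df(self):
        """At the 95% quantile of chi2(13), ~22.362, p must be 0.05."""
        q95 = chi2.ppf(0.95, 13)
        assert q95 == pytest.approx(22.362, abs=5e-4)
        delta = np.zeros(13)
        delta[0] = np.sqrt(q95)
        t, df, p = overall_test(delta, np.eye(13))
        assert df == 13
        assert p == pytest.approx(0.05, rel=1e-10)

    def test_degenerate_covariance_reduces_df(self):
        v = np.outer([1.0, 1.0], [1.0, 1.0])  # rank 1
        t, df, p = overall_test(np.array([1.0, 1.0]), v)
        assert df == 1
        # V+ = vv'/2 with v = (1,1)/sqrt(2), so T = (delta.v)^2/2 = 1
        assert t == pytest.approx(1.0)

    def test_null_calibration_through_full_pipeline(self, small_system):
        """Null studies projected through the basis give uniform p-values."""
        panel, basis = small_system["panel"], small_system["basis"]
        rng = np.random.default_rng(123)
        betas, se = simulate_null_betas(panel, 400, 2_000, 2_000, rng)
        ss0 = simulate_null_study(panel, 2_000, 2_000, 1)
        v = delta_covariance(basis, ss0, panel)
        deltas = (betas * (basis.w / basis.sigma_maf)) @ \
            basis.projection_rotation()
        ps = np.array([overall_test(d, v)[2] for d in deltas])
        assert kstest(ps, "uniform").pvalue > 0.01
        rate = (ps < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)


class TestComponents:
    def test_zero_delta_unit_p(self):
        z, p = component_tests(np.zeros(3), np.eye(3))
        np.testing.assert_array_equal(p, 1.0)

    def test_normal_tail_oracle(self):
        z, p = component_tests(np.array([1.959964]), np.eye(1))
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_sign_invariance(self):
        v = np.diag([0.5, 2.0])
        _, p_pos = component_tests(np.array([0.3, -1.0]), v)
        _, p_neg = component_tests(np.array([-0.3, 1.0]), v)
        np.testing.assert_allclose(p_pos, p_neg)


class TestFDR:
    def test_bh_step_up_oracle(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_groups_adjusted_independently(self):
        p = [0.01, 0.02, 0.03, 0.04]
        joint = fdr_adjust(p)
        grouped = fdr_adjust(p, grouping=["a", "a", "b", "b"])
        np.testing.assert_allclose(grouped, [0.02, 0.02, 0.04, 0.04])
        assert not np.allclose(joint, grouped)

    def test_monotone_within_group(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFlagSignificant:
    def _proj(self, trait, p_overall, p_comp, category="default"):
        m = len(p_comp)
        return Projection(trait_id=trait, delta=np.zeros(m),
                          var_delta=np.eye(m), z=np.zeros(m),
                          p_component=np.array(p_comp, float),
                          chi2_stat=0.0, df=m, p_overall=p_overall,
                          category=category)

    def test_overall_failure_blocks_component_flags(self):
        prs = [self._proj("a", 0.5, [1e-6, 1e-6]),
               self._proj("b", 1e-5, [0.5, 0.5])]
        tab = flag_significant(prs)
        a = tab[tab["trait"] == "a"]
        assert not a["significant.component"].any()

    def test_conjunction_flags_when_both_pass(self):
        prs = [self._proj("a", 0.001, [0.004, 0.9]),
               self._proj("b", 0.9, [0.9, 0.9])]
        tab = flag_significant(prs)
        a = tab[tab["trait"] == "a"]
        assert a["significant.component"].tolist() == [True, False]

    def test_threshold_is_strict(self):
        prs = [self._proj("a", 0.01, [0.01, 0.01])]
        tab = flag_significant(prs, overall_fdr_threshold=0.01,
                               component_fdr_threshold=0.01)
        assert not tab["significant.overall"].any()


def test_project_study_end_to_end(small_system):
    pr = project_study(small_system["basis"], small_system["studies"][0],
                       small_system["panel"])
    assert pr.p_overall < 1e-6  # a training trait is strongly non-null
    assert pr.var_delta.shape == (pr.m, pr.m)
    evals = np.linalg.eigvalsh(pr.var_delta)
    assert evals.min() > -1e-12


class TestPowerProperties:
    def test_power_monotone_in_effect_scale(self, small_system):
        """Median chi-square grows with the multiplier on a true signal."""
        from gwasbasis.simulate import draw_study

        panel, basis = small_system["panel"], small_system["basis"]
        beta_true = small_system["truth"]["beta_true"][0]
        rng = np.random.default_rng(17)
        medians = []
        for lam in [0.0, 0.5, 1.0]:
            stats = []
            for _ in range(30):
                ss = draw_study(panel, lam * beta_true, 2_000, 2_000, rng,
                                trait_id="scaled")
                pr = project_study(basis, ss, panel)
                stats.append(pr.chi2_stat)
            medians.append(np.median(stats))
        assert medians[0] < medians[1] < medians[2]

    def test_power_monotone_in_sample_size(self, small_system):
        from gwasbasis.simulate import draw_study

        panel, basis = small_system["panel"], small_system["basis"]
        beta_true = small_system["truth"]["beta_true"][0]
        rng = np.random.default_rng(18)
        medians = []
        for n in [200, 2_000, 20_000]:
            stats = []
            for _ in range(30):
                ss = draw_study(panel, beta_true, n, n, rng, trait_id="s")
                pr = project_study(basis, ss, panel)
                stats.append(pr.chi2_stat)
            medians.append(np.median(stats))
        assert medians[0] < medians[1] < medians[2]

    def test_missingness_attenuates_expected_delta(self, small_system):
        """Zero-filling missing variants is conservative: the average
        projected delta shrinks toward zero as missingness grows."""
        basis = small_system["basis"]
        ss = small_system["studies"][0]
        rng = np.random.default_rng(19)
        norms = []
        for frac in [0.0, 0.5, 0.9]:
            deltas = []
            for _ in range(50):
                betas = ss.beta.to_numpy().copy()
                betas[rng.random(betas.size) < frac] = np.nan
                deltas.append(project(basis, _with_betas(ss, betas)).delta)
            norms.append(np.linalg.norm(np.mean(deltas, axis=0)))
        assert norms[0] > norms[1] > norms[2]

    def test_small_replicate_detected_while_null_is_not(self, small_system):
        """A few-hundred-case replicate of a basis trait reaches overall
        significance in most seeds; matched null studies do not."""
        from gwasbasis.simulate import draw_study

        panel, basis = small_system["panel"], small_system["basis"]
        beta_true = small_system["truth"]["beta_true"][0]
        hits_signal, hits_null = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(1_000 + seed)
            rep = draw_study(panel, beta_true, 150, 150, rng, trait_id="rep")
            null = draw_study(panel, np.zeros_like(beta_true), 150, 150, rng,
                              trait_id="null")
            hits_signal += project_study(basis, rep, panel).p_overall < 0.01
            hits_null += project_study(basis, null, panel).p_overall < 0.01
        assert hits_signal > 5
        assert hits_null <= 1
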