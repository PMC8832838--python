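"""REML engine, likelihood-ratio tests, derived genetic parameters,
SNP-BLUP and the Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest

from xgrr import pedrel, simdata, vc


def _plain_records(y, parents=None):
    parents = parents if parents is not None else [f"p{i}" for i in range(len(y))]
    return pd.DataFrame(
        {
            "parent_id": parents,
            "offspring_id": [f"o{i}" for i in range(len(y))],
            "parent_sex": "M",
            "co_count": y,
        }
    )


class TestRemlEngine:
    def test_residual_only_equals_sample_variance(self, rng):
        y = rng.normal(5, 2, 150)
        col = vc.collapse_records(_plain_records(y), ())
        est = vc.reml(col, [])
        assert est.variances["e"] == pytest.approx(np.var(y, ddof=1), rel=1e-8)
        assert est.converged

    def test_balanced_identity_matches_anova(self, rng):
        J, m = 60, 5
        u = rng.normal(0, 2, J)
        y = (u[:, None] + rng.normal(0, 3, (J, m))).ravel()
        rec = _plain_records(y, np.repeat([f"p{i:02d}" for i in range(J)], m))
        col = vc.collapse_records(rec, ())
        est = vc.reml(col, [vc.VarTerm("p", np.eye(J))])
        ybar = y.reshape(J, m).mean(1)
        msb = m * np.sum((ybar - ybar.mean()) ** 2) / (J - 1)
        msw = np.sum((y.reshape(J, m) - ybar[:, None]) ** 2) / (J * (m - 1))
        assert est.variances["p"] == pytest.approx((msb - msw) / m, rel=1e-6)
        assert est.variances["e"] == pytest.approx(msw, rel=1e-6)

    def test_em_loglik_monotone(self, rng):
        J, m = 40, 4
        y = (rng.normal(0, 1.5, J)[:, None] + rng.normal(0, 2, (J, m))).ravel()
        rec = _plain_records(y, np.repeat([f"p{i:02d}" for i in range(J)], m))
        col = vc.collapse_records(rec, ())
        est = vc.reml(col, [vc.VarTerm("p", np.eye(J))], method="em", max_iter=60)
        assert np.all(np.diff(est.logl_path) >= -1e-9)

    def test_record_order_invariance(self, small_cohort):
        truth = simdata.TruthConfig(var_a=2, var_s=1, var_i=0, var_p=0.5, var_e=5, seed=5)
        rec = simdata.simulate_phenotypes(
            small_cohort["ped"], None, small_cohort["gametes"], truth
        )
        spec = vc.ModelSpec(random=("u", "p", "s"))
        structures = {"u": small_cohort["A"], "s": small_cohort["S"]}
        a = vc.fit_reml(spec, rec, structures)
        b = vc.fit_reml(spec, rec.sample(frac=1, random_state=1), structures)
        for k in a.variances:
            assert a.variances[k] == pytest.approx(b.variances[k], rel=1e-5, abs=1e-8)

    def test_scale_equivariance(self, small_cohort):
        truth = simdata.TruthConfig(var_a=2, var_s=1, var_i=0, var_p=0.5, var_e=5, seed=6)
        rec = simdata.simulate_phenotypes(
            small_cohort["ped"], None, small_cohort["gametes"], truth
        )
        spec = vc.ModelSpec(random=("u", "s"))
        structures = {"u": small_cohort["A"], "s": small_cohort["S"]}
        a = vc.fit_reml(spec, rec, structures)
        rec2 = rec.assign(co_count=2.0 * rec["co_count"])
        b = vc.fit_reml(spec, rec2, structures)
        for k in a.variances:
            assert b.variances[k] == pytest.approx(4.0 * a.variances[k], rel=1e-4, abs=1e-6)

    def test_mme_route_agrees_with_dense(self, small_cohort, rng):
        truth = simdata.TruthConfig(var_a=2, var_s=1, var_i=0, var_p=0.5, var_e=5, seed=7)
        rec = simdata.simulate_phenotypes(
            small_cohort["ped"], None, small_cohort["gametes"], truth
        )
        spec = vc.ModelSpec(random=("u", "p", "s"))
        structures = {"u": small_cohort["A"], "s": small_cohort["S"]}
        est = vc.fit_reml(spec, rec, structures)
        col = vc.collapse_records(rec, spec.fixed)
        terms = vc.build_terms(spec.random, col.parents, structures)
        mme = vc.mme_restricted_loglik(col, terms, est.variances)
        assert mme == pytest.approx(est.loglik, abs=1e-7)

    def test_too_few_records_rejected(self):
        with pytest.raises(vc.ModelError):
            vc.fit_reml(vc.ModelSpec(fixed=()), _plain_records([1.0]), {})


class TestLrt:
    def _est(self, logl, names=("u", "e")):
        return vc.VCEstimate(
            variances={n: 1.0 for n in names},
            loglik=logl,
            cov=pd.DataFrame(np.eye(len(names)), index=names, columns=names),
            converged=True,
            n_iter=1,
            method="ai",
            n_records=10,
        )

    def test_identical_likelihoods(self):
        stat, p = vc.lrt_vc(self._est(-50.0, ("u", "s", "e")), self._est(-50.0))
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        stat, p = vc.lrt_vc(
            self._est(-50.0, ("u", "s", "e")), self._est(-50.0 - 3.841459 / 2)
        )
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_mixture_halves_tail(self):
        full, red = self._est(-48.0, ("u", "s", "e")), self._est(-50.0)
        _, p_plain = vc.lrt_vc(full, red)
        _, p_mix = vc.lrt_vc(full, red, mixture=True)
        assert p_mix == pytest.approx(0.5 * p_plain)

    def test_non_nested_rejected(self):
        with pytest.raises(vc.NotNestedError):
            vc.lrt_vc(self._est(-1.0), self._est(-2.0))

    def test_null_rejection_rate_conservative(self, rng):
        """sg2_s = 0 truth: chi2(1) LRT rejects at most ~alpha."""
        J, m = 50, 4
        n_rep, alpha = 120, 0.05
        rejections = 0
        ids = [f"p{i:02d}" for i in range(J)]
        K = np.eye(J)
        for _ in range(n_rep):
            y = (rng.normal(0, 1, J)[:, None] + rng.normal(0, 2, (J, m))).ravel()
            rec = _plain_records(y, np.repeat(ids, m))
            col = vc.collapse_records(rec, ())
            full = vc.reml(col, [vc.VarTerm("p", K), vc.VarTerm("s", _random_psd(J, rng))])
            red = vc.reml(col, [vc.VarTerm("p", K)])
            _, p = vc.lrt_vc(full, red)
            rejections += p < alpha
        rate = rejections / n_rep
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_rep)


def _random_psd(J, rng):
    B = rng.normal(size=(J, J + 5))
    K = B @ B.T / (J + 5)
    d = np.sqrt(np.diag(K))
    return K / np.outer(d, d)


class TestDerivedParams:
    def _est(self, variances, cov=None):
        names = list(variances)
        c = cov if cov is not None else np.full((len(names), len(names)), np.nan)
        return vc.VCEstimate(
            variances=variances,
            loglik=0.0,
            cov=pd.DataFrame(c, index=names, columns=names),
            converged=True,
            n_iter=1,
            method="ai",
            n_records=100,
        )

    def test_study_partition_arithmetic(self):
        # the male GRR partition: genetic 11.1 + 4.7 of 100 -> h2 15.8%,
        # X fraction 4.7/15.8 = 29.7%
        est = self._est({"u": 11.1, "s": 4.7, "p": 1.0, "e": 83.2})
        d = vc.derived_params(est)
        assert d.heritability == pytest.approx(0.158, abs=1e-3)
        assert d.x_fraction == pytest.approx(4.7 / 15.8, abs=1e-3)
        assert d.repeatability == pytest.approx(0.168, abs=1e-3)

    def test_no_genetic_variance(self):
        est = self._est({"u": 0.0, "p": 2.0, "e": 8.0})
        d = vc.derived_params(est)
        assert d.heritability == 0.0
        assert d.repeatability == pytest.approx(0.2)

    def test_sampled_sd_matches_delta_method(self):
        # tight independent uncertainty: SD of h2 = |dh/dv| sigma combined
        v = {"u": 4.0, "e": 16.0}
        cov = np.diag([0.04, 0.0])  # only sg2_u uncertain
        est = self._est(v, cov)
        d = vc.derived_params(est, n_draws=40_000, seed=1)
        # h2 = u/(u+e); dh/du = e/(u+e)^2 = 16/400
        delta_sd = (16.0 / 400.0) * 0.2
        assert d.heritability_sd == pytest.approx(delta_sd, rel=0.05)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(vc.ModelError):
            vc.derived_params(self._est({"u": 0.0, "e": 0.0}))


class TestSnpBlup:
    def _panel_and_records(self, rng, n=120, M=30, h2x=0.4):
        pos = np.arange(1, M + 1, dtype=np.int64)
        table = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(M)],
                "pos": pos,
                "region": "X-specific",
                "ref": "A",
                "alt": "B",
                "cm_female": np.arange(M, dtype=float),
                "cm_male": 0.0,
            }
        )
        mm = simdata.MarkerMap(table, par_boundary=M + 1)
        haps = np.zeros((n, 2, M), dtype=np.uint8)
        haps[:, 0] = rng.random((n, M)) < 0.5
        haps[:, 1] = simdata.HaplotypePanel.INVALID
        ids = np.array([f"P{i}" for i in range(n)])
        panel = simdata.HaplotypePanel(
            mm, ids, np.array(["M"] * n, dtype=object), haps
        )
        xmat = pedrel.scaled_X(panel, maf_min=0.0)
        g = xmat.values @ rng.normal(0, np.sqrt(h2x), M) * np.sqrt(M)
        rows = []
        for i, pid in enumerate(ids):
            for r in range(3):
                rows.append((pid, f"o{i}_{r}", "M", g[i] + rng.normal(0, 1.5)))
        rec = pd.DataFrame(
            rows, columns=["parent_id", "offspring_id", "parent_sex", "co_count"]
        )
        return xmat, rec

    def test_null_phenotypes_boundary(self, rng):
        xmat, rec = self._panel_and_records(rng, h2x=0.0)
        rec["co_count"] = rng.normal(0, 1, len(rec))
        est = vc.snp_blup_variance(rec, xmat, spec=vc.ModelSpec(random=("p", "m"), fixed=()))
        assert est.variances["m"] < 0.05

    def test_equivalent_to_grm_model(self, rng):
        xmat, rec = self._panel_and_records(rng)
        est_m = vc.snp_blup_variance(rec, xmat, spec=vc.ModelSpec(random=("p", "m"), fixed=()))
        grm = pedrel.RelationshipMatrix("realized-X", xmat.ids, xmat.grm())
        est_g = vc.fit_reml(vc.ModelSpec(random=("p", "s"), fixed=()), rec, {"s": grm})
        assert est_m.loglik == pytest.approx(est_g.loglik, abs=1e-6)
        assert est_m.variances["m"] == pytest.approx(est_g.variances["s"], rel=1e-3, abs=1e-6)

    def test_spec_must_name_marker_term(self, rng):
        xmat, rec = self._panel_and_records(rng)
        with pytest.raises(vc.ModelError):
            vc.snp_blup_variance(rec, xmat, spec=vc.ModelSpec(random=("p",), fixed=()))


class TestGibbs:
    def _setup(self, rng):
        J, m = 50, 5
        u = rng.normal(0, 2, J)
        y = (u[:, None] + rng.normal(0, 2, (J, m))).ravel()
        rec = _plain_records(y, np.repeat([f"p{i:02d}" for i in range(J)], m))
        col = vc.collapse_records(rec, ())
        terms = [vc.VarTerm("p", np.eye(J))]
        return col, terms

    def test_same_seed_identical_chains(self, rng):
        col, terms = self._setup(rng)
        a = vc.gibbs_vc(col, terms, n_iter=200, burn_in=50, seed=3)
        b = vc.gibbs_vc(col, terms, n_iter=200, burn_in=50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_posterior_mean_near_reml(self, rng):
        col, terms = self._setup(rng)
        reml_est = vc.reml(col, terms)
        draws = vc.gibbs_vc(col, terms, n_iter=3000, burn_in=500, seed=4)
        for k in ("p", "e"):
            post = draws[k].mean()
            spread = 3 * draws[k].std()
            assert abs(post - reml_est.variances[k]) < spread

    def test_chain_shorter_than_burnin_rejected(self, rng):
        col, terms = self._setup(rng)
        with pytest.raises(vc.ModelError):
            vc.gibbs_vc(col, terms, n_iter=100, burn_in=100)


class TestRecoverySmoke:
    def test_components_within_three_se(self, small_cohort):
        """One moderate replicate at the study's variance ratios."""
        truth = simdata.TruthConfig(
            mu=70, var_a=11, var_s=5, var_i=0, var_p=1, var_e=83,
            round_counts=False, seed=9,
        )
        rec = simdata.simulate_phenotypes(
            small_cohort["ped"], None, small_cohort["gametes"], truth
        )
        est = vc.fit_reml(
            vc.ModelSpec(random=("u", "p", "s")),
            rec,
            {"u": small_cohort["A"], "s": small_cohort["S"]},
        )
        for k, true in (("u", 11.0), ("s", 5.0), ("p", 1.0), ("e", 83.0)):
            se = est.se(k)
            if np.isnan(se):
                se = true  # boundary component: wide interval
            assert abs(est.variances[k] - true) <= 3 * se + 1e-6
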