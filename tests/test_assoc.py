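"""Association machinery: thresholds, single-locus variance, credible
sets against brute force, GLS scan properties, conditional analysis and
joint variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from xgrr import assoc, hapclust, simdata


@pytest.fixture(scope="module")
def qtl_study(small_cohort):
    """Records with one male X QTL of effect +1.0 CO on the shared cohort."""
    mm = small_cohort["map"]
    panel = small_cohort["panel"]
    freqs = panel.allele_frequencies()
    xids = mm.ids[mm.region_mask("X-specific")]
    # a common marker makes the small-sample effect estimate stable
    qcol = int(np.argmin(np.abs(freqs - 0.5)))
    qid = mm.ids[qcol]
    truth = simdata.TruthConfig(
        var_a=0.5, var_s=0.2, var_i=0.0, var_p=0.1, var_e=4.0,
        qtls=(simdata.QTL(qid, 1.0, "male"),),
        round_counts=False,
        seed=77,
    )
    rec = simdata.simulate_phenotypes(
        small_cohort["ped"], panel, small_cohort["gametes"], truth
    )
    dosages = panel.dosages("X-specific").loc[small_cohort["sires"]]
    variants = pd.DataFrame(
        {"pos": mm.positions[mm.region_mask("X-specific")]}, index=xids
    )
    structures = {"u": small_cohort["A"], "s": small_cohort["S"]}
    return {
        "records": rec,
        "dosages": dosages.astype(float),
        "variants": variants,
        "structures": structures,
        "qid": qid,
        "qcol": qcol,
    }


class TestThresholdAndVariance:
    def test_bonferroni_paper_value(self):
        thr = assoc.bonferroni_threshold(0.05, 30_000)
        assert thr == pytest.approx(1.67e-6, rel=5e-3)
        assert assoc.bonferroni_threshold(0.05, 1) == 0.05
        assert assoc.bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)

    def test_bonferroni_validation(self):
        with pytest.raises(assoc.AssocError):
            assoc.bonferroni_threshold(0.0, 10)
        with pytest.raises(assoc.AssocError):
            assoc.bonferroni_threshold(0.05, 0)

    def test_qtl_variance_table1_row(self):
        # chrX:116625345: frequency 24.1%, effect 0.78 CO
        assert assoc.qtl_variance(0.241, 0.78) == pytest.approx(0.1113, abs=5e-5)
        assert assoc.qtl_variance(0.3, 0.0) == 0.0
        assert assoc.qtl_variance(0.5, 1.0) == 0.25
        with pytest.raises(assoc.AssocError):
            assoc.qtl_variance(0.0, 1.0)


class TestCredibleSet:
    def _ld_dosages(self, rng, n=150, m=40):
        mm_pos = pd.Series(np.arange(m) * 1000 + 1)
        pool = rng.integers(0, 2, (6, m)).astype(float)
        rowsel = rng.integers(0, 6, n)
        X = pool[rowsel] + (rng.random((n, m)) < 0.1)  # noise breaks ties
        X = np.clip(X, 0, 1)
        dos = pd.DataFrame(X, columns=[f"v{i}" for i in range(m)])
        dos = dos.loc[:, dos.std() > 0]
        pos = pd.Series(mm_pos.values[: m], index=[f"v{i}" for i in range(m)])
        return dos, pos.loc[dos.columns]

    def test_membership_matches_brute_force(self, rng):
        dos, pos = self._ld_dosages(rng)
        for lead in rng.choice(dos.columns.to_numpy(), 5, replace=False):
            cs = assoc.credible_set(dos, pos, lead, 0.9)
            brute = {
                v
                for v in dos.columns
                if v == lead
                or np.corrcoef(dos[lead], dos[v])[0, 1] ** 2 > 0.9
            }
            assert set(cs.members.index) == brute
            assert cs.members.loc[lead, "r2"] == 1.0

    def test_duplicate_column_is_member(self, rng):
        dos, pos = self._ld_dosages(rng)
        lead = dos.columns[0]
        dos = dos.assign(dup=dos[lead])
        pos = pd.concat([pos, pd.Series({"dup": 99_999})])
        cs = assoc.credible_set(dos, pos, lead, 0.9)
        assert "dup" in cs
        assert cs.span >= 0

    def test_monomorphic_lead_rejected(self, rng):
        dos, pos = self._ld_dosages(rng)
        dos = dos.assign(mono=1.0)
        pos = pd.concat([pos, pd.Series({"mono": 5})])
        with pytest.raises(assoc.AssocError):
            assoc.credible_set(dos, pos, "mono", 0.9)


class TestSeqScan:
    def test_maf_filter_excludes_rare_variant(self, qtl_study):
        dos = qtl_study["dosages"].copy()
        rare = np.zeros(len(dos))
        rare[0] = 1.0  # MAF ~ 0.005 at ~120 sires: below 0.01
        dos["rare"] = rare
        variants = pd.concat(
            [qtl_study["variants"], pd.DataFrame({"pos": [999]}, index=["rare"])]
        )
        res = assoc.seq_scan(
            qtl_study["records"], variants, dos, qtl_study["structures"]
        )
        assert "rare" not in set(res["id"])
        assert res.attrs["variants_removed_maf"] >= 1

    def test_rsq_filter(self, qtl_study):
        variants = qtl_study["variants"].copy()
        variants["rsq"] = 1.0
        variants.iloc[0, variants.columns.get_loc("rsq")] = 0.5
        res = assoc.seq_scan(
            qtl_study["records"], variants, qtl_study["dosages"], qtl_study["structures"]
        )
        assert res.attrs["variants_removed_rsq"] == 1

    def test_effect_recovery(self, qtl_study):
        res = assoc.seq_scan(
            qtl_study["records"],
            qtl_study["variants"],
            qtl_study["dosages"],
            qtl_study["structures"],
        ).set_index("id")
        row = res.loc[qtl_study["qid"]]
        assert abs(row["effect"] - 1.0) <= 2 * row["se"]

    def test_duplicate_variant_identical_statistic(self, qtl_study):
        dos = qtl_study["dosages"].copy()
        dos["dup"] = dos[qtl_study["qid"]]
        variants = pd.concat(
            [qtl_study["variants"], pd.DataFrame({"pos": [123]}, index=["dup"])]
        )
        res = assoc.seq_scan(
            qtl_study["records"], variants, dos, qtl_study["structures"]
        ).set_index("id")
        assert res.loc["dup", "stat"] == pytest.approx(
            res.loc[qtl_study["qid"], "stat"], abs=1e-9
        )

    def test_equivariance_scaling_and_allele_flip(self, qtl_study):
        rec2 = qtl_study["records"].assign(
            co_count=2.0 * qtl_study["records"]["co_count"]
        )
        res1 = assoc.seq_scan(
            qtl_study["records"], qtl_study["variants"], qtl_study["dosages"],
            qtl_study["structures"],
        ).set_index("id")
        # doubling y doubles beta but the background refit keeps |Z|
        res2 = assoc.seq_scan(
            rec2, qtl_study["variants"], qtl_study["dosages"], qtl_study["structures"]
        ).set_index("id")
        assert np.allclose(res2["effect"], 2.0 * res1["effect"], rtol=1e-4)
        assert np.allclose(res2["stat"], res1["stat"], rtol=1e-4)
        flipped = qtl_study["dosages"].copy()
        qid = qtl_study["qid"]
        flipped[qid] = 1.0 - flipped[qid]
        res3 = assoc.seq_scan(
            qtl_study["records"], qtl_study["variants"], flipped,
            qtl_study["structures"],
        ).set_index("id")
        assert res3.loc[qid, "effect"] == pytest.approx(-res1.loc[qid, "effect"], rel=1e-6)
        assert abs(res3.loc[qid, "stat"]) == pytest.approx(abs(res1.loc[qid, "stat"]), rel=1e-6)


class TestHapScan:
    def test_identical_clusters_give_null_result(self, qtl_study, small_cohort):
        sires = small_cohort["sires"]
        states = np.zeros((len(sires), 4), dtype=np.int32)
        asg = hapclust.ClusterAssignment(states, [(s, 0) for s in sires])
        res = assoc.hap_scan(
            qtl_study["records"], asg, qtl_study["structures"], positions=np.arange(4)
        )
        assert (res["sigma2_h"] == 0).all()
        assert (res["p"] == 1.0).all()
        assert len(res.attrs["skipped"]) == 4

    def test_cluster_tagging_causal_dosage_is_detected(self, qtl_study, small_cohort):
        """A position whose clusters tag the causal dosage shows the signal."""
        sires = small_cohort["sires"]
        rng = np.random.default_rng(9)
        qdose = qtl_study["dosages"][qtl_study["qid"]].reindex(sires).to_numpy()
        states = rng.integers(2, 6, (len(sires), 5)).astype(np.int32)
        states[:, 2] = qdose  # clusters 0/1 carry the causal allele split
        asg = hapclust.ClusterAssignment(states, [(s, 0) for s in sires])
        res = assoc.hap_scan(
            qtl_study["records"], asg, qtl_study["structures"],
            positions=np.arange(5),
        ).set_index("pos")
        assert res.loc[2, "p"] < 0.01
        assert res.loc[2, "p"] < res.drop(index=2)["p"].min()
        assert res.loc[2, "sigma2_h"] > 0


class TestConditional:
    def test_conditioning_on_causal_removes_signal(self, qtl_study):
        thr = 1e-3
        res, leads, dropped = assoc.conditional_scan(
            qtl_study["records"],
            qtl_study["variants"],
            qtl_study["dosages"],
            qtl_study["structures"],
            leads=[qtl_study["qid"]],
            threshold=thr,
            iterate=False,
        )
        assert qtl_study["qid"] not in set(res["id"])
        # nearby linked variants collapse once the causal dosage is fixed
        base = assoc.seq_scan(
            qtl_study["records"], qtl_study["variants"], qtl_study["dosages"],
            qtl_study["structures"],
        ).set_index("id")
        cond = res.set_index("id")
        strong = base[base["p"] < 1e-4].index.difference([qtl_study["qid"]])
        for v in strong:
            assert cond.loc[v, "p"] > base.loc[v, "p"]

    def test_conditioning_on_independent_variant_preserves_lead(self, qtl_study):
        base = assoc.seq_scan(
            qtl_study["records"], qtl_study["variants"], qtl_study["dosages"],
            qtl_study["structures"],
        ).set_index("id")
        qid = qtl_study["qid"]
        corrs = {
            v: np.corrcoef(qtl_study["dosages"][qid], qtl_study["dosages"][v])[0, 1] ** 2
            for v in qtl_study["dosages"].columns
            if v != qid and qtl_study["dosages"][v].std() > 0
        }
        indep = min(corrs, key=corrs.get)
        res, _, _ = assoc.conditional_scan(
            qtl_study["records"], qtl_study["variants"], qtl_study["dosages"],
            qtl_study["structures"], leads=[indep], iterate=False,
        )
        cond_p = res.set_index("id").loc[qid, "p"]
        l0, l1 = -np.log10(base.loc[qid, "p"]), -np.log10(cond_p)
        assert abs(l1 - l0) <= 0.1 * l0 + 0.3

    def test_two_independent_qtl_found_then_stops(self, small_cohort):
        """Iterative conditioning promotes both planted QTL, then halts."""
        mm = small_cohort["map"]
        panel = small_cohort["panel"]
        freqs = panel.allele_frequencies()
        common = np.argsort(np.abs(freqs - 0.5))
        q1 = int(common[0])
        # second QTL: common but nearly uncorrelated with the first
        dos_all = panel.dosages("X-specific").loc[small_cohort["sires"]].astype(float)
        r2_to_q1 = {
            c: np.corrcoef(dos_all.iloc[:, q1], dos_all.iloc[:, c])[0, 1] ** 2
            for c in common[1:40]
            if dos_all.iloc[:, c].std() > 0
        }
        q2 = min(r2_to_q1, key=r2_to_q1.get)
        truth = simdata.TruthConfig(
            var_a=0.3, var_s=0.1, var_i=0.0, var_p=0.05, var_e=3.0,
            qtls=(
                simdata.QTL(mm.ids[q1], 1.0, "male"),
                simdata.QTL(mm.ids[q2], -1.0, "male"),
            ),
            round_counts=False,
            seed=88,
        )
        rec = simdata.simulate_phenotypes(
            small_cohort["ped"], panel, small_cohort["gametes"], truth
        )
        variants = pd.DataFrame(
            {"pos": mm.positions[mm.region_mask("X-specific")]},
            index=mm.ids[mm.region_mask("X-specific")],
        )
        structures = {"u": small_cohort["A"], "s": small_cohort["S"]}
        first = assoc.seq_scan(rec, variants, dos_all, structures)
        lead1 = first.loc[first["p"].idxmin(), "id"]
        res, leads, dropped = assoc.conditional_scan(
            rec, variants, dos_all, structures, leads=[lead1], threshold=1e-4
        )
        assert {mm.ids[q1], mm.ids[q2]} <= set(leads)
        assert len(res) == 0 or res["p"].min() >= 1e-4

    def test_collinear_lead_dropped(self, qtl_study):
        dos = qtl_study["dosages"].copy()
        dos["dup"] = dos[qtl_study["qid"]]
        variants = pd.concat(
            [qtl_study["variants"], pd.DataFrame({"pos": [5]}, index=["dup"])]
        )
        res, leads, dropped = assoc.conditional_scan(
            qtl_study["records"], variants, dos, qtl_study["structures"],
            leads=[qtl_study["qid"], "dup"], iterate=False,
        )
        assert dropped == ["dup"]


class TestJointFit:
    def test_fitting_causal_variant_reduces_x_variance(self, qtl_study):
        dos = qtl_study["dosages"][[qtl_study["qid"]]]
        table, report = assoc.joint_fit_variants(
            qtl_study["records"], dos, qtl_study["structures"]
        )
        d = qtl_study["dosages"][qtl_study["qid"]].to_numpy()
        p_hat = d.mean()  # male haploid dosage
        v_qtl = assoc.qtl_variance(p_hat, 1.0)
        drop = (
            report["base_variances"]["s"] - report["joint_variances"]["s"]
        )
        assert drop == pytest.approx(v_qtl, abs=0.75 * v_qtl)
        assert table.loc[qtl_study["qid"], "share"] > 0

    def test_null_variant_changes_nothing_much(self, qtl_study, rng):
        # a random dosage independent of the phenotype
        dos = pd.DataFrame(
            {"null_v": rng.integers(0, 2, len(qtl_study["dosages"]))},
            index=qtl_study["dosages"].index,
        ).astype(float)
        table, report = assoc.joint_fit_variants(
            qtl_study["records"], dos, qtl_study["structures"]
        )
        est = table.loc["null_v"]
        se = est["effect"] / _z_of(est["p"]) if est["p"] < 1 else np.inf
        assert abs(est["effect"]) <= 2.5 * abs(se) + 0.5


def _z_of(p):
    from scipy import stats

    return stats.norm.isf(p / 2)


class TestPermutation:
    def test_permutation_preserves_counts_and_values(self, qtl_study):
        rec = qtl_study["records"]
        perm = assoc.permute_parent_phenotypes(rec, seed=5)
        assert sorted(perm["co_count"]) == sorted(rec["co_count"])
        a = rec.groupby("parent_id")["c1"].first()
        b = perm.groupby("parent_id")["c1"].first()
        pd.testing.assert_series_equal(a, b)
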