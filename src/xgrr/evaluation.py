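"""Reference checks of the pipeline against its statistical oracles.

Each function here re-derives one quantitative property of the method
from scratch at a fixed, documented problem size: the Bonferroni
threshold, the Hardy-Weinberg scaling of the X dosage matrix, the
gene-dropping oracle for the pedigree S matrix, the SNP-BLUP/GRM
equivalence, REML parameter recovery at the study's variance partition,
scan calibration and power at a reported-scale QTL, the HMM forward
oracle, and the brute-force credible-set check. The acceptance script
and the acceptance tests both call these, so the reported numbers are
always recomputed by the package itself.
"""

from __future__ import annotations

import functools

import numpy as np
import pandas as pd

from . import assoc, hapclust, pedrel, simdata, vc
from .pedigree import FEMALE, MALE, Pedigree


def _sub(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# t: Bonferroni threshold
# ---------------------------------------------------------------------------


def bonferroni_check() -> float:
    """Genome-wide threshold for FWER 0.05 over 30,000 tests."""
    return assoc.bonferroni_threshold(0.05, 30_000)


# ---------------------------------------------------------------------------
# t: female XX' diagonal under Hardy-Weinberg
# ---------------------------------------------------------------------------


def female_xx_diagonal(seed: int, n_females: int = 5000, n_markers: int = 300) -> float:
    """Mean diagonal of the rescaled female dosage cross-product.

    Haplotypes drawn independently per female under Hardy-Weinberg at
    uniform(0.05, 0.95) frequencies; the centering/scaling convention
    should give a mean diagonal of 1.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.95, n_markers)
    mm = _flat_map(n_markers)
    haps = (rng.random((n_females, 2, n_markers)) < freqs).astype(np.uint8)
    panel = simdata.HaplotypePanel(
        mm,
        np.array([f"F{i}" for i in range(n_females)]),
        np.array([FEMALE] * n_females, dtype=object),
        haps,
    )
    xmat = pedrel.scaled_X(panel, maf_min=0.0)
    diag = np.einsum("ij,ij->i", xmat.values, xmat.values)
    return float(diag.mean())


def _flat_map(n_markers: int, spacing_cm: float = 1.0) -> simdata.MarkerMap:
    """All-X-specific marker map with even genetic spacing."""
    pos = np.arange(1, n_markers + 1, dtype=np.int64) * 1000
    table = pd.DataFrame(
        {
            "id": [f"M{i}" for i in range(n_markers)],
            "pos": pos,
            "region": simdata.X_SPECIFIC,
            "ref": "A",
            "alt": "B",
            "cm_female": np.arange(n_markers) * spacing_cm,
            "cm_male": 0.0,
        }
    )
    return simdata.MarkerMap(table, par_boundary=int(pos[-1]) + 1)


# ---------------------------------------------------------------------------
# t: S-matrix gene-dropping oracle
# ---------------------------------------------------------------------------


def s_matrix_oracle(seed: int, n_loci: int = 100_000, chunk: int = 10_000) -> dict:
    """Pedigree S versus averaged realized X relationships.

    A ~200-individual, 5-generation pedigree; biallelic loci at frequency
    one half spaced 5 Morgans apart (switch probability ~0.5, effectively
    independent) are dropped through every meiosis, and the realized
    relationship matrices from the scaled dosages are averaged. Returns
    the largest absolute deviation from the pedigree S, plus the
    canonical first-degree S values from a nuclear family.
    """
    ped = simdata.simulate_pedigree(
        n_founders=50,
        n_generations=5,
        mean_offspring_per_sire=4,
        mean_gametes_per_parent=1.75,
        seed=_sub(seed, 31),
    )
    S = pedrel.xlinked_S(ped).values
    acc = np.zeros_like(S)
    n_chunks = max(1, n_loci // chunk)
    for c in range(n_chunks):
        mm = _flat_map(chunk, spacing_cm=500.0)
        panel = simdata.drop_genomes(
            ped, mm, founder_freqs=0.5, seed=_sub(seed, 100 + c), track_origins=False
        )
        xmat = pedrel.scaled_X(panel, freqs=np.full(chunk, 0.5), maf_min=0.0)
        acc += xmat.grm()
    realized = acc / n_chunks
    max_err = float(np.max(np.abs(realized - S)))

    fam = Pedigree(
        pd.DataFrame(
            [
                ("sire", "0", "0", "M"),
                ("dam", "0", "0", "F"),
                ("son1", "sire", "dam", "M"),
                ("son2", "sire", "dam", "M"),
                ("dau1", "sire", "dam", "F"),
                ("dau2", "sire", "dam", "F"),
            ],
            columns=["id", "sire", "dam", "sex"],
        )
    )
    Sf = pedrel.xlinked_S(fam)
    return {
        "n_individuals": int(ped.n),
        "n_loci": n_chunks * chunk,
        "max_abs_error": max_err,
        "sire_son": Sf.loc("sire", "son1"),
        "sire_daughter": Sf.loc("sire", "dau1"),
        "full_sisters": Sf.loc("dau1", "dau2"),
        "full_brothers": Sf.loc("son1", "son2"),
    }


# ---------------------------------------------------------------------------
# t: SNP-BLUP <-> GRM equivalence
# ---------------------------------------------------------------------------


def snp_blup_equivalence(
    seed: int, n_instances: int = 20, n: int = 200, M: int = 50
) -> dict:
    """Restricted log-likelihood agreement between the two formulations.

    For random male panels and phenotypes, the marker-effect model (one
    random effect per SNP with common variance, fitted marker-side) and
    the equivalent individual-effect model with the realized GRM XX' are
    fitted independently; their maximized restricted likelihoods must
    coincide. The marker-side MME evaluation is also compared with the
    dense V-based evaluation at the fitted parameters.
    """
    max_fit_diff = 0.0
    max_route_diff = 0.0
    for inst in range(n_instances):
        rng = np.random.default_rng(_sub(seed, 200 + inst))
        freqs = rng.uniform(0.1, 0.9, M)
        mm = _flat_map(M)
        haps = np.zeros((n, 2, M), dtype=np.uint8)
        haps[:, 0] = rng.random((n, M)) < freqs
        haps[:, 1] = simdata.HaplotypePanel.INVALID
        ids = np.array([f"P{i}" for i in range(n)])
        panel = simdata.HaplotypePanel(
            mm, ids, np.array([MALE] * n, dtype=object), haps
        )
        xmat = pedrel.scaled_X(panel, maf_min=0.0)
        effects = rng.normal(0, np.sqrt(2.0 / M), M)
        g = xmat.values @ effects * np.sqrt(M)
        n_rec = rng.integers(2, 5, n)
        rows = []
        for i, pid in enumerate(ids):
            pe = rng.normal(0, 1.0)
            for r in range(n_rec[i]):
                rows.append((pid, f"o{i}_{r}", "M", g[i] + pe + rng.normal(0, 2.0)))
        rec = pd.DataFrame(
            rows, columns=["parent_id", "offspring_id", "parent_sex", "co_count"]
        )
        est_m = vc.snp_blup_variance(
            rec, xmat, spec=vc.ModelSpec(random=("p", "m"), fixed=())
        )
        grm = pedrel.RelationshipMatrix("realized-X", ids, xmat.grm())
        est_g = vc.fit_reml(
            vc.ModelSpec(random=("p", "s"), fixed=()), rec, {"s": grm}
        )
        max_fit_diff = max(max_fit_diff, abs(est_m.loglik - est_g.loglik))
        col = vc.collapse_records(rec, ())
        terms = vc.build_terms(("p", "m"), col.parents, {"m": xmat})
        mme = vc.mme_restricted_loglik(col, terms, est_m.variances)
        max_route_diff = max(max_route_diff, abs(mme - est_m.loglik))
    return {
        "max_loglik_difference": max_fit_diff,
        "max_route_difference": max_route_diff,
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# t: REML parameter recovery at the study's variance partition
# ---------------------------------------------------------------------------

RECOVERY_TRUTH = {"u": 11.0, "s": 5.0, "p": 1.0, "e": 83.0}


def recovery_pedigree(seed: int):
    """The fixed cohort used for parameter recovery (~940 sires x 20)."""
    ped = simdata.simulate_pedigree(
        n_founders=1400,
        n_generations=5,
        mean_offspring_per_sire=20,
        mean_gametes_per_parent=2.7,
        seed=_sub(seed, 7),
    )
    sires = sorted(set(ped.table["sire"]) - {"0"})
    anc = ped.ancestor_closure(sires)
    A = pedrel.autosomal_A(anc)
    S = pedrel.xlinked_S(anc)
    gametes = [
        (s, o) for s, o in zip(ped.table["sire"], ped.table["id"]) if s != "0"
    ]
    return ped, anc, sires, A, S, gametes


def reml_recovery(seed: int, n_rep: int = 50) -> dict:
    """Recovery of (sg2_a, sg2_s, sg2_p, sg2_e) = (11, 5, 1, 83).

    Phenotypes are redrawn ``n_rep`` times over one pedigree; each
    component is counted as recovered when the REML estimate falls within
    2 asymptotic SE of the truth. Also returns the mean recovered X share
    of genetic variance (truth 5/16 = 0.3125).
    """
    ped, anc, sires, A, S, gametes = recovery_pedigree(seed)
    spec = vc.ModelSpec(random=("u", "p", "s"))
    within = {k: 0 for k in RECOVERY_TRUTH}
    xshares = []
    for rep in range(n_rep):
        truth = simdata.TruthConfig(
            mu=70.0,
            var_a=RECOVERY_TRUTH["u"],
            var_s=RECOVERY_TRUTH["s"],
            var_i=0.0,
            var_p=RECOVERY_TRUTH["p"],
            var_e=RECOVERY_TRUTH["e"],
            round_counts=False,
            seed=_sub(seed, 300 + rep),
        )
        rec = simdata.simulate_phenotypes(ped, None, gametes, truth)
        est = vc.fit_reml(spec, rec, {"u": A, "s": S})
        for k, true in RECOVERY_TRUTH.items():
            se = est.se(k)
            if np.isnan(se):
                se = np.sqrt(est.cov.to_numpy()[np.isfinite(est.cov.to_numpy())].max())
            if abs(est.variances[k] - true) <= 2.0 * se:
                within[k] += 1
        xshares.append(est.variances["s"] / (est.variances["u"] + est.variances["s"]))
    return {
        "n_replicates": n_rep,
        "n_records": len(gametes),
        "n_sires": len(sires),
        "within_2se": within,
        "min_within_2se": min(within.values()),
        "mean_x_share": float(np.mean(xshares)),
    }


# ---------------------------------------------------------------------------
# t: scan power and calibration
# ---------------------------------------------------------------------------

QTL_EFFECT = 1.16
QTL_FREQ = 0.057
N_X_MARKERS = 150
SCAN_K = 40


@functools.lru_cache(maxsize=2)
def scan_cohort(seed: int):
    """Fixed breeding pedigree (~1,000 recorded sires) for the scan checks.

    Restricted to the ancestor closure of the sires, which carries all the
    genetic and genealogical information the scans use.
    """
    ped = simdata.simulate_pedigree(
        n_founders=1100,
        n_generations=5,
        mean_offspring_per_sire=10,
        mean_gametes_per_parent=2.5,
        seed=_sub(seed, 11),
    )
    sires = sorted(set(ped.table["sire"]) - {"0"})
    anc = ped.ancestor_closure(sires)
    A = pedrel.autosomal_A(anc)
    S = pedrel.xlinked_S(anc)
    return anc, sires, A, S


def _scan_panel(anc, seed: int, qcol: int):
    """Drop an LD panel with the QTL allele planted at its target frequency."""
    mm = simdata.default_marker_map(n_x=N_X_MARKERS, n_par=10)
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, mm.n_markers)
    pool = simdata.mosaic_founder_haps(
        mm, 4 * anc.n // 3, n_ancestral=35, founder_freqs=freqs, seed=seed
    )
    simdata.plant_allele_on_background(pool, qcol, QTL_FREQ)
    panel = simdata.drop_genomes(
        anc, mm, founder_haps=pool, seed=seed + 1, track_origins=False
    )
    return mm, panel


def scan_power(seed: int, n_rep: int = 10) -> dict:
    """Detection of a (p=0.057, a=+1.16 CO) male X QTL, genome-wide.

    Per replicate: fresh LD panel and phenotypes over the fixed pedigree,
    haplotype clustering (K=40), null background REML, haplotype LRT scan
    and sequence dosage scan. Detection = sequence-scan p below the
    genome-wide threshold within 3 markers of the QTL; the haplotype
    scan's localization is recorded alongside.
    """
    anc, sires, A, S = scan_cohort(seed)
    structures = {"u": A, "s": S}
    threshold = assoc.bonferroni_threshold(0.05, 30_000)
    qcol = N_X_MARKERS // 2
    detected = 0
    hap_local = 0
    hap_ps = []
    seq_ps = []
    freqs_realized = []
    for rep in range(n_rep):
        sd = _sub(seed, 500 + rep)
        mm, panel = _scan_panel(anc, sd, qcol)
        xmask = mm.region_mask(simdata.X_SPECIFIC)
        qid = mm.ids[qcol]
        freqs_realized.append(float(panel.allele_frequencies()[qcol]))
        truth = simdata.TruthConfig(
            qtls=(simdata.QTL(qid, QTL_EFFECT, "male"),), seed=sd + 2
        )
        rec = simdata.simulate_phenotypes(
            anc, panel, [(s, f"r{i}") for s in sires for i in range(20)], truth
        )
        rows = [panel.index_of(s) for s in sires]
        H = panel.haps[rows][:, 0, :][:, xmask]
        model = hapclust.fit_cluster_model(
            H,
            K=SCAN_K,
            n_starts=1,
            max_iter=20,
            seed=sd + 3,
            positions_cm=mm.table["cm_female"].to_numpy()[xmask],
        )
        asg = hapclust.assign_clusters(model, H, [(s, 0) for s in sires])
        bg = assoc.fit_null_background(rec, structures)
        hres = assoc.hap_scan(
            rec, asg, structures, positions=np.nonzero(xmask)[0], background=bg
        )
        dos = panel.dosages(simdata.X_SPECIFIC).loc[sires]
        variants = pd.DataFrame(
            {"pos": np.nonzero(xmask)[0]}, index=mm.ids[xmask]
        )
        sres = assoc.seq_scan(rec, variants, dos, structures, background=bg).set_index("id")
        near = [mm.ids[c] for c in range(qcol - 3, qcol + 4)]
        p_near = sres.loc[[v for v in near if v in sres.index], "p"]
        seq_ps.append(float(p_near.min()))
        if p_near.min() < threshold:
            detected += 1
        hap_min = hres.loc[hres["p"].idxmin()]
        hap_ps.append(float(hap_min["p"]))
        if abs(int(hap_min["pos"]) - qcol) <= 5:
            hap_local += 1
    return {
        "n_replicates": n_rep,
        "n_sires": len(sires),
        "threshold": threshold,
        "power": detected / n_rep,
        "median_seq_p": float(np.median(seq_ps)),
        "median_hap_min_p": float(np.median(hap_ps)),
        "hap_localized_fraction": hap_local / n_rep,
        "mean_realized_qtl_freq": float(np.mean(freqs_realized)),
    }


def scan_calibration(seed: int, n_perm: int = 20) -> dict:
    """Type-I error of both scans under the permutation null.

    One null cohort (no QTL); phenotype blocks are permuted across
    parents and both scans rerun per permutation (background re-fitted on
    the permuted data). Reports the mean fraction of positions with
    p < 0.05 for the sequence Z-test, the haplotype LRT with the
    boundary-correct mixture reference, and the conservative chi2(1)
    convention, each with its empirical standard error over permutations.
    """
    anc, sires, A, S = scan_cohort(seed)
    structures = {"u": A, "s": S}
    qcol = N_X_MARKERS // 2
    sd = _sub(seed, 900)
    mm, panel = _scan_panel(anc, sd, qcol)
    xmask = mm.region_mask(simdata.X_SPECIFIC)
    truth = simdata.TruthConfig(seed=sd + 2)  # no QTL
    rec = simdata.simulate_phenotypes(
        anc, panel, [(s, f"r{i}") for s in sires for i in range(20)], truth
    )
    rows = [panel.index_of(s) for s in sires]
    H = panel.haps[rows][:, 0, :][:, xmask]
    model = hapclust.fit_cluster_model(
        H, K=SCAN_K, n_starts=1, max_iter=20, seed=sd + 3,
        positions_cm=mm.table["cm_female"].to_numpy()[xmask],
    )
    asg = hapclust.assign_clusters(model, H, [(s, 0) for s in sires])
    dos = panel.dosages(simdata.X_SPECIFIC).loc[sires]
    variants = pd.DataFrame({"pos": np.nonzero(xmask)[0]}, index=mm.ids[xmask])
    rate_seq, rate_mix, rate_chi2 = [], [], []
    for b in range(n_perm):
        prec = assoc.permute_parent_phenotypes(rec, seed=_sub(seed, 950 + b))
        bg = assoc.fit_null_background(prec, structures)
        hres = assoc.hap_scan(
            prec, asg, structures, positions=np.nonzero(xmask)[0],
            mixture=False, background=bg,
        )
        rate_chi2.append(float((hres["p"] < 0.05).mean()))
        # the mixture p is 0.5 x the chi2(1) p off the boundary, 1 at it
        p_mix = np.where(hres["lrt"] > 0, 0.5 * hres["p"], 1.0)
        rate_mix.append(float((p_mix < 0.05).mean()))
        sres = assoc.seq_scan(prec, variants, dos, structures, background=bg)
        rate_seq.append(float((sres["p"] < 0.05).mean()))
    out = {}
    for name, rates in (
        ("seq", rate_seq),
        ("hap_mixture", rate_mix),
        ("hap_chi2", rate_chi2),
    ):
        out[f"type1_{name}"] = float(np.mean(rates))
        out[f"type1_{name}_se"] = float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
    out["n_permutations"] = n_perm
    return out


# ---------------------------------------------------------------------------
# t: HMM forward oracle and credible sets
# ---------------------------------------------------------------------------


def hmm_forward_oracle(seed: int, n_instances: int = 10) -> dict:
    """Forward likelihood versus exhaustive path enumeration (m<=6, K<=3)."""
    max_diff = 0.0
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        K = int(rng.integers(1, 4))
        M = int(rng.integers(2, 7))
        nh = int(rng.integers(1, 5))
        H = rng.integers(0, 2, (nh, M)).astype(np.uint8)
        theta = rng.uniform(0.05, 0.95, (K, M))
        alpha = rng.dirichlet(np.ones(K), M).T
        rho = np.concatenate([[0.0], rng.uniform(0.0, 1.0, M - 1)])
        model = hapclust.ClusterModel(theta, alpha, rho, 0.0, np.empty(0))
        fwd = hapclust.loglikelihood(H, model)
        bf = hapclust.brute_force_loglik(H, theta, alpha, rho)
        max_diff = max(max_diff, abs(fwd - bf))
    return {"max_abs_difference": max_diff, "n_instances": n_instances}


def em_monotone(seed: int) -> float:
    """Worst per-iteration log-likelihood decrease across EM fits (>= ~0)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(3):
        H = rng.integers(0, 2, (40, 30)).astype(np.uint8)
        model = hapclust.fit_cluster_model(H, K=3, n_starts=2, max_iter=30, seed=int(rng.integers(2**31)))
        worst = min(worst, float(np.min(np.diff(model.loglik_path))))
    return worst


def credible_set_oracle(seed: int) -> dict:
    """Credible-set membership versus a brute-force r^2 recomputation."""
    rng = np.random.default_rng(seed)
    mm = _flat_map(60, spacing_cm=0.5)
    pool = simdata.mosaic_founder_haps(mm, 300, n_ancestral=12, seed=seed)
    dos = pd.DataFrame(pool[:200].astype(float), columns=mm.ids)
    dos = dos.loc[:, dos.std() > 0]
    positions = pd.Series(
        mm.table.set_index("id")["pos"].reindex(dos.columns), index=dos.columns
    )
    mismatches = 0
    n_sets = 0
    for lead in rng.choice(dos.columns.to_numpy(), size=8, replace=False):
        for thr in (0.5, 0.9):
            cs = assoc.credible_set(dos, positions, lead, thr)
            brute = set()
            g0 = dos[lead].to_numpy()
            for v in dos.columns:
                r = np.corrcoef(g0, dos[v].to_numpy())[0, 1]
                if v == lead or r * r > thr:
                    brute.add(v)
            n_sets += 1
            if brute != set(cs.members.index):
                mismatches += 1
    return {"n_sets": n_sets, "mismatches": mismatches, "match_fraction": 1.0 - mismatches / n_sets}
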