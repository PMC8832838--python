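"""End-to-end orchestration: simulate -> relationship matrices -> REML ->
scans -> fine-mapping, with every artifact stamped by seed and config hash.

Each stage is a thin call into the library modules; the pipeline exists so
a whole synthetic study can be rerun from one YAML config and so the
analysis scripts stay narrative.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import assoc, hapclust, io, pedrel, simdata, vc

log = logging.getLogger("xgrr")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _config_hash(config: io.RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def simulate_cohort(config: io.RunConfig):
    """Generate pedigree, panel and records for one synthetic study.

    Returns (pedigree restricted to breeding animals + record offspring,
    panel over breeding animals, records of all sires, truth).
    """
    ped = simdata.simulate_pedigree(
        config.n_founders,
        config.n_generations,
        config.mean_offspring_per_sire,
        config.mean_gametes_per_parent,
        seed=config.seed,
    )
    parents = sorted((set(ped.table["sire"]) | set(ped.table["dam"])) - {"0"})
    breeding = ped.ancestor_closure(parents)
    mm = simdata.default_marker_map(
        n_x=config.n_x_markers,
        n_par=config.n_par_markers,
        par_boundary=config.par_boundary,
    )
    rng = np.random.default_rng(config.seed + 1)
    freqs = rng.uniform(0.1, 0.9, mm.n_markers)
    pool = simdata.mosaic_founder_haps(
        mm, max(4 * config.n_founders, 100), founder_freqs=freqs, seed=config.seed + 2
    )
    qcol = mm.n_markers // 2
    simdata.plant_allele_on_background(pool, qcol, config.qtl_freq)
    panel = simdata.drop_genomes(
        breeding, mm, founder_haps=pool, seed=config.seed + 3
    )
    qtl = simdata.QTL(mm.ids[qcol], config.qtl_effect, config.qtl_sex)
    truth = simdata.TruthConfig(qtls=(qtl,), seed=config.seed + 4)
    sires = sorted(set(ped.table["sire"]) - {"0"})
    gametes = [
        (s, o) for s, o in zip(ped.table["sire"], ped.table["id"]) if s != "0"
    ]
    records = simdata.simulate_phenotypes(breeding, panel, gametes, truth)
    return breeding, panel, records, truth


def run_pipeline(config: io.RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the report dictionary (also written as report.json).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": _config_hash(config)}
    report: dict = {"stamp": stamp}

    def stage(name):
        log.info("stage=%s", name)
        return name

    try:
        name = stage("simulate")
        breeding, panel, records, truth = simulate_cohort(config)
        io.write_pedigree(breeding, f"{config.out_dir}/pedigree.tsv")
        io.write_records(records, f"{config.out_dir}/records.tsv")
        io.write_phased_vcf(panel, f"{config.out_dir}/haplotypes.vcf")
        io.write_truth_sidecar(truth, f"{config.out_dir}/truth.yaml")
        config.to_yaml(f"{config.out_dir}/config.yaml")
        report["simulate"] = {
            "n_individuals": int(breeding.n),
            "n_records": int(len(records)),
            "n_markers": int(panel.markers.n_markers),
        }

        name = stage("relmat")
        sires = sorted(records["parent_id"].unique())
        A = pedrel.autosomal_A(breeding)
        S = pedrel.xlinked_S(breeding)
        lin = pedrel.y_lineages(breeding)
        xmat = pedrel.scaled_X(panel, maf_min=config.maf_min)
        io.write_matrix_triplets(
            pedrel.RelationshipMatrix("X-linked-S", np.array(sires), S.submatrix(sires)),
            f"{config.out_dir}/S_parents.triplets.tsv",
        )
        grm_diag = np.einsum("ij,ij->i", xmat.values, xmat.values)
        report["relmat"] = {
            "n_lineages": lin.n_lineages,
            "mean_xx_diagonal": float(grm_diag.mean()),
        }

        name = stage("reml")
        structures = {"u": A, "s": S, "i": lin}
        m_ap = vc.fit_reml(vc.ModelSpec(random=("u", "p")), records, structures)
        m_aps = vc.fit_reml(vc.ModelSpec(random=("u", "p", "s")), records, structures)
        m_api = vc.fit_reml(vc.ModelSpec(random=("u", "p", "i")), records, structures)
        m_apsi = vc.fit_reml(
            vc.ModelSpec(random=("u", "p", "s", "i")), records, structures
        )
        lrt_s = vc.lrt_vc(m_aps, m_ap)
        lrt_i = vc.lrt_vc(m_api, m_ap)
        lrt_i_with_s = vc.lrt_vc(m_apsi, m_aps)
        der = vc.derived_params(m_aps, seed=config.seed)
        report["reml"] = {
            "base": m_ap.variances,
            "with_x": m_aps.variances,
            "with_y": m_api.variances,
            "with_xy": m_apsi.variances,
            "lrt_x": lrt_s,
            "lrt_y": lrt_i,
            "lrt_y_given_x": lrt_i_with_s,
            "heritability": der.heritability,
            "heritability_sd": der.heritability_sd,
            "repeatability": der.repeatability,
            "x_fraction_of_genetic": der.x_fraction,
            "x_fraction_sd": der.x_fraction_sd,
        }

        name = stage("snp_blup")
        blup = vc.snp_blup_variance(records, xmat, structures=structures)
        report["snp_blup"] = {
            "variances": blup.variances,
            "sigma2_m": blup.variances["m"],
        }

        name = stage("scan_hap")
        xmask = panel.markers.region_mask(simdata.X_SPECIFIC)
        H, hidx = panel.haplotypes(simdata.X_SPECIFIC)
        keep = [r for r, (s, _) in enumerate(hidx) if s in set(sires)]
        H = H[keep]
        hidx = [hidx[r] for r in keep]
        model = hapclust.fit_cluster_model(
            H,
            K=min(config.n_clusters, len(H) - 1),
            n_starts=1,
            max_iter=30,
            seed=config.seed + 5,
            positions_cm=panel.markers.table["cm_female"].to_numpy()[xmask],
        )
        assign = hapclust.assign_clusters(model, H, hidx)
        threshold = assoc.bonferroni_threshold(config.alpha, config.n_tests)
        bg = assoc.fit_null_background(records, structures)
        hres = assoc.hap_scan(
            records,
            assign,
            structures,
            positions=panel.markers.positions[xmask],
            background=bg,
        )
        hres.to_csv(f"{config.out_dir}/hap_scan.tsv", sep="\t", index=False)
        report["scan_hap"] = {
            "threshold": threshold,
            "min_p": float(hres["p"].min()),
            "min_p_pos": int(hres.loc[hres["p"].idxmin(), "pos"]),
            "n_significant": int((hres["p"] < threshold).sum()),
        }

        name = stage("scan_seq")
        dosages = panel.dosages(simdata.X_SPECIFIC).loc[sires]
        variants = pd.DataFrame(
            {"pos": panel.markers.positions[xmask], "rsq": 1.0},
            index=panel.markers.ids[xmask],
        )
        sres = assoc.seq_scan(
            records,
            variants,
            dosages,
            structures,
            maf_min=config.maf_min,
            rsq_min=config.rsq_min,
            background=bg,
        )
        sres.to_csv(f"{config.out_dir}/seq_scan.tsv", sep="\t", index=False)
        log.info(
            "variants_removed_maf=%d variants_removed_rsq=%d",
            sres.attrs["variants_removed_maf"],
            sres.attrs["variants_removed_rsq"],
        )
        lead = sres.loc[sres["p"].idxmin(), "id"] if len(sres) else None
        report["scan_seq"] = {
            "n_tested": int(len(sres)),
            "removed_maf": sres.attrs["variants_removed_maf"],
            "lead": lead,
            "lead_p": float(sres["p"].min()) if len(sres) else None,
        }

        name = stage("fine_map")
        if lead is not None and report["scan_seq"]["lead_p"] < threshold:
            cres, leads, dropped = assoc.conditional_scan(
                records,
                variants,
                dosages,
                structures,
                leads=[lead],
                threshold=threshold,
                background=None,
            )
            cset = assoc.credible_set(
                dosages, variants["pos"], lead, config.r2_credible
            )
            jtab, jrep = assoc.joint_fit_variants(
                records, dosages[leads], structures
            )
            jtab.to_csv(f"{config.out_dir}/variant_effects.tsv", sep="\t")
            report["fine_map"] = {
                "leads": list(leads),
                "dropped": dropped,
                "credible_set_size": int(len(cset.members)),
                "credible_set_span": cset.span,
                "variant_effects": jtab.reset_index().to_dict("records"),
                "polygenic_reduction": jrep["reduction"],
            }
        else:
            report["fine_map"] = {"leads": [], "note": "no genome-wide significant lead"}
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise StageError(name, err) from err

    with open(f"{config.out_dir}/report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
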