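"""Readers and writers for the pipeline's interchange formats.

Pedigree and record tables travel as TSV, phased genotypes as VCF (the
natural format for haploid male X calls), relationship matrices as TSV or
sparse triplets, and run configuration as YAML. All coordinates are
1-based and inclusive, matching VCF.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import pysam
import yaml

from .pedigree import FEMALE, MALE, Pedigree, PedigreeError
from .simdata import (
    PAR,
    RECORD_COLUMNS,
    X_SPECIFIC,
    GenotypeInconsistencyError,
    HaplotypePanel,
    MarkerMap,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pedigree and records
# ---------------------------------------------------------------------------


def read_pedigree(path: str) -> Pedigree:
    """Read a 4-column pedigree TSV (id, sire, dam, sex; "0" unknown).

    Rows may list offspring before parents; construction reorders them.
    Errors carry the 1-based line number of the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:4]) != ["id", "sire", "dam", "sex"]:
        raise ParseError(f"{path}: expected columns id, sire, dam, sex")
    try:
        return Pedigree(df)
    except PedigreeError as err:
        # map the offending id back to its line for a useful message
        msg = str(err)
        for token in df["id"].tolist() + df["sire"].tolist() + df["dam"].tolist():
            if repr(token) in msg:
                line = int(df.index[(df == token).any(axis=1)][0]) + 2
                raise ParseError(f"{path}:{line}: {msg}") from err
        raise ParseError(f"{path}: {msg}") from err


def write_pedigree(ped: Pedigree, path: str) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_records(path: str) -> pd.DataFrame:
    """Read a meiosis record table TSV (parent, offspring, sex, count, c1..c4)."""
    df = pd.read_csv(path, sep="\t", dtype={"parent_id": str, "offspring_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if not np.isfinite(df[["co_count", "c1", "c2", "c3", "c4"]].to_numpy()).all():
        raise ParseError(f"{path}: non-finite phenotype or covariate")
    if (df["co_count"] < 0).any():
        raise ParseError(f"{path}: negative crossover count")
    return df[RECORD_COLUMNS]


def write_records(records: pd.DataFrame, path: str) -> None:
    records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------


def write_phased_vcf(panel: HaplotypePanel, path: str, chrom: str = "X") -> None:
    """Write the panel as a phased VCF.

    Male X-specific calls are haploid ("0"/"1"); all PAR calls and all
    female calls are phased diploid.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={int(panel.markers.positions[-1]) + 1}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">'
    )
    header.add_line(f"##par_boundary={panel.markers.par_boundary}")
    for s in panel.samples:
        header.add_sample(str(s))
    t = panel.markers.table
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j in range(panel.markers.n_markers):
            rec = vcf.new_record(
                contig=chrom,
                start=int(t["pos"].iloc[j]) - 1,
                alleles=(str(t["ref"].iloc[j]), str(t["alt"].iloc[j])),
                id=str(t["id"].iloc[j]),
            )
            xspec = t["region"].iloc[j] == X_SPECIFIC
            for k, s in enumerate(panel.samples):
                male = panel.sex[k] == MALE
                if male and xspec:
                    rec.samples[str(s)]["GT"] = (int(panel.haps[k, 0, j]),)
                else:
                    rec.samples[str(s)]["GT"] = (
                        int(panel.haps[k, 0, j]),
                        int(panel.haps[k, 1, j]),
                    )
                    rec.samples[str(s)].phased = True
            vcf.write(rec)


def read_phased_vcf(
    path: str, par_boundary: int, sex: dict | None = None
) -> HaplotypePanel:
    """Read phased X genotypes into a HaplotypePanel.

    ``sex`` maps sample id to "M"/"F"; without it, sex is inferred from
    ploidy at X-specific sites (haploid calls mean male). Homozygous
    diploid male calls in the X-specific region collapse to one
    haplotype; a heterozygous male call there raises
    GenotypeInconsistencyError naming the site.
    """
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        rows = []
        gts = []
        for rec in vcf:
            rows.append(
                (
                    rec.id or f"{rec.chrom}_{rec.pos}",
                    rec.pos,
                    X_SPECIFIC if rec.pos < par_boundary else PAR,
                    rec.ref,
                    rec.alts[0] if rec.alts else ".",
                )
            )
            gts.append([rec.samples[s]["GT"] for s in samples])
    if not rows:
        raise ParseError(f"{path}: empty VCF")
    t = pd.DataFrame(rows, columns=["id", "pos", "region", "ref", "alt"])
    m = len(t)
    n = len(samples)
    xspec = (t["region"] == X_SPECIFIC).to_numpy()
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    inferred_sex = np.array([FEMALE] * n, dtype=object)
    if sex:
        inferred_sex = np.array([sex.get(s, FEMALE) for s in samples], dtype=object)
    for j in range(m):
        for k in range(n):
            gt = tuple(a for a in gts[j][k] if a is not None)
            if len(gt) == 1:
                if not xspec[j]:
                    raise ParseError(
                        f"{path}: haploid PAR call for {samples[k]} at {t['pos'][j]}"
                    )
                if sex is None:
                    inferred_sex[k] = MALE
                haps[k, 0, j] = gt[0]
                haps[k, 1, j] = HaplotypePanel.INVALID
            else:
                haps[k, 0, j], haps[k, 1, j] = gt
    # collapse homozygous-diploid male dialect and validate
    for k in range(n):
        if inferred_sex[k] != MALE:
            continue
        both = haps[k, :, xspec]
        het = (both[:, 1] != HaplotypePanel.INVALID) & (both[:, 0] != both[:, 1])
        if het.any():
            pos = t["pos"][np.nonzero(xspec)[0][np.argmax(het)]]
            raise GenotypeInconsistencyError(
                f"{path}: heterozygous male X-specific call for "
                f"{samples[k]} at position {pos}"
            )
        haps[k, 1, xspec] = HaplotypePanel.INVALID
    # rebuild genetic positions (not stored in VCF): bp-proportional stub
    cm_f = (t["pos"] - t["pos"].iloc[0]) / max(
        t["pos"].iloc[-1] - t["pos"].iloc[0], 1
    ) * 100.0
    cm_m = np.where(xspec, 0.0, cm_f - (cm_f[xspec].max() if xspec.any() else 0.0))
    table = t.assign(cm_female=cm_f, cm_male=np.maximum(cm_m, 0.0))
    mm = MarkerMap(table, par_boundary=par_boundary)
    return HaplotypePanel(mm, np.array(samples), inferred_sex, haps)


# ---------------------------------------------------------------------------
# matrices and config
# ---------------------------------------------------------------------------


def write_matrix_tsv(rel, path: str) -> None:
    """Dense TSV with ids as header and index."""
    rel.to_frame().to_csv(path, sep="\t")


def write_matrix_triplets(rel, path: str, tol: float = 0.0) -> None:
    """Sparse 3-column (row id, col id, value) upper triangle."""
    vals = rel.values
    ids = rel.ids
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for i in range(len(ids)):
            for j in range(i, len(ids)):
                if abs(vals[i, j]) > tol:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{vals[i, j]:.10g}\n")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 1
    out_dir: str = "results/run"
    # simulation scale
    n_founders: int = 300
    n_generations: int = 4
    mean_offspring_per_sire: float = 20.0
    mean_gametes_per_parent: float = 2.4
    n_x_markers: int = 150
    n_par_markers: int = 15
    par_boundary: int = 133_300_000
    # analysis thresholds
    maf_min: float = 0.01
    rsq_min: float = 0.80
    r2_credible: float = 0.90
    alpha: float = 0.05
    n_tests: int = 30_000
    n_clusters: int = 40
    # truth overrides (variance partition defaults live in TruthConfig)
    qtl_effect: float = 1.16
    qtl_freq: float = 0.057
    qtl_sex: str = "male"

    def __post_init__(self) -> None:
        checks = [
            0 <= self.maf_min < 0.5,
            0 < self.rsq_min <= 1,
            0 < self.r2_credible <= 1,
            0 < self.alpha < 1,
            self.n_tests >= 1,
            self.n_clusters >= 1,
            self.par_boundary > 0,
        ]
        if not all(checks):
            raise ParseError("run configuration value out of range")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_truth_sidecar(truth, path: str) -> None:
    """Flat YAML record of the generative truth, including the seed."""
    d = asdict(truth)
    d["qtls"] = [asdict(q) if not isinstance(q, dict) else q for q in truth.qtls]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
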