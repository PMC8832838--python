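"""Association mapping of X-linked loci for recombination rate.

Two scans share one background model, the mixed model with autosomal (A)
and X-linked (S) polygenic effects fitted once under the null:

* haplotype scan — at each marker a random haplotype-cluster effect
  h ~ N(0, I sg2_h) is added, with each parent incident on its one (male)
  or two (female) Viterbi cluster states, and sg2_h > 0 is tested by LRT;
* sequence scan — each variant's allelic dosage enters as a fixed
  regressor estimated by GLS and tested with a Z-test, after MAF and
  imputation-accuracy filters.

Background variance components are held fixed at their null REML
estimates across positions; only the position-specific parameter is
profiled. Conditional analysis re-runs a scan with lead-variant dosages
as fixed covariates until no test passes the genome-wide (Bonferroni)
threshold, and each QTL is summarized by the LD-based credible set of
variants in high r^2 with the lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import MALE
from .vc import Collapsed, ModelSpec, VCEstimate, build_terms, collapse_records, fit_reml


class AssocError(ValueError):
    pass


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide per-test significance threshold, alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise AssocError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise AssocError("n_tests must be >= 1")
    return alpha / n_tests


def qtl_variance(p: float, a: float) -> float:
    """Additive variance p q a^2 of a biallelic locus.

    The single-dose form: exact for a haploid (male X) locus with allele
    frequency p and additive effect a.
    """
    if not 0.0 < p < 1.0:
        raise AssocError("allele frequency must lie in (0, 1)")
    return p * (1.0 - p) * a * a


# ---------------------------------------------------------------------------
# whitened null background
# ---------------------------------------------------------------------------


@dataclass
class NullBackground:
    """Null-model fit plus the whitening transform it implies.

    Sigma0 = sg2_a A + sg2_s S + sg2_e diag(1/m) over recorded parents;
    L is its Cholesky factor, so L^-1 y has identity covariance under the
    null and every per-position test reduces to ordinary algebra on
    whitened quantities.
    """

    estimate: VCEstimate
    collapsed: Collapsed
    L: np.ndarray
    Xw: np.ndarray
    yw: np.ndarray

    @property
    def parents(self) -> np.ndarray:
        return self.collapsed.parents


def fit_null_background(
    records: pd.DataFrame,
    structures: dict,
    fixed: tuple = ("c1", "c2", "c3", "c4"),
    dosages: pd.DataFrame | None = None,
    random: tuple = ("u", "s"),
    **kwargs,
) -> NullBackground:
    """REML-fit the scan null model and precompute the whitening factor.

    The scan model deliberately carries no permanent-environment term
    (pass ``random=("u", "p", "s")`` to add it).
    """
    spec = ModelSpec(
        random=random,
        fixed=fixed,
        dosage_cols=tuple(dosages.columns) if dosages is not None else (),
    )
    est = fit_reml(spec, records, structures, dosages=dosages, **kwargs)
    dcols = dosages[list(spec.dosage_cols)] if dosages is not None else None
    col = collapse_records(records, fixed, dcols)
    terms = build_terms(spec.random, col.parents, structures)
    J = len(col.parents)
    sigma0 = est.variances["e"] * np.diag(1.0 / col.m)
    for t in terms:
        sigma0 += est.variances[t.name] * t.K()
    L = np.linalg.cholesky(sigma0)
    Xw = linalg.solve_triangular(L, col.X, lower=True)
    yw = linalg.solve_triangular(L, col.ybar, lower=True)
    return NullBackground(est, col, L, Xw, yw)


def _whiten(bg: NullBackground, v: np.ndarray) -> np.ndarray:
    return linalg.solve_triangular(bg.L, v, lower=True)


# ---------------------------------------------------------------------------
# haplotype-cluster scan
# ---------------------------------------------------------------------------


def parent_cluster_incidence(
    assign, parents, marker_col: int, hap_rows: dict | None = None
) -> np.ndarray:
    """Parent x cluster incidence at one marker.

    Males load 1 on the state of their single X-specific haplotype,
    females 1 on the state of each of their two haplotypes (2 if both
    haplotypes sit in the same cluster).
    """
    if hap_rows is None:
        hap_rows = _hap_rows(assign)
    K = int(assign.states.max()) + 1
    Z = np.zeros((len(parents), K))
    for j, p in enumerate(parents):
        for r in hap_rows[p]:
            Z[j, assign.states[r, marker_col]] += 1.0
    return Z


def _hap_rows(assign) -> dict:
    rows: dict = {}
    for r, (s, _) in enumerate(assign.hap_index):
        rows.setdefault(s, []).append(r)
    return rows


def _profile_cluster_variance(Zw, Xw, yw):
    """Profile restricted log-likelihood of the cluster variance.

    With whitened data the model is yw = Xw b + Zw h + eps, eps ~ N(0, I),
    h ~ N(0, I v). Returns (vhat, logl at vhat, logl at 0); all linear
    algebra is K x K via the Woodbury identity.
    """
    G = Zw.T @ Zw
    Zy = Zw.T @ yw
    ZX = Zw.T @ Xw
    XtX = Xw.T @ Xw
    Xy = Xw.T @ yw
    yy = float(yw @ yw)
    K = G.shape[0]

    def negrll(v):
        if v < 0:
            return np.inf
        if v == 0:
            XtMX, XMy, yMy, logdet = XtX, Xy, yy, 0.0
        else:
            W = G + np.eye(K) / v
            sign, ld_w = np.linalg.slogdet(W)
            if sign <= 0:
                return np.inf
            Wi_Zy = np.linalg.solve(W, Zy)
            Wi_ZX = np.linalg.solve(W, ZX)
            XtMX = XtX - ZX.T @ Wi_ZX
            XMy = Xy - ZX.T @ Wi_Zy
            yMy = yy - float(Zy @ Wi_Zy)
            logdet = ld_w + K * np.log(v)
        sign, ldx = np.linalg.slogdet(XtMX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtMX, XMy)
        quad = yMy - float(XMy @ beta)
        return 0.5 * (logdet + ldx + quad)

    l0 = -negrll(0.0)
    res = optimize.minimize_scalar(
        lambda t: negrll(np.exp(t)), bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-6},
    )
    vhat = float(np.exp(res.x))
    l1 = -float(res.fun)
    if l1 < l0:  # boundary solution
        vhat, l1 = 0.0, l0
    return vhat, l1, l0


def hap_scan(
    records: pd.DataFrame,
    assign,
    structures: dict,
    fixed: tuple = ("c1", "c2", "c3", "c4"),
    dosages: pd.DataFrame | None = None,
    positions: np.ndarray | None = None,
    mixture: bool = False,
    background: NullBackground | None = None,
) -> pd.DataFrame:
    """Random haplotype-cluster LRT at every marker of an assignment.

    ``assign`` must index the haplotypes of every recorded parent.
    Positions with a single observed cluster are skipped and logged in
    ``result.attrs["skipped"]``. P-values use chi-square(1) by convention;
    ``mixture=True`` applies the boundary-correct 50:50 mixture.
    """
    bg = background or fit_null_background(records, structures, fixed, dosages)
    M = assign.states.shape[1]
    pos = np.asarray(positions) if positions is not None else np.arange(M)
    rows = []
    skipped = []
    hap_rows = _hap_rows(assign)
    missing = [p for p in bg.parents if p not in hap_rows]
    if missing:
        raise AssocError(f"no haplotype assignment for parent {missing[0]!r}")
    for mcol in range(M):
        Z = parent_cluster_incidence(assign, bg.parents, mcol, hap_rows)
        used = Z.sum(axis=0) > 0
        if used.sum() < 2:
            # one observed cluster: confounded with the intercept, no test
            skipped.append(int(pos[mcol]))
            rows.append((int(pos[mcol]), int(used.sum()), 0.0, 0.0, 1.0))
            continue
        Zw = _whiten(bg, Z[:, used])
        vhat, l1, l0 = _profile_cluster_variance(Zw, bg.Xw, bg.yw)
        lrt = max(0.0, 2.0 * (l1 - l0))
        if mixture:
            p = 0.5 * stats.chi2.sf(lrt, 1) + (0.5 if lrt <= 0 else 0.0)
        else:
            p = stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
        rows.append((int(pos[mcol]), int(used.sum()), vhat, lrt, float(min(p, 1.0))))
    out = pd.DataFrame(rows, columns=["pos", "n_clusters", "sigma2_h", "lrt", "p"])
    out.attrs["skipped"] = skipped
    out.attrs["background"] = bg.estimate.variances
    return out


# ---------------------------------------------------------------------------
# sequence-variant scan
# ---------------------------------------------------------------------------


def _counted_freq(dosage: np.ndarray, sex: np.ndarray) -> float:
    """Allele frequency counting one allele per male, two per female."""
    male = sex == MALE
    alleles = dosage[male].sum() + dosage[~male].sum()
    n = male.sum() + 2 * (~male).sum()
    return float(alleles / n)


def seq_scan(
    records: pd.DataFrame,
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    structures: dict,
    fixed: tuple = ("c1", "c2", "c3", "c4"),
    covariate_dosages: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    rsq_min: float = 0.80,
    background: NullBackground | None = None,
) -> pd.DataFrame:
    """Single-variant dosage regression with GLS under the null covariance.

    ``variants`` carries per-variant metadata (index = variant id, columns
    ``pos`` and optionally ``rsq`` imputation accuracy, defaulting to 1);
    ``dosages`` is parents x variants. Variants failing the MAF or
    imputation-accuracy filter, or with zero dosage variance among
    recorded parents, are removed and counted in ``result.attrs``.
    The effect is tested with a two-sided Z-test.
    """
    bg = background or fit_null_background(
        records, structures, fixed, covariate_dosages
    )
    parents = bg.parents
    sex = (
        records.drop_duplicates("parent_id")
        .set_index("parent_id")["parent_sex"]
        .reindex(parents)
        .to_numpy()
    )
    # residual-forming projector on whitened scale
    Q, _ = np.linalg.qr(bg.Xw)
    ry = bg.yw - Q @ (Q.T @ bg.yw)
    n_maf = n_rsq = n_mono = 0
    rows = []
    rsq = variants["rsq"] if "rsq" in variants else pd.Series(1.0, index=variants.index)
    for vid in variants.index:
        if float(rsq.loc[vid]) < rsq_min:
            n_rsq += 1
            continue
        d = dosages[vid].reindex(parents).to_numpy(dtype=float)
        freq = _counted_freq(d, sex)
        if min(freq, 1 - freq) < maf_min:
            n_maf += 1
            continue
        if np.ptp(d) == 0:
            n_mono += 1
            continue
        gw = _whiten(bg, d)
        gr = gw - Q @ (Q.T @ gw)
        ss = float(gr @ gr)
        if ss <= 0:
            n_mono += 1
            continue
        beta = float(gr @ ry) / ss
        se = 1.0 / np.sqrt(ss)
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((vid, int(variants.loc[vid, "pos"]), freq, beta, se, z, p))
    out = pd.DataFrame(
        rows, columns=["id", "pos", "freq", "effect", "se", "stat", "p"]
    )
    out.attrs.update(
        variants_removed_maf=n_maf,
        variants_removed_rsq=n_rsq,
        variants_removed_monomorphic=n_mono,
        background=bg.estimate.variances,
    )
    return out


def conditional_scan(
    records: pd.DataFrame,
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    structures: dict,
    leads: list,
    fixed: tuple = ("c1", "c2", "c3", "c4"),
    covariate_dosages: pd.DataFrame | None = None,
    threshold: float | None = None,
    iterate: bool = True,
    max_rounds: int = 10,
    **scan_kwargs,
):
    """Sequence scan conditional on lead variants, optionally iterated.

    Lead dosages join the fixed effects (collinear leads, r^2 = 1 with an
    earlier one, are dropped and logged). While any remaining variant
    passes the threshold the strongest is promoted to lead and the scan
    repeats; returns (final scan result, final lead list, dropped leads).
    """
    if threshold is None:
        threshold = bonferroni_threshold(0.05, 30_000)
    leads = list(leads)
    dropped = []
    for lead in leads:
        if lead not in dosages.columns:
            raise AssocError(f"lead {lead!r} not among variants")
    for _ in range(max_rounds):
        kept = []
        for lead in leads:
            collinear = False
            for prev in kept:
                r = np.corrcoef(dosages[lead], dosages[prev])[0, 1]
                if abs(r) > 1 - 1e-12:
                    collinear = True
                    dropped.append(lead)
                    break
            if not collinear:
                kept.append(lead)
        leads = kept
        cov = dosages[leads].copy()
        if covariate_dosages is not None:
            cov = pd.concat([covariate_dosages, cov], axis=1)
        res = seq_scan(
            records,
            variants.drop(index=leads),
            dosages.drop(columns=leads),
            structures,
            fixed=fixed,
            covariate_dosages=cov,
            **scan_kwargs,
        )
        if not iterate or len(res) == 0 or res["p"].min() >= threshold:
            return res, leads, dropped
        leads.append(res.loc[res["p"].idxmin(), "id"])
    return res, leads, dropped


# ---------------------------------------------------------------------------
# credible sets and joint variance decomposition
# ---------------------------------------------------------------------------


@dataclass
class CredibleSet:
    """LD-based candidate set around a lead variant."""

    lead: str
    members: pd.DataFrame  # index id, columns r2 and pos
    span: int

    def __contains__(self, vid: str) -> bool:
        return vid in self.members.index


def credible_set(
    dosages: pd.DataFrame,
    positions: pd.Series,
    lead: str,
    r2_threshold: float = 0.90,
) -> CredibleSet:
    """All variants in LD r^2 > threshold with the lead.

    r^2 is the squared Pearson correlation of dosages across the supplied
    individuals (recorded parents). The lead itself (r^2 = 1) is always a
    member; the span is the bp distance between the extreme members.
    """
    if lead not in dosages.columns:
        raise AssocError(f"lead {lead!r} not among variants")
    g0 = dosages[lead].to_numpy(dtype=float)
    if np.ptp(g0) == 0:
        raise AssocError("monomorphic lead variant")
    X = dosages.to_numpy(dtype=float)
    g0c = g0 - g0.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (g0c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, (Xc.T @ g0c) ** 2 / denom**2, 0.0)
    r2 = pd.Series(r2, index=dosages.columns)
    r2[lead] = 1.0
    member_ids = r2.index[r2 > r2_threshold]
    members = pd.DataFrame(
        {"r2": r2[member_ids], "pos": positions.reindex(member_ids)}
    ).sort_values("pos")
    span = int(members["pos"].max() - members["pos"].min())
    return CredibleSet(lead, members, span)


def joint_fit_variants(
    records: pd.DataFrame,
    dosages: pd.DataFrame,
    structures: dict,
    fixed: tuple = ("c1", "c2", "c3", "c4"),
    random: tuple = ("u", "s"),
    **kwargs,
):
    """Fit identified variants jointly and decompose genetic variance.

    All supplied dosage columns enter as simultaneous fixed effects
    (collinear columns dropped and logged); polygenic variances are
    re-estimated with and without the variants. Returns a
    VariantEffectTable with each variant's frequency, jointly estimated
    effect, Z-test p-value and variance share p q a^2 / sigma^2_A (the
    additive genetic variance of the model without the variants), plus a
    report of the percent reduction of each polygenic variance.
    """
    kept, droppedv = [], []
    for v in dosages.columns:
        collinear = any(
            abs(np.corrcoef(dosages[v], dosages[w])[0, 1]) > 1 - 1e-12 for w in kept
        )
        (droppedv if collinear else kept).append(v)
    use = dosages[kept]
    sex = (
        records.drop_duplicates("parent_id").set_index("parent_id")["parent_sex"]
    )
    base = fit_reml(ModelSpec(random=random, fixed=fixed), records, structures, **kwargs)
    spec = ModelSpec(random=random, fixed=fixed, dosage_cols=tuple(kept))
    full = fit_reml(spec, records, structures, dosages=use, **kwargs)
    gen_base = sum(base.variances[k] for k in random if k != "p")
    table = []
    for v in kept:
        est = full.fixed_effects.loc[str(v)]
        d = use[v]
        freq = _counted_freq(d.to_numpy(dtype=float), sex.reindex(d.index).to_numpy())
        z = est["estimate"] / est["se"]
        table.append(
            {
                "id": v,
                "freq": freq,
                "effect": est["estimate"],
                "p": 2.0 * stats.norm.sf(abs(z)),
                "share": qtl_variance(freq, est["estimate"]) / gen_base,
            }
        )
    report = {
        "dropped": droppedv,
        "base_variances": base.variances,
        "joint_variances": full.variances,
        "reduction": {
            k: 1.0 - full.variances[k] / base.variances[k]
            for k in random
            if base.variances[k] > 0
        },
    }
    return pd.DataFrame(table).set_index("id"), report


def permute_parent_phenotypes(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permute record blocks across parents (null for both scans).

    Whole per-parent record sets swap parent labels, so record counts and
    the phenotype distribution are preserved while the link between a
    parent's genotype and its phenotypes is broken.
    """
    rng = np.random.default_rng(seed)
    parents = records["parent_id"].unique()
    perm = dict(zip(parents, rng.permutation(parents)))
    out = records.copy()
    grouped = {p: g for p, g in records.groupby("parent_id")}
    blocks = []
    for p in parents:
        src = grouped[perm[p]]
        blk = src.copy()
        blk["parent_id"] = p
        # covariates belong to the (genotyped) parent, phenotypes move
        for c in ("c1", "c2", "c3", "c4", "parent_sex"):
            if c in records.columns:
                blk[c] = grouped[p][c].iloc[0]
        blk["offspring_id"] = [f"{p}_perm{i}" for i in range(len(blk))]
        blocks.append(blk)
    return pd.concat(blocks, ignore_index=True)
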