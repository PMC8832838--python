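"""Variance-component estimation for repeated crossover-count records.

The observation model is the Gaussian linear mixed model

    y = 1*mu + P c + Z_u u + Z_p p [+ Z_s s] [+ Z_i i] [+ X m] + e

with u ~ N(0, A sg2_a) the autosomal polygenic effect, s ~ N(0, S sg2_s)
the X-linked polygenic effect, i ~ N(0, I sg2_i) the Y-lineage effect,
p ~ N(0, I sg2_p) the per-parent permanent environment, m ~ N(0, I sg2_m)
scaled X SNP effects, and e ~ N(0, I sg2_e).

Every fixed covariate and every random term except the residual is
constant across the repeated records of a parent, so the restricted
likelihood factorizes exactly into (i) within-parent contrasts, which
depend on sg2_e alone, and (ii) the parent-mean model whose covariance is
sum_k sg2_k K_k + sg2_e diag(1/m_j). REML is maximized on this collapsed
form with average-information (AI) updates and an EM fallback; the result
is identical to record-level REML but scales with the number of parents
rather than the number of records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pedrel import RelationshipMatrix, ScaledDosageMatrix, YLineageMap

GENETIC_TERMS = {"u", "s", "i", "m"}

LOG2PI = np.log(2.0 * np.pi)


class ModelError(ValueError):
    """Misspecified variance-component model."""


class NotNestedError(ValueError):
    """Likelihood-ratio test between non-nested models."""


@dataclass
class ModelSpec:
    """Which effects enter the mixed model.

    ``random`` is a subset of {"u", "p", "s", "i", "m"}; ``fixed`` names
    record-table covariate columns (the intercept is implicit);
    ``dosage_cols`` are additional per-parent fixed regressors (variant
    dosages) supplied at fit time.
    """

    random: tuple = ("u", "p")
    fixed: tuple = ("c1", "c2", "c3", "c4")
    dosage_cols: tuple = ()
    method: str = "ai"  # "ai" (with EM fallback) or "em"
    max_iter: int = 200

    def __post_init__(self) -> None:
        if len(set(self.random)) != len(self.random):
            raise ModelError("duplicate random terms")
        unknown = set(self.random) - {"u", "p", "s", "i", "m"}
        if unknown:
            raise ModelError(f"unknown random terms {sorted(unknown)}")


@dataclass
class VarTerm:
    """One random term: covariance contribution F G F' at parent level."""

    name: str
    F: np.ndarray  # J x q design
    G: np.ndarray | None = None  # q x q structure; None = identity

    @property
    def q(self) -> int:
        return self.F.shape[1]

    def K(self) -> np.ndarray:
        if self.G is None:
            return self.F @ self.F.T
        return self.F @ self.G @ self.F.T


@dataclass
class Collapsed:
    """Parent-level sufficient statistics of the record table."""

    parents: np.ndarray
    ybar: np.ndarray
    m: np.ndarray
    X: np.ndarray
    fixed_names: list
    extra_df: int
    extra_ss: float
    n_records: int


@dataclass
class VCEstimate:
    """REML (or Gibbs) variance components with asymptotic covariance."""

    variances: dict
    loglik: float
    cov: pd.DataFrame
    converged: bool
    n_iter: int
    method: str
    n_records: int
    boundary: tuple = ()
    fixed_effects: pd.DataFrame | None = None
    logl_path: tuple = ()

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))


@dataclass
class DerivedParams:
    """Genetic-parameter ratios with sampling-based standard deviations."""

    heritability: float
    heritability_sd: float
    repeatability: float
    repeatability_sd: float
    x_fraction: float | None
    x_fraction_sd: float | None


# ---------------------------------------------------------------------------
# collapsing records to parent level
# ---------------------------------------------------------------------------


def collapse_records(
    records: pd.DataFrame, fixed: tuple = (), dosages: pd.DataFrame | None = None
) -> Collapsed:
    """Exact parent-level reduction of the record table.

    Requires every fixed covariate to be constant within parent (true for
    breed covariates and variant dosages, which are properties of the
    parent); raises otherwise because the reduction would then be lossy.
    """
    y = records["co_count"].to_numpy(dtype=float)
    parents, inverse = np.unique(records["parent_id"].to_numpy(), return_inverse=True)
    J = len(parents)
    m = np.bincount(inverse, minlength=J).astype(float)
    ybar = np.bincount(inverse, weights=y, minlength=J) / m
    extra_ss = float(np.sum((y - ybar[inverse]) ** 2))
    cols = [np.ones(J)]
    names = ["intercept"]
    for c in fixed:
        v = records[c].to_numpy(dtype=float)
        vbar = np.bincount(inverse, weights=v, minlength=J) / m
        if np.max(np.abs(v - vbar[inverse])) > 1e-8 * max(1.0, np.abs(v).max()):
            raise ModelError(f"fixed covariate {c!r} varies within parent")
        cols.append(vbar)
        names.append(c)
    if dosages is not None:
        d = dosages.reindex(parents)
        if d.isna().to_numpy().any():
            missing = d.index[d.isna().any(axis=1)][0]
            raise ModelError(f"no dosage for parent {missing!r}")
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient")
    return Collapsed(
        parents, ybar, m, X, names, len(y) - J, extra_ss, len(y)
    )


def build_terms(
    random: tuple, parents: np.ndarray, structures: dict, sexes: dict | None = None
) -> list:
    """Assemble VarTerms for the requested random effects.

    ``structures`` maps "u"/"s" to RelationshipMatrix, "i" to YLineageMap
    and "m" to ScaledDosageMatrix. Pedigree structures are marginalized to
    the recorded parents (a principal submatrix), which leaves the
    likelihood unchanged. With a Y-lineage term, females (which carry no Y)
    get a zero incidence row.
    """
    J = len(parents)
    terms = []
    for name in random:
        if name in ("u", "s"):
            rel: RelationshipMatrix = structures[name]
            terms.append(VarTerm(name, np.eye(J), rel.submatrix(parents)))
        elif name == "p":
            terms.append(VarTerm("p", np.eye(J)))
        elif name == "i":
            lin: YLineageMap = structures["i"]
            males = [p for p in parents if lin.lineage_of.get(p) is not None]
            Zm, _ = lin.incidence(males)
            Z = np.zeros((J, Zm.shape[1]))
            rowix = {p: k for k, p in enumerate(parents)}
            for r, p in enumerate(males):
                Z[rowix[p]] = Zm[r]
            terms.append(VarTerm("i", Z))
        elif name == "m":
            sd: ScaledDosageMatrix = structures["m"]
            terms.append(VarTerm("m", sd.rows_for(parents)))
        else:  # pragma: no cover
            raise ModelError(name)
    return terms


# ---------------------------------------------------------------------------
# restricted likelihood and derivatives
# ---------------------------------------------------------------------------


def _reml_state(theta: np.ndarray, col: Collapsed, Ks: list, want_derivs: bool):
    """logL (and score/AI) at theta = (term variances..., residual)."""
    J = len(col.ybar)
    th_e = theta[-1]
    V = th_e * np.diag(1.0 / col.m)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise ModelError("covariance structure is not positive definite") from err
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = linalg.cho_solve(cf, np.eye(J), check_finite=False)
    X = col.X
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise ModelError("X'V^-1 X not positive definite")
    beta = np.linalg.solve(XtVinvX, VinvX.T @ col.ybar)
    r = col.ybar - X @ beta
    Py = Vinv @ r  # X'V^-1 r = 0 at the GLS solution
    quad = float(r @ Py)
    p = X.shape[1]
    logl = -0.5 * (
        logdetV
        + logdetX
        + quad
        + col.extra_df * np.log(th_e)
        + col.extra_ss / th_e
        + (col.n_records - p) * LOG2PI
    )
    out = {
        "logl": logl,
        "beta": beta,
        "beta_cov": np.linalg.inv(XtVinvX),
        "Py": Py,
    }
    if not want_derivs:
        return out
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    d = 1.0 / col.m
    nt = len(Ks)
    score = np.empty(nt + 1)
    fvecs = []
    for k, K in enumerate(Ks):
        f = K @ Py
        fvecs.append(f)
        score[k] = -0.5 * (float(np.sum(P * K)) - float(Py @ f))
    f_e = d * Py
    fvecs.append(f_e)
    score[-1] = -0.5 * (float(np.sum(np.diag(P) * d)) - float(Py @ f_e))
    score[-1] += -0.5 * (col.extra_df / th_e - col.extra_ss / th_e**2)
    Fm = np.column_stack(fvecs)
    AI = 0.5 * (Fm.T @ P @ Fm)
    AI[-1, -1] += col.extra_df / (2.0 * th_e**2)
    out.update(score=score, AI=AI, P=P)
    return out


def reml(
    col: Collapsed,
    terms: list,
    method: str = "ai",
    max_iter: int = 200,
    tol_logl: float = 1e-8,
    tol_par: float = 1e-6,
    start: np.ndarray | None = None,
) -> VCEstimate:
    """Maximize the restricted likelihood over the variance components.

    AI (average-information) Newton steps with step halving; after five
    consecutive rejected steps, or with ``method="em"``, the monotone EM
    update ``theta + 2 theta^2 / q * score`` is used. Variances are
    constrained to a floor of 1e-8 times the phenotypic variance; floored
    components are reported as boundary estimates.
    """
    Ks = [t.K() for t in terms]
    qs = np.array([t.q for t in terms] + [col.n_records], dtype=float)
    ss_tot = float(
        np.sum(col.m * (col.ybar - np.average(col.ybar, weights=col.m)) ** 2)
        + col.extra_ss
    )
    vary = ss_tot / max(col.n_records - 1, 1)
    floor = 1e-8 * vary
    nt = len(terms)
    if start is None:
        theta = np.full(nt + 1, 0.5 * vary / max(nt, 1))
        theta[-1] = 0.5 * vary
    else:
        theta = np.maximum(np.asarray(start, dtype=float), floor)
    state = _reml_state(theta, col, Ks, True)
    logl_path = [state["logl"]]
    consec_fail = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        use_em = method == "em" or consec_fail >= 5
        if use_em:
            delta = 2.0 * theta**2 / qs * state["score"]
        else:
            AI = state["AI"]
            free = theta > floor * 1.5
            free |= state["score"] > 0  # let boundary components re-enter
            delta = np.zeros_like(theta)
            try:
                delta[free] = np.linalg.solve(
                    AI[np.ix_(free, free)], state["score"][free]
                )
            except np.linalg.LinAlgError:
                delta = 2.0 * theta**2 / qs * state["score"]
        step = 1.0
        new_state = None
        for _ in range(8):
            prop = np.maximum(theta + step * delta, floor)
            try:
                cand = _reml_state(prop, col, Ks, True)
            except ModelError:
                step *= 0.5
                continue
            if cand["logl"] >= state["logl"] - 1e-10 or use_em:
                new_state = cand
                break
            step *= 0.5
        if new_state is None:
            consec_fail += 1
            continue
        consec_fail = 0 if new_state["logl"] >= state["logl"] - 1e-10 else consec_fail + 1
        dlogl = new_state["logl"] - state["logl"]
        dpar = np.max(np.abs(prop - theta) / np.maximum(np.abs(theta), floor))
        theta, state = prop, new_state
        logl_path.append(state["logl"])
        if abs(dlogl) < tol_logl and dpar < tol_par:
            converged = True
            break
    names = [t.name for t in terms] + ["e"]
    boundary = tuple(n for n, v in zip(names, theta) if v <= floor * 1.5)
    cov = np.full((nt + 1, nt + 1), np.nan)
    free = np.array([v > floor * 1.5 for v in theta])
    if free.any():
        try:
            cov_free = np.linalg.inv(state["AI"][np.ix_(free, free)])
            cov[np.ix_(free, free)] = cov_free
        except np.linalg.LinAlgError:
            pass
    fe = pd.DataFrame(
        {
            "estimate": state["beta"],
            "se": np.sqrt(np.diag(state["beta_cov"])),
        },
        index=col.fixed_names,
    )
    return VCEstimate(
        variances=dict(zip(names, theta.tolist())),
        loglik=float(state["logl"]),
        cov=pd.DataFrame(cov, index=names, columns=names),
        converged=converged,
        n_iter=it,
        method=method,
        n_records=col.n_records,
        boundary=boundary,
        fixed_effects=fe,
        logl_path=tuple(logl_path),
    )


def fit_reml(
    spec: ModelSpec,
    records: pd.DataFrame,
    structures: dict,
    dosages: pd.DataFrame | None = None,
    **kwargs,
) -> VCEstimate:
    """Fit the mixed model named by ``spec`` to a record table.

    ``structures`` supplies the covariance structures for the pedigree and
    marker terms (see :func:`build_terms`); ``dosages`` optionally adds
    per-parent variant dosages as fixed regressors (indexed by parent id,
    one column per variant).
    """
    if len(records) < 2:
        raise ModelError("need at least two records")
    dcols = None
    if spec.dosage_cols:
        if dosages is None:
            raise ModelError("spec names dosage columns but none supplied")
        dcols = dosages[list(spec.dosage_cols)]
    col = collapse_records(records, spec.fixed, dcols)
    terms = build_terms(spec.random, col.parents, structures)
    return reml(col, terms, method=spec.method, max_iter=spec.max_iter, **kwargs)


# ---------------------------------------------------------------------------
# MME route: an independent evaluation of the same restricted likelihood
# ---------------------------------------------------------------------------


def mme_restricted_loglik(col: Collapsed, terms: list, theta: dict) -> float:
    """Restricted log-likelihood via Henderson's mixed-model equations.

    Builds the full coefficient matrix over fixed effects and every latent
    random vector (marker effects stay marker-sided, q columns per term)
    and uses the determinant identities of the MME, a numerically distinct
    route from the dense V-based evaluation in :func:`_reml_state`. Used
    to verify the SNP-BLUP <-> GRM equivalence.
    """
    th_e = theta["e"]
    Rinv = col.m / th_e  # residual precision of parent means
    blocks = [col.X] + [t.F for t in terms]
    W = np.column_stack(blocks)
    C = (W.T * Rinv) @ W
    ofs = col.X.shape[1]
    extra_logdet = 0.0
    for t in terms:
        q = t.q
        sl = slice(ofs, ofs + q)
        if t.G is None:
            C[sl, sl] += np.eye(q) / theta[t.name]
        else:
            cfG = linalg.cho_factor(t.G, lower=True)
            extra_logdet += 2.0 * np.sum(np.log(np.diag(cfG[0])))
            C[sl, sl] += linalg.cho_solve(cfG, np.eye(q)) / theta[t.name]
        extra_logdet += q * np.log(theta[t.name])
        ofs += q
    rhs = W.T @ (Rinv * col.ybar)
    cfC = linalg.cho_factor(C, lower=True)
    sol = linalg.cho_solve(cfC, rhs)
    logdetC = 2.0 * np.sum(np.log(np.diag(cfC[0])))
    ypy = float(col.ybar @ (Rinv * col.ybar) - sol @ rhs)
    logdetR = float(np.sum(np.log(th_e / col.m)))
    p = col.X.shape[1]
    return -0.5 * (
        logdetR
        + extra_logdet
        + logdetC
        + ypy
        + col.extra_df * np.log(th_e)
        + col.extra_ss / th_e
        + (col.n_records - p) * LOG2PI
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test and derived parameters
# ---------------------------------------------------------------------------


def lrt_vc(full: VCEstimate, reduced: VCEstimate, mixture: bool = False):
    """LRT for one extra variance component.

    The reference distribution is chi-square with 1 df by convention;
    ``mixture=True`` uses the boundary-correct 50:50 mixture of a point
    mass at zero and chi-square(1).
    """
    full_terms = set(full.variances)
    red_terms = set(reduced.variances)
    if not red_terms < full_terms:
        raise NotNestedError("reduced model terms are not a strict subset")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if mixture:
        p = 0.5 * stats.chi2.sf(stat, 1) + (0.5 if stat <= 0 else 0.0)
    else:
        p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    return stat, float(min(p, 1.0))


def derived_params(
    est: VCEstimate, n_draws: int = 10_000, seed: int = 0
) -> DerivedParams:
    """Heritability, repeatability and the X share of genetic variance.

    Standard deviations come from resampling the variance vector from its
    asymptotic multivariate normal distribution, truncating negative draws
    at zero and recomputing each ratio per draw.
    """
    names = list(est.variances)
    v = np.array([est.variances[n] for n in names])
    total = v.sum()
    if total <= 0:
        raise ModelError("total phenotypic variance is zero")
    gen = [i for i, n in enumerate(names) if n in GENETIC_TERMS]
    x_ix = [i for i, n in enumerate(names) if n in ("s", "m")]
    pe = [i for i, n in enumerate(names) if n == "p"]

    def ratios(vec):
        tot = vec.sum(axis=-1)
        g = vec[..., gen].sum(axis=-1)
        h2 = g / tot
        rep = (g + vec[..., pe].sum(axis=-1)) / tot
        xf = vec[..., x_ix].sum(axis=-1) / np.where(g > 0, g, np.nan) if x_ix else None
        return h2, rep, xf

    h2, rep, xf = ratios(v[None, :])
    cov = est.cov.to_numpy()
    ok = ~np.isnan(np.diag(cov))
    rng = np.random.default_rng(seed)
    draws = np.tile(v, (n_draws, 1))
    if ok.any():
        sub = cov[np.ix_(ok, ok)]
        # clip tiny negative eigenvalues from the AI inverse
        w, Q = np.linalg.eigh(sub)
        sub = (Q * np.maximum(w, 0)) @ Q.T
        draws[:, ok] = rng.multivariate_normal(v[ok], sub, size=n_draws)
    draws = np.maximum(draws, 0.0)
    h2_d, rep_d, xf_d = ratios(draws)
    return DerivedParams(
        float(h2[0]),
        float(np.nanstd(h2_d)),
        float(rep[0]),
        float(np.nanstd(rep_d)),
        float(xf[0]) if xf is not None else None,
        float(np.nanstd(xf_d)) if xf is not None else None,
    )


# ---------------------------------------------------------------------------
# SNP-BLUP
# ---------------------------------------------------------------------------


def snp_blup_variance(
    records: pd.DataFrame,
    xmat: ScaledDosageMatrix,
    spec: ModelSpec | None = None,
    structures: dict | None = None,
    **kwargs,
) -> VCEstimate:
    """Variance of scaled X SNP effects fitted jointly (SNP-BLUP).

    All marker effects share one variance sg2_m; with the sex-specific
    centering and scaling of :func:`xgrr.pedrel.scaled_X`, sg2_m estimates
    the X-linked individual genetic variance sg2_s. The background model
    (autosomal polygenic and permanent environment by default) comes from
    ``spec``/``structures``.
    """
    if spec is None:
        spec = ModelSpec(random=("u", "p", "m"))
    if "m" not in spec.random:
        raise ModelError("SNP-BLUP spec must include the marker term 'm'")
    structures = dict(structures or {})
    structures["m"] = xmat
    return fit_reml(spec, records, structures, **kwargs)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def gibbs_vc(
    col: Collapsed,
    terms: list,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    prior_df: float = 4.0,
    prior_scale: dict | None = None,
) -> pd.DataFrame:
    """Blocked Gibbs sampler for the same model class as :func:`reml`.

    Location effects (fixed plus all random vectors) are drawn jointly
    from their Gaussian full conditional through the mixed-model
    equations; each variance is drawn from its scaled-inverse-chi-square
    full conditional with a weakly informative prior (df ``prior_df``,
    scale defaulting to an equal split of the sample variance). Returns
    posterior draws after burn-in, one column per variance.
    """
    if n_iter <= burn_in:
        raise ModelError("chain length must exceed burn-in")
    rng = np.random.default_rng(seed)
    names = [t.name for t in terms] + ["e"]
    ss_tot = float(
        np.sum(col.m * (col.ybar - np.average(col.ybar, weights=col.m)) ** 2)
        + col.extra_ss
    )
    vary = ss_tot / max(col.n_records - 1, 1)
    if prior_scale is None:
        prior_scale = {n: 0.5 * vary / max(len(terms), 1) for n in names}
        prior_scale["e"] = 0.5 * vary
    theta = {n: prior_scale[n] for n in names}
    Ginvs = []
    for t in terms:
        if t.G is None:
            Ginvs.append(None)
        else:
            Ginvs.append(np.linalg.inv(t.G))
    W = np.column_stack([col.X] + [t.F for t in terms])
    p = col.X.shape[1]
    draws = np.empty((n_iter - burn_in, len(names)))
    for it in range(n_iter):
        Rinv = col.m / theta["e"]
        C = (W.T * Rinv) @ W
        ofs = p
        for t, Gi in zip(terms, Ginvs):
            sl = slice(ofs, ofs + t.q)
            C[sl, sl] += (np.eye(t.q) if Gi is None else Gi) / theta[t.name]
            ofs += t.q
        rhs = W.T @ (Rinv * col.ybar)
        L = np.linalg.cholesky(C)
        mean = linalg.cho_solve((L, True), rhs)
        z = rng.standard_normal(len(rhs))
        sol = mean + linalg.solve_triangular(L.T, z, lower=False)
        resid_ss = col.extra_ss + float(np.sum(col.m * (col.ybar - W @ sol) ** 2))
        df_e = col.n_records + prior_df
        theta["e"] = (resid_ss + prior_df * prior_scale["e"]) / rng.chisquare(df_e)
        ofs = p
        for t, Gi in zip(terms, Ginvs):
            u = sol[ofs : ofs + t.q]
            ss = float(u @ u if Gi is None else u @ Gi @ u)
            df = t.q + prior_df
            theta[t.name] = (ss + prior_df * prior_scale[t.name]) / rng.chisquare(df)
            ofs += t.q
        if it >= burn_in:
            draws[it - burn_in] = [theta[n] for n in names]
    return pd.DataFrame(draws, columns=names)
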