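"""Synthetic cohorts for recombination-rate genetics.

Generates the three ingredients every downstream stage consumes, with known
ground truth:

* a multi-generation sexed pedigree shaped like a dairy-cattle mapping
  cohort (a modest breeding nucleus whose sires each leave many genotyped
  offspring, i.e. many observed gametes);
* phased X-chromosome haplotypes dropped through the pedigree with
  female-only recombination in the X-specific region and recombination in
  both sexes in the pseudo-autosomal region (PAR);
* per-gamete crossover-count phenotypes drawn from a Gaussian linear mixed
  model with autosomal polygenic, X-linked polygenic, Y-lineage, permanent
  environment and residual components, breed-admixture covariates and
  optional X-linked QTL, rounded to non-negative integers.

Crossover counts per map interval are Poisson with mean equal to the map
distance in Morgans (Haldane, no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, UNKNOWN, Pedigree

X_SPECIFIC = "X-specific"
PAR = "PAR"

RECORD_COLUMNS = [
    "parent_id",
    "offspring_id",
    "parent_sex",
    "co_count",
    "c1",
    "c2",
    "c3",
    "c4",
]


class SimulationError(ValueError):
    """Invalid generator configuration."""


class GenotypeInconsistencyError(ValueError):
    """A gamete allele is incompatible with its parent's genotype."""


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """X-chromosome marker map with sex-specific genetic positions.

    ``table`` columns: ``id``, ``pos`` (bp, 1-based, strictly increasing),
    ``region`` (``X-specific`` or ``PAR``), ``ref``, ``alt``, ``cm_female``
    (female genetic position over the whole chromosome) and ``cm_male``
    (male genetic position, constant across the X-specific part where males
    do not recombine).
    """

    table: pd.DataFrame
    par_boundary: int

    def __post_init__(self) -> None:
        t = self.table
        pos = t["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise SimulationError("marker positions must be strictly increasing")
        for col in ("cm_female", "cm_male"):
            if np.any(np.diff(t[col].to_numpy()) < 0):
                raise SimulationError(f"{col} must be non-decreasing")
        regions = t["region"].to_numpy()
        want = np.where(pos >= self.par_boundary, PAR, X_SPECIFIC)
        if not np.array_equal(regions, want):
            raise SimulationError("region labels inconsistent with PAR boundary")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def region_mask(self, region: str) -> np.ndarray:
        return (self.table["region"] == region).to_numpy()


def default_marker_map(
    n_x: int = 744,
    n_par: int = 73,
    chrom_length: int = 146_000_000,
    par_boundary: int = 133_300_000,
    female_cm_x: float = 97.0,
    female_cm_par: float = 11.0,
    male_cm_par: float = 45.0,
    seed: int | None = None,
) -> MarkerMap:
    """Evenly spaced map emulating a bovine X SNP array.

    Defaults follow the array used for X-linked recombination mapping in
    cattle: ~744 X-specific and ~73 PAR markers. The male PAR map is long
    (obligate male crossover in the short PAR); the X-specific part has no
    male recombination, so ``cm_male`` is flat there.
    """
    px = np.linspace(1, par_boundary - 1, n_x).round().astype(np.int64)
    pp = np.linspace(par_boundary, chrom_length, n_par).round().astype(np.int64)
    pos = np.concatenate([px, pp])
    region = np.array([X_SPECIFIC] * n_x + [PAR] * n_par)
    cm_f = np.empty(n_x + n_par)
    cm_f[:n_x] = female_cm_x * (px - px[0]) / max(px[-1] - px[0], 1)
    cm_f[n_x:] = female_cm_x + female_cm_par * (pp - pp[0]) / max(pp[-1] - pp[0], 1)
    cm_m = np.zeros(n_x + n_par)
    cm_m[n_x:] = male_cm_par * (pp - pp[0]) / max(pp[-1] - pp[0], 1)
    table = pd.DataFrame(
        {
            "id": [f"X_{p}" for p in pos],
            "pos": pos,
            "region": region,
            "ref": "A",
            "alt": "B",
            "cm_female": cm_f,
            "cm_male": cm_m,
        }
    )
    return MarkerMap(table, par_boundary=par_boundary)


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased X haplotypes for a set of individuals.

    Storage is ``haps[sample, copy, marker]`` with alleles in {0, 1}.
    Copy 0 is the maternally inherited X for non-founders. Males carry a
    single X-specific haplotype: copy 1 is only meaningful inside the PAR
    (it is the PAR of the Y) and is masked with ``INVALID`` elsewhere.

    ``origins`` optionally maps ``(parent_id, offspring_id)`` to the
    gamete's origin track (0/1 = which parental haplotype each transmitted
    allele came from, over the markers where the parent is diploid) and the
    generator's true crossover count.
    """

    INVALID = 255

    markers: MarkerMap
    samples: np.ndarray
    sex: np.ndarray
    haps: np.ndarray
    origins: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.haps.shape != (len(self.samples), 2, self.markers.n_markers):
            raise SimulationError("haplotype array shape mismatch")
        self._index = {s: k for k, s in enumerate(self.samples)}

    def index_of(self, sample: str) -> int:
        return self._index[sample]

    def is_male(self, sample: str) -> bool:
        return self.sex[self._index[sample]] == MALE

    def dosages(self, region: str = X_SPECIFIC) -> pd.DataFrame:
        """Allele-1 dosage per individual: males 0/1 (haploid), females 0/1/2."""
        mask = self.markers.region_mask(region)
        h = self.haps[:, :, mask].astype(np.int16)
        male = self.sex == MALE
        d = h.sum(axis=1)
        if region == X_SPECIFIC:
            d[male] = h[male, 0, :]
        return pd.DataFrame(
            d, index=self.samples, columns=self.markers.ids[mask], dtype=np.int16
        )

    def haplotypes(self, region: str = X_SPECIFIC):
        """(matrix, index) of all valid haplotypes in a region.

        Rows are haplotypes; the index lists ``(sample, copy)`` pairs. In
        the X-specific region males contribute one row, females two.
        """
        mask = self.markers.region_mask(region)
        rows = []
        idx = []
        for k, s in enumerate(self.samples):
            ncopy = 1 if (region == X_SPECIFIC and self.sex[k] == MALE) else 2
            for c in range(ncopy):
                rows.append(self.haps[k, c, mask])
                idx.append((s, c))
        return np.asarray(rows, dtype=np.uint8), idx

    def allele_frequencies(self, region: str = X_SPECIFIC) -> np.ndarray:
        """Counted frequencies: one allele per male, two per female."""
        H, _ = self.haplotypes(region)
        return H.mean(axis=0)


# ---------------------------------------------------------------------------
# truth configuration
# ---------------------------------------------------------------------------


@dataclass
class QTL:
    """An X-linked biallelic QTL acting on the parent's crossover count."""

    marker_id: str
    effect: float  # additive effect per copy of allele 1, in CO
    sex: str = "both"  # "male", "female" or "both"


@dataclass
class TruthConfig:
    """Generative parameters of the crossover-count mixed model.

    Defaults partition a total phenotypic variance of 6.25 CO^2 (SD 2.5 CO
    around a mean of 25 CO per gamete) into 11.1% autosomal polygenic,
    4.7% X-linked polygenic, 0.5% Y-lineage, 1.0% permanent environment
    and the remainder residual — the partition estimated for male global
    recombination rate in dairy cattle.
    """

    mu: float = 25.0
    var_a: float = 0.694  # autosomal polygenic, CO^2
    var_s: float = 0.294  # X-linked polygenic
    var_i: float = 0.031  # Y lineage
    var_p: float = 0.0625  # permanent environment
    var_e: float = 5.17  # residual
    beta: tuple = (0.4, -0.2, 0.3, -0.1)  # admixture covariate effects
    qtls: tuple = ()
    round_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_a", "var_s", "var_i", "var_p", "var_e"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mean_offspring_per_sire: float = 20.0,
    mean_gametes_per_parent: float = 2.0,
    seed: int = 0,
) -> Pedigree:
    """Discrete-generation breeding pedigree.

    Each generation's cohort size is ``n_dams * mean_gametes_per_parent``
    (dam-limited, as in cattle where dams leave few genotyped offspring).
    Sires are a random subset of the previous generation's males of size
    ``round(cohort / mean_offspring_per_sire)`` and are assigned offspring
    uniformly, so offspring counts per active sire are approximately
    Poisson with the requested mean. Offspring sex is Bernoulli(1/2),
    nudged so both sexes occur in every generation.
    """
    if n_founders < 2 or n_generations < 1:
        raise SimulationError("need n_founders >= 2 and n_generations >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_f_male = n_founders // 2
    if n_f_male == 0 or n_f_male == n_founders:
        raise SimulationError("need at least one founder of each sex")
    males = [f"G0_{k}" for k in range(n_f_male)]
    females = [f"G0_{k}" for k in range(n_f_male, n_founders)]
    for iid in males:
        rows.append((iid, UNKNOWN, UNKNOWN, MALE))
    for iid in females:
        rows.append((iid, UNKNOWN, UNKNOWN, FEMALE))
    for g in range(1, n_generations + 1):
        cohort = int(round(len(females) * mean_gametes_per_parent))
        cohort = max(cohort, 2)
        n_sires = int(np.clip(round(cohort / mean_offspring_per_sire), 1, len(males)))
        sires = rng.choice(males, size=n_sires, replace=False)
        sire_of = rng.choice(sires, size=cohort, replace=True)
        dam_of = rng.choice(females, size=cohort, replace=True)
        sex = np.where(rng.random(cohort) < 0.5, MALE, FEMALE)
        # both sexes must be present in every generation
        if (sex == MALE).all():
            sex[rng.integers(cohort)] = FEMALE
        elif (sex == FEMALE).all():
            sex[rng.integers(cohort)] = MALE
        ids = [f"G{g}_{k}" for k in range(cohort)]
        for iid, s, d, x in zip(ids, sire_of, dam_of, sex):
            rows.append((iid, s, d, x))
        males = [i for i, x in zip(ids, sex) if x == MALE]
        females = [i for i, x in zip(ids, sex) if x == FEMALE]
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


def mosaic_founder_haps(
    marker_map: MarkerMap,
    n_haps: int,
    n_ancestral: int = 20,
    switch_cm: float = 5.0,
    founder_freqs: np.ndarray | float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Founder haplotype pool with linkage disequilibrium.

    A small panel of ancestral haplotypes draws alleles independently at
    ``founder_freqs``; each founder haplotype is then a mosaic copying
    from the panel with template switches at rate 1/``switch_cm`` per cM
    (female map). Allele frequencies stay near the targets while nearby
    markers become strongly correlated, emulating the LD that lets
    haplotype clusters tag unobserved variants.
    """
    rng = np.random.default_rng(seed)
    m = marker_map.n_markers
    freqs = np.broadcast_to(np.asarray(founder_freqs, dtype=float), (m,))
    pool = (rng.random((n_ancestral, m)) < freqs).astype(np.uint8)
    cm = marker_map.table["cm_female"].to_numpy()
    p_switch = 1.0 - np.exp(-np.diff(cm) / switch_cm)
    out = np.empty((n_haps, m), dtype=np.uint8)
    for h in range(n_haps):
        tpl = np.empty(m, dtype=np.int64)
        tpl[0] = rng.integers(n_ancestral)
        switches = rng.random(m - 1) < p_switch
        cur = tpl[0]
        for i, sw in enumerate(switches, start=1):
            if sw:
                cur = rng.integers(n_ancestral)
            tpl[i] = cur
        out[h] = pool[tpl, np.arange(m)]
    return out


def plant_allele_on_background(
    pool: np.ndarray, col: int, target_freq: float, window: int = 2
) -> float:
    """Rewrite one pool column as a young mutation on a local haplotype.

    The allele is assigned to every pool haplotype carrying the flanking
    ``window``-marker pattern whose frequency is closest to
    ``target_freq``, so it starts in complete LD with its background —
    the situation that lets haplotype clusters tag a causal variant.
    Modifies ``pool`` in place and returns the realized frequency.
    """
    cols = [c for c in range(col - window, col + window + 1) if c != col]
    pats, inv, counts = np.unique(
        pool[:, cols], axis=0, return_inverse=True, return_counts=True
    )
    freqs = counts / pool.shape[0]
    best = int(np.argmin(np.abs(freqs - target_freq)))
    pool[:, col] = (inv == best).astype(np.uint8)
    return float(freqs[best])


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _interval_switch_probs(cm: np.ndarray) -> np.ndarray:
    """P(odd number of crossovers) per interval under Haldane's map."""
    d = np.diff(cm) / 100.0  # Morgans
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _meiosis(h0: np.ndarray, h1: np.ndarray, switch_p: np.ndarray, rng):
    """One gamete from a diploid parent; returns (gamete, origin, n_co)."""
    m = h0.shape[0]
    if m == 0:
        return np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.uint8), 0
    origin = np.empty(m, dtype=np.uint8)
    start = rng.integers(2)
    flips = rng.random(m - 1) < switch_p if m > 1 else np.empty(0, dtype=bool)
    origin[0] = start
    if m > 1:
        origin[1:] = (start + np.cumsum(flips)) % 2
    gamete = np.where(origin == 0, h0, h1).astype(np.uint8)
    return gamete, origin, int(flips.sum())


def drop_genomes(
    ped: Pedigree,
    marker_map: MarkerMap,
    founder_freqs: np.ndarray | float = 0.5,
    seed: int = 0,
    founder_haps: np.ndarray | None = None,
    track_origins: bool = True,
) -> HaplotypePanel:
    """Drop X haplotypes through every meiosis of the pedigree.

    Founder haplotypes are i.i.d. Bernoulli at ``founder_freqs`` unless an
    explicit ``founder_haps`` pool (n_pool x n_markers) is supplied, in
    which case founder haplotypes are sampled from it with replacement
    (useful to seed linkage disequilibrium).

    Inheritance rules: a female meiosis recombines over the whole
    chromosome with the female map; a male transmits his X-specific
    haplotype unrecombined to daughters and nothing X-specific to sons,
    while his PAR recombines between the X-PAR and Y-PAR with the male map.
    """
    m = marker_map.n_markers
    freqs = np.broadcast_to(np.asarray(founder_freqs, dtype=float), (m,))
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise SimulationError("founder frequencies must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    par = marker_map.region_mask(PAR)
    xsp = ~par
    sw_f = _interval_switch_probs(marker_map.table["cm_female"].to_numpy())
    sw_m = _interval_switch_probs(marker_map.table["cm_male"].to_numpy())

    sire_ix, dam_ix = ped.parent_indices()
    sex = ped.sex_array()
    haps = np.zeros((ped.n, 2, m), dtype=np.uint8)
    origins: dict = {}

    def founder_hap():
        if founder_haps is not None:
            return founder_haps[rng.integers(founder_haps.shape[0])].astype(np.uint8)
        return (rng.random(m) < freqs).astype(np.uint8)

    ids = ped.ids
    for k in range(ped.n):
        s, d = sire_ix[k], dam_ix[k]
        # maternal gamete -> copy 0
        if d < 0:
            haps[k, 0] = founder_hap()
        else:
            gam, origin, nco = _meiosis(haps[d, 0], haps[d, 1], sw_f, rng)
            haps[k, 0] = gam
            if track_origins:
                origins[(ids[d], ids[k])] = {"origin": origin, "n_co": nco}
        # paternal contribution -> copy 1
        if s < 0:
            haps[k, 1] = founder_hap()
        else:
            sire_par0 = haps[s, 0][par]
            sire_par1 = haps[s, 1][par]
            gam_par, origin_par, nco_par = _meiosis(
                sire_par0, sire_par1, sw_m[par[:-1] & par[1:]], rng
            )
            pat = np.empty(m, dtype=np.uint8)
            pat[par] = gam_par
            pat[xsp] = haps[s, 0][xsp]  # daughters: sire's X-specific, uncut
            haps[k, 1] = pat
            if track_origins:
                origins[(ids[s], ids[k])] = {"origin": origin_par, "n_co": nco_par}
        if sex[k] == MALE:
            haps[k, 1, xsp] = HaplotypePanel.INVALID
    return HaplotypePanel(marker_map, ids.copy(), sex.copy(), haps, origins)


# ---------------------------------------------------------------------------
# crossover counting
# ---------------------------------------------------------------------------


def count_crossovers(
    parent_hap1: np.ndarray, parent_hap2: np.ndarray, gamete: np.ndarray
) -> int:
    """Crossovers observable as origin switches along a gamete.

    Only markers where the parent is heterozygous are informative; each
    informative allele is labelled with the parental haplotype it matches
    and the number of label switches along the map is returned. At
    homozygous markers the gamete must carry the shared allele.
    """
    h1 = np.asarray(parent_hap1)
    h2 = np.asarray(parent_hap2)
    g = np.asarray(gamete)
    if not (h1.shape == h2.shape == g.shape):
        raise ValueError("haplotype length mismatch")
    hom = h1 == h2
    if np.any(g[hom] != h1[hom]):
        bad = int(np.nonzero(hom & (g != h1))[0][0])
        raise GenotypeInconsistencyError(
            f"gamete allele at marker index {bad} matches neither parental allele"
        )
    info = ~hom
    origin = (g[info] == h2[info]).astype(np.int8)
    if origin.size < 2:
        return 0
    return int(np.sum(np.diff(origin) != 0))


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def simulate_covariates(ped: Pedigree, seed: int = 0, concentration: float = 2.0):
    """Breed-admixture covariates c1..c4.

    Founders draw admixture proportions from a 5-component Dirichlet;
    offspring average their parents (unknown parents draw fresh). The
    first four coordinates serve as the fixed covariates standing in for
    principal components of genetic structure.
    """
    rng = np.random.default_rng(seed)
    sire_ix, dam_ix = ped.parent_indices()
    adm = np.empty((ped.n, 5))
    for k in range(ped.n):
        s, d = sire_ix[k], dam_ix[k]
        a_s = adm[s] if s >= 0 else rng.dirichlet(np.full(5, concentration))
        a_d = adm[d] if d >= 0 else rng.dirichlet(np.full(5, concentration))
        adm[k] = 0.5 * (a_s + a_d)
    return pd.DataFrame(
        adm[:, :4], index=ped.ids, columns=["c1", "c2", "c3", "c4"]
    )


def _pedigree_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients; exact below ~4,000 individuals, else 0.

    Simulated random-mating pedigrees carry negligible inbreeding; the
    exact tabular computation is quadratic in pedigree size, so very large
    pedigrees fall back to f = 0 for the Mendelian-sampling variances.
    """
    if ped.n > 4000:
        return np.zeros(ped.n)
    from .pedrel import autosomal_A

    A = autosomal_A(ped)
    return np.diag(A.values) - 1.0


def simulate_genetic_effects(ped: Pedigree, var_a: float, var_s: float, rng):
    """Autosomal (u) and X-linked (s) polygenic values by pedigree recursion.

    u follows the standard Mendelian-sampling recursion with covariance
    A * var_a. The X effect uses a gametic recursion: each founder gamete
    has variance var_s; a daughter's paternal gametic value copies the
    sire's, any maternal gametic value is a fair draw refreshed with
    Mendelian noise so every gametic value keeps variance var_s.
    Individual values are w (males) and (w_pat + w_mat)/sqrt(2) (females),
    matching the equal-variance X relationship matrix convention.
    """
    sire_ix, dam_ix = ped.parent_indices()
    sex = ped.sex_array()
    f = _pedigree_inbreeding(ped)
    n = ped.n
    u = np.zeros(n)
    w = np.zeros((n, 2))  # [paternal, maternal] gametic X values; males use col 1
    sd_a = np.sqrt(var_a) if var_a > 0 else 0.0
    for k in range(n):
        s, d = sire_ix[k], dam_ix[k]
        if var_a > 0:
            if s < 0 and d < 0:
                u[k] = rng.normal(0, sd_a)
            else:
                mean = 0.5 * ((u[s] if s >= 0 else 0.0) + (u[d] if d >= 0 else 0.0))
                fs = f[s] if s >= 0 else 0.0
                fd = f[d] if d >= 0 else 0.0
                if s >= 0 and d >= 0:
                    # exact Mendelian-sampling variance given both parents
                    msv = var_a * (0.5 - 0.25 * (fs + fd))
                else:
                    # one unknown parent contributes a fresh founder half
                    msv = var_a * (0.75 - 0.25 * (fs + fd))
                u[k] = mean + rng.normal(0, np.sqrt(max(msv, 0.0)))
        # X gametic values
        if d >= 0:
            wd = w[d]
            pick = 0.5 * (wd[0] + wd[1])
            # refresh to full gametic variance; the within-dam gametic
            # correlation (X-linked inbreeding) is ~0 under random mating
            w_mat = pick + (rng.normal(0, np.sqrt(var_s * 0.5)) if var_s > 0 else 0.0)
        else:
            w_mat = rng.normal(0, np.sqrt(var_s)) if var_s > 0 else 0.0
        if sex[k] == FEMALE:
            if s >= 0:
                w_pat = w[s, 1]  # sire's single X gamete, copied
            else:
                w_pat = rng.normal(0, np.sqrt(var_s)) if var_s > 0 else 0.0
            w[k] = (w_pat, w_mat)
        else:
            w[k] = (np.nan, w_mat)
    s_val = np.where(
        sex == MALE, w[:, 1], (np.nan_to_num(w[:, 0]) + w[:, 1]) / np.sqrt(2.0)
    )
    return u, s_val


def simulate_phenotypes(
    ped: Pedigree,
    panel: HaplotypePanel | None,
    gametes: list[tuple[str, str]],
    truth: TruthConfig,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gamete crossover-count records.

    ``gametes`` lists (parent_id, offspring_id) pairs; each becomes one
    record of the parent. Offspring ids only label records and need not be
    genotyped. Returns a MeiosisRecordTable DataFrame with columns
    parent_id, offspring_id, parent_sex, co_count, c1..c4.
    """
    for p, _ in gametes:
        if p not in ped:
            raise SimulationError(f"gamete parent {p!r} not in pedigree")
    rng = np.random.default_rng(truth.seed)
    u, s_val = simulate_genetic_effects(ped, truth.var_a, truth.var_s, rng)
    from .pedrel import y_lineages

    lin = y_lineages(ped)
    lineage_effect = {
        l: rng.normal(0, np.sqrt(truth.var_i)) if truth.var_i > 0 else 0.0
        for l in sorted(set(lin.lineage_of.values()))
    }
    if covariates is None:
        covariates = simulate_covariates(ped, seed=truth.seed + 1)
    beta = np.asarray(truth.beta, dtype=float)

    qtl_value = np.zeros(ped.n)
    if truth.qtls:
        if panel is None:
            raise SimulationError("QTL effects require a haplotype panel")
        dos = panel.dosages(X_SPECIFIC)
        sex = ped.sex_array()
        for q in truth.qtls:
            if q.marker_id not in dos.columns:
                raise SimulationError(f"QTL marker {q.marker_id!r} not in panel")
            x = dos[q.marker_id].reindex(ped.ids).to_numpy(dtype=float)
            x = np.nan_to_num(x)
            expressed = np.ones(ped.n, dtype=bool)
            if q.sex == "male":
                expressed = sex == MALE
            elif q.sex == "female":
                expressed = sex == FEMALE
            qtl_value += np.where(expressed, q.effect * x, 0.0)

    perm_env: dict[str, float] = {}
    rows = []
    sd_p = np.sqrt(truth.var_p)
    sd_e = np.sqrt(truth.var_e)
    for parent, offspring in gametes:
        k = ped.index_of(parent)
        if parent not in perm_env:
            perm_env[parent] = rng.normal(0, sd_p) if truth.var_p > 0 else 0.0
        c = covariates.loc[parent].to_numpy(dtype=float)
        mean = (
            truth.mu
            + float(c @ beta)
            + u[k]
            + s_val[k]
            + lineage_effect.get(lin.lineage_of.get(parent), 0.0)
            + qtl_value[k]
            + perm_env[parent]
        )
        y = mean + (rng.normal(0, sd_e) if truth.var_e > 0 else 0.0)
        if truth.round_counts:
            y = max(0.0, round(y))
        rows.append(
            (parent, offspring, ped.table["sex"].iloc[k], y, c[0], c[1], c[2], c[3])
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
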