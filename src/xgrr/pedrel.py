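"""Pedigree and marker-based relationship structures.

Implements the autosomal additive relationship matrix A (tabular method,
with inbreeding), the X-linked additive relationship matrix S built by a
gametic recursion (males carry one X gamete, females two; a daughter's
paternal gamete is an exact copy of the sire's), Y-chromosome patrilines,
and the sex-specific centering/scaling of X dosages whose cross-product
acts as the realized (genomic) X relationship matrix.

The S convention is the equal-variance one: expected diagonal 1 for both
sexes (females 1 + f_X when X-inbred), with a sqrt(2) factor on cross-sex
entries. It is the unique convention under which the scaled-dosage
cross-product XX' has unit expected diagonal in both sexes and the
SNP-effect variance equals the X-linked individual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Pedigree
from .simdata import X_SPECIFIC, HaplotypePanel


@dataclass
class RelationshipMatrix:
    """Symmetric PSD covariance structure over an ordered id list."""

    kind: str
    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape mismatch")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def submatrix(self, ids) -> np.ndarray:
        ix = np.array([self._index[i] for i in ids])
        return self.values[np.ix_(ix, ix)]

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class YLineageMap:
    """Patriline membership: every male maps to his male-line founder."""

    lineage_of: dict

    @property
    def n_lineages(self) -> int:
        return len(set(self.lineage_of.values()))

    def incidence(self, males) -> tuple[np.ndarray, list]:
        """0/1 matrix mapping the given males to lineage columns."""
        lineages = sorted({self.lineage_of[m] for m in males})
        col = {l: j for j, l in enumerate(lineages)}
        Z = np.zeros((len(males), len(lineages)))
        for i, m in enumerate(males):
            Z[i, col[self.lineage_of[m]]] = 1.0
        return Z, lineages


@dataclass
class ScaledDosageMatrix:
    """Centered, sex-specifically scaled X-specific dosages.

    Rows are individuals, columns retained markers. Male entries are
    (x - p)/sqrt(sum p(1-p)), female entries (x - 2p)/sqrt(2 sum p(1-p)),
    sums over retained markers, so diag(XX') has expectation 1 in both
    sexes under Hardy-Weinberg.
    """

    values: np.ndarray
    ids: np.ndarray
    marker_ids: np.ndarray
    freqs: np.ndarray

    def rows_for(self, ids) -> np.ndarray:
        ix = {i: k for k, i in enumerate(self.ids)}
        return self.values[[ix[i] for i in ids]]

    def grm(self) -> np.ndarray:
        return self.values @ self.values.T


# ---------------------------------------------------------------------------


def autosomal_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    sire, dam = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for k in range(n):
        s, d = sire[k], dam[k]
        row = np.zeros(k)
        if s >= 0:
            row += 0.5 * A[s, :k]
        if d >= 0:
            row += 0.5 * A[d, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix("autosomal-A", ped.ids.copy(), A)


def _gametic_R(ped: Pedigree):
    """IBD relationship among X gametes (males one, females two).

    Returns (R, gidx) where gidx[i] lists the gamete rows of individual i
    as [paternal, maternal] for females, [maternal] for males.
    """
    sire, dam = ped.parent_indices()
    sex = ped.sex_array()
    n_g = int(np.sum(sex == FEMALE) * 2 + np.sum(sex == MALE))
    R = np.zeros((n_g, n_g))
    gidx: list[list[int]] = []
    g = 0

    def new_maternal(d):
        nonlocal g
        if d >= 0:
            d1, d2 = gidx[d]
            R[g, :g] = 0.5 * (R[d1, :g] + R[d2, :g])
        R[:g, g] = R[g, :g]
        R[g, g] = 1.0
        g += 1
        return g - 1

    for k in range(ped.n):
        s, d = sire[k], dam[k]
        if sex[k] == MALE:
            gidx.append([new_maternal(d)])
        else:
            # paternal gamete: exact copy of the sire's single gamete
            if s >= 0:
                sg = gidx[s][0]
                R[g, :g] = R[sg, :g]
            R[:g, g] = R[g, :g]
            R[g, g] = 1.0
            pat = g
            g += 1
            gidx.append([pat, new_maternal(d)])
    return R, gidx


def xlinked_S(ped: Pedigree) -> RelationshipMatrix:
    """X-linked additive relationship matrix from the gametic recursion.

    Individual entries combine gametic IBD as S = W' R W with weights 1 on
    a male's gamete and 1/sqrt(2) on each female gamete: male-male r(g,g'),
    female-female quarter-sum/2, male-female sum/sqrt(2), male diagonal
    exactly 1.
    """
    R, gidx = _gametic_R(ped)
    sex = ped.sex_array()
    n = ped.n
    W = np.zeros((R.shape[0], n))
    for k in range(n):
        if sex[k] == MALE:
            W[gidx[k][0], k] = 1.0
        else:
            W[gidx[k][0], k] = W[gidx[k][1], k] = 1.0 / np.sqrt(2.0)
    S = W.T @ R @ W
    return RelationshipMatrix("X-linked-S", ped.ids.copy(), S)


def y_lineages(ped: Pedigree) -> YLineageMap:
    """Assign every male to his patriline founder (Y-chromosome lineage)."""
    sire, _ = ped.parent_indices()
    sex = ped.sex_array()
    ids = ped.ids
    lineage: dict[str, str] = {}
    for k in range(ped.n):
        if sex[k] != MALE:
            continue
        s = sire[k]
        lineage[ids[k]] = lineage[ids[s]] if s >= 0 else ids[k]
    return YLineageMap(lineage)


class EmptyPanelError(ValueError):
    """No polymorphic markers survive filtering."""


def scaled_X(
    panel: HaplotypePanel,
    freqs: np.ndarray | str = "counted",
    maf_min: float = 0.0,
) -> ScaledDosageMatrix:
    """Center and scale X-specific dosages for SNP-BLUP / realized-X use.

    Frequencies are counted from the panel (one allele per male, two per
    female) unless an explicit array of per-marker frequencies is supplied
    (e.g. true founder frequencies in simulation oracles). Markers with
    minor allele frequency below ``maf_min`` are dropped before scaling.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    dos = panel.dosages(X_SPECIFIC)
    marker_ids = dos.columns.to_numpy()
    if isinstance(freqs, str):
        if freqs != "counted":
            raise ValueError("freqs must be 'counted' or an array")
        p = panel.allele_frequencies(X_SPECIFIC)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (len(marker_ids),):
            raise ValueError("supplied frequency length mismatch")
    keep = np.minimum(p, 1 - p) >= maf_min
    keep &= (p > 0) & (p < 1)
    if not keep.any():
        raise EmptyPanelError("no polymorphic markers retained after MAF filter")
    p = p[keep]
    x = dos.to_numpy(dtype=float)[:, keep]
    denom = np.sum(p * (1 - p))
    male = panel.sex == MALE
    out = np.empty_like(x)
    out[male] = (x[male] - p) / np.sqrt(denom)
    out[~male] = (x[~male] - 2 * p) / np.sqrt(2 * denom)
    return ScaledDosageMatrix(out, panel.samples.copy(), marker_ids[keep], p)
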