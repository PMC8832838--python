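"""Localized haplotype-cluster model (fastPHASE-style HMM).

Phased haplotypes are modelled as mosaics of K latent clusters. The
hidden path jumps between markers with interval-specific probability
rho_m; on a jump the new cluster is drawn from the marker-specific
cluster weights alpha[:, m] (also the initial distribution), otherwise
the path stays in its cluster. Alleles are emitted Bernoulli(theta[k, m]).
Haplotypes that are locally similar therefore share a cluster at each
marker, which is what the haplotype-based association scan tests.

The transition matrix (1 - rho) I + rho 1 alpha' is rank-one plus
identity, so the forward, backward and Viterbi recursions all run in
O(K) per marker instead of O(K^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EMISSION_FLOOR = 1e-4


class ClusterModelError(ValueError):
    pass


@dataclass
class ClusterModel:
    """Fitted haplotype-cluster HMM parameters."""

    theta: np.ndarray  # (K, M) emission P(allele 1)
    alpha: np.ndarray  # (K, M) cluster weights, columns on the simplex
    rho: np.ndarray  # (M,) jump probability into marker m; rho[0] unused
    loglik: float
    loglik_path: np.ndarray  # per-EM-iteration total log-likelihood

    @property
    def K(self) -> int:
        return self.theta.shape[0]

    @property
    def n_markers(self) -> int:
        return self.theta.shape[1]


@dataclass
class ClusterAssignment:
    """Viterbi cluster state per haplotype per marker."""

    states: np.ndarray  # (H, M) int
    hap_index: list  # H pairs (sample, copy)

    def states_for(self, sample: str) -> np.ndarray:
        rows = [i for i, (s, _) in enumerate(self.hap_index) if s == sample]
        return self.states[rows]

    def to_frame(self, marker_ids=None):
        """Haplotype x marker table of cluster states (for TSV export)."""
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(self.hap_index, names=["sample", "copy"])
        cols = marker_ids if marker_ids is not None else range(self.states.shape[1])
        return pd.DataFrame(self.states, index=idx, columns=cols)


def _emissions(H: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """B[h, k, m] = P(allele H[h, m] | cluster k)."""
    return np.where(H[:, None, :] == 1, theta[None], 1.0 - theta[None])


def _forward_backward(H: np.ndarray, theta, alpha, rho):
    """Scaled forward-backward for all haplotypes at once.

    Returns per-marker posteriors ``gamma`` (H, K, M), the per-haplotype
    log-likelihoods, scaled forward variables and scale factors needed
    for the jump posteriors.
    """
    nh, M = H.shape
    K = theta.shape[0]
    B = _emissions(H, theta)
    f = np.empty((nh, K, M))
    c = np.empty((nh, M))
    a = alpha[:, 0][None] * B[:, :, 0]
    c[:, 0] = a.sum(axis=1)
    f[:, :, 0] = a / c[:, 0][:, None]
    for m in range(1, M):
        pred = (1.0 - rho[m]) * f[:, :, m - 1] + rho[m] * alpha[:, m][None]
        a = pred * B[:, :, m]
        c[:, m] = a.sum(axis=1)
        f[:, :, m] = a / c[:, m][:, None]
    b = np.empty((nh, K, M))
    b[:, :, M - 1] = 1.0
    for m in range(M - 2, -1, -1):
        nxt = B[:, :, m + 1] * b[:, :, m + 1]
        b[:, :, m] = ((1.0 - rho[m + 1]) * nxt + rho[m + 1] * (nxt * alpha[:, m + 1][None]).sum(axis=1)[:, None]) / c[:, m + 1][:, None]
    gamma = f * b
    gamma /= gamma.sum(axis=1, keepdims=True)
    logl = np.log(c).sum(axis=1)
    return gamma, logl, f, b, c, B


def loglikelihood(H: np.ndarray, model: ClusterModel) -> float:
    """Total forward-algorithm log-likelihood of a haplotype matrix."""
    _, logl, *_ = _forward_backward(H, model.theta, model.alpha, model.rho)
    return float(logl.sum())


def brute_force_loglik(H: np.ndarray, theta, alpha, rho) -> float:
    """Likelihood by explicit enumeration of all K^M hidden paths.

    Exponential in the number of markers; an oracle for tiny instances.
    """
    from itertools import product

    nh, M = H.shape
    K = theta.shape[0]
    total = 0.0
    for h in range(nh):
        like = 0.0
        for path in product(range(K), repeat=M):
            pr = alpha[path[0], 0]
            for m in range(1, M):
                stay = (1.0 - rho[m]) if path[m] == path[m - 1] else 0.0
                pr *= stay + rho[m] * alpha[path[m], m]
            for m in range(M):
                th = theta[path[m], m]
                pr *= th if H[h, m] == 1 else 1.0 - th
            like += pr
        total += np.log(like)
    return float(total)


def fit_cluster_model(
    H: np.ndarray,
    K: int,
    n_starts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    positions_cm: np.ndarray | None = None,
) -> ClusterModel:
    """EM fit of the cluster HMM to phased binary haplotypes.

    ``H`` is (haplotypes x markers) in {0, 1}; in the X-specific region
    males contribute one row and females two. Emission probabilities are
    floored at 1e-4; jump probabilities are initialized from inter-marker
    map distance when ``positions_cm`` is given, else at 0.05. The best of
    ``n_starts`` random restarts by log-likelihood is returned.
    """
    H = np.asarray(H, dtype=np.uint8)
    nh, M = H.shape
    if K < 1:
        raise ClusterModelError("K must be >= 1")
    if K > nh:
        raise ClusterModelError("more clusters than haplotypes")
    master = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(max(n_starts, 1)):
        rng = np.random.default_rng(master.integers(2**31))
        theta = np.clip(
            H[_spread_centers(H, K, rng)].astype(float)
            + rng.normal(0, 0.05, (K, M)),
            EMISSION_FLOOR,
            1 - EMISSION_FLOOR,
        )
        alpha = np.full((K, M), 1.0 / K)
        if positions_cm is not None:
            d = np.diff(np.asarray(positions_cm, dtype=float)) / 100.0
            rho = np.concatenate([[0.0], 1.0 - np.exp(-4.0 * K * d / 2)])
        else:
            rho = np.full(M, 0.05)
            rho[0] = 0.0
        rho = np.clip(rho, 1e-6, 1 - 1e-6)
        rho[0] = 0.0
        path = []
        prev = -np.inf
        for _it in range(max_iter):
            gamma, logl_h, f, b, c, B = _forward_backward(H, theta, alpha, rho)
            logl = float(logl_h.sum())
            path.append(logl)
            # M-step: emissions
            wsum = gamma.sum(axis=0)  # (K, M)
            theta = np.clip(
                np.einsum("hkm,hm->km", gamma, H.astype(float)) / np.maximum(wsum, 1e-300),
                EMISSION_FLOOR,
                1 - EMISSION_FLOOR,
            )
            if K > 1 and M > 1:
                # posterior probability that the path jumped into (k, m):
                # xi[h,k,m] = rho_m alpha[k,m] B[h,k,m] b[h,k,m] / c[h,m]
                xi = (
                    rho[None, None, 1:]
                    * alpha[None, :, 1:]
                    * B[:, :, 1:]
                    * b[:, :, 1:]
                    / c[:, None, 1:]
                )
                jump = xi.sum(axis=1)  # (H, M-1) P(jump at marker m)
                tot_jump = jump.sum(axis=0)  # per marker
                rho[1:] = np.clip(tot_jump / nh, 1e-6, 1 - 1e-6)
                num = xi.sum(axis=0)  # (K, M-1) expected jumps into k
                ok = tot_jump > 1e-12
                alpha[:, 1:][:, ok] = num[:, ok] / tot_jump[ok]
                alpha[:, 0] = gamma[:, :, 0].sum(axis=0) / nh
                alpha = np.maximum(alpha, 1e-12)
                alpha /= alpha.sum(axis=0, keepdims=True)
            elif K > 1:
                alpha[:, 0] = gamma[:, :, 0].sum(axis=0) / nh
                alpha /= alpha.sum(axis=0, keepdims=True)
            if logl - prev < tol and _it > 0:
                prev = logl
                break
            prev = logl
        gamma, logl_h, *_ = _forward_backward(H, theta, alpha, rho)
        final = float(logl_h.sum())
        path.append(final)
        cand = ClusterModel(theta, alpha, rho, final, np.array(path))
        if best is None or cand.loglik > best.loglik:
            best = cand
    return best


def _spread_centers(H: np.ndarray, K: int, rng) -> np.ndarray:
    """Greedy max-min-Hamming seed haplotypes (k-means++-style).

    Spread-out emission centers keep EM away from the label-switching
    local optima the per-interval jump parameterization admits.
    """
    nh = H.shape[0]
    first = int(rng.integers(nh))
    chosen = [first]
    d = (H != H[first]).sum(axis=1).astype(float)
    for _ in range(1, K):
        d[chosen] = -1.0
        best = int(np.argmax(d + 1e-3 * rng.random(nh)))
        chosen.append(best)
        d = np.minimum(d, (H != H[best]).sum(axis=1))
    return np.array(chosen)


def assign_clusters(model: ClusterModel, H: np.ndarray, hap_index=None) -> ClusterAssignment:
    """Maximum a posteriori (Viterbi) cluster path per haplotype.

    Exploits the stay-or-jump transition structure: the best predecessor
    is either the same cluster (stay or jump-to-self) or the globally best
    previous cluster (jump), giving an O(K) update per marker.
    """
    H = np.asarray(H, dtype=np.uint8)
    nh, M = H.shape
    if M != model.n_markers:
        raise ClusterModelError("marker count mismatch between model and panel")
    K = model.K
    with np.errstate(divide="ignore"):
        logB = np.log(_emissions(H, model.theta))
        la = np.log(model.alpha)
    score = la[:, 0][None] + logB[:, :, 0]
    back = np.zeros((nh, K, M), dtype=np.int32)
    for m in range(1, M):
        rho = model.rho[m]
        # log((1-rho) + rho*alpha_k) for staying in k; log(rho*alpha_k) for a jump
        stay_lp = np.log((1.0 - rho) + rho * model.alpha[:, m])[None]
        jump_lp = np.log(rho * model.alpha[:, m] + 1e-300)[None]
        best_prev = score.max(axis=1)
        arg_prev = score.argmax(axis=1)
        stay_score = score + stay_lp
        jump_score = best_prev[:, None] + jump_lp
        take_jump = jump_score > stay_score
        score = np.where(take_jump, jump_score, stay_score) + logB[:, :, m]
        back[:, :, m] = np.where(take_jump, arg_prev[:, None], np.arange(K)[None])
    states = np.empty((nh, M), dtype=np.int32)
    states[:, M - 1] = score.argmax(axis=1)
    for m in range(M - 1, 0, -1):
        states[:, m - 1] = back[np.arange(nh), states[:, m], m]
    return ClusterAssignment(states, hap_index or [(str(i), 0) for i in range(nh)])


def posterior_decode(model: ClusterModel, H: np.ndarray):
    """Per-marker posterior cluster probabilities (forward-backward)."""
    gamma, logl, *_ = _forward_backward(H, model.theta, model.alpha, model.rho)
    return gamma, logl
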