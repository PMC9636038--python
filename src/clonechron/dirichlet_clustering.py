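"""Dirichlet-process clustering of mutations by cancer cell fraction.

Mutations are clustered on their cellular prevalence jointly across all
sequenced regions of a tumor with a truncated stick-breaking Gibbs
sampler. Each cluster k has a per-sample CCF center pi_ks; the emission for
mutation i in sample s is

    alt_is ~ Binomial(depth_is, pi_ks * xi_is)

where xi_is = expected_vaf(multiplicity, total CN, purity) converts a CCF
of 1 into the expected VAF at that locus. Because a mutation only enters
the dataset if the caller saw enough supporting reads, each cluster's
likelihood is divided by the probability of detection — at least
``min_alt_detect`` alt reads in at least one sample — which corrects the
bias that would otherwise shrink low-CCF clusters toward detectable
frequencies.

Cluster centers are non-conjugate after that correction, so they are
updated with a per-coordinate Metropolis step using a Beta proposal;
stick weights and (optionally) the DP concentration follow standard
conjugate updates. Hard assignments are the modal cluster over post-burn-in
sweeps, and clusters smaller than ``min_cluster_size`` are merged into the
nearest retained center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .ccf_engine import expected_vaf

logger = logging.getLogger(__name__)


@dataclass
class ClusteringConfig:
    max_clusters: int = 30
    n_iter: int = 2000
    burn_in: int = 500
    concentration: float | str = 1.0  # positive float, or "gamma" for a Gamma(1,1) prior
    min_alt_detect: int = 4
    seed: int = 0
    min_cluster_size: int = 5
    ccf_max: float = 1.5  # support of the cluster-center prior (raw CCFs exceed 1)
    proposal_concentration: float = 80.0  # Beta-proposal tightness for center moves

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if isinstance(self.concentration, str) and self.concentration != "gamma":
            raise ValueError("concentration must be a positive float or 'gamma'")


@dataclass
class MutationCluster:
    cluster_id: str
    ccf_center: dict[str, float]
    n_mutations: int
    members: list[str] = field(default_factory=list)

    def mean_center(self) -> float:
        return float(np.mean(list(self.ccf_center.values())))


@dataclass
class ClusteringResult:
    clusters: list[MutationCluster]
    assignments: pd.DataFrame  # mutation_id, cluster_id
    posterior: pd.DataFrame  # index mutation_id, columns cluster ids, rows sum to 1
    converged: bool
    samples: list[str]


def _prepare_matrices(annotations: pd.DataFrame):
    ann = annotations[~annotations["excluded"].astype(bool)].copy()
    if ann.empty:
        raise ValueError("no usable annotations to cluster")
    samples = sorted(ann["sample"].unique())
    ann["xi1"] = [
        expected_vaf(int(m), int(t), float(p))
        for m, t, p in zip(ann["multiplicity"], ann["total_cn"], ann["purity"])
    ]
    alt = ann.pivot(index="mutation_id", columns="sample", values="alt_reads")
    depth = ann.pivot(index="mutation_id", columns="sample", values="depth")
    xi1 = ann.pivot(index="mutation_id", columns="sample", values="xi1")
    if alt.isna().any().any():
        bad = alt.index[alt.isna().any(axis=1)][:3].tolist()
        raise ValueError(
            f"every mutation needs an annotation in every sample; missing for {bad} "
            "(record absent mutations with 0 alt reads at observed depth)"
        )
    ids = alt.index.to_list()
    return (
        ids,
        samples,
        alt[samples].to_numpy(dtype=float),
        depth[samples].to_numpy(dtype=float),
        xi1[samples].to_numpy(dtype=float),
    )


def cluster_mutations(annotations: pd.DataFrame, config: ClusteringConfig) -> ClusteringResult:
    """Cluster mutations by CCF across samples. Deterministic given the seed."""
    ids, samples, alt, depth, f = _prepare_matrices(annotations)
    n, S = alt.shape
    K = min(config.max_clusters, max(n, 2))
    rng = np.random.default_rng(config.seed)
    eps = 1e-9

    log_choose = special.gammaln(depth + 1) - special.gammaln(alt + 1) - special.gammaln(depth - alt + 1)
    obs_ccf = np.clip(np.divide(alt, np.maximum(depth, 1.0)) / np.maximum(f, eps), 0.0, config.ccf_max)

    # init centers from observed per-mutation CCF vectors, assignments by
    # nearest center
    pick = rng.choice(n, size=K, replace=n < K)
    pi = np.clip(obs_ccf[pick] + rng.normal(0, 0.02, size=(K, S)), 0.01, config.ccf_max)
    z = np.argmin(((obs_ccf[:, None, :] - pi[None, :, :]) ** 2).sum(axis=2), axis=1)

    alpha = 1.0 if config.concentration == "gamma" else float(config.concentration)
    kdet = max(config.min_alt_detect - 1, 0)

    def binom_cdf_le(n_arr, p_arr):
        """P(X <= kdet) via the regularized incomplete beta function."""
        n_b = np.broadcast_to(n_arr, p_arr.shape)
        a = n_b - kdet
        out = np.ones_like(p_arr)
        ok = a > 0
        out[ok] = special.betainc(a[ok], kdet + 1.0, 1.0 - p_arr[ok])
        return out

    def full_loglik(pi_mat):
        """(n, K) member log-likelihood incl. the detection correction."""
        xi = np.clip(pi_mat[None, :, :] * f[:, None, :], eps, 1.0 - eps)
        ll = (
            log_choose[:, None, :]
            + alt[:, None, :] * np.log(xi)
            + (depth - alt)[:, None, :] * np.log1p(-xi)
        )
        cdf = binom_cdf_le(depth[:, None, :], xi)
        pdet = np.maximum(1.0 - np.prod(cdf, axis=2), 1e-12)
        return ll.sum(axis=2) - np.log(pdet)

    def member_loglik(idx, pivec):
        xi = np.clip(pivec[None, :] * f[idx], eps, 1.0 - eps)
        ll = log_choose[idx] + alt[idx] * np.log(xi) + (depth[idx] - alt[idx]) * np.log1p(-xi)
        cdf = binom_cdf_le(depth[idx], xi)
        pdet = np.maximum(1.0 - np.prod(cdf, axis=1), 1e-12)
        return float(ll.sum() - np.log(pdet).sum())

    n_saved = 0
    posterior_counts = np.zeros((n, K))
    pi_sum = np.zeros((K, S))
    pi_occ = np.zeros(K)  # iterations in which each stick held members
    occupied_trace = []
    nu = config.proposal_concentration

    for it in range(config.n_iter):
        # --- stick-breaking weights
        n_k = np.bincount(z, minlength=K).astype(float)
        n_gt = n - np.cumsum(n_k)
        V = rng.beta(1.0 + n_k, alpha + np.maximum(n_gt, 0.0))
        V = np.clip(V, 1e-12, 1.0 - 1e-12)
        V[-1] = 1.0
        logw = np.log(V)
        logw[1:] += np.cumsum(np.log1p(-V[:-1]))

        # --- concentration update under a Gamma(1,1) prior
        if config.concentration == "gamma":
            rate = 1.0 - np.sum(np.log1p(-V[:-1]))
            alpha = float(rng.gamma(1.0 + (K - 1), 1.0 / rate))

        # --- assignments
        ll = full_loglik(pi)
        gumbel = rng.gumbel(size=(n, K))
        z = np.argmax(logw[None, :] + ll + gumbel, axis=1)

        # --- center updates (per-coordinate Metropolis, Beta proposal)
        for k in range(K):
            idx = np.flatnonzero(z == k)
            if idx.size == 0:
                pi[k] = rng.uniform(0.01, config.ccf_max, size=S)
                continue
            cur_ll = member_loglik(idx, pi[k])
            for s in range(S):
                u = pi[k, s] / config.ccf_max
                a, b = 1.0 + nu * u, 1.0 + nu * (1.0 - u)
                u_new = float(np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6))
                prop = pi[k].copy()
                prop[s] = u_new * config.ccf_max
                a2, b2 = 1.0 + nu * u_new, 1.0 + nu * (1.0 - u_new)
                new_ll = member_loglik(idx, prop)
                log_acc = (
                    new_ll
                    - cur_ll
                    + stats.beta.logpdf(u, a2, b2)
                    - stats.beta.logpdf(u_new, a, b)
                )
                if np.log(rng.random()) < log_acc:
                    pi[k] = prop
                    cur_ll = new_ll

        if it >= config.burn_in:
            posterior_counts[np.arange(n), z] += 1.0
            # average centers only over iterations where the stick is
            # occupied, so prior refreshes of empty sticks cannot bias them
            occ = np.bincount(z, minlength=K) > 0
            pi_sum[occ] += pi[occ]
            pi_occ += occ
            occupied_trace.append(len(np.unique(z)))
            n_saved += 1

    posterior = posterior_counts / n_saved
    pi_mean = pi_sum / np.maximum(pi_occ, 1.0)[:, None]
    modal = np.argmax(posterior, axis=1)

    # crude convergence diagnostic: occupancy stable across trace halves
    half = len(occupied_trace) // 2
    occ_a = float(np.mean(occupied_trace[:half]))
    occ_b = float(np.mean(occupied_trace[half:]))
    converged = abs(occ_a - occ_b) <= 1.0
    if not converged:
        logger.warning(
            "cluster-occupancy trace drifted (%.1f vs %.1f occupied): results may "
            "not have converged", occ_a, occ_b,
        )

    # --- merge undersized clusters into the nearest retained center, and
    # fold every stick's residual posterior mass onto a retained cluster
    sizes = np.bincount(modal, minlength=K)
    keep = np.flatnonzero(sizes >= config.min_cluster_size)
    if keep.size == 0:
        keep = np.array([int(np.argmax(sizes))])
    remap = {}
    for k in range(K):
        if k in keep:
            remap[k] = k
        elif sizes[k] > 0 or posterior[:, k].sum() > 0:
            d = ((pi_mean[keep] - pi_mean[k]) ** 2).sum(axis=1)
            remap[k] = int(keep[np.argmin(d)])
    modal = np.array([remap[k] for k in modal])
    for src, dst in remap.items():
        if src != dst:
            posterior[:, dst] += posterior[:, src]
            posterior[:, src] = 0.0

    # --- package results, ordered by descending mean center; the reported
    # center is the per-sample binomial MLE over final members
    # (sum alt / sum depth*xi1), which is robust to transient label splits
    final_ks = sorted(np.unique(modal), key=lambda k: -pi_mean[k].mean())
    id_of = {k: f"c{j + 1}" for j, k in enumerate(final_ks)}
    clusters = []
    for k in final_ks:
        idx = np.flatnonzero(modal == k)
        members = [ids[i] for i in idx]
        num = alt[idx].sum(axis=0)
        den = (depth[idx] * f[idx]).sum(axis=0)
        center = np.clip(np.divide(num, np.maximum(den, 1e-12)), 0.0, config.ccf_max)
        clusters.append(
            MutationCluster(
                cluster_id=id_of[k],
                ccf_center={s: float(center[si]) for si, s in enumerate(samples)},
                n_mutations=len(members),
                members=members,
            )
        )
    assignments = pd.DataFrame(
        {"mutation_id": ids, "cluster_id": [id_of[k] for k in modal]}
    )
    post_df = pd.DataFrame(
        posterior[:, final_ks], index=pd.Index(ids, name="mutation_id"),
        columns=[id_of[k] for k in final_ks],
    )
    return ClusteringResult(clusters, assignments, post_df, converged, samples)


def subclonal_fraction_summary(
    clusters: list[MutationCluster],
    assignments: pd.DataFrame | None = None,
    clonal_threshold: float = 0.9,
) -> tuple[float | None, float]:
    """(mean CCF of subclonal mutations, fraction of mutations subclonal).

    The clonal cluster is any cluster whose center is at least
    ``clonal_threshold`` in every sample; if none qualifies all mutations
    are treated as subclonal (a warning is logged). The mean CCF averages
    cluster centers over samples, weighted by cluster size; it is None when
    there are no subclonal mutations.
    """
    clonal = [c for c in clusters if min(c.ccf_center.values()) >= clonal_threshold]
    if not clonal:
        logger.warning("no clonal cluster found (threshold %.2f): treating all as subclonal",
                       clonal_threshold)
    subclonal = [c for c in clusters if c not in clonal]
    total = sum(c.n_mutations for c in clusters)
    n_sub = sum(c.n_mutations for c in subclonal)
    if total == 0:
        raise ValueError("empty clustering")
    if n_sub == 0:
        return None, 0.0
    mean_ccf = sum(c.mean_center() * c.n_mutations for c in subclonal) / n_sub
    return float(mean_ccf), n_sub / total
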