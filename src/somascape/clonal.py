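"""Clonal structure: cellular prevalence estimation and DP mixture clustering.

A somatic variant observed at variant allele fraction ``f`` in a tumour of
purity ``rho``, at a locus of total copy number ``C`` with the mutation on
``m`` copies, implies a cellular prevalence (fraction of tumour cells
carrying it) of::

    phi = f * (rho * C + (1 - rho) * 2) / (rho * m)

Prevalences are clustered with a Dirichlet-process binomial mixture: each
cluster has a latent prevalence ``phi`` in [0, 1] (uniform base measure), and
an observation's alt-read count is Binomial(depth, phi * c_i) where
``c_i = rho * m / (rho * C_i + (1 - rho) * 2)`` converts prevalence to
expected allele fraction at that locus.  Inference is collapsed Gibbs
sampling with auxiliary components (Neal's algorithm 8), a Gamma(1, 1) prior
on the concentration resampled by the Escobar-West auxiliary-variable move,
and cluster prevalences resampled on a discrete grid.  The reported
clustering is the posterior sample minimizing Binder loss against the
pairwise co-clustering matrix; the cluster count is the number of non-empty
clusters in that partition.

A deterministic fallback (:func:`bin_prevalences`) bins point-estimate
prevalences at fixed width and merges adjacent occupied bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variants import SomaticVariant

__all__ = [
    "PrevalenceObservation",
    "ClonalCluster",
    "estimate_prevalence",
    "select_variants",
    "DirichletProcessBinomialMixture",
    "cluster_prevalences",
    "bin_prevalences",
    "sensitivity_over_dna_index",
]


@dataclass(frozen=True)
class PrevalenceObservation:
    """One variant's read counts, local copy number and prevalence estimate."""

    key: tuple
    alt_reads: int
    depth: int
    total_cn: int
    purity: float
    multiplicity: int = 1
    prevalence: float = field(default=float("nan"))
    clamped: bool = False

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth

    @property
    def vaf_coefficient(self) -> float:
        """Expected VAF per unit prevalence at this locus."""
        return (self.purity * self.multiplicity
                / (self.purity * self.total_cn + (1 - self.purity) * 2))


def estimate_prevalence(
    key: tuple,
    alt_reads: int,
    depth: int,
    total_cn: int,
    purity: float,
    multiplicity: int = 1,
) -> PrevalenceObservation:
    """Point-estimate cellular prevalence from read counts, CN and purity.

    Estimates above 1 (sampling noise, CN mis-specification) are clamped to
    [0, 1] with ``clamped=True``.  A locus with total copy number 0 cannot
    carry an observable mutation and raises; callers exclude such variants
    with a log entry.
    """
    if depth <= 0:
        raise ValueError(f"{key}: depth must be > 0")
    if not 0 < purity <= 1:
        raise ValueError(f"{key}: purity {purity} outside (0, 1]")
    if total_cn < 1:
        raise ValueError(f"{key}: total_cn {total_cn} < 1; variant not observable")
    if multiplicity < 1:
        raise ValueError(f"{key}: multiplicity must be >= 1")
    vaf = alt_reads / depth
    raw = vaf * (purity * total_cn + (1 - purity) * 2) / (purity * multiplicity)
    clamped = not 0.0 <= raw <= 1.0
    return PrevalenceObservation(
        key=key, alt_reads=alt_reads, depth=depth, total_cn=total_cn,
        purity=purity, multiplicity=multiplicity,
        prevalence=float(min(max(raw, 0.0), 1.0)), clamped=clamped,
    )


def observations_from_variants(
    variants: Sequence[SomaticVariant],
    segments: Sequence,
    purity: float,
    multiplicity: int = 1,
) -> tuple[list[PrevalenceObservation], list[tuple]]:
    """Build prevalence observations, reading total CN from segment overlap.

    Returns ``(observations, excluded_keys)``; variants at CN-0 loci or with
    missing read counts are excluded and their keys returned for logging.
    """
    by_chrom: dict[str, list] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    obs, excluded = [], []
    for v in variants:
        if v.depth in (None, 0) or v.alt_reads is None:
            excluded.append(v.key)
            continue
        cn = 2
        for s in by_chrom.get(v.chrom, ()):
            if s.start <= v.pos <= s.end:
                cn = s.total_cn
                break
        if cn < 1:
            excluded.append(v.key)
            continue
        obs.append(estimate_prevalence(v.key, v.alt_reads, v.depth, cn, purity,
                                       multiplicity))
    return obs, excluded


def select_variants(
    candidates: Sequence[SomaticVariant],
    all_snvs: Sequence[SomaticVariant],
    n_random: int = 50,
    seed: int | None = None,
) -> list[SomaticVariant]:
    """Candidate driver mutations plus ``n_random`` random genome-wide SNVs.

    The random draw is uniform without replacement from ``all_snvs``
    excluding the candidates, deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cand_keys = {v.key for v in candidates}
    pool = [v for v in all_snvs if v.key not in cand_keys]
    k = min(n_random, len(pool))
    extra = []
    if k > 0:
        idx = rng.choice(len(pool), size=k, replace=False)
        extra = [pool[i] for i in sorted(idx)]
    return list(candidates) + extra


@dataclass
class ClonalCluster:
    """A recovered sub-clone: cellular prevalence and member variants."""

    cluster_id: int
    prevalence: float
    members: list[tuple]


class DirichletProcessBinomialMixture:
    """DP binomial mixture over cellular prevalences, fit by Gibbs sampling.

    Parameters
    ----------
    n_iterations, burn_in
        Total Gibbs sweeps and discarded initial sweeps.
    seed
        Mandatory random seed for the sampler.
    grid_size
        Resolution of the discrete prevalence grid used for cluster-parameter
        updates (uniform base measure on [0, 1]).
    aux_m
        Number of auxiliary empty components per assignment step.
    thin
        Keep every ``thin``-th post-burn-in partition for the point estimate.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : per-observation cluster labels of the reported partition
    cluster_prevalences_ : posterior-mean prevalence per reported cluster
    n_clusters_ : number of non-empty clusters in the reported partition
    trace_n_clusters_ : cluster count per sweep (convergence diagnostic)
    alpha_trace_ : sampled concentration parameter per sweep
    """

    def __init__(
        self,
        n_iterations: int = 5_000,
        burn_in: int = 1_000,
        seed: int | None = None,
        grid_size: int = 101,
        aux_m: int = 3,
        thin: int = 10,
    ) -> None:
        if seed is None:
            raise ValueError("a seed is mandatory for the Gibbs sampler")
        if burn_in >= n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.seed = seed
        self.grid_size = grid_size
        self.aux_m = aux_m
        self.thin = thin

    # -- internal -----------------------------------------------------------
    @staticmethod
    def _clamp(p: np.ndarray) -> np.ndarray:
        return np.clip(p, 1e-9, 1 - 1e-9)

    def _loglik(self, i: int, phis: np.ndarray) -> np.ndarray:
        """Log binomial likelihood of observation ``i`` at prevalences ``phis``."""
        p = self._clamp(phis * self._c[i])
        return self._a[i] * np.log(p) + (self._d[i] - self._a[i]) * np.log1p(-p)

    def _grid_loglik(self, members: np.ndarray) -> np.ndarray:
        """Posterior log density of a cluster's prevalence on the grid."""
        p = self._clamp(np.outer(self._grid, self._c[members]))  # G x n
        ll = (self._a[members] * np.log(p)
              + (self._d[members] - self._a[members]) * np.log1p(-p))
        return ll.sum(axis=1)

    def _sample_grid(self, logw: np.ndarray, rng: np.random.Generator) -> float:
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return float(rng.choice(self._grid, p=w))

    # -- fitting ------------------------------------------------------------
    def fit(self, observations: Sequence[PrevalenceObservation]
            ) -> "DirichletProcessBinomialMixture":
        obs = list(observations)
        if not obs:
            raise ValueError("at least one observation is required")
        n = len(obs)
        rng = np.random.default_rng(self.seed)
        self._a = np.array([o.alt_reads for o in obs], dtype=float)
        self._d = np.array([o.depth for o in obs], dtype=float)
        self._c = np.array([o.vaf_coefficient for o in obs], dtype=float)
        self._grid = np.linspace(0.0, 1.0, self.grid_size)

        # init: everyone in one cluster at the median point-estimate prevalence
        labels = np.zeros(n, dtype=int)
        phis: dict[int, float] = {0: float(np.median([o.prevalence for o in obs]))}
        next_label = 1
        alpha = 1.0

        kept_partitions: list[np.ndarray] = []
        trace_k: list[int] = []
        alpha_trace: list[float] = []

        for sweep in range(self.n_iterations):
            # (a) reassign each observation (Neal algorithm 8)
            for i in range(n):
                old = labels[i]
                labels[i] = -1
                counts: dict[int, int] = {}
                for lab in labels:
                    if lab >= 0:
                        counts[lab] = counts.get(lab, 0) + 1
                if old not in counts:
                    phis.pop(old, None)
                existing = sorted(counts)
                aux_phis = rng.uniform(0.0, 1.0, size=self.aux_m)
                cand_phis = np.array([phis[k] for k in existing] + list(aux_phis))
                logw = self._loglik(i, cand_phis)
                logw[: len(existing)] += np.log([counts[k] for k in existing])
                logw[len(existing):] += np.log(alpha / self.aux_m)
                w = np.exp(logw - logw.max())
                w /= w.sum()
                choice = int(rng.choice(len(cand_phis), p=w))
                if choice < len(existing):
                    labels[i] = existing[choice]
                else:
                    labels[i] = next_label
                    phis[next_label] = float(cand_phis[choice])
                    next_label += 1

            # (b) resample cluster prevalences on the grid
            for k in sorted(set(labels)):
                members = np.flatnonzero(labels == k)
                phis[k] = self._sample_grid(self._grid_loglik(members), rng)

            # (c) concentration update (Escobar & West 1995), Gamma(1,1) prior
            k_occ = len(set(labels))
            eta = rng.beta(alpha + 1.0, n)
            a0, b0 = 1.0, 1.0
            odds = (a0 + k_occ - 1) / (n * (b0 - np.log(eta)))
            pi_eta = odds / (1.0 + odds)
            if rng.uniform() < pi_eta:
                alpha = rng.gamma(a0 + k_occ, 1.0 / (b0 - np.log(eta)))
            else:
                alpha = rng.gamma(a0 + k_occ - 1, 1.0 / (b0 - np.log(eta)))

            trace_k.append(k_occ)
            alpha_trace.append(alpha)
            if sweep >= self.burn_in and (sweep - self.burn_in) % self.thin == 0:
                kept_partitions.append(labels.copy())

        self.trace_n_clusters_ = np.array(trace_k)
        self.alpha_trace_ = np.array(alpha_trace)

        # (d) point-estimate partition: minimize Binder loss against the
        # pairwise posterior co-clustering matrix, over the kept samples
        psi = np.zeros((n, n))
        for part in kept_partitions:
            psi += part[:, None] == part[None, :]
        psi /= len(kept_partitions)
        best, best_loss = None, np.inf
        for part in kept_partitions:
            eq = part[:, None] == part[None, :]
            loss = float(((eq - psi) ** 2).sum())
            if loss < best_loss:
                best, best_loss = part, loss
        self.coclustering_ = psi

        # relabel 0..K-1 in order of appearance, recompute posterior-mean phi
        remap: dict[int, int] = {}
        final = np.empty(n, dtype=int)
        for i, lab in enumerate(best):
            final[i] = remap.setdefault(lab, len(remap))
        self.labels_ = final
        self.n_clusters_ = len(remap)
        prevs = []
        for k in range(self.n_clusters_):
            members = np.flatnonzero(final == k)
            logw = self._grid_loglik(members)
            w = np.exp(logw - logw.max())
            w /= w.sum()
            prevs.append(float(w @ self._grid))
        self.cluster_prevalences_ = np.array(prevs)
        self._obs = obs
        return self

    def clusters(self) -> list[ClonalCluster]:
        """The reported partition as :class:`ClonalCluster` records."""
        out = []
        for k in range(self.n_clusters_):
            members = [self._obs[i].key for i in np.flatnonzero(self.labels_ == k)]
            out.append(ClonalCluster(cluster_id=k,
                                     prevalence=float(self.cluster_prevalences_[k]),
                                     members=members))
        return out


def cluster_prevalences(
    observations: Sequence[PrevalenceObservation],
    n_iterations: int = 5_000,
    burn_in: int = 1_000,
    seed: int | None = None,
) -> list[ClonalCluster]:
    """Convenience wrapper: fit the DP mixture and return its clusters."""
    model = DirichletProcessBinomialMixture(
        n_iterations=n_iterations, burn_in=burn_in, seed=seed
    )
    return model.fit(observations).clusters()


def bin_prevalences(
    observations: Sequence[PrevalenceObservation], width: float = 0.1
) -> list[ClonalCluster]:
    """Deterministic fallback: bin prevalences, merge adjacent occupied bins.

    Point-estimate prevalences are histogrammed at fixed ``width``; runs of
    adjacent occupied bins form one cluster whose prevalence is the mean of
    its members.  No randomness; suitable for fast, reproducible checks.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    n_bins = int(np.ceil(1.0 / width))
    binned: dict[int, list[int]] = {}
    for i, o in enumerate(observations):
        b = min(int(o.prevalence / width), n_bins - 1)
        binned.setdefault(b, []).append(i)
    clusters: list[list[int]] = []
    prev_bin = None
    for b in sorted(binned):
        if prev_bin is not None and b == prev_bin + 1:
            clusters[-1].extend(binned[b])
        else:
            clusters.append(list(binned[b]))
        prev_bin = b
    out = []
    for k, members in enumerate(clusters):
        prev = float(np.mean([observations[i].prevalence for i in members]))
        out.append(ClonalCluster(
            cluster_id=k, prevalence=prev,
            members=[observations[i].key for i in members],
        ))
    return out


def sensitivity_over_dna_index(
    observations: Sequence[PrevalenceObservation],
    dna_index_candidates: Sequence[float],
    seed: int | None = None,
    use_gibbs: bool = False,
    **gibbs_kwargs,
) -> dict:
    """Re-cluster under alternative DNA-index (ploidy) models.

    Each candidate DNA index rescales every locus's total copy number by
    ``dna_index / reference`` (reference = first candidate), mimicking the
    alternative genome-size solutions of a copy-number model.  Returns one
    clustering per candidate plus whether the cluster counts agree within
    +/- 1 (``qualitative_agreement``).  Candidates implying degenerate
    effective purity (< 0.05) are flagged unreliable.
    """
    if len(dna_index_candidates) == 0:
        raise ValueError("no DNA index candidates")
    ref = dna_index_candidates[0]
    results = []
    for di in dna_index_candidates:
        scale = di / ref
        rescaled = []
        unreliable = False
        for o in observations:
            cn = max(1, int(round(o.total_cn * scale)))
            if o.purity < 0.05:
                unreliable = True
            rescaled.append(estimate_prevalence(
                o.key, o.alt_reads, o.depth, cn, o.purity, o.multiplicity
            ))
        if any(r.clamped for r in rescaled) and sum(
                r.clamped for r in rescaled) > len(rescaled) / 2:
            unreliable = True
        if use_gibbs:
            clusters = cluster_prevalences(rescaled, seed=seed, **gibbs_kwargs)
        else:
            clusters = bin_prevalences(rescaled)
        results.append({
            "dna_index": di,
            "n_clusters": len(clusters),
            "clusters": clusters,
            "unreliable": unreliable,
        })
    counts = [r["n_clusters"] for r in results]
    agreement = max(counts) - min(counts) <= 1
    return {"results": results, "qualitative_agreement": agreement}
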