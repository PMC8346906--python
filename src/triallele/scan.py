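"""Two-filter sliding-window scan for triallelic population structure.

The genome is tiled with overlapping windows (2,500 bp, 500-bp step by
default).  Each window's population x SNP allele-frequency matrix is
analysed two ways:

* **PCA filter** — percent variance explained (PVE) of the first two
  principal components across populations; windows with PC2 >= 20 and
  PC1 + PC2 >= 75 show variation along multiple axes, the signature of
  more than two population clusters.  Passing windows within 10 kb are
  merged.
* **k-means filter** — populations are clustered at k = 2 and k = 3 and
  the sum ``s`` of average intracluster genetic distances computed; a
  window passes if ``s`` drops by > 65% going from one cluster to three
  AND by > 20% going from two clusters to three.  Passing windows within
  5 kb are merged.

The final call set is the base-pair intersection of the two merged
tracks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import GenomicInterval, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class ScanParams:
    window_bp: int = 2500
    step_bp: int = 500
    pc2_min: float = 20.0
    pc12_min: float = 75.0
    k3_min: float = 0.65
    transition_min: float = 0.20
    merge_pca_bp: int = 10_000
    merge_kmeans_bp: int = 5_000
    min_sites: int = 3
    restarts: int = 20
    distance: str = "rms"  # per-site RMS difference; "manhattan" = mean |diff|
    seed: int = 0


@dataclass
class WindowPcaResult:
    window: GenomicInterval
    pve: np.ndarray  # percent variance explained per component, sums to 100
    n_sites: int


@dataclass
class ClusterGainResult:
    window: GenomicInterval
    s1: float
    s2: float
    s3: float
    n_sites: int

    @property
    def reduction_k3(self) -> float:
        return 1.0 - self.s3 / self.s1 if self.s1 > 0 else 0.0

    @property
    def transition_gain(self) -> float:
        return 1.0 - self.s3 / self.s2 if self.s2 > 0 else 0.0


@dataclass
class TriallelicRegion:
    interval: GenomicInterval
    passed_pca: bool = True
    passed_kmeans: bool = True


# ------------------------------------------------------------------ windows

def iter_windows(sites: pd.DataFrame, window_bp: int = 2500,
                 step_bp: int = 500):
    """Yield (interval, site index array) tiling each chromosome.

    Windows start at 0 and advance by ``step_bp`` until the window start
    passes the chromosome's last SNP.  Site filtering (min_sites) is the
    caller's concern.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    pos = sites["pos"].to_numpy()
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cpos = pos[idx]
        last = int(cpos.max())
        start = 0
        while start <= last:
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, start + window_bp, side="left")
            yield (GenomicInterval(chrom, start, start + window_bp),
                   idx[lo:hi])
            start += step_bp


# ------------------------------------------------------------------ PCA

def window_pca(freqs: np.ndarray) -> WindowPcaResult | None:
    """PVE spectrum of a site x sample frequency matrix.

    Samples are the observations, sites the variables; the matrix is
    centred per site and the PVE taken from the squared singular values.
    Missing frequencies are mean-imputed per site.  Returns None for
    degenerate (constant) windows.
    """
    X = np.asarray(freqs, dtype=float).T  # samples x sites
    if X.shape[0] < 2 or X.shape[1] < 1:
        return None
    X = _impute_sites(X)
    X = X - X.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(X, compute_uv=False)
    total = float(np.sum(sv**2))
    if total <= 1e-12:
        return None
    pve = 100.0 * sv**2 / total
    return WindowPcaResult(window=None, pve=pve, n_sites=freqs.shape[0])


def _impute_sites(X: np.ndarray) -> np.ndarray:
    """Mean-impute missing values per site (column) of a samples x sites matrix."""
    if not np.isnan(X).any():
        return X
    X = X.copy()
    mean = np.nanmean(np.where(np.isnan(X).all(axis=0), 0.0, X), axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = mean[idx[1]]
    return X


def pca_filter(result: WindowPcaResult, pc2_min: float = 20.0,
               pc12_min: float = 75.0) -> bool:
    """True iff PC2 >= pc2_min and PC1 + PC2 >= pc12_min (inclusive)."""
    pc1 = result.pve[0] if len(result.pve) > 0 else 0.0
    pc2 = result.pve[1] if len(result.pve) > 1 else 0.0
    return bool(pc2 >= pc2_min and pc1 + pc2 >= pc12_min)


# ------------------------------------------------------------------ k-means

def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    n_sites = X.shape[1]
    if metric == "rms":
        d = pdist(X, metric="euclidean") / np.sqrt(n_sites)
    elif metric == "manhattan":
        d = pdist(X, metric="cityblock") / n_sites
    else:
        raise ValueError(f"unknown distance metric {metric!r}")
    return squareform(d)


def _intracluster_sum(dmat: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of the mean pairwise distance within the cluster.

    Singleton clusters contribute 0.
    """
    s = 0.0
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        m = len(members)
        if m < 2:
            continue
        sub = dmat[np.ix_(members, members)]
        s += sub[np.triu_indices(m, k=1)].sum() / (m * (m - 1) / 2)
    return float(s)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 100) -> np.ndarray:
    """One seeded run of Lloyd's algorithm with k-means++ initialisation."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    for j in range(1, k):
        d2 = np.min(((X[:, None, :] - centers[None, :j, :])**2).sum(-1), axis=1)
        tot = d2.sum()
        if tot <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / tot)]
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :])**2).sum(-1)
        new = d2.argmin(axis=1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                centers[j] = X[d2.min(axis=1).argmax()]
    return labels


def _relocation_refine(dmat: np.ndarray, labels: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Best-improvement single-point relocation local search on s.

    Moves one sample to a different cluster whenever that lowers the
    intracluster-distance sum, until no move helps.  Keeps exactly k
    non-empty clusters.
    """
    labels = labels.copy()
    best = _intracluster_sum(dmat, labels)
    n = len(labels)
    improved = True
    while improved:
        improved = False
        best_move, best_s = None, best
        for i in range(n):
            src = labels[i]
            if np.sum(labels == src) == 1:
                continue  # would empty a cluster
            for dst in range(k):
                if dst == src:
                    continue
                labels[i] = dst
                s = _intracluster_sum(dmat, labels)
                if s < best_s - 1e-12:
                    best_s, best_move = s, (i, dst)
            labels[i] = src
        if best_move is not None:
            labels[best_move[0]] = best_move[1]
            best = best_s
            improved = True
    return labels, best


def _exhaustive_min_s(dmat: np.ndarray, k: int) -> float:
    """Exact minimum s over all partitions into exactly k non-empty clusters."""
    n = dmat.shape[0]
    best = np.inf

    def grow(i: int, labels: list[int], used: int):
        nonlocal best
        if i == n:
            if used == k:
                best = min(best, _intracluster_sum(dmat, np.array(labels)))
            return
        for c in range(min(used + 1, k)):
            grow(i + 1, labels + [c], max(used, c + 1))

    grow(0, [], 0)
    return float(best)


#: largest sample count for which the partition minimum is found exactly
EXACT_PARTITION_MAX_N = 9


def _best_partition_s(X: np.ndarray, dmat: np.ndarray, k: int,
                      restarts: int, seed: int) -> float:
    """Minimum intracluster-distance sum s over k-partitions.

    Exact enumeration for small sample counts (the optimum often isolates
    outliers into singleton clusters, which contribute 0 to s and are not
    reachable by centroid-based moves); for larger n, seeded k-means
    restarts scored by s (not inertia), the best labelling polished by
    single-point relocation.  Ties break to the lowest s and then the
    lowest restart index by construction of the running minimum.
    """
    if X.shape[0] <= EXACT_PARTITION_MAX_N:
        return _exhaustive_min_s(dmat, k)
    best_s, best_labels = np.inf, None
    for r in range(restarts):
        rng = np.random.default_rng((seed, r))
        labels = _lloyd(X, k, rng)
        if len(np.unique(labels)) < k:
            continue
        s = _intracluster_sum(dmat, labels)
        if s < best_s - 1e-12:
            best_s, best_labels = s, labels
    if best_labels is None:  # all restarts collapsed (duplicate points)
        return 0.0
    _, best_s = _relocation_refine(dmat, best_labels, k)
    return best_s


def cluster_gain(freqs: np.ndarray, distance: str = "rms",
                 restarts: int = 20, seed: int = 0) -> ClusterGainResult:
    """Intracluster-distance sums s1, s2, s3 at k = 1, 2, 3.

    ``freqs`` is site x sample; distances are computed between sample
    frequency vectors.  s1 places all samples in one cluster.
    """
    X = np.asarray(freqs, dtype=float).T
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"cluster_gain needs >= 3 samples, got {n}")
    X = _impute_sites(X)
    dmat = _distance_matrix(X, distance)
    s1 = _intracluster_sum(dmat, np.zeros(n, dtype=int))
    s2 = _best_partition_s(X, dmat, 2, restarts, seed)
    s3 = _best_partition_s(X, dmat, 3, restarts, seed)
    return ClusterGainResult(window=None, s1=s1, s2=min(s1, s2),
                             s3=min(s1, s2, s3), n_sites=freqs.shape[0])


def exhaustive_partition_s(freqs: np.ndarray, k: int,
                           distance: str = "rms") -> float:
    """Exact minimum s over all partitions into exactly k non-empty clusters.

    Exponential; intended for small n (<= 10) cross-checks.
    """
    X = np.asarray(freqs, dtype=float).T
    dmat = _distance_matrix(_impute_sites(X), distance)
    return _exhaustive_min_s(dmat, k)


def kmeans_filter(result: ClusterGainResult, k3_min: float = 0.65,
                  transition_min: float = 0.20) -> bool:
    """True iff reduction_k3 > k3_min and transition_gain > transition_min (strict)."""
    if result.s1 <= 0:
        return False  # no variation
    return (result.reduction_k3 > k3_min
            and result.transition_gain > transition_min)


# ------------------------------------------------------------------ intervals

def merge_within(intervals: list[GenomicInterval],
                 gap_bp: int) -> list[GenomicInterval]:
    """Union intervals whose gap on the same chromosome is <= gap_bp."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and \
                iv.start - out[-1].end <= gap_bp:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_tracks(pca_regions: list[GenomicInterval],
                     kmeans_regions: list[GenomicInterval]
                     ) -> list[TriallelicRegion]:
    """Base-pair intersection of two sorted, merged interval sets."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in kmeans_regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    calls = []
    for a in sorted(pca_regions, key=lambda v: (v.chrom, v.start)):
        for b in by_chrom.get(a.chrom, ()):
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if hi > lo:
                calls.append(TriallelicRegion(GenomicInterval(a.chrom, lo, hi)))
    calls.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return calls


# ------------------------------------------------------------------ driver

@dataclass
class ScanResult:
    calls: list[TriallelicRegion]
    pca_track: list[GenomicInterval]
    kmeans_track: list[GenomicInterval]
    diagnostics: pd.DataFrame  # one row per analysed window

    @property
    def call_intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.calls]


def scan(table: GenotypeTable, params: ScanParams | None = None) -> ScanResult:
    """Run the full two-filter scan over a genotype table."""
    params = params or ScanParams()
    pca_hits: list[GenomicInterval] = []
    km_hits: list[GenomicInterval] = []
    diag_rows = []
    for window, idx in iter_windows(table.sites, params.window_bp,
                                    params.step_bp):
        if len(idx) < params.min_sites:
            continue
        freqs = table.values[idx]
        pca = window_pca(freqs)
        if pca is None:
            logger.debug("skipping degenerate window %s", window)
            continue
        pca_pass = pca_filter(pca, params.pc2_min, params.pc12_min)
        gain = cluster_gain(freqs, params.distance, params.restarts,
                            params.seed)
        km_pass = kmeans_filter(gain, params.k3_min, params.transition_min)
        if pca_pass:
            pca_hits.append(window)
        if km_pass:
            km_hits.append(window)
        diag_rows.append({
            "chrom": window.chrom, "start": window.start, "end": window.end,
            "n_sites": len(idx),
            "pc1": pca.pve[0],
            "pc2": pca.pve[1] if len(pca.pve) > 1 else 0.0,
            "s1": gain.s1, "s2": gain.s2, "s3": gain.s3,
            "reduction_k3": gain.reduction_k3,
            "transition_gain": gain.transition_gain,
            "passed_pca": pca_pass, "passed_kmeans": km_pass,
        })
    pca_track = merge_within(pca_hits, params.merge_pca_bp)
    kmeans_track = merge_within(km_hits, params.merge_kmeans_bp)
    calls = intersect_tracks(pca_track, kmeans_track)
    diagnostics = pd.DataFrame(diag_rows)
    return ScanResult(calls, pca_track, kmeans_track, diagnostics)
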