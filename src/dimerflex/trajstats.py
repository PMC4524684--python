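"""Ensemble statistics for characterizing cooperativity of domain motions.

Principal component analysis of trajectory coordinates (essential
dynamics), projections of other trajectories onto the PC basis,
PC-subspace comparison through generalized dot products, cosine contents,
windowed Pearson correlations between paired measure series, and
hierarchical frame clustering.

PCA convention: every frame is first least-squares superposed on the
first frame over an *alignment* selection (e.g. the C-alphas of the
stable core domains); the covariance is then accumulated over the
Cartesian coordinates of an *analysis* selection (e.g. the mobile
domains), mass-unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import biotite.structure as struc
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .structures import Structure, SelectionSpec

__all__ = [
    "PCAResult",
    "CorrelationSeries",
    "pca",
    "project",
    "generalized_dot",
    "subspace_coverage",
    "cosine_content",
    "windowed_pearson",
    "cluster_frames",
]


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of an aligned trajectory."""

    mean: np.ndarray               # (3m,) mean coordinates, analysis sel.
    eigenvectors: np.ndarray       # (3m, k) orthonormal, descending variance
    eigenvalues: np.ndarray        # (k,) >= 0
    align_indices: np.ndarray
    analyze_indices: np.ndarray
    reference: Structure           # frame the alignment is anchored to

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def to_csv(self, path: str | Path) -> None:
        k = self.eigenvectors.shape[1]
        df = pd.DataFrame(self.eigenvectors,
                          columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "coord", np.arange(len(self.mean)))
        df.insert(1, "mean", self.mean)
        df.to_csv(path, index=False)
        pd.DataFrame({"PC": np.arange(1, k + 1),
                      "eigenvalue": self.eigenvalues,
                      "variance_fraction": self.variance_fractions}) \
          .to_csv(str(path) + ".eigenvalues.csv", index=False)


@dataclass
class CorrelationSeries:
    """Windowed Pearson correlations between two measure series."""

    window: int
    stride: int
    starts: np.ndarray
    values: np.ndarray             # per-window R, NaN where undefined
    overall: float

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def std(self) -> float:
        return float(np.nanstd(self.values, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts, "R": self.values})


def _aligned_coords(frames: Structure, align_indices: np.ndarray,
                    analyze_indices: np.ndarray,
                    reference: Structure | None = None) -> np.ndarray:
    """(n_frames, 3m) analysis coordinates after core alignment."""
    ref = (reference or frames).stack[0]
    fixed = ref[align_indices.tolist()]
    rows = []
    for f in range(frames.n_models):
        frame = frames.stack[f]
        mobile = frame[align_indices.tolist()]
        _, transform = struc.superimpose(fixed, mobile)
        moved = transform.apply(frame)
        rows.append(np.asarray(moved.coord, dtype=float)[analyze_indices]
                    .ravel())
    return np.array(rows)


def pca(frames: Structure, align_selection: SelectionSpec | None = None,
        analyze_selection: SelectionSpec | None = None,
        n_components: int | None = None) -> PCAResult:
    """Essential dynamics of a trajectory.

    Raises on fewer than two frames or an all-identical trajectory.
    """
    if frames.n_models < 2:
        raise ValueError("PCA needs at least two frames")
    align_sel = align_selection or SelectionSpec(atom_names=("CA",))
    analyze_sel = analyze_selection or SelectionSpec(atom_names=("CA",))
    align_idx = align_sel.resolve(frames)
    analyze_idx = analyze_sel.resolve(frames)
    x = _aligned_coords(frames, align_idx, analyze_idx)
    mean = x.mean(axis=0)
    centered = x - mean
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("degenerate trajectory: all frames identical")
    cov = centered.T @ centered / (len(x) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    if n_components is not None:
        vals = vals[:n_components]
        vecs = vecs[:, :n_components]
    return PCAResult(mean=mean, eigenvectors=vecs, eigenvalues=vals,
                     align_indices=align_idx, analyze_indices=analyze_idx,
                     reference=frames.model(0))


def project(frames: Structure, result: PCAResult, k: int = 1) -> np.ndarray:
    """Per-frame scalar projection onto PC ``k`` (1-based).

    Accepts any trajectory sharing the PCA's atom identities -- including
    geometric-simulation trajectories projected onto MD-derived PCs.
    """
    if not 1 <= k <= result.eigenvectors.shape[1]:
        raise IndexError(f"PC {k} out of range")
    x = _aligned_coords(frames, result.align_indices,
                        result.analyze_indices, reference=result.reference)
    return (x - result.mean) @ result.eigenvectors[:, k - 1]


def generalized_dot(v1: np.ndarray, v2: np.ndarray) -> float:
    """Plain inner product of two PC eigenvectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("eigenvector length mismatch")
    return float(v1 @ v2)


def subspace_coverage(v: np.ndarray, basis: np.ndarray) -> float:
    """Sum of squared generalized dots of ``v`` against a vector set.

    1.0 means ``v`` lies entirely in the span of the set -- e.g. a PC from
    one trajectory window against PC1/PC2 of another window that are
    merely a rotated form of the same basis.
    """
    basis = np.atleast_2d(basis)
    return float(sum(generalized_dot(v, b) ** 2 for b in basis))


def cosine_content(series: np.ndarray, i: int = 1) -> float:
    """Cosine content of a projection series against cos(i*pi*t/T).

    The standard essential-dynamics diagnostic: the squared normalized
    inner product of the (mean-centred) series with the ``i``-th
    half-period cosine over the sampling interval.  Values near 1 signal
    random-diffusion-like sampling; a constant series returns 0.
    """
    p = np.asarray(series, dtype=float)
    if len(p) < 4:
        raise ValueError("series too short for a cosine content")
    p = p - p.mean()
    if not np.any(np.abs(p) > 1e-300):
        return 0.0
    t = np.arange(len(p))
    c = np.cos(i * np.pi * t / (len(p) - 1))
    c = c - c.mean()
    num = (c @ p) ** 2
    den = (c @ c) * (p @ p)
    return float(num / den) if den > 0 else 0.0


def windowed_pearson(x: np.ndarray, y: np.ndarray, window: int,
                     stride: int | None = None,
                     burn_in: int = 0) -> CorrelationSeries:
    """Pearson R between two series over moving windows.

    Uses the sample (n-1) convention; zero-variance windows are recorded
    as NaN (missing), never as 0.  ``burn_in`` frames are dropped from the
    front of both series before windowing (equilibration).
    """
    x = np.asarray(x, dtype=float)[burn_in:]
    y = np.asarray(y, dtype=float)[burn_in:]
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    if len(x) < window:
        raise ValueError("series shorter than the window")
    stride = stride or window
    starts = np.arange(0, len(x) - window + 1, stride)
    values = np.empty(len(starts))
    for n, s in enumerate(starts):
        xs = x[s: s + window]
        ys = y[s: s + window]
        sx, sy = xs.std(ddof=1), ys.std(ddof=1)
        if sx < 1e-15 or sy < 1e-15:
            values[n] = np.nan
        else:
            values[n] = float(np.corrcoef(xs, ys)[0, 1])
    if x.std(ddof=1) < 1e-15 or y.std(ddof=1) < 1e-15:
        overall = np.nan
    else:
        overall = float(np.corrcoef(x, y)[0, 1])
    return CorrelationSeries(window=window, stride=stride, starts=starts,
                             values=values, overall=overall)


def _pairwise_rmsd(frames: Structure, fit_indices: np.ndarray,
                   rmsd_indices: np.ndarray) -> np.ndarray:
    n = frames.n_models
    coords = np.asarray(frames.stack.coord, dtype=float)
    dist = np.zeros((n, n))
    for i in range(n):
        fixed = frames.stack[i][fit_indices.tolist()]
        for j in range(i + 1, n):
            mobile = frames.stack[j][fit_indices.tolist()]
            _, transform = struc.superimpose(fixed, mobile)
            moved = transform.apply(frames.stack[j])
            diff = (np.asarray(moved.coord, dtype=float)[rmsd_indices]
                    - coords[i][rmsd_indices])
            dist[i, j] = dist[j, i] = np.sqrt((diff ** 2).sum(axis=1)
                                              .mean())
    return dist


def cluster_frames(frames: Structure, n_clusters: int,
                   fit_selection: SelectionSpec | None = None,
                   cluster_selection: SelectionSpec | None = None):
    """Average-linkage agglomerative clustering of trajectory frames.

    Frames are pairwise-superposed on ``fit_selection`` and compared by
    C-alpha RMSD over ``cluster_selection`` (fit on the stable core,
    cluster on the moving domain).  Returns ``(medoid_frame_indices,
    assignments, mean_distance_to_medoid)``; the centroid of a cluster is
    its medoid.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if frames.n_models < n_clusters:
        raise ValueError("fewer frames than clusters")
    fit_sel = fit_selection or SelectionSpec(atom_names=("CA",))
    clu_sel = cluster_selection or SelectionSpec(atom_names=("CA",))
    dist = _pairwise_rmsd(frames, fit_sel.resolve(frames),
                          clu_sel.resolve(frames))
    if n_clusters == frames.n_models:
        assignments = np.arange(frames.n_models)
    elif n_clusters == 1:
        assignments = np.zeros(frames.n_models, dtype=int)
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        assignments = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    medoids = []
    mean_dists = []
    for c in range(assignments.max() + 1):
        members = np.where(assignments == c)[0]
        sub = dist[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.sum(axis=1)))]
        medoids.append(int(medoid))
        mean_dists.append(float(dist[medoid, members].mean()))
    return medoids, assignments, np.array(mean_dists)
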