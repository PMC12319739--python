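"""Searchlight representational similarity analysis.

For every gray-matter voxel, a searchlight of exactly ``n_voxels`` (default
10) nearest in-mask voxels within a 10 mm radius is formed.  Within each
searchlight, event regression coefficients are spatially prewhitened with a
shrinkage estimate of the residual covariance (multivariate noise
normalization), pairwise squared Euclidean distances between the whitened
patterns -- equivalent to Mahalanobis distances on the raw patterns -- form
the representational dissimilarity matrix (RDM), and the RDM is rank-
correlated (Spearman, optionally partial with respect to a timing
covariate) with a behavioral model RDM built from the temporal scaling
measures.  Subject correlation maps are Fisher-z transformed, smoothed with
a 6 mm FWHM mask-normalized Gaussian kernel, and tested at the group level
with one-sample t statistics and sign-flip max-cluster-mass permutation
inference (cluster-forming threshold p = 0.001, FWER 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = ["Searchlight", "build_searchlights", "shrinkage_covariance",
           "prewhiten", "pairwise_distances", "within_episode_model",
           "between_episode_model", "within_episode_pairs",
           "between_episode_pairs", "model_correlation", "smooth_map",
           "group_cluster_mass", "GroupClusterResult", "subject_rho_map"]


@dataclass
class Searchlight:
    """One searchlight: a center voxel and its member voxel coordinates."""

    center: tuple[int, int, int]
    members: np.ndarray            # (n_voxels, 3) grid coordinates
    member_index: np.ndarray       # indices into the flat in-mask voxel list


def build_searchlights(mask: np.ndarray, n_voxels: int = 10,
                       max_radius_mm: float = 10.0,
                       voxel_size_mm: float = 3.0
                       ) -> tuple[list[Searchlight], list[tuple[int, int, int]]]:
    """Build fixed-size searchlights over an in-mask voxel grid.

    Every in-mask voxel is a candidate center; its searchlight is the
    ``n_voxels`` nearest in-mask voxels (center included) by Euclidean mm
    distance, all within ``max_radius_mm``.  Ties at the cutoff distance are
    broken by lexicographic grid order.  Centers that cannot gather
    ``n_voxels`` members within the radius are skipped and reported.

    Returns (searchlights, skipped_centers).
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] < n_voxels:
        raise ValueError(
            f"mask has {coords.shape[0]} voxels, fewer than n_voxels={n_voxels}")
    mm = coords * float(voxel_size_mm)
    tree = cKDTree(mm)
    searchlights: list[Searchlight] = []
    skipped: list[tuple[int, int, int]] = []
    for ci, center_mm in enumerate(mm):
        idx = tree.query_ball_point(center_mm, r=max_radius_mm + 1e-9)
        if len(idx) < n_voxels:
            skipped.append(tuple(coords[ci]))
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(mm[idx] - center_mm, axis=1)
        # sort by (distance, lexicographic grid order)
        order = np.lexsort((coords[idx, 2], coords[idx, 1],
                            coords[idx, 0], np.round(d, 9)))
        chosen = idx[order[:n_voxels]]
        searchlights.append(Searchlight(
            center=tuple(coords[ci]), members=coords[chosen],
            member_index=chosen))
    return searchlights, skipped


def shrinkage_covariance(residuals: np.ndarray) -> np.ndarray:
    """Residual covariance with analytic shrinkage toward its diagonal.

    Implements the optimal-shrinkage estimator for the off-diagonal entries
    (Ledoit-Wolf/Schafer-Strimmer form with a diagonal target): the
    shrinkage intensity is the ratio of the summed sampling variances of the
    off-diagonal covariances to their summed squares, clipped to [0, 1].
    ``residuals`` is frames x voxels.
    """
    X = np.asarray(residuals, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two residual frames")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    # sampling variance of each covariance entry
    W = np.einsum("ti,tj->tij", Xc, Xc)
    varS = W.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(S[off] ** 2))
    lam = 1.0 if denom == 0 else float(np.clip(np.sum(varS[off]) / denom, 0.0, 1.0))
    S_shrunk = S.copy()
    S_shrunk[off] *= (1.0 - lam)
    return S_shrunk


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, 1e-12 * vals.max())
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def prewhiten(betas: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """Multivariate noise normalization of patterns within one searchlight.

    ``betas`` is conditions x voxels, ``residuals`` frames x voxels (same
    voxels).  Patterns are multiplied by the inverse matrix square root of
    the shrinkage residual covariance, so squared Euclidean distances on the
    output equal Mahalanobis distances on the input.
    """
    S = shrinkage_covariance(residuals)
    return np.asarray(betas, dtype=float) @ _inv_sqrt(S)


def pairwise_distances(patterns: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance for each (i, j) row of ``pairs``."""
    P = np.asarray(patterns, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    diff = P[pairs[:, 0]] - P[pairs[:, 1]]
    return np.einsum("ij,ij->i", diff, diff)


# ---------------------------------------------------------------------------
# model RDMs

def within_episode_pairs(n_episodes: int, n_objects: int = 5) -> np.ndarray:
    """Condition-index pairs for all same-episode object pairs.

    Conditions are ordered episode-major (episode 0 objects 0..4, ...).
    """
    pairs = []
    for e in range(n_episodes):
        base = e * n_objects
        for i in range(n_objects):
            for j in range(i + 1, n_objects):
                pairs.append((base + i, base + j))
    return np.asarray(pairs, dtype=int)


def between_episode_pairs(n_episodes: int) -> np.ndarray:
    """All episode pairs (i < j)."""
    return np.asarray([(i, j) for i in range(n_episodes)
                       for j in range(i + 1, n_episodes)], dtype=int)


def within_episode_model(scaling: np.ndarray, pairs: np.ndarray,
                         n_objects: int = 5, binary: bool = False) -> np.ndarray:
    """Model RDM values for same-episode object pairs.

    Each pair inherits its episode's signed scaling contrast
    ``scaling - 1`` (= Scaling^Exp - Scaling^Compr): patterns are predicted
    more *similar* (lower dissimilarity) when the episode was compressed in
    memory, more dissimilar when expanded.  With ``binary=True`` the
    contrast is the sign only.
    """
    scaling = np.asarray(scaling, dtype=float)
    ep = pairs[:, 0] // n_objects
    contrast = scaling[ep] - 1.0
    return np.sign(contrast) if binary else contrast


def between_episode_model(values: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Model RDM: |v_i - v_j| for a per-episode scaling variable.

    ``values`` is the per-episode measure (e.g. Episode scaling^Exp); larger
    differences in temporal expansion predict more dissimilar episode
    patterns.
    """
    values = np.asarray(values, dtype=float)
    return np.abs(values[pairs[:, 0]] - values[pairs[:, 1]])


# ---------------------------------------------------------------------------
# correlation maps

def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=-1)


def model_correlation(rdms: np.ndarray, model: np.ndarray,
                      covariate: np.ndarray | None = None) -> np.ndarray:
    """Spearman correlation of observed dissimilarities with a model RDM.

    ``rdms`` is (n_searchlights, n_pairs) (a single 1-D RDM is also
    accepted); ``model`` and the optional ``covariate`` are length
    ``n_pairs``.  With a covariate, the partial Spearman correlation is
    computed by residualizing the ranks of both the observed and model
    values on the covariate ranks.  A constant model vector yields NaN.
    """
    rdms = np.atleast_2d(np.asarray(rdms, dtype=float))
    model = np.asarray(model, dtype=float)
    if np.allclose(model, model[0]):
        return np.full(rdms.shape[0], np.nan)
    rx = _rank_rows(rdms)
    rm = stats.rankdata(model)
    if covariate is not None:
        rc = stats.rankdata(np.asarray(covariate, dtype=float))
        rc = rc - rc.mean()
        denom = float(rc @ rc)
        rm = rm - rm.mean()
        rm = rm - (rm @ rc) / denom * rc
        rx = rx - rx.mean(axis=1, keepdims=True)
        rx = rx - ((rx @ rc) / denom)[:, None] * rc[None, :]
    rm = rm - rm.mean()
    rx = rx - rx.mean(axis=1, keepdims=True)
    num = rx @ rm
    den = np.sqrt(np.einsum("ij,ij->i", rx, rx) * float(rm @ rm))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    return rho


def subject_rho_map(betas: np.ndarray, residuals: np.ndarray,
                    searchlights: list[Searchlight], mask_shape,
                    pairs: np.ndarray, model: np.ndarray,
                    covariate: np.ndarray | None = None,
                    fisher_z: bool = True) -> np.ndarray:
    """One subject's searchlight model-correlation map.

    ``betas`` is conditions x in-mask-voxels, ``residuals`` frames x
    in-mask-voxels, both indexed like the searchlight ``member_index``.
    Returns a dense map of shape ``mask_shape`` (NaN outside covered
    centers), Fisher-z transformed by default.
    """
    n_pairs = pairs.shape[0]
    rdms = np.empty((len(searchlights), n_pairs))
    for k, sl in enumerate(searchlights):
        W = prewhiten(betas[:, sl.member_index], residuals[:, sl.member_index])
        rdms[k] = pairwise_distances(W, pairs)
    rho = model_correlation(rdms, model, covariate)
    if fisher_z:
        rho = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    out = np.full(mask_shape, np.nan)
    for k, sl in enumerate(searchlights):
        out[sl.center] = rho[k]
    return out


# ---------------------------------------------------------------------------
# smoothing and group inference

def smooth_map(vol: np.ndarray, mask: np.ndarray, fwhm_mm: float = 6.0,
               voxel_size_mm: float = 3.0) -> np.ndarray:
    """Mask-normalized Gaussian smoothing of a statistic map.

    The kernel is renormalized within the mask (out-of-mask voxels carry no
    weight), preserving the in-mask mean of a constant map.  NaNs inside the
    mask are treated as missing (zero weight).
    """
    mask = np.asarray(mask, dtype=bool)
    sigma = fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * voxel_size_mm)
    data = np.where(mask & np.isfinite(vol), vol, 0.0)
    weight = (mask & np.isfinite(vol)).astype(float)
    num = ndimage.gaussian_filter(data, sigma)
    den = ndimage.gaussian_filter(weight, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mask & (den > 1e-12), num / den, np.nan)
    return out


@dataclass
class GroupClusterResult:
    """Group one-sample t map with max-cluster-mass corrected inference."""

    t_map: np.ndarray
    t_threshold: float
    cluster_labels: np.ndarray
    cluster_masses: np.ndarray
    cluster_p: np.ndarray
    null_max_mass: np.ndarray
    n_permutations: int

    @property
    def significant_clusters(self) -> np.ndarray:
        """Labels of clusters with corrected p <= 0.05."""
        return np.where(self.cluster_p <= 0.05)[0] + 1


def _t_map(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _max_cluster_mass(t: np.ndarray, thresh: float) -> float:
    supra = t > thresh
    if not supra.any():
        return 0.0
    labels, n = ndimage.label(supra, structure=_STRUCT26)
    masses = ndimage.sum_labels(t, labels, index=np.arange(1, n + 1))
    return float(masses.max())


def group_cluster_mass(subject_maps: np.ndarray, mask: np.ndarray,
                       n_perm: int = 1024, cluster_p: float = 0.001,
                       alpha: float = 0.05, seed=None,
                       enumerate_max_n: int = 12) -> GroupClusterResult:
    """Sign-flip max-cluster-mass permutation test of subject maps vs zero.

    ``subject_maps`` is (n_subjects, *grid).  Per voxel, a one-sample t is
    computed; clusters (26-connectivity) are formed above the t value
    corresponding to one-sided ``cluster_p`` (default 0.001); the cluster
    mass is the sum of t over members.  The null is the maximum cluster mass
    over sign-flip permutations -- all 2^n flips when n_subjects <=
    ``enumerate_max_n``, otherwise ``n_perm`` random flips (the identity
    included) -- and corrected cluster p-values are the proportion of null
    masses at least as large.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 5:
        raise ValueError("need at least 5 subjects")
    mask = np.asarray(mask, dtype=bool)
    maps = np.where(np.isfinite(maps) & mask[None], maps, 0.0)
    t_thresh = float(stats.t.isf(cluster_p, n_sub - 1))
    t_obs = np.where(mask, _t_map(maps), 0.0)

    labels, n_clust = ndimage.label(t_obs > t_thresh, structure=_STRUCT26)
    masses = (ndimage.sum_labels(t_obs, labels, index=np.arange(1, n_clust + 1))
              if n_clust else np.array([]))

    flat = maps.reshape(n_sub, -1)
    if n_sub <= enumerate_max_n:
        n_total = 2 ** n_sub
        signs_iter = (np.array([1 if (k >> b) & 1 == 0 else -1
                                for b in range(n_sub)])
                      for k in range(n_total))
        n_used = n_total
    else:
        rng = np.random.default_rng(seed)
        def _rand():
            yield np.ones(n_sub)   # identity flip always in the null
            for _ in range(n_perm - 1):
                yield rng.choice([-1.0, 1.0], size=n_sub)
        signs_iter = _rand()
        n_used = n_perm

    null = np.empty(n_used)
    for i, signs in enumerate(signs_iter):
        t_perm = _t_map(signs[:, None] * flat).reshape(mask.shape)
        null[i] = _max_cluster_mass(np.where(mask, t_perm, 0.0), t_thresh)

    if n_clust:
        p = np.array([(null >= m).mean() for m in masses])
        p = np.maximum(p, 1.0 / n_used)
    else:
        p = np.array([])
    return GroupClusterResult(
        t_map=t_obs, t_threshold=t_thresh, cluster_labels=labels,
        cluster_masses=np.asarray(masses), cluster_p=p,
        null_max_mass=null, n_permutations=n_used)
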