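"""Conformational-landscape construction from inter-Calpha distances.

Pipeline: select a residue subset of the TMD, build the pairwise
Calpha-distance feature matrix over frames, reduce with PCA, cluster the
first two principal components with DBSCAN, and summarize clusters by their
medoid frame (the member minimizing mean pairwise RMSD after optimal rigid
superposition).  The 2-D landscape can be rendered as -RT ln(delta) of the
normalized bin counts, a free-energy-like surface.

Features are raw distances in Angstrom, deliberately unstandardized: the
DBSCAN radius (eps, default 2) is meaningful only in unscaled PC units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .trajectory import MolecularSystem, TrajectoryFrame, resolve_selection

__all__ = [
    "FeatureMatrix",
    "LandscapeModel",
    "select_feature_residues",
    "build_distance_features",
    "fit_pca",
    "project",
    "cluster_landscape",
    "cluster_centroid",
    "pairwise_rmsd_matrix",
    "landscape_surface",
]

#: RT in kcal/mol at 298.15 K, the default for the -RT ln(delta) rendering
RT_298 = 0.593


def select_feature_residues(
    tmd_range: tuple[int, int] = (76, 505),
    start: int = 76,
    step: int = 5,
    available: set[int] | None = None,
) -> list[int]:
    """Arithmetic residue-id sequence restricted to the TMD residue set.

    Default: every 5th residue of 76..505 (76, 81, 86, ...), the sparse
    subset that keeps the pair-distance feature space tractable while
    covering all TM segments.
    """
    lo, hi = tmd_range
    seq = [r for r in range(start, hi + 1, step) if r >= lo]
    if available is not None:
        seq = [r for r in seq if r in available]
    if not seq:
        raise ValueError("feature residue subset is empty")
    return seq


@dataclass
class FeatureMatrix:
    """Sample-by-feature matrix of inter-Calpha distances (Angstrom)."""

    values: np.ndarray  # (n_samples, n_pairs)
    residue_pairs: list[tuple[int, int]]
    sample_index: list[tuple[int, str]]  # (frame, chain)

    def __post_init__(self) -> None:
        k = len({r for p in self.residue_pairs for r in p})
        if self.values.shape[1] != k * (k - 1) // 2:
            raise ValueError("feature count must be k(k-1)/2 for k residues")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


def build_distance_features(
    frames: list[TrajectoryFrame],
    system: MolecularSystem,
    chain: str,
    residue_subset: list[int],
) -> FeatureMatrix:
    """One row per frame of the chain; one column per unordered residue pair."""
    idx = []
    for resid in residue_subset:
        sel = np.flatnonzero(
            (system.resids == resid)
            & (system.names == "CA")
            & (system.chains == chain)
        )
        if sel.size == 0:
            raise ValueError(f"residue {resid} has no CA in chain {chain!r}")
        idx.append(sel[0])
    idx = np.array(idx)
    rows = np.empty((len(frames), len(idx) * (len(idx) - 1) // 2))
    for i, frame in enumerate(frames):
        rows[i] = pdist(frame.xyz[idx])
    pairs = list(combinations(residue_subset, 2))
    samples = [(i, chain) for i in range(len(frames))]
    return FeatureMatrix(values=rows, residue_pairs=pairs, sample_index=samples)


@dataclass
class LandscapeModel:
    """PCA basis with projections and (optional) DBSCAN cluster labels."""

    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    projections: np.ndarray  # (n_samples, n_components)
    labels: np.ndarray | None = None
    centroid_samples: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = self.explained_variance_ratio
        if np.any(r < -1e-12) or r.sum() > 1 + 1e-9:
            raise ValueError("explained-variance ratios must lie in [0,1], sum <= 1")
        if np.any(np.diff(r) > 1e-12):
            raise ValueError("explained-variance ratios must be non-increasing")


def fit_pca(features: FeatureMatrix, n_components: int = 2) -> LandscapeModel:
    """Mean-centered PCA of the distance features.

    Zero-variance (degenerate) input keeps the components defined but
    yields zero variances, with a warning.
    """
    x = features.values
    if x.shape[0] < n_components:
        raise ValueError("need at least as many samples as components")
    if np.allclose(x.var(axis=0), 0):
        warnings.warn("zero-variance features: PCA is degenerate", stacklevel=2)
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(x)
    ratios = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return LandscapeModel(
        components=pca.components_,
        explained_variance_ratio=ratios,
        mean=pca.mean_,
        projections=proj,
    )


def project(structure_features: np.ndarray, model: LandscapeModel) -> np.ndarray:
    """Map feature vectors onto the PCA basis (center by the training mean)."""
    x = np.atleast_2d(np.asarray(structure_features, dtype=float))
    if x.shape[1] != model.components.shape[1]:
        raise ValueError(
            f"feature length {x.shape[1]} does not match model "
            f"({model.components.shape[1]})"
        )
    return (x - model.mean) @ model.components.T


def cluster_landscape(
    pc_coords: np.ndarray,
    eps: float = 2.0,
    min_samples: int = 150,
) -> np.ndarray:
    """DBSCAN labels over the first two principal components.

    Returns one label per sample; -1 marks noise (the "unassigned
    cluster").  Defaults are eps=2 (in PC units) and min_samples=150.
    """
    coords = np.asarray(pc_coords, dtype=float)[:, :2]
    if coords.shape[0] < min_samples:
        warnings.warn(
            "fewer samples than min_samples: everything is noise", stacklevel=2
        )
        return np.full(coords.shape[0], -1)
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs Calpha RMSD after optimal rigid superposition (Kabsch).

    ``coords`` is (n_frames, n_atoms, 3).  Uses batched 3x3 SVDs; O(n^2)
    in frames but vectorized per row.
    """
    coords = np.asarray(coords, dtype=float)
    n, m, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    sq = np.einsum("nij,nij->n", centered, centered)
    out = np.zeros((n, n))
    for i in range(n - 1):
        rest = centered[i + 1 :]
        h = np.einsum("mk,jml->jkl", centered[i], rest)
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(u @ vt)
        d = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
        ms = np.maximum(sq[i] + sq[i + 1 :] - 2.0 * d, 0.0) / m
        out[i, i + 1 :] = out[i + 1 :, i] = np.sqrt(ms)
    return out


def cluster_centroid(
    frames: list[TrajectoryFrame],
    member_ids: np.ndarray,
    align_indices: np.ndarray,
) -> int:
    """Medoid frame of a cluster: minimizes mean pairwise aligned RMSD.

    ``member_ids`` are frame indices of the cluster; ``align_indices`` the
    atoms (typically TMD Calpha of one chain) used for superposition.
    Returns the winning frame id; a single-member cluster returns that
    member.
    """
    member_ids = np.asarray(member_ids)
    if member_ids.size == 0:
        raise ValueError("empty cluster")
    if member_ids.size == 1:
        return int(member_ids[0])
    coords = np.stack([frames[i].xyz[align_indices] for i in member_ids])
    mat = pairwise_rmsd_matrix(coords)
    mean_rmsd = mat.sum(axis=1) / (len(member_ids) - 1)
    return int(member_ids[int(np.argmin(mean_rmsd))])


def landscape_surface(
    pc_coords: np.ndarray,
    bins: int | tuple[int, int] = 60,
    rt: float = RT_298,
) -> tuple[np.ma.MaskedArray, np.ndarray, np.ndarray]:
    """Free-energy-like surface -RT ln(delta) over the first two PCs.

    delta is the normalized 2-D histogram count.  Empty bins are masked
    (undefined), not infinite.  Returns (surface, x_edges, y_edges);
    the surface minimum coincides with the densest bin.
    """
    coords = np.asarray(pc_coords, dtype=float)[:, :2]
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    counts, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins)
    delta = counts / counts.sum()
    with np.errstate(divide="ignore"):
        surface = -rt * np.log(delta)
    return np.ma.masked_invalid(surface), xe, ye
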