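"""Per-sample training-label generation from spectral intensity alone.

Every in-tissue pixel spectrum of the whole 3D volume is pooled and split
into two clusters by K-means (k = 2 is the only clustering parameter).  The
premise: melanin makes tumor pixels globally brighter, and increasingly so
toward shorter wavelengths, so the higher-mean-intensity cluster is labeled
*non-healthy* and the other *healthy*.  Because a tumor is not expected to
extend through the entire biopsy, clustering is volume-pooled, never
per-slice.  A spatial margin (default 0.5 mm) around the non-healthy cluster
is then relabeled *unlabeled*: those ambiguous boundary pixels are withheld
from training and decided later by the classifier.  Finally an exactly
class-balanced training set of spectra is drawn at random.

Raw (unstandardized) spectra are clustered on purpose -- absolute intensity
IS the discriminating signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .core_io import PAVolume, TissueMask, VoxelGeometry

__all__ = [
    "BACKGROUND", "HEALTHY", "NONHEALTHY", "UNLABELED",
    "LabelMap", "TrainingSet", "SpectralKMeansLabeler",
    "cluster_pixels", "apply_margin", "sample_balanced",
]

# Label codes shared across the pipeline.
BACKGROUND, HEALTHY, NONHEALTHY, UNLABELED = 0, 1, 2, 3
_LABEL_NAMES = {BACKGROUND: "background", HEALTHY: "healthy",
                NONHEALTHY: "non-healthy", UNLABELED: "unlabeled"}


@dataclass
class LabelMap:
    """Per-pixel categorical map on the sample grid ``(slice, z, x)``."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D (slice, z, x)")
        bad = ~np.isin(self.labels, list(_LABEL_NAMES))
        if bad.any():
            raise ValueError("label map contains unknown label codes")

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum())
                for code, name in _LABEL_NAMES.items()}

    def copy(self) -> "LabelMap":
        return LabelMap(labels=self.labels.copy())


@dataclass
class TrainingSet:
    """Balanced spectra/labels pairs with full pixel provenance.

    ``labels`` are 0 (healthy) / 1 (non-healthy); ``provenance`` holds the
    flat voxel index of every spectrum in the source volume, so each training
    point is traceable to a labeled pixel.
    """

    spectra: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels)
        self.provenance = np.asarray(self.provenance)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be (n_points, n_wavelengths)")
        if len(self.spectra) != len(self.labels) or len(self.labels) != len(self.provenance):
            raise ValueError("spectra, labels and provenance lengths differ")
        n0, n1 = int((self.labels == 0).sum()), int((self.labels == 1).sum())
        if n0 != n1:
            raise ValueError(f"training set must be exactly balanced, got {n0}/{n1}")

    @property
    def n_per_class(self) -> int:
        return int((self.labels == 0).sum())


class SpectralKMeansLabeler(ClusterMixin, BaseEstimator):
    """Two-cluster K-means over pixel spectra with intensity-based naming.

    sklearn-style estimator: ``fit(X)`` on an ``(n_pixels, n_wavelengths)``
    spectra matrix; ``labels_`` holds 0 (healthy) / 1 (non-healthy) with the
    higher-mean-total-intensity cluster always named non-healthy, which makes
    the naming invariant to the arbitrary cluster order K-means returns under
    different seeds.

    Parameters
    ----------
    random_state : int
        Seed for the k-means++ initialisation (10 restarts, tol 1e-6).
    """

    def __init__(self, random_state: int = 0, n_init: int = 10, tol: float = 1e-6):
        self.random_state = random_state
        self.n_init = n_init
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 2:
            raise ValueError("need at least 2 pixel spectra to cluster")
        if np.ptp(X, axis=0).max() == 0:
            raise ValueError("all spectra are identical; no contrast to cluster")
        km = KMeans(n_clusters=2, n_init=self.n_init, tol=self.tol,
                    random_state=self.random_state)
        raw = km.fit_predict(X)
        # Higher-intensity cluster (by mean total spectrum) is non-healthy.
        totals = X.sum(axis=1)
        mean0 = totals[raw == 0].mean()
        mean1 = totals[raw == 1].mean()
        tumor_cluster = 1 if mean1 > mean0 else 0
        self.labels_ = (raw == tumor_cluster).astype(np.int8)
        self.cluster_centers_ = (
            km.cluster_centers_ if tumor_cluster == 1
            else km.cluster_centers_[::-1]
        )
        self.inertia_ = km.inertia_
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_pixels(pa: PAVolume, mask: TissueMask, seed: int = 0) -> LabelMap:
    """Cluster every in-tissue pixel spectrum of the whole volume into
    healthy / non-healthy and return the spatial label map."""
    if pa.spatial_shape != mask.mask.shape:
        raise ValueError("PA and mask shapes do not match")
    eligible = mask.mask
    n_eligible = int(eligible.sum())
    if n_eligible < 2:
        raise ValueError(f"only {n_eligible} eligible pixels; nothing to cluster")
    X = pa.data[eligible]
    binary = SpectralKMeansLabeler(random_state=seed).fit_predict(X)
    labels = np.full(pa.spatial_shape, BACKGROUND, dtype=np.int8)
    labels[eligible] = np.where(binary == 1, NONHEALTHY, HEALTHY)
    return LabelMap(labels=labels)


def apply_margin(
    label_map: LabelMap,
    margin_mm: float,
    geometry: VoxelGeometry,
    in_plane: bool = True,
) -> LabelMap:
    """Relabel healthy pixels within ``margin_mm`` of a non-healthy pixel as
    unlabeled.

    Distance is the in-plane (z, x) Euclidean distance per slice, respecting
    the physical pixel anisotropy; ``in_plane=False`` switches to a
    depth-only (vertical) margin.  Non-healthy pixels are never eroded, and
    a zero margin is the identity.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    out = label_map.copy()
    if margin_mm == 0:
        return out
    labels = out.labels
    # Depth-only mode: an effectively infinite lateral pitch confines the
    # distance transform to vertical propagation.
    sampling = ((geometry.axial_mm, geometry.lateral_mm) if in_plane
                else (geometry.axial_mm, 1e9))
    for s in range(labels.shape[0]):
        sl = labels[s]
        tumor = sl == NONHEALTHY
        if not tumor.any():
            continue
        dist = ndimage.distance_transform_edt(~tumor, sampling=sampling)
        relabel = (sl == HEALTHY) & (dist <= margin_mm)
        sl[relabel] = UNLABELED
    return out


def sample_balanced(
    label_map: LabelMap,
    pa: PAVolume,
    n_per_class: int | None = None,
    seed: int = 0,
) -> TrainingSet:
    """Draw an exactly balanced training set of labeled spectra.

    ``n_per_class`` defaults to the minority-class size; sampling is uniform
    without replacement and reproducible given the seed.  Unlabeled and
    background pixels are never sampled.
    """
    labels = label_map.labels
    if labels.shape != pa.spatial_shape:
        raise ValueError("label map and PA volume shapes do not match")
    flat = labels.ravel()
    healthy_idx = np.flatnonzero(flat == HEALTHY)
    tumor_idx = np.flatnonzero(flat == NONHEALTHY)
    if healthy_idx.size == 0 or tumor_idx.size == 0:
        raise ValueError(
            f"both classes must be nonempty (healthy={healthy_idx.size}, "
            f"non-healthy={tumor_idx.size})"
        )
    minority = min(healthy_idx.size, tumor_idx.size)
    n = minority if n_per_class is None else int(n_per_class)
    if n < 1 or n > minority:
        raise ValueError(
            f"n_per_class={n} out of range; class sizes are "
            f"healthy={healthy_idx.size}, non-healthy={tumor_idx.size}"
        )
    rng = np.random.default_rng(seed)
    pick_h = rng.choice(healthy_idx, size=n, replace=False)
    pick_t = rng.choice(tumor_idx, size=n, replace=False)
    provenance = np.concatenate([pick_h, pick_t])
    spectra_flat = pa.data.reshape(-1, pa.data.shape[3])
    spectra = spectra_flat[provenance]
    y = np.concatenate([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    return TrainingSet(spectra=spectra, labels=y, provenance=provenance, seed=seed)
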