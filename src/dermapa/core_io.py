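"""Data model and container I/O for multispectral photoacoustic (PA) samples.

A sample couples a 4D PA intensity volume -- indexed ``(slice, depth, lateral,
wavelength)`` -- with a co-registered 3D ultrasound (US) volume on the same
spatial grid.  The slice axis is the coarse mechanical scan direction
(typically 0.5 mm steps), depth ``z`` increases downward from the tissue
surface, and the wavelength axis carries the excitation spectral sweep
(59 wavelengths, 680-970 nm in 5 nm steps, for the instrument this package
models).

Samples are exchanged as single HDF5 files with datasets ``/pa``, ``/us``,
``/axis``, ``/geometry`` and, for phantoms, a ``/truth`` group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import yaml

__all__ = [
    "SpectralAxis",
    "VoxelGeometry",
    "PAVolume",
    "USVolume",
    "TissueMask",
    "PipelineConfig",
    "Sample",
    "build_spectral_axis",
    "read_volume",
    "write_volume",
    "read_sample",
    "write_sample",
]

_WAVELENGTH_SANITY_NM = (300.0, 2000.0)


@dataclass(frozen=True)
class SpectralAxis:
    """Evenly spaced excitation wavelength axis in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("spectral axis must be a non-empty 1D array")
        if v.size > 1:
            d = np.diff(v)
            if not np.all(d > 0):
                raise ValueError("wavelengths must be strictly increasing")
            if not np.allclose(d, self.step_nm, atol=1e-9):
                raise ValueError("wavelengths must be evenly spaced by step_nm")
        lo, hi = _WAVELENGTH_SANITY_NM
        if not (lo <= v[0] and v[-1] <= hi):
            raise ValueError(
                f"wavelengths outside sanity range [{lo}, {hi}] nm: "
                f"{v[0]}..{v[-1]}"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


def build_spectral_axis(start_nm: float, stop_nm: float, step_nm: float) -> SpectralAxis:
    """Build an inclusive, evenly spaced wavelength axis.

    The span must be an integer multiple of the step (within 1e-6 nm), so the
    axis has exactly ``(stop - start) / step + 1`` values, endpoints included.
    The instrument default, ``build_spectral_axis(680, 970, 5)``, yields 59
    wavelengths.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if stop_nm < start_nm:
        raise ValueError("stop_nm must be >= start_nm")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-6:
        raise ValueError(
            f"span {span} nm is not divisible by step {step_nm} nm; "
            "choose endpoints on the step grid"
        )
    n = int(round(n_steps)) + 1
    values = start_nm + step_nm * np.arange(n, dtype=float)
    return SpectralAxis(start_nm=float(start_nm), stop_nm=float(stop_nm),
                        step_nm=float(step_nm), values=values)


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel pitch in mm.

    ``slice_spacing_mm`` is the coarse scan-direction step; ``axial_mm`` the
    depth pixel pitch; ``lateral_mm`` the in-plane lateral pitch.  The scan
    axis is assumed to be the low-resolution one.
    """

    slice_spacing_mm: float = 0.5
    axial_mm: float = 0.05
    lateral_mm: float = 0.06

    def __post_init__(self) -> None:
        for name in ("slice_spacing_mm", "axial_mm", "lateral_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.slice_spacing_mm < self.axial_mm:
            raise ValueError(
                "slice_spacing_mm must be >= axial_mm (slice axis is the "
                "low-resolution scan direction)"
            )


@dataclass
class PAVolume:
    """4D photoacoustic intensity volume ``(slice, depth, lateral, wavelength)``."""

    data: np.ndarray
    geometry: VoxelGeometry
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("PA data must be 4D (slice, depth, lateral, wavelength)")
        if self.data.shape[3] != len(self.axis):
            raise ValueError(
                f"wavelength planes ({self.data.shape[3]}) do not match the "
                f"spectral axis ({len(self.axis)} values)"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PA data must be finite")
        if np.any(self.data < 0):
            raise ValueError("PA intensities must be nonnegative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def spectra(self, where: Optional[np.ndarray] = None) -> np.ndarray:
        """Pixel spectra as an ``(n_pixels, n_wavelengths)`` matrix."""
        if where is None:
            return self.data.reshape(-1, self.data.shape[3])
        return self.data[where]


@dataclass
class USVolume:
    """3D ultrasound intensity volume ``(slice, depth, lateral)``."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("US data must be 3D (slice, depth, lateral)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("US data must be finite")
        if np.any(self.data < 0):
            raise ValueError("US intensities must be nonnegative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TissueMask:
    """Boolean tissue-vs-background mask on the sample's spatial grid."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("tissue mask must be 3D (slice, depth, lateral)")

    @property
    def empty_slices(self) -> np.ndarray:
        """Indices of slices in which no tissue was found."""
        return np.flatnonzero(~self.mask.any(axis=(1, 2)))


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    ``margin_mm`` is the unlabeled band left between the two K-means clusters
    (default 0.5 mm); ``prob_threshold`` the tumor-probability cut (default
    0.5, with p <= threshold read as healthy); ``n_clusters`` is fixed at 2 --
    it is the single clustering parameter the label generator sets.
    ``n_train_per_class`` caps the balanced training draw (None = the full
    minority-class size).
    """

    margin_mm: float = 0.5
    prob_threshold: float = 0.5
    n_clusters: int = 2
    rng_seed: int = 0
    n_train_per_class: Optional[int] = 1000
    classifier: dict = field(default_factory=dict)
    sandpile: dict = field(default_factory=dict)
    contour: dict = field(default_factory=dict)
    reconstruct: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must lie strictly inside (0, 1)")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        if self.n_clusters != 2:
            raise ValueError("n_clusters is fixed at 2 (healthy vs non-healthy)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path


@dataclass
class Sample:
    """A PA volume with its co-registered US volume and optional ground truth."""

    pa: PAVolume
    us: USVolume
    truth: Optional["object"] = None  # phantom.PhantomTruth when present

    def __post_init__(self) -> None:
        if self.pa.spatial_shape != self.us.spatial_shape:
            raise ValueError(
                f"PA spatial shape {self.pa.spatial_shape} does not match "
                f"US shape {self.us.spatial_shape}"
            )


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def _write_geometry(grp: h5py.Group, geom: VoxelGeometry) -> None:
    grp.create_dataset(
        "geometry",
        data=np.array([geom.slice_spacing_mm, geom.axial_mm, geom.lateral_mm]),
    )


def _read_geometry(grp: h5py.Group) -> VoxelGeometry:
    if "geometry" not in grp:
        raise ValueError("container is missing the /geometry dataset")
    s, a, l = np.asarray(grp["geometry"][()], dtype=float)
    return VoxelGeometry(slice_spacing_mm=s, axial_mm=a, lateral_mm=l)


def _write_axis(grp: h5py.Group, axis: SpectralAxis) -> None:
    ds = grp.create_dataset("axis", data=axis.values)
    ds.attrs["start_nm"] = axis.start_nm
    ds.attrs["stop_nm"] = axis.stop_nm
    ds.attrs["step_nm"] = axis.step_nm


def _read_axis(grp: h5py.Group) -> SpectralAxis:
    if "axis" not in grp:
        raise ValueError("container is missing the /axis dataset")
    ds = grp["axis"]
    return SpectralAxis(
        start_nm=float(ds.attrs["start_nm"]),
        stop_nm=float(ds.attrs["stop_nm"]),
        step_nm=float(ds.attrs["step_nm"]),
        values=np.asarray(ds[()], dtype=float),
    )


def write_volume(volume: PAVolume | USVolume, path: str | Path) -> Path:
    """Write a single PA or US volume (with metadata) to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        if isinstance(volume, PAVolume):
            fh.create_dataset("pa", data=volume.data, chunks=True)
            _write_axis(fh, volume.axis)
        elif isinstance(volume, USVolume):
            fh.create_dataset("us", data=volume.data, chunks=True)
        else:
            raise TypeError(f"cannot write object of type {type(volume).__name__}")
        _write_geometry(fh, volume.geometry)
    return path


def read_volume(path: str | Path) -> PAVolume | USVolume:
    """Read a single-volume container; the dataset present decides the type."""
    with h5py.File(path, "r") as fh:
        geom = _read_geometry(fh)
        if "pa" in fh:
            axis = _read_axis(fh)
            data = np.asarray(fh["pa"][()])
            return PAVolume(data=data, geometry=geom, axis=axis)
        if "us" in fh:
            return USVolume(data=np.asarray(fh["us"][()]), geometry=geom)
    raise ValueError(f"{path}: container holds neither /pa nor /us")


def write_sample(sample: Sample, path: str | Path) -> Path:
    """Write a full sample (PA + US + optional phantom truth) to one file."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("pa", data=sample.pa.data, chunks=True)
        fh.create_dataset("us", data=sample.us.data, chunks=True)
        _write_axis(fh, sample.pa.axis)
        _write_geometry(fh, sample.pa.geometry)
        if sample.truth is not None:
            t = fh.create_group("truth")
            t.create_dataset("tumor_mask", data=sample.truth.tumor_mask)
            t.create_dataset("tissue_mask", data=sample.truth.tissue_mask)
            t.attrs["true_depth_mm"] = sample.truth.true_depth_mm
            t.attrs["true_volume_mm3"] = sample.truth.true_volume_mm3
    return path


def read_sample(path: str | Path) -> Sample:
    """Read a full sample container written by :func:`write_sample`."""
    from .phantom import PhantomTruth  # local import to avoid a cycle

    with h5py.File(path, "r") as fh:
        for name in ("pa", "us"):
            if name not in fh:
                raise ValueError(f"{path}: container is missing /{name}")
        geom = _read_geometry(fh)
        axis = _read_axis(fh)
        pa = PAVolume(data=np.asarray(fh["pa"][()]), geometry=geom, axis=axis)
        us = USVolume(data=np.asarray(fh["us"][()]), geometry=geom)
        truth = None
        if "truth" in fh:
            t = fh["truth"]
            truth = PhantomTruth(
                tumor_mask=np.asarray(t["tumor_mask"][()], dtype=bool),
                tissue_mask=np.asarray(t["tissue_mask"][()], dtype=bool),
                true_depth_mm=float(t.attrs["true_depth_mm"]),
                true_volume_mm3=float(t.attrs["true_volume_mm3"]),
            )
    return Sample(pa=pa, us=us, truth=truth)
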