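"""Synthetic PA/US phantoms with exact ground truth.

The phantom emulates the structure the analysis framework assumes about an
excised, saline-immersed skin lesion:

* a tissue slab below a flat surface, surrounded by near-signal-free saline;
* a melanotic tumor shaped as a superellipsoid touching the tissue surface,
  whose pixel spectra follow a melanin-like power law -- absorption rising
  monotonically toward shorter wavelengths -- and are globally brighter than
  healthy tissue;
* healthy tissue with a weaker, flatter spectrum (a mild linear slope, no
  explicit chromophore bands: amplitude and slope are the only cues the
  downstream classifier is entitled to rely on);
* optional amelanotic rim: over the outer ``rim_mm`` of the tumor the melanin
  content blends linearly into the healthy spectrum, producing genuinely
  ambiguous boundary pixels that exercise the unlabeled-margin logic;
* multiplicative Gaussian noise plus a small additive floor, clipped at zero;
* a US volume with strong tissue/saline contrast and independent noise.

Ground truth (tumor mask, tissue mask, maximum vertical tumor extent, tumor
volume) is recorded exactly, so every downstream stage can be scored against
a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_io import (
    PAVolume,
    Sample,
    SpectralAxis,
    USVolume,
    VoxelGeometry,
    build_spectral_axis,
    write_sample,
)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_sample",
           "generate_cohort", "max_vertical_extent_mm"]

#: Reference wavelength (nm) for the melanin-like power law; eumelanin
#: absorption is conventionally tabulated against 694 nm (ruby laser line).
MELANIN_REFERENCE_NM = 694.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic sample.

    Spatial sizes are voxel counts ``(n_slices, n_z, n_x)``; all physical
    lengths are mm.  ``tumor_half_axes_mm`` are the superellipsoid half-axes
    along (slice, depth, lateral); the tumor top touches the tissue surface,
    so the depth half-axis is (up to voxel quantization) the true maximum
    thickness.  ``contrast`` is the tumor/healthy amplitude ratio A_t/A_h at
    the reference wavelength; the premise of the whole framework is that it
    exceeds 1.
    """

    shape: tuple[int, int, int] = (6, 48, 96)
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    axis: SpectralAxis = field(default_factory=lambda: build_spectral_axis(680, 970, 5))
    tumor_center_mm: Optional[tuple[float, float]] = None  # (slice, lateral); grid centre if None
    tumor_half_axes_mm: tuple[float, float, float] = (1.1, 0.6, 1.4)
    superellipse_exponent: float = 3.0
    healthy_amplitude: float = 1.0
    contrast: float = 3.0
    melanin_exponent: float = 3.0
    healthy_slope: float = -0.2
    rim_mm: float = 0.2
    noise_sigma: float = 0.1
    additive_floor: float = 0.01
    attenuation_per_mm: float = 0.0
    surface_mm: float = 0.2
    lateral_margin_mm: float = 0.25
    bottom_margin_mm: float = 0.2
    us_tissue_level: float = 100.0
    us_background_level: float = 2.0
    us_noise_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast <= 1.0:
            raise ValueError("contrast A_t/A_h must exceed 1 (tumor brighter)")
        if self.noise_sigma < 0 or self.us_noise_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if min(self.tumor_half_axes_mm) <= 0:
            raise ValueError("tumor half-axes must be positive")
        if self.rim_mm < 0:
            raise ValueError("rim_mm must be >= 0")

    @property
    def tumor_amplitude(self) -> float:
        return self.healthy_amplitude * self.contrast


@dataclass
class PhantomTruth:
    """Exact ground truth for one phantom."""

    tumor_mask: np.ndarray
    tissue_mask: np.ndarray
    true_depth_mm: float
    true_volume_mm3: float

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.tumor_mask.shape != self.tissue_mask.shape:
            raise ValueError("tumor and tissue masks must share a shape")
        if np.any(self.tumor_mask & ~self.tissue_mask):
            raise ValueError("tumor mask must be contained in the tissue mask")


def max_vertical_extent_mm(mask: np.ndarray, axial_mm: float) -> float:
    """Longest contiguous vertical (depth-axis) run of True, in mm.

    ``mask`` is ``(slice, z, x)``; runs are counted per (slice, lateral)
    column along z.  This is the mask-level definition of maximum tumor
    thickness used as the ground-truth oracle.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    # Cumulative run-length trick along z, vectorized over all columns.
    m = mask.astype(np.int64)
    run = np.zeros_like(m)
    for z in range(m.shape[1]):
        prev = run[:, z - 1, :] if z > 0 else 0
        run[:, z, :] = (prev + 1) * m[:, z, :]
    return float(run.max() * axial_mm)


def _grids_mm(spec: PhantomSpec):
    g = spec.geometry
    s = np.arange(spec.shape[0]) * g.slice_spacing_mm
    z = np.arange(spec.shape[1]) * g.axial_mm
    x = np.arange(spec.shape[2]) * g.lateral_mm
    return s, z, x


def _tissue_mask(spec: PhantomSpec) -> np.ndarray:
    s_mm, z_mm, x_mm = _grids_mm(spec)
    z_ok = (z_mm >= spec.surface_mm) & (z_mm <= z_mm[-1] - spec.bottom_margin_mm)
    x_ok = (x_mm >= spec.lateral_margin_mm) & (x_mm <= x_mm[-1] - spec.lateral_margin_mm)
    mask = np.broadcast_to(z_ok[None, :, None] & x_ok[None, None, :], spec.shape)
    return np.ascontiguousarray(mask)


def _tumor_mask(spec: PhantomSpec, tissue: np.ndarray) -> np.ndarray:
    s_mm, z_mm, x_mm = _grids_mm(spec)
    if spec.tumor_center_mm is None:
        cs, cx = s_mm[-1] / 2.0, x_mm[-1] / 2.0
    else:
        cs, cx = spec.tumor_center_mm
    a_s, a_z, a_x = spec.tumor_half_axes_mm
    p = spec.superellipse_exponent
    # Top of the tumor sits at the tissue surface; only z >= surface counts.
    dz = (z_mm - spec.surface_mm) / a_z
    ds = (s_mm - cs) / a_s
    dx = (x_mm - cx) / a_x
    r = (np.abs(ds[:, None, None]) ** p
         + np.abs(dz[None, :, None]) ** p
         + np.abs(dx[None, None, :]) ** p)
    mask = (r <= 1.0) & (z_mm[None, :, None] >= spec.surface_mm)
    if np.any(mask & ~tissue):
        raise ValueError("tumor does not fit inside the tissue slab; shrink "
                         "the half-axes or enlarge the grid")
    return mask


def _melanin_fraction(spec: PhantomSpec, tumor: np.ndarray) -> np.ndarray:
    """Melanin content in [0, 1]: 1 in the core, linear ramp over the rim.

    The ramp distance is measured to the lateral and deep tumor boundary
    only, never to the skin surface: a melanoma is pigmented where it meets
    the surface, and the amelanotic transition sits at the invasion front.
    (Eroding melanin from the top face would also break the generator's
    premise that tumor pixels are brighter, for lesions shallower than the
    rim.)
    """
    if spec.rim_mm == 0 or not tumor.any():
        return tumor.astype(float)
    g = spec.geometry
    iz0 = int(np.argmax(tumor.any(axis=(0, 2))))  # first depth row with tumor
    sub = tumor[:, iz0:, :]
    pad_n = int(np.ceil(spec.rim_mm / g.axial_mm)) + 1
    padded = np.pad(sub, ((0, 0), (pad_n, 0), (0, 0)), mode="edge")
    dist = ndimage.distance_transform_edt(
        padded, sampling=(g.slice_spacing_mm, g.axial_mm, g.lateral_mm))
    m = np.zeros(tumor.shape, dtype=float)
    m[:, iz0:, :] = np.clip(dist[:, pad_n:, :] / spec.rim_mm, 0.0, 1.0)
    return m * tumor


def generate_phantom(spec: PhantomSpec) -> tuple[PAVolume, USVolume, PhantomTruth]:
    """Synthesize one phantom sample with exact ground truth.

    Tumor voxels carry ``m*A_t*(lam/694)^(-k)`` blended with the healthy
    spectrum by melanin fraction ``m``, healthy voxels ``A_h*f(lam)`` with a
    mild linear slope ``f``; both are attenuated by ``exp(-mu * depth_mm)``
    and perturbed multiplicatively by ``(1 + eps)``, ``eps ~ N(0, sigma)``,
    plus a small nonnegative additive floor.  Identical seeds reproduce the
    volumes bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    lam = spec.axis.values
    n_lam = lam.size
    tissue = _tissue_mask(spec)
    tumor = _tumor_mask(spec, tissue)
    m = _melanin_fraction(spec, tumor)

    tumor_shape = (lam / MELANIN_REFERENCE_NM) ** (-spec.melanin_exponent)
    mid = 0.5 * (lam[0] + lam[-1])
    span = lam[-1] - lam[0] if n_lam > 1 else 1.0
    healthy_shape = 1.0 + spec.healthy_slope * (lam - mid) / span

    s_mm, z_mm, x_mm = _grids_mm(spec)
    depth_mm = np.clip(z_mm - spec.surface_mm, 0.0, None)
    atten = np.exp(-spec.attenuation_per_mm * depth_mm)  # (n_z,)

    # Clean signal: blend tumor and healthy spectra by melanin fraction.
    A_t, A_h = spec.tumor_amplitude, spec.healthy_amplitude
    clean = np.zeros(spec.shape + (n_lam,), dtype=float)
    healthy_spec = A_h * healthy_shape
    tumor_spec = A_t * tumor_shape
    clean[tissue] = healthy_spec
    if tumor.any():
        mt = m[tumor][:, None]
        clean[tumor] = mt * tumor_spec + (1.0 - mt) * healthy_spec
    clean *= atten[None, :, None, None]

    eps = rng.normal(0.0, spec.noise_sigma, size=clean.shape) if spec.noise_sigma > 0 else 0.0
    floor = spec.additive_floor * np.abs(rng.normal(0.0, 1.0, size=clean.shape)) \
        if spec.additive_floor > 0 else 0.0
    pa_data = np.clip(clean * (1.0 + eps) + floor, 0.0, None)

    us_noise = rng.normal(0.0, spec.us_noise_sigma, size=spec.shape)
    us_clean = np.where(tissue, spec.us_tissue_level, spec.us_background_level)
    us_data = np.clip(us_clean * (1.0 + us_noise), 0.0, None)

    truth = PhantomTruth(
        tumor_mask=tumor,
        tissue_mask=tissue,
        true_depth_mm=max_vertical_extent_mm(tumor, spec.geometry.axial_mm),
        true_volume_mm3=float(tumor.sum()) * spec.geometry.slice_spacing_mm
        * spec.geometry.axial_mm * spec.geometry.lateral_mm,
    )
    pa = PAVolume(data=pa_data, geometry=spec.geometry, axis=spec.axis)
    us = USVolume(data=us_data, geometry=spec.geometry)
    return pa, us, truth


def generate_sample(spec: PhantomSpec) -> Sample:
    """Convenience wrapper returning a :class:`~dermapa.core_io.Sample`."""
    pa, us, truth = generate_phantom(spec)
    return Sample(pa=pa, us=us, truth=truth)


def generate_cohort(
    n_samples: int,
    depth_range_mm: tuple[float, float] = (0.2, 1.0),
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    base_spec: Optional[PhantomSpec] = None,
) -> list[Sample] | list[Path]:
    """Generate a cohort of phantoms with tumor depths spanning a range.

    Depths cover ``depth_range_mm`` evenly (both endpoints included, so the
    cohort's depth extremes equal the configured bounds) and are assigned to
    samples in a seed-shuffled order; per-sample noise seeds derive
    deterministically from the master seed.  With ``out_dir`` set, each
    sample is written to ``sample_###.h5`` and the file paths are returned;
    otherwise the in-memory samples are returned.
    """
    if n_samples < 2:
        raise ValueError("a cohort needs at least 2 samples")
    lo, hi = depth_range_mm
    if not (0 < lo <= hi):
        raise ValueError("depth_range_mm must be a nonempty positive range")
    rng = np.random.default_rng(seed)
    depths = np.linspace(lo, hi, n_samples)
    rng.shuffle(depths)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_samples) % (2**31)
    base = base_spec if base_spec is not None else PhantomSpec()

    samples: list[Sample] = []
    for depth, child in zip(depths, child_seeds):
        a_s, _, a_x = base.tumor_half_axes_mm
        spec = replace(base, tumor_half_axes_mm=(a_s, float(depth), a_x),
                       seed=int(child))
        samples.append(generate_sample(spec))

    if out_dir is None:
        return samples
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(samples):
        paths.append(write_sample(s, out_dir / f"sample_{i:03d}.h5"))
    return paths
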