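"""Background segmentation: separate the sample from the saline bath.

The US volume carries the structural contrast (tissue scatters, saline does
not), so each US cross-section is thresholded automatically with Otsu's
between-class-variance criterion, the binary map is smoothed morphologically
(closing then opening with a disk), and only the largest connected component
per slice is kept -- which also discards bright acquisition artifacts such as
gel bubbles or transducer plastic floating above the surface.  The resulting
tissue mask is then transferred to the co-registered PA data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening

from .core_io import PAVolume, TissueMask, USVolume

__all__ = ["ThresholdParams", "segment_background", "apply_mask"]


@dataclass(frozen=True)
class ThresholdParams:
    """Parameters of the automatic US thresholding.

    ``smoothing_radius_px`` is the disk radius of the morphological
    closing/opening; ``min_component_fraction`` is the minimum fraction of
    slice pixels a foreground component must reach for the slice to count as
    containing tissue; ``per_slice`` switches between per-slice (default) and
    whole-volume thresholding.
    """

    smoothing_radius_px: int = 2
    min_component_fraction: float = 0.001
    n_bins: int = 256
    per_slice: bool = True

    def __post_init__(self) -> None:
        if self.smoothing_radius_px < 0:
            raise ValueError("smoothing radius must be >= 0")
        if not (0 < self.min_component_fraction <= 1):
            raise ValueError("min_component_fraction must lie in (0, 1]")


def _otsu_or_none(values: np.ndarray, n_bins: int) -> float | None:
    """Otsu threshold, or None when the histogram is degenerate (unimodal).

    When the two modes are far apart the between-class variance is flat
    across the whole gap and the argmax lands on the gap's lower edge, where
    the tail of the background mode can leak through.  The Otsu threshold is
    therefore re-centered by intermeans iterations (t := mean of the two
    class means), which keeps the same variance-maximizing partition but
    places the cut mid-gap.
    """
    if values.size == 0 or np.ptp(values) == 0:
        return None
    t = float(threshold_otsu(values, nbins=n_bins))
    for _ in range(50):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (float(lo.mean()) + float(hi.mean()))
        if abs(t_new - t) < 1e-9:
            break
        t = t_new
    return t


def _largest_component(binary: np.ndarray, min_pixels: int) -> np.ndarray:
    labeled, n = ndimage.label(binary)
    if n == 0:
        return np.zeros_like(binary)
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_pixels:
        return np.zeros_like(binary)
    return labeled == best


def segment_background(us: USVolume, params: ThresholdParams | None = None) -> TissueMask:
    """Segment tissue from background in a US volume.

    Per slice: Otsu threshold on the intensity histogram, morphological
    closing then opening with a disk of ``smoothing_radius_px``, then keep
    the largest connected component.  A slice whose histogram has no contrast
    (empty or unimodal) is flagged empty rather than masked arbitrarily.
    """
    params = params or ThresholdParams()
    data = us.data
    if data.size == 0:
        raise ValueError("US volume is empty")
    n_slices = data.shape[0]
    mask = np.zeros(data.shape, dtype=bool)
    selem = disk(params.smoothing_radius_px) if params.smoothing_radius_px > 0 else None

    global_thr = None
    if not params.per_slice:
        global_thr = _otsu_or_none(data.ravel(), params.n_bins)

    for s in range(n_slices):
        sl = data[s]
        thr = global_thr if global_thr is not None else _otsu_or_none(sl.ravel(), params.n_bins)
        if thr is None:
            continue  # flagged empty via TissueMask.empty_slices
        binary = sl > thr
        if selem is not None:
            binary = opening(closing(binary, selem), selem)
        min_px = max(1, int(params.min_component_fraction * sl.size))
        mask[s] = _largest_component(binary, min_px)

    provenance = (
        f"otsu(nbins={params.n_bins}, per_slice={params.per_slice}), "
        f"closing+opening(disk r={params.smoothing_radius_px}), "
        f"largest component (>= {params.min_component_fraction:g} of slice)"
    )
    return TissueMask(mask=mask, provenance=provenance)


def apply_mask(pa: PAVolume, mask: TissueMask) -> PAVolume:
    """Transfer the tissue mask to the PA volume.

    Spectra inside the mask are preserved bit-exactly; voxels outside are
    zeroed and treated as background by every downstream stage (which also
    receives the mask explicitly).  Applying the same mask twice is a no-op.
    """
    if pa.spatial_shape != mask.mask.shape:
        raise ValueError(
            f"PA spatial shape {pa.spatial_shape} does not match mask shape "
            f"{mask.mask.shape}"
        )
    data = np.where(mask.mask[..., None], pa.data, 0.0)
    return PAVolume(data=data, geometry=pa.geometry, axis=pa.axis)
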