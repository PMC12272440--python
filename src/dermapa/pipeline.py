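"""End-to-end orchestration: segment -> label -> train -> predict ->
classify -> thickness -> delineate -> reconstruct, with provenance.

A single master seed fans out deterministically to per-stage seeds (seed k
for stage k via ``SeedSequence([master, k])``), so a rerun with the same
sample, config and seed reproduces every deterministic stage bit-exactly;
classifier training is deterministic given its derived seed by contract.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .core_io import PipelineConfig, Sample
from .classifier import (ClassifierSpec, ProbabilityMap, TrainedClassifier,
                         classify, predict_map, train_classifier)
from .delineation import (ContourParams, SandpileParams, SliceContour,
                          delineate_volume, rasterize_contours)
from .labeling import LabelMap, TrainingSet, apply_margin, cluster_pixels, sample_balanced
from .phantom import max_vertical_extent_mm
from .preprocess import ThresholdParams, apply_mask, segment_background
from .reconstruct3d import TumorModel3D, assemble_model, interpolate_contours
from .thickness import ThicknessReport, compute_thickness

__all__ = ["RunManifest", "PipelineResult", "run_all", "stage_seed"]

_STAGES = ("segment", "cluster", "sample", "train", "predict", "classify",
           "thickness", "delineate", "reconstruct")


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed: SeedSequence([master, stage])."""
    return int(np.random.SeedSequence([int(master_seed), int(stage_index)])
               .generate_state(1)[0] % (2 ** 31))


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    stage_log: dict[str, dict] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    tissue_mask: np.ndarray
    cluster_labels: LabelMap
    margined_labels: LabelMap
    training_set_size: int
    model: TrainedClassifier
    prob_map: ProbabilityMap
    final_labels: LabelMap
    thickness: ThicknessReport
    thickness_contoured_mm: float
    contours: list[Optional[SliceContour]]
    contour_mask: np.ndarray
    model3d: Optional[TumorModel3D]
    manifest: RunManifest


def run_all(sample: Sample, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole analysis chain on one sample.

    Any stage failure raises with the manifest built so far attached to the
    exception (``exc.manifest``).
    """
    config = config or PipelineConfig()
    manifest = RunManifest(config=asdict(config), master_seed=config.rng_seed)
    for i, name in enumerate(_STAGES):
        manifest.stage_seeds[name] = stage_seed(config.rng_seed, i)

    def timed(name):
        class _T:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                return self_t
            def __exit__(self_t, exc_type, exc, tb):
                manifest.timings_s[name] = round(time.perf_counter() - self_t.t0, 4)
                if exc_type is None:
                    manifest.completed.append(name)
                else:
                    exc.manifest = manifest
                return False
        return _T()

    with timed("segment"):
        mask = segment_background(sample.us, ThresholdParams())
        pa = apply_mask(sample.pa, mask)
        manifest.digests["tissue_mask"] = _digest(mask.mask)
        manifest.stage_log["segment"] = {
            "tissue_pixels": int(mask.mask.sum()),
            "empty_slices": mask.empty_slices.tolist(),
        }

    with timed("cluster"):
        clustered = cluster_pixels(pa, mask, seed=manifest.stage_seeds["cluster"])
        margined = apply_margin(clustered, config.margin_mm, pa.geometry)
        manifest.digests["labels_clustered"] = _digest(clustered.labels)
        manifest.digests["labels_margined"] = _digest(margined.labels)
        manifest.stage_log["cluster"] = {
            "clustered": clustered.counts(), "margined": margined.counts(),
            "margin_mm": config.margin_mm,
        }

    with timed("sample"):
        counts = margined.counts()
        minority = min(counts["healthy"], counts["non-healthy"])
        n_per_class = minority if config.n_train_per_class is None \
            else min(int(config.n_train_per_class), minority)
        ts = sample_balanced(margined, pa, n_per_class=n_per_class,
                             seed=manifest.stage_seeds["sample"])
        manifest.stage_log["sample"] = {"n_per_class": ts.n_per_class}

    with timed("train"):
        cspec = ClassifierSpec(**{**config.classifier,
                                  "seed": manifest.stage_seeds["train"]})
        model = train_classifier(ts, cspec)
        h = model.history
        manifest.stage_log["train"] = {
            "epochs": len(h.train_loss), "best_epoch": h.best_epoch,
            "final_val_accuracy": h.val_accuracy[h.best_epoch] if h.val_accuracy else None,
        }

    with timed("predict"):
        pmap = predict_map(model, pa, margined)
        manifest.digests["prob_map"] = _digest(np.nan_to_num(pmap.prob))

    with timed("classify"):
        final = classify(pmap, margined, threshold=config.prob_threshold)
        manifest.digests["labels_final"] = _digest(final.labels)
        manifest.stage_log["classify"] = {
            "threshold": config.prob_threshold, "final": final.counts(),
        }

    with timed("thickness"):
        report = compute_thickness(final, pa.geometry)
        manifest.stage_log["thickness"] = {
            "max_thickness_mm": report.max_thickness_mm,
            "argmax_slice": report.argmax_slice,
            "tumor_detected": report.tumor_detected,
        }

    with timed("delineate"):
        sand = SandpileParams(**config.sandpile)
        cont = ContourParams(**config.contour)
        contours = delineate_volume(pmap, final, sand, cont)
        contour_mask = rasterize_contours(contours, pa.spatial_shape)
        thickness_contoured = max_vertical_extent_mm(contour_mask, pa.geometry.axial_mm)
        manifest.stage_log["delineate"] = {
            "slices_with_contour": sum(c is not None for c in contours),
            "contour_energies": [None if c is None else round(c.final_energy, 4)
                                 for c in contours],
            "thickness_contoured_mm": thickness_contoured,
        }
        manifest.digests["contour_mask"] = _digest(contour_mask)

    with timed("reconstruct"):
        model3d = None
        n_present = sum(c is not None for c in contours)
        if n_present >= 2:
            target = float(config.reconstruct.get("target_spacing_mm", 0.1))
            stack = interpolate_contours(
                contours, pa.geometry.slice_spacing_mm, target,
                in_plane_shape=pa.spatial_shape[1:])
            model3d = assemble_model(stack, pa.geometry)
            manifest.stage_log["reconstruct"] = {
                "dense_slices": len(stack.contours),
                "volume_mm3": model3d.volume_mm3,
                "watertight": bool(model3d.mesh.is_watertight) if model3d.mesh else False,
            }
        else:
            manifest.stage_log["reconstruct"] = {
                "skipped": f"only {n_present} slice(s) with a contour"}

    return PipelineResult(
        tissue_mask=mask.mask,
        cluster_labels=clustered,
        margined_labels=margined,
        training_set_size=2 * ts.n_per_class,
        model=model,
        prob_map=pmap,
        final_labels=final,
        thickness=report,
        thickness_contoured_mm=thickness_contoured,
        contours=contours,
        contour_mask=contour_mask,
        model3d=model3d,
        manifest=manifest,
    )
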