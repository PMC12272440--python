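# dermapa

Spectroscopy-driven analysis of multispectral photoacoustic (PA) volumes of
excised skin lesions: fully automated tumor-depth estimation (a Breslow-depth
analogue) and 3D tumor delineation, with no human labeling anywhere in the
chain.

## The problem

Breslow's depth — the thickness of a melanoma in mm from the epidermis to the
tumor's deepest point — determines excision margins and prognosis, but today
it can only be measured by histopathology after excision. Multispectral PA
imaging can resolve optical absorption at depth: melanin dominates melanoma
absorption and rises steeply toward shorter wavelengths, so tumor pixels carry
both a globally stronger PA signal and a characteristically sloped spectrum.
`dermapa` turns that spectral contrast into per-sample, human-free analysis
for lesions imaged with a ~59-wavelength sweep (680–970 nm in 5 nm steps) and
a co-registered ultrasound (US) volume on the same grid.

## The method

For each sample (one lesion, one model instance — no cross-patient transfer):

1. **Background segmentation** — per-slice automatic intensity thresholding of
   the US volume (Otsu's between-class-variance criterion, re-centered by
   intermeans iterations), morphological smoothing, largest connected
   component; the mask transfers to the PA data.
2. **Label generation** — K-means with k = 2 over all in-tissue pixel spectra
   of the whole 3D volume (raw intensities; amplitude *is* the signal). The
   higher-intensity cluster is *non-healthy*, the other *healthy*. A 0.5 mm
   in-plane margin around the non-healthy cluster is left *unlabeled* —
   deliberately withheld from training.
3. **Per-pixel classification** — a small 1D convolutional network
   (conv 16×9 → pool → conv 32×5 → GAP → dense) is trained on an exactly
   class-balanced random draw of labeled spectra and assigns every pixel a
   tumor probability `p ∈ [0, 1]`; `p ≤ 0.5` reads healthy, `p > 0.5`
   non-healthy, and only the unlabeled band is decided by the network.
4. **Thickness** — for each cross-section, the longest contiguous vertical run
   of non-healthy pixels; the deepest run × axial pitch is the maximum tumor
   thickness.
5. **Delineation** — per slice, a *sandpile energy landscape*: sand `γ·p` is
   poured on tumor-classified pixels, healthy pixels act as finite sinks, and
   supercritical pixels (height > `h_crit`) topple their sand in equal
   quarters to their 4 neighbours until stable. Isolated misclassified specks
   are absorbed entirely; coherent regions keep a broad pile. A greedy active
   contour (homogeneity + stiffness + centre-of-mass gravity + attraction to
   the landscape's rim) then settles on the tumor boundary.
6. **3D reconstruction** — per-slice contours are interpolated along the
   0.5 mm scan axis by blending signed distance fields, voxelized, and meshed
   (watertight STL/PLY), giving the tumor volume.

A phantom generator synthesizes PA/US volumes with melanin-like tumor
spectra, an optional amelanotic rim, noise, and exact ground truth, so the
whole pipeline is testable at desk scale.

## Worked example

```sh
$ dermapa phantom --out demo.h5 --seed 3 --depth-mm 0.5
wrote demo.h5 (true depth 0.500 mm)

$ dermapa run-all --in demo.h5 --seed 5 --out demo_results
{
  "max_thickness_mm": 0.45,
  "thickness_contoured_mm": 0.55,
  "volume_mm3": 2.0007
}
```

The phantom's true maximum depth is 0.500 mm. The classifier map recovers
0.45 mm (one 0.05 mm axial pixel under truth — the phantom's amelanotic rim
blends the deepest tumor voxels into the healthy spectrum, so the spectral
boundary sits just above the geometric one), and the contoured region gives
0.55 mm. `demo_results/` also holds the provenance manifest (per-stage seeds,
label counts, training history, digests), the final label map, and the
watertight tumor mesh (`tumor.stl`, `tumor.ply`). The manifest records, for
example, that volume-pooled K-means labeled 1 268 pixels non-healthy and the
0.5 mm margin moved 2 420 healthy pixels to unlabeled, and that training
reached validation accuracy 1.0 at epoch 13.

The same stages are available as a library (`dermapa.run_all`,
`dermapa.generate_cohort`, sklearn-style `SpectralConvNetClassifier` and
`SpectralKMeansLabeler` estimators) and as individual CLI steps
(`segment`, `label`, `train`, `predict`, `thickness`, `delineate`,
`reconstruct`, `report`).

## Limitations

Phantoms emulate spectral contrast and geometry, not acoustic physics (no
speckle, fluence inhomogeneity, or spectral coloring); accuracy statements
apply to phantom recovery, not clinical data. Delineation assumes one
connected tumor per slice. See `docs/methods.md` for the full model
description, parameter defaults, and design rationale.
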