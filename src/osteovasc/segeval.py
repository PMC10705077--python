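"""Multi-class segmentation evaluation and a classical baseline segmenter.

The evaluation metric is the Dice coefficient, Dice = 2|A∩B| / (|A| + |B|),
computed per foreground class (bone, vessel, metastasis) between a candidate
segmentation A and a reference B.

The baseline segmenter is a deliberately simple classical pipeline —
smoothing, multi-Otsu thresholding into bone and vessel, small-object
removal, and morphological inference of metastases as sufficiently large
cavities in the closed bone envelope (metastases carry no contrast of their
own and can only be found as missing bone).  It exists to exercise the
evaluation and morphometry stages end-to-end on phantoms; it is not a
state-of-the-art segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu

from .morphometry import _closing
from .volume import (
    BONE,
    CLASS_NAMES,
    FOREGROUND_CLASSES,
    METASTASIS,
    VESSEL,
    IntensityVolume,
    LabelVolume,
)

__all__ = [
    "DiceReport",
    "SegmenterParams",
    "dice_coefficient",
    "dice_report",
    "calibrate_thresholds",
    "baseline_segment",
    "training_size_experiment",
]


# ---------------------------------------------------------------------------
# Dice


@dataclass
class DiceReport:
    """Per-class Dice with the voxel counts it derives from.

    ``dice[c] = 2 * intersection[c] / (seg_counts[c] + ref_counts[c])`` is
    recomputable from the stored counts; the empty-vs-empty case is defined as
    1.0 (perfect agreement on absence).
    """

    dice: dict[int, float]
    seg_counts: dict[int, int]
    ref_counts: dict[int, int]
    intersection: dict[int, int]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class_id": c,
                "class": CLASS_NAMES[c],
                "dice": self.dice[c],
                "seg_voxels": self.seg_counts[c],
                "ref_voxels": self.ref_counts[c],
                "intersection_voxels": self.intersection[c],
            }
            for c in sorted(self.dice)
        ]
        return pd.DataFrame(rows)


def dice_coefficient(seg_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice = 2|A∩B| / (|A| + |B|) for two binary masks.

    Symmetric; defined as 1.0 when both masks are empty.  Shapes must match
    exactly (no broadcasting).
    """
    seg_mask = np.asarray(seg_mask, bool)
    ref_mask = np.asarray(ref_mask, bool)
    if seg_mask.shape != ref_mask.shape:
        raise ValueError(f"mask shapes differ: {seg_mask.shape} vs {ref_mask.shape}")
    a = int(seg_mask.sum())
    b = int(ref_mask.sum())
    if a + b == 0:
        return 1.0
    inter = int((seg_mask & ref_mask).sum())
    return 2.0 * inter / (a + b)


def dice_report(seg: LabelVolume, ref: LabelVolume) -> DiceReport:
    """Per-class Dice for the three foreground classes (background excluded)."""
    if seg.shape != ref.shape:
        raise ValueError(f"volume shapes differ: {seg.shape} vs {ref.shape}")
    dice, sc, rc, ic = {}, {}, {}, {}
    for c in FOREGROUND_CLASSES:
        a = seg.data == c
        b = ref.data == c
        sc[c] = int(a.sum())
        rc[c] = int(b.sum())
        ic[c] = int((a & b).sum())
        dice[c] = 1.0 if sc[c] + rc[c] == 0 else 2.0 * ic[c] / (sc[c] + rc[c])
    return DiceReport(dice=dice, seg_counts=sc, ref_counts=rc, intersection=ic)


# ---------------------------------------------------------------------------
# baseline segmenter


@dataclass
class SegmenterParams:
    """Parameters of the classical baseline segmenter.

    ``bone_threshold``/``vessel_threshold`` of ``None`` trigger four-class
    Otsu auto-thresholding (one threshold per attenuation-population boundary;
    the upper two become the bone and vessel thresholds).  ``envelope_closing_um`` is the ball radius
    used to close the bone mask before cavity inference; it must exceed the
    half-width of lesion breaches but stay below the marrow-canal radius.
    ``connectivity`` is the foreground neighborhood (3 → 26-connected).
    """

    smoothing_um: float = 1.0
    bone_threshold: float | None = None
    vessel_threshold: float | None = None
    min_size_bone: int = 30
    min_size_vessel: int = 10
    min_size_metastasis: int = 50
    envelope_closing_um: float = 30.0
    connectivity: int = 3

    def validate(self) -> None:
        if (self.bone_threshold is None) != (self.vessel_threshold is None):
            raise ValueError("set both thresholds or neither (auto-threshold)")
        if self.bone_threshold is not None and self.bone_threshold >= self.vessel_threshold:
            raise ValueError("bone threshold must lie below the vessel threshold")
        if self.smoothing_um < 0 or self.envelope_closing_um <= 0:
            raise ValueError("smoothing must be >= 0 and closing radius > 0")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")


def calibrate_thresholds(images: list[IntensityVolume], params: SegmenterParams | None = None) -> SegmenterParams:
    """Estimate bone/vessel thresholds from one or more calibration images.

    Four-class Otsu on the pooled smoothed intensities, matching the four
    attenuation populations (background, marrow/metastasis, bone, vessel);
    the two upper thresholds become the bone and vessel thresholds.  A plain
    hierarchical two-class Otsu is unreliable here because the background
    population dominates the histogram and absorbs the marrow mode.
    """
    if not images:
        raise ValueError("need at least one calibration image")
    params = params or SegmenterParams()
    pooled = []
    for img in images:
        sm = _smooth(img, params.smoothing_um)
        pooled.append(sm.ravel())
    x = np.concatenate(pooled)
    try:
        _, t_bone, t_vessel = threshold_multiotsu(x, classes=4)
    except ValueError:  # degenerate histogram (e.g. a compartment missing)
        t_bone = threshold_otsu(x)
        t_vessel = threshold_otsu(x[x > t_bone])
    return replace(params, bone_threshold=float(t_bone), vessel_threshold=float(t_vessel))


def _smooth(img: IntensityVolume, smoothing_um: float) -> np.ndarray:
    if smoothing_um <= 0:
        return img.data
    sigma = [smoothing_um / h for h in img.voxel_size_um]
    return ndi.gaussian_filter(img.data, sigma=sigma)


def _remove_small(mask: np.ndarray, min_size: int, connectivity: int) -> np.ndarray:
    if min_size <= 1 or not mask.any():
        return mask
    structure = ndi.generate_binary_structure(3, connectivity)
    lab, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


def baseline_segment(img: IntensityVolume, params: SegmenterParams | None = None) -> LabelVolume:
    """Classical four-class segmentation of a contrast-enhanced µCT volume.

    Pipeline: Gaussian smoothing → threshold into bone and vessel (fixed or
    auto multi-Otsu thresholds) → remove components below the per-class
    minimum size → close the bone mask into an envelope → label
    envelope-interior cavities of sufficient size, not occupied by bone or
    vessel, as metastasis.  Deterministic.
    """
    params = params or SegmenterParams()
    params.validate()
    if params.bone_threshold is None:
        params = calibrate_thresholds([img], params)
    sm = _smooth(img, params.smoothing_um)
    vessel = sm >= params.vessel_threshold
    bone = (sm >= params.bone_threshold) & ~vessel
    bone = _remove_small(bone, params.min_size_bone, params.connectivity)
    vessel = _remove_small(vessel, params.min_size_vessel, params.connectivity)
    if not bone.any():
        raise ValueError("no bone detected above the bone threshold")
    # metastases appear only as missing bone: close the bone into its envelope
    # and call sufficiently large interior cavities metastasis
    envelope = _closing(bone, params.envelope_closing_um, img.voxel_size_um) | bone
    cavities = envelope & ~bone & ~vessel
    cavities = _remove_small(cavities, params.min_size_metastasis, params.connectivity)
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[bone] = BONE
    labels[vessel] = VESSEL
    labels[cavities] = METASTASIS
    return LabelVolume(labels, img.voxel_size_um)


# ---------------------------------------------------------------------------
# calibration-set-size sweep


def training_size_experiment(
    calibration: list[tuple[IntensityVolume, LabelVolume]],
    test_set: list[tuple[IntensityVolume, LabelVolume]],
    sizes: list[int],
    params: SegmenterParams | None = None,
) -> pd.DataFrame:
    """Sweep the number of calibration samples for the auto-thresholds.

    For each size, thresholds are calibrated on the first ``size`` calibration
    pairs and the per-class Dice is evaluated on the fixed test set.  Returns
    one row per size with mean and SD of each class Dice.  Median quality is
    reported, not asserted, as a function of size.
    """
    if any(s > len(calibration) for s in sizes):
        raise ValueError(f"sizes {sizes} exceed the {len(calibration)} calibration samples")
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1")
    rows = []
    for size in sizes:
        fitted = calibrate_thresholds([img for img, _ in calibration[:size]], params)
        per_class: dict[int, list[float]] = {c: [] for c in FOREGROUND_CLASSES}
        for img, ref in test_set:
            rep = dice_report(baseline_segment(img, fitted), ref)
            for c in FOREGROUND_CLASSES:
                per_class[c].append(rep.dice[c])
        row: dict = {"size": size, "n_test": len(test_set)}
        for c in FOREGROUND_CLASSES:
            vals = np.array(per_class[c])
            row[f"dice_{CLASS_NAMES[c]}_mean"] = float(vals.mean())
            row[f"dice_{CLASS_NAMES[c]}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    columns = ["size", "n_test"] + [
        f"dice_{CLASS_NAMES[c]}_{s}" for c in FOREGROUND_CLASSES for s in ("mean", "sd")
    ]
    return pd.DataFrame(rows, columns=columns)
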