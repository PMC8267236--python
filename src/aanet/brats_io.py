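"""BraTS-layout NIfTI reading and the preprocessing pipeline.

A BraTS case is a folder ``<case_id>/`` holding four co-registered MRI
modalities (``_t1``, ``_t2``, ``_t1ce``, ``_flair``) and an integer label
volume (``_seg``), each 240 x 240 x 155 voxels.  Labels use the BraTS
convention: 0 background/normal tissue, 1 necrotic/non-enhancing tumor core
(NCR/NET), 2 peritumoral edema (ED), 4 GD-enhancing tumor (ET).

The pipeline applied here: z-score normalization over the nonzero (brain)
support, a 160 x 160 in-plane center crop, axial slicing along Z into 155
planes, and stacking the four modality planes into a 4-channel slice.  The
nested evaluation regions are derived from labels as
WT = {1,2,4}, CT = {1,4}, ET = {4}, giving ET <= CT <= WT.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES: Tuple[str, ...] = ("t1", "t2", "t1ce", "flair")
VALID_LABELS = frozenset({0, 1, 2, 4})

#: label sets defining each nested evaluation region.  The alternative
#: reading (ET = label 1) is one edit away here.
REGION_LABELS: Dict[str, Tuple[int, ...]] = {
    "wt": (1, 2, 4),
    "ct": (1, 4),
    "et": (4,),
}

CROP_SIZE = 160
EXPECTED_SHAPE = (240, 240, 155)


@dataclasses.dataclass
class ModalityVolume:
    """One modality of one case: a real 3-D array plus identity."""

    data: np.ndarray
    modality: str
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"modality volume must be 3-D, got {self.data.ndim}-D")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")


@dataclasses.dataclass
class SliceSample:
    """One training/evaluation unit: a 4-channel image and its label map."""

    image: np.ndarray  # (4, H, W) float
    label: np.ndarray  # (H, W) int, values in {0,1,2,4}
    id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.label = np.asarray(self.label)
        if self.image.ndim != 3 or self.image.shape[0] != len(MODALITIES):
            raise ValueError(f"image must be ({len(MODALITIES)}, H, W), got {self.image.shape}")
        if self.label.shape != self.image.shape[1:]:
            raise ValueError("label and image spatial shapes differ")


@dataclasses.dataclass
class RegionTargets:
    """Nested binary masks: whole tumor, core tumor, enhancing tumor."""

    wt: np.ndarray
    ct: np.ndarray
    et: np.ndarray

    def __post_init__(self):
        self.wt = np.asarray(self.wt, dtype=bool)
        self.ct = np.asarray(self.ct, dtype=bool)
        self.et = np.asarray(self.et, dtype=bool)
        if not (self.wt.shape == self.ct.shape == self.et.shape):
            raise ValueError("region masks must share one shape")
        if np.any(self.et & ~self.ct) or np.any(self.ct & ~self.wt):
            raise ValueError("region nesting violated: require ET <= CT <= WT")

    def stack(self) -> np.ndarray:
        """Masks as a (3, H, W) float array, channel order WT, CT, ET."""
        return np.stack([self.wt, self.ct, self.et]).astype(np.float32)

    @classmethod
    def unchecked(cls, wt, ct, et) -> "RegionTargets":
        """Build without the nesting check — for raw model predictions,
        whose three channels are thresholded independently."""
        obj = object.__new__(cls)
        obj.wt = np.asarray(wt, dtype=bool)
        obj.ct = np.asarray(ct, dtype=bool)
        obj.et = np.asarray(et, dtype=bool)
        return obj

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "RegionTargets":
        return cls(wt=arr[0] > 0.5, ct=arr[1] > 0.5, et=arr[2] > 0.5)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def zscore_normalize(vol: ModalityVolume) -> ModalityVolume:
    """Standardize to zero mean / unit variance over the nonzero support.

    Background voxels (exactly zero) stay zero so they do not dominate the
    statistics of the brain tissue.
    """
    data = vol.data.astype(np.float64)
    support = data != 0
    if not support.any():
        raise ValueError("cannot normalize an all-zero volume")
    vals = data[support]
    sd = vals.std()
    if sd < 1e-12:
        raise ValueError("cannot normalize a constant volume (zero variance)")
    out = np.zeros_like(data)
    out[support] = (vals - vals.mean()) / sd
    # keep accidental zeros produced by the shift inside the support
    out[support & (out == 0)] = np.nextafter(0, 1)
    return ModalityVolume(out, vol.modality, vol.case_id)


def center_crop(data: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Crop the in-plane (first two) axes to ``size`` x ``size``, centered."""
    x, y = data.shape[:2]
    if x < size or y < size:
        raise ValueError(f"in-plane size {x}x{y} smaller than crop target {size}")
    ox, oy = (x - size) // 2, (y - size) // 2
    return data[ox:ox + size, oy:oy + size]


def crop_offsets(shape: Sequence[int], size: int = CROP_SIZE) -> Tuple[int, int]:
    return (shape[0] - size) // 2, (shape[1] - size) // 2


def slice_and_stack(vols: Sequence[ModalityVolume],
                    label_vol: np.ndarray) -> List[SliceSample]:
    """Slice co-registered volumes along Z and stack modalities per plane.

    ``vols`` must be the four modalities in the canonical order
    T1, T2, T1ce, FLAIR, already cropped; each axial plane k becomes one
    :class:`SliceSample` whose channel c is plane k of modality c.
    """
    if len(vols) != len(MODALITIES):
        raise ValueError(f"need {len(MODALITIES)} modalities, got {len(vols)}")
    order = tuple(v.modality for v in vols)
    if order != MODALITIES:
        raise ValueError(f"modalities must arrive in order {MODALITIES}, got {order}")
    shapes = {v.data.shape for v in vols} | {np.asarray(label_vol).shape}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among modalities/label: {sorted(shapes)}")
    label_vol = np.asarray(label_vol)
    _check_labels(label_vol)
    case = vols[0].case_id
    samples = []
    for k in range(vols[0].data.shape[2]):
        image = np.stack([v.data[:, :, k] for v in vols]).astype(np.float32)
        samples.append(SliceSample(image=image,
                                   label=label_vol[:, :, k].astype(np.uint8),
                                   id=f"{case}_z{k:03d}"))
    return samples


def stack_to_label_volume(labels: Sequence[np.ndarray]) -> np.ndarray:
    """Inverse of the slicing step for label maps: planes -> X x Y x Z."""
    return np.stack(labels, axis=2)


def _check_labels(label: np.ndarray) -> None:
    found = set(np.unique(label).tolist())
    bad = found - VALID_LABELS
    if bad:
        raise ValueError(f"unexpected label value(s) {sorted(bad)}; allowed {sorted(VALID_LABELS)}")


def labels_to_regions(label: np.ndarray) -> RegionTargets:
    """Map a BraTS label map to the nested WT/CT/ET binary masks."""
    label = np.asarray(label)
    _check_labels(label)
    masks = {name: np.isin(label, vals) for name, vals in REGION_LABELS.items()}
    return RegionTargets(**masks)


def regions_to_labels(regions: RegionTargets) -> np.ndarray:
    """Inverse of :func:`labels_to_regions` under the nesting convention."""
    label = np.zeros(regions.wt.shape, dtype=np.uint8)
    label[regions.wt] = 2          # edema = whole tumor outside the core
    label[regions.ct] = 1          # NCR/NET = core outside enhancing
    label[regions.et] = 4          # enhancing
    return label


# ---------------------------------------------------------------------------
# case-level I/O
# ---------------------------------------------------------------------------

def load_case(case_dir) -> Tuple[List[ModalityVolume], np.ndarray]:
    """Read one BraTS case folder (four modalities + segmentation)."""
    case_dir = Path(case_dir)
    case_id = case_dir.name
    vols = []
    for mod in MODALITIES:
        path = _find_nifti(case_dir, f"{case_id}_{mod}")
        vols.append(ModalityVolume(np.asarray(nib.load(str(path)).dataobj),
                                   mod, case_id))
    seg_path = _find_nifti(case_dir, f"{case_id}_seg")
    label = np.asarray(nib.load(str(seg_path)).dataobj).astype(np.int16)
    shapes = {v.data.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"case {case_id}: modality shapes differ: {sorted(shapes)}")
    return vols, label


def _find_nifti(case_dir: Path, stem: str) -> Path:
    for suffix in (".nii.gz", ".nii"):
        path = case_dir / f"{stem}{suffix}"
        if path.exists():
            return path
    raise FileNotFoundError(f"missing NIfTI file {stem}.nii[.gz] in {case_dir}")


def preprocess_case(vols: Sequence[ModalityVolume], label: np.ndarray,
                    crop: int = CROP_SIZE) -> List[SliceSample]:
    """Normalize, center-crop and slice one case into stacked samples."""
    normed = [zscore_normalize(v) for v in vols]
    cropped = [ModalityVolume(center_crop(v.data, crop), v.modality, v.case_id)
               for v in normed]
    label_c = center_crop(np.asarray(label), crop)
    return slice_and_stack(cropped, label_c)


def save_dataset(samples: Sequence[SliceSample], out_dir) -> Path:
    """Write samples as compressed archives plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"{s.id or i}.npz"
        np.savez_compressed(out_dir / fname, image=s.image.astype(np.float32),
                            label=s.label.astype(np.uint8))
        case_id, _, z = s.id.rpartition("_z")
        rows.append({"sample_id": s.id, "case_id": case_id or s.id,
                     "slice_index": int(z) if z.isdigit() else i, "path": fname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_dataset(manifest_path) -> List[SliceSample]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    samples = []
    for row in manifest.itertuples():
        with np.load(base / row.path) as arc:
            samples.append(SliceSample(image=arc["image"], label=arc["label"],
                                       id=str(row.sample_id)))
    return samples
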