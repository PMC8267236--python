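"""Synthetic multi-modal brain-slice phantoms with nested tumor compartments.

Each phantom slice carries a circular "brain" on a zero background and a
tumor built from three concentric ellipses: peritumoral edema (label 2)
containing enhancing tumor (label 4) containing necrotic core (label 1) —
the same nesting the BraTS label convention encodes, so region extraction
(WT/CT/ET) works identically on phantoms and real cases.  The four intensity
channels mimic the clinical contrast pattern: FLAIR highlights edema, T1ce
highlights enhancing tumor.  Shapes are deliberately simple; the phantoms
exist to exercise the full pipeline, not to look like gliomas.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

from .brats_io import MODALITIES, ModalityVolume, SliceSample

#: tissue classes indexing the columns of the intensity table
TISSUES: Tuple[str, ...] = ("background", "brain", "edema", "enhancing", "necrotic")

#: per-modality (rows: T1, T2, T1ce, FLAIR), per-tissue mean intensity in [0,1].
#: FLAIR is brightest on edema, T1ce on enhancing tumor; T1 shows a dark
#: necrotic core.  Package defaults chosen for clear compartment separability.
DEFAULT_INTENSITIES = np.array([
    # bg   brain  edema  enh   necrotic
    [0.0, 0.55, 0.40, 0.45, 0.20],   # T1
    [0.0, 0.45, 0.70, 0.60, 0.80],   # T2
    [0.0, 0.50, 0.45, 0.90, 0.25],   # T1ce
    [0.0, 0.40, 0.85, 0.65, 0.55],   # FLAIR
])

#: label value written for each tumor tissue (BraTS convention)
_TUMOR_LABELS = {"edema": 2, "enhancing": 4, "necrotic": 1}


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the phantom family.

    ``compartment_radii`` are (edema, enhancing, necrotic) semi-axes as
    fractions of the image size; they must be strictly decreasing and the
    outermost compartment must fit inside the brain disc of radius
    ``brain_radius`` (also a fraction).
    """

    image_size: int = 160
    n_modalities: int = 4
    compartment_radii: Tuple[float, float, float] = (0.30, 0.18, 0.08)
    intensity_table: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_INTENSITIES.copy())
    noise_sd: float = 0.05
    brain_radius: float = 0.45
    seed: int = 0

    def __post_init__(self):
        self.intensity_table = np.asarray(self.intensity_table, dtype=float)
        if self.n_modalities != 4:
            raise ValueError("phantoms are four-modality by construction")
        if self.intensity_table.shape != (self.n_modalities, len(TISSUES)):
            raise ValueError(
                f"intensity_table must be {self.n_modalities}x{len(TISSUES)} "
                f"(modalities x {TISSUES}), got {self.intensity_table.shape}")
        r = self.compartment_radii
        if not (r[0] > r[1] > r[2] > 0):
            raise ValueError(f"compartment radii must be strictly decreasing, got {r}")
        if r[0] >= self.brain_radius:
            raise ValueError("edema compartment must fit inside the brain disc")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")


def _label_map(spec: PhantomSpec, offset: Tuple[float, float],
               radius_scale: float = 1.0,
               axis_ratio: float = 1.0) -> np.ndarray:
    """Render brain disc + three concentric tumor ellipses as a label map."""
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    brain = ((yy - c) ** 2 + (xx - c) ** 2) <= (spec.brain_radius * n) ** 2

    max_r = spec.compartment_radii[0] * radius_scale * max(axis_ratio, 1.0 / axis_ratio)
    if np.hypot(*offset) + max_r * n > spec.brain_radius * n:
        raise ValueError(
            f"offset {offset} pushes the tumor (radius {max_r:.3f} of image) "
            f"outside the brain disc (radius {spec.brain_radius})")

    cy, cx = c + offset[0], c + offset[1]
    label = np.zeros((n, n), dtype=np.uint8)
    for tissue, frac in zip(("edema", "enhancing", "necrotic"),
                            spec.compartment_radii):
        ry = frac * radius_scale * axis_ratio * n
        rx = frac * radius_scale / axis_ratio * n
        if ry < 0.5 or rx < 0.5:
            continue  # compartment too small to cover any pixel center
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        label[inside] = _TUMOR_LABELS[tissue]
    label[~brain] = 0
    return label, brain


def _render_image(spec: PhantomSpec, label: np.ndarray, brain: np.ndarray,
                  rng: Optional[np.random.Generator]) -> np.ndarray:
    tissue_idx = np.zeros(label.shape, dtype=np.int8)        # background
    tissue_idx[brain] = 1                                    # brain
    for tissue, lab in _TUMOR_LABELS.items():
        tissue_idx[label == lab] = TISSUES.index(tissue)
    image = spec.intensity_table[:, tissue_idx].astype(np.float32)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, image.shape).astype(np.float32)
        image[:, ~brain] = 0.0   # keep the zero background exact for z-scoring
    return image


def generate_slice(spec: PhantomSpec, offset: Tuple[float, float] = (0.0, 0.0),
                   radius_scale: float = 1.0, axis_ratio: float = 1.0,
                   rng: Optional[np.random.Generator] = None,
                   sample_id: str = "phantom") -> SliceSample:
    """Generate one 4-channel phantom slice with its label map.

    Reproducible: with ``rng=None`` the spec's own seed drives the noise, so
    two calls with the same spec produce bit-identical samples.
    """
    label, brain = _label_map(spec, offset, radius_scale, axis_ratio)
    image = _render_image(spec, label, brain, rng)
    return SliceSample(image=image, label=label, id=sample_id)


def generate_dataset(spec: PhantomSpec, n: int, seed: Optional[int] = None) -> List[SliceSample]:
    """Generate ``n`` slices with randomized offsets and radius jitter."""
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    size = spec.image_size
    samples = []
    for i in range(n):
        scale = rng.uniform(0.85, 1.1)
        ratio = rng.uniform(0.85, 1.18)
        max_r = spec.compartment_radii[0] * scale * max(ratio, 1.0 / ratio)
        slack = (spec.brain_radius - max_r) * size
        r_off = rng.uniform(0.0, max(0.0, slack - 1.0))
        theta = rng.uniform(0.0, 2 * np.pi)
        offset = (r_off * np.sin(theta), r_off * np.cos(theta))
        samples.append(generate_slice(spec, offset, scale, ratio, rng=rng,
                                      sample_id=f"phantom_{i:03d}"))
    return samples


# ---------------------------------------------------------------------------
# 3-D case writer (BraTS on-disk layout)
# ---------------------------------------------------------------------------

def generate_case_volumes(spec: PhantomSpec, shape: Tuple[int, int, int] = (240, 240, 155),
                          seed: Optional[int] = None
                          ) -> Tuple[List[ModalityVolume], np.ndarray]:
    """Build a full 3-D phantom case: a tumor "ball" whose in-plane radius
    shrinks away from the central slice, zero-padded to the requested shape.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x, y, z = shape
    plane_spec = dataclasses.replace(spec, image_size=min(x, y))
    n = plane_spec.image_size
    images = np.zeros((4, x, y, z), dtype=np.float32)
    labels = np.zeros((x, y, z), dtype=np.uint8)
    ox, oy = (x - n) // 2, (y - n) // 2
    z0, zr = (z - 1) / 2.0, z / 2.5
    for k in range(z):
        t = 1.0 - ((k - z0) / zr) ** 2
        scale = float(np.sqrt(t)) if t > 0 else 0.0
        if scale * spec.compartment_radii[2] * n < 1.0:
            label, brain = np.zeros((n, n), np.uint8), _brain_disc(plane_spec)
        else:
            label, brain = _label_map(plane_spec, (0.0, 0.0), radius_scale=scale)
        img = _render_image(plane_spec, label, brain, rng)
        images[:, ox:ox + n, oy:oy + n, k] = img
        labels[ox:ox + n, oy:oy + n, k] = label
    vols = [ModalityVolume(images[c], mod, "phantom_case")
            for c, mod in enumerate(MODALITIES)]
    return vols, labels


def _brain_disc(spec: PhantomSpec) -> np.ndarray:
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return ((yy - c) ** 2 + (xx - c) ** 2) <= (spec.brain_radius * n) ** 2


def write_brats_case(spec: PhantomSpec, out_dir, case_id: str = "phantom_case",
                     shape: Tuple[int, int, int] = (240, 240, 155),
                     seed: Optional[int] = None) -> Path:
    """Write a phantom case in the BraTS folder layout (NIfTI quartet + seg)."""
    vols, labels = generate_case_volumes(spec, shape, seed)
    case_dir = Path(out_dir) / case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for vol in vols:
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine),
                 str(case_dir / f"{case_id}_{vol.modality}.nii.gz"))
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), affine),
             str(case_dir / f"{case_id}_seg.nii.gz"))
    return case_dir
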