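"""Volume I/O and the standardized preprocessing chain.

Raw co-registered CE-T1WI / T2-Flair volumes are brought onto a common grid
(resampling the T1 contrast volume to the Flair grid), intensity-windowed to
mean +/- 3 SD, cropped slice-wise to the smallest square around the brain
mask, rescaled to 240x240 and min-max normalized to [0, 255].  Deformable
registration and skull stripping are upstream prerequisites: inputs are
assumed co-registered, and the brain mask is supplied by the caller (the
phantom generator emits one; for clinical data any skull-stripping output
works).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as _sk_resize

from .fusion import Modality

TARGET_SIZE = 240
WINDOW_SIGMA = 3.0


class InvalidGeometryError(ValueError):
    """Raised when a volume's direction matrix is not orthonormal."""


class NoForegroundError(ValueError):
    """Raised when a brain mask contains no foreground pixels."""


@dataclass
class Volume:
    """A 3D scalar image with physical-space metadata.

    ``voxels`` is indexed (z, y, x) (the numpy view of an ITK image);
    ``spacing``/``origin`` are world-space (x, y, z) triples in mm and
    ``direction`` the row-major 3x3 direction-cosine matrix, as stored in
    NIfTI headers.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("Volume expects a 3D voxel array")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be positive")
        self._check_direction()

    def _check_direction(self):
        d = self.direction
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise InvalidGeometryError("direction matrix is not orthonormal")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class SliceImage:
    """A single 2D slice of one modality."""

    pixels: np.ndarray
    modality: Modality

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("SliceImage expects a 2D pixel array")


@dataclass
class PatientRecord:
    """One patient: a class label plus an ordered stack of co-registered
    modality slice pairs and (optionally) per-slice lesion masks."""

    patient_id: str
    label: str  # one of CLASSES
    slices: list[tuple[SliceImage, SliceImage]]
    lesion_masks: list[np.ndarray | None] | None = None

    def __post_init__(self):
        if not self.slices:
            raise ValueError("a patient needs at least one slice pair")
        for a, b in self.slices:
            if a.pixels.shape != b.pixels.shape:
                raise ValueError("paired slices must share a pixel grid")
        if self.lesion_masks is not None and len(self.lesion_masks) != len(self.slices):
            raise ValueError("one lesion mask entry per slice (None allowed)")

    def tumor_slice_indices(self) -> list[int]:
        """Indices of slices whose lesion mask is present and non-empty."""
        if self.lesion_masks is None:
            return list(range(len(self.slices)))
        return [i for i, m in enumerate(self.lesion_masks)
                if m is not None and np.any(m)]


CLASSES = ("GBM", "SBM", "PCNSL")


# ---------------------------------------------------------------------------
# ITK bridge
# ---------------------------------------------------------------------------

def _to_sitk(v: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(v.voxels)
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    img.SetDirection(tuple(v.direction.ravel()))
    return img


def _from_sitk(img: sitk.Image) -> Volume:
    return Volume(
        voxels=sitk.GetArrayFromImage(img),
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (.nii / .nii.gz) volume with its geometry."""
    return _from_sitk(sitk.ReadImage(str(path), sitk.sitkFloat64))


def write_volume(v: Volume, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(v), str(path))


def read_slice_png(path: str | Path, modality: Modality) -> SliceImage:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(str(path)), dtype=float)
    if img.ndim == 3:  # collapse RGB(A) fixtures to luminance
        img = img[..., :3].mean(axis=-1)
    return SliceImage(img, modality)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def resample_to_reference(moving: Volume, reference: Volume,
                          interpolation: str = "linear") -> Volume:
    """Resample ``moving`` onto the grid of ``reference``.

    Output spacing, origin, direction and shape equal the reference's;
    intensities are interpolated from the moving volume and voxels that fall
    outside its physical extent are filled with 0.
    """
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}
    if interpolation not in interp:
        raise ValueError(f"interpolation must be one of {sorted(interp)}")
    out = sitk.Resample(_to_sitk(moving), _to_sitk(reference), sitk.Transform(),
                        interp[interpolation], 0.0, sitk.sitkFloat64)
    return _from_sitk(out)


def intensity_window(v: Volume, sigma: float = WINDOW_SIGMA) -> Volume:
    """Clip voxel intensities to [mu - sigma*SD, mu + sigma*SD].

    The mean and population standard deviation are computed over the whole
    volume; a constant volume (SD = 0) is returned unchanged.
    """
    if v.voxels.size == 0:
        raise ValueError("volume is empty")
    mu = float(v.voxels.mean())
    sd = float(v.voxels.std())  # population (divide-by-N)
    if sd == 0.0:
        return dataclasses.replace(v, voxels=v.voxels.copy())
    clipped = np.clip(v.voxels, mu - sigma * sd, mu + sigma * sd)
    return dataclasses.replace(v, voxels=clipped)


def crop_to_brain_square(s: SliceImage, brain_mask: np.ndarray) -> SliceImage:
    """Crop the smallest axis-aligned square containing the brain mask's
    bounding box, centred on that box; the window is shifted to stay inside
    the image where possible and zero-padded where it cannot."""
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != s.pixels.shape:
        raise ValueError("mask and slice shapes differ")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise NoForegroundError("brain mask has no foreground pixels")
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    side = max(r1 - r0 + 1, c1 - c0 + 1)
    starts = []
    for lo, extent, dim in ((r0, r1 - r0 + 1, s.pixels.shape[0]),
                            (c0, c1 - c0 + 1, s.pixels.shape[1])):
        start = lo - (side - extent) // 2
        if side <= dim:
            start = min(max(start, 0), dim - side)
        starts.append(start)
    out = np.zeros((side, side), dtype=s.pixels.dtype)
    rs, cs = starts
    src_r = slice(max(rs, 0), min(rs + side, s.pixels.shape[0]))
    src_c = slice(max(cs, 0), min(cs + side, s.pixels.shape[1]))
    out[src_r.start - rs:src_r.stop - rs, src_c.start - cs:src_c.stop - cs] = \
        s.pixels[src_r, src_c]
    return SliceImage(out, s.modality)


def crop_mask_like(mask: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Apply the same square crop to a boolean mask (nearest semantics)."""
    cropped = crop_to_brain_square(SliceImage(mask.astype(float), Modality.FUSED), brain_mask)
    return cropped.pixels > 0.5


def rescale_and_normalize(s: SliceImage, target_size: int = TARGET_SIZE) -> SliceImage:
    """Bilinear resize to ``target_size`` square, then min-max map to [0, 255].

    Constant slices map to all zeros (no contrast to stretch)."""
    resized = _sk_resize(s.pixels, (target_size, target_size), order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    lo, hi = float(resized.min()), float(resized.max())
    if hi == lo:
        return SliceImage(np.zeros_like(resized), s.modality)
    # clip shields the [0, 255] contract from floating-point round-off
    return SliceImage(np.clip((resized - lo) * (255.0 / (hi - lo)), 0.0, 255.0),
                      s.modality)


def resize_mask(mask: np.ndarray, target_size: int = TARGET_SIZE) -> np.ndarray:
    """Nearest-neighbour resize for boolean masks."""
    out = _sk_resize(mask.astype(float), (target_size, target_size), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return out > 0.5


def preprocess_patient(record: PatientRecord, brain_masks: list[np.ndarray],
                       target_size: int = TARGET_SIZE,
                       window_sigma: float = WINDOW_SIGMA) -> PatientRecord:
    """Run the slice-level chain (window, square crop, rescale, normalize)
    over every slice pair of a patient.

    ``brain_masks`` gives one whole-brain mask per slice.  Intensity
    windowing uses per-modality statistics pooled over the patient's stack,
    mirroring the per-volume statistics of the 3D chain.  Lesion masks, when
    present, are cropped and resized alongside their slices.
    """
    if len(brain_masks) != len(record.slices):
        raise ValueError("need one brain mask per slice")
    stacks = [np.stack([pair[m].pixels for pair in record.slices]) for m in range(2)]
    windowed = [intensity_window(Volume(stack), sigma=window_sigma).voxels for stack in stacks]

    new_slices, new_masks = [], []
    for i, pair in enumerate(record.slices):
        out_pair = []
        for m, sl in enumerate(pair):
            cropped = crop_to_brain_square(SliceImage(windowed[m][i], sl.modality),
                                           brain_masks[i])
            out_pair.append(rescale_and_normalize(cropped, target_size))
        new_slices.append(tuple(out_pair))
        lesion = None if record.lesion_masks is None else record.lesion_masks[i]
        if lesion is not None:
            lesion = resize_mask(crop_mask_like(lesion, brain_masks[i]), target_size)
        new_masks.append(lesion)
    return PatientRecord(record.patient_id, record.label, new_slices, new_masks)
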