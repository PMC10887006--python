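"""Seeded co-registered two-modality phantom cohorts.

The generator emits per-patient axial slice stacks of an elliptical "brain"
carrying one of three lesion phenotypes whose appearance differs between the
two channels, loosely mimicking how the corresponding tumors present on
contrast-enhanced T1 and T2-Flair:

* ``GBM``  — ring enhancement with a dark necrotic core on modality 1 and a
  moderate surrounding hyperintense halo on modality 2;
* ``SBM``  — a compact bright nodule on modality 1 inside a broad
  hyperintense halo on modality 2 (edema out of proportion to the nodule);
* ``PCNSL`` — a homogeneously bright mass on modality 1 with only a thin
  halo on modality 2.

Mean lesion brightness is deliberately similar across classes: telling the
ring from the homogeneous mass needs spatial features, and telling the
nodule apart needs the second channel, so both the encoders and the fusion
path carry real signal.  Every quantity is drawn from a generator seeded by
(cohort seed, patient index): a cohort is a pure function of its spec.

Phantoms are produced at 128x128 and are expected to flow through the
preprocessing chain (windowing, brain-square crop, 240x240 rescale) before
reaching the network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fusion import Modality
from .io_preprocess import CLASSES, PatientRecord, SliceImage, Volume, write_volume

DEFAULT_IMAGE_SIZE = 128
DEFAULT_NOISE_SD = 6.0
DEFAULT_SLICES = (3, 8)


@dataclass
class PhantomSpec:
    """Cohort-level phantom parameters (intensities in arbitrary units)."""

    image_size: int = DEFAULT_IMAGE_SIZE
    noise_sd: float = DEFAULT_NOISE_SD
    patients_per_class: int = 30
    slices_per_patient: tuple[int, int] = DEFAULT_SLICES
    seed: int = 0
    background: float = 100.0       # brain parenchyma level, both modalities
    lesion_radius: float = 18.0     # mean mid-lesion radius, pixels
    brain_clear_slices: tuple[int, int] = (1, 2)  # lesion-free slices emitted

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.patients_per_class < 1:
            raise ValueError("patients_per_class must be >= 1")
        lo, hi = self.slices_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("invalid slices_per_patient range")
        # widest halo is 2.6x a radius jittered up to 1.2x
        if self.lesion_radius * 1.2 * 2.6 > self.image_size / 2:
            raise ValueError("lesion does not fit inside the phantom brain")


# per-phenotype appearance, (modality-1, modality-2), relative to background
_PHENOTYPES = {
    "GBM": dict(core=0.45, rim=2.2, body=None, rim_width=0.38, halo=1.55, halo_scale=1.5),
    "SBM": dict(core=None, rim=None, body=2.25, body_scale=0.55, halo=1.75, halo_scale=2.6),
    "PCNSL": dict(core=None, rim=None, body=1.95, body_scale=1.0, halo=1.35, halo_scale=1.3),
}


def _disk(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _brain_ellipse(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    return _disk(size, c, c, 0.42 * size, 0.36 * size)


def generate_patient(phenotype: str, spec: PhantomSpec, patient_seed: int) -> PatientRecord:
    """Generate one patient's co-registered slice stack with lesion masks.

    Deterministic in (spec.seed, patient_seed).  Slice-level lesion radii
    follow a spherical profile across the stack; one or two lesion-free
    brain slices (empty mask) are appended so downstream "slices containing
    the tumor" filtering is exercised.
    """
    if phenotype not in _PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rng = np.random.default_rng([spec.seed, patient_seed])
    size = spec.image_size
    look = _PHENOTYPES[phenotype]
    brain = _brain_ellipse(size)

    # per-patient jitter: lesion position, size, contrast
    c = (size - 1) / 2.0
    cy = c + rng.uniform(-0.10, 0.10) * size
    cx = c + rng.uniform(-0.10, 0.10) * size
    radius = spec.lesion_radius * rng.uniform(0.8, 1.2)
    gain = rng.uniform(0.9, 1.1)

    n_lesion = int(rng.integers(spec.slices_per_patient[0], spec.slices_per_patient[1] + 1))
    n_clear = int(rng.integers(spec.brain_clear_slices[0], spec.brain_clear_slices[1] + 1))

    slices, masks = [], []
    # spherical cap profile: radius shrinks toward the stack ends
    zs = np.linspace(-0.75, 0.75, n_lesion)
    for z in zs:
        r = radius * float(np.sqrt(1.0 - z ** 2))
        m1 = np.full((size, size), 0.0)
        m2 = np.full((size, size), 0.0)
        m1[brain] = spec.background
        m2[brain] = spec.background
        lesion = _disk(size, cy, cx, r, r)
        bg = spec.background
        if look["body"] is not None:  # nodular / homogeneous phenotypes
            body = _disk(size, cy, cx, r * look["body_scale"], r * look["body_scale"])
            m1[body] = bg * look["body"] * gain
            focal = body
        else:  # ring-enhancing phenotype
            core = _disk(size, cy, cx, r * (1 - look["rim_width"]), r * (1 - look["rim_width"]))
            m1[lesion] = bg * look["rim"] * gain
            m1[core] = bg * look["core"] * gain
            focal = lesion
        halo = _disk(size, cy, cx, r * look["halo_scale"], r * look["halo_scale"]) & brain
        m2[halo] = bg * look["halo"] * gain
        # whole-lesion mask: focal abnormality plus its hyperintense halo,
        # the usual whole-tumor convention for brain-lesion segmentations
        mask = focal | halo
        if spec.noise_sd > 0:
            m1 = m1 + rng.normal(0.0, spec.noise_sd, m1.shape)
            m2 = m2 + rng.normal(0.0, spec.noise_sd, m2.shape)
        slices.append((SliceImage(m1, Modality.T1CE), SliceImage(m2, Modality.FLAIR)))
        masks.append(mask & brain)

    for _ in range(n_clear):
        m1 = np.where(brain, spec.background, 0.0)
        m2 = np.where(brain, spec.background, 0.0)
        if spec.noise_sd > 0:
            m1 = m1 + rng.normal(0.0, spec.noise_sd, m1.shape)
            m2 = m2 + rng.normal(0.0, spec.noise_sd, m2.shape)
        slices.append((SliceImage(m1, Modality.T1CE), SliceImage(m2, Modality.FLAIR)))
        masks.append(np.zeros((size, size), dtype=bool))

    return PatientRecord(f"{phenotype.lower()}-{patient_seed:04d}", phenotype, slices, masks)


def brain_masks_for(record: PatientRecord) -> list[np.ndarray]:
    """Whole-brain masks matching a generated record (the known ellipse)."""
    size = record.slices[0][0].pixels.shape[0]
    brain = _brain_ellipse(size)
    return [brain] * len(record.slices)


def generate_cohort(spec: PhantomSpec) -> list[PatientRecord]:
    """A balanced cohort: ``patients_per_class`` records per phenotype."""
    records = []
    idx = 0
    for cls in CLASSES:
        for _ in range(spec.patients_per_class):
            records.append(generate_patient(cls, spec, idx))
            idx += 1
    return records


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> Path:
    """Write each patient as NIfTI volumes (two modalities + lesion mask)
    plus a cohort manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "n_slices", "t1ce", "flair", "mask"])
        for rec in records:
            stacks = {
                "t1ce": np.stack([p[0].pixels for p in rec.slices]),
                "flair": np.stack([p[1].pixels for p in rec.slices]),
                "mask": np.stack([
                    (m if m is not None else np.zeros_like(rec.slices[0][0].pixels, bool))
                    .astype(np.uint8) for m in rec.lesion_masks]),
            }
            paths = {}
            for key, arr in stacks.items():
                p = out / f"{rec.patient_id}_{key}.nii.gz"
                write_volume(Volume(arr.astype(float)), p)
                paths[key] = p.name
            writer.writerow([rec.patient_id, rec.label, len(rec.slices),
                             paths["t1ce"], paths["flair"], paths["mask"]])
    return manifest


def read_cohort(manifest: str | Path) -> list[PatientRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    from .io_preprocess import read_volume

    manifest = Path(manifest)
    records = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            base = manifest.parent
            t1 = read_volume(base / row["t1ce"]).voxels
            fl = read_volume(base / row["flair"]).voxels
            mk = read_volume(base / row["mask"]).voxels > 0.5
            slices = [(SliceImage(t1[i], Modality.T1CE), SliceImage(fl[i], Modality.FLAIR))
                      for i in range(t1.shape[0])]
            masks = [mk[i] for i in range(mk.shape[0])]
            records.append(PatientRecord(row["patient_id"], row["label"], slices, masks))
    return records
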