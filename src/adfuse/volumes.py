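"""Volume I/O, intensity normalization, and synthetic paired-modality cohorts.

The package operates on pairs of co-registered 3D brain volumes per subject —
one structural MRI channel and one FDG-PET channel — already preprocessed to a
common grid (the canonical working size is 64x64x64).  Registration,
segmentation, bias-field correction and smoothing are upstream concerns; this
module only reads/writes NIfTI, rescales intensities to [0, 1], block-averages
down to a working grid, and simulates cohorts with a planted focal lesion for
testing and calibration.

The lesion model is a sphere in which intensity is multiplicatively reduced,
with a 1-voxel Gaussian falloff at the boundary so the planted signal looks
like regional atrophy (sMRI) or hypometabolism (PET) rather than a hard box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Volume", "Subject", "SyntheticConfig", "normalize_minmax",
    "normalize_subject", "read_volume", "write_volume", "downsample_volume",
    "generate_cohort", "save_cohort", "load_cohort", "LABELS",
    "DegenerateVolumeError",
]

LABELS = ("CN", "AD")  # index = integer class label; AD is the positive class


class DegenerateVolumeError(ValueError):
    """Raised when an operation cannot be applied to a constant volume."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with a voxel-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires 3D data, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_mm(self, ijk) -> np.ndarray:
        """Map a voxel index to millimetre coordinates through the affine."""
        ijk1 = np.append(np.asarray(ijk, dtype=float), 1.0)
        return (self.affine @ ijk1)[:3]


@dataclass
class Subject:
    """One study participant: co-registered sMRI and PET volumes plus a label."""

    subject_id: str
    smri: Volume
    pet: Volume
    label: str  # "AD" or "CN"

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.smri.shape != self.pet.shape:
            raise ValueError(
                f"modalities must be co-registered to the same grid: "
                f"sMRI {self.smri.shape} vs PET {self.pet.shape}")

    @property
    def y(self) -> int:
        return LABELS.index(self.label)


def normalize_minmax(vol: Volume) -> Volume:
    """Rescale intensities to [0, 1] by the volume's min and max.

    z = (x - min(x)) / (max(x) - min(x)); the transform is monotone, so the
    ordering of voxel values is preserved.  A constant volume has no dynamic
    range and raises :class:`DegenerateVolumeError` rather than emitting NaNs.
    """
    x = np.asarray(vol.data, dtype=np.float32)
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        raise DegenerateVolumeError(
            f"cannot min-max normalize a constant volume (value={lo})")
    return Volume((x - lo) / (hi - lo), vol.affine.copy())


def normalize_subject(smri: Volume, pet: Volume, pooled: bool = False
                      ) -> tuple[Volume, Volume]:
    """Normalize a subject's two modalities to [0, 1].

    By default each modality is rescaled by its own min/max.  With
    ``pooled=True`` a single min/max pooled over both volumes is used, so the
    two modalities keep their relative intensity scale.
    """
    if not pooled:
        return normalize_minmax(smri), normalize_minmax(pet)
    lo = min(float(smri.data.min()), float(pet.data.min()))
    hi = max(float(smri.data.max()), float(pet.data.max()))
    if hi == lo:
        raise DegenerateVolumeError("cannot normalize: both volumes are constant")
    scale = 1.0 / (hi - lo)
    return (Volume((smri.data - lo) * scale, smri.affine.copy()),
            Volume((pet.data - lo) * scale, pet.affine.copy()))


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (.nii / .nii.gz) file into a :class:`Volume`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
    except Exception as exc:  # nibabel raises a zoo of types
        raise IOError(f"could not read NIfTI volume from {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine if img.affine is not None else np.eye(4)
    return Volume(data, affine)


def write_volume(vol: Volume, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))


def downsample_volume(vol: Volume, target: tuple[int, int, int]) -> Volume:
    """Block-mean resample to ``target``; each target dim must divide the source.

    Averaging preserves the intensity range within [min, max] of the source.
    The affine is scaled so voxel-to-mm coordinates stay consistent.
    """
    src = vol.data.shape
    if any(t > s for t, s in zip(target, src)):
        raise ValueError(f"cannot upsample: target {target} exceeds source {src}")
    if any(s % t for s, t in zip(src, target)):
        raise ValueError(
            f"block-mean downsampling requires target dims to divide source "
            f"dims; got {src} -> {target}")
    fx, fy, fz = (s // t for s, t in zip(src, target))
    x = np.asarray(vol.data, dtype=np.float32)
    blocks = x.reshape(target[0], fx, target[1], fy, target[2], fz)
    out = blocks.mean(axis=(1, 3, 5))
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag([fx, fy, fz])
    return Volume(out, affine)


@dataclass
class SyntheticConfig:
    """Parameters of the simulated paired-modality cohort.

    Defaults mirror the reference study population: 88 AD and 122 CN subjects
    on a 64^3 grid.  The lesion is a sphere of radius ``lesion_radius`` voxels
    centred at ``lesion_center`` (default: a medial, slightly inferior-anterior
    offset from the grid centre, i.e. a medial-temporal-lobe analogue) in which
    intensity is reduced by the fraction ``effect_size`` in AD subjects, in
    both modalities.
    """

    n_ad: int = 88
    n_cn: int = 122
    grid: int = 64
    lesion_center: tuple[int, int, int] | None = None
    lesion_radius: int | None = None
    effect_size: float = 0.3
    noise_sd: float = 0.1
    subject_sd: float = 0.1
    seed: int = 0

    def resolved(self) -> "SyntheticConfig":
        g = self.grid
        center = self.lesion_center
        radius = self.lesion_radius
        if radius is None:
            radius = max(2, g // 6)
        if center is None:
            center = (g // 2 - g // 8, g // 2, g // 2 - g // 10)
        cfg = replace(self, lesion_center=tuple(int(c) for c in center),
                      lesion_radius=int(radius))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.n_ad < 0 or self.n_cn < 0 or self.grid < 4:
            raise ValueError("invalid cohort sizes or grid")
        c, r = self.lesion_center, self.lesion_radius
        if any(ci - r < 0 or ci + r >= self.grid for ci in c):
            raise ValueError(
                f"lesion sphere (center {c}, radius {r}) extends outside the "
                f"{self.grid}^3 grid")


def _brain_support(grid: int) -> np.ndarray:
    """Smooth ellipsoidal 'brain' support in [0, 1], shared by all subjects."""
    g = grid
    idx = np.indices((g, g, g), dtype=np.float32)
    center = (g - 1) / 2.0
    radii = np.array([0.40, 0.34, 0.38], dtype=np.float32) * g
    dist2 = sum(((idx[a] - center) / radii[a]) ** 2 for a in range(3))
    mask = (dist2 <= 1.0).astype(np.float32)
    return gaussian_filter(mask, sigma=max(1.0, g / 32.0))


def _lesion_field(cfg: SyntheticConfig) -> np.ndarray:
    """Soft spherical lesion indicator in [0, 1] (1 = fully lesioned)."""
    g = cfg.grid
    idx = np.indices((g, g, g), dtype=np.float32)
    c = np.asarray(cfg.lesion_center, dtype=np.float32)
    dist = np.sqrt(sum((idx[a] - c[a]) ** 2 for a in range(3)))
    hard = (dist <= cfg.lesion_radius).astype(np.float32)
    return gaussian_filter(hard, sigma=1.0)  # 1-voxel boundary falloff


_MODALITY_BASE = {"smri": 0.85, "pet": 0.70}


def generate_cohort(cfg: SyntheticConfig) -> list[Subject]:
    """Simulate a labelled cohort of co-registered sMRI/PET pairs.

    Each subject is the shared brain support scaled by a per-subject global
    intensity jitter, with independent voxel noise per modality; AD subjects
    additionally have intensities inside the lesion sphere reduced by
    ``effect_size`` in both modalities.  Volumes are min-max normalized to
    [0, 1].  The cohort is a pure function of ``cfg.seed``.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    support = _brain_support(cfg.grid)
    lesion = _lesion_field(cfg)
    subjects: list[Subject] = []
    labels = ["AD"] * cfg.n_ad + ["CN"] * cfg.n_cn
    for i, label in enumerate(labels):
        jitter = 1.0 + cfg.subject_sd * rng.standard_normal()
        jitter = max(jitter, 0.2)
        vols = {}
        for modality in ("smri", "pet"):
            base = _MODALITY_BASE[modality] * jitter * support
            if label == "AD" and cfg.effect_size > 0:
                base = base * (1.0 - cfg.effect_size * lesion)
            noisy = base + cfg.noise_sd * rng.standard_normal(base.shape).astype(
                np.float32)
            vols[modality] = normalize_minmax(Volume(noisy.astype(np.float32)))
        subjects.append(Subject(subject_id=f"sub-{i:04d}", smri=vols["smri"],
                                pet=vols["pet"], label=label))
    return subjects


def save_cohort(subjects: list[Subject], out_dir: str | Path) -> Path:
    """Write each volume as NIfTI plus a manifest CSV; returns the manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        smri_path = out_dir / f"{s.subject_id}_smri.nii.gz"
        pet_path = out_dir / f"{s.subject_id}_pet.nii.gz"
        write_volume(s.smri, smri_path)
        write_volume(s.pet, pet_path)
        rows.append({"subject_id": s.subject_id, "smri_path": smri_path.name,
                     "pet_path": pet_path.name, "label": s.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest: str | Path) -> list[Subject]:
    """Load a cohort from a manifest CSV (paths relative to the manifest)."""
    import pandas as pd

    manifest = Path(manifest)
    root = manifest.parent
    df = pd.read_csv(manifest)
    subjects = []
    for _, row in df.iterrows():
        subjects.append(Subject(
            subject_id=str(row["subject_id"]),
            smri=read_volume(root / row["smri_path"]),
            pet=read_volume(root / row["pet_path"]),
            label=str(row["label"]),
        ))
    return subjects
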