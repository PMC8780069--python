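"""Dataset loading and synthetic MRI-like phantom generation.

Two public layouts are supported: a class-per-subfolder tree of JPEG/PNG
slices (the Kaggle four-class layout), and a directory of MATLAB container
files each holding one slice and an integer label in {1, 2, 3} (the Figshare
three-class dialect, struct ``cjdata`` with ``label`` and ``image`` fields;
both the legacy and the HDF5-based container versions are read).

The phantom generator produces seeded 224×224 brain-like slices so the whole
pipeline builds and tests offline: an elliptical skull/brain mask with smooth
intensity texture plus Gaussian noise, and for tumor classes a superellipse
lesion whose location prior, size range, contrast and edge sharpness are
class-specific.  Class 0 has no lesion.  The classes are learnable but
overlap in appearance; they emulate the geometry of MRI slices, not their
acquisition physics (no bias fields, no partial-volume effects, no scanner
variation), so a model that separates phantoms is shown to exploit
lesion-locality signal, not to be clinically validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import io as sio
from scipy import ndimage

__all__ = ["DatasetIndex", "PhantomConfig", "load_folder_dataset",
           "load_mat_dataset", "generate_phantoms", "write_phantom_tree",
           "index_to_arrays", "PHANTOM_CLASS_NAMES"]

IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".bmp", ".tif", ".tiff"}
PHANTOM_CLASS_NAMES = ("normal", "focal_small", "central_mass", "diffuse_large")


@dataclass
class DatasetIndex:
    """records: list of (Path or 2-D uint8 array, class id)."""
    records: list
    class_names: list

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([cid for _, cid in self.records], dtype=int)


def _load_gray(source, size: int | None) -> np.ndarray:
    if isinstance(source, (str, Path)):
        with Image.open(source) as im:
            img = im.convert("L")
            if size is not None:
                img = img.resize((size, size), Image.BILINEAR)
            return np.asarray(img, dtype=np.uint8)
    arr = np.asarray(source)
    if size is not None and arr.shape != (size, size):
        img = Image.fromarray(arr.astype(np.uint8)).resize((size, size),
                                                           Image.BILINEAR)
        arr = np.asarray(img)
    return arr.astype(np.uint8)


def index_to_arrays(index: DatasetIndex, size: int = 224):
    """Materialize an index as ((N, 1, size, size) uint8, (N,) labels)."""
    imgs = np.stack([_load_gray(src, size) for src, _ in index.records])
    return imgs[:, None, :, :], index.labels


# ------------------------------------------------------------------- loaders
def load_folder_dataset(root) -> DatasetIndex:
    """Index a class-per-subfolder image tree, deterministically ordered.

    Undecodable files are skipped with a warning; an empty class directory is
    an error.  Heterogeneous resolutions are allowed and resized downstream.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    records, class_names = [], []
    for cid, d in enumerate(class_dirs):
        class_names.append(d.name)
        files = sorted(f for f in d.iterdir()
                       if f.suffix.lower() in IMAGE_SUFFIXES)
        kept = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as exc:
                warnings.warn(f"skipping undecodable image {f}: {exc}")
                continue
            records.append((f, cid))
            kept += 1
        if kept == 0:
            raise ValueError(f"class directory {d} holds no readable images")
    return DatasetIndex(records, class_names)


def _mat_record(path: Path):
    """Read (label, image) from one MATLAB container file, either dialect."""
    import h5py
    if h5py.is_hdf5(path):          # v7.3 containers are HDF5 files
        with h5py.File(path, "r") as f:
            grp = f["cjdata"] if "cjdata" in f else f
            if "label" not in grp or "image" not in grp:
                raise KeyError("no 'cjdata' struct or 'label'/'image' entries")
            # HDF5 stores MATLAB arrays transposed
            return int(np.squeeze(grp["label"][()])), np.asarray(grp["image"][()]).T
    mat = sio.loadmat(path)
    if "cjdata" in mat:
        rec = mat["cjdata"][0, 0]
        return int(np.squeeze(rec["label"])), np.asarray(rec["image"])
    if "label" in mat and "image" in mat:
        return int(np.squeeze(mat["label"])), np.asarray(mat["image"])
    raise KeyError("no 'cjdata' struct or 'label'/'image' entries")


def load_mat_dataset(directory) -> DatasetIndex:
    """Index a directory of per-slice .mat files; labels {1,2,3} are remapped
    to dense 0-based ids in sorted label order."""
    directory = Path(directory)
    files = sorted(directory.glob("*.mat"))
    if not files:
        raise ValueError(f"no .mat files under {directory}")
    raw = []
    for f in files:
        try:
            label, image = _mat_record(f)
        except Exception as exc:
            raise ValueError(f"cannot read {f}: {exc}") from exc
        if image.ndim != 2:
            raise ValueError(f"{f}: image must be 2-D, got shape {image.shape}")
        raw.append((image, label))
    labels = sorted({lab for _, lab in raw})
    remap = {lab: i for i, lab in enumerate(labels)}
    records = [(img, remap[lab]) for img, lab in raw]
    return DatasetIndex(records, [f"class_{lab}" for lab in labels])


# ------------------------------------------------------------------- phantoms
@dataclass
class PhantomConfig:
    n_per_class: int = 100
    n_classes: int = 4
    image_size: int = 224
    noise_sd: float = 6.0          # grey levels, on the 0–255 scale
    seed: int = 0

    def validate(self) -> "PhantomConfig":
        if self.n_classes not in (2, 3, 4):
            raise ValueError("n_classes must be 2, 3 or 4")
        if self.n_per_class < 1 or self.image_size < 32 or self.noise_sd < 0:
            raise ValueError("invalid phantom configuration")
        return self


# per tumor class: center prior (fractions of size), radius range (fraction),
# intensity contrast (grey levels, sign = hyper/hypo), edge blur sigma (px at 224)
_LESION_SPEC = {
    1: {"cx": (0.32, 0.42), "cy": (0.30, 0.40), "r": (0.045, 0.075),
        "contrast": 70.0, "blur": 1.0},
    2: {"cx": (0.45, 0.55), "cy": (0.45, 0.55), "r": (0.07, 0.11),
        "contrast": 95.0, "blur": 2.0},
    3: {"cx": (0.58, 0.68), "cy": (0.60, 0.70), "r": (0.09, 0.14),
        "contrast": -60.0, "blur": 4.0},
}


def _superellipse(size, cx, cy, rx, ry, power, theta):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x, y = xx - cx, yy - cy
    xr = np.cos(theta) * x + np.sin(theta) * y
    yr = -np.sin(theta) * x + np.cos(theta) * y
    return (np.abs(xr / rx) ** power + np.abs(yr / ry) ** power) <= 1.0


def _phantom_image(cls: int, size: int, noise_sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    s = size
    cx, cy = s / 2 + rng.uniform(-0.02, 0.02) * s, s / 2 + rng.uniform(-0.02, 0.02) * s
    rx = s * rng.uniform(0.40, 0.44)
    ry = s * rng.uniform(0.34, 0.38)
    skull = _superellipse(s, cx, cy, rx, ry, 2.0, rng.uniform(-0.15, 0.15))
    brain = _superellipse(s, cx, cy, rx * 0.93, ry * 0.93, 2.0, 0.0)

    img = np.zeros((s, s), dtype=np.float64)
    img[skull] = 220.0                       # bright skull rim
    # texture amplitude is kept below the lesion contrasts (contrast-enhanced
    # regime) so the classes are learnable at desk scale yet still overlap
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (s, s)), s / 18.0)
    texture *= 15.0 / max(texture.std(), 1e-9)
    img[brain] = 120.0 + texture[brain]
    # darker ventricle-like core common to every class
    vent = _superellipse(s, cx, cy + 0.02 * s, rx * 0.18, ry * 0.28, 2.0, 0.0)
    img[vent & brain] -= 35.0

    if cls > 0:
        spec = _LESION_SPEC[cls]
        lx = s * rng.uniform(*spec["cx"])
        ly = s * rng.uniform(*spec["cy"])
        r = s * rng.uniform(*spec["r"])
        ecc = rng.uniform(0.7, 1.3)
        power = rng.uniform(1.8, 3.0)        # superellipse squareness
        blob = _superellipse(s, lx, ly, r * ecc, r / ecc, power,
                             rng.uniform(0, np.pi))
        blob &= brain
        lesion = blob.astype(np.float64) * spec["contrast"]
        lesion = ndimage.gaussian_filter(lesion, spec["blur"] * s / 224.0)
        img += lesion

    img += rng.normal(0.0, noise_sd, (s, s))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_phantoms(cfg: PhantomConfig) -> DatasetIndex:
    """Seeded in-memory phantom dataset with ``n_per_class`` images per class."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records = []
    for cls in range(cfg.n_classes):
        for _ in range(cfg.n_per_class):
            records.append((_phantom_image(cls, cfg.image_size, cfg.noise_sd,
                                           rng), cls))
    return DatasetIndex(records, list(PHANTOM_CLASS_NAMES[:cfg.n_classes]))


def write_phantom_tree(index: DatasetIndex, out_dir) -> Path:
    """Write an index as root/<class_name>/<id>.png, consumable by
    load_folder_dataset."""
    out_dir = Path(out_dir)
    counters = {}
    for img, cid in index.records:
        name = index.class_names[cid]
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(cid, 0)
        counters[cid] = i + 1
        Image.fromarray(np.asarray(img)).save(d / f"{i:05d}.png")
    return out_dir
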