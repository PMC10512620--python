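"""Tile I/O, preprocessing, label manifests, splits, and a synthetic
H&E-like tile generator for fully offline training and testing.

HER2 labels are the four immunohistochemistry scores ``0, 1+, 2+, 3+``;
they are serialized as those strings in manifests and encoded 0..3 in
memory (the fixed mapping is :data:`LABELS`).

The synthetic generator does **not** attempt histological realism.  It
emulates just the statistical structure the classifier needs: four
separable texture classes at tile scale, built from a class-dependent
eosin/hematoxylin colour mixture with nucleus-like dark blobs whose
density increases with the HER2 class, plus Gaussian pixel noise.  A seed
makes the dataset bitwise-reproducible.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError

__all__ = [
    "LABELS", "LABEL_TO_INDEX", "TileRecord", "SynthConfig",
    "preprocess_tile", "load_manifest", "save_manifest",
    "generate_synthetic_tiles", "write_tiles", "split_dataset",
    "partition_by_split", "load_tile_image",
]

LABELS = ("0", "1+", "2+", "3+")
LABEL_TO_INDEX = {s: i for i, s in enumerate(LABELS)}

#: ImageNet-style channel statistics used by default for normalization.
DEFAULT_MEAN = (0.485, 0.456, 0.406)
DEFAULT_STD = (0.229, 0.224, 0.225)


@dataclass
class TileRecord:
    """One tile: pixels (or a path to them) plus its HER2 class 0..3."""

    id: str
    label: int
    image: np.ndarray | None = None   # (H, W, 3) uint8 or float
    path: str | None = None
    split: str | None = None

    def __post_init__(self):
        if not 0 <= int(self.label) < len(LABELS):
            raise ValueError(f"label must be in [0, {len(LABELS)}), got {self.label}")
        if self.image is None and self.path is None:
            raise ValueError("a TileRecord needs pixels or a file path")

    @property
    def label_name(self) -> str:
        return LABELS[self.label]


@dataclass
class SynthConfig:
    """Parameters of the synthetic four-class tile generator.

    ``blob_density_by_class`` is the expected nucleus-like blob count per
    tile for classes 0..3; ``stain_mix_by_class`` is the hematoxylin
    fraction of the background colour mixture (0 = pure eosin pink,
    1 = pure hematoxylin purple).  Defaults give four well-separated
    classes whose blob-pixel fraction and mean colour are both monotone
    in the class index.
    """

    n_per_class: int = 50
    size: int = 96
    blob_density_by_class: tuple = (5, 15, 30, 60)
    stain_mix_by_class: tuple = (0.15, 0.35, 0.60, 0.85)
    noise_sd: float = 0.02
    seed: int = 0
    blob_radius_frac: float = 0.035   # blob radius as fraction of tile size

    def __post_init__(self):
        if self.size < 32:
            raise ConfigError("tile size must be >= 32")
        if len(self.blob_density_by_class) != 4 or len(self.stain_mix_by_class) != 4:
            raise ConfigError("per-class parameter tuples must have 4 entries")
        if any(d < 0 for d in self.blob_density_by_class):
            raise ConfigError("blob densities must be non-negative")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_tile(image: np.ndarray, target: int = 299, *,
                    normalize: bool = False,
                    mean=DEFAULT_MEAN, std=DEFAULT_STD) -> np.ndarray:
    """Resize to ``target`` x ``target`` (bilinear), scale to [0, 1], and
    optionally standardize per channel.  Returns float32 (H, W, 3).

    Resizing an already target-sized tile is the identity, so the
    operation is idempotent at target size.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
    if min(image.shape[:2]) < 32:
        raise ValueError("image too small; minimum dimension is 32")

    if np.issubdtype(image.dtype, np.floating):
        arr01 = image.astype(np.float32)
    else:
        arr01 = image.astype(np.float32) / 255.0

    if image.shape[0] != target or image.shape[1] != target:
        pil = Image.fromarray(np.clip(arr01 * 255.0, 0, 255).astype(np.uint8))
        pil = pil.resize((target, target), Image.BILINEAR)
        arr01 = np.asarray(pil, dtype=np.float32) / 255.0

    if normalize:
        arr01 = (arr01 - np.asarray(mean, dtype=np.float32)) \
            / np.asarray(std, dtype=np.float32)
    return arr01


def load_tile_image(record: TileRecord) -> np.ndarray:
    """Pixels of a record, reading from disk if needed."""
    if record.image is not None:
        return record.image
    if not os.path.exists(record.path):
        raise FileNotFoundError(f"tile {record.id}: missing file {record.path}")
    return np.asarray(Image.open(record.path).convert("RGB"))


def records_to_arrays(records, input_size: int, *, normalize: bool = False):
    """Stack records into (N, 3, S, S) float32 and label vector (N,)."""
    xs = np.stack([
        preprocess_tile(load_tile_image(r), input_size, normalize=normalize)
        .transpose(2, 0, 1)
        for r in records
    ])
    ys = np.array([r.label for r in records], dtype=np.int64)
    return xs, ys


# ---------------------------------------------------------------------------
# manifests

def load_manifest(path, *, check_files: bool = True) -> list[TileRecord]:
    """Read a CSV manifest with columns id, filepath, label[, split].

    Labels must be the strings "0", "1+", "2+", "3+"; unknown labels,
    duplicate ids and (optionally) missing files are rejected with the
    offending row number.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"manifest {path} is empty", stacklevel=2)
        return []
    required = {"id", "filepath", "label"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    records = []
    seen = {}
    base = os.path.dirname(os.fspath(path))
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        label = str(row.label).strip()
        if label not in LABEL_TO_INDEX:
            raise ValueError(
                f"manifest row {i}: unknown label {label!r} "
                f"(expected one of {LABELS})")
        if row.id in seen:
            raise ValueError(
                f"manifest row {i}: duplicate id {row.id!r} (first at row {seen[row.id]})")
        seen[row.id] = i
        fp = row.filepath
        if not os.path.isabs(fp):
            fp = os.path.join(base, fp)
        if check_files and not os.path.exists(fp):
            raise FileNotFoundError(f"manifest row {i}: missing file {fp}")
        split = getattr(row, "split", None)
        records.append(TileRecord(id=row.id, label=LABEL_TO_INDEX[label],
                                  path=fp, split=split))
    if not records:
        warnings.warn(f"manifest {path} is empty", stacklevel=2)
    return records


def save_manifest(records, path, *, relative_to=None):
    rows = []
    for r in records:
        fp = r.path or ""
        if relative_to is not None and fp:
            fp = os.path.relpath(fp, relative_to)
        row = {"id": r.id, "filepath": fp, "label": r.label_name}
        if r.split is not None:
            row["split"] = r.split
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic tiles

# RGB anchors of the colour mixture (values in [0, 1])
_EOSIN = np.array([0.92, 0.65, 0.75])        # cytoplasm pink
_HEMATOXYLIN = np.array([0.48, 0.38, 0.68])  # nuclear blue-purple
_BLOB = np.array([0.30, 0.20, 0.48])         # dense chromatin


def _render_tile(rng: np.random.Generator, cfg: SynthConfig, cls: int) -> np.ndarray:
    s = cfg.size
    mix = cfg.stain_mix_by_class[cls]
    background = (1 - mix) * _EOSIN + mix * _HEMATOXYLIN
    img = np.broadcast_to(background, (s, s, 3)).copy()

    n_blobs = rng.poisson(cfg.blob_density_by_class[cls])
    radius = max(1.5, cfg.blob_radius_frac * s)
    yy, xx = np.mgrid[0:s, 0:s]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, s, 2)
        r = radius * rng.uniform(0.7, 1.3)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        depth = rng.uniform(0.6, 1.0)
        img[mask] = (1 - depth) * img[mask] + depth * _BLOB

    img = img + rng.normal(0.0, cfg.noise_sd, (s, s, 3))
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_synthetic_tiles(cfg: SynthConfig) -> list[TileRecord]:
    """Exactly ``4 * n_per_class`` tiles, classes interleaved, bitwise
    reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_per_class):
        for cls in range(4):
            img = _render_tile(rng, cfg, cls)
            records.append(TileRecord(
                id=f"synth-{LABELS[cls]}-{i:04d}", label=cls, image=img))
    return records


def write_tiles(records, out_dir, *, manifest_name="manifest.csv") -> str:
    """Write tiles as PNGs plus a manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for r in records:
        img = load_tile_image(r)
        if np.issubdtype(np.asarray(img).dtype, np.floating):
            img = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
        path = os.path.join(out_dir, f"{r.id}.png")
        Image.fromarray(img).save(path)
        written.append(TileRecord(id=r.id, label=r.label, path=path,
                                  split=r.split))
    manifest = os.path.join(out_dir, manifest_name)
    save_manifest(written, manifest, relative_to=out_dir)
    return manifest


# ---------------------------------------------------------------------------
# splitting

def split_dataset(records, fractions=(0.8, 0.2), seed: int = 0):
    """Stratified, seeded, disjoint and exhaustive split into len(fractions)
    parts (returned in order, e.g. train/test for two fractions)."""
    fractions = tuple(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_parts = len(fractions)
    rng = np.random.default_rng(seed)
    by_class: dict[int, list] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)
    parts = [[] for _ in range(n_parts)]
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) < n_parts:
            raise ValueError(
                f"class {LABELS[cls]} has {len(members)} records, fewer than "
                f"{n_parts} splits")
        order = rng.permutation(len(members))
        # largest-remainder apportionment keeps the split exhaustive
        quotas = [f * len(members) for f in fractions]
        counts = [int(q) for q in quotas]
        remainder = len(members) - sum(counts)
        by_frac = sorted(range(n_parts), key=lambda i: quotas[i] - counts[i],
                         reverse=True)
        for i in range(remainder):
            counts[by_frac[i]] += 1
        counts = [max(c, 1) for c in counts]
        while sum(counts) > len(members):          # min-1 may overfill
            counts[int(np.argmax(counts))] -= 1
        start = 0
        for part, c in zip(parts, counts):
            part.extend(members[i] for i in order[start:start + c])
            start += c
    return tuple(parts)


def partition_by_split(records):
    """Honor a predefined split column: returns (train, test)."""
    train = [r for r in records if (r.split or "train") == "train"]
    test = [r for r in records if r.split == "test"]
    return train, test
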