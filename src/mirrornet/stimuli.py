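"""Synthetic stimulus families for pixel-level bilateral-symmetry experiments.

All stimuli are 20x20 grids of 8-bit gray levels. An image is *symmetric*
when its left flank equals the column-reversed right flank exactly; an
uninformative central band (constant gray 128) of configurable even width can
separate the flanks, and "Stripe" images reduce each flank to a single
informative column at a configurable distance from the vertical midline.

Conventions
-----------
* Columns are 0-based, left to right; the midline of the 20-wide grid lies
  between columns 9 and 10.
* A band of width ``b`` occupies the half-open column interval
  ``[10 - b/2, 10 + b/2)``.
* Normal-brightness flank pixels are uniform integers on ``[1, 255]``;
  dark-family flank pixels are uniform integers on ``[0, 128]``.
* A stripe at position ``x`` occupies columns ``x`` and ``19 - x`` (the
  mirror pair of ``x``), so ``x = 10`` gives the pair adjacent to the
  midline and ``x = 2`` the pair nearest the image edges.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import InvalidDataError, InvalidSpecError

IMAGE_SIZE = 20
BAND_VALUE = 128
#: Band widths used in the study: {0, 4} for training, the rest for testing.
STUDY_BAND_SIZES = (0, 2, 4, 6, 14, 16, 18)
#: Stripe positions; distance from the midline is ``10 - x`` pixels.
STRIPE_POSITIONS = (2, 4, 6, 8, 10)

_KINDS = ("band", "stripe", "mirrored")
_BRIGHTNESS = ("normal", "dark")


def _check_band_size(band_size: int) -> int:
    if band_size != int(band_size) or band_size % 2 != 0 or not 0 <= band_size <= 18:
        raise InvalidSpecError(
            f"band_size must be an even integer in [0, 18], got {band_size!r}"
        )
    return int(band_size)


@dataclass(frozen=True)
class FamilySpec:
    """Metadata defining one image family.

    Parameters
    ----------
    kind : {"band", "stripe", "mirrored"}
    band_size : even int in [0, 18], band kind only
    brightness : {"normal", "dark"}
    stripe_x : int in {2, 4, 6, 8, 10}, stripe kind only
    symmetric : bool or None
        Class label of the family; ``None`` for a family holding both classes.
    """

    kind: str
    band_size: int | None = None
    brightness: str = "normal"
    stripe_x: int | None = None
    symmetric: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidSpecError(f"unknown family kind {self.kind!r}")
        if self.brightness not in _BRIGHTNESS:
            raise InvalidSpecError(f"unknown brightness {self.brightness!r}")
        if self.kind == "band":
            if self.band_size is None:
                raise InvalidSpecError("band families require band_size")
            _check_band_size(self.band_size)
            if self.stripe_x is not None:
                raise InvalidSpecError("stripe_x is only defined for stripe families")
        elif self.kind == "stripe":
            if self.stripe_x not in STRIPE_POSITIONS:
                raise InvalidSpecError(
                    f"stripe_x must be one of {STRIPE_POSITIONS}, got {self.stripe_x!r}"
                )
            if self.band_size is not None:
                raise InvalidSpecError("band_size is only defined for band families")
        else:  # mirrored
            if self.band_size is not None or self.stripe_x is not None:
                raise InvalidSpecError(
                    "mirrored families take neither band_size nor stripe_x"
                )

    @property
    def name(self) -> str:
        """Short human-readable family identifier, e.g. ``band4dark``."""
        if self.kind == "band":
            base = f"band{self.band_size}"
            if self.brightness == "dark":
                base += "dark"
        elif self.kind == "stripe":
            base = f"stripe{self.stripe_x}"
        else:
            base = "mirrored"
        if self.symmetric is True:
            base += "_sym"
        elif self.symmetric is False:
            base += "_nonsym"
        return base

    @property
    def oracle_band_size(self) -> int:
        """Band width to exclude when testing flank symmetry (0 for non-band)."""
        return self.band_size if self.kind == "band" else 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FamilySpec":
        return cls(**d)


@dataclass
class DatasetFamily:
    """A generated family: ``n`` images, balanced labels, and its seed."""

    spec: FamilySpec
    images: np.ndarray  # (n, 20, 20) uint8
    labels: np.ndarray  # (n,) int, 1 = symmetric
    seed: int

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class SplitCorpus:
    """Training pool partitioned into disjoint train/validation splits."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    split_fraction: float
    #: band size of the family each training/validation image came from
    train_band_sizes: np.ndarray | None = None
    val_band_sizes: np.ndarray | None = None

    @property
    def n_total(self) -> int:
        return len(self.train_images) + len(self.val_images)


def _flank_values(rng: np.random.Generator, shape, brightness: str) -> np.ndarray:
    if brightness == "dark":
        return rng.integers(0, BAND_VALUE + 1, size=shape, dtype=np.uint8)
    return rng.integers(1, 256, size=shape, dtype=np.uint8)


def make_band_image(
    band_size: int,
    symmetric: bool,
    brightness: str = "normal",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate one Band image.

    The flanks are random gray levels; the central ``band_size`` columns are
    the constant 128. Symmetric images have the right flank equal to the
    column-reversed left flank.
    """
    band_size = _check_band_size(band_size)
    if brightness not in _BRIGHTNESS:
        raise InvalidSpecError(f"unknown brightness {brightness!r}")
    rng = np.random.default_rng() if rng is None else rng
    flank_w = (IMAGE_SIZE - band_size) // 2
    left = _flank_values(rng, (IMAGE_SIZE, flank_w), brightness)
    if symmetric:
        right = left[:, ::-1]
    else:
        right = _flank_values(rng, (IMAGE_SIZE, flank_w), brightness)
    band = np.full((IMAGE_SIZE, band_size), BAND_VALUE, dtype=np.uint8)
    return np.concatenate([left, band, right], axis=1)


def make_stripe_image(
    stripe_x: int,
    symmetric: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate one Stripe image: constant 128 except the column pair
    ``(x, 19 - x)``, which carries the only symmetry information."""
    if stripe_x not in STRIPE_POSITIONS:
        raise InvalidSpecError(
            f"stripe_x must be one of {STRIPE_POSITIONS}, got {stripe_x!r}"
        )
    rng = np.random.default_rng() if rng is None else rng
    img = np.full((IMAGE_SIZE, IMAGE_SIZE), BAND_VALUE, dtype=np.uint8)
    left_col = _flank_values(rng, (IMAGE_SIZE,), "normal")
    right_col = left_col if symmetric else _flank_values(rng, (IMAGE_SIZE,), "normal")
    img[:, stripe_x] = left_col
    img[:, IMAGE_SIZE - 1 - stripe_x] = right_col
    return img


def mirror_image(img: np.ndarray) -> np.ndarray:
    """Replace the right half of ``img`` by the mirrored left half."""
    img = np.asarray(img)
    if img.shape[-1] % 2 != 0:
        raise InvalidSpecError("mirror_image requires an even number of columns")
    half = img.shape[-1] // 2
    out = img.copy()
    out[..., half:] = np.flip(out[..., :half], axis=-1)
    return out


def upscale_blocks(img: np.ndarray, block_px: int) -> np.ndarray:
    """Nearest-neighbour upscale: each logical pixel becomes a constant
    ``block_px`` x ``block_px`` tile."""
    if block_px != int(block_px) or block_px < 1:
        raise InvalidSpecError(f"block_px must be a positive integer, got {block_px!r}")
    return np.kron(img, np.ones((int(block_px), int(block_px)), dtype=img.dtype))


def oracle_classify(img: np.ndarray, band_size: int = 0) -> int:
    """Ground-truth symmetry test: 1 iff the left flank equals the
    column-reversed right flank exactly, band columns excluded."""
    band_size = _check_band_size(band_size)
    img = np.asarray(img)
    flank_w = (IMAGE_SIZE - band_size) // 2
    left = img[:, :flank_w]
    right = img[:, IMAGE_SIZE - flank_w :]
    return int(np.array_equal(left, right[:, ::-1]))


def _batch_flanks(images: np.ndarray, band_size: int):
    flank_w = (IMAGE_SIZE - band_size) // 2
    left = images[:, :, :flank_w]
    right = images[:, :, IMAGE_SIZE - flank_w :][:, :, ::-1]
    return left, right


def oracle_classify_batch(images: np.ndarray, band_size: int = 0) -> np.ndarray:
    """Vectorised :func:`oracle_classify` over an (n, 20, 20) stack."""
    left, right_flipped = _batch_flanks(np.asarray(images), _check_band_size(band_size))
    return np.all(left == right_flipped, axis=(1, 2)).astype(np.int64)


def _make_one(spec: FamilySpec, symmetric: bool, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "band":
        return make_band_image(spec.band_size, symmetric, spec.brightness, rng)
    if spec.kind == "stripe":
        return make_stripe_image(spec.stripe_x, symmetric, rng)
    # mirrored: start from full-field noise; symmetric members are mirrored
    base = _flank_values(rng, (IMAGE_SIZE, IMAGE_SIZE), spec.brightness)
    return mirror_image(base) if symmetric else base


def generate_family(spec: FamilySpec, n: int, seed: int) -> DatasetFamily:
    """Generate ``n`` images of one family, equally split between symmetric
    (label 1) and non-symmetric (label 0) samples; bit-reproducible per
    ``(spec, n, seed)``."""
    if n % 2 != 0 or n <= 0:
        raise InvalidSpecError(f"family size must be positive and even, got {n}")
    rng = np.random.default_rng(seed)
    half = n // 2
    images = np.empty((n, IMAGE_SIZE, IMAGE_SIZE), dtype=np.uint8)
    labels = np.concatenate([np.ones(half, np.int64), np.zeros(half, np.int64)])
    for i in range(half):
        images[i] = _make_one(spec, True, rng)
    for i in range(half, n):
        images[i] = _make_one(spec, False, rng)
    return DatasetFamily(spec=spec, images=images, labels=labels, seed=seed)


def generate_images(
    spec: FamilySpec, n: int, symmetric: bool, seed: int
) -> np.ndarray:
    """Generate ``n`` single-class images of a family (used by the RSA
    design, whose 16 cells are single-class)."""
    if n <= 0:
        raise InvalidSpecError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    out = np.empty((n, IMAGE_SIZE, IMAGE_SIZE), dtype=np.uint8)
    for i in range(n):
        out[i] = _make_one(spec, symmetric, rng)
    return out


def make_training_corpus(
    n_total: int, split_fraction: float = 0.05, seed: int = 0
) -> SplitCorpus:
    """Build the training corpus: equal parts band-size-0 and band-size-4
    images (each half balanced in class), shuffled and split into disjoint
    train/validation sets with ``split_fraction`` held out for validation."""
    if n_total % 4 != 0 or n_total <= 0:
        raise InvalidSpecError(
            f"n_total must be a positive multiple of 4, got {n_total}"
        )
    if not 0.0 < split_fraction < 1.0:
        raise InvalidSpecError("split_fraction must lie strictly between 0 and 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    per_family = n_total // 2
    fams = [
        generate_family(FamilySpec("band", band_size=b), per_family, cs)
        for b, cs in zip((0, 4), child_seeds[:2])
    ]
    images = np.concatenate([f.images for f in fams])
    labels = np.concatenate([f.labels for f in fams])
    band_sizes = np.concatenate(
        [np.full(per_family, f.spec.band_size, np.int64) for f in fams]
    )
    order = np.random.default_rng(child_seeds[2]).permutation(n_total)
    images, labels, band_sizes = images[order], labels[order], band_sizes[order]
    n_val = int(round(n_total * split_fraction))
    if not 0 < n_val < n_total:
        raise InvalidSpecError("split_fraction leaves an empty train or validation set")
    return SplitCorpus(
        train_images=images[n_val:],
        train_labels=labels[n_val:],
        val_images=images[:n_val],
        val_labels=labels[:n_val],
        split_fraction=split_fraction,
        train_band_sizes=band_sizes[n_val:],
        val_band_sizes=band_sizes[:n_val],
    )


# ---------------------------------------------------------------------------
# family archive I/O

def save_family(family: DatasetFamily, path: str | Path) -> Path:
    """Save a family as ``<path>.npz`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), images=family.images, labels=family.labels)
    sidecar = {
        "spec": family.spec.to_dict(),
        "n": len(family),
        "seed": family.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_family(path: str | Path) -> DatasetFamily:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        images, labels = data["images"], data["labels"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if len(images) != sidecar["n"]:
        raise InvalidDataError(f"archive {path} is inconsistent with its sidecar")
    return DatasetFamily(
        spec=FamilySpec.from_dict(sidecar["spec"]),
        images=images,
        labels=labels,
        seed=sidecar["seed"],
    )


def save_png(img: np.ndarray, path: str | Path, block_px: int = 1) -> None:
    """Export one stimulus as an 8-bit grayscale PNG (optionally upscaled)."""
    from PIL import Image

    Image.fromarray(upscale_blocks(np.asarray(img, np.uint8), block_px), mode="L").save(path)
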