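"""Miniature seeded fixtures and constructed ideal representations.

These make every downstream stage (evaluation, RSA, clustering, reporting)
testable in seconds without training a network: tiny families covering the
full 16-cell design, feature-coding "ideal" representations whose RDMs equal
the prototypical patterns exactly, and model-like test doubles (oracle,
chance, band detector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidSpecError
from .rsa import SMALL_BAND_THRESHOLD, RepresentationMatrix, design16
from .stimuli import (
    BAND_VALUE,
    FamilySpec,
    DatasetFamily,
    generate_family,
    generate_images,
    oracle_classify_batch,
)

IDEAL_REPRESENTATION_KINDS = (
    "symmetry",
    "band_presence",
    "brightness",
    "band_width",
    "symmetry_small_band",
)


@dataclass
class FixtureBundle:
    """Tiny design-covering families plus constructed representations."""

    families: dict[str, DatasetFamily]
    design_images: dict[int, np.ndarray]  # per design cell, single class
    seed: int
    per_family: int

    def representation(self, kind: str, per_family: int | None = None) -> RepresentationMatrix:
        """A representation matrix whose rows deterministically encode one
        family-level feature (so its RDM equals that feature's prototype)."""
        return ideal_representation(kind, per_family or self.per_family)


def _feature_code(spec: FamilySpec, kind: str) -> np.ndarray:
    """Unit-norm one-hot code of the requested feature for one design cell.

    Distinct feature values map to orthogonal codes, so the cosine distance
    between two images is exactly 0 (same value) or 1 (different value).
    """
    b = spec.band_size or 0
    if kind == "symmetry":
        v, dim = int(bool(spec.symmetric)), 2
    elif kind == "band_presence":
        v, dim = int(b > 0), 2
    elif kind == "brightness":
        v, dim = int(spec.brightness == "dark"), 2
    elif kind == "band_width":
        sizes = (0, 2, 4, 6, 14, 16, 18)
        v, dim = sizes.index(b), len(sizes)
    elif kind == "symmetry_small_band":
        # small-band cells code symmetry; all large-band cells share a code
        if b < SMALL_BAND_THRESHOLD:
            v, dim = int(bool(spec.symmetric)), 3
        else:
            v, dim = 2, 3
    else:
        raise InvalidSpecError(f"unknown ideal representation kind {kind!r}")
    out = np.zeros(dim)
    out[v] = 1.0
    return out


def ideal_representation(kind: str, per_family: int = 4) -> RepresentationMatrix:
    """Stack the feature code of every design cell, ``per_family`` rows each."""
    design = design16()
    feats = np.vstack(
        [np.tile(_feature_code(s, kind), (per_family, 1)) for s in design]
    )
    index = np.repeat(np.arange(len(design)), per_family)
    return RepresentationMatrix(features=feats, family_index=index, design=design)


def build_fixture_bundle(seed: int = 0, per_family: int = 8) -> FixtureBundle:
    """Generate the bundle: one tiny two-class family per study spec and
    one single-class image block per design cell; bit-reproducible."""
    if per_family % 2 != 0 or per_family <= 0:
        raise InvalidSpecError("per_family must be positive and even")
    ss = np.random.SeedSequence(seed)
    specs = [FamilySpec("band", band_size=b) for b in (0, 2, 4, 6, 14, 16, 18)]
    specs.append(FamilySpec("band", band_size=4, brightness="dark"))
    specs += [FamilySpec("stripe", stripe_x=x) for x in (2, 4, 6, 8, 10)]
    fam_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(specs) + 16)]
    families = {
        spec.name: generate_family(spec, per_family, s)
        for spec, s in zip(specs, fam_seeds[: len(specs)])
    }
    design_images = {
        i: generate_images(spec, per_family // 2, bool(spec.symmetric), s)
        for i, (spec, s) in enumerate(zip(design16(), fam_seeds[len(specs) :]))
    }
    return FixtureBundle(
        families=families, design_images=design_images, seed=seed, per_family=per_family
    )


def save_bundle(bundle: FixtureBundle, directory) -> None:
    """Write the bundle under a directory with a manifest (seeds, counts,
    content hash) so regeneration can be verified bit-exactly."""
    import hashlib
    import json
    from pathlib import Path

    from .stimuli import save_family

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256()
    for name in sorted(bundle.families):
        fam = bundle.families[name]
        save_family(fam, directory / name)
        digest.update(fam.images.tobytes())
    manifest = {
        "seed": bundle.seed,
        "per_family": bundle.per_family,
        "families": sorted(bundle.families),
        "sha256": digest.hexdigest(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# model-like test doubles


class _Predictor:
    is_recurrent = False

    def predict_proba(self, images) -> np.ndarray:
        p1 = self._p1(np.asarray(images))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, images) -> np.ndarray:
        return (self.predict_proba(images)[:, 1] > 0.5).astype(np.int64)


class OraclePredictor(_Predictor):
    """Wraps the exact mirror test; emits probability 0/1."""

    def __init__(self, band_size: int = 0):
        self.band_size = band_size

    def _p1(self, images):
        return oracle_classify_batch(images, self.band_size).astype(np.float64)


class ChancePredictor(_Predictor):
    """Always emits probability 0.5 (ties resolve to non-symmetric)."""

    def _p1(self, images):
        return np.full(len(images), 0.5)


class BandDetectorPredictor(_Predictor):
    """Predicts from band presence only: probability 1 when the two midline
    columns are the constant band value (uninformative of symmetry)."""

    def _p1(self, images):
        mid = images[:, :, 9:11]
        return np.all(mid == BAND_VALUE, axis=(1, 2)).astype(np.float64)


def make_ideal_predictor(kind: str, band_size: int = 0) -> _Predictor:
    """Build a test-double predictor: ``oracle``, ``chance``, or
    ``band_detector``."""
    if kind == "oracle":
        return OraclePredictor(band_size)
    if kind == "chance":
        return ChancePredictor()
    if kind == "band_detector":
        return BandDetectorPredictor()
    raise InvalidSpecError(f"unknown predictor kind {kind!r}")
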