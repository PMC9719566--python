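"""Representational similarity analysis.

Representations of the pre-readout activation layer are extracted for the
16-cell design (8 Band datasets x {symmetric, non-symmetric}), turned into a
cosine-distance representational dissimilarity matrix (RDM), and compared —
by Pearson correlation over unmasked upper-triangle cells — against six
prototypical RDMs describing perfect classifiers of single image features:

* ``symmetry1`` — dissimilar iff the two images differ in symmetry class;
* ``symmetry2`` — as ``symmetry1`` but agnostic about how non-symmetric
  images relate to each other (those cells are masked out);
* ``symmetry_small_band`` — symmetry-based only while both images have a
  small band; all large-band images collapse onto one representation;
* ``band_presence`` — dissimilar iff exactly one image has a band;
* ``brightness`` — dissimilar iff the brightness levels differ;
* ``band_width`` — dissimilar iff the band sizes differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .exceptions import InvalidDataError, InvalidSpecError, UndefinedStatisticError
from .stimuli import FamilySpec, generate_images

PROTOTYPE_KINDS = (
    "symmetry1",
    "symmetry2",
    "symmetry_small_band",
    "band_presence",
    "brightness",
    "band_width",
)

#: band widths below this are "small" for the symmetry_small_band prototype
SMALL_BAND_THRESHOLD = 14


def design16() -> list[FamilySpec]:
    """The canonical 16-family design: the 8 Band datasets, symmetric
    families first, then the non-symmetric ones, in band-size order."""
    cells = []
    for symmetric in (True, False):
        for b, bright in [(0, "normal"), (2, "normal"), (4, "normal"),
                          (4, "dark"), (6, "normal"), (14, "normal"),
                          (16, "normal"), (18, "normal")]:
            cells.append(
                FamilySpec("band", band_size=b, brightness=bright, symmetric=symmetric)
            )
    return cells


@dataclass
class RepresentationMatrix:
    """n x d feature matrix with a per-row family index into the design."""

    features: np.ndarray
    family_index: np.ndarray  # (n,) ints in [0, len(design))
    design: list[FamilySpec]

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class RDMatrix:
    """Square dissimilarity matrix in [0, 1] with family-block metadata and
    the min/max used for rescaling (so the raw distances are recoverable)."""

    values: np.ndarray
    family_index: np.ndarray
    design: list[FamilySpec]
    rescale_min: float = 0.0
    rescale_max: float = 1.0


@dataclass
class PrototypeRDM:
    """Block-level 0/1 dissimilarity pattern with an exclusion mask."""

    kind: str
    values: np.ndarray  # (16, 16) in {0, 1}
    mask: np.ndarray  # (16, 16) bool, True = excluded from correlations
    design: list[FamilySpec] = field(default_factory=design16)


def extract_representations(
    model, per_family: int = 500, seed: int = 0, design: list[FamilySpec] | None = None
) -> RepresentationMatrix:
    """Pre-readout activation vectors for ``per_family`` images of each
    design cell (the recurrent net contributes the final-step last-cell
    hidden state, the dilated net its last ReLU layer)."""
    if not hasattr(model, "representations"):
        raise InvalidSpecError("model does not expose representations()")
    design = design16() if design is None else design
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(design))]
    feats, index = [], []
    for i, (spec, s) in enumerate(zip(design, seeds)):
        imgs = generate_images(spec, per_family, bool(spec.symmetric), s)
        feats.append(np.asarray(model.representations(imgs), dtype=np.float64))
        index.append(np.full(per_family, i, dtype=np.int64))
    return RepresentationMatrix(
        features=np.vstack(feats), family_index=np.concatenate(index), design=design
    )


def compute_rdm(reps: RepresentationMatrix) -> RDMatrix:
    """Pairwise cosine distances, min-max rescaled over off-diagonal entries
    to [0, 1], diagonal forced to zero."""
    X = np.asarray(reps.features, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise UndefinedStatisticError("cosine distance undefined for all-zero rows")
    d = squareform(pdist(X, metric="cosine"))
    off = ~np.eye(len(d), dtype=bool)
    lo, hi = float(d[off].min()), float(d[off].max())
    if hi == lo:
        raise UndefinedStatisticError("constant off-diagonal distances cannot be rescaled")
    vals = (d - lo) / (hi - lo)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, 1.0)
    return RDMatrix(
        values=vals,
        family_index=reps.family_index,
        design=reps.design,
        rescale_min=lo,
        rescale_max=hi,
    )


def _is_small(spec: FamilySpec, threshold: int) -> bool:
    return (spec.band_size or 0) < threshold


def prototype_rdm(
    kind: str,
    design: list[FamilySpec] | None = None,
    small_band_threshold: int = SMALL_BAND_THRESHOLD,
) -> PrototypeRDM:
    """Build one of the six prototypical block RDMs over the design."""
    if kind not in PROTOTYPE_KINDS:
        raise InvalidSpecError(f"unknown prototype kind {kind!r}")
    design = design16() if design is None else design
    nf = len(design)
    values = np.zeros((nf, nf))
    mask = np.zeros((nf, nf), dtype=bool)
    for i, a in enumerate(design):
        for j, b in enumerate(design):
            if kind in ("symmetry1", "symmetry2"):
                values[i, j] = float(a.symmetric != b.symmetric)
                if kind == "symmetry2" and not a.symmetric and not b.symmetric:
                    mask[i, j] = True
            elif kind == "band_presence":
                values[i, j] = float(((a.band_size or 0) > 0) != ((b.band_size or 0) > 0))
            elif kind == "brightness":
                values[i, j] = float(a.brightness != b.brightness)
            elif kind == "band_width":
                values[i, j] = float((a.band_size or 0) != (b.band_size or 0))
            else:  # symmetry_small_band
                sa, sb = (_is_small(s, small_band_threshold) for s in (a, b))
                if sa and sb:
                    values[i, j] = float(a.symmetric != b.symmetric)
                else:
                    # every large-band image shares one collapsed
                    # representation: 0 among large, 1 against small
                    values[i, j] = float(sa != sb)
    return PrototypeRDM(kind=kind, values=values, mask=mask, design=design)


def rdm_prototype_correlation(rdm: RDMatrix, proto: PrototypeRDM) -> float:
    """Pearson r between an image-level RDM and a block prototype expanded
    to image level, over unmasked strict-upper-triangle cells."""
    if len(proto.values) != len(rdm.design):
        raise InvalidDataError("prototype design does not match RDM design")
    fi = rdm.family_index
    expanded = proto.values[np.ix_(fi, fi)]
    exmask = proto.mask[np.ix_(fi, fi)]
    n = len(fi)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    sel = upper & ~exmask
    x, y = rdm.values[sel], expanded[sel]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in correlation input")
    return float(pearsonr(x, y).statistic)


def prototype_correlation_report(rdm: RDMatrix, model_id: str = "") -> pd.DataFrame:
    """Pearson r of one RDM against all six prototypes."""
    rows = [
        dict(model=model_id, prototype=k,
             pearson_r=rdm_prototype_correlation(rdm, prototype_rdm(k, rdm.design)))
        for k in PROTOTYPE_KINDS
    ]
    return pd.DataFrame(rows)
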