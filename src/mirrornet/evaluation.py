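"""Cross-dataset evaluation, the inference time-step sweep, and the
degree-of-non-symmetry misclassification analysis.

The decision rule everywhere is: predict symmetric (1) when the model's
probability strictly exceeds the threshold; exact ties count as
non-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidDataError, InvalidSpecError, UndefinedStatisticError
from .stimuli import IMAGE_SIZE, DatasetFamily, _check_band_size


def _probabilities(model, images) -> np.ndarray:
    """Symmetric-class probability from anything predictor-shaped."""
    p = model.predict_proba(images)
    p = np.asarray(p)
    return p[:, 1] if p.ndim == 2 else p


def evaluate(model, family: DatasetFamily, threshold: float = 0.5) -> float:
    """Accuracy of ``model`` on one generated family."""
    if len(family) == 0:
        raise InvalidDataError("cannot evaluate an empty family")
    pred = (_probabilities(model, family.images) > threshold).astype(np.int64)
    return float(np.mean(pred == family.labels))


def cross_dataset_eval(model, families, threshold: float = 0.5,
                       model_id: str = "", seed: int | None = None) -> pd.DataFrame:
    """One accuracy row per held-out family (the cross-dataset report)."""
    rows = [
        dict(
            family=f.spec.name,
            n=len(f),
            accuracy=evaluate(model, f, threshold),
            model=model_id,
            seed=f.seed if seed is None else seed,
        )
        for f in families
    ]
    return pd.DataFrame(rows)


def timestep_sweep(model, family: DatasetFamily, steps,
                   threshold: float = 0.5) -> pd.DataFrame:
    """Accuracy of a recurrent model under several inference step budgets.

    A single forward pass to ``max(steps)`` yields every budget's readout,
    since a truncated run shares its hidden-state prefix with longer runs.
    """
    if not getattr(model, "is_recurrent", False):
        raise InvalidSpecError("timestep_sweep requires a recurrent model")
    steps = [int(s) for s in steps]
    if steps != sorted(steps) or any(s < 1 for s in steps):
        raise InvalidSpecError("steps must be positive and ascending")
    probs = model.predict_proba_steps(family.images, steps)
    accs = [
        float(np.mean((probs[:, j] > threshold).astype(np.int64) == family.labels))
        for j in range(len(steps))
    ]
    return pd.DataFrame({"steps": steps, "accuracy": accs, "family": family.spec.name})


def degree_of_nonsymmetry(img: np.ndarray, band_size: int = 0) -> float:
    """Pearson correlation between the left flank and the flipped right
    flank (band columns excluded); 1.0 for a perfectly symmetric image."""
    band_size = _check_band_size(band_size)
    img = np.asarray(img, dtype=np.float64)
    flank_w = (IMAGE_SIZE - band_size) // 2
    left = img[:, :flank_w].ravel()
    right = img[:, IMAGE_SIZE - flank_w :][:, ::-1].ravel()
    if np.ptp(left) == 0 or np.ptp(right) == 0:
        raise UndefinedStatisticError("flank has zero variance")
    return float(np.corrcoef(left, right)[0, 1])


def degrees_of_nonsymmetry(images: np.ndarray, band_size: int = 0) -> np.ndarray:
    """Vectorised :func:`degree_of_nonsymmetry` over an image stack."""
    band_size = _check_band_size(band_size)
    images = np.asarray(images, dtype=np.float64)
    flank_w = (IMAGE_SIZE - band_size) // 2
    left = images[:, :, :flank_w].reshape(len(images), -1)
    right = images[:, :, IMAGE_SIZE - flank_w :][:, :, ::-1].reshape(len(images), -1)
    if np.any(np.ptp(left, axis=1) == 0) or np.any(np.ptp(right, axis=1) == 0):
        raise UndefinedStatisticError("some flank has zero variance")
    lc = left - left.mean(axis=1, keepdims=True)
    rc = right - right.mean(axis=1, keepdims=True)
    num = np.sum(lc * rc, axis=1)
    den = np.sqrt(np.sum(lc**2, axis=1) * np.sum(rc**2, axis=1))
    return num / den


@dataclass
class NonSymmetryHistogram:
    """Counts of correct/incorrect predictions binned by the degree of
    non-symmetry, for one class of one family."""

    bin_edges: np.ndarray
    correct: np.ndarray
    incorrect: np.ndarray
    which_class: int
    family: str = ""

    @property
    def n_total(self) -> int:
        return int(self.correct.sum() + self.incorrect.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "correct": self.correct,
                "incorrect": self.incorrect,
            }
        )


def misclassification_analysis(
    model,
    family: DatasetFamily,
    which_class: int = 0,
    bins: int = 20,
    threshold: float = 0.5,
) -> NonSymmetryHistogram:
    """Histogram of correct/incorrect classifications keyed by the
    left-right flank correlation, over one class of a family."""
    mask = family.labels == which_class
    if not np.any(mask):
        raise InvalidDataError(f"family holds no class-{which_class} images")
    images, labels = family.images[mask], family.labels[mask]
    corr = degrees_of_nonsymmetry(images, family.spec.oracle_band_size)
    pred = (_probabilities(model, images) > threshold).astype(np.int64)
    ok = pred == labels
    edges = np.linspace(-1.0, 1.0, bins + 1)
    # clip so r = 1.0 (symmetric images) lands in the last bin
    ix = np.clip(np.digitize(corr, edges) - 1, 0, bins - 1)
    correct = np.bincount(ix[ok], minlength=bins)
    incorrect = np.bincount(ix[~ok], minlength=bins)
    return NonSymmetryHistogram(
        bin_edges=edges,
        correct=correct,
        incorrect=incorrect,
        which_class=which_class,
        family=family.spec.name,
    )
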