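"""Synthetic fixtures: classifier probability matrices and phantom brain slices.

``generate_predictions`` emulates M trained classifiers of known accuracy
emitting row-stochastic probability matrices over C classes, with an
optional shared-error structure between models — the situation a weighted
ensemble is fit on.  ``generate_phantom`` draws a bright elliptical "brain"
on a dark background with bright off-brain noise specks and returns the
tight ground-truth crop box, the situation the cropping preprocessor must
recover from.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import PredictionSet
from .errors import ValidationError
from .preprocess import CropBox


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic prediction fixture.

    ``model_accuracies`` are the target argmax accuracies, one per model,
    each above chance (1/C).  ``concentration`` controls how peaked the
    Dirichlet-drawn probability rows are (larger = closer to one-hot).
    ``pair_correlation`` in [0, 1) is the probability that a sample's
    correct/incorrect outcome is decided by one draw shared across all
    models, inducing co-occurring errors without changing any model's
    marginal accuracy.
    """

    n_samples: int = 500
    n_classes: int = 3
    n_models: int = 5
    model_accuracies: tuple[float, ...] = (0.95, 0.93, 0.91, 0.89, 0.87)
    concentration: float = 8.0
    pair_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_models < 1:
            raise ValidationError(f"n_models must be >= 1, got {self.n_models}")
        accs = tuple(float(a) for a in self.model_accuracies)
        if len(accs) != self.n_models:
            raise ValidationError(
                f"model_accuracies has {len(accs)} entries for n_models={self.n_models}"
            )
        chance = 1.0 / self.n_classes
        for i, a in enumerate(accs):
            if not chance < a <= 1.0:
                raise ValidationError(
                    f"model_accuracies[{i}]={a} outside (1/C, 1] = ({chance:.4f}, 1]"
                )
        if self.concentration <= 0:
            raise ValidationError(f"concentration must be positive, got {self.concentration}")
        if not 0.0 <= self.pair_correlation < 1.0:
            raise ValidationError(
                f"pair_correlation must be in [0, 1), got {self.pair_correlation}"
            )
        object.__setattr__(self, "model_accuracies", accs)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom brain image.

    A filled axis-aligned ellipse of ``brain_intensity`` on a
    ``background_intensity`` background, plus ``n_noise_specks`` small
    bright discs placed strictly outside the ellipse.
    """

    width: int = 200
    height: int = 200
    ellipse_center: tuple[int, int] = (100, 100)  # (row, col)
    ellipse_axes: tuple[int, int] = (50, 40)  # (semi-height, semi-width)
    brain_intensity: int = 200
    background_intensity: int = 10
    n_noise_specks: int = 5
    speck_max_radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        cr, cc = self.ellipse_center
        a, b = self.ellipse_axes
        if a < 1 or b < 1:
            raise ValidationError(f"ellipse axes must be >= 1, got {self.ellipse_axes}")
        if not (0 <= cr - a and cr + a < self.height and 0 <= cc - b and cc + b < self.width):
            raise ValidationError(
                f"ellipse (center {self.ellipse_center}, axes {self.ellipse_axes}) "
                f"exceeds {self.height}x{self.width} image bounds"
            )
        for name in ("brain_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValidationError(f"{name}={v} outside [0, 255]")
        if self.brain_intensity <= self.background_intensity:
            raise ValidationError("brain_intensity must exceed background_intensity")
        if self.n_noise_specks < 0 or self.speck_max_radius < 1:
            raise ValidationError("invalid speck parameters")


def generate_predictions(spec: FixtureSpec) -> tuple[PredictionSet, np.ndarray]:
    """Draw labels and per-model probability matrices matching the spec.

    Labels are uniform over the C classes.  Each model decides per sample
    whether its argmax ("winning") class is the true class — a Bernoulli
    with the model's accuracy — or a uniformly chosen wrong class.  With
    probability ``pair_correlation`` a sample's Bernoulli uses a single
    uniform draw shared by all models (comonotone coupling), so weaker
    models fail on a superset of the samples stronger models fail on;
    otherwise draws are independent.  Either way each model's marginal
    accuracy is exactly its target.

    The probability row is then drawn from a Dirichlet peaked on the
    winning class (alpha = concentration there, 1 elsewhere); the maximum
    entry is swapped into the winning position so the row's argmax equals
    the intended winner even at low concentration.
    """
    rng = np.random.default_rng(spec.seed)
    n, c, m = spec.n_samples, spec.n_classes, spec.n_models
    labels = rng.integers(0, c, size=n)

    shared = rng.random(n) < spec.pair_correlation  # samples with a common fate
    shared_u = rng.random(n)
    accs = np.asarray(spec.model_accuracies)

    matrices = np.empty((m, n, c))
    for i in range(m):
        u = rng.random(n)
        u[shared] = shared_u[shared]
        correct = u < accs[i]
        winners = labels.copy()
        wrong_offset = rng.integers(1, c, size=n)  # uniform over the C-1 wrong classes
        winners[~correct] = (labels[~correct] + wrong_offset[~correct]) % c
        alpha = np.ones((n, c))
        alpha[np.arange(n), winners] = spec.concentration
        # vectorized Dirichlet with per-row alpha via normalized gammas
        gammas = rng.gamma(alpha)
        rows = gammas / gammas.sum(axis=1, keepdims=True)
        # force the argmax onto the winning class by swapping in the row max
        top = rows.argmax(axis=1)
        idx = np.arange(n)
        rows[idx, winners], rows[idx, top] = rows[idx, top], rows[idx, winners].copy()
        matrices[i] = rows

    sample_ids = tuple(f"s{j:05d}" for j in range(n))
    model_ids = tuple(f"model_{i}" for i in range(m))
    return PredictionSet(model_ids, matrices, sample_ids), labels


def _ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    cr, ccenter = spec.ellipse_center
    a, b = spec.ellipse_axes
    return ((rr - cr) / a) ** 2 + ((cc - ccenter) / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, CropBox]:
    """Render the phantom and return it with the ground-truth crop box.

    The box is the tight half-open bounding box of the rendered ellipse
    pixels.  Specks are small bright discs rejected until every pixel lies
    strictly outside the ellipse equation.
    """
    rng = np.random.default_rng(spec.seed)
    image = np.full((spec.height, spec.width), spec.background_intensity, dtype=np.uint8)
    ellipse = _ellipse_mask(spec)
    image[ellipse] = spec.brain_intensity

    rows, cols = np.nonzero(ellipse)
    box = CropBox(int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)

    cr, cc = spec.ellipse_center
    a, b = spec.ellipse_axes
    placed = 0
    attempts = 0
    while placed < spec.n_noise_specks:
        attempts += 1
        if attempts > 10000:
            raise ValidationError(
                "could not place noise specks outside the ellipse; "
                "reduce n_noise_specks or speck_max_radius"
            )
        r = int(rng.integers(0, spec.height))
        col = int(rng.integers(0, spec.width))
        radius = int(rng.integers(1, spec.speck_max_radius + 1))
        rr, ccg = np.mgrid[
            max(0, r - radius) : min(spec.height, r + radius + 1),
            max(0, col - radius) : min(spec.width, col + radius + 1),
        ]
        disc = (rr - r) ** 2 + (ccg - col) ** 2 <= radius**2
        outside = ((rr - cr) / a) ** 2 + ((ccg - cc) / b) ** 2 > 1.0
        if not np.all(outside[disc]):
            continue
        image[rr[disc], ccg[disc]] = spec.brain_intensity
        placed += 1

    return image, box
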