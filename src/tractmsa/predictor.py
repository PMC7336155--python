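"""Performance predictor over graded lesion patterns, with validation.

The coalition analysis needs the performance of *every* binary
perturbation configuration, but a clinical cohort supplies only ~25
observed lesion patterns.  A support-vector classifier trained on the
observed patients' graded intactness vectors (values in [0, 1], one
column per player) stands in as the characteristic function: any
binary configuration is just another point of the same cube.

Validation mirrors standard practice for small-n classifiers:
leave-one-out accuracy, an empirical permutation chance level, and the
Youden index (sensitivity + specificity - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "GradedDataset",
    "PredictorSpec",
    "Predictor",
    "ValidationReport",
    "DEFAULT_KERNELS",
    "train",
    "predict_configuration",
    "loo_accuracy",
    "loo_predictions",
    "chance_level",
    "chance_level_closed_form",
    "youden",
    "validate",
    "kernel_scan",
]

logger = logging.getLogger(__name__)

#: per-test kernel choices that maximised leave-one-out accuracy in the
#: motivating cohort (linear / polynomial / quadratic)
DEFAULT_KERNELS = {
    "line_bisection": "linear",
    "bells": "polynomial",
    "letter": "quadratic",
}

KERNELS = ("linear", "polynomial", "quadratic")


@dataclass(frozen=True)
class GradedDataset:
    """Patients x players intactness matrix with performance labels.

    Only patients with a non-missing score for this test belong here;
    ``y`` is the post-inversion performance label (1 = normal).
    """

    test: str
    X: np.ndarray
    y: np.ndarray
    patient_ids: tuple[str, ...]
    player_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X rows must match y length")
        if len(self.patient_ids) != len(y):
            raise ValueError("patient_ids must match y length")
        if X.shape[1] != len(self.player_names):
            raise ValueError("X columns must match player_names")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("intactness values must lie in [0, 1]")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_players(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: np.ndarray) -> "GradedDataset":
        indices = np.asarray(indices)
        return GradedDataset(
            test=self.test,
            X=self.X[indices],
            y=self.y[indices],
            patient_ids=tuple(self.patient_ids[i] for i in indices),
            player_names=self.player_names,
        )


@dataclass(frozen=True)
class PredictorSpec:
    """Kernel family and box constraint for the SVM.

    ``quadratic`` is a degree-2 polynomial kernel; ``polynomial``
    defaults to degree 3 (the common library default) — both degrees
    are overridable via ``degree``.
    """

    kernel: str = "linear"
    box_constraint: float = 1.0
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")

    def _svc(self) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=self.box_constraint)
        degree = self.degree if self.degree is not None else (
            2 if self.kernel == "quadratic" else 3
        )
        return SVC(kernel="poly", degree=degree, C=self.box_constraint)


@dataclass
class Predictor:
    """A trained classifier over player-state vectors in [0, 1]^M."""

    spec: PredictorSpec
    player_names: tuple[str, ...]
    _clf: SVC

    @property
    def n_players(self) -> int:
        return len(self.player_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_players:
            raise ValueError(
                f"expected vectors of length {self.n_players}, got {X.shape[1]}"
            )
        return self._clf.predict(X).astype(int)


def train(dataset: GradedDataset, spec: PredictorSpec = PredictorSpec()) -> Predictor:
    """Fit the SVM on the original-graded dataset.

    Deterministic for fixed inputs.  A single-class label vector is a
    degenerate training set and is rejected.
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValueError(f"{dataset.test}: training labels contain a single class")
    clf = spec._svc().fit(dataset.X, dataset.y)
    return Predictor(spec=spec, player_names=dataset.player_names, _clf=clf)


def predict_configuration(predictor: Predictor, config: np.ndarray) -> int:
    """Predicted performance of one binary perturbation configuration.

    The configuration (0 = perturbed = fully damaged, 1 = intact) is
    evaluated as an intactness vector, so a patient whose graded vector
    happens to be binary gets the same label by either path.
    """
    config = np.asarray(config)
    if config.shape != (predictor.n_players,):
        raise ValueError(
            f"configuration length {config.shape} != {predictor.n_players} players"
        )
    if not set(np.unique(config)) <= {0, 1}:
        raise ValueError("configuration must be binary")
    return int(predictor.predict(config[None, :].astype(float))[0])


def loo_predictions(
    dataset: GradedDataset, spec: PredictorSpec = PredictorSpec()
) -> np.ndarray:
    """Leave-one-out predicted label for each patient.

    Each patient is held out in turn and predicted by a model trained
    on the remaining n-1.  A fold whose training labels collapse to a
    single class cannot fit an SVM; its prediction falls back to the
    training-fold majority class, with a logged warning.
    """
    n = dataset.n
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    preds = np.empty(n, dtype=int)
    degenerate = 0
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = dataset.y[keep]
        if len(np.unique(y_tr)) < 2:
            preds[i] = int(np.round(y_tr.mean()))
            degenerate += 1
            continue
        clf = spec._svc().fit(dataset.X[keep], y_tr)
        preds[i] = int(clf.predict(dataset.X[i : i + 1])[0])
    if degenerate:
        logger.warning(
            "%s: %d leave-one-out fold(s) had single-class training labels; "
            "used majority-class fallback",
            dataset.test, degenerate,
        )
    return preds


def loo_accuracy(dataset: GradedDataset, spec: PredictorSpec = PredictorSpec()) -> float:
    """Fraction of held-out patients predicted correctly (1.0 = all)."""
    return float(np.mean(loo_predictions(dataset, spec) == dataset.y))


def chance_level(labels: np.ndarray, reps: int = 1000, seed: int = 0) -> float:
    """Empirical chance accuracy under score permutation.

    Mirrors the leave-one-out structure of the validation: each case in
    turn is compared against a randomly permuted score drawn from the
    *remaining* cases, and the agreement rate is averaged over ``reps``
    shuffles.  Converges on sum_k n_k (n_k - 1) / (n (n - 1)) for class
    counts n_k (the closed form of :func:`chance_level_closed_form`).
    """
    labels = np.asarray(labels)
    n = labels.size
    if n == 0:
        raise ValueError("empty label vector")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    agree = np.empty(reps)
    idx = np.arange(n)
    for r in range(reps):
        # for each held-out case, a uniformly drawn *other* case's score
        j = rng.integers(0, n - 1, size=n)
        j[j >= idx] += 1
        agree[r] = np.mean(labels == labels[j])
    return float(agree.mean())


def chance_level_closed_form(labels: np.ndarray) -> float:
    """Exact expectation of the permutation agreement rate."""
    labels = np.asarray(labels)
    n = labels.size
    if n < 2:
        raise ValueError("need at least 2 labels")
    _, counts = np.unique(labels, return_counts=True)
    return float(sum(c * (c - 1) for c in counts) / (n * (n - 1)))


def youden(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Youden index: sensitivity + specificity - 1, in [-1, 1].

    1 means no false positives or negatives; labels must contain both
    classes, otherwise one of the two rates is undefined.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("labels contain a single class; Youden undefined")
    sensitivity = float(np.mean(predictions[pos] == 1))
    specificity = float(np.mean(predictions[neg] == 0))
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class ValidationReport:
    """Predictor validity summary for one test's subcohort."""

    test: str
    n: int
    loo_accuracy: float
    chance_level: float
    sensitivity: float
    specificity: float
    youden: float

    def to_dict(self) -> dict:
        return asdict(self)


def validate(
    dataset: GradedDataset,
    spec: PredictorSpec = PredictorSpec(),
    reps: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """Full validation: LOO accuracy, permutation chance, Youden."""
    preds = loo_predictions(dataset, spec)
    pos = dataset.y == 1
    neg = dataset.y == 0
    if not pos.any() or not neg.any():
        raise ValueError(f"{dataset.test}: labels contain a single class")
    return ValidationReport(
        test=dataset.test,
        n=dataset.n,
        loo_accuracy=float(np.mean(preds == dataset.y)),
        chance_level=chance_level(dataset.y, reps=reps, seed=seed),
        sensitivity=float(np.mean(preds[pos] == 1)),
        specificity=float(np.mean(preds[neg] == 0)),
        youden=youden(preds, dataset.y),
    )


def kernel_scan(
    dataset: GradedDataset,
    kernels: tuple[str, ...] = KERNELS,
    box_constraint: float = 1.0,
) -> dict[str, float]:
    """LOO accuracy per kernel family — the kernel sensitivity scan."""
    return {
        k: loo_accuracy(dataset, PredictorSpec(kernel=k, box_constraint=box_constraint))
        for k in kernels
    }
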