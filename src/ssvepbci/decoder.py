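"""Participant-specific SVM attention decoding.

The decoder is trained per participant on the 60 instructed baseline trials
(30 attend-Gabor, 30 attend-Face).  :class:`AttentionDecoder` is the model
object; its :meth:`~AttentionDecoder.fit` performs a stratified 80/20
train/validation split, fits the SVM on the training portion, fits a Platt
sigmoid to the validation decision values, and returns a
:class:`DecoderResults` carrying the calibrated model, its five-fold
cross-validated accuracy and a ``summary()`` table.  The calibrated output
is the probability that attention was on the Gabor; attend-Gabor is the
positive class everywhere.

Configuration profiling (:func:`profile_configurations`) sweeps a menu of
feature configurations against the three kernels (linear, polynomial, RBF)
and reports mean +/- SD cross-validated accuracy per cell, mirroring how the
deployed classifier is chosen: best accuracy, optionally excluding
forward-feature-selection cells whose training time is incompatible with a
live session.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import ATTEND_GABOR, TrialEpoch
from .features import (
    COSINE_CORR,
    POWER_BANK,
    PSD,
    FeatureConfig,
    FeatureMatrix,
    assemble_feature_matrix,
    extract_features,
)

KERNELS = ("linear", "polynomial", "rbf")
#: sklearn name for the polynomial kernel
_SK_KERNEL = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}

DEFAULT_C = 1.0
DEFAULT_DEGREE = 3
DEFAULT_COEF0 = 1.0


class NotCalibratedError(RuntimeError):
    """A probability was requested from a model without Platt coefficients."""


def _make_svm(kernel: str, C: float = DEFAULT_C):
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    svm = SVC(
        kernel=_SK_KERNEL[kernel],
        C=C,
        degree=DEFAULT_DEGREE,
        coef0=DEFAULT_COEF0,
        gamma="scale",
    )
    return make_pipeline(StandardScaler(), svm)


def _encode_labels(labels) -> np.ndarray:
    """Binary encoding with attend-Gabor as the positive class."""
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    positive = ATTEND_GABOR if ATTEND_GABOR in classes else classes[1]
    return np.array([1 if lab == positive else 0 for lab in labels])


def _as_xy(X, labels=None):
    if isinstance(X, FeatureMatrix):
        return X.values, _encode_labels(X.labels)
    return np.asarray(X, dtype=float), _encode_labels(labels)


# ---------------------------------------------------------------------------
# Cross-validation and forward feature selection
# ---------------------------------------------------------------------------

def cross_validate(
    X, kernel: str = "linear", k: int = 5, seed: int = 0, labels=None
) -> tuple[float, float]:
    """Stratified k-fold CV accuracy of an SVM.

    Returns ``(mean, sd)`` of the per-fold accuracies; deterministic given
    the seed.  ``X`` may be a :class:`FeatureMatrix` or an array with
    ``labels`` given separately.
    """
    values, y = _as_xy(X, labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("cross-validation requires both classes present")
    if counts.min() < k and k != len(y):
        raise ValueError(f"need >= {k} trials per class for {k}-fold CV, got {counts.min()}")
    accs = _fold_accuracies(values, y, kernel, _folds(y, k, seed))
    return float(np.mean(accs)), float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0


def _folds(y: np.ndarray, k: int, seed: int):
    if k == len(y):  # leave-one-out
        return [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _fold_accuracies(values, y, kernel, folds) -> list[float]:
    accs = []
    for train_idx, test_idx in folds:
        clf = _make_svm(kernel)
        clf.fit(values[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(values[test_idx]) == y[test_idx])))
    return accs


def forward_feature_selection(
    X, kernel: str = "linear", seed: int = 0, k: int = 5, labels=None
) -> list[int]:
    """Greedy forward selection minimizing CV misclassification.

    Starting from an empty bank, candidate features (visited in a seeded
    random order each round) are tentatively added; the candidate with the
    lowest cross-validated misclassification joins the bank (ties broken by
    lowest feature index).  Growth stops when no candidate strictly improves
    the rate, and the subset achieving the minimal observed
    misclassification is returned (as column indices).
    """
    values, y = _as_xy(X, labels)
    n_features = values.shape[1]
    if n_features == 1:
        return [0]
    rng = np.random.default_rng(seed)
    folds = _folds(y, k, seed)  # fixed folds: subsets compared on equal terms

    def miscls(cols: list[int]) -> float:
        accs = _fold_accuracies(values[:, cols], y, kernel, folds)
        return 1.0 - float(np.mean(accs))

    selected: list[int] = []
    best_rate = np.inf
    best_subset: list[int] = []
    while len(selected) < n_features:
        remaining = [j for j in range(n_features) if j not in selected]
        rng.shuffle(remaining)
        round_best, round_rate = None, np.inf
        for j in remaining:
            rate = miscls(selected + [j])
            if rate < round_rate or (rate == round_rate and j < round_best):
                round_best, round_rate = j, rate
        if round_rate >= best_rate:  # no strict improvement: stop
            break
        selected.append(round_best)
        best_rate = round_rate
        best_subset = list(selected)
    return sorted(best_subset)


# ---------------------------------------------------------------------------
# Platt sigmoid calibration
# ---------------------------------------------------------------------------

def fit_platt(decision_values, labels) -> tuple[float, float]:
    """Fit Platt's sigmoid ``P(y=1|s) = 1 / (1 + exp(A*s + B))``.

    Regularized maximum likelihood with Platt's shifted targets
    ``(N+ + 1)/(N+ + 2)`` and ``1/(N- + 2)``, solved by Newton's method with
    backtracking line search.  Raises if only one class is present.
    """
    s = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = _encode_labels(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt calibration requires both classes in the labels")

    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)

    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))

    def objective(a, b):
        f = a * s + b
        # t*f + log(1+exp(-f)), computed stably for either sign of f
        return float(np.sum(np.where(f >= 0, t * f + np.log1p(np.exp(-f)),
                                     (t - 1) * f + np.log1p(np.exp(f)))))

    fval = objective(A, B)
    for _ in range(100):
        f = A * s + B
        p = np.where(f >= 0, np.exp(-f) / (1 + np.exp(-f)), 1 / (1 + np.exp(f)))
        d1 = t - p  # dF/df per point
        d2 = p * (1 - p)
        g_a = float(np.dot(d1, s))
        g_b = float(np.sum(d1))
        if abs(g_a) < 1e-10 and abs(g_b) < 1e-10:
            break
        h_aa = float(np.dot(d2, s * s)) + 1e-12
        h_ab = float(np.dot(d2, s))
        h_bb = float(np.sum(d2)) + 1e-12
        det = h_aa * h_bb - h_ab * h_ab
        dA = -(h_bb * g_a - h_ab * g_b) / det
        dB = -(h_aa * g_b - h_ab * g_a) / det
        step = 1.0
        while step >= 1e-10:
            new = objective(A + step * dA, B + step * dB)
            if new < fval + 1e-4 * step * (g_a * dA + g_b * dB):
                A, B, fval = A + step * dA, B + step * dB, new
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def platt_probability(s, platt: tuple[float, float]) -> np.ndarray:
    """Apply a fitted sigmoid to decision value(s)."""
    A, B = platt
    f = A * np.asarray(s, dtype=float) + B
    return np.where(f >= 0, np.exp(-f) / (1 + np.exp(-f)), 1 / (1 + np.exp(f)))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class FeedbackScore:
    """Calibrated probability that attention was on the Gabor for one trial."""

    probability: float
    trial_index: int = 0
    face_id: str | None = None
    epoch_number: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def gabor_won(self) -> bool:
        return self.probability > 0.5


class AttentionDecoder:
    """Participant-specific SVM attention decoder (unfitted model).

    Parameters
    ----------
    epochs : list of TrialEpoch
        Balanced labeled baseline epochs (attend-Gabor vs attend-Face).
    config : FeatureConfig
        Feature family and parameters used to featurize epochs.
    kernel : {'linear', 'polynomial', 'rbf'}
    C : float
        SVM regularization constant.
    """

    def __init__(
        self,
        epochs: list[TrialEpoch] | None = None,
        config: FeatureConfig = FeatureConfig(),
        kernel: str = "linear",
        C: float = DEFAULT_C,
        feature_matrix: FeatureMatrix | None = None,
    ):
        if kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if (epochs is None) == (feature_matrix is None):
            raise ValueError("provide exactly one of epochs or feature_matrix")
        self.config = config
        self.kernel = kernel
        self.C = C
        self.trial_duration = (
            epochs[0].n_samples / epochs[0].fs if epochs else 5.0
        )
        self.fm = feature_matrix or assemble_feature_matrix(epochs, config)
        y = _encode_labels(self.fm.labels)
        counts = np.bincount(y, minlength=2)
        if counts[0] != counts[1]:
            raise ValueError(
                f"baseline classes must be balanced, got {counts[1]} vs {counts[0]}"
            )
        if len(y) < 10:
            raise ValueError(f"need at least 10 balanced baseline trials, got {len(y)}")
        self._y = y

    def fit(self, seed: int = 0, validation_fraction: float = 0.2) -> "DecoderResults":
        """Train on a stratified 80/20 split and calibrate on the held-out 20%.

        The SVM is fitted on the training portion; Platt's sigmoid is fitted
        to the decision values of the validation portion; five-fold CV
        accuracy is measured within the training portion.  Deterministic
        given the seed.
        """
        X = self.fm.values
        cols = list(range(X.shape[1]))
        if self.config.use_feature_selection:
            cols = forward_feature_selection(
                X, self.kernel, seed=seed, labels=self.fm.labels
            )
        Xs = X[:, cols]

        idx_train, idx_val = train_test_split(
            np.arange(len(self._y)),
            test_size=validation_fraction,
            stratify=self._y,
            random_state=seed,
        )
        clf = _make_svm(self.kernel, self.C)
        clf.fit(Xs[idx_train], self._y[idx_train])
        s_val = clf.decision_function(Xs[idx_val])
        platt = fit_platt(s_val, self._y[idx_val])
        val_acc = float(np.mean(clf.predict(Xs[idx_val]) == self._y[idx_val]))
        cv_mean, cv_sd = cross_validate(
            Xs[idx_train], self.kernel, seed=seed,
            labels=[self.fm.labels[i] for i in idx_train],
        )
        return DecoderResults(
            model=self,
            estimator=clf,
            selected_columns=cols,
            selected_features=[self.fm.feature_names[j] for j in cols],
            platt=platt,
            cv_accuracy=cv_mean,
            cv_sd=cv_sd,
            validation_accuracy=val_acc,
            n_train=len(idx_train),
            n_validation=len(idx_val),
            seed=seed,
        )


@dataclass
class DecoderResults:
    """A fitted, calibrated attention decoder.

    Carries the SVM, the selected feature subset, the Platt sigmoid
    coefficients ``(A, B)`` (``P = 1/(1+exp(A*s+B))``), the cross-validated
    accuracy measured on the training portion and the held-out validation
    accuracy.
    """

    model: AttentionDecoder
    estimator: object
    selected_columns: list[int]
    selected_features: list[str]
    platt: tuple[float, float]
    cv_accuracy: float
    cv_sd: float
    validation_accuracy: float
    n_train: int
    n_validation: int
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_accuracy <= 1.0:
            raise ValueError("cv_accuracy outside [0, 1]")
        self.hyperparameters = {
            "C": self.model.C,
            "degree": DEFAULT_DEGREE,
            "coef0": DEFAULT_COEF0,
            "gamma": "scale",
        }

    # -- scoring -----------------------------------------------------------

    def config_duration(self) -> float:
        """Epoch length (s) this decoder expects."""
        return self.model.trial_duration

    def decision_value(self, ep: TrialEpoch) -> float:
        vec, _ = extract_features(ep, self.model.config)
        return float(self.estimator.decision_function(vec[self.selected_columns][None, :])[0])

    def gabor_probability(self, ep: TrialEpoch) -> FeedbackScore:
        """Calibrated probability that attention was on the Gabor."""
        if self.platt is None:
            raise NotCalibratedError("decoder has no Platt coefficients")
        p = float(platt_probability(self.decision_value(ep), self.platt))
        return FeedbackScore(
            probability=p,
            trial_index=ep.trial_index,
            face_id=ep.face_id,
        )

    def face_probability(self, ep: TrialEpoch) -> float:
        """Binary complement of :meth:`gabor_probability`."""
        return 1.0 - self.gabor_probability(ep).probability

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Attention decoder (SVM, Platt-calibrated)",
            "=" * 45,
            f"Feature family:        {cfg.describe()}",
            f"Kernel:                {self.kernel}",
            f"Hyperparameters:       {self.hyperparameters}",
            f"Features used:         {len(self.selected_features)}"
            + (" (forward-selected)" if cfg.use_feature_selection else ""),
            f"Train / validation:    {self.n_train} / {self.n_validation} trials",
            f"CV accuracy (5-fold):  {self.cv_accuracy:.3f} +/- {self.cv_sd:.3f}",
            f"Validation accuracy:   {self.validation_accuracy:.3f}",
            f"Platt (A, B):          ({self.platt[0]:.4f}, {self.platt[1]:.4f})",
        ]
        return "\n".join(lines)

    @property
    def kernel(self) -> str:
        return self.model.kernel

    # -- serialization -----------------------------------------------------

    def save(self, basepath: str | Path) -> None:
        """Write ``<basepath>.json`` metadata + ``<basepath>.npz`` weights."""
        import pickle

        basepath = Path(basepath)
        meta = {
            "kernel": self.kernel,
            "hyperparameters": self.hyperparameters,
            "feature_config": {
                "family": self.model.config.family,
                "n_harmonics": self.model.config.n_harmonics,
                "f0": self.model.config.f0,
                "tag_frequencies": list(self.model.config.tag_frequencies),
                "channels": list(self.model.config.channels),
                "use_feature_selection": self.model.config.use_feature_selection,
            },
            "selected_features": self.selected_features,
            "platt": list(self.platt),
            "cv_accuracy": self.cv_accuracy,
            "cv_sd": self.cv_sd,
            "validation_accuracy": self.validation_accuracy,
            "seed": self.seed,
        }
        basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        with open(basepath.with_suffix(".pkl"), "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(basepath: str | Path) -> "DecoderResults":
        import pickle

        with open(Path(basepath).with_suffix(".pkl"), "rb") as fh:
            return pickle.load(fh)


def train_participant_decoder(
    baseline_epochs: list[TrialEpoch],
    cfg: FeatureConfig,
    kernel: str = "linear",
    seed: int = 0,
) -> DecoderResults:
    """Convenience wrapper: build and fit an :class:`AttentionDecoder`."""
    return AttentionDecoder(baseline_epochs, config=cfg, kernel=kernel).fit(seed=seed)


# ---------------------------------------------------------------------------
# Configuration profiling
# ---------------------------------------------------------------------------

def standard_menu() -> list[FeatureConfig]:
    """The 14-configuration profiling menu (x 3 kernels = 42 cells)."""
    menu = [
        FeatureConfig(family=PSD),
        FeatureConfig(family=PSD, use_feature_selection=True),
    ]
    for f0 in (1.5, 2.0):
        for n in (1, 2, 3):
            menu.append(FeatureConfig(family=POWER_BANK, n_harmonics=n, f0=f0))
        menu.append(
            FeatureConfig(family=POWER_BANK, n_harmonics=3, f0=f0, use_feature_selection=True)
        )
    for n in (1, 2, 3):
        menu.append(FeatureConfig(family=COSINE_CORR, n_harmonics=n))
    menu.append(FeatureConfig(family=COSINE_CORR, n_harmonics=3, use_feature_selection=True))
    return menu


@dataclass
class ProfilingGrid:
    """CV accuracy per (feature configuration x kernel) cell.

    ``table`` has one row per configuration with, per kernel, the mean and
    SD of participant-level CV accuracies and the wall-clock training time
    of the cell (reported, never asserted).
    """

    table: pd.DataFrame
    menu: list[FeatureConfig]
    kernels: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return len(self.menu) * len(self.kernels)

    def accuracy(self, config_row: int, kernel: str) -> float:
        return float(self.table.loc[config_row, f"{kernel}_mean"])

    def best_cell(self, exclude_feature_selection: bool = False):
        """Highest-mean cell; optionally skip FS rows (session-time limits).

        Returns ``(config, kernel, mean, sd)``.
        """
        best = None
        for i, cfg in enumerate(self.menu):
            if exclude_feature_selection and cfg.use_feature_selection:
                continue
            for kern in self.kernels:
                mean = self.accuracy(i, kern)
                if best is None or mean > best[2]:
                    best = (cfg, kern, mean, float(self.table.loc[i, f"{kern}_sd"]))
        if best is None:
            raise ValueError("no eligible cells")
        return best

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def profile_configurations(
    epochs_by_participant: dict[str, list[TrialEpoch]] | list[list[TrialEpoch]],
    menu: list[FeatureConfig] | None = None,
    kernels: tuple[str, ...] = KERNELS,
    seed: int = 0,
    k: int = 5,
) -> ProfilingGrid:
    """Sweep feature configurations x kernels over a cohort of participants.

    Per cell: each participant's baseline epochs are featurized and scored by
    stratified k-fold CV (after forward feature selection when the
    configuration asks for it); the cell reports the mean and SD of the
    participant-level accuracies (fold-level SD when the cohort has a single
    participant).
    """
    if isinstance(epochs_by_participant, dict):
        cohorts = list(epochs_by_participant.values())
    else:
        cohorts = list(epochs_by_participant)
    if not cohorts:
        raise ValueError("no participants supplied")
    menu = menu if menu is not None else standard_menu()
    if not menu:
        raise ValueError("empty configuration menu")

    rows = []
    for cfg in menu:
        fms = [assemble_feature_matrix(eps, cfg) for eps in cohorts]
        row = {"feature_type": cfg.describe(), "config": cfg}
        for kern in kernels:
            tic = time.perf_counter()
            accs, sds = [], []
            for fm in fms:
                if cfg.use_feature_selection:
                    cols = forward_feature_selection(fm, kern, seed=seed, k=k)
                    mean, sd = cross_validate(
                        fm.values[:, cols], kern, k=k, seed=seed, labels=fm.labels
                    )
                else:
                    mean, sd = cross_validate(fm, kern, k=k, seed=seed)
                accs.append(mean)
                sds.append(sd)
            row[f"{kern}_mean"] = float(np.mean(accs))
            row[f"{kern}_sd"] = (
                float(np.std(accs, ddof=1)) if len(accs) > 1 else float(sds[0])
            )
            row[f"{kern}_time_s"] = time.perf_counter() - tic
        rows.append(row)
    table = pd.DataFrame(rows)
    return ProfilingGrid(table=table, menu=list(menu), kernels=tuple(kernels))
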