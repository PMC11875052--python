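"""Trial-wise population decoding of (frequency, level) with PCA + LDA.

Each trial is summarized by the per-neuron mean dF/F over the 1 s (15
frames at 15 Hz) following tone onset, giving a trials x neurons feature
matrix with one (frequency, level) class label per trial.  Decoding uses
stratified 90/10 splits repeated 10 times so that every trial is tested
exactly once; per split, PCA is fit on the training rows only and the
smallest number of components explaining >= 90% of variance feeds a
pooled-covariance linear discriminant classifier with uniform priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .grid import StimulusGrid, TrialTensor

__all__ = ["DecodingResult", "trial_feature_matrix", "decode_pca_lda", "chance_level"]

FEATURE_WINDOW_FRAMES = 15


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome."""

    accuracy: float
    per_class_accuracy: np.ndarray  # (n_classes,)
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    fold_assignments: np.ndarray  # (n_trials,) test-fold index per trial
    n_components: np.ndarray  # PCA components retained per fold
    seed: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.accuracy <= 1.0


def trial_feature_matrix(
    dff: TrialTensor, grid: StimulusGrid | None = None, window_frames: int = FEATURE_WINDOW_FRAMES
) -> tuple[np.ndarray, np.ndarray]:
    """(trials x neurons) features and (f, a) class labels.

    Feature = per-neuron mean dF/F over ``window_frames`` after tone onset;
    label = ``f_index * n_levels + a_index``.
    """
    grid = grid or dff.grid
    on = grid.onset_frame
    if on + window_frames > grid.trial_frames:
        raise ValueError("feature window overflows the trial")
    amp = dff.values[:, on : on + window_frames].mean(axis=1)  # (N, F, A, R)
    n = amp.shape[0]
    features = amp.reshape(n, -1).T  # trials ordered (f, a, r) C-style
    f_idx, a_idx, _ = np.unravel_index(
        np.arange(features.shape[0]), (grid.n_frequencies, grid.n_levels, grid.n_repeats)
    )
    labels = f_idx * grid.n_levels + a_idx
    return features, labels


def decode_pca_lda(
    features: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.9,
    var_explained: float = 0.90,
    n_splits: int = 10,
    seed: int = 0,
) -> DecodingResult:
    """Stratified 90/10 x 10 cross-validated PCA + LDA decoding.

    The splits partition the trials (every trial tested exactly once); PCA
    and LDA are fit on training rows only per split.  Reported accuracy is
    the average over splits.  Deterministic given ``seed``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if not np.isclose(1.0 - train_frac, 1.0 / n_splits):
        raise ValueError("n_splits must match the held-out fraction")

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    n_classes = classes.size
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    fold_assignments = np.full(len(labels), -1, dtype=int)
    fold_accuracies = []
    components = []
    for fold, (train, test) in enumerate(skf.split(features, labels)):
        if np.unique(labels[train]).size < n_classes:
            raise ValueError(f"class absent from training fold {fold}")
        pca = PCA()
        z_train = pca.fit_transform(features[train])
        k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), var_explained) + 1)
        k = min(k, z_train.shape[1])
        lda = LinearDiscriminantAnalysis(priors=np.full(n_classes, 1.0 / n_classes))
        lda.fit(z_train[:, :k], labels[train])
        pred = lda.predict(pca.transform(features[test])[:, :k])
        fold_assignments[test] = fold
        fold_accuracies.append(float(np.mean(pred == labels[test])))
        components.append(k)
        for t, p in zip(labels[test], pred):
            confusion[t, p] += 1

    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, np.diag(confusion) / row_sums, np.nan)
    return DecodingResult(
        accuracy=float(np.mean(fold_accuracies)),
        per_class_accuracy=per_class,
        confusion=confusion,
        fold_assignments=fold_assignments,
        n_components=np.asarray(components),
        seed=seed,
    )


def chance_level(grid: StimulusGrid) -> float:
    """Chance accuracy for the (frequency, level) classification: 1/(F*A)."""
    return 1.0 / grid.n_conditions
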