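"""Sample weighting: duplicate confidently-expressed training windows.

A random-forest classifier fit on the facial-activity descriptors of the
training set scores every training window; windows whose score for their
own class exceeds a threshold (default 0.3) — i.e. windows with a clear
facial response — are duplicated exactly once.  The duplicated set is what
the LSTM-SW variants train on.  The score read here is the forest's
probability for the window's *true* class.
"""

from __future__ import annotations

import numpy as np

from .rf import RandomForestWindowClassifier

SW_THRESHOLD = 0.3


def sample_weight_indices(fad_features: np.ndarray, y_class: np.ndarray,
                          threshold: float = SW_THRESHOLD,
                          random_state=None) -> np.ndarray:
    """Row indices of the augmented training set (duplicates adjacent).

    Fits the scoring forest on ``(fad_features, y_class)`` and returns an
    index vector where every qualifying row appears twice, in stable order.
    """
    y_class = np.asarray(y_class)
    fad = np.asarray(fad_features)
    if fad.shape[0] != y_class.shape[0]:
        raise ValueError("facial features and targets disagree in length")
    if fad.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    rf = RandomForestWindowClassifier(random_state=random_state)
    rf.fit(fad, y_class)
    proba = rf.predict_proba(fad)
    cols = np.searchsorted(rf.classes_, y_class)
    true_score = proba[np.arange(y_class.size), cols]
    repeats = np.where(true_score > threshold, 2, 1)
    return np.repeat(np.arange(y_class.size, dtype=np.int64), repeats)


def apply_sample_weighting(features: np.ndarray, targets: np.ndarray,
                           fad_features: np.ndarray, y_class: np.ndarray,
                           threshold: float = SW_THRESHOLD,
                           random_state=None) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(features, targets)`` with qualifying rows duplicated once.

    ``features``/``targets`` are the arrays the downstream model trains on
    (any modality and task); qualification is always judged on the facial
    descriptors and the class targets.
    """
    idx = sample_weight_indices(fad_features, y_class, threshold, random_state)
    return np.asarray(features)[idx], np.asarray(targets)[idx]
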