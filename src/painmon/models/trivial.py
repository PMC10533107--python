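"""Trivial majority-vote baseline: always predict no pain."""

from __future__ import annotations

import numpy as np


def trivial_classifier_scores(n_windows: int, n_classes: int) -> np.ndarray:
    """(n, K) score matrix putting all mass on the no-pain class (index 0)."""
    if n_windows < 0 or n_classes < 1:
        raise ValueError("invalid sizes")
    scores = np.zeros((n_windows, n_classes))
    if n_windows:
        scores[:, 0] = 1.0
    return scores


def trivial_regression(n_windows: int) -> np.ndarray:
    """Constant 0.0 predictions (the no-pain continuous target)."""
    if n_windows < 0:
        raise ValueError("invalid size")
    return np.zeros(n_windows)
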