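"""Decision-level fusion of the two modalities' model outputs.

Late fusion with a fixed mean-score mapping: per window, classifier score
vectors from the EDA and facial models are averaged class-wise and the
highest fused score wins; regression outputs are averaged element-wise.
Fusion is only meaningful within one method family (forest with forest,
LSTM with LSTM, LSTM-SW with LSTM-SW).
"""

from __future__ import annotations

import numpy as np


def _check_aligned(a: np.ndarray, b: np.ndarray,
                   keys_a=None, keys_b=None) -> None:
    if a.shape != b.shape:
        raise ValueError(f"prediction shapes disagree: {a.shape} vs {b.shape}")
    if keys_a is not None or keys_b is not None:
        ka, kb = np.asarray(keys_a), np.asarray(keys_b)
        if ka.shape != kb.shape or not (ka == kb).all():
            raise ValueError("predictions are not aligned window-for-window")


def fuse_classifier_scores(scores_eda: np.ndarray, scores_fad: np.ndarray,
                           keys_eda=None, keys_fad=None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-score fusion of two aligned (n, K) classifier outputs.

    Returns ``(fused_scores, fused_classes)``; argmax ties resolve to the
    lowest class index.
    """
    a = np.asarray(scores_eda, dtype=float)
    b = np.asarray(scores_fad, dtype=float)
    _check_aligned(a, b, keys_eda, keys_fad)
    fused = (a + b) / 2.0
    return fused, np.argmax(fused, axis=1)


def fuse_regression(pred_eda: np.ndarray, pred_fad: np.ndarray,
                    keys_eda=None, keys_fad=None) -> np.ndarray:
    """Element-wise mean of two aligned regression outputs."""
    a = np.asarray(pred_eda, dtype=float)
    b = np.asarray(pred_fad, dtype=float)
    _check_aligned(a, b, keys_eda, keys_fad)
    return (a + b) / 2.0
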