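"""Temporal-integration descriptors and sliding-window assembly.

Raw 25 Hz channels are condensed to one descriptor frame per whole second:
four statistics (min, max, mean, population std) of the raw samples and of
their first and second finite differences, i.e. 12 features per channel.
For the single EDA channel this gives the 12-dimensional EDA descriptor
(EDA-D); for the 21 facial channels the 252-dimensional facial activity
descriptor (FAD).

Descriptor frames are z-scored per subject (person-specific
standardization), the label stream is shifted forward by 3 s to account for
the latency of pain expression, and model inputs are 10-row windows of
consecutive frames labelled by the second that follows the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import (
    ARTIFACT_CODES,
    BASELINE,
    SAMPLING_RATE_HZ,
    SessionRecording,
    code_intensity,
)

N_STATS = 4                     # min, max, mean, std
N_DERIV_ORDERS = 3              # raw, first, second differences
FEATURES_PER_CHANNEL = N_STATS * N_DERIV_ORDERS   # 12
WINDOW_S = 10
LABEL_SHIFT_S = 3


def finite_derivatives(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second finite differences of a 1-D series (lengths n-1, n-2)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("need a 1-D series of length >= 3")
    d1 = np.diff(x)
    return d1, np.diff(d1)


def summarize(x: np.ndarray) -> tuple[float, float, float, float]:
    """(min, max, mean, population std) of a non-empty series."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty series")
    return float(x.min()), float(x.max()), float(x.mean()), float(x.std(ddof=0))


def _second_stats(x: np.ndarray, n_seconds: int, fs: int) -> np.ndarray:
    """Per-second (min, max, mean, std) of one series, segmented by left index.

    Second ``s`` covers sample indices [fs*s, fs*s+fs); near the end of a
    derivative series a second may hold fewer than ``fs`` samples.
    Returns an (n_seconds, 4) array.
    """
    n = x.shape[0]
    out = np.empty((n_seconds, N_STATS), dtype=float)
    n_full = min(n_seconds, n // fs)
    if n_full:
        blocks = x[: n_full * fs].reshape(n_full, fs)
        out[:n_full, 0] = blocks.min(axis=1)
        out[:n_full, 1] = blocks.max(axis=1)
        out[:n_full, 2] = blocks.mean(axis=1)
        out[:n_full, 3] = blocks.std(axis=1, ddof=0)
    for s in range(n_full, n_seconds):
        seg = x[s * fs: s * fs + fs]
        if seg.size == 0:
            raise ValueError("series too short for requested seconds")
        out[s] = summarize(seg)
    return out


def compute_descriptor_frames(channels: np.ndarray,
                              fs: int = SAMPLING_RATE_HZ) -> np.ndarray:
    """Per-second temporal-integration descriptors of a (C, N) channel block.

    Derivatives are taken once over the full series; statistics per second
    use the samples whose left index falls inside that second.  The feature
    layout is channel-major: for each channel
    (raw-min, raw-max, raw-mean, raw-std, d1-min, ..., d2-std).

    Returns an (T, 12*C) array with T = N // fs whole seconds.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim == 1:
        channels = channels[None, :]
    if channels.ndim != 2:
        raise ValueError("channels must be 1-D or (C, N)")
    c, n = channels.shape
    if n < 3 * fs:
        raise ValueError("need at least 3 s of samples")
    n_seconds = n // fs
    out = np.empty((n_seconds, c * FEATURES_PER_CHANNEL), dtype=float)
    for ci in range(c):
        x = channels[ci]
        d1, d2 = finite_derivatives(x)
        base = ci * FEATURES_PER_CHANNEL
        for oi, series in enumerate((x, d1, d2)):
            cols = slice(base + oi * N_STATS, base + (oi + 1) * N_STATS)
            out[:, cols] = _second_stats(series, n_seconds, fs)
    return out


def person_standardize(features: np.ndarray, subject_ids: np.ndarray) -> np.ndarray:
    """Z-score each feature within each subject's own frames.

    Zero-variance features map to 0.  Raises if a subject contributes fewer
    than two frames (its std would be meaningless).
    """
    features = np.asarray(features, dtype=float)
    subject_ids = np.asarray(subject_ids)
    out = np.empty_like(features)
    for sid in np.unique(subject_ids):
        mask = subject_ids == sid
        block = features[mask]
        if block.shape[0] < 2:
            raise ValueError(f"subject {sid!r} has fewer than 2 frames")
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        z = np.where(sd > 0, (block - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out[mask] = z
    return out


def shift_labels(labels: np.ndarray, shift_s: float = LABEL_SHIFT_S,
                 fs: int = SAMPLING_RATE_HZ, fill: int = BASELINE) -> np.ndarray:
    """Shift the 25 Hz label stream forward by ``shift_s`` seconds.

    ``shifted[i] = labels[i - fs*shift_s]``; the first ``fs*shift_s`` samples
    become baseline.
    """
    if shift_s < 0:
        raise ValueError("shift_s must be >= 0")
    k = int(round(shift_s * fs))
    labels = np.asarray(labels)
    if k == 0:
        return labels.copy()
    out = np.full_like(labels, fill)
    out[k:] = labels[:-k] if k < labels.shape[0] else fill
    return out


def _label_priority(code: int) -> tuple[int, int, int]:
    # artifacts beat everything; then higher stimulus intensity; then the
    # lower code (heat before electrical) for a fixed deterministic order
    return (1 if code in ARTIFACT_CODES else 0, code_intensity(code), -code)


def per_second_labels(labels: np.ndarray, fs: int = SAMPLING_RATE_HZ) -> np.ndarray:
    """One label per whole second: the within-second majority code.

    Ties go to artifact codes first, then to the higher stimulus intensity.
    """
    labels = np.asarray(labels)
    n_seconds = labels.shape[0] // fs
    out = np.empty(n_seconds, dtype=labels.dtype)
    blocks = labels[: n_seconds * fs].reshape(n_seconds, fs)
    for s in range(n_seconds):
        codes, counts = np.unique(blocks[s], return_counts=True)
        best = counts.max()
        tied = codes[counts == best]
        out[s] = max(tied.tolist(), key=_label_priority)
    return out


@dataclass
class WindowSet:
    """Aligned 10-s windows for one or more modalities.

    ``features`` maps modality name ('eda', 'facial') to an (n, 10, F)
    array; rows share ``subject_ids``, window-end seconds ``t_end`` and the
    per-second ``label_codes``.  Class / continuous targets are filled in by
    the dataset builder.
    """

    subject_ids: np.ndarray
    t_end: np.ndarray
    label_codes: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)
    y_class: np.ndarray | None = None
    y_cont: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.label_codes.shape[0])

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            subject_ids=self.subject_ids[mask],
            t_end=self.t_end[mask],
            label_codes=self.label_codes[mask],
            features={k: v[mask] for k, v in self.features.items()},
            y_class=None if self.y_class is None else self.y_class[mask],
            y_cont=None if self.y_cont is None else self.y_cont[mask],
        )

    def concat(self, other: "WindowSet") -> "WindowSet":
        cat = np.concatenate
        return WindowSet(
            subject_ids=cat([self.subject_ids, other.subject_ids]),
            t_end=cat([self.t_end, other.t_end]),
            label_codes=cat([self.label_codes, other.label_codes]),
            features={k: cat([v, other.features[k]]) for k, v in self.features.items()},
        )


def build_windows(frames: np.ndarray, second_labels: np.ndarray,
                  window_s: int = WINDOW_S) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding 10-row windows over per-second frames, stepped once per second.

    Window ``t`` stacks frames ``t-10 .. t-1`` and predicts the label of
    second ``t``; the first 10 seconds produce no window.  Returns
    ``(X (n,10,F), labels (n,), t_end (n,))``.
    """
    frames = np.asarray(frames, dtype=float)
    second_labels = np.asarray(second_labels)
    t_total = frames.shape[0]
    if second_labels.shape[0] != t_total:
        raise ValueError("frames and per-second labels disagree in length")
    if t_total <= window_s:
        f = frames.shape[1] if frames.ndim == 2 else 0
        return (np.empty((0, window_s, f)), np.empty(0, dtype=second_labels.dtype),
                np.empty(0, dtype=np.int64))
    t_end = np.arange(window_s, t_total, dtype=np.int64)
    sw = np.lib.stride_tricks.sliding_window_view(frames, window_s, axis=0)
    x = np.ascontiguousarray(np.moveaxis(sw[: t_total - window_s], 2, 1))
    return x, second_labels[window_s:], t_end


def featurize_recording(rec: SessionRecording, shift_s: float = LABEL_SHIFT_S,
                        standardize: bool = True) -> WindowSet:
    """Full descriptor pipeline for one recording.

    EDA-D and FAD frames, optional person-specific standardization over the
    subject's whole recording, 3-s label shift, per-second label reduction
    and 10-s window assembly.  The returned windows carry both modalities,
    aligned row by row.
    """
    eda_frames = compute_descriptor_frames(rec.eda, rec.sampling_rate_hz)
    fad_frames = compute_descriptor_frames(rec.facial, rec.sampling_rate_hz)
    if standardize:
        sid = np.full(eda_frames.shape[0], rec.profile.subject_id)
        eda_frames = person_standardize(eda_frames, sid)
        fad_frames = person_standardize(fad_frames, sid)
    shifted = shift_labels(rec.labels, shift_s, rec.sampling_rate_hz)
    sec_labels = per_second_labels(shifted, rec.sampling_rate_hz)
    x_eda, labels, t_end = build_windows(eda_frames, sec_labels)
    x_fad, _, _ = build_windows(fad_frames, sec_labels)
    subject_ids = np.full(labels.shape[0], rec.profile.subject_id, dtype=object)
    return WindowSet(subject_ids=subject_ids, t_end=t_end, label_codes=labels,
                     features={"eda": x_eda, "facial": x_fad})


def featurize_cohort(recordings, shift_s: float = LABEL_SHIFT_S,
                     standardize: bool = True) -> WindowSet:
    """Featurize every recording and stack the windows subject after subject."""
    sets = [featurize_recording(r, shift_s, standardize) for r in recordings]
    out = sets[0]
    for ws in sets[1:]:
        out = out.concat(ws)
    return out
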