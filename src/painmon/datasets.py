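"""Construction of the 11 task datasets from windowed samples.

The continuous recording is heavily dominated by no-pain (baseline, BL)
windows, so the task is split into datasets by stimulus type (phasic /
tonic) and quality (heat / electrical / both), each with artifact windows
removed and baseline runs attributed to the pain sequence that follows
them.  The *reduced* variants additionally shrink each baseline run to at
most as many windows as the pain sequence it precedes, bringing the BL
share of phasic datasets to ~50%.

Dataset ids: PD, HPD, EPD, TD, HTD, ETD and the reduced RPD, RHPD, REPD,
RTD, RETD (there is no reduced heat-tonic dataset: HTD is already close to
balanced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import WindowSet
from .simulate import ARTIFACT_CODES, BASELINE, decode_label

INTENSITY_NAMES = {1: "low", 2: "moderate", 3: "severe"}


@dataclass(frozen=True)
class DatasetSpec:
    """Filter, class-count and reduction rules of one named dataset."""

    id: str
    stim_type: str          # "phasic" | "tonic"
    quality: str            # "heat" | "electrical" | "both"
    reduced: bool

    @property
    def n_classes(self) -> int:
        return 7 if self.quality == "both" else 4

    def keeps_code(self, code: int) -> bool:
        if code == BASELINE or code in ARTIFACT_CODES:
            return False
        stim_type, quality, _ = decode_label(code)
        if stim_type != self.stim_type:
            return False
        return self.quality in ("both", quality)

    def class_index(self, code: int) -> int:
        """Class encoding: 0 = BL; 7-class order BL,H1,H2,H3,E1,E2,E3."""
        if code == BASELINE:
            return 0
        _, quality, intensity = decode_label(code)
        if self.n_classes == 4:
            return intensity
        return intensity + (3 if quality == "electrical" else 0)


DATASET_SPECS: dict[str, DatasetSpec] = {
    "PD": DatasetSpec("PD", "phasic", "both", False),
    "HPD": DatasetSpec("HPD", "phasic", "heat", False),
    "EPD": DatasetSpec("EPD", "phasic", "electrical", False),
    "TD": DatasetSpec("TD", "tonic", "both", False),
    "HTD": DatasetSpec("HTD", "tonic", "heat", False),
    "ETD": DatasetSpec("ETD", "tonic", "electrical", False),
    "RPD": DatasetSpec("RPD", "phasic", "both", True),
    "RHPD": DatasetSpec("RHPD", "phasic", "heat", True),
    "REPD": DatasetSpec("REPD", "phasic", "electrical", True),
    "RTD": DatasetSpec("RTD", "tonic", "both", True),
    "RETD": DatasetSpec("RETD", "tonic", "electrical", True),
}


def get_spec(dataset_id: str) -> DatasetSpec:
    try:
        return DATASET_SPECS[dataset_id]
    except KeyError:
        raise ValueError(f"unknown dataset id {dataset_id!r}; "
                         f"expected one of {sorted(DATASET_SPECS)}") from None


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal codes as (start, stop, code) over an index range."""
    if codes.size == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [codes.size]))
    return [(int(a), int(b), int(codes[a])) for a, b in zip(starts, stops)]


def _filter_subject_mask(codes: np.ndarray, spec: DatasetSpec) -> np.ndarray:
    """Keep-mask for one subject's time-ordered window codes.

    Artifact windows are dropped first; in the remaining stream each BL run
    is attributed to the pain sequence immediately following it and is kept
    only if that sequence is kept; trailing BL is dropped.
    """
    keep = np.zeros(codes.size, dtype=bool)
    valid = ~np.isin(codes, ARTIFACT_CODES)
    idx = np.flatnonzero(valid)
    stream = codes[idx]
    runs = _runs(stream)
    # merge adjacent BL runs that became contiguous after artifact removal
    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if merged and run[2] == BASELINE and merged[-1][2] == BASELINE:
            merged[-1] = (merged[-1][0], run[1], BASELINE)
        else:
            merged.append(run)
    for i, (a, b, code) in enumerate(merged):
        if code == BASELINE:
            nxt = merged[i + 1] if i + 1 < len(merged) else None
            keep_run = nxt is not None and spec.keeps_code(nxt[2])
        else:
            keep_run = spec.keeps_code(code)
        if keep_run:
            keep[idx[a:b]] = True
    return keep


def filter_windows(windows: WindowSet, spec: DatasetSpec | str) -> WindowSet:
    """Apply a dataset's artifact/type/quality filters to a window stream.

    ``windows`` must be time-ordered within each subject.  Returns the kept
    subset (baseline runs follow their pain sequence, per the attribution
    rule above).
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    mask = np.zeros(len(windows), dtype=bool)
    for sid in np.unique(windows.subject_ids):
        smask = windows.subject_ids == sid
        mask[smask] = _filter_subject_mask(windows.label_codes[smask], spec)
    return windows.subset(mask)


def reduce_no_pain(windows: WindowSet, spec: DatasetSpec | str) -> WindowSet:
    """Shrink each BL run to the length of the pain sequence that follows it.

    A pain sequence of m windows keeps only the m baseline windows
    immediately preceding it (all of them if fewer exist); pain windows are
    never touched.  Requires a reduced dataset spec.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    if not spec.reduced:
        raise ValueError(f"dataset {spec.id} is not a reduced dataset")
    mask = np.ones(len(windows), dtype=bool)
    for sid in np.unique(windows.subject_ids):
        sidx = np.flatnonzero(windows.subject_ids == sid)
        runs = _runs(windows.label_codes[sidx])
        for i, (a, b, code) in enumerate(runs):
            if code != BASELINE:
                continue
            nxt = runs[i + 1] if i + 1 < len(runs) else None
            m = (nxt[1] - nxt[0]) if nxt is not None and nxt[2] != BASELINE else 0
            drop_until = max(a, b - m)
            mask[sidx[a:drop_until]] = False
    return windows.subset(mask)


def encode_labels(windows: WindowSet, spec: DatasetSpec | str) -> WindowSet:
    """Attach class indices and normalized continuous targets.

    Classes: 0 = BL; 4-class datasets use 1..3 by intensity; 7-class use
    BL, H1..H3, E1..E3.  The continuous target is intensity / 3 (BL -> 0,
    low -> 1/3, moderate -> 2/3, severe -> 1), ignoring quality.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    codes = windows.label_codes
    bad = [int(c) for c in np.unique(codes)
           if c != BASELINE and not spec.keeps_code(int(c))]
    if bad:
        raise ValueError(f"codes {bad} are inconsistent with dataset {spec.id}")
    windows.y_class = np.array([spec.class_index(int(c)) for c in codes],
                               dtype=np.int64)
    windows.y_cont = np.array(
        [0.0 if c == BASELINE else decode_label(int(c))[2] / 3.0 for c in codes])
    return windows


def class_to_continuous(y_class: np.ndarray, n_classes: int) -> np.ndarray:
    """Map class indices back to the normalized intensity scale.

    4-class: index/3.  7-class: BL -> 0, H1..H3 -> 1/3..1, E1..E3 -> 1/3..1
    (quality ignored).
    """
    y = np.asarray(y_class, dtype=np.int64)
    if n_classes == 4:
        return y / 3.0
    intensity = np.where(y == 0, 0, (y - 1) % 3 + 1)
    return intensity / 3.0


def build_dataset(windows: WindowSet, dataset_id: str) -> WindowSet:
    """Filter (+ reduce, for R* datasets) and encode one named dataset."""
    spec = get_spec(dataset_id)
    out = filter_windows(windows, spec)
    if spec.reduced:
        out = reduce_no_pain(out, spec)
    return encode_labels(out, spec)


def class_counts(windows: WindowSet, spec: DatasetSpec | str) -> dict[int, int]:
    if isinstance(spec, str):
        spec = get_spec(spec)
    if windows.y_class is None:
        raise ValueError("encode_labels must run first")
    counts = dict.fromkeys(range(spec.n_classes), 0)
    vals, n = np.unique(windows.y_class, return_counts=True)
    counts.update({int(v): int(c) for v, c in zip(vals, n)})
    return counts
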