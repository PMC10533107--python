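"""Synthetic multimodal pain-session generator.

Emulates a stimulation protocol in which each of two pain qualities (heat,
electrical) is applied at three intensities, either as short 5-s *phasic*
stimuli repeated 30 times with 8-12 s pauses, or as 60-s *tonic* stimuli
applied once per (quality, intensity) and followed by a 5-minute pause.
The recording is a 25 Hz multichannel time series: one electrodermal
activity (EDA) channel, 21 facial-activity channels (head pose + action-unit
style intensities), and a per-sample integer label stream.

Stimulus-locked EDA responses use a difference-of-exponentials skin
conductance response (SCR) kernel whose peak amplitude grows linearly with
stimulus intensity; facial responses are scaled by a per-subject
expressiveness category (1-4), category 1 meaning no facial response to
pain.  Short artifact spans can overwrite labels with the codes -10/-11
used for experimental issues; artifact injection never touches the signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SAMPLING_RATE_HZ = 25

BASELINE = 0
ART_NEG10 = -10
ART_NEG11 = -11
ARTIFACT_CODES = (ART_NEG10, ART_NEG11)

QUALITIES = ("heat", "electrical")
INTENSITIES = (1, 2, 3)

# 21 facial channels: 3 head-pose angles, one binary AU occurrence channel,
# and 17 AU-intensity channels (OpenFace-style layout).
FACIAL_CHANNEL_NAMES = (
    "pose_yaw", "pose_pitch", "pose_roll", "au01_occ",
    "au01", "au02", "au04", "au05", "au06", "au07", "au09", "au10",
    "au12", "au14", "au15", "au17", "au20", "au23", "au25", "au26", "au45",
)
N_FACIAL_CHANNELS = len(FACIAL_CHANNEL_NAMES)

# Channels carrying stimulus-locked pain expression (brow lowerer AU4,
# orbit tightening AU6/AU7, nose wrinkle AU9, upper-lip raise AU10,
# mouth opening AU25/AU26); the rest are noise-only.
PAIN_RESPONSIVE_CHANNELS = (6, 8, 9, 10, 11, 18, 19)
# Relative loading of each responsive channel on the pain response.
_CHANNEL_LOADING = (1.0, 0.9, 0.8, 0.7, 0.7, 0.5, 0.5)


def stimulus_code(stim_type: str, quality: str, intensity: int) -> int:
    """Integer label code for a pain stimulus class.

    Phasic heat 1-3 -> 1,2,3; phasic electrical -> 4,5,6; tonic heat ->
    7,8,9; tonic electrical -> 10,11,12.  Baseline (no pain) is 0.
    """
    base = {"phasic": 0, "tonic": 6}[stim_type]
    offset = {"heat": 0, "electrical": 3}[quality]
    if intensity not in INTENSITIES:
        raise ValueError(f"intensity must be 1..3, got {intensity}")
    return base + offset + intensity


def decode_label(code: int) -> tuple[str, str, int]:
    """Inverse of :func:`stimulus_code` for pain codes 1..12."""
    if not 1 <= code <= 12:
        raise ValueError(f"not a pain code: {code}")
    stim_type = "phasic" if code <= 6 else "tonic"
    rem = (code - 1) % 6
    quality = "heat" if rem < 3 else "electrical"
    intensity = rem % 3 + 1
    return stim_type, quality, intensity


def code_intensity(code: int) -> int:
    """Stimulus intensity of a label code; 0 for baseline and artifacts."""
    if 1 <= code <= 12:
        return decode_label(code)[2]
    return 0


@dataclass(frozen=True)
class StimulusEvent:
    """One pain stimulus in the session schedule."""

    onset_s: float
    duration_s: float
    stim_type: str      # "phasic" | "tonic"
    quality: str        # "heat" | "electrical"
    intensity: int      # 1 | 2 | 3

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def code(self) -> int:
        return stimulus_code(self.stim_type, self.quality, self.intensity)


@dataclass
class SubjectProfile:
    """Per-subject response parameters.

    ``expressiveness_category`` follows the 1-4 grading of facial pain
    response intensity; category 1 subjects show no facial response
    (facial_gain 0) while EDA responses are present in every category.
    """

    subject_id: str
    expressiveness_category: int
    eda_gain: float          # SCR peak amplitude per intensity unit (uS)
    facial_gain: float       # facial bump amplitude per intensity unit
    scr_latency_s: float     # SCR onset latency, 1-3 s
    noise_sd: float          # i.i.d. Gaussian noise scale per channel

    def __post_init__(self) -> None:
        if self.expressiveness_category not in (1, 2, 3, 4):
            raise ValueError("expressiveness_category must be in 1..4")
        if self.eda_gain < 0 or self.facial_gain < 0 or self.noise_sd < 0:
            raise ValueError("gains and noise_sd must be >= 0")
        if self.expressiveness_category == 1 and self.facial_gain > 1e-9:
            raise ValueError("category 1 implies facial_gain ~ 0")


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic protocol."""

    n_subjects: int = 10
    qualities: Sequence[str] = QUALITIES
    intensities: Sequence[int] = INTENSITIES
    phasic_reps: int = 30
    phasic_duration_s: float = 5.0
    phasic_pause_range_s: tuple[float, float] = (8.0, 12.0)
    tonic_reps: int = 1
    tonic_duration_s: float = 60.0
    tonic_pause_s: float = 300.0
    lead_in_s: float = 15.0
    tail_pause_s: float = 10.0
    interleave: str = "phasic_first"   # or "tonic_first"
    artifact_fraction: float = 0.02
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    eda_baseline_us: float = 2.0
    eda_drift_amplitude: float = 0.05
    scr_rise_s: float = 0.75
    scr_decay_s: float = 4.0
    facial_rise_s: float = 0.3
    facial_decay_s: float = 1.5
    amplitude_jitter_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.phasic_reps < 0 or self.tonic_reps < 0:
            raise ValueError("repetition counts must be >= 0")
        for d in (self.phasic_duration_s, self.tonic_duration_s):
            if d <= 0:
                raise ValueError("stimulus durations must be > 0")
        lo, hi = self.phasic_pause_range_s
        if not 0 <= lo <= hi:
            raise ValueError("invalid phasic pause range")
        if not math.isclose(sum(self.split_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("split_fractions must sum to 1")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.interleave not in ("phasic_first", "tonic_first"):
            raise ValueError("interleave must be 'phasic_first' or 'tonic_first'")


@dataclass
class SessionRecording:
    """One subject's 25 Hz recording: EDA, facial channels, label stream."""

    eda: np.ndarray                 # (N,)
    facial: np.ndarray              # (21, N)
    labels: np.ndarray              # (N,) integer codes
    schedule: list[StimulusEvent]
    profile: SubjectProfile
    sampling_rate_hz: int = SAMPLING_RATE_HZ

    @property
    def n_samples(self) -> int:
        return self.eda.shape[0]

    def __post_init__(self) -> None:
        n = self.eda.shape[0]
        if self.facial.shape != (N_FACIAL_CHANNELS, n) or self.labels.shape != (n,):
            raise ValueError("channel lengths disagree")


# ---------------------------------------------------------------------------
# schedule


def generate_schedule(cfg: GeneratorConfig, rng: np.random.Generator) -> list[StimulusEvent]:
    """Draw one randomized stimulation schedule.

    The phasic part interleaves all (quality, intensity) repetitions in
    randomized order with uniform 8-12 s pauses; the tonic part applies each
    (quality, intensity) once for 60 s followed by a 300 s pause.  Block
    order is configurable (``cfg.interleave``); the default runs the phasic
    block first.
    """
    cfg.validate()
    phasic_specs = [
        ("phasic", q, i)
        for q in cfg.qualities for i in cfg.intensities
        for _ in range(cfg.phasic_reps)
    ]
    tonic_specs = [
        ("tonic", q, i)
        for q in cfg.qualities for i in cfg.intensities
        for _ in range(cfg.tonic_reps)
    ]
    rng.shuffle(phasic_specs)
    rng.shuffle(tonic_specs)

    blocks = [phasic_specs, tonic_specs]
    if cfg.interleave == "tonic_first":
        blocks.reverse()

    events: list[StimulusEvent] = []
    t = cfg.lead_in_s
    lo, hi = cfg.phasic_pause_range_s
    for block in blocks:
        for stim_type, quality, intensity in block:
            if stim_type == "phasic":
                dur, pause = cfg.phasic_duration_s, float(rng.uniform(lo, hi))
            else:
                dur, pause = cfg.tonic_duration_s, cfg.tonic_pause_s
            events.append(StimulusEvent(t, dur, stim_type, quality, intensity))
            t = t + dur + pause
    return events


def session_duration_s(schedule: Sequence[StimulusEvent], cfg: GeneratorConfig) -> float:
    """Total session length: lead-in through the last pause plus a short tail."""
    if not schedule:
        return cfg.lead_in_s + cfg.tail_pause_s
    last = schedule[-1]
    pause = cfg.tonic_pause_s if last.stim_type == "tonic" else np.mean(cfg.phasic_pause_range_s)
    return last.offset_s + float(pause) + cfg.tail_pause_s


def labels_from_schedule(schedule: Sequence[StimulusEvent], n_samples: int,
                         fs: int = SAMPLING_RATE_HZ) -> np.ndarray:
    """Per-sample label stream: the covering event's code, baseline elsewhere."""
    labels = np.full(n_samples, BASELINE, dtype=np.int64)
    for ev in schedule:
        i0 = int(round(ev.onset_s * fs))
        i1 = min(int(round(ev.offset_s * fs)), n_samples)
        labels[i0:i1] = ev.code
    return labels


# ---------------------------------------------------------------------------
# signal synthesis


def scr_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials response kernel, peak-normalized to 1."""
    if decay_s <= rise_s:
        raise ValueError("decay must be slower than rise")
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s)
                 - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    t_peak = scr_kernel_peak_time(rise_s, decay_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def scr_kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Closed-form argmax of the difference-of-exponentials kernel."""
    return rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)


def _add_response(out: np.ndarray, onset_s: float, duration_s: float,
                  sustained: bool, amplitude: float, rise_s: float,
                  decay_s: float, fs: int) -> None:
    """Add one stimulus-locked response to ``out`` in place."""
    n = out.shape[0]
    i0 = int(round(onset_s * fs))
    if i0 >= n or amplitude == 0.0:
        return
    if not sustained:
        span = int(round((scr_kernel_peak_time(rise_s, decay_s) + 8 * decay_s) * fs))
        i1 = min(n, i0 + span)
        t = (np.arange(i1 - i0)) / fs
        out[i0:i1] += amplitude * scr_kernel(t, rise_s, decay_s)
    else:
        # saturating rise to a plateau over the stimulus, exponential release
        i_off = min(n, int(round((onset_s + duration_s) * fs)))
        t_on = np.arange(i_off - i0) / fs
        out[i0:i_off] += amplitude * (1.0 - np.exp(-t_on / rise_s))
        level = amplitude * (1.0 - np.exp(-duration_s / rise_s))
        i1 = min(n, i_off + int(round(8 * decay_s * fs)))
        t_off = np.arange(i1 - i_off) / fs
        out[i_off:i1] += level * np.exp(-t_off / decay_s)


def synthesize_eda(schedule: Sequence[StimulusEvent], profile: SubjectProfile,
                   cfg: GeneratorConfig, rng: np.random.Generator,
                   n_samples: int | None = None) -> np.ndarray:
    """Simulate the skin-conductance channel.

    Tonic level + optional slow drift + one SCR per stimulus (peak amplitude
    ``eda_gain * intensity`` with multiplicative jitter; tonic stimuli hold a
    sustained plateau) + i.i.d. Gaussian noise.
    """
    if n_samples is None:
        n_samples = int(math.ceil(session_duration_s(schedule, cfg) * SAMPLING_RATE_HZ))
    fs = SAMPLING_RATE_HZ
    t = np.arange(n_samples) / fs
    out = np.full(n_samples, cfg.eda_baseline_us, dtype=float)
    if cfg.eda_drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += cfg.eda_drift_amplitude * np.sin(2 * np.pi * t / 300.0 + phase)
    for ev in schedule:
        jitter = 1.0 + cfg.amplitude_jitter_sd * rng.standard_normal()
        amp = profile.eda_gain * ev.intensity * max(jitter, 0.1)
        _add_response(out, ev.onset_s + profile.scr_latency_s, ev.duration_s,
                      ev.stim_type == "tonic", amp, cfg.scr_rise_s,
                      cfg.scr_decay_s, fs)
    if profile.noise_sd > 0:
        out += rng.normal(0.0, profile.noise_sd, n_samples)
    return out


def synthesize_facial(schedule: Sequence[StimulusEvent], profile: SubjectProfile,
                      cfg: GeneratorConfig, rng: np.random.Generator,
                      n_samples: int | None = None) -> np.ndarray:
    """Simulate the 21 facial channels.

    A fixed subset of pain-responsive channels receives stimulus-locked
    bumps of amplitude ``facial_gain * intensity`` (times a per-channel
    loading); all other channels are noise only.  Category-1 subjects have
    facial_gain 0, hence flat responsive channels.
    """
    if n_samples is None:
        n_samples = int(math.ceil(session_duration_s(schedule, cfg) * SAMPLING_RATE_HZ))
    fs = SAMPLING_RATE_HZ
    out = np.zeros((N_FACIAL_CHANNELS, n_samples), dtype=float)
    for ev in schedule:
        jitter = 1.0 + cfg.amplitude_jitter_sd * rng.standard_normal()
        amp = profile.facial_gain * ev.intensity * max(jitter, 0.1)
        if amp == 0.0:
            continue
        # facial response onset lags the stimulus by ~0.5 s
        for ch, loading in zip(PAIN_RESPONSIVE_CHANNELS, _CHANNEL_LOADING):
            _add_response(out[ch], ev.onset_s + 0.5, ev.duration_s,
                          ev.stim_type == "tonic", amp * loading,
                          cfg.facial_rise_s, cfg.facial_decay_s, fs)
    if profile.noise_sd > 0:
        out += rng.normal(0.0, profile.noise_sd, out.shape)
    return out


def inject_artifacts(recording: SessionRecording, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> SessionRecording:
    """Overwrite labels on random non-overlapping spans with -10/-11.

    The signal itself is untouched; spans are 1-4 s long and are drawn until
    roughly ``artifact_fraction`` of samples carry an artifact code.
    """
    if not 0 <= cfg.artifact_fraction < 1:
        raise ValueError("artifact_fraction must be in [0, 1)")
    if cfg.artifact_fraction == 0:
        return recording
    n = recording.n_samples
    fs = recording.sampling_rate_hz
    target = int(cfg.artifact_fraction * n)
    labels = recording.labels.copy()
    covered = 0
    for _ in range(10 * n):           # bounded retry loop
        if covered >= target:
            break
        span = int(rng.uniform(1.0, 4.0) * fs)
        i0 = int(rng.integers(0, max(1, n - span)))
        seg = labels[i0:i0 + span]
        if np.isin(seg, ARTIFACT_CODES).any():
            continue
        labels[i0:i0 + span] = ART_NEG10 if rng.random() < 0.5 else ART_NEG11
        covered += span
    recording.labels = labels
    return recording


# ---------------------------------------------------------------------------
# cohort


def _facial_gain_base(category: int) -> float:
    # category 1: no facial response; 2-4: increasing expressiveness
    return 0.0 if category == 1 else 0.4 * (category - 1)


def sample_profile(subject_id: str, category: int,
                   rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's response parameters."""
    base = _facial_gain_base(category)
    return SubjectProfile(
        subject_id=subject_id,
        expressiveness_category=category,
        eda_gain=float(rng.uniform(0.4, 0.8)),
        facial_gain=0.0 if base == 0.0 else float(base * rng.uniform(0.8, 1.2)),
        scr_latency_s=float(rng.uniform(1.0, 3.0)),
        noise_sd=float(rng.uniform(0.02, 0.08)),
    )


def generate_session(profile: SubjectProfile, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> SessionRecording:
    """Generate one subject's full session (schedule, signals, labels, artifacts)."""
    schedule = generate_schedule(cfg, rng)
    n = int(math.ceil(session_duration_s(schedule, cfg) * SAMPLING_RATE_HZ))
    eda = synthesize_eda(schedule, profile, cfg, rng, n)
    facial = synthesize_facial(schedule, profile, cfg, rng, n)
    labels = labels_from_schedule(schedule, n)
    rec = SessionRecording(eda=eda, facial=facial, labels=labels,
                           schedule=schedule, profile=profile)
    return inject_artifacts(rec, cfg, rng)


def split_subjects(subject_ids: Sequence[str], categories: Sequence[int],
                   fractions: tuple[float, float, float],
                   rng: np.random.Generator) -> dict[str, str]:
    """Subject-level train/val/test assignment, stratified by category.

    Split sizes honour the requested fractions on the whole cohort (each
    split gets at least one subject); subjects are allocated category by
    category so every split sees every represented category where counts
    allow.
    """
    n = len(subject_ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to populate all splits")
    n_test = max(1, int(round(fractions[2] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("split fractions leave no training subjects")
    target = {"train": n_train, "val": n_val, "test": n_test}
    quota = dict(target)
    # walk subjects category by category (shuffled within category) and give
    # each to the split with the largest unfilled share, ties favouring the
    # small splits so val/test draw from distinct categories first
    ordered: list[str] = []
    for cat in sorted(set(categories)):
        members = [s for s, c in zip(subject_ids, categories) if c == cat]
        ordered.extend(members[i] for i in rng.permutation(len(members)))
    assignment: dict[str, str] = {}
    for subj in ordered:
        split = max(("val", "test", "train"), key=lambda s: quota[s] / target[s])
        assignment[subj] = split
        quota[split] -= 1
    return assignment


def generate_cohort(cfg: GeneratorConfig) -> tuple[list[SessionRecording], dict[str, str]]:
    """Generate all subjects' sessions plus the train/val/test assignment.

    Deterministic given ``cfg.seed``: the cohort RNG spawns one child stream
    per subject, so sessions do not depend on generation order.
    """
    cfg.validate()
    if cfg.n_subjects < 3:
        raise ValueError("need n_subjects >= 3 to populate all splits")
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subject_ids = [f"S{i + 1:03d}" for i in range(cfg.n_subjects)]
    # roughly uniform categories 1-4, shuffled
    categories = [(i % 4) + 1 for i in range(cfg.n_subjects)]
    categories = [categories[i] for i in rng.permutation(cfg.n_subjects)]
    assignment = split_subjects(subject_ids, categories, cfg.split_fractions, rng)
    recordings = []
    for sid, cat, child in zip(subject_ids, categories, ss.spawn(cfg.n_subjects + 1)[1:]):
        sub_rng = np.random.default_rng(child)
        profile = sample_profile(sid, cat, sub_rng)
        recordings.append(generate_session(profile, cfg, sub_rng))
    return recordings, assignment


# ---------------------------------------------------------------------------
# session files & manifest


def session_to_frame(rec: SessionRecording) -> pd.DataFrame:
    """Columnar view of a recording: time_s, eda, f01..f21, label."""
    data = {"time_s": np.round(np.arange(rec.n_samples) / rec.sampling_rate_hz, 6),
            "eda": rec.eda}
    for i in range(N_FACIAL_CHANNELS):
        data[f"f{i + 1:02d}"] = rec.facial[i]
    data["label"] = rec.labels
    return pd.DataFrame(data)


def write_session(rec: SessionRecording, path: str | Path) -> None:
    session_to_frame(rec).to_csv(path, index=False, float_format="%.6f")


def read_session(path: str | Path, profile: SubjectProfile | None = None) -> SessionRecording:
    """Load a session file written by :func:`write_session`.

    The schedule is not stored in the file; it is reconstructed only as far
    as the label stream allows (per-sample codes), which is all downstream
    stages need.
    """
    df = pd.read_csv(path)
    facial = df[[f"f{i + 1:02d}" for i in range(N_FACIAL_CHANNELS)]].to_numpy().T
    if profile is None:
        profile = SubjectProfile(subject_id=Path(path).stem,
                                 expressiveness_category=2, eda_gain=0.5,
                                 facial_gain=0.4, scr_latency_s=2.0, noise_sd=0.05)
    return SessionRecording(eda=df["eda"].to_numpy(), facial=facial,
                            labels=df["label"].to_numpy(dtype=np.int64),
                            schedule=[], profile=profile)


def write_cohort(recordings: Sequence[SessionRecording], assignment: dict[str, str],
                 out_dir: str | Path, cfg: GeneratorConfig) -> Path:
    """Write one CSV per subject plus a JSON cohort manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        sid = rec.profile.subject_id
        fname = f"{sid}.csv"
        write_session(rec, out_dir / fname)
        entries.append({
            "subject_id": sid,
            "category": rec.profile.expressiveness_category,
            "split": assignment[sid],
            "file": fname,
        })
    manifest = {"seed": cfg.seed, "sampling_rate_hz": SAMPLING_RATE_HZ,
                "config": {k: v for k, v in asdict(cfg).items()},
                "subjects": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=list))
    return path
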