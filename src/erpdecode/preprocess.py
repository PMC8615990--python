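"""Continuous-to-epochs preprocessing.

Stages, in the order the pipeline applies them: zero-phase band-pass of the
continuous recording, common average reference, segmentation into epochs
around target onset, baseline correction over the 300 ms preceding prime
onset, and deterministic peak-to-peak artifact rejection. All user-facing
times are in ms relative to target onset; windows are half-open
``[start, end)``; sample 0 of an epoch is ``tmin``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RawRecording",
    "EpochSet",
    "bandpass",
    "common_average",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
    "preprocess_study",
    "validate_events",
]

#: label encoding of the two conditions: near = +1, far = -1
LABEL_OF_CONDITION = {"near": 1, "far": -1}
CONDITION_OF_LABEL = {1: "near", -1: "far"}


@dataclass
class RawRecording:
    """One subject's continuous multichannel recording (uV)."""

    data: np.ndarray  # channels x samples
    sfreq_hz: float
    ch_names: list[str]
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length mismatch")


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with labels and bookkeeping.

    ``labels`` uses the +1 (near) / -1 (far) encoding that the decoder's sign
    rule assumes. ``subject_ids`` assigns every trial to a subject, which
    defines the leave-one-subject-out folds downstream.
    """

    data: np.ndarray  # trials x channels x samples
    times_ms: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    sfreq_hz: float
    ch_names: list[str]
    rt_ms: np.ndarray | None = None
    n_rejected: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.isin(self.labels, [-1, 1]).all():
            raise ValueError("labels must be +1 (near) or -1 (far)")
        if len(self.labels) != len(self.data) or len(self.subject_ids) != len(self.data):
            raise ValueError("labels/subject_ids length mismatch")
        if len(self.times_ms) != self.data.shape[2]:
            raise ValueError("times_ms length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, idx) -> "EpochSet":
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            rt_ms=None if self.rt_ms is None else self.rt_ms[idx],
        )

    def time_mask(self, window_ms) -> np.ndarray:
        """Boolean sample mask for a half-open [start, end) ms window."""
        start, end = window_ms
        if start >= end:
            raise ValueError("window must be an increasing pair")
        return (self.times_ms >= start) & (self.times_ms < end)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    required = {"onset_sample", "condition", "trial_type"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    onsets = events["onset_sample"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    bad = ~events["condition"].isin(["near", "far"])
    if bad.any():
        raise ValueError("condition must be 'near' or 'far'")
    return events


def bandpass(raw: RawRecording, low_hz: float = 1.0, high_hz: float = 40.0,
             order: int = 2) -> RawRecording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    The filter is designed at the given order and applied forward and backward
    (``sosfiltfilt``), which squares the magnitude response -- a second-order
    design therefore yields a fourth-order effective roll-off and exactly zero
    phase. Edge transients are mitigated by odd-reflection padding.
    """
    if not (0 < low_hz < high_hz < raw.sfreq_hz / 2):
        raise ValueError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist "
            f"({raw.sfreq_hz / 2})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=raw.sfreq_hz, output="sos")
    out = signal.sosfiltfilt(sos, raw.data, axis=-1)
    return replace(raw, data=out)


def common_average(x: RawRecording | EpochSet):
    """Re-reference to the common average: subtract the instantaneous mean
    across channels at every sample (per trial for an :class:`EpochSet`)."""
    if isinstance(x, RawRecording):
        if x.data.shape[0] < 2:
            raise ValueError("common average reference needs >= 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=0, keepdims=True))
    if isinstance(x, EpochSet):
        if x.n_channels < 2:
            raise ValueError("common average reference needs >= 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=1, keepdims=True))
    raise TypeError(f"unsupported input type {type(x).__name__}")


def epoch(raw: RawRecording, events: pd.DataFrame, tmin_ms: float = -1500.0,
          tmax_ms: float = 1500.0) -> EpochSet:
    """Cut one epoch per go event, time-locked to target onset.

    No-go events never enter the returned :class:`EpochSet` (the decoding
    analysis is restricted to executed go trials). Events whose epoch would
    extend past either edge of the recording are dropped with a warning.
    The epoch has ``round((tmax - tmin)/1000 * sfreq)`` samples covering the
    half-open window ``[tmin, tmax)``.
    """
    validate_events(events)
    sfreq = raw.sfreq_hz
    n_samp = int(round((tmax_ms - tmin_ms) / 1000.0 * sfreq))
    offset = int(round(tmin_ms / 1000.0 * sfreq))
    times = tmin_ms + np.arange(n_samp) * 1000.0 / sfreq

    go = events[events["trial_type"] == "go"]
    data, labels, rts = [], [], []
    n_dropped = 0
    for _, ev in go.iterrows():
        start = int(ev["onset_sample"]) + offset
        if start < 0 or start + n_samp > raw.data.shape[1]:
            n_dropped += 1
            continue
        data.append(raw.data[:, start:start + n_samp])
        labels.append(LABEL_OF_CONDITION[ev["condition"]])
        rts.append(ev.get("rt_ms", np.nan))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} event(s) too close to the "
                      f"recording edge ({raw.subject_id})")
    data = (np.stack(data) if data
            else np.empty((0, raw.data.shape[0], n_samp)))
    return EpochSet(
        data=data,
        times_ms=times,
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.asarray([raw.subject_id] * len(data)),
        sfreq_hz=sfreq,
        ch_names=list(raw.ch_names),
        rt_ms=np.asarray(rts, dtype=float),
    )


def baseline_correct(ep: EpochSet,
                     window_ms: tuple[float, float] = (-1500.0, -1200.0)) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window."""
    mask = ep.time_mask(window_ms)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - base)


def reject_artifacts(ep: EpochSet, peak_to_peak_uv: float = 150.0,
                     min_epochs: int = 40) -> EpochSet:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold on any
    channel; enforce a minimum surviving count per subject and condition.

    Raises
    ------
    ValueError
        If the threshold is not positive, or any subject falls below
        ``min_epochs`` surviving epochs in either condition (the error names
        the offending subject and condition).
    """
    if peak_to_peak_uv <= 0:
        raise ValueError("peak_to_peak_uv must be positive")
    ptp = ep.data.max(axis=2) - ep.data.min(axis=2)  # trials x channels
    keep = (ptp <= peak_to_peak_uv).all(axis=1)
    out = ep.select(keep)
    counts: dict = {}
    for subj in np.unique(out.subject_ids):
        for lab, cond in CONDITION_OF_LABEL.items():
            n = int(((out.subject_ids == subj) & (out.labels == lab)).sum())
            counts[f"{subj}/{cond}"] = n
            if n < min_epochs:
                raise ValueError(
                    f"subject {subj}, condition '{cond}': only {n} clean "
                    f"epochs survive rejection (minimum {min_epochs})")
    out.n_rejected = {"n_rejected": int((~keep).sum()),
                      "surviving_per_condition": counts}
    return out


def preprocess_study(study, low_hz: float = 1.0, high_hz: float = 40.0,
                     baseline_ms: tuple[float, float] = (-1500.0, -1200.0),
                     tmin_ms: float = -1500.0, tmax_ms: float = 1500.0,
                     peak_to_peak_uv: float = 150.0,
                     min_epochs: int = 40) -> EpochSet:
    """Run the full preprocessing chain on a simulated (or loaded) study and
    concatenate all subjects into a single :class:`EpochSet`."""
    per_subject = []
    for k, subj in enumerate(study.subject_ids()):
        raw = RawRecording(study.recordings[k], study.sfreq_hz,
                           study.ch_names, subject_id=subj)
        raw = bandpass(raw, low_hz, high_hz)
        raw = common_average(raw)
        ep = epoch(raw, study.events[k], tmin_ms, tmax_ms)
        ep = baseline_correct(ep, baseline_ms)
        ep = reject_artifacts(ep, peak_to_peak_uv, min_epochs)
        per_subject.append(ep)
    first = per_subject[0]
    return EpochSet(
        data=np.concatenate([e.data for e in per_subject]),
        times_ms=first.times_ms,
        labels=np.concatenate([e.labels for e in per_subject]),
        subject_ids=np.concatenate([e.subject_ids for e in per_subject]),
        sfreq_hz=first.sfreq_hz,
        ch_names=first.ch_names,
        rt_ms=np.concatenate([e.rt_ms for e in per_subject]),
        n_rejected={e.subject_ids[0] if len(e.subject_ids) else k: e.n_rejected
                    for k, e in enumerate(per_subject)},
    )
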