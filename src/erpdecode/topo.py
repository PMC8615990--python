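"""Channel-space statistics inside significant intervals.

For a significant interval, each channel's amplitude is averaged per subject
and condition (first across the subject's trials of that condition, then
across the samples of the interval), and the far-vs-near contrast is assessed
per channel with a two-tailed paired t-test across subjects -- the subject is
the unit of analysis. The result is a signed far-minus-near difference
topography with the set of significant channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet
from .permstat import SignificantInterval

__all__ = ["ChannelWindowMeans", "TopoStats", "interval_channel_means",
           "paired_ttest", "topo_difference"]

CONDITION_ORDER = ("near", "far")


@dataclass
class ChannelWindowMeans:
    """Per-subject, per-channel mean amplitudes over one interval.

    ``values`` has shape (n_subjects, n_channels, 2) with the condition axis
    ordered (near, far).
    """

    values: np.ndarray
    subjects: list[str]
    ch_names: list[str]
    interval: SignificantInterval | tuple[float, float]

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("values must be subjects x channels x 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window means contain non-finite values")


@dataclass
class TopoStats:
    """Per-channel far-vs-near paired statistics over one interval."""

    ch_names: list[str]
    diff_uv: np.ndarray  # far - near, uV
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.ch_names,
            "diff_uv": self.diff_uv,
            "t": self.t,
            "p": self.p,
            "significant": self.significant,
        })


def _window_of(interval) -> tuple[float, float]:
    if isinstance(interval, SignificantInterval):
        return interval.start_ms, interval.end_ms
    return float(interval[0]), float(interval[1])


def interval_channel_means(ep: EpochSet, interval) -> ChannelWindowMeans:
    """Average each channel over the interval, per subject and condition.

    Raises if a subject has no trials in one of the conditions (the paired
    contrast would be undefined for that subject).
    """
    window = _window_of(interval)
    tmask = ep.time_mask(window)
    if not tmask.any():
        raise ValueError(f"interval {window} contains no samples")
    subjects = list(dict.fromkeys(np.asarray(ep.subject_ids)))
    vals = np.empty((len(subjects), ep.n_channels, 2))
    for si, subj in enumerate(subjects):
        for ci, cond in enumerate(CONDITION_ORDER):
            lab = 1 if cond == "near" else -1
            sel = (ep.subject_ids == subj) & (ep.labels == lab)
            if not sel.any():
                raise ValueError(
                    f"subject {subj} has no '{cond}' trials in this EpochSet")
            # trials first, then samples (equivalent to a flat mean here)
            vals[si, :, ci] = ep.data[sel][:, :, tmask].mean(axis=(0, 2))
    return ChannelWindowMeans(vals, [str(s) for s in subjects],
                              list(ep.ch_names), interval)


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Two-tailed paired Student t-test; returns ``(t, df, p)``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and ``df = n - 1``.
    Identical inputs give ``(0, n-1, 1)``; zero-variance differences with a
    nonzero mean have no finite t and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t is undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return t, n - 1, p


def topo_difference(means: ChannelWindowMeans, alpha: float = 0.05,
                    bonferroni: bool = False) -> TopoStats:
    """Per-channel paired far-vs-near contrast across subjects.

    Channels with two-tailed ``p < alpha`` are flagged (``alpha / n_channels``
    if ``bonferroni``). The difference is signed far minus near, so its sign
    matches the sign of t on every channel.
    """
    n_subj, n_ch, _ = means.values.shape
    if n_subj < 2:
        raise ValueError("need >= 2 subjects for a paired contrast")
    near = means.values[:, :, 0]
    far = means.values[:, :, 1]
    t = np.empty(n_ch)
    p = np.empty(n_ch)
    for c in range(n_ch):
        t[c], df, p[c] = paired_ttest(far[:, c], near[:, c])
    thr = alpha / n_ch if bonferroni else alpha
    return TopoStats(
        ch_names=list(means.ch_names),
        diff_uv=(far - near).mean(axis=0),
        t=t, p=p,
        significant=p < thr,
        alpha=alpha,
        df=n_subj - 1,
    )
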