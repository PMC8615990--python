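"""Permutation-based significance of the accuracy time course.

The empirical null is built by shuffling the condition labels across the
pooled trial set (trial-to-subject assignment, and hence the fold structure,
stays fixed) and re-running the complete cross-validated decoding for every
shuffle. A time point is significant when the observed accuracy exceeds the
chosen percentile (default 99th) of its per-time-point null AND an absolute
chance threshold (default 60%); contiguous runs of significant samples are
reported as intervals. Both criteria can be disabled individually, which the
calibration studies use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .decoding import DEFAULT_WINDOW_MS, DecodingResults, TimeResolvedDecoder
from .preprocess import EpochSet

__all__ = ["NullDistribution", "SignificantInterval", "permutation_null",
           "significant_mask", "extract_intervals"]

_EXHAUSTIVE_CAP = 200_000


@dataclass
class NullDistribution:
    """Per-time-point permutation accuracies (n_perm x n_times)."""

    accuracies: np.ndarray
    times_ms: np.ndarray
    n_perm: int
    seed: int | None
    cv_scheme: str
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 1):
            raise ValueError("null accuracies must lie in [0, 1]")

    def percentile(self, q: float) -> np.ndarray:
        """Per-time-point empirical percentile (linear interpolation)."""
        return np.percentile(self.accuracies, q, axis=0)


@dataclass
class SignificantInterval:
    """A maximal run of significant time points, as a half-open ms window."""

    start_ms: float
    end_ms: float
    peak_accuracy: float = np.nan
    mean_accuracy: float = np.nan

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("interval must satisfy start < end")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def permutation_null(ep: EpochSet, n_perm: int = 500,
                     cv_scheme: str = "subject", shrinkage="ledoit",
                     window_ms=DEFAULT_WINDOW_MS, seed: int = 0,
                     exhaustive: bool = False) -> NullDistribution:
    """Empirical null of the accuracy time course under label exchange.

    Each permutation redraws the +1/-1 labels uniformly over all distinct
    arrangements of the observed label multiset across the pooled trials and
    re-runs the full leave-one-out decoding. With ``exhaustive=True`` every
    distinct arrangement is evaluated exactly once (``n_perm`` is ignored);
    this is only feasible for toy problems and errors out beyond
    ``200_000`` arrangements.
    """
    if not exhaustive and n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if len(np.unique(np.asarray(ep.labels))) < 2:
        raise ValueError("labels contain a single class; nothing to permute")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: percentile estimates will be "
                      "unstable")

    dec = TimeResolvedDecoder(ep, cv=cv_scheme, shrinkage=shrinkage,
                              window_ms=window_ms)
    eng = dec._engine
    y = eng.y.copy()

    if exhaustive:
        n = len(y)
        n_p = int((y == 1).sum())
        from math import comb
        total = comb(n, n_p)
        if total > _EXHAUSTIVE_CAP:
            raise ValueError(
                f"{total} distinct label arrangements exceed the exhaustive "
                f"cap ({_EXHAUSTIVE_CAP})")
        rows = []
        for pos in combinations(range(n), n_p):
            yp = -np.ones(n, dtype=int)
            yp[list(pos)] = 1
            rows.append(eng.fold_accuracies(yp).mean(axis=0))
        null = np.stack(rows)
        return NullDistribution(null, eng.times_ms.copy(), total, None,
                                cv_scheme, exhaustive=True)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, eng.T))
    for p in range(n_perm):
        null[p] = eng.fold_accuracies(rng.permutation(y)).mean(axis=0)
    return NullDistribution(null, eng.times_ms.copy(), n_perm, seed, cv_scheme)


def significant_mask(obs: DecodingResults, null: NullDistribution,
                     percentile: float | None = 99.0,
                     chance_threshold: float | None = 0.60) -> np.ndarray:
    """Boolean per-time-point significance mask.

    A time point is flagged when the observed accuracy strictly exceeds the
    per-time-point null percentile AND the absolute chance threshold. Pass
    ``None`` for either criterion to disable it.
    """
    if len(obs.times_ms) != null.accuracies.shape[1] or not np.allclose(
            obs.times_ms, null.times_ms):
        raise ValueError("observed and null time axes differ")
    mask = np.ones(len(obs.times_ms), dtype=bool)
    if percentile is not None:
        mask &= obs.accuracy > null.percentile(percentile)
    if chance_threshold is not None:
        mask &= obs.accuracy > chance_threshold
    return mask


def extract_intervals(mask: np.ndarray, times_ms: np.ndarray,
                      min_duration_ms: float = 0.0,
                      accuracy: np.ndarray | None = None
                      ) -> list[SignificantInterval]:
    """Maximal runs of True samples, as half-open ms intervals.

    A run covering samples i..j maps to ``[times[i], times[j] + dt)`` with dt
    the sampling step; runs shorter than ``min_duration_ms`` are discarded.
    ``accuracy`` (aligned with ``times_ms``) fills the peak/mean fields.
    """
    mask = np.asarray(mask, dtype=bool)
    times_ms = np.asarray(times_ms, dtype=float)
    if len(mask) != len(times_ms):
        raise ValueError("mask and time axis lengths differ")
    if not mask.any():
        return []
    dt = float(np.median(np.diff(times_ms))) if len(times_ms) > 1 else 0.0
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    starts, stops = edges[::2], edges[1::2]  # stop is exclusive
    out = []
    for i0, i1 in zip(starts, stops):
        start, end = times_ms[i0], times_ms[i1 - 1] + dt
        if end - start < min_duration_ms:
            continue
        seg = accuracy[i0:i1] if accuracy is not None else None
        out.append(SignificantInterval(
            start_ms=float(start), end_ms=float(end),
            peak_accuracy=float(seg.max()) if seg is not None else np.nan,
            mean_accuracy=float(seg.mean()) if seg is not None else np.nan))
    return sorted(out, key=lambda iv: iv.start_ms)
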