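"""Synthetic multi-subject EEG for a two-condition go/no-go priming study.

The simulator emulates the structure of a visual priming experiment in which a
prime picture (700 ms), an inter-stimulus interval (500 ms) and a target
picture (700 ms) are shown on every trial and the subject releases a foot
pedal at target onset on go trials. Each trial carries a binary condition
label -- ``near`` vs ``far`` framing of the depicted environment -- and
condition differences are injected as source-space waveforms projected to the
scalp through a toy lead field, so every downstream stage (decoding,
permutation statistics, topography tests, source localization) can be checked
against known ground truth.

Timing defaults follow the emulated design: 250 Hz sampling, epochs from
-1500 to +1500 ms around target onset, prime onset at -1200 ms, 128 channels,
30 subjects with 84 go trials per condition. The default injected effects are
a positive far-minus-near fronto-central wave at -550..-450 ms and a negative
far-minus-near posterior wave at 600..700 ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .headmodel import HeadModel, build_toy_headmodel, nearest_sources

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "RTModel",
    "StudyConfig",
    "SyntheticStudy",
    "pink_noise",
    "simulate_study",
    "default_effects",
]

# anatomical anchors (head-radius units) for the default effect topographies
FRONTO_CENTRAL_ANCHOR = (0.0, 0.45, 0.50)
POSTERIOR_ANCHOR = (0.0, -0.55, 0.35)


@dataclass
class EffectSpec:
    """A condition-difference effect injected in a fixed time window.

    ``amplitude_uv`` is the signed far-minus-near difference of the peak scalp
    projection: positive means the far condition projects more positively than
    near on the effect's best-coupled channel. The effect waveform is a Hann
    envelope over ``window_ms`` (times relative to target onset). Sources are
    either given explicitly (``source_indices``) or resolved per head model as
    the ``n_sources`` sources nearest to ``anchor``.
    """

    window_ms: tuple[float, float]
    amplitude_uv: float
    source_indices: tuple[int, ...] | None = None
    anchor: tuple[float, float, float] | None = None
    n_sources: int = 2

    def resolve_sources(self, head: HeadModel) -> np.ndarray:
        if self.source_indices is not None:
            idx = np.asarray(self.source_indices, dtype=int)
            if idx.min() < 0 or idx.max() >= head.n_sources:
                raise ValueError("effect source indices outside head model")
            return idx
        if self.anchor is None:
            raise ValueError("EffectSpec needs source_indices or an anchor")
        return nearest_sources(head, self.anchor, self.n_sources)


def default_effects() -> list[EffectSpec]:
    """The two default effects: early fronto-central (+), late posterior (-)."""
    return [
        EffectSpec(window_ms=(-550.0, -450.0), amplitude_uv=+5.0,
                   anchor=FRONTO_CENTRAL_ANCHOR),
        EffectSpec(window_ms=(600.0, 700.0), amplitude_uv=-5.0,
                   anchor=POSTERIOR_ANCHOR),
    ]


@dataclass
class NoiseSpec:
    """Background-noise mixture.

    Total per-channel standard deviation ``std_uv`` is split (by variance)
    between spatially correlated pink noise (a few deep noise sources mixed
    into all channels through a smooth Gaussian-decay pattern), per-channel
    independent pink noise, and per-channel white noise.
    """

    std_uv: float = 9.0
    slope: float = -1.0
    shared_fraction: float = 0.5
    indep_pink_fraction: float = 0.3
    white_fraction: float = 0.2
    n_noise_sources: int = 8

    def __post_init__(self) -> None:
        total = self.shared_fraction + self.indep_pink_fraction + self.white_fraction
        if not np.isclose(total, 1.0):
            raise ValueError("noise variance fractions must sum to 1")
        if self.std_uv < 0:
            raise ValueError("std_uv must be non-negative")


@dataclass
class RTModel:
    """Shifted-lognormal foot-pedal release times (ms from target onset).

    Per-condition means default to a faster far than near response. Subjects
    get a shared intercept (``subject_sd_ms``) and an idiosyncratic
    near-minus-far offset (``subject_diff_sd_ms``), so the across-subject
    paired comparison has realistic, finite power rather than being driven by
    trial counts alone.
    """

    near_mean_ms: float = 935.0
    far_mean_ms: float = 905.0
    sd_ms: float = 140.0
    shift_ms: float = 350.0
    subject_sd_ms: float = 60.0
    subject_diff_sd_ms: float = 70.0

    def _lognorm_params(self, mean_ms: float) -> tuple[float, float]:
        m = mean_ms - self.shift_ms
        if m <= 0:
            raise ValueError("rt mean must exceed shift")
        s2 = np.log1p((self.sd_ms / m) ** 2)
        return np.log(m) - s2 / 2, np.sqrt(s2)


@dataclass
class StudyConfig:
    """Full study description; defaults mirror the emulated design."""

    n_subjects: int = 30
    n_trials_per_condition: int = 84
    n_channels: int = 128
    sfreq_hz: float = 250.0
    epoch_ms: tuple[float, float] = (-1500.0, 1500.0)
    prime_onset_ms: float = -1200.0
    picture_duration_ms: float = 700.0
    isi_ms: float = 500.0
    iti_ms: float = 2500.0
    nogo_fraction: float = 0.25  # no-go trials per go trial (8 : 32)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: list[EffectSpec] = field(default_factory=default_effects)
    rt_model: RTModel = field(default_factory=RTModel)
    amp_subject_sd: float = 0.2  # relative between-subject effect scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("n_subjects and n_trials_per_condition must be >= 1")
        if self.epoch_ms[0] >= self.epoch_ms[1]:
            raise ValueError("epoch_ms must be an increasing pair")
        for eff in self.effects:
            if eff.window_ms[0] < self.epoch_ms[0] or eff.window_ms[1] > self.epoch_ms[1]:
                raise ValueError(
                    f"effect window {eff.window_ms} outside epoch {self.epoch_ms}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class SyntheticStudy:
    """Simulated continuous recordings with events and ground truth."""

    recordings: list[np.ndarray]  # per subject, channels x samples, uV
    events: list[pd.DataFrame]  # onset_sample, condition, trial_type, rt_ms
    sfreq_hz: float
    ch_names: list[str]
    head: HeadModel
    config: StudyConfig
    ground_truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    def subject_ids(self) -> list[str]:
        return [f"S{k:02d}" for k in range(self.n_subjects)]


def pink_noise(
    n_channels: int,
    n_samples: int,
    sfreq_hz: float,
    slope: float = -1.0,
    seed: int | np.random.Generator = 0,
    scale: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with power-law spectrum ``PSD ~ f**slope``.

    Shaped in the frequency domain: white Gaussian noise is transformed with
    an rFFT, each positive-frequency bin is scaled by ``f**(slope/2)`` (DC is
    zeroed), and the result is normalized to unit standard deviation per
    channel before applying ``scale``.

    Raises
    ------
    ValueError
        If ``n_samples < 64`` or ``slope`` outside [-2, 0].
    """
    if n_samples < 64:
        raise ValueError(f"n_samples must be >= 64, got {n_samples}")
    if not -2.0 <= slope <= 0.0:
        raise ValueError(f"slope must lie in [-2, 0], got {slope}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    from scipy.fft import irfft, next_fast_len, rfft

    nfft = next_fast_len(n_samples)  # avoid awkward prime-factor FFT sizes
    white = rng.standard_normal((n_channels, nfft))
    spec = rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sfreq_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (slope / 2.0)
    x = irfft(spec * shaping, n=nfft, axis=-1)[:, :n_samples]
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * x / sd


def _background_noise(
    noise: NoiseSpec,
    head: HeadModel,
    n_samples: int,
    sfreq_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Channel-correlated pink + white background, per-channel std ``std_uv``."""
    n_ch = head.n_channels
    out = np.zeros((n_ch, n_samples))
    if noise.std_uv == 0:
        return out
    if noise.shared_fraction > 0:
        # deep noise sources mixed through a smooth Gaussian-decay pattern
        pos = rng.uniform(-0.6, 0.6, size=(noise.n_noise_sources, 3))
        pos[:, 2] = np.abs(pos[:, 2])
        d2 = ((head.sensor_positions[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        mix = np.exp(-d2 / (2 * head.spread**2))
        src = pink_noise(noise.n_noise_sources, n_samples, sfreq_hz,
                         slope=noise.slope, seed=rng)
        shared = mix @ src
        shared /= shared.std(axis=-1, keepdims=True)
        out += np.sqrt(noise.shared_fraction) * shared
    if noise.indep_pink_fraction > 0:
        out += np.sqrt(noise.indep_pink_fraction) * pink_noise(
            n_ch, n_samples, sfreq_hz, slope=noise.slope, seed=rng)
    if noise.white_fraction > 0:
        w = rng.standard_normal((n_ch, n_samples))
        out += np.sqrt(noise.white_fraction) * (w - w.mean(-1, keepdims=True))
    return noise.std_uv * out


def _draw_rts(cfg: StudyConfig, conditions: np.ndarray, subj_icept: float,
              subj_diff: float, rng: np.random.Generator) -> np.ndarray:
    """Per-trial shifted-lognormal RTs; ``subj_diff`` widens/narrows near-far."""
    rt = np.empty(len(conditions))
    for cond in ("near", "far"):
        m = (cfg.rt_model.near_mean_ms if cond == "near"
             else cfg.rt_model.far_mean_ms)
        # subject condition offset is split antisymmetrically
        m = m + subj_icept + (0.5 if cond == "near" else -0.5) * subj_diff
        mu, sigma = cfg.rt_model._lognorm_params(m)
        sel = conditions == cond
        rt[sel] = cfg.rt_model.shift_ms + rng.lognormal(mu, sigma, size=sel.sum())
    return rt


def simulate_study(cfg: StudyConfig | None = None,
                   head: HeadModel | None = None) -> SyntheticStudy:
    """Simulate the full multi-subject study.

    Events are laid out on a regular grid (one trial every
    ``prime + ISI + target + ITI`` ms) with enough padding that every epoch
    fits inside the recording. Go/no-go status and condition are balanced per
    subject and shuffled. Condition effects are added to far-condition trials
    only, as ``gain[:, sources] summed -> unit-peak pattern`` times a Hann
    waveform times the (subject-scaled) signed amplitude, so the expected
    far-minus-near scalp difference in the window equals
    ``amplitude_uv * pattern * waveform``.

    Deterministic for a fixed ``cfg`` (including ``cfg.seed``).
    """
    cfg = cfg if cfg is not None else StudyConfig()
    if head is None:
        head = build_toy_headmodel(n_channels=cfg.n_channels, seed=cfg.seed)
    if head.n_channels != cfg.n_channels:
        raise ValueError("head model channel count disagrees with config")

    sfreq = cfg.sfreq_hz
    ms2smp = lambda ms: int(round(ms / 1000.0 * sfreq))

    n_go = 2 * cfg.n_trials_per_condition
    n_nogo = int(round(n_go * cfg.nogo_fraction))
    n_ev = n_go + n_nogo
    trial_ms = (cfg.picture_duration_ms + cfg.isi_ms + cfg.picture_duration_ms
                + cfg.iti_ms)
    pad = ms2smp(max(abs(cfg.epoch_ms[0]), cfg.epoch_ms[1]) + 500.0)
    spacing = ms2smp(trial_ms)
    n_samples = 2 * pad + (n_ev - 1) * spacing + 1

    # effect patterns/waveforms are shared across subjects
    epoch0 = ms2smp(cfg.epoch_ms[0])
    resolved = []
    for eff in cfg.effects:
        idx = eff.resolve_sources(head)
        pattern = head.gain[:, idx].sum(axis=1)
        pattern = pattern / np.abs(pattern).max()
        i0 = ms2smp(eff.window_ms[0])
        i1 = ms2smp(eff.window_ms[1])
        if i1 <= i0:
            raise ValueError(f"degenerate effect window {eff.window_ms}")
        wave = np.hanning(i1 - i0 + 2)[1:-1]  # strictly interior Hann lobe
        resolved.append((eff, idx, pattern, np.arange(i0, i1), wave))

    root = np.random.SeedSequence(cfg.seed)
    sub_seeds = root.spawn(cfg.n_subjects)

    recordings, event_tables = [], []
    for k in range(cfg.n_subjects):
        rng = np.random.default_rng(sub_seeds[k])
        data = _background_noise(cfg.noise, head, n_samples, sfreq, rng)

        cond = np.array(["near"] * cfg.n_trials_per_condition
                        + ["far"] * cfg.n_trials_per_condition
                        + (["near", "far"] * ((n_nogo + 1) // 2))[:n_nogo])
        ttype = np.array(["go"] * n_go + ["nogo"] * n_nogo)
        order = rng.permutation(n_ev)
        cond, ttype = cond[order], ttype[order]
        onsets = pad + spacing * np.arange(n_ev)

        amp_scale = max(0.2, 1.0 + cfg.amp_subject_sd * rng.standard_normal())
        for eff, _idx, pattern, smp, wave in resolved:
            amp = eff.amplitude_uv * amp_scale
            if amp == 0:
                continue
            for onset in onsets[cond == "far"]:
                data[:, onset + smp] += amp * pattern[:, None] * wave[None, :]

        rt = np.full(n_ev, np.nan)
        icept = cfg.rt_model.subject_sd_ms * rng.standard_normal()
        diff = cfg.rt_model.subject_diff_sd_ms * rng.standard_normal()
        go_sel = ttype == "go"
        rt[go_sel] = _draw_rts(cfg, cond[go_sel], icept, diff, rng)

        recordings.append(data)
        event_tables.append(pd.DataFrame({
            "onset_sample": onsets,
            "condition": cond,
            "trial_type": ttype,
            "rt_ms": rt,
        }))

    ground_truth = {
        "seed": cfg.seed,
        "effects": [
            {"window_ms": list(eff.window_ms),
             "amplitude_uv": eff.amplitude_uv,
             "source_indices": [int(i) for i in idx]}
            for eff, idx, *_ in resolved
        ],
    }
    ch_names = [f"E{i + 1}" for i in range(cfg.n_channels)]
    return SyntheticStudy(recordings, event_tables, sfreq, ch_names, head,
                          cfg, ground_truth)
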