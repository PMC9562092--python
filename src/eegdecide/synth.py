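"""Synthetic EEG cohort generator with planted, parameterized structure.

Emulates a four-block emotional decision-making protocol: each block is a
run of fixed-length trials under one condition (no stimulus, or a positive
/ fear / sad film), recorded as continuous multichannel EEG.  The signal
is the sum of

* 1/f-shaped Gaussian background noise, independent per channel,
* a condition-specific evoked template (P2 / P3 / N3 bumps) inserted at
  every trial onset, and
* lagged additive coupling between chosen channel pairs, which plants a
  known lead–lag direction for connectivity analysis.

Behavioral accuracy is drawn with a configurable correlation against a
per-block network metric, and pre/post valence self-reports are drawn with
condition-dependent shifts, so every downstream statistic has a known
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EEGRecording, make_event_table
from .montage import DEFAULT_32, positions_for

_REQUIRED_CHANNELS = ("Fp1", "Fpz", "Fp2", "AF3", "AF4", "Fz", "Cz", "Pz")


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the protocol constants: 250 Hz sampling, four blocks
    (None/H/Q/T) of 40 trials, 6.5 s per trial, and a P2 amplitude ordering
    with the positive condition (H) largest and fear (Q) smallest with a
    delayed latency.
    """

    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_32))
    fs: float = 250.0
    n_blocks: int = 4
    trials_per_block: int = 40
    trial_dur: float = 6.5
    condition_labels: tuple[str, ...] = ("None", "H", "Q", "T")
    # frontal P2: amplitude (µV) and latency (ms) per condition
    p2_amplitudes: dict = field(
        default_factory=lambda: {"None": 6.0, "H": 8.0, "Q": 4.0, "T": 5.0}
    )
    p2_latency: dict = field(
        default_factory=lambda: {"None": 180.0, "H": 180.0, "Q": 205.0, "T": 185.0}
    )
    p3_amplitude: float = 6.0
    p3_latency_ms: float = 350.0
    n3_amplitude: float = -5.0
    n3_latency_ms: float = 3350.0  # 350 ms after the 3,000-ms second-picture onset
    # (source, target, lag in samples, gain); plants source->target lead
    coupling_spec: list = field(
        default_factory=lambda: [("Fz", "Cz", 5, 0.8), ("Cz", "Pz", 5, 0.8)]
    )
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    accuracy_metric_corr: float = -0.6
    n_subjects: int = 16
    valence_shift: dict = field(
        default_factory=lambda: {"H": 3.0, "Q": -3.0, "T": -2.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_dur <= 0 or self.trials_per_block < 0:
            raise ValueError("trial_dur and trials_per_block must be positive")
        if len(self.condition_labels) != self.n_blocks:
            raise ValueError("need one condition label per block")
        missing = [c for c in _REQUIRED_CHANNELS
                   if c.lower() not in {l.lower() for l in self.channel_labels}]
        if missing:
            raise ValueError(f"channel list must include {missing}")
        for cond in self.condition_labels:
            if cond not in self.p2_amplitudes or cond not in self.p2_latency:
                raise ValueError(f"P2 amplitude/latency missing for {cond!r}")
        labset = {l.lower() for l in self.channel_labels}
        for src, dst, lag, _gain in self.coupling_spec:
            if src.lower() not in labset or dst.lower() not in labset:
                raise ValueError(f"coupling channels {src}->{dst} not in channel list")
            if lag < 1:
                raise ValueError("coupling lags must be >= 1 sample")
        if abs(self.accuracy_metric_corr) >= 1:
            raise ValueError("accuracy_metric_corr must lie in (-1, 1)")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_dur * self.fs))

    @property
    def block_samples(self) -> int:
        return self.trial_samples * self.trials_per_block

    def channel_index(self, label: str) -> int:
        low = label.lower()
        for i, l in enumerate(self.channel_labels):
            if l.lower() == low:
                return i
        raise KeyError(label)


@dataclass
class GroundTruth:
    """What was planted: evoked templates (after coupling), the coupling
    spec, and the per-condition valence shifts.  ``planted_accuracy`` is
    filled once behavior has been drawn."""

    erp_templates: dict  # condition -> (n_channels, trial_samples) µV
    coupling_spec: list
    planted_valence_shift: dict
    planted_accuracy: np.ndarray | None = None


# --------------------------------------------------------------------------
# evoked templates

def _bump(n_samples: int, fs: float, latency_ms: float, width_ms: float) -> np.ndarray:
    """Gaussian-windowed half-sine bump, unit peak at *latency_ms*, zero
    outside [latency - width, latency + width]."""
    t = np.arange(n_samples) * 1000.0 / fs
    lo, hi = latency_ms - width_ms, latency_ms + width_ms
    out = np.zeros(n_samples)
    sel = (t >= lo) & (t <= hi)
    phase = (t[sel] - lo) / (2.0 * width_ms)  # 0..1 over the support
    half_sine = np.sin(np.pi * phase)
    gauss = np.exp(-0.5 * ((t[sel] - latency_ms) / (width_ms / 2.0)) ** 2)
    out[sel] = half_sine * gauss
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


def _spatial_profile(positions: np.ndarray, center: tuple[float, float],
                     sigma: float) -> np.ndarray:
    d2 = ((positions - np.asarray(center)) ** 2).sum(axis=1)
    w = np.exp(-0.5 * d2 / sigma**2)
    return w / w.max()


def condition_template(config: SynthConfig, condition: str,
                       positions: np.ndarray) -> np.ndarray:
    """Evoked template for one condition, (n_channels, trial_samples), µV.

    Three components: a positive prefrontal P2 whose amplitude/latency vary
    by condition, a positive fronto-central P3, and a negative-frontal /
    positive-posterior N3 following the second-picture onset.
    """
    n = config.trial_samples
    tpl = np.zeros((len(config.channel_labels), n))
    # P2: prefrontal positive
    p2 = _bump(n, config.fs, config.p2_latency[condition], 50.0)
    tpl += np.outer(_spatial_profile(positions, (0.0, 0.95), 0.45)
                    * config.p2_amplitudes[condition], p2)
    # P3: fronto-central positive
    p3 = _bump(n, config.fs, config.p3_latency_ms, 80.0)
    tpl += np.outer(_spatial_profile(positions, (0.0, 0.4), 0.5)
                    * config.p3_amplitude, p3)
    # N3: frontal negative with a posterior positive counterpart
    n3 = _bump(n, config.fs, config.n3_latency_ms, 60.0)
    prof = (_spatial_profile(positions, (0.0, 0.9), 0.45) * config.n3_amplitude
            - 0.6 * config.n3_amplitude
            * _spatial_profile(positions, (0.0, -0.8), 0.5))
    tpl += np.outer(prof, n3)
    return tpl


def _apply_coupling(config: SynthConfig, data: np.ndarray) -> np.ndarray:
    """Add lagged copies: target += gain * source delayed by lag samples.

    Sources are taken from the pre-coupling signal, so chained couplings do
    not compound and the planted lead–lag structure is exactly the
    configured list.
    """
    out = data.copy()
    for src, dst, lag, gain in config.coupling_spec:
        i, j = config.channel_index(src), config.channel_index(dst)
        shifted = np.zeros_like(data[i])
        shifted[..., lag:] = data[i][..., :-lag]
        out[j] += gain * shifted
    return out


def _shaped_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                  fs: float, exponent: float, scale: float) -> np.ndarray:
    """Gaussian background with amplitude spectrum f^(-exponent/2) inside
    1–40 Hz and zero outside, scaled to per-channel std *scale* µV."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= 1.0) & (freqs <= 40.0)
    shape[band] = freqs[band] ** (-exponent / 2.0)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1) * shape
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std * scale


# --------------------------------------------------------------------------
# public generators

def generate_recording(config: SynthConfig, seed: int | None = None):
    """Generate one subject's continuous recording plus events and truth.

    Returns ``(EEGRecording, events, GroundTruth)`` where *events* has one
    row per trial (block, trial, onset_s, condition).  Deterministic given
    the seed (``config.seed`` unless overridden).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    positions = positions_for(config.channel_labels)
    n_ch = len(config.channel_labels)
    n_total = config.n_blocks * config.block_samples

    if config.noise_scale > 0:
        data = _shaped_noise(rng, n_ch, n_total, config.fs,
                             config.noise_exponent, config.noise_scale)
    else:
        data = np.zeros((n_ch, n_total))

    base_templates = {
        cond: condition_template(config, cond, positions)
        for cond in config.condition_labels
    }
    blocks, trials, onsets, conds = [], [], [], []
    for b, cond in enumerate(config.condition_labels):
        block_start = b * config.block_samples
        for t in range(config.trials_per_block):
            s0 = block_start + t * config.trial_samples
            data[:, s0:s0 + config.trial_samples] += base_templates[cond]
            blocks.append(b + 1)
            trials.append(t + 1)
            onsets.append(s0 / config.fs)
            conds.append(cond)

    data = _apply_coupling(config, data)
    coupled_templates = {
        cond: _apply_coupling(config, tpl) for cond, tpl in base_templates.items()
    }

    rec = EEGRecording(data=data, fs=config.fs, labels=list(config.channel_labels),
                       positions=positions, reference="raw")
    events = make_event_table(blocks, trials, onsets, conds)
    truth = GroundTruth(erp_templates=coupled_templates,
                        coupling_spec=list(config.coupling_spec),
                        planted_valence_shift=dict(config.valence_shift))
    return rec, events, truth


def generate_behavior(config: SynthConfig, metric_values,
                      seed: int | None = None) -> pd.DataFrame:
    """Per-block decision behavior correlated with a network metric.

    Correct counts (out of 40) are drawn from a latent Gaussian that mixes
    the standardized *metric_values* with independent noise at weight
    ``accuracy_metric_corr``, so the sample correlation between accuracy
    and the metric approaches the configured value as the number of blocks
    grows.  Reaction times are drawn independently around 470 ms.
    """
    if abs(config.accuracy_metric_corr) >= 1:
        raise ValueError("accuracy_metric_corr must lie in (-1, 1)")
    metric_values = np.asarray(metric_values, dtype=float)
    n = metric_values.shape[0]
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 7919])
    if n == 0:
        return pd.DataFrame(columns=["block", "condition", "correct", "rt_ms"])

    sd = metric_values.std()
    z = (metric_values - metric_values.mean()) / sd if sd > 0 else np.zeros(n)
    rho = config.accuracy_metric_corr
    latent = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    correct = np.clip(np.round(32.0 + 4.5 * latent), 0, 40).astype(int)
    rt = np.maximum(150.0, 470.0 + 60.0 * rng.standard_normal(n))
    conds = [config.condition_labels[i % config.n_blocks] for i in range(n)]
    return pd.DataFrame({
        "block": np.arange(1, n + 1),
        "condition": conds,
        "correct": correct,
        "rt_ms": rt,
    })


def generate_valence(config: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Pre/post valence self-reports (1–9 integers) per subject and film.

    The planted shift is positive for the positive film (H) and negative
    for the fear and sad films (Q, T); unit Gaussian rating noise is added
    before rounding and clipping to the scale.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 104729])
    rows = []
    for cond, shift in config.valence_shift.items():
        pre_latent = 5.0 + rng.standard_normal(config.n_subjects)
        post_latent = pre_latent + shift + rng.standard_normal(config.n_subjects)
        pre = np.clip(np.round(pre_latent), 1, 9).astype(int)
        post = np.clip(np.round(post_latent), 1, 9).astype(int)
        for s in range(config.n_subjects):
            rows.append((s + 1, cond, pre[s], post[s]))
    df = pd.DataFrame(rows, columns=["subject", "condition", "pre", "post"])
    if ((df[["pre", "post"]] < 1) | (df[["pre", "post"]] > 9)).any().any():
        warnings.warn("valence scores escaped the 1-9 scale")  # pragma: no cover
    return df
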