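"""Deterministic signal conditioning: resampling, band-pass filtering,
average referencing, epoching, and amplitude-based epoch rejection.

Artifact-subspace reconstruction, bad-channel interpolation and ICA — the
data-driven cleaning steps used on real recordings — are deliberately
replaced by a simple peak-to-peak amplitude rejection: the synthetic data
this pipeline is exercised on contains no ocular or muscular artifacts,
and amplitude rejection is fully deterministic and testable.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EEGRecording, EpochSet

logger = logging.getLogger(__name__)


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase resampling to *target_fs* Hz (anti-aliased on the way down)."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    if target_fs > rec.fs:
        logger.info("upsampling from %g Hz to %g Hz", rec.fs, target_fs)
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, fs=rec.fs * frac.numerator / frac.denominator)


def bandpass(rec: EEGRecording, lo: float = 1.0, hi: float = 40.0) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward–backward)."""
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous mean across channels."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=out, reference="average")


def epoch(rec: EEGRecording, events: pd.DataFrame,
          tmin: float = 0.0, tmax: float = 3.5) -> EpochSet:
    """Cut one epoch per event row over [tmin, tmax) s relative to onset.

    Events whose window would run past either end of the recording are
    dropped with a warning.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    n_samp = int(round((tmax - tmin) * rec.fs))
    slabs, conds = [], []
    n_dropped = 0
    for _, row in events.iterrows():
        start = int(round(row["onset_s"] * rec.fs)) + int(round(tmin * rec.fs))
        if start < 0 or start + n_samp > rec.n_samples:
            n_dropped += 1
            continue
        slabs.append(rec.data[:, start:start + n_samp])
        conds.append(row["condition"])
    if n_dropped:
        warnings.warn(f"{n_dropped} event(s) beyond recording bounds dropped")
    data = (np.stack(slabs) if slabs
            else np.empty((0, rec.n_channels, n_samp)))
    return EpochSet(data=data, tmin=tmin, tmax=tmax, fs=rec.fs,
                    condition=np.asarray(conds, dtype=object),
                    labels=list(rec.labels), positions=rec.positions)


def reject_epochs(epochs: EpochSet, peak_to_peak_max: float = 200.0) -> EpochSet:
    """Drop trials whose any-channel peak-to-peak exceeds the threshold (µV)."""
    if peak_to_peak_max <= 0:
        raise ValueError("threshold must be positive")
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, channels)
    bad = (p2p > peak_to_peak_max).any(axis=1)
    mask = epochs.kept_mask & ~bad
    n_rejected = int(epochs.kept_mask.sum() - mask.sum())
    logger.info("rejected %d/%d epochs above %g µV peak-to-peak",
                n_rejected, epochs.n_trials, peak_to_peak_max)
    if epochs.n_trials > 0 and not mask.any():
        raise ValueError(
            "all epochs rejected; review the peak-to-peak threshold")
    return EpochSet(data=epochs.data, tmin=epochs.tmin, tmax=epochs.tmax,
                    fs=epochs.fs, condition=epochs.condition,
                    labels=list(epochs.labels), positions=epochs.positions,
                    kept_mask=mask)


def preprocess_recording(rec: EEGRecording, events: pd.DataFrame, *,
                         target_fs: float = 250.0, lo: float = 1.0,
                         hi: float = 40.0, tmin: float = 0.0,
                         tmax: float = 3.5,
                         peak_to_peak_max: float = 200.0) -> EpochSet:
    """Convenience chain: resample -> bandpass -> average ref -> epoch -> reject."""
    scale = target_fs / rec.fs
    rec = resample(rec, target_fs)
    rec = bandpass(rec, lo, hi)
    rec = average_reference(rec)
    if scale != 1.0:
        events = events.copy()  # onsets are in seconds, unaffected by fs change
    eps = epoch(rec, events, tmin, tmax)
    return reject_epochs(eps, peak_to_peak_max)
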