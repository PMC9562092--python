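"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolt.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    positions : ndarray, shape (n_channels, 2), optional
        Flattened 2-D scalp coordinates.
    reference : str
        ``"raw"`` or ``"average"``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    positions: np.ndarray | None = None
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 2):
                raise ValueError("positions must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        return replace(self, **changes)

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class EpochSet:
    """Trials cut around event onsets.

    ``data`` is (n_trials, n_channels, n_samples); ``condition`` carries one
    label per trial and ``kept_mask`` marks trials that survived rejection.
    """

    data: np.ndarray
    tmin: float
    tmax: float
    fs: float
    condition: np.ndarray
    labels: list[str]
    positions: np.ndarray | None = None
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_expected = int(round((self.tmax - self.tmin) * self.fs))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"sample count {self.data.shape[2]} does not match window "
                f"({n_expected} samples expected)"
            )
        self.condition = np.asarray(self.condition)
        if self.condition.shape[0] != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if not np.isfinite(self.data[self.kept_mask]).all():
            raise ValueError("kept trials contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event onset."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Data of kept trials, optionally restricted to one condition."""
        mask = self.kept_mask.copy()
        if condition is not None:
            mask &= self.condition == condition
        return self.data[mask]


def make_event_table(block, trial, onset_s, condition) -> pd.DataFrame:
    """Assemble the canonical event table (block, trial, onset_s, condition)."""
    return pd.DataFrame(
        {
            "block": np.asarray(block, dtype=int),
            "trial": np.asarray(trial, dtype=int),
            "onset_s": np.asarray(onset_s, dtype=float),
            "condition": np.asarray(condition, dtype=object),
        }
    )
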