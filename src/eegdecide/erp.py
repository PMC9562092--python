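"""Event-related potential analysis: condition-wise averaging, component
amplitude/latency measurement, and pointwise one-way ANOVA across
conditions.

Default component windows (config-exposed; the task presents the maze for
3,000 ms and the choice point for 500 ms, so the N3 window follows the
second-picture onset at 3,000 ms):

* P2: 150-275 ms, positive
* P3: 275-450 ms, positive
* N3: 3,250-3,450 ms, negative
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import EpochSet

#: (lo_ms, hi_ms, polarity) per component
COMPONENT_WINDOWS: dict[str, tuple[float, float, str]] = {
    "P2": (150.0, 275.0, "positive"),
    "P3": (275.0, 450.0, "positive"),
    "N3": (3250.0, 3450.0, "negative"),
}


@dataclass
class ERPWaveform:
    condition: str
    electrode: str
    values: np.ndarray  # µV per timepoint
    fs: float
    n_trials: int
    tmin: float = 0.0

    @property
    def times_ms(self) -> np.ndarray:
        return (self.tmin + np.arange(self.values.size) / self.fs) * 1000.0


@dataclass
class ComponentMeasure:
    component: str
    amplitude: float  # µV at the extremum
    latency: float    # ms of the extremum
    window: tuple[float, float]


def average_epochs(epochs: EpochSet, condition: str,
                   electrode: str) -> ERPWaveform:
    """Pointwise mean over kept trials of one condition at one electrode."""
    ch = epochs.channel_index(electrode)
    trials = epochs.kept(condition)[:, ch, :]
    if trials.shape[0] == 0:
        raise ValueError(f"no kept trials for condition {condition!r}")
    return ERPWaveform(condition=condition, electrode=electrode,
                       values=trials.mean(axis=0), fs=epochs.fs,
                       n_trials=trials.shape[0], tmin=epochs.tmin)


def measure_component(erp: ERPWaveform, component: str,
                      window_ms: tuple[float, float] | None = None,
                      polarity: str | None = None) -> ComponentMeasure:
    """Extremum amplitude and latency of a component within its window.

    Positive components take the maximum, negative the minimum; the
    earliest timepoint wins ties (``argmax``/``argmin`` return the first).
    """
    if window_ms is None or polarity is None:
        try:
            lo, hi, default_pol = COMPONENT_WINDOWS[component]
        except KeyError:
            raise ValueError(f"unknown component {component!r}; give a window")
        window_ms = window_ms or (lo, hi)
        polarity = polarity or default_pol
    t = erp.times_ms
    sel = np.where((t >= window_ms[0]) & (t <= window_ms[1]))[0]
    if sel.size == 0:
        raise ValueError(f"window {window_ms} ms lies outside the epoch")
    seg = erp.values[sel]
    idx = int(np.argmax(seg)) if polarity == "positive" else int(np.argmin(seg))
    return ComponentMeasure(component=component,
                            amplitude=float(seg[idx]),
                            latency=float(t[sel[idx]]),
                            window=tuple(window_ms))


def component_table(epochs: EpochSet, electrodes: list[str],
                    components: list[str] | None = None) -> pd.DataFrame:
    """Component measures per condition x electrode, long format."""
    components = components or list(COMPONENT_WINDOWS)
    rows = []
    for cond in pd.unique(epochs.condition):
        for el in electrodes:
            wave = average_epochs(epochs, cond, el)
            for comp in components:
                m = measure_component(wave, comp)
                rows.append((cond, el, comp, m.amplitude, m.latency,
                             wave.n_trials))
    return pd.DataFrame(rows, columns=["condition", "electrode", "component",
                                       "amplitude_uv", "latency_ms",
                                       "n_trials"])


def _pointwise_f(groups: list[np.ndarray]):
    """Vectorized one-way ANOVA over the time axis.

    Each group is (n_trials, n_timepoints).  Returns (F, p); timepoints
    with zero within-group variance get p = 1 when the group means agree
    and p -> 0 when they differ.
    """
    k = len(groups)
    ns = np.array([g.shape[0] for g in groups])
    n_total = ns.sum()
    grand = np.vstack(groups).mean(axis=0)
    means = np.stack([g.mean(axis=0) for g in groups])
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = sstats.f.sf(F, df_b, df_w)
    degenerate = ssw <= 0
    p = np.where(degenerate & (ssb <= 1e-30), 1.0, p)
    p = np.where(degenerate & (ssb > 1e-30), 0.0, p)
    F = np.where(degenerate, np.inf, F)
    F = np.where(degenerate & (ssb <= 1e-30), 0.0, F)
    return F, p


def pointwise_anova(epochs: EpochSet, electrode: str, *,
                    alpha: float = 0.05, min_run_ms: float = 20.0,
                    conditions: list[str] | None = None,
                    fdr: bool = False) -> list[tuple[float, float]]:
    """Timepoint-by-timepoint one-way ANOVA across conditions.

    Significant timepoints (p <= alpha, optionally Benjamini-Hochberg
    corrected across timepoints) are grouped into contiguous runs; runs
    shorter than *min_run_ms* are discarded.  Returns (start_ms, end_ms)
    intervals.
    """
    conds = conditions or list(pd.unique(epochs.condition))
    if len(conds) < 2:
        raise ValueError("pointwise ANOVA needs at least two conditions")
    ch = epochs.channel_index(electrode)
    groups = [epochs.kept(c)[:, ch, :] for c in conds]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("every condition needs at least two kept trials")
    _, p = _pointwise_f(groups)
    if fdr:
        p = sstats.false_discovery_control(p, method="bh")
    sig = p <= alpha
    intervals = []
    t0 = epochs.tmin * 1000.0
    step = 1000.0 / epochs.fs
    start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if (i - start) * step >= min_run_ms:
                intervals.append((t0 + start * step, t0 + i * step))
            start = None
    return intervals
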