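"""Phase-slope-index (PSI) effective connectivity.

Cross-spectra are estimated Welch-style from 50%-overlapping,
Hamming-tapered, demeaned segments; coherency normalizes them; the PSI of
a channel pair over a band is the imaginary part of the sum over
neighboring frequency bins of conj(K(f)) * K(f + df).  A positive
Psi_ij means channel i temporally leads channel j: for signals whose phase
difference grows linearly with frequency (a fixed transmission delay), the
phase slope — and hence the imaginary part — is positive in the leading
direction.

The PSI is left un-normalized (no division by its jackknife standard
deviation); an optional jackknife normalization is provided for users who
want the dimensionless variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

#: canonical EEG band edges in Hz (half-open [lo, hi))
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class CrossSpectrum:
    S: np.ndarray       # (n_channels, n_channels, n_freqs), Hermitian per f
    freqs: np.ndarray   # Hz grid
    delta_f: float      # grid resolution, Hz
    n_segments: int
    labels: list[str] | None = None


@dataclass
class PsiMatrix:
    psi: np.ndarray     # (n_channels, n_channels), antisymmetric
    band: str
    band_hz: tuple[float, float]
    freq_indices: np.ndarray
    labels: list[str] | None = None


def _segment_fft(data: np.ndarray, nperseg: int) -> np.ndarray:
    """Hamming-tapered rFFT of 50%-overlapping, per-segment-demeaned
    segments.  *data* is (..., n_samples); output (n_segments_total, ...,
    n_freqs) stacking segments from all leading axes."""
    step = nperseg // 2
    n = data.shape[-1]
    if n < nperseg:
        raise ValueError("segment longer than the data")
    window = np.hamming(nperseg)
    starts = range(0, n - nperseg + 1, step)
    segs = np.stack([data[..., s:s + nperseg] for s in starts], axis=0)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    return np.fft.rfft(segs * window, axis=-1)


def cross_spectra(data, fs: float | None = None, seg_len_s: float = 1.0,
                  labels: list[str] | None = None) -> CrossSpectrum:
    """Welch-averaged cross-spectral matrix.

    *data* is an :class:`EpochSet` (kept trials are pooled, each trial
    segmented independently) or a (n_channels, n_samples) continuous
    array with *fs* given.  ``delta_f = 1/seg_len_s``.
    """
    if isinstance(data, EpochSet):
        fs = data.fs
        labels = labels or list(data.labels)
        arrays = list(data.kept())          # (n_channels, n_samples) each
    else:
        if fs is None:
            raise ValueError("fs required for array input")
        arrays = [np.atleast_2d(np.asarray(data, dtype=float))]
    nperseg = int(round(seg_len_s * fs))
    if nperseg < 8:
        raise ValueError("segment must hold at least 8 samples")
    ffts = [_segment_fft(a, nperseg) for a in arrays]
    X = np.concatenate(ffts, axis=0)        # (n_segments, n_channels, n_freqs)
    scale = 1.0 / (fs * (np.hamming(nperseg) ** 2).sum())
    S = np.einsum("scf,szf->czf", X, X.conj()) * (scale / X.shape[0])
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return CrossSpectrum(S=S, freqs=freqs, delta_f=fs / nperseg,
                         n_segments=X.shape[0], labels=labels)


def coherency(cs: CrossSpectrum) -> np.ndarray:
    """Complex coherency K_ij(f) = S_ij / sqrt(S_ii S_jj), |K| <= 1.

    Pairs with a vanishing auto-spectrum at some frequency are set to 0
    there, with a warning.
    """
    auto = np.real(np.einsum("iif->if", cs.S))  # (n_channels, n_freqs)
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    bad = denom <= 0
    if bad.any():
        warnings.warn("zero auto-spectrum encountered; coherency set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(bad, 0.0, cs.S / np.where(bad, 1.0, denom))
    return K


def psi(K: np.ndarray, freqs: np.ndarray, band: tuple[float, float],
        delta_f: float | None = None, band_name: str = "",
        labels: list[str] | None = None) -> PsiMatrix:
    """Phase slope index over a band.

    Psi_ij = Im sum_{f in F} conj(K_ij(f)) K_ij(f + df), with F the grid
    frequencies where both f and f + df fall inside [lo, hi).  The result
    is exactly antisymmetric with a zero diagonal.
    """
    freqs = np.asarray(freqs, dtype=float)
    if delta_f is None:
        delta_f = float(freqs[1] - freqs[0])
    lo, hi = band
    idx = np.where((freqs >= lo) & (freqs + delta_f < hi))[0]
    idx = idx[idx + 1 < freqs.size]
    if idx.size < 1 or np.sum((freqs >= lo) & (freqs < hi)) < 2:
        raise ValueError(f"band {band} holds fewer than 2 grid frequencies")
    val = np.imag((K[..., idx].conj() * K[..., idx + 1]).sum(axis=-1))
    np.fill_diagonal(val, 0.0)
    return PsiMatrix(psi=val, band=band_name, band_hz=(lo, hi),
                     freq_indices=idx, labels=labels)


def psi_normalized(data, band: tuple[float, float], fs: float | None = None,
                   seg_len_s: float = 1.0, **kw) -> PsiMatrix:
    """Jackknife-normalized PSI: raw PSI divided by its leave-one-segment-
    out standard deviation (dimensionless)."""
    if isinstance(data, EpochSet):
        fs = data.fs
        arrays = list(data.kept())
    else:
        arrays = [np.atleast_2d(np.asarray(data, dtype=float))]
    nperseg = int(round(seg_len_s * fs))
    X = np.concatenate([_segment_fft(a, nperseg) for a in arrays], axis=0)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    n_seg = X.shape[0]
    full_S = np.einsum("scf,szf->czf", X, X.conj())
    psis = []
    for leave in range(n_seg):
        S = (full_S - X[leave, :, None, :] * X[leave].conj()[None, :, :]) \
            / (n_seg - 1)
        cs = CrossSpectrum(S=S, freqs=freqs, delta_f=fs / nperseg,
                           n_segments=n_seg - 1)
        psis.append(psi(coherency(cs), freqs, band,
                        delta_f=fs / nperseg).psi)
    psis = np.stack(psis)
    sd = np.sqrt((n_seg - 1) / n_seg
                 * ((psis - psis.mean(axis=0)) ** 2).sum(axis=0))
    cs = CrossSpectrum(S=full_S / n_seg, freqs=freqs, delta_f=fs / nperseg,
                       n_segments=n_seg)
    raw = psi(coherency(cs), freqs, band, delta_f=fs / nperseg, **kw)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(sd > 0, raw.psi / np.where(sd > 0, sd, 1.0), 0.0)
    raw.psi = norm
    return raw


def psi_to_adjacency(pm: PsiMatrix) -> np.ndarray:
    """Directed weighted adjacency: W_ij = Psi_ij where positive, else 0
    (edge i -> j when channel i leads j).  Antisymmetry guarantees no
    reciprocal edge pair."""
    W = np.where(pm.psi > 0, pm.psi, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def band_adjacencies(epochs_or_data, fs: float | None = None,
                     seg_len_s: float = 1.0,
                     bands: dict[str, tuple[float, float]] | None = None,
                     labels: list[str] | None = None
                     ) -> dict[str, np.ndarray]:
    """Per-band PSI adjacency from one cross-spectral estimate."""
    cs = cross_spectra(epochs_or_data, fs=fs, seg_len_s=seg_len_s,
                       labels=labels)
    K = coherency(cs)
    out = {}
    for name, (lo, hi) in (bands or BANDS).items():
        pm = psi(K, cs.freqs, (lo, hi), delta_f=cs.delta_f, band_name=name,
                 labels=cs.labels)
        out[name] = psi_to_adjacency(pm)
    return out
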