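"""Signal preprocessing: band filtering, windowing, spectral features,
raw-topology construction, and MIC association maps.

The raw topology A(0) is the fixed initial adjacency among electrodes built
from placement distance and/or full-recording signal correlation; the MIC
map is the static association-map baseline that the dynamic graph generator
is meant to improve on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_data import Recording

__all__ = [
    "GAMMA_BAND", "EEG_BANDS",
    "RawTopology", "WindowedFeatures", "AssociationMap", "WindowSegment",
    "bandpass", "segment_windows", "spectral_features", "windowed_features",
    "distance_topology", "correlation_topology", "blend_topology", "mic_map",
    "export_matrix_tsv",
]

#: Default band limits in Hz. Gamma is capped at 70 Hz, safely below the
#: 125 Hz Nyquist limit of 250 Hz recordings.
GAMMA_BAND = (30.0, 70.0)
EEG_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": GAMMA_BAND,
}


@dataclass
class RawTopology:
    """Initial adjacency A(0): symmetric, zero diagonal, nonnegative."""

    a0: np.ndarray
    source: str  # distance | correlation | blend

    def __post_init__(self):
        self.a0 = np.asarray(self.a0, float)
        if not np.all(np.isfinite(self.a0)):
            raise ValueError("topology entries must be finite")
        if not np.allclose(self.a0, self.a0.T):
            raise ValueError("topology must be symmetric")


@dataclass
class WindowedFeatures:
    """Per-window feature tensor x of shape [N x C_in x T]."""

    x: np.ndarray
    window_index: int
    window_interval: tuple[float, float]

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        if self.x.ndim != 3:
            raise ValueError("features must be [N x C_in x T]")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("features contain non-finite values")


@dataclass
class AssociationMap:
    """Pairwise MIC scores in [0, 1]; symmetric with unit diagonal."""

    mic: np.ndarray


@dataclass
class WindowSegment:
    """One half-open time window of a recording."""

    signal: np.ndarray  # [N x samples]
    fs: float
    window_index: int
    window_interval: tuple[float, float]


def bandpass(rec: Recording, low_hz: float = GAMMA_BAND[0],
             high_hz: float = GAMMA_BAND[1], order: int = 4,
             notch_hz: float | None = None) -> Recording:
    """Zero-phase Butterworth band-pass; default band is gamma (30-70 Hz)."""
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) must lie inside (0, {nyq})")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    if notch_hz is not None:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        filtered = sps.filtfilt(b, a, filtered, axis=1)
    return Recording(signal=filtered, fs=rec.fs,
                     channel_names=list(rec.channel_names),
                     lobe_of=dict(rec.lobe_of), onset=rec.onset, label=rec.label)


def segment_windows(rec: Recording, window_s: float = 5.0) -> list[WindowSegment]:
    """Non-overlapping half-open windows [kW, (k+1)W); trailing partial dropped."""
    if window_s <= 0:
        raise ValueError("window length must be positive")
    w = int(round(window_s * rec.fs))
    count = rec.n_samples // w
    segments = []
    for k in range(count):
        segments.append(WindowSegment(
            signal=rec.signal[:, k * w:(k + 1) * w], fs=rec.fs,
            window_index=k,
            window_interval=(k * window_s, (k + 1) * window_s)))
    return segments


def _band_log_power(frame: np.ndarray, fs: float, bands) -> np.ndarray:
    """Log band power of one [N x samples] frame for each band; [N x len(bands)]."""
    freqs = np.fft.rfftfreq(frame.shape[1], d=1.0 / fs)
    spec = np.abs(np.fft.rfft(frame, axis=1)) ** 2 / frame.shape[1]
    out = np.empty((frame.shape[0], len(bands)))
    for b, (lo, hi) in enumerate(bands):
        sel = (freqs >= lo) & (freqs < hi)
        power = spec[:, sel].sum(axis=1) if sel.any() else np.zeros(frame.shape[0])
        out[:, b] = np.log(power + 1e-12)
    return out


def spectral_features(segment: WindowSegment, n_bands: int = 5,
                      n_frames: int = 10, normalize: bool = True,
                      norm_stats: tuple[float, float] | None = None,
                      ) -> WindowedFeatures:
    """Short-time band-power features over canonical EEG bands.

    The window is split into `n_frames` sub-frames; per channel and sub-frame
    the log power in each band gives x of shape [N x n_bands x n_frames].
    With ``normalize`` the log powers are z-scored — by the recording-level
    (mean, sd) in ``norm_stats`` when given, else by the segment's own
    statistics — with an epsilon guard so constant input maps to zeros.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be at least 1")
    if segment.signal.size == 0:
        raise ValueError("segment is empty")
    bands = list(EEG_BANDS.values())[:n_bands]
    n = segment.signal.shape[1]
    edges = np.linspace(0, n, n_frames + 1).astype(int)
    feats = np.stack([
        _band_log_power(segment.signal[:, edges[t]:edges[t + 1]], segment.fs, bands)
        for t in range(n_frames)
    ], axis=-1)  # [N x n_bands x T]
    if normalize:
        if norm_stats is None:
            mu, sd = float(feats.mean()), float(feats.std())
        else:
            mu, sd = norm_stats
        # epsilon guard: constant input (e.g. all-zero signal) maps to zeros
        feats = np.zeros_like(feats) if sd < 1e-8 else (feats - mu) / sd
    return WindowedFeatures(x=feats, window_index=segment.window_index,
                            window_interval=segment.window_interval)


def windowed_features(rec: Recording, window_s: float = 5.0, n_bands: int = 5,
                      n_frames: int = 10, onset_only: bool = False,
                      ) -> list[WindowedFeatures]:
    """Window a recording and extract per-recording z-normalized features.

    The normalization statistics are the global mean and sd of the log band
    powers over the whole recording, so relative power differences between
    channels and bands (the discriminative signal) are preserved.
    With ``onset_only`` only windows fully inside the annotated onset
    interval are returned (all windows when the recording has no onset).
    """
    segments = segment_windows(rec, window_s)
    raw = [spectral_features(s, n_bands, n_frames, normalize=False)
           for s in segments]
    if not raw:
        return []
    allx = np.stack([f.x for f in raw])
    mu, sd = float(allx.mean()), float(allx.std())
    out = []
    for f in raw:
        if onset_only and rec.onset is not None:
            t0, t1 = f.window_interval
            if not (rec.onset[0] <= t0 and t1 <= rec.onset[1]):
                continue
        z = np.zeros_like(f.x) if sd < 1e-8 else (f.x - mu) / sd
        out.append(WindowedFeatures(
            x=z, window_index=f.window_index,
            window_interval=f.window_interval))
    return out


def distance_topology(coords: np.ndarray, bandwidth: float = 1.0,
                      k_nearest: int | None = None) -> RawTopology:
    """Gaussian distance kernel a0[i,j] = exp(-d(i,j)^2 / bandwidth^2)."""
    coords = np.asarray(coords, float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    a0 = np.exp(-d2 / bandwidth ** 2)
    np.fill_diagonal(a0, 0.0)
    if k_nearest is not None:
        keep = np.zeros_like(a0, bool)
        for i in range(a0.shape[0]):
            nbr = np.argsort(-a0[i])[:k_nearest]
            keep[i, nbr] = True
        keep = keep | keep.T  # symmetrize by max
        a0 = a0 * keep
    return RawTopology(a0=a0, source="distance")


def correlation_topology(rec: Recording) -> RawTopology:
    """Absolute Pearson correlation over the full recording, zero diagonal."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    sd = rec.signal.std(axis=1)
    dead = sd < 1e-12
    if dead.any():
        warnings.warn(f"zero-variance channels {np.where(dead)[0].tolist()}: "
                      "their edges are set to 0")
    safe = rec.signal.copy()
    safe[dead] = np.random.default_rng(0).normal(size=(dead.sum(), rec.n_samples))
    a0 = np.abs(np.corrcoef(safe))
    a0[dead, :] = 0.0
    a0[:, dead] = 0.0
    np.fill_diagonal(a0, 0.0)
    return RawTopology(a0=a0, source="correlation")


def blend_topology(rec: Recording, coords: np.ndarray,
                   bandwidth: float = 1.0) -> RawTopology:
    """Elementwise mean of the distance and correlation topologies."""
    a = distance_topology(coords, bandwidth).a0
    b = correlation_topology(rec).a0
    return RawTopology(a0=0.5 * (a + b), source="blend")


# ---------------------------------------------------------------------------
# maximal information coefficient

def _equicount_bins(x: np.ndarray, k: int) -> np.ndarray:
    """Assign ranks to k near-equal-count bins (stable ordering for ties)."""
    n = x.size
    order = np.argsort(x, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = (np.arange(n) * k) // n
    return bins


def _grid_mi(bx: np.ndarray, by: np.ndarray, a: int, b: int) -> float:
    joint = np.zeros((a, b))
    np.add.at(joint, (bx, by), 1.0)
    joint /= bx.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def mic_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Maximal information coefficient of one variable pair.

    Grid-maximized normalized mutual information: over all grids (a x b)
    with a, b >= 2 and a*b <= n^0.6, partition both variables into
    equi-count bins and take max I(a,b) / log(min(a, b)). This equi-count
    grid search is a documented approximation of the exact
    dynamic-programming partition optimization.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for MIC")
    if x.std() < 1e-12 or y.std() < 1e-12:
        return 0.0
    limit = max(4.0, n ** 0.6)
    best = 0.0
    amax = int(limit // 2)
    bins_x = {a: _equicount_bins(x, a) for a in range(2, amax + 1)}
    bins_y = {b: _equicount_bins(y, b) for b in range(2, amax + 1)}
    for a in range(2, amax + 1):
        for b in range(2, amax + 1):
            if a * b > limit:
                break
            mi = _grid_mi(bins_x[a], bins_y[b], a, b)
            score = mi / np.log(min(a, b))
            if score > best:
                best = score
    return min(best, 1.0)


def mic_map(rec: Recording) -> AssociationMap:
    """Pairwise MIC association map over all channels."""
    if rec.n_samples < 20:
        raise ValueError("need at least 20 samples per channel")
    n = rec.n_channels
    mic = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mic[i, j] = mic[j, i] = mic_pair(rec.signal[i], rec.signal[j])
    return AssociationMap(mic=mic)


def export_matrix_tsv(matrix: np.ndarray, channel_names: list[str], path) -> None:
    """Write a square matrix as TSV with channel-name header row/column."""
    with open(path, "w") as f:
        f.write("\t" + "\t".join(channel_names) + "\n")
        for name, row in zip(channel_names, np.asarray(matrix)):
            f.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
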