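"""Raw recordings to normalized regions x regions x frequency feature tensors.

The pipeline is: mask artifact samples (30 Hz high-pass, 20x MAD), average
same-region channels in the time domain, cut non-overlapping 2 s windows, and
estimate Welch cross-power spectral densities between every pair of region
traces.  The diagonal of the resulting tensor is within-region spectral power;
the off-diagonal magnitude is the synchrony measure.  Twenty-nine frequency
bins linearly spaced from 0 to 54.7 Hz are kept (fs=1000, 512-sample segments
give a 1.953 Hz grid, bins k=0..28).  Finally every entry is divided by the
recording's single median over all valid windows, region pairs and
frequencies, removing between-subject gain differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

DEFAULT_FS = 1000.0
WINDOW_S = 2.0
SEGMENT_SAMPLES = 512
F_MAX = 54.7
N_FREQ_BINS = 29


@dataclass
class Recording:
    """Multi-channel LFP recording with channel->region map and optional EMG.

    ``signals`` is channels x samples; ``channel_region_map`` maps channel
    index -> region name (the EMG channel, if any, is identified by
    ``emg_channel`` and must not appear in the map).
    """

    signals: np.ndarray
    fs: float
    channel_region_map: dict[int, str]
    emg_channel: int | None = None
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be channels x samples")
        nchan = self.signals.shape[0]
        for ch in self.channel_region_map:
            if not (0 <= ch < nchan):
                raise ValueError(f"channel {ch} outside recording with {nchan} channels")
        if self.emg_channel is not None and self.emg_channel in self.channel_region_map:
            raise ValueError("EMG channel must not be mapped to a region")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for ch in sorted(self.channel_region_map):
            r = self.channel_region_map[ch]
            if r not in seen:
                seen.append(r)
        return seen

    @property
    def emg(self) -> np.ndarray | None:
        if self.emg_channel is None:
            return None
        return self.signals[self.emg_channel]

    def n_windows(self, window_s: float = WINDOW_S) -> int:
        return int(self.n_samples // round(window_s * self.fs))


@dataclass
class OutlierMask:
    """Per-channel boolean sample mask plus per-window exclusion flags."""

    sample_mask: np.ndarray        # channels x samples, True = outlier
    window_invalid: np.ndarray     # n_windows bool, True = excluded
    suspect_channels: list[int] = field(default_factory=list)


@dataclass
class FeatureTensor:
    """Per-window regions x regions x frequency power/synchrony features.

    ``values`` is windows x R x R x F, non-negative and symmetric in the two
    region axes; the diagonal holds within-region Welch power, off-diagonals
    the magnitude of the averaged cross-spectrum.
    """

    values: np.ndarray
    freqs: np.ndarray
    regions: list[str]
    valid_mask: np.ndarray
    window_s: float = WINDOW_S
    normalization_scalar: float | None = None
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[1] != v.shape[2]:
            raise ValueError("values must be windows x R x R x F")
        if (v < 0).any():
            raise ValueError("feature values must be non-negative")
        if not np.allclose(v, np.swapaxes(v, 1, 2), rtol=1e-10, atol=1e-12):
            raise ValueError("feature tensor must be symmetric in the region axes")
        self.values = v
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_freqs(self) -> int:
        return self.values.shape[3]

    @property
    def d(self) -> int:
        """Flattened per-window feature dimension, R^2 * F (1,856 for 8 regions)."""
        return self.n_regions ** 2 * self.n_freqs


def detect_outliers(
    recording: Recording,
    highpass_hz: float = 30.0,
    mad_multiplier: float = 20.0,
    window_s: float = WINDOW_S,
) -> OutlierMask:
    """Flag artifact samples: |30 Hz high-passed signal| > 20 x channel MAD.

    Any flagged sample in any region-mapped channel invalidates its whole 2 s
    window.  Constant channels (MAD = 0) produce no flags — the strict
    inequality against a zero threshold is never satisfied by zero residuals —
    but are reported as suspect.
    """
    sos = sps.butter(4, highpass_hz, btype="highpass", fs=recording.fs, output="sos")
    nchan, nsamp = recording.signals.shape
    mask = np.zeros((nchan, nsamp), dtype=bool)
    suspects: list[int] = []
    used = sorted(recording.channel_region_map)
    if recording.emg_channel is not None:
        used = used + [recording.emg_channel]
    for ch in used:
        hp = sps.sosfiltfilt(sos, recording.signals[ch])
        mad = np.median(np.abs(hp - np.median(hp)))
        if mad == 0:
            suspects.append(ch)
            continue
        mask[ch] = np.abs(hp) > mad_multiplier * mad
    wlen = int(round(window_s * recording.fs))
    nwin = nsamp // wlen
    region_rows = sorted(recording.channel_region_map)
    any_flag = mask[region_rows].any(axis=0)[: nwin * wlen]
    window_invalid = any_flag.reshape(nwin, wlen).any(axis=1)
    return OutlierMask(mask, window_invalid, suspects)


def screen_saturation(
    trace: np.ndarray, plateau_fraction: float = 0.01
) -> bool:
    """Heuristic saturation screen: True if the trace looks clipped.

    A channel is suspect when more than ``plateau_fraction`` of its samples
    sit exactly at the running min or max plateau (clipping rails).
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) == 0 or np.ptp(trace) == 0:
        return True
    at_rail = (trace == trace.max()) | (trace == trace.min())
    return float(at_rail.mean()) > plateau_fraction


def average_regions(
    recording: Recording,
    mask: OutlierMask | None = None,
    exclusions: set[int] | frozenset[int] = frozenset(),
    region_order: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Average same-region channels sample-wise in the time domain.

    Returns (regions x samples array, region name list in fixed order).  The
    EMG channel is never averaged; access it via ``recording.emg``.
    """
    groups: dict[str, list[int]] = {}
    for ch, reg in recording.channel_region_map.items():
        if ch in exclusions:
            continue
        groups.setdefault(reg, []).append(ch)
    order = region_order if region_order is not None else recording.regions
    traces = []
    for reg in order:
        chans = groups.get(reg, [])
        if not chans:
            raise ValueError(f"region {reg!r} has no remaining channels after exclusions")
        traces.append(recording.signals[sorted(chans)].mean(axis=0))
    return np.stack(traces), list(order)


def welch_frequency_grid(
    fs: float = DEFAULT_FS,
    segment_samples: int = SEGMENT_SAMPLES,
    f_max: float = F_MAX,
) -> np.ndarray:
    """Welch frequency bins: multiples of fs/segment from 0 up to f_max inclusive."""
    if f_max >= fs / 2:
        raise ValueError("f_max must be below the Nyquist frequency")
    df = fs / segment_samples
    kmax = int(np.floor(f_max / df + 1e-9))
    return df * np.arange(kmax + 1)


def welch_feature_tensor(
    region_traces: np.ndarray,
    fs: float = DEFAULT_FS,
    regions: list[str] | None = None,
    window_s: float = WINDOW_S,
    segment_samples: int = SEGMENT_SAMPLES,
    overlap_fraction: float = 0.5,
    f_max: float = F_MAX,
    valid_windows: np.ndarray | None = None,
    subject_id: str = "",
    session_id: str = "",
) -> FeatureTensor:
    """Per-2 s-window Welch cross-power spectral density tensor.

    For each ordered region pair (i, j) the cross-spectrum is estimated over
    Hann-windowed, 50%-overlapping segments within the window; the stored
    feature is its magnitude (which on the diagonal reduces to the ordinary
    Welch power spectral density).  The trailing partial window is dropped.
    """
    traces = np.asarray(region_traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("region_traces must be regions x samples")
    R, nsamp = traces.shape
    wlen = int(round(window_s * fs))
    if wlen <= 0 or segment_samples <= 0:
        raise ValueError("window and segment lengths must be positive")
    if segment_samples > wlen:
        raise ValueError("segment_samples must not exceed the window length")
    nwin = nsamp // wlen
    if nwin < 1:
        raise ValueError("trace shorter than one window")
    freqs = welch_frequency_grid(fs, segment_samples, f_max)
    F = len(freqs)
    noverlap = int(round(segment_samples * overlap_fraction))

    # windows x R x wlen view for vectorized scipy.signal.csd along last axis
    wins = traces[:, : nwin * wlen].reshape(R, nwin, wlen).transpose(1, 0, 2)
    values = np.empty((nwin, R, R, F))
    for i in range(R):
        for j in range(i, R):
            f, pxy = sps.csd(
                wins[:, i, :], wins[:, j, :],
                fs=fs, window="hann", nperseg=segment_samples,
                noverlap=noverlap, detrend="constant", axis=-1,
            )
            mag = np.abs(pxy[..., :F])
            values[:, i, j, :] = mag
            values[:, j, i, :] = mag
    if valid_windows is None:
        valid = np.ones(nwin, dtype=bool)
    else:
        valid = np.asarray(valid_windows, dtype=bool)[:nwin]
    return FeatureTensor(
        values=values, freqs=freqs,
        regions=list(regions) if regions is not None else [f"r{i}" for i in range(R)],
        valid_mask=valid, window_s=window_s,
        subject_id=subject_id, session_id=session_id,
    )


def median_normalize(tensor: FeatureTensor) -> FeatureTensor:
    """Divide every entry by the recording's single median over valid windows.

    The scalar is the median of all entries across valid windows, region
    pairs and frequencies (one per subject/session), stored in
    ``normalization_scalar``.  Scale-invariance: multiplying the raw signals
    by g scales raw features by g^2 and leaves the normalized tensor fixed.
    """
    if not tensor.valid_mask.any():
        raise ValueError("no valid windows to normalize over")
    scalar = float(np.median(tensor.values[tensor.valid_mask]))
    if scalar == 0:
        raise ValueError("degenerate recording: median feature value is 0")
    return FeatureTensor(
        values=tensor.values / scalar,
        freqs=tensor.freqs,
        regions=tensor.regions,
        valid_mask=tensor.valid_mask,
        window_s=tensor.window_s,
        normalization_scalar=scalar,
        subject_id=tensor.subject_id,
        session_id=tensor.session_id,
    )


def flatten(tensor: FeatureTensor) -> np.ndarray:
    """Row-major flatten of the full R x R x F block per window (length R^2*F).

    Both symmetric copies are retained, so 8 regions x 29 bins gives the
    1,856-dimensional per-window vector the classifier consumes.
    """
    n = tensor.n_windows
    return tensor.values.reshape(n, -1)


def unflatten(vectors: np.ndarray, n_regions: int, n_freqs: int) -> np.ndarray:
    """Inverse of :func:`flatten`: windows x d -> windows x R x R x F."""
    v = np.asarray(vectors, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[None, :]
    if v.shape[1] != n_regions ** 2 * n_freqs:
        raise ValueError("vector length inconsistent with R^2 * F")
    out = v.reshape(v.shape[0], n_regions, n_regions, n_freqs)
    return out[0] if single else out
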