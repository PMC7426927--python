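"""Preprocessing: filter bank, zero-phase FIR filtering, Laplacian reference,
level definitions and artifact-free epoch selection.

The analysis operates on band-limited versions of the recording: a slow band
(0.1-4 Hz) and a set of contiguous 2 Hz-wide bands tiling 4-50 Hz, each with
a 1 Hz transition band. Filtering is zero-phase FIR (a Hamming windowed-sinc
kernel applied forward and backward, realized as a single linear convolution
with the kernel's autocorrelation). Sensor-level analyses use a surface
Laplacian reference based on first nearest neighbors. Within each
constant-dose level, analyses use ``n`` disjoint artifact-free epochs
(default 10 x 30 s), placed earliest-first so the selection is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy.signal import firwin

from .containers import LevelSchedule, SessionRecording

__all__ = [
    "BandSpec",
    "FilterBank",
    "EpochSet",
    "design_filter_bank",
    "fir_kernel",
    "BandFilterer",
    "zero_phase_bandpass",
    "analytic_bandpass",
    "bandpass_downsample",
    "build_neighbor_graph",
    "laplacian_transform",
    "laplacian_reference",
    "compute_artifact_mask",
    "detect_bridged_channels",
    "define_levels",
    "select_epochs",
    "read_eeg",
]

LEVEL_NAMES = ("Baseline", "Sedation", "UncLow", "UncHigh")


@dataclass(frozen=True)
class BandSpec:
    """Passband edges (Hz) and transition width (Hz) for one FIR band."""

    low_hz: float
    high_hz: float
    transition_hz: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"need 0 <= low < high, got ({self.low_hz}, {self.high_hz})")
        if self.transition_hz <= 0:
            raise ValueError("transition width must be positive")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)

    @property
    def label(self) -> str:
        return f"{self.low_hz:g}-{self.high_hz:g}Hz"


@dataclass(frozen=True)
class FilterBank:
    """Slow band plus the contiguous high-band tiling and a summary band."""

    slow_band: BandSpec
    high_bands: tuple[BandSpec, ...]
    summary_band: BandSpec

    def __post_init__(self) -> None:
        for a, b in zip(self.high_bands, self.high_bands[1:]):
            if not math.isclose(a.high_hz, b.low_hz):
                raise ValueError("high bands must tile contiguously without overlap")


def design_filter_bank(
    low_stop: float = 4.0,
    high_stop: float = 50.0,
    band_width: float = 2.0,
    transition: float = 1.0,
    slow_low: float = 0.1,
    summary: tuple[float, float] = (8.0, 16.0),
) -> FilterBank:
    """Build the slow band plus a ``band_width``-Hz tiling of [low_stop, high_stop].

    Defaults give the 0.1-4 Hz slow band and 23 bands 4-6, 6-8, ..., 48-50 Hz,
    each with a 1 Hz transition band.
    """
    if not high_stop > low_stop >= 0:
        raise ValueError("need high_stop > low_stop >= 0")
    n_bands = (high_stop - low_stop) / band_width
    if abs(n_bands - round(n_bands)) > 1e-9:
        raise ValueError(
            f"band width {band_width} Hz does not divide the range "
            f"[{low_stop}, {high_stop}] Hz"
        )
    n_bands = int(round(n_bands))
    highs = tuple(
        BandSpec(low_stop + k * band_width, low_stop + (k + 1) * band_width, transition)
        for k in range(n_bands)
    )
    return FilterBank(
        slow_band=BandSpec(slow_low, low_stop, transition),
        high_bands=highs,
        summary_band=BandSpec(summary[0], summary[1], transition),
    )


# ---------------------------------------------------------------------------
# Zero-phase FIR filtering
# ---------------------------------------------------------------------------

def fir_kernel(band: BandSpec, fs: float) -> np.ndarray:
    """Hamming windowed-sinc FIR kernel for one band.

    The order is ceil(3.3 / (transition/fs)) rounded up to even (odd tap
    count, symmetric type-I kernel). At a low edge narrower than the nominal
    transition width (the 0.1 Hz edge of the slow band) the transition is
    clamped to the edge frequency so the stopband stays non-negative.
    """
    if band.high_hz + band.transition_hz >= fs / 2:
        raise ValueError(
            f"band {band.label} with transition {band.transition_hz} Hz does not "
            f"fit below the Nyquist frequency {fs / 2} Hz"
        )
    trans = band.transition_hz
    if band.low_hz > 0:
        trans = min(trans, band.low_hz)
    order = int(math.ceil(3.3 * fs / trans))
    order += order % 2
    numtaps = order + 1
    if band.low_hz > 0:
        return firwin(numtaps, [band.low_hz, band.high_hz], pass_zero=False, fs=fs, window="hamming")
    return firwin(numtaps, band.high_hz, pass_zero=True, fs=fs, window="hamming")


class BandFilterer:
    """Cached FFT-based zero-phase filtering for one session length.

    Zero phase is obtained by applying the linear-phase kernel forward and
    backward, i.e. convolving once with the kernel autocorrelation (an even,
    zero-phase kernel). ``analytic`` additionally zeroes the negative
    frequencies of the padded spectrum, returning the analytic signal of the
    band-limited data in the same pass.
    """

    def __init__(self, n_samples: int, fs: float):
        self.n_samples = int(n_samples)
        self.fs = float(fs)
        self._cache: dict[tuple, tuple] = {}
        self._data_fft: dict[tuple, tuple] = {}  # (id(data), nfft, kind) -> (ref, X)

    def _plan(self, band: BandSpec, kind: str):
        key = (band, kind)
        if key not in self._cache:
            h = fir_kernel(band, self.fs)
            g = np.convolve(h, h[::-1])  # forward-backward, zero-phase
            if len(g) > 2 * self.n_samples:
                raise ValueError(
                    f"recording ({self.n_samples} samples) shorter than the "
                    f"filter span for band {band.label} ({len(g)} taps)"
                )
            nfft = sfft.next_fast_len(self.n_samples + len(g) - 1)
            offset = (len(g) - 1) // 2
            if kind == "real":
                G = sfft.rfft(g, nfft)
            else:
                # fold the one-sided (analytic-signal) selection into the
                # kernel spectrum: positive frequencies doubled, negative zeroed
                G = sfft.fft(g, nfft)
                half = nfft // 2
                G[1:half] *= 2.0
                G[half + 1 :] = 0.0
            self._cache[key] = (nfft, G, offset)
        return self._cache[key]

    def _fft_of(self, data: np.ndarray, nfft: int, kind: str) -> np.ndarray:
        """Forward FFT of zero-padded data, cached per (array, nfft)."""
        key = (id(data), nfft, kind)
        hit = self._data_fft.get(key)
        if hit is not None and hit[0] is data:
            return hit[1]
        if kind == "real":
            X = sfft.rfft(data, nfft, axis=-1)
        else:
            cdtype = np.complex64 if data.dtype == np.float32 else np.complex128
            buf = np.zeros(data.shape[:-1] + (nfft,), dtype=cdtype)
            buf[..., : data.shape[-1]] = data
            X = sfft.fft(buf, axis=-1, overwrite_x=True)
        self._data_fft[key] = (data, X)
        return X

    def filter(self, data: np.ndarray, band: BandSpec) -> np.ndarray:
        """Zero-phase band-limited version of ``data`` (last axis = time)."""
        data = np.asarray(data)
        nfft, G, offset = self._plan(band, "real")
        Y = self._fft_of(data, nfft, "real") * G
        y = sfft.irfft(Y, nfft, axis=-1)[..., offset : offset + self.n_samples]
        return np.ascontiguousarray(y.astype(data.dtype, copy=False))

    def analytic(self, data: np.ndarray, band: BandSpec) -> np.ndarray:
        """Complex analytic signal of the zero-phase band-limited data."""
        data = np.asarray(data)
        nfft, G, offset = self._plan(band, "complex")
        cdtype = np.complex64 if data.dtype == np.float32 else np.complex128
        X = self._fft_of(data, nfft, "complex") * G.astype(cdtype)
        z = sfft.ifft(X, nfft, axis=-1, overwrite_x=True)[..., offset : offset + self.n_samples]
        return z

    def edge_samples(self, band: BandSpec) -> int:
        """Half the filter span: samples to flag as edge-distorted."""
        h = fir_kernel(band, self.fs)
        return (len(h) - 1) // 2


def zero_phase_bandpass(data: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    return BandFilterer(np.asarray(data).shape[-1], fs).filter(data, band)


def analytic_bandpass(data: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    return BandFilterer(np.asarray(data).shape[-1], fs).analytic(data, band)


def bandpass_downsample(
    recording: SessionRecording, band: BandSpec, target_rate: float
) -> SessionRecording:
    """Zero-phase bandpass filter and decimate to ``target_rate``.

    The passband (plus transition) must sit below the new Nyquist frequency;
    the decimation factor must be an integer. Annotations are carried over
    (they are in seconds); the artifact mask is decimated alongside.
    """
    if target_rate < 2 * (band.high_hz + band.transition_hz):
        raise ValueError(
            f"target rate {target_rate} Hz violates Nyquist for band {band.label} "
            f"(+{band.transition_hz} Hz transition)"
        )
    q = recording.sample_rate_hz / target_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"sample rate ratio {recording.sample_rate_hz}/{target_rate} is not an integer"
        )
    q = int(round(q))
    filt = BandFilterer(recording.n_samples, recording.sample_rate_hz)
    data = filt.filter(recording.data, band)[:, ::q]
    mask = None
    if recording.artifact_mask is not None:
        mask = recording.artifact_mask[:, ::q]
    return recording.copy_with(data=data, sample_rate_hz=target_rate, artifact_mask=mask)


# ---------------------------------------------------------------------------
# Surface Laplacian reference
# ---------------------------------------------------------------------------

def build_neighbor_graph(positions: np.ndarray, scale: float = 1.25) -> dict[int, set[int]]:
    """First-nearest-neighbor graph by mutual closeness.

    ``j`` is a neighbor of ``i`` if ||i - j|| <= ``scale`` x the distance from
    ``i`` to its single nearest channel; the relation is symmetrized by union.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels to build a neighbor graph")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    off = d + np.diag(np.full(n, np.inf))
    if np.any(off < 1e-12):
        dup = np.argwhere(off < 1e-12)
        raise ValueError(f"duplicate channel positions: pairs {dup[:3].tolist()}")
    nearest = off.min(axis=1)
    adj = off <= scale * nearest[:, None]
    adj |= adj.T  # union symmetrization
    return {i: set(np.flatnonzero(adj[i]).tolist()) for i in range(n)}


def laplacian_transform(data: np.ndarray, graph: dict[int, set[int]]) -> np.ndarray:
    """Each channel minus the mean of its neighbors."""
    isolated = [i for i in range(data.shape[0]) if not graph.get(i)]
    if isolated:
        raise ValueError(f"channels without neighbors: {isolated}")
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        nbrs = sorted(graph[i])
        out[i] = data[i] - data[nbrs].mean(axis=0)
    return out


def laplacian_reference(
    recording: SessionRecording, neighbor_graph: dict[int, set[int]] | None = None
) -> SessionRecording:
    """Apply the first-nearest-neighbor surface Laplacian reference."""
    if neighbor_graph is None:
        neighbor_graph = build_neighbor_graph(recording.channel_positions)
    return recording.copy_with(data=laplacian_transform(recording.data, neighbor_graph))


# ---------------------------------------------------------------------------
# Artifact mask and bridged electrodes
# ---------------------------------------------------------------------------

def compute_artifact_mask(
    recording: SessionRecording,
    amp_threshold_uv: float = 500.0,
    flat_window_s: float = 1.0,
) -> np.ndarray:
    """Threshold-based stand-in for visual artifact rejection.

    Marks samples whose absolute amplitude exceeds ``amp_threshold_uv`` and
    whole ``flat_window_s`` windows that are flat (zero variance).
    """
    mask = np.abs(recording.data) > amp_threshold_uv
    w = int(round(flat_window_s * recording.sample_rate_hz))
    if w >= 2:
        n_win = recording.n_samples // w
        seg = recording.data[:, : n_win * w].reshape(recording.n_channels, n_win, w)
        flat = seg.std(axis=-1) == 0
        mask[:, : n_win * w] |= np.repeat(flat, w, axis=1)
    return mask


def detect_bridged_channels(data: np.ndarray, threshold: float = 0.999) -> list[int]:
    """Channels to drop because they are near-duplicates of an earlier channel.

    A simple whole-session correlation heuristic standing in for dedicated
    bridged-electrode detection: for each pair with |corr| > threshold the
    later channel is flagged.
    """
    x = data - data.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    c = (x / sd[:, None]) @ (x / sd[:, None]).T / x.shape[1]
    drop = set()
    n = data.shape[0]
    for i in range(n):
        if i in drop:
            continue
        for j in range(i + 1, n):
            if abs(c[i, j]) > threshold:
                drop.add(j)
    return sorted(drop)


# ---------------------------------------------------------------------------
# Level definitions and epoch selection
# ---------------------------------------------------------------------------

def define_levels(schedule: LevelSchedule) -> dict[str, str | None]:
    """Map the four levels of interest to schedule labels.

    Baseline: the period before drug onset. Sedation: the level prior to the
    one in which LOC occurred (absent when LOC fell in the first drug level).
    UncLow: the first full level after LOC. UncHigh: the highest-dose level,
    or the level before the first burst-suppression level for subjects who
    entered burst suppression.
    """
    if schedule.loc_time_s is None:
        raise ValueError("schedule has no LOC marker; cannot define levels of interest")
    levels = schedule.levels
    drug_idx = [k for k, lv in enumerate(levels) if lv.dose > 0]
    if not drug_idx or drug_idx[0] == 0:
        raise ValueError("schedule has no pre-drug period")
    baseline = levels[drug_idx[0] - 1]

    loc_level = schedule.level_containing(schedule.loc_time_s)
    if loc_level is None:
        raise ValueError(f"LOC time {schedule.loc_time_s} s falls outside the schedule")
    loc_idx = levels.index(loc_level)

    sedation = None
    if loc_idx - 1 >= 0 and levels[loc_idx - 1].dose > 0:
        sedation = levels[loc_idx - 1]

    unc_low = levels[loc_idx + 1] if loc_idx + 1 < len(levels) else None

    post = levels[loc_idx + 1 :]
    unc_high = None
    bs = [k for k, lv in enumerate(post) if lv.burst_suppression]
    if bs:
        if bs[0] > 0:
            unc_high = post[bs[0] - 1]
    else:
        candidates = [lv for lv in post if lv.dose > 0]
        if candidates:
            unc_high = max(candidates, key=lambda lv: lv.dose)

    return {
        "Baseline": baseline.label,
        "Sedation": sedation.label if sedation else None,
        "UncLow": unc_low.label if unc_low else None,
        "UncHigh": unc_high.label if unc_high else None,
    }


@dataclass(frozen=True)
class EpochSet:
    """Disjoint artifact-free analysis windows inside one level."""

    level: str
    windows: tuple[tuple[float, float], ...]
    duration_s: float

    @property
    def count(self) -> int:
        return len(self.windows)

    def sample_slices(self, fs: float) -> list[slice]:
        out = []
        for s0, s1 in self.windows:
            i0 = int(round(s0 * fs))
            out.append(slice(i0, i0 + int(round(self.duration_s * fs))))
        return out


def select_epochs(
    recording: SessionRecording,
    level: str,
    n: int = 10,
    duration_s: float = 30.0,
    mask: np.ndarray | None = None,
) -> EpochSet:
    """Earliest-first disjoint placement of ``n`` artifact-free epochs.

    A sample is unusable if any channel's artifact mask flags it. Raises with
    the achievable count when fewer than ``n`` clean epochs fit.
    """
    lv = recording.schedule.level(level)
    fs = recording.sample_rate_hz
    if mask is None:
        mask = recording.artifact_mask
    bad = (
        np.zeros(recording.n_samples, dtype=bool)
        if mask is None
        else np.asarray(mask).any(axis=0)
    )
    L = int(round(duration_s * fs))
    i0 = int(round(lv.start_s * fs))
    i_end = min(int(round(lv.end_s * fs)), recording.n_samples)
    csum = np.concatenate([[0], np.cumsum(bad)])

    windows: list[tuple[float, float]] = []
    i = i0
    while i + L <= i_end:
        n_bad = csum[i + L] - csum[i]
        if n_bad == 0:
            windows.append((i / fs, (i + L) / fs))
            i += L
        else:
            # jump past the last bad sample in the current window
            last_bad = i + L - 1 - int(np.argmax(bad[i : i + L][::-1]))
            i = last_bad + 1
    if len(windows) < n:
        raise ValueError(
            f"level {level!r}: only {len(windows)} clean epochs of {duration_s} s "
            f"available, {n} requested"
        )
    return EpochSet(level=level, windows=tuple(windows[:n]), duration_s=duration_s)


# ---------------------------------------------------------------------------
# Standard EEG container readers
# ---------------------------------------------------------------------------

def read_eeg(path, schedule: LevelSchedule | None = None, subject_id: str | None = None) -> SessionRecording:
    """Read a standard EEG container (FIF, EDF, BrainVision) into a recording.

    Voltages are converted to microvolts; channel positions come from the
    file's montage/digitization. The level schedule is not part of these
    formats and must be supplied (e.g. from the annotation CSV).
    """
    import mne

    path = str(path)
    if path.endswith(".fif"):
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    elif path.endswith(".edf"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.endswith(".vhdr"):
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unrecognized EEG container: {path}")
    data_uv = raw.get_data() * 1e6
    pos = np.array([ch["loc"][:3] for ch in raw.info["chs"]])
    if not np.all(np.isfinite(pos)):
        # no digitization in the file: distinct placeholder positions
        n = data_uv.shape[0]
        pos = np.column_stack([np.linspace(-1, 1, n), np.zeros(n), np.ones(n)])
    if schedule is None:
        from .containers import Level

        duration = data_uv.shape[1] / raw.info["sfreq"]
        schedule = LevelSchedule([Level("session", 0.0, duration, 0.0)])
    return SessionRecording(
        data=data_uv,
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        channel_positions=pos,
        schedule=schedule,
        subject_id=subject_id or "s0",
    )
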