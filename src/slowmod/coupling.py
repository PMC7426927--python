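"""Correlation-based cross-frequency coupling and the mean-vector estimator.

Coupling between the slow wave and a high band is the Pearson-style
correlation

    r = V'A / (sqrt(V'V) * sqrt(A'A))

where ``V`` is the band-passed slow voltage (0.1-4 Hz) and ``A`` the
instantaneous amplitude (analytic-signal magnitude) of the band-passed high
band. ``A`` is centered by subtracting its mean within each 30 s epoch; ``V``
is deliberately left uncentered — its expected value is zero, and centering
it would change the stacked estimator. Positive ``r`` means the high-band
amplitude is largest at the slow-wave peak (peakmax), negative at the trough
(troughmax).

Averaging over epochs, electrodes or source locations is done by stacking
the segments vertically into single ``V`` and ``A`` vectors before the one
correlation is taken: the covariance and the two norms are each pooled
first, then normalized. This is NOT the mean of per-segment correlations.

The mean vector ``mean(A * exp(i*phi_S))`` — with ``phi_S`` the slow band's
analytic phase — is kept as an independent validation of the correlation
metric: its preferred phase concentrates at 0 (peakmax) or pi (troughmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy.signal import hilbert

from .containers import SessionRecording
from .preprocess import BandFilterer, BandSpec, EpochSet, FilterBank

__all__ = [
    "CouplingRecord",
    "Modulogram",
    "LevelTopography",
    "MeanVector",
    "instantaneous_amplitude",
    "instantaneous_phase",
    "cfc_correlation",
    "stacked_correlation",
    "center_epochs",
    "stacked_correlation_nd",
    "compute_modulogram",
    "modulogram_from_envelopes",
    "level_topography",
    "mean_vector",
]


@dataclass(frozen=True)
class CouplingRecord:
    """One signed coupling value with its provenance.

    ``defined`` is False (and ``r`` NaN) when either stacked vector has zero
    norm: an undefined correlation is signalled explicitly rather than
    silently reported as "no coupling".
    """

    r: float
    n_samples: int
    band: BandSpec | None = None
    location: str | None = None
    scope: str | None = None
    subject: str | None = None
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


@dataclass
class Modulogram:
    """Coupling over (high band x time window) for one location set."""

    values: np.ndarray  # (n_bands, n_windows), NaN where a window is masked
    bands: tuple[BandSpec, ...]
    window_starts_s: np.ndarray
    window_s: float
    locations: tuple[str, ...]


@dataclass
class LevelTopography:
    """Per-location level-based coupling; ``present`` is False when the level
    of interest is absent for this subject (e.g. no Sedation period)."""

    values: dict[str, CouplingRecord]
    band: BandSpec
    level: str | None
    present: bool = True


@dataclass(frozen=True)
class MeanVector:
    """Complex mean of amplitude-weighted slow phase."""

    value: complex

    @property
    def magnitude(self) -> float:
        return abs(self.value)

    @property
    def preferred_phase(self) -> float:
        return float(np.angle(self.value))


# ---------------------------------------------------------------------------
# Primitive estimators
# ---------------------------------------------------------------------------

def instantaneous_amplitude(band_signal: np.ndarray) -> np.ndarray:
    """Envelope: magnitude of the analytic signal of a band-limited series.

    An all-zero input yields an all-zero envelope. Samples within half the
    slow-band filter span of an edge are distorted and should be excluded by
    the caller (see ``BandFilterer.edge_samples``).
    """
    x = np.asarray(band_signal, dtype=float)
    n = x.shape[-1]
    z = hilbert(x, N=sfft.next_fast_len(n), axis=-1)[..., :n]
    return np.abs(z)


def instantaneous_phase(band_signal: np.ndarray) -> np.ndarray:
    """Analytic phase of a band-limited series (for the mean vector)."""
    x = np.asarray(band_signal, dtype=float)
    n = x.shape[-1]
    z = hilbert(x, N=sfft.next_fast_len(n), axis=-1)[..., :n]
    return np.angle(z)


def cfc_correlation(slow: np.ndarray, env: np.ndarray, **meta) -> CouplingRecord:
    """Signed coupling between one slow segment and one envelope segment.

    The envelope is centered here (one segment = one epoch); the slow
    voltage is used as-is. Callers must not pre-center ``slow``.
    """
    V = np.asarray(slow, dtype=float).ravel()
    A = np.asarray(env, dtype=float).ravel()
    if V.shape != A.shape:
        raise ValueError(f"length mismatch: slow {V.shape} vs envelope {A.shape}")
    A = A - A.mean()
    vv = float(V @ V)
    aa = float(A @ A)
    if vv == 0.0 or aa == 0.0:
        return CouplingRecord(r=np.nan, n_samples=len(V), defined=False, **meta)
    r = float(V @ A) / np.sqrt(vv * aa)
    return CouplingRecord(r=float(np.clip(r, -1.0, 1.0)), n_samples=len(V), **meta)


def stacked_correlation(pairs, **meta) -> CouplingRecord:
    """One correlation from segments stacked vertically.

    ``pairs`` is a sequence of (slow, envelope) segments (one per epoch
    and/or location). Each envelope is centered within its own segment, the
    segments are concatenated, and a single correlation is computed — the
    pooled-covariance average, not the mean of per-segment correlations.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("stacked_correlation needs at least one (slow, envelope) pair")
    num = vv = aa = 0.0
    n = 0
    for slow, env in pairs:
        V = np.asarray(slow, dtype=float).ravel()
        A = np.asarray(env, dtype=float).ravel()
        if V.shape != A.shape:
            raise ValueError("slow/envelope length mismatch within a pair")
        A = A - A.mean()
        num += float(V @ A)
        vv += float(V @ V)
        aa += float(A @ A)
        n += len(V)
    if vv == 0.0 or aa == 0.0:
        return CouplingRecord(r=np.nan, n_samples=n, defined=False, **meta)
    return CouplingRecord(r=float(np.clip(num / np.sqrt(vv * aa), -1, 1)), n_samples=n, **meta)


def center_epochs(A: np.ndarray) -> np.ndarray:
    """Subtract the per-epoch mean (last axis = time within epoch)."""
    A = np.asarray(A)
    return A - A.mean(axis=-1, keepdims=True)


def stacked_correlation_nd(V: np.ndarray, A_centered: np.ndarray, stack_axes) -> np.ndarray:
    """Vectorized stacked correlation.

    ``V`` and ``A_centered`` share a shape; ``stack_axes`` are the axes
    stacked into the single correlation (e.g. (epoch, time) or
    (location, epoch, time)). Entries with zero pooled norm come out NaN.
    """
    V = np.asarray(V)
    A = np.asarray(A_centered)
    num = np.sum(V * A, axis=stack_axes, dtype=np.float64)
    vv = np.sum(V * V, axis=stack_axes, dtype=np.float64)
    aa = np.sum(A * A, axis=stack_axes, dtype=np.float64)
    denom = np.sqrt(vv * aa)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, np.nan)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Session- and level-scoped analyses
# ---------------------------------------------------------------------------

def modulogram_from_envelopes(
    slow: np.ndarray,
    envelopes: dict[BandSpec, np.ndarray],
    fs: float,
    window_s: float = 30.0,
    bad: np.ndarray | None = None,
    locations: tuple[str, ...] = ("loc0",),
) -> Modulogram:
    """Modulogram from precomputed band envelopes.

    ``slow`` and each envelope are (n_locations, n_samples); per window the
    locations are stacked into one correlation. Windows overlapping the bad
    mask are NaN.
    """
    slow = np.atleast_2d(slow)
    n = slow.shape[1]
    L = int(round(window_s * fs))
    n_win = n // L
    bands = tuple(envelopes)
    values = np.full((len(bands), n_win), np.nan)
    starts = np.arange(n_win) * L / fs
    win_bad = np.zeros(n_win, dtype=bool)
    if bad is not None:
        bad = np.asarray(bad, dtype=bool)
        win_bad = bad[: n_win * L].reshape(n_win, L).any(axis=1)
    Vw = slow[:, : n_win * L].reshape(slow.shape[0], n_win, L)
    for bi, band in enumerate(bands):
        env = np.atleast_2d(envelopes[band])
        Aw = center_epochs(env[:, : n_win * L].reshape(env.shape[0], n_win, L))
        r = stacked_correlation_nd(
            np.swapaxes(Vw, 0, 1), np.swapaxes(Aw, 0, 1), stack_axes=(-2, -1)
        )
        r[win_bad] = np.nan
        values[bi] = r
    return Modulogram(
        values=values,
        bands=bands,
        window_starts_s=starts,
        window_s=window_s,
        locations=tuple(locations),
    )


def compute_modulogram(
    recording: SessionRecording,
    bank: FilterBank,
    locations,
    window_s: float = 30.0,
) -> Modulogram:
    """Session-based modulogram for a set of locations (channel labels).

    Filters the recording into the slow band and every high band, computes
    envelopes, and stacks the location set within each window.
    """
    idx = [recording.channel_labels.index(loc) for loc in locations]
    filt = BandFilterer(recording.n_samples, recording.sample_rate_hz)
    data = recording.data[idx]
    slow = filt.filter(data, bank.slow_band)
    envs = {b: np.abs(filt.analytic(data, b)) for b in bank.high_bands}
    bad = None
    if recording.artifact_mask is not None:
        bad = recording.artifact_mask[idx].any(axis=0)
    return modulogram_from_envelopes(
        slow,
        envs,
        recording.sample_rate_hz,
        window_s=window_s,
        bad=bad,
        locations=tuple(locations),
    )


def level_topography(
    recording: SessionRecording,
    bank: FilterBank,
    level: str | None,
    band: BandSpec | None = None,
    epochs: EpochSet | None = None,
    n_epochs: int = 10,
    epoch_s: float = 30.0,
) -> LevelTopography:
    """Level-based coupling map: one value per channel from stacked epochs.

    The summary band (default 8-16 Hz) is filtered directly, not assembled
    from 2 Hz tiles. A missing level (e.g. absent Sedation) yields an empty
    map flagged ``present=False``.
    """
    from .preprocess import select_epochs

    band = band or bank.summary_band
    if level is None:
        return LevelTopography(values={}, band=band, level=None, present=False)
    if epochs is None:
        epochs = select_epochs(recording, level, n=n_epochs, duration_s=epoch_s)
    filt = BandFilterer(recording.n_samples, recording.sample_rate_hz)
    slow = filt.filter(recording.data, bank.slow_band)
    env = np.abs(filt.analytic(recording.data, band))
    slices = epochs.sample_slices(recording.sample_rate_hz)
    V = np.stack([slow[:, sl] for sl in slices], axis=1)  # (ch, epoch, time)
    A = center_epochs(np.stack([env[:, sl] for sl in slices], axis=1))
    r = stacked_correlation_nd(V, A, stack_axes=(-2, -1))
    n = V.shape[1] * V.shape[2]
    values = {
        lab: CouplingRecord(
            r=float(ri) if np.isfinite(ri) else np.nan,
            n_samples=n,
            band=band,
            location=lab,
            scope=level,
            subject=recording.subject_id,
            defined=bool(np.isfinite(ri)),
        )
        for lab, ri in zip(recording.channel_labels, r)
    }
    return LevelTopography(values=values, band=band, level=level)


def mean_vector(env: np.ndarray, slow_phase: np.ndarray) -> MeanVector:
    """Mean-vector phase-amplitude coupling estimate: mean(A * exp(i*phi))."""
    A = np.asarray(env, dtype=float).ravel()
    phi = np.asarray(slow_phase, dtype=float).ravel()
    if A.shape != phi.shape:
        raise ValueError(f"length mismatch: envelope {A.shape} vs phase {phi.shape}")
    return MeanVector(value=complex(np.mean(A * np.exp(1j * phi))))
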