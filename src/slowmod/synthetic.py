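"""Synthetic stepped-anesthesia EEG sessions with known coupling structure.

Every downstream stage of the analysis is validated against sessions whose
slow-wave phase-amplitude coupling is known exactly. A session emulates the
stepped-propofol study design: an ordered schedule of constant-dose levels,
a loss-of-consciousness (LOC) marker, and a spatial progression of coupling —
frontal alpha troughmax during sedation, posterior-only broadband peakmax at
the low unconscious dose, and global broadband peakmax at the high dose.

Each channel carries:

* a slow wave: a (optionally frequency-jittered and non-sinusoidal) ~1 Hz
  oscillation whose waveform shape is controlled by a monotone phase
  distortion ``cos(phi + skew*sin(phi))`` that keeps its energy below 4 Hz;
* modulated components per planned band: band-limited Gaussian noise (or a
  sinusoid for rhythmic/alpha entries) whose instantaneous envelope is
  ``base * (1 + depth * s_hat)`` with ``s_hat`` the channel's slow wave
  rescaled to [-1, 1] — ``depth > 0`` is peakmax, ``depth < 0`` troughmax;
* a 1/f-like broadband background and white sensor noise;
* optional large-amplitude step artifacts.

The generator is bit-deterministic under a fixed seed: every random draw
comes from a named substream of ``numpy.random.SeedSequence(seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .containers import Level, LevelSchedule, SessionRecording

__all__ = [
    "PlanEntry",
    "SyntheticConfig",
    "GroundTruth",
    "default_montage",
    "generate_slow_wave",
    "generate_modulated_component",
    "generate_session",
    "preset_config",
    "broadband_entries",
    "ground_truth_to_json",
]

# substream ids for SeedSequence spawn keys
_STREAM_SLOW = 0
_STREAM_COMPONENT = 1
_STREAM_BACKGROUND = 2
_STREAM_SENSOR = 3


@dataclass(frozen=True)
class PlanEntry:
    """One planned coupling: a band, a signed modulation depth, a carrier."""

    band: tuple[float, float]
    depth: float
    carrier: str = "noise"  # "noise" or "sinusoid"

    def __post_init__(self) -> None:
        if not -1.0 <= self.depth <= 1.0:
            raise ValueError(
                f"modulation depth {self.depth} outside [-1, 1]: the modulated "
                "envelope would go negative"
            )
        if self.carrier not in ("noise", "sinusoid"):
            raise ValueError(f"unknown carrier {self.carrier!r}")


def default_montage(n_channels: int) -> tuple[np.ndarray, list[str], dict[str, tuple[int, ...]]]:
    """Channel positions on the upper unit hemisphere plus region groups.

    Channels are laid out on a Fibonacci spiral over the upper hemisphere and
    sorted front (+y) to back (-y). Groups split the montage by the anterior-
    posterior coordinate: frontal (y > 0.25), posterior (y < -0.25), central
    (in between) — the sensor-level analogue of cortical lobes.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    k = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = (k + 0.5) / n_channels  # upper hemisphere only
    theta = 2 * np.pi * k / golden
    r = np.sqrt(1 - z**2)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    order = np.argsort(-pos[:, 1], kind="stable")
    pos = pos[order]
    labels = [f"CH{i:02d}" for i in range(n_channels)]
    groups = {
        "frontal": tuple(i for i in range(n_channels) if pos[i, 1] > 0.25),
        "central": tuple(i for i in range(n_channels) if -0.25 <= pos[i, 1] <= 0.25),
        "posterior": tuple(i for i in range(n_channels) if pos[i, 1] < -0.25),
    }
    return pos, labels, {g: idx for g, idx in groups.items() if idx}


@dataclass
class SyntheticConfig:
    """Full description of one synthetic session (one subject)."""

    level_schedule: list[tuple[str, float, float]]  # (label, duration_s, dose)
    n_channels: int = 32
    sample_rate_hz: float = 200.0
    channel_positions: np.ndarray | None = None
    channel_groups: dict[str, tuple[int, ...]] | None = None
    loc_time_s: float | None = None
    roc_time_s: float | None = None
    slow_freq_hz: float = 1.0
    slow_jitter: float = 0.1  # fractional frequency jitter
    slow_amplitude_uv: float | dict = 50.0  # scalar or {(group, level): uV}
    waveform_skew: float = 0.0
    alpha_freq_hz: float = 10.0
    coupling_plan: dict[tuple[str, str], list[PlanEntry]] = field(default_factory=dict)
    component_base_sd_uv: float = 2.0
    broadband_noise_sd_uv: float = 1.0
    sensor_noise_sd_uv: float = 0.5
    burst_suppression_levels: frozenset = frozenset()
    artifact_plan: list[tuple[int, float, float]] = field(default_factory=list)
    band_tiling: tuple[float, float, float] = (4.0, 50.0, 2.0)  # low, high, width
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.level_schedule:
            raise ValueError("level schedule is empty")
        if not 0 <= self.waveform_skew < 1:
            raise ValueError("waveform_skew must lie in [0, 1)")
        for (label, dur, _dose) in self.level_schedule:
            if dur <= 0:
                raise ValueError(f"level {label!r} has non-positive duration {dur}")
        known = {label for label, _, _ in self.level_schedule}
        for (group, level) in self.coupling_plan:
            if level not in known:
                raise ValueError(f"coupling plan references unknown level {level!r}")
        if self.channel_positions is None:
            pos, labels, groups = default_montage(self.n_channels)
            self.channel_positions = pos
            self.channel_labels = labels
            if self.channel_groups is None:
                self.channel_groups = groups
        else:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            self.channel_labels = [f"CH{i:02d}" for i in range(self.n_channels)]
            if self.channel_groups is None:
                self.channel_groups = {"all": tuple(range(self.n_channels))}
        for (group, _level) in self.coupling_plan:
            if group not in self.channel_groups:
                raise ValueError(f"coupling plan references unknown group {group!r}")

    # -- helpers ------------------------------------------------------------

    def schedule(self) -> LevelSchedule:
        levels, t = [], 0.0
        for label, dur, dose in self.level_schedule:
            levels.append(
                Level(label, t, t + dur, dose, burst_suppression=label in self.burst_suppression_levels)
            )
            t += dur
        return LevelSchedule(levels, loc_time_s=self.loc_time_s, roc_time_s=self.roc_time_s)

    def level_index(self, label: str) -> int:
        for k, (lab, _, _) in enumerate(self.level_schedule):
            if lab == label:
                return k
        raise KeyError(f"unknown level label: {label!r}")

    def amplitude(self, group: str, level: str) -> float:
        if isinstance(self.slow_amplitude_uv, dict):
            for key in ((group, level), (group, "*"), ("*", level), ("*", "*")):
                if key in self.slow_amplitude_uv:
                    return float(self.slow_amplitude_uv[key])
            return 0.0
        return float(self.slow_amplitude_uv)

    def group_of(self, channel: int) -> str:
        for g, idx in self.channel_groups.items():
            if channel in idx:
                return g
        return "ungrouped"

    def tiles(self) -> list[tuple[float, float]]:
        lo, hi, w = self.band_tiling
        n = int(round((hi - lo) / w))
        return [(lo + k * w, lo + (k + 1) * w) for k in range(n)]

    def _seed_seq(self, stream: int, *key: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(stream, *key))


@dataclass
class GroundTruth:
    """The generator's per-(channel, band, level) coupling plan, plus context.

    ``sign``/``depth`` return 0 for any triple not present in the plan.
    """

    coupling: dict[tuple[str, tuple[float, float], str], float]
    slow_trace: np.ndarray  # (n_channels, n_samples)
    channel_labels: list[str]
    loc_time_s: float | None
    roc_time_s: float | None
    burst_suppression_levels: frozenset

    def depth(self, channel: str, band: tuple[float, float], level: str) -> float:
        return self.coupling.get((channel, band, level), 0.0)

    def sign(self, channel: str, band: tuple[float, float], level: str) -> int:
        return int(np.sign(self.depth(channel, band, level)))


def ground_truth_to_json(gt: GroundTruth, path) -> None:
    records = [
        {"channel": ch, "band_low": b[0], "band_high": b[1], "level": lv, "depth": d}
        for (ch, b, lv), d in sorted(gt.coupling.items())
    ]
    payload = {
        "coupling": records,
        "loc_time_s": gt.loc_time_s,
        "roc_time_s": gt.roc_time_s,
        "burst_suppression_levels": sorted(gt.burst_suppression_levels),
        "channel_labels": gt.channel_labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Component generators
# ---------------------------------------------------------------------------

def _smooth_unit_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float = 0.2) -> np.ndarray:
    """Slow random trace in [-1, 1] (frequency content below ``cutoff_hz``)."""
    freqs = sfft.rfftfreq(n, 1 / fs)
    keep = (freqs > 0) & (freqs <= cutoff_hz)
    spec = np.zeros(len(freqs), dtype=complex)
    k = int(keep.sum())
    if k == 0:
        return np.zeros(n)
    spec[keep] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    u = sfft.irfft(spec, n)
    m = np.max(np.abs(u))
    return u / m if m > 0 else u


def generate_slow_wave(config: SyntheticConfig, channel: int, level: str) -> np.ndarray:
    """Slow-wave voltage for one channel over one level.

    A sinusoid at ``slow_freq_hz`` with fractional frequency jitter, warped
    by the monotone phase distortion ``cos(phi + skew*sin(phi))`` (skew=0 is
    a pure sinusoid), scaled by the (group, level) amplitude, with the level
    mean removed. Energy stays below 4 Hz for any skew < 1.
    """
    idx = config.level_index(level)  # raises KeyError naming the label
    _, dur, _ = config.level_schedule[idx]
    fs = config.sample_rate_hz
    n = int(round(dur * fs))
    amp = config.amplitude(config.group_of(channel), level)
    if amp == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(config._seed_seq(_STREAM_SLOW, channel, idx))
    phi0 = rng.uniform(0, 2 * np.pi)
    if config.slow_jitter > 0:
        u = _smooth_unit_noise(rng, n, fs)
        freq = config.slow_freq_hz * (1.0 + config.slow_jitter * u)
    else:
        freq = np.full(n, config.slow_freq_hz)
    phase = phi0 + 2 * np.pi * np.cumsum(freq) / fs
    wave = amp * np.cos(phase + config.waveform_skew * np.sin(phase))
    return wave - wave.mean()


def _band_noise_batch(rngs, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, one row per rng."""
    freqs = sfft.rfftfreq(n, 1 / fs)
    keep = (freqs >= band[0]) & (freqs < band[1])
    k = int(keep.sum())
    if k == 0:
        return np.zeros((len(rngs), n), dtype=np.float32)
    spec = np.zeros((len(rngs), len(freqs)), dtype=np.complex64)
    for row, rng in enumerate(rngs):
        z = rng.standard_normal(2 * k)
        spec[row, keep] = z[:k] + 1j * z[k:]
    x = sfft.irfft(spec, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_modulated_component(
    slow: np.ndarray,
    band: tuple[float, float],
    depth: float,
    base_sd: float,
    seed,
    fs: float,
    carrier: str = "noise",
    carrier_freq_hz: float | None = None,
) -> np.ndarray:
    """High-band component whose envelope follows the slow wave.

    The instantaneous envelope is ``base_sd * (1 + depth * s_hat)`` with
    ``s_hat`` the slow wave rescaled to [-1, 1]; the sign of ``depth``
    determines peakmax (+) versus troughmax (-) coupling. The carrier is
    band-limited Gaussian noise synthesized in the frequency domain, or a
    sinusoid at the band center (``carrier_freq_hz`` to override).
    """
    if not -1.0 <= depth <= 1.0:
        raise ValueError(f"|depth| must be <= 1, got {depth}")
    slow = np.asarray(slow, dtype=float)
    n = len(slow)
    m = np.max(np.abs(slow))
    s_hat = slow / m if m > 0 else np.zeros(n)
    envelope = 1.0 + depth * s_hat
    rng = np.random.default_rng(seed)
    if carrier == "sinusoid":
        f_c = carrier_freq_hz if carrier_freq_hz is not None else 0.5 * (band[0] + band[1])
        phi0 = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        x = np.sqrt(2.0) * np.cos(2 * np.pi * f_c * t + phi0)
    else:
        x = _band_noise_batch([rng], n, fs, band)[0].astype(float)
    return base_sd * envelope * x


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude background, flattened below 0.5 Hz, with total SD ``sd``."""
    freqs = sfft.rfftfreq(n, 1 / fs)
    shape = np.zeros(len(freqs), dtype=np.float32)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 0.5))
    z = rng.standard_normal(2 * len(freqs)).astype(np.float32)
    spec = (shape * (z[: len(freqs)] + 1j * z[len(freqs) :])).astype(np.complex64)
    x = sfft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def generate_session(config: SyntheticConfig) -> tuple[SessionRecording, GroundTruth]:
    """Assemble a full session: slow + modulated components + noise.

    Returns the recording (with level annotations, LOC/ROC markers,
    burst-suppression flags and the artifact mask) and the ground truth the
    generator used, expanded onto the 2 Hz analysis tiling.
    """
    if not config.level_schedule:
        raise ValueError("level schedule is empty")
    fs = config.sample_rate_hz
    schedule = config.schedule()
    n_total = int(round(schedule.end_s * fs))
    n_ch = config.n_channels
    data = np.zeros((n_ch, n_total))
    slow_trace = np.zeros((n_ch, n_total), dtype=np.float32)

    level_slices = {}
    for lv in schedule.levels:
        i0 = int(round(lv.start_s * fs))
        i1 = int(round(lv.end_s * fs))
        level_slices[lv.label] = slice(i0, i1)

    # slow wave, per channel and level
    slows: dict[tuple[int, str], np.ndarray] = {}
    for ch in range(n_ch):
        for lv in schedule.levels:
            s = generate_slow_wave(config, ch, lv.label)
            slows[(ch, lv.label)] = s
            sl = level_slices[lv.label]
            data[ch, sl] += s
            slow_trace[ch, sl] = s

    # planned modulated components
    coupling: dict[tuple[str, tuple[float, float], str], float] = {}
    tiles = config.tiles()
    for (group, level), entries in config.coupling_plan.items():
        sl = level_slices[level]
        lv_idx = config.level_index(level)
        chans = list(config.channel_groups[group])
        n_lvl = sl.stop - sl.start
        for e_idx, entry in enumerate(entries):
            if entry.carrier == "sinusoid":
                for ch in chans:
                    data[ch, sl] += generate_modulated_component(
                        slows[(ch, level)], entry.band, entry.depth,
                        config.component_base_sd_uv,
                        config._seed_seq(_STREAM_COMPONENT, ch, lv_idx, e_idx),
                        fs, carrier="sinusoid", carrier_freq_hz=config.alpha_freq_hz,
                    )
            else:
                rngs = [
                    np.random.default_rng(config._seed_seq(_STREAM_COMPONENT, ch, lv_idx, e_idx))
                    for ch in chans
                ]
                x = _band_noise_batch(rngs, n_lvl, fs, entry.band)
                for row, ch in enumerate(chans):
                    s = slows[(ch, level)]
                    m = np.max(np.abs(s))
                    s_hat = s / m if m > 0 else 0.0
                    data[ch, sl] += config.component_base_sd_uv * (1.0 + entry.depth * s_hat) * x[row]
            for ch in chans:
                lab = config.channel_labels[ch]
                for tile in tiles:
                    if min(tile[1], entry.band[1]) - max(tile[0], entry.band[0]) > 1e-9:
                        coupling[(lab, tile, level)] = entry.depth

    # background + sensor noise
    for ch in range(n_ch):
        if config.broadband_noise_sd_uv > 0:
            rng = np.random.default_rng(config._seed_seq(_STREAM_BACKGROUND, ch))
            data[ch] += _one_over_f_noise(rng, n_total, fs, config.broadband_noise_sd_uv)
        if config.sensor_noise_sd_uv > 0:
            rng = np.random.default_rng(config._seed_seq(_STREAM_SENSOR, ch))
            data[ch] += config.sensor_noise_sd_uv * rng.standard_normal(n_total)

    # artifacts: large-amplitude steps
    mask = np.zeros((n_ch, n_total), dtype=bool)
    for ch, t0, t1 in config.artifact_plan:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        data[ch, i0:i1] += 1000.0
        mask[ch, i0:i1] = True

    recording = SessionRecording(
        data=data,
        sample_rate_hz=fs,
        channel_labels=list(config.channel_labels),
        channel_positions=config.channel_positions,
        schedule=schedule,
        artifact_mask=mask,
    )
    gt = GroundTruth(
        coupling=coupling,
        slow_trace=slow_trace,
        channel_labels=list(config.channel_labels),
        loc_time_s=config.loc_time_s,
        roc_time_s=config.roc_time_s,
        burst_suppression_levels=config.burst_suppression_levels,
    )
    return recording, gt


# ---------------------------------------------------------------------------
# Named cohort presets
# ---------------------------------------------------------------------------

def broadband_entries(depth: float, tiling=(4.0, 50.0, 2.0), carrier: str = "noise") -> list[PlanEntry]:
    """One independent-noise plan entry per 2 Hz analysis tile."""
    lo, hi, w = tiling
    n = int(round((hi - lo) / w))
    return [PlanEntry((lo + k * w, lo + (k + 1) * w), depth, carrier) for k in range(n)]


def preset_config(
    name: str,
    seed: int,
    n_channels: int = 32,
    level_duration_s: float = 120.0,
    sample_rate_hz: float = 200.0,
) -> SyntheticConfig:
    """Named study-condition presets.

    ``paper-like``: frontal alpha troughmax during Sedation, posterior-only
    broadband peakmax (depth +0.6) at the Unconscious Low Dose, global
    broadband peakmax (depth +0.8) at the Unconscious High Dose.
    ``null``: identical structure with no coupling anywhere.
    ``broadband-only``: every region broadband peakmax (+0.7) at both
    unconscious doses; no rhythmic alpha component.

    Levels: Baseline (dose 0), L1 (Sedation), a short L2 transition level in
    which LOC occurs, L3 (Unconscious Low Dose), L4 (Unconscious High Dose).
    Short lead-in and tail segments keep the analysis levels clear of
    filter-edge distortion at the session boundaries. The default 2 min per
    level keeps a full cohort fast; pass the full 14 min (840 s) to match
    the emulated protocol's level length.
    """
    transition_s = 60.0
    schedule = [
        ("lead", 30.0, 0.0),
        ("Base", level_duration_s, 0.0),
        ("L1", level_duration_s, 1.0),
        ("L2", transition_s, 2.0),
        ("L3", level_duration_s, 3.0),
        ("L4", level_duration_s, 4.0),
        ("tail", 30.0, 3.5),
    ]
    loc = 30.0 + 2 * level_duration_s + transition_s / 2  # inside L2
    if name == "paper-like":
        plan: dict[tuple[str, str], list[PlanEntry]] = {
            ("frontal", "L1"): [PlanEntry((8.0, 12.0), -0.6, "sinusoid")],
            ("posterior", "L3"): broadband_entries(+0.6),
            ("frontal", "L4"): broadband_entries(+0.8),
            ("central", "L4"): broadband_entries(+0.8),
            ("posterior", "L4"): broadband_entries(+0.8),
        }
    elif name == "null":
        plan = {}
    elif name == "broadband-only":
        plan = {
            (g, lv): broadband_entries(+0.7)
            for g in ("frontal", "central", "posterior")
            for lv in ("L3", "L4")
        }
    else:
        raise ValueError(f"unknown preset {name!r}")
    # tiny montages may lack some anterior-posterior groups
    _, _, groups = default_montage(n_channels)
    plan = {(g, lv): e for (g, lv), e in plan.items() if g in groups}
    return SyntheticConfig(
        level_schedule=schedule,
        n_channels=n_channels,
        sample_rate_hz=sample_rate_hz,
        loc_time_s=loc,
        coupling_plan=plan,
        seed=seed,
    )
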