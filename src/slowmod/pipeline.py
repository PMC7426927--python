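"""End-to-end orchestration: simulate/load, preprocess, couple, decompose,
project, bootstrap, and write a reproducible set of result tables.

The pipeline mirrors the analysis sequence of the study design it emulates:

1. obtain sessions (synthetic cohort preset, or interchange containers);
2. artifact mask + bridged-channel drop + nearest-neighbor Laplacian;
3. zero-phase filter bank (slow 0.1-4 Hz, 2 Hz bands 4-50 Hz, 8-16 Hz
   summary band) and analytic envelopes;
4. level-based coupling (stacked 10 x 30 s epochs) per channel and band,
   session-based modulograms for named channel groups, region-stacked
   coupling, and mean-vector validation values for the summary band;
5. aggregate matrix -> non-centered PCA -> principal frequency modes;
6. projection of region-resolved patterns onto the modes and a percentile
   bootstrap over subjects for the first-mode scores.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` substreams, so a run is reproducible
bit-for-bit from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .containers import SessionRecording, load_session
from .coupling import Modulogram, center_epochs, stacked_correlation_nd
from .modes import (
    AggregateCouplingMatrix,
    ModeDecomposition,
    ModeProjection,
    assemble_aggregate,
    bootstrap_subject_ci,
    noncentered_pca,
    project_onto_modes,
)
from .preprocess import (
    LEVEL_NAMES,
    BandFilterer,
    FilterBank,
    build_neighbor_graph,
    compute_artifact_mask,
    define_levels,
    design_filter_bank,
    detect_bridged_channels,
    select_epochs,
)
from .synthetic import GroundTruth, generate_session, ground_truth_to_json, preset_config

logger = logging.getLogger("slowmod")

__all__ = [
    "RunConfig",
    "PipelineError",
    "SubjectResult",
    "CohortResult",
    "analyze_subject",
    "run_synthetic_cohort",
    "run_pipeline",
    "expected_region_signs",
    "infer_groups",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    preset: str = "paper-like"
    input_sessions: list[str] | None = None
    n_subjects: int = 6
    n_channels: int = 32
    level_duration_s: float = 120.0
    sample_rate_hz: float = 200.0
    low_stop_hz: float = 4.0
    high_stop_hz: float = 50.0
    band_width_hz: float = 2.0
    transition_hz: float = 1.0
    slow_low_hz: float = 0.1
    summary_band_hz: tuple[float, float] = (8.0, 16.0)
    n_epochs: int | None = None  # None: min(10, level_duration_s // epoch_s)
    epoch_s: float = 30.0
    apply_laplacian: bool = True
    n_modes_report: int = 3
    n_boot: int = 2000
    modulogram_groups: tuple[str, ...] = ("frontal", "posterior")
    make_plots: bool = False
    out_dir: str = "slowmod_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "summary_band_hz" in raw:
            raw["summary_band_hz"] = tuple(raw["summary_band_hz"])
        if "modulogram_groups" in raw:
            raw["modulogram_groups"] = tuple(raw["modulogram_groups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["summary_band_hz"] = list(self.summary_band_hz)
        d["modulogram_groups"] = list(self.modulogram_groups)
        return d

    def resolved_n_epochs(self) -> int:
        if self.n_epochs is not None:
            return self.n_epochs
        return min(10, int(self.level_duration_s // self.epoch_s))

    def filter_bank(self) -> FilterBank:
        return design_filter_bank(
            self.low_stop_hz,
            self.high_stop_hz,
            self.band_width_hz,
            self.transition_hz,
            slow_low=self.slow_low_hz,
            summary=self.summary_band_hz,
        )

    def config_hash(self) -> str:
        """Hash of the scientifically relevant configuration (paths and
        logging verbosity do not affect the computed results)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def infer_groups(positions: np.ndarray, labels: list[str]) -> dict[str, list[str]]:
    """Anterior-posterior channel groups from 3-D positions (y axis)."""
    groups: dict[str, list[str]] = {"frontal": [], "central": [], "posterior": []}
    for lab, p in zip(labels, np.asarray(positions)):
        if p[1] > 0.25:
            groups["frontal"].append(lab)
        elif p[1] < -0.25:
            groups["posterior"].append(lab)
        else:
            groups["central"].append(lab)
    return {g: ls for g, ls in groups.items() if ls}


@dataclass
class SubjectResult:
    subject_id: str
    level_map: dict[str, str | None]
    records: pd.DataFrame  # tidy: subject, level, location, band_low, band_high, r, n_samples
    region_records: pd.DataFrame
    topography: pd.DataFrame  # summary-band per-channel r per level
    mean_vectors: pd.DataFrame  # per (level, epoch, channel) magnitude & phase
    modulograms: dict[str, Modulogram]
    groups: dict[str, list[str]]
    dropped_channels: list[str]
    channel_positions: dict[str, tuple] = field(default_factory=dict)


def analyze_subject(
    recording: SessionRecording,
    bank: FilterBank,
    n_epochs: int = 10,
    epoch_s: float = 30.0,
    apply_laplacian: bool = True,
    groups: dict[str, list[str]] | None = None,
    modulogram_groups=("frontal", "posterior"),
) -> SubjectResult:
    """Full per-subject analysis.

    Two signal tracks are analyzed:

    * the sensor track — Laplacian-referenced channels — feeds the per-channel
      coupling records (the PCA aggregate), summary-band topographies,
      modulograms, and mean vectors;
    * the location track — the unreferenced channel signals standing in for
      pre-localized band-limited location series — feeds the region-stacked
      coupling used for mode projection, since a surface re-reference is a
      sensor-level construct.
    """
    fs = recording.sample_rate_hz

    # -- artifact mask, bridged channels, reference -------------------------
    mask = compute_artifact_mask(recording)
    if recording.artifact_mask is not None:
        mask |= recording.artifact_mask
    drop = detect_bridged_channels(recording.data[:, ::5])
    keep = [i for i in range(recording.n_channels) if i not in drop]
    labels = [recording.channel_labels[i] for i in keep]
    raw = np.ascontiguousarray(recording.data[keep], dtype=np.float32)
    positions = recording.channel_positions[keep]
    mask = mask[keep]
    if groups is None:
        groups = infer_groups(positions, labels)
    else:
        groups = {g: [l for l in ls if l in labels] for g, ls in groups.items()}

    # Laplacian as a channel-mixing matrix: it is linear, so it commutes with
    # filtering and the analytic transform; each band is filtered once on the
    # raw (location-track) signals and mixed into the sensor track.
    if apply_laplacian:
        graph = build_neighbor_graph(positions)
        W = np.eye(len(keep), dtype=np.float32)
        for i, nbrs in graph.items():
            W[i, sorted(nbrs)] -= 1.0 / len(nbrs)
    else:
        W = None

    def mix(z: np.ndarray) -> np.ndarray:
        return z if W is None else W @ z

    # -- filter bank ---------------------------------------------------------
    filt = BandFilterer(raw.shape[1], fs)
    z_slow_loc = filt.analytic(raw, bank.slow_band)
    z_slow = mix(z_slow_loc)
    slow = np.ascontiguousarray(z_slow.real)
    del z_slow
    # mean-vector phase from the unreferenced track: the Laplacian mixes
    # neighboring slow waves and would shift the apparent preferred phase
    phase = np.angle(z_slow_loc)
    slow_loc = np.ascontiguousarray(z_slow_loc.real) if apply_laplacian else slow
    del z_slow_loc
    edge = filt.edge_samples(bank.slow_band)
    bad_sess = mask.any(axis=0)
    bad_sess[:edge] = True  # analytic-signal / filter edge distortion
    bad_sess[len(bad_sess) - edge :] = True
    sess_mask = np.broadcast_to(bad_sess, (len(keep), len(bad_sess)))

    # -- levels and epochs ----------------------------------------------------
    level_map = define_levels(recording.schedule)
    epoch_slices: dict[str, list[slice]] = {}
    for name in LEVEL_NAMES:
        label = level_map[name]
        if label is None:
            continue
        es = select_epochs(recording, label, n=n_epochs, duration_s=epoch_s, mask=sess_mask)
        epoch_slices[name] = es.sample_slices(fs)

    def gather(x: np.ndarray, sls) -> np.ndarray:
        return np.stack([x[:, sl] for sl in sls], axis=1)  # (ch, epoch, time)

    V_by_level = {name: gather(slow, sls) for name, sls in epoch_slices.items()}
    Vloc_by_level = (
        {name: gather(slow_loc, sls) for name, sls in epoch_slices.items()}
        if apply_laplacian
        else V_by_level
    )

    group_idx = {g: [labels.index(l) for l in ls] for g, ls in groups.items()}
    rows, region_rows, mv_rows, topo_rows = [], [], [], []
    # modulogram scaffolding: 30 s windows over the whole session
    L_win = int(round(epoch_s * fs))
    n_win = raw.shape[1] // L_win
    win_bad = bad_sess[: n_win * L_win].reshape(n_win, L_win).any(axis=1)
    modulo_rows: dict[str, list[np.ndarray]] = {g: [] for g in modulogram_groups if g in groups}
    V_win = {
        g: np.swapaxes(
            slow[group_idx[g], : n_win * L_win].reshape(len(group_idx[g]), n_win, L_win), 0, 1
        )
        for g in modulo_rows
    }

    def couple_band(env, env_loc, lo, hi, is_tile) -> None:
        for name in epoch_slices:
            sls = epoch_slices[name]
            V = V_by_level[name]
            A = center_epochs(gather(env, sls))
            r = stacked_correlation_nd(V, A, stack_axes=(-2, -1))
            n = V.shape[1] * V.shape[2]
            if is_tile:
                for lab, ri in zip(labels, r):
                    rows.append((recording.subject_id, name, lab, lo, hi, float(ri), n))
            else:
                for lab, ri in zip(labels, r):
                    topo_rows.append((recording.subject_id, name, lab, float(ri), n))
            Vl = Vloc_by_level[name]
            Al = A if env_loc is env else center_epochs(gather(env_loc, sls))
            for g, idx in group_idx.items():
                rg = stacked_correlation_nd(Vl[idx], Al[idx], stack_axes=(0, 1, 2))
                region_rows.append(
                    (recording.subject_id, name, g, lo, hi, float(rg),
                     len(idx) * n, bool(is_tile))
                )

    for band in bank.high_bands:
        z = filt.analytic(raw, band)
        env_loc = np.abs(z)
        env = np.abs(mix(z)) if apply_laplacian else env_loc
        del z
        couple_band(env, env_loc, band.low_hz, band.high_hz, is_tile=True)
        for g in modulo_rows:
            idx = group_idx[g]
            A_win = center_epochs(
                np.swapaxes(env[idx, : n_win * L_win].reshape(len(idx), n_win, L_win), 0, 1)
            )
            r = stacked_correlation_nd(V_win[g], A_win, stack_axes=(-2, -1))
            r[win_bad] = np.nan
            modulo_rows[g].append(r)

    # summary band: filtered directly, never assembled from tiles
    z = filt.analytic(raw, bank.summary_band)
    env_sum_loc = np.abs(z)
    env_sum = np.abs(mix(z)) if apply_laplacian else env_sum_loc
    del z
    couple_band(env_sum, env_sum_loc, bank.summary_band.low_hz, bank.summary_band.high_hz, is_tile=False)

    # mean-vector validation on the summary band (location track)
    for name, sls in epoch_slices.items():
        A_ep = gather(env_sum_loc, sls)
        P_ep = gather(phase, sls)
        mv = (A_ep * np.exp(1j * P_ep)).mean(axis=-1)  # (ch, epoch)
        for ep in range(mv.shape[1]):
            for ci, lab in enumerate(labels):
                mv_rows.append(
                    (recording.subject_id, name, ep, lab,
                     float(np.abs(mv[ci, ep])), float(np.angle(mv[ci, ep])))
                )

    modulograms = {
        g: Modulogram(
            values=np.vstack(rows_g),
            bands=tuple(bank.high_bands),
            window_starts_s=np.arange(n_win) * epoch_s,
            window_s=epoch_s,
            locations=tuple(groups[g]),
        )
        for g, rows_g in modulo_rows.items()
    }

    return SubjectResult(
        subject_id=recording.subject_id,
        level_map=level_map,
        records=pd.DataFrame(
            rows, columns=["subject", "level", "location", "band_low", "band_high", "r", "n_samples"]
        ),
        region_records=pd.DataFrame(
            region_rows,
            columns=["subject", "level", "location", "band_low", "band_high", "r", "n_samples", "is_tile"],
        ),
        topography=pd.DataFrame(
            topo_rows, columns=["subject", "level", "location", "r", "n_samples"]
        ),
        mean_vectors=pd.DataFrame(
            mv_rows, columns=["subject", "level", "epoch", "location", "magnitude", "phase"]
        ),
        modulograms=modulograms,
        groups=groups,
        dropped_channels=[recording.channel_labels[i] for i in drop],
        channel_positions={lab: tuple(p) for lab, p in zip(labels, positions)},
    )


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    ground_truths: list[GroundTruth]
    records: pd.DataFrame
    region_records: pd.DataFrame
    aggregate: AggregateCouplingMatrix
    decomposition: ModeDecomposition
    region_aggregate: AggregateCouplingMatrix
    projection: ModeProjection
    cis: pd.DataFrame
    config: RunConfig


def _subject_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(k,)).generate_state(1)[0] % 2**31)


def run_synthetic_cohort(config: RunConfig, recordings=None, ground_truths=None) -> CohortResult:
    """Generate (or accept) a cohort and run the complete analysis in memory."""
    bank = config.filter_bank()
    subjects: list[SubjectResult] = []
    gts: list[GroundTruth] = []
    if recordings is None:
        recordings = []
        for k in range(config.n_subjects):
            scfg = preset_config(
                config.preset,
                _subject_seed(config.seed, k),
                n_channels=config.n_channels,
                level_duration_s=config.level_duration_s,
                sample_rate_hz=config.sample_rate_hz,
            )
            rec, gt = generate_session(scfg)
            rec.subject_id = f"S{k:02d}"
            recordings.append(rec)
            gts.append(gt)
    elif ground_truths is not None:
        gts = list(ground_truths)

    for rec in recordings:
        logger.info("analyzing subject %s", rec.subject_id)
        try:
            subjects.append(
                analyze_subject(
                    rec,
                    bank,
                    n_epochs=config.resolved_n_epochs(),
                    epoch_s=config.epoch_s,
                    apply_laplacian=config.apply_laplacian,
                    modulogram_groups=config.modulogram_groups,
                )
            )
        except Exception as e:  # surface the stage and subject
            raise PipelineError("analyze_subject", f"subject {rec.subject_id}: {e}") from e

    records = pd.concat([s.records for s in subjects], ignore_index=True)
    region_tiles = pd.concat(
        [s.region_records[s.region_records["is_tile"]] for s in subjects], ignore_index=True
    )

    levels_present = [n for n in LEVEL_NAMES if any(n in s.records["level"].values for s in subjects)]
    try:
        aggregate = assemble_aggregate(records, levels_present, scope="sensor")
        decomp = noncentered_pca(aggregate)
    except Exception as e:
        raise PipelineError("modes", str(e)) from e

    try:
        region_agg = assemble_aggregate(
            region_tiles, levels_present, bands=aggregate.bands, scope="region"
        )
        projection = project_onto_modes(decomp, region_agg)
    except Exception as e:
        raise PipelineError("projection", str(e)) from e

    first = projection.first_mode()
    ci_rows = []
    for (level, region), grp in first.groupby(["level", "location"], sort=True):
        vals = grp.sort_values("subject")["projection"].to_numpy()
        if len(vals) >= 2:
            ci = bootstrap_subject_ci(vals, n_boot=config.n_boot, seed=config.seed)
            ci_rows.append(
                (level, region, ci.mean, ci.lower, ci.upper, len(vals), ci.n_boot)
            )
    cis = pd.DataFrame(
        ci_rows, columns=["level", "region", "mean", "lower", "upper", "n_subjects", "n_boot"]
    )
    return CohortResult(
        subjects=subjects,
        ground_truths=gts,
        records=records,
        region_records=pd.concat([s.region_records for s in subjects], ignore_index=True),
        aggregate=aggregate,
        decomposition=decomp,
        region_aggregate=region_agg,
        projection=projection,
        cis=cis,
        config=config,
    )


def expected_region_signs(
    gt: GroundTruth,
    groups: dict[str, list[str]],
    level_map: dict[str, str | None],
    band: tuple[float, float] = (8.0, 16.0),
) -> dict[tuple[str, str], int]:
    """Planned coupling sign per (region, level-of-interest) within a band."""
    out = {}
    for name, label in level_map.items():
        if label is None:
            continue
        for region, chans in groups.items():
            signs = set()
            for (ch, tile, lv), depth in gt.coupling.items():
                if lv != label or ch not in chans:
                    continue
                if min(tile[1], band[1]) - max(tile[0], band[0]) > 1e-9:
                    signs.add(int(np.sign(depth)))
            signs.discard(0)
            out[(region, name)] = signs.pop() if len(signs) == 1 else 0
    return out


# ---------------------------------------------------------------------------
# Disk-writing entry point
# ---------------------------------------------------------------------------

def _write_modulograms(path, subjects: list[SubjectResult]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for s in subjects:
            for g, m in s.modulograms.items():
                grp = f.create_group(f"{s.subject_id}/{g}")
                grp.create_dataset("values", data=m.values)
                grp.create_dataset("window_starts_s", data=m.window_starts_s)
                grp.attrs["window_s"] = m.window_s
                grp.attrs["bands"] = [(b.low_hz, b.high_hz) for b in m.bands]
                grp.attrs["locations"] = list(m.locations)


def _plot_outputs(out: Path, result: CohortResult) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    s0 = result.subjects[0]
    for g, m in s0.modulograms.items():
        fig, ax = plt.subplots(figsize=(8, 4))
        extent = [m.window_starts_s[0], m.window_starts_s[-1] + m.window_s,
                  m.bands[0].low_hz, m.bands[-1].high_hz]
        ax.imshow(m.values, aspect="auto", origin="lower", extent=extent,
                  cmap="RdBu_r", vmin=-0.8, vmax=0.8)
        ax.set(xlabel="time (s)", ylabel="amplitude band (Hz)",
               title=f"{s0.subject_id} {g}: slow-wave modulogram")
        p = out / f"modulogram_{s0.subject_id}_{g}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        made.append(str(p))
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(result.decomposition.bands))
    for k in range(min(3, result.decomposition.n_modes)):
        ax.plot(x, result.decomposition.modes[:, k],
                label=f"mode {k + 1} ({result.decomposition.percent_energy[k]:.0f}%)")
    ax.set(xlabel="band index", ylabel="mode weight", title="principal frequency modes")
    ax.legend()
    p = out / "modes.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    made.append(str(p))

    # scalp topography of summary-band coupling, subject 0 (top-down view)
    topo = s0.topography
    levels = [lv for lv in ("Baseline", "Sedation", "UncLow", "UncHigh")
              if lv in set(topo.level)]
    fig, axes = plt.subplots(1, len(levels), figsize=(3 * len(levels), 3.2))
    axes = np.atleast_1d(axes)
    for ax, lv in zip(axes, levels):
        sub = topo[topo.level == lv].set_index("location")
        labs = [l for l in sub.index if l in s0.channel_positions]
        x = [s0.channel_positions[l][0] for l in labs]
        y = [s0.channel_positions[l][1] for l in labs]
        sc = ax.scatter(
            x, y, c=sub.loc[labs, "r"], cmap="RdBu_r", vmin=-0.8, vmax=0.8, s=80,
        )
        ax.set_title(lv)
        ax.set_aspect("equal")
        ax.set_axis_off()
    fig.colorbar(sc, ax=axes, shrink=0.8, label="r (8-16 Hz)")
    p = out / "topography.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    made.append(str(p))
    return made


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write result tables + manifest to disk."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"slowmod": _pkg_version, "numpy": np.__version__},
        "status": "incomplete",
        "outputs": [],
    }
    manifest_path = out / "manifest.json"

    def _save_manifest():
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    _save_manifest()
    try:
        recordings = gts = None
        if config.input_sessions:
            try:
                recordings = [load_session(p) for p in config.input_sessions]
            except Exception as e:
                raise PipelineError("load", str(e)) from e
        result = run_synthetic_cohort(config, recordings=recordings, ground_truths=gts)

        float_fmt = "%.10g"
        tables = {
            "coupling_levels.csv": result.records,
            "coupling_regions.csv": result.region_records,
            "topography.csv": pd.concat([s.topography for s in result.subjects], ignore_index=True),
            "mean_vectors.csv": pd.concat([s.mean_vectors for s in result.subjects], ignore_index=True),
            "projections.csv": result.projection.first_mode(),
            "bootstrap_cis.csv": result.cis,
        }
        agg = result.aggregate
        tables["aggregate_matrix.csv"] = pd.DataFrame(
            agg.values,
            index=[f"{b[0]:g}-{b[1]:g}" for b in agg.bands],
            columns=[f"{s}|{lv}|{loc}" for s, lv, loc in agg.columns],
        ).reset_index(names="band")
        d = result.decomposition
        k = min(config.n_modes_report, d.n_modes)
        tables["modes.csv"] = pd.DataFrame(
            d.modes[:, :k], columns=[f"mode{j + 1}" for j in range(k)]
        ).assign(band_low=[b[0] for b in d.bands], band_high=[b[1] for b in d.bands])
        tables["percent_energy.csv"] = pd.DataFrame(
            {"mode": np.arange(1, d.n_modes + 1), "percent_energy": d.percent_energy}
        )
        for fname, df in tables.items():
            p = out / fname
            df.to_csv(p, index=False, float_format=float_fmt)
            manifest["outputs"].append(fname)

        _write_modulograms(out / "modulograms.h5", result.subjects)
        manifest["outputs"].append("modulograms.h5")
        for k_, gt in enumerate(result.ground_truths):
            p = out / f"ground_truth_S{k_:02d}.json"
            ground_truth_to_json(gt, p)
            manifest["outputs"].append(p.name)
        if config.make_plots:
            manifest["outputs"] += [Path(p).name for p in _plot_outputs(out, result)]

        manifest["level_maps"] = {
            s.subject_id: s.level_map for s in result.subjects
        }
        manifest["status"] = "complete"
        _save_manifest()
        return manifest
    except Exception:
        manifest["status"] = "incomplete"
        _save_manifest()
        raise
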