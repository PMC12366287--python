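"""End-to-end pipeline: images (real or synthetic) → traces, QC, statistics.

Per position: build the droplet mask from frame 0 of the 667 nm probe
channel (droplets are immobilized in wells, so the mask is reused across
frames by default), index the wells onto the grid, track labeled cells in
the GREEN/UV channels, assign tracks to droplets by the central-area rule,
classify occupancy with cross-channel reconciliation, convert per-droplet
probe intensities to pH traces and raw ΔpH, and finally audit the calls
with the ΔpH QC windows and compute group statistics.

Every output table carries (position, row, col) keys so the stage outputs
join.  Re-running with the same config and seed reproduces the outputs
bit-for-bit for synthetic inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dropletmap, phquant, qcstats, synthgen, tracker
from .config import LABEL_CHANNELS, RunConfig
from .fileio import load_position_stacks, sort_images

__all__ = [
    "track_position",
    "map_position",
    "quantify_position",
    "group_statistics",
    "run_pipeline",
]

log = logging.getLogger("scoph")


def track_position(stacks: dict, params) -> pd.DataFrame:
    """Track cells in both label channels of one position.

    Label intensities are additionally reported bleaching-corrected
    (divided by the channel's frame-wide median intensity trend).
    """
    frames = []
    for channel in LABEL_CHANNELS:
        if channel not in stacks:
            continue
        tracks = tracker.track_stack(stacks[channel], params, channel=channel)
        df = tracker.tracks_to_dataframe(tracks)
        df["intensity_corrected"] = _debleach(df)
        frames.append(df)
    if not frames:
        df = tracker.tracks_to_dataframe([])
        df["intensity_corrected"] = pd.Series(dtype=float)
        return df
    return pd.concat(frames, ignore_index=True)


def _debleach(df: pd.DataFrame) -> pd.Series:
    if len(df) == 0:
        return pd.Series(dtype=float)
    medians = df.groupby("frame")["intensity"].median()
    if len(medians) < 3 or not (medians > 0).sum() >= 3:
        return df["intensity"].astype(float)
    trend = phquant.bleach_trend(medians.to_numpy(), medians.index.to_numpy(dtype=float))
    per_frame = pd.Series(trend, index=medians.index)
    return df["intensity"] / df["frame"].map(per_frame)


def map_position(
    stacks: dict,
    tracks: pd.DataFrame,
    config: RunConfig,
    position: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mask, index and classify the droplets of one position."""
    acq = config.acquisition
    mask = dropletmap.build_droplet_mask(stacks["CY5_667"][0], acq.droplet_diameter_px)
    wells = dropletmap.index_wells(mask, acq.grid_rows, acq.grid_cols, position=position)
    wells, diagnostics = dropletmap.assign_cells(
        tracks,
        wells,
        central_fraction=0.60,
        min_track_length=config.tracker.min_track_length,
    )
    wells = dropletmap.classify_wells(wells)
    log.info(
        "position %d: %d droplets (%s), diagnostics %s",
        position,
        len(wells),
        wells["occ_class"].value_counts().to_dict(),
        diagnostics,
    )
    return wells, mask


def quantify_position(
    stacks: dict,
    wells: pd.DataFrame,
    mask: np.ndarray,
    config: RunConfig,
    position: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-droplet pH traces and summary (ΔpH) for one position."""
    acq = config.acquisition
    calib = config.calibration
    times = acq.times_min
    labels = wells["label"].to_numpy()
    cy3, cy5 = stacks["CY3_600"], stacks["CY5_667"]
    n_frames = cy3.shape[0]
    f600 = np.empty((len(labels), n_frames))
    f667 = np.empty((len(labels), n_frames))
    for f in range(n_frames):
        f600[:, f] = phquant.droplet_intensities(cy3[f], mask, labels)
        f667[:, f] = phquant.droplet_intensities(cy5[f], mask, labels)
    r = phquant.ratio(f600, f667)
    ph = phquant.ph_from_ratio(r, calib)

    trace_rows = []
    summary_rows = []
    for i, (_, well) in enumerate(wells.iterrows()):
        norm, _anchor = phquant.normalize_trace(ph[i])
        dph = phquant.delta_ph(ph[i])
        for f in range(n_frames):
            trace_rows.append(
                {
                    "position": position,
                    "row": well["row"],
                    "col": well["col"],
                    "frame": f,
                    "time_min": float(times[f]) if f < len(times) else float("nan"),
                    "F600": f600[i, f],
                    "F667": f667[i, f],
                    "R": r[i, f],
                    "pH": ph[i, f],
                    "pH_norm": norm[f],
                }
            )
        summary_rows.append(
            {
                "position": position,
                "row": well["row"],
                "col": well["col"],
                "x": well["x"],
                "y": well["y"],
                "radius": well["radius"],
                "n_green": well["n_green"],
                "n_uv": well["n_uv"],
                "occ_class": well["occ_class"],
                "emulsion": well["emulsion"],
                "mixed": well["mixed"],
                "border": well["border"],
                "delta_ph": dph,
                "out_of_range": bool(np.any(~phquant.in_linear_range(ph[i][np.isfinite(ph[i])], calib))),
            }
        )
    return pd.DataFrame(trace_rows), pd.DataFrame(summary_rows)


def group_statistics(amended: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-tests between kept droplet groups (class × emulsion)."""
    kept = amended[(amended["qc_action"] == qcstats.KEPT) & (~amended["border"])]

    def _values(occ_class, emulsion=None):
        sel = kept[kept["qc_class"] == occ_class]
        if emulsion is not None:
            sel = sel[sel["emulsion"] == emulsion]
        return sel["delta_ph"].to_numpy(dtype=float)

    pairs = [
        ("HG_single", _values("SINGLE", "HG"), "UT_single", _values("SINGLE", "UT")),
        ("HG_single", _values("SINGLE", "HG"), "HG_multi", _values("MULTI", "HG")),
        ("HG_single", _values("SINGLE", "HG"), "empty", _values("EMPTY")),
        ("UT_single", _values("SINGLE", "UT"), "UT_multi", _values("MULTI", "UT")),
        ("UT_single", _values("SINGLE", "UT"), "empty", _values("EMPTY")),
    ]
    rows = []
    for name_a, a, name_b, b in pairs:
        if len(a) < 2 or len(b) < 2:
            continue
        t, p, symbol = qcstats.compare_groups(a, b)
        rows.append(
            {
                "group_a": name_a,
                "group_b": name_b,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "sd_a": a.std(ddof=1),
                "sd_b": b.std(ddof=1),
                "t": t,
                "p": p,
                "symbol": symbol,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
            "sd_a", "sd_b", "t", "p", "symbol",
        ],
    )


def run_pipeline(config: RunConfig, truth: bool = False):
    """Run every stage and write all artifacts to ``config.output_dir``.

    With ``config.synthesize`` the input stacks are generated from
    ``config.synth``; otherwise they are read from ``config.input_dir``.
    Returns a dict with the main tables (droplets, traces, summary,
    qc_report, group_stats) plus ground truth when synthesizing.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = config.acquisition

    truth_droplets = None
    if config.synthesize:
        if config.synth is None:
            raise ValueError("synthesize=True requires synth parameters")
        seeds = np.random.SeedSequence(config.synth.seed).spawn(acq.n_positions)

        def _stacks(p):
            rng = np.random.default_rng(seeds[p])
            stacks, droplets, cells = synthgen.render_position(
                p, config.synth, acq, config.calibration, rng
            )
            if config.write_images:
                import tifffile

                img_dir = out / "images"
                img_dir.mkdir(exist_ok=True)
                for channel, stack in stacks.items():
                    tifffile.imwrite(img_dir / f"pos{p:03d}_{channel}.tif", stack)
            return stacks, droplets

        positions = list(range(acq.n_positions))
        truth_parts = []
    else:
        if config.input_dir is None:
            raise ValueError("either synthesize=True or input_dir is required")
        manifest, unmatched = sort_images(config.input_dir)
        if unmatched:
            log.warning("unmatched files: %s", unmatched)
        positions = sorted(manifest["position"].unique())

        def _stacks(p):
            return load_position_stacks(manifest, p), None

    all_tracks, all_wells, all_traces, all_summaries = [], [], [], []
    for p in positions:
        stage = "input"
        try:
            stacks, pos_truth = _stacks(p)
            if config.synthesize:
                truth_parts.append(pos_truth)
            stage = "tracker"
            tracks = track_position(stacks, config.tracker)
            stage = "dropletmap"
            wells, mask = map_position(stacks, tracks, config, p)
            stage = "phquant"
            traces, summary = quantify_position(stacks, wells, mask, config, p)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed at position {p}: {exc}") from exc
        tracks = tracks.assign(position=p)
        all_tracks.append(tracks)
        all_wells.append(wells.assign(position=p))
        all_traces.append(traces)
        all_summaries.append(summary)

    tracks_df = pd.concat(all_tracks, ignore_index=True)
    wells_df = pd.concat(all_wells, ignore_index=True)
    traces_df = pd.concat(all_traces, ignore_index=True)
    summary_df = pd.concat(all_summaries, ignore_index=True)

    report, amended = qcstats.apply_qc(summary_df, config.qc)
    rates_df = qcstats.rates(amended)
    stats_df = group_statistics(amended)

    tracks_df.to_csv(out / "tracks.csv", index=False)
    wells_df.to_csv(out / "droplets.csv", index=False)
    traces_df.to_csv(out / "ph_traces.csv", index=False)
    amended.to_csv(out / "droplet_summary.csv", index=False)
    stats_df.to_csv(out / "group_stats.csv", index=False)
    qc_payload = {
        "n_input": report.n_input,
        "counts": report.counts,
        "error_rates": report.error_rates,
        "rates": rates_df.to_dict(orient="records"),
    }
    (out / "qc_report.json").write_text(json.dumps(qc_payload, indent=2, sort_keys=True))
    provenance = {
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    result = {
        "tracks": tracks_df,
        "droplets": wells_df,
        "traces": traces_df,
        "summary": amended,
        "qc_report": report,
        "rates": rates_df,
        "group_stats": stats_df,
    }
    if config.synthesize:
        truth_droplets = pd.concat(truth_parts, ignore_index=True)
        truth_droplets.to_csv(out / "truth_droplets.csv", index=False)
        result["truth"] = truth_droplets
    return result


def _versions() -> dict:
    import scipy
    import skimage

    return {
        "scoph": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }
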