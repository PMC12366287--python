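"""Ground-truthed synthetic microwell-array image stacks.

Emulates the raw data of a droplet microwell acidification experiment:
a regular grid of probe-loaded droplets imaged in four channels over 3 h.
Cell occupancy is Poisson(λ); each droplet belongs to the hyperglycolytic
(HG, green-labeled) or untreated (UT, violet-labeled) emulsion; per-cell
acidification rates are lognormal; the droplet's pH trajectory declines
linearly to the summed 3-h drop plus an empty-droplet drift.  The probe
channels render droplets as uniform disks whose intensities follow the
forward ratiometric model at the simulated pH; label channels render the
cells as Gaussian spots undergoing confined Brownian motion, bleaching
exponentially.  Everything is reproducible bit-for-bit from the seed, and
the ground truth (per-droplet occupancy, rates, pH endpoints; per-cell
coordinates) is returned and written alongside the images.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import phquant
from .config import (
    CHANNEL_EMULSION,
    LABEL_CHANNELS,
    AcquisitionConfig,
    SynthParams,
)
from .phquant import CalibrationModel

__all__ = [
    "GroundTruth",
    "sample_occupancy",
    "sample_emulsions",
    "per_cell_drop_mean",
    "sample_cell_rates",
    "sample_delta_ph",
    "simulate_ph_trajectory",
    "render_position",
    "render_dataset",
]

EMULSION_LABEL_CHANNEL = {v: k for k, v in CHANNEL_EMULSION.items()}  # HG->GREEN, UT->UV
_MAX_UINT16 = 65535


@dataclass
class GroundTruth:
    """Truth tables of a rendered dataset.

    ``droplets`` has one row per rendered droplet (well id, emulsion, true
    cell count, total 3-h drop, pH endpoints); ``cells`` is long-format
    per-cell per-frame coordinates and the per-cell 3-h drop.
    """

    droplets: pd.DataFrame
    cells: pd.DataFrame


def sample_occupancy(lambda_cells: float, n_droplets: int, seed) -> np.ndarray:
    """Independent Poisson(λ) cell counts for ``n_droplets`` droplets."""
    if lambda_cells < 0:
        raise ValueError("lambda_cells must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lambda_cells, size=n_droplets)


def sample_emulsions(n_droplets: int, frac_hg: float, rng: np.random.Generator) -> np.ndarray:
    """Label each droplet HG with probability ``frac_hg`` (1:1 mix default)."""
    return np.where(rng.random(n_droplets) < frac_hg, "HG", "UT")


def per_cell_drop_mean(params: SynthParams, emulsion: str, n_cells: int) -> float:
    """Mean per-cell 3-h pH drop in a droplet with ``n_cells`` cells.

    A single cell contributes the single-cell mean minus the empty drift;
    in crowded droplets the per-cell contribution shrinks by
    ``crowding**(n_cells - 1)`` (shared-substrate saturation), so 2-cell
    droplets average less than twice the single-cell drop.
    """
    if emulsion == "HG":
        single = params.dph_mean_hg_single
    elif emulsion == "UT":
        single = params.dph_mean_ut_single
    else:
        raise ValueError(f"unknown emulsion {emulsion!r}")
    base = max(single - params.dph_empty, 0.0)
    return base * params.crowding ** max(n_cells - 1, 0)


def sample_cell_rates(
    n_cells: int, emulsion: str, params: SynthParams, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal per-cell 3-h drops with mean from :func:`per_cell_drop_mean`."""
    if n_cells == 0:
        return np.zeros(0)
    mean = per_cell_drop_mean(params, emulsion, n_cells)
    if mean <= 0 or params.cell_cv == 0:
        return np.full(n_cells, mean)
    sigma2 = np.log1p(params.cell_cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_cells)


def sample_delta_ph(
    n_droplets: int,
    emulsion: str,
    cell_count: int,
    params: SynthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw total 3-h ΔpH values for droplets of fixed occupancy and emulsion."""
    out = np.full(n_droplets, params.dph_empty)
    for i in range(n_droplets):
        out[i] += sample_cell_rates(cell_count, emulsion, params, rng).sum()
    return out


def simulate_ph_trajectory(
    cell_count: int,
    emulsion: str,
    per_cell_rates,
    times,
    dph_empty: float = 0.021,
    initial_ph: float = 6.4,
    calibration: CalibrationModel | None = None,
) -> np.ndarray:
    """pH time series of one droplet: linear decline to the summed 3-h drop.

    The total drop over the observation window is exactly
    ``sum(per_cell_rates) + dph_empty`` (additive by construction), so two
    identical cells drop twice as much as one, plus drift.  Trajectories
    leaving the probe's linear range are flagged with a warning, never
    clipped.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    per_cell_rates = np.asarray(per_cell_rates, dtype=float)
    if len(per_cell_rates) != cell_count:
        raise ValueError("per_cell_rates must have one entry per cell")
    calib = calibration or CalibrationModel()
    if not phquant.in_linear_range(initial_ph, calib):
        raise ValueError("initial pH must lie inside the probe's linear range")
    total = float(per_cell_rates.sum()) + dph_empty
    span = times[-1] if times[-1] > 0 else 1.0
    ph = initial_ph - total * times / span
    if not np.all(phquant.in_linear_range(ph, calib)):
        warnings.warn("pH trajectory leaves the probe's linear range", stacklevel=2)
    return ph


def _spot_footprint_radius(params: SynthParams) -> float:
    return 4.0 * params.spot_sigma_px


def _simulate_cell_path(
    center: tuple[float, float],
    radius_px: float,
    n_frames: int,
    params: SynthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Confined Brownian path: reflection at ``confinement × droplet radius``."""
    rmax = params.confinement * radius_px
    r0 = rmax * np.sqrt(rng.random())
    theta = rng.random() * 2 * np.pi
    pos = np.array([r0 * np.cos(theta), r0 * np.sin(theta)])
    path = np.empty((n_frames, 2))
    path[0] = pos
    for f in range(1, n_frames):
        pos = pos + rng.normal(0.0, params.step_sd_px, size=2)
        r = np.hypot(*pos)
        if r > rmax:
            r_ref = 2 * rmax - r
            if r_ref < 0:
                r_ref = rmax
            pos = pos * (r_ref / r)
        path[f] = pos
    return path + np.asarray(center)


def render_position(
    position: int,
    params: SynthParams,
    acq: AcquisitionConfig,
    calibration: CalibrationModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Render one imaging window: four (T, H, W) uint16 stacks plus truth tables."""
    calib = calibration or CalibrationModel()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    radius_px = acq.droplet_radius_px
    if _spot_footprint_radius(params) >= radius_px:
        raise ValueError("cell spot footprint must be smaller than the droplet radius")

    h, w = acq.image_shape
    times = acq.times_min
    n_frames = acq.n_frames
    background = params.background_frac * _MAX_UINT16

    grid = acq.grid_centers()
    n_droplets = len(grid)
    counts = sample_occupancy(params.lambda_cells, n_droplets, rng)
    emulsions = sample_emulsions(n_droplets, params.frac_hg, rng)

    # per-droplet pH trajectories
    ph = np.empty((n_droplets, n_frames))
    droplet_rows = []
    cell_meta = []  # (droplet_id, emulsion, rate, path)
    for i, (row, col, cx, cy) in enumerate(grid):
        rates = sample_cell_rates(int(counts[i]), emulsions[i], params, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph[i] = simulate_ph_trajectory(
                int(counts[i]),
                emulsions[i],
                rates,
                times,
                dph_empty=params.dph_empty,
                initial_ph=params.initial_ph,
                calibration=calib,
            )
        out_of_range = bool(np.any(~phquant.in_linear_range(ph[i], calib)))
        droplet_rows.append(
            {
                "position": position,
                "droplet_id": i,
                "row": int(row),
                "col": int(col),
                "x": cx,
                "y": cy,
                "radius_px": radius_px,
                "emulsion": emulsions[i],
                "n_cells": int(counts[i]),
                "dph_true": float(rates.sum() + params.dph_empty),
                "ph_initial": float(ph[i, 0]),
                "ph_final": float(ph[i, -1]),
                "out_of_range": out_of_range,
            }
        )
        for rate in rates:
            path = _simulate_cell_path((cx, cy), radius_px, n_frames, params, rng)
            cell_meta.append((i, emulsions[i], float(rate), path))

    f600, f667 = phquant.probe_intensities(ph, calib, scale=params.probe_scale)

    # precompute each droplet's disk pixel indices once
    disk_idx = []
    for _, _, cx, cy in grid:
        x0, x1 = int(np.floor(cx - radius_px)) - 1, int(np.ceil(cx + radius_px)) + 2
        y0, y1 = int(np.floor(cy - radius_px)) - 1, int(np.ceil(cy + radius_px)) + 2
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px**2
        disk_idx.append((ys[inside], xs[inside]))

    stacks: dict[str, np.ndarray] = {}
    for channel, values in (("CY3_600", f600), ("CY5_667", f667)):
        stack = np.full((n_frames, h, w), background, dtype=np.float32)
        for f in range(n_frames):
            frame = stack[f]
            for i, (ys, xs) in enumerate(disk_idx):
                frame[ys, xs] = background + values[i, f]
        stacks[channel] = stack

    bleach = 2.0 ** (-times / params.bleach_halflife) if params.bleach_halflife > 0 else np.ones(n_frames)
    sig = params.spot_sigma_px
    half = int(np.ceil(_spot_footprint_radius(params)))
    for channel in LABEL_CHANNELS:
        stacks[channel] = np.full((n_frames, h, w), background, dtype=np.float32)
    cell_rows = []
    for cell_id, (droplet_id, emulsion, rate, path) in enumerate(cell_meta):
        channel = EMULSION_LABEL_CHANNEL[emulsion]
        stack = stacks[channel]
        for f in range(n_frames):
            cx, cy = path[f]
            x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
            y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            ys, xs = np.mgrid[y0:y1, x0:x1]
            amp = params.spot_amplitude * bleach[f]
            stack[f, y0:y1, x0:x1] += amp * np.exp(
                -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sig**2)
            ).astype(np.float32)
            cell_rows.append(
                {
                    "position": position,
                    "droplet_id": droplet_id,
                    "cell_id": cell_id,
                    "emulsion": emulsion,
                    "drop_3h": rate,
                    "frame": f,
                    "t_min": float(times[f]),
                    "x": float(cx),
                    "y": float(cy),
                }
            )

    for channel in list(stacks):
        stack = stacks[channel]
        if params.noise_sigma > 0:
            stack = stack + rng.normal(0.0, params.noise_sigma, size=stack.shape).astype(np.float32)
        stacks[channel] = np.clip(np.rint(stack), 0, _MAX_UINT16).astype(np.uint16)

    truth_droplets = pd.DataFrame(droplet_rows)
    cell_cols = ["position", "droplet_id", "cell_id", "emulsion", "drop_3h", "frame", "t_min", "x", "y"]
    truth_cells = pd.DataFrame(cell_rows, columns=cell_cols)
    return stacks, truth_droplets, truth_cells


def render_dataset(
    params: SynthParams,
    acq: AcquisitionConfig,
    out_dir,
    calibration: CalibrationModel | None = None,
) -> GroundTruth:
    """Render all positions to disk: TIFF stacks, truth CSVs, config snapshot.

    Stacks are written as ``pos{P:03d}_{CHANNEL}.tif`` multi-frame TIFFs;
    ground truth as ``truth_droplets.csv`` / ``truth_cells.csv``; the
    parameters are echoed to ``synth_config.yaml``.  Identical seed and
    parameters produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calib = calibration or CalibrationModel()
    seeds = np.random.SeedSequence(params.seed).spawn(acq.n_positions)
    all_droplets, all_cells = [], []
    for p in range(acq.n_positions):
        rng = np.random.default_rng(seeds[p])
        stacks, droplets, cells = render_position(p, params, acq, calib, rng)
        for channel, stack in stacks.items():
            tifffile.imwrite(out / f"pos{p:03d}_{channel}.tif", stack)
        all_droplets.append(droplets)
        all_cells.append(cells)
    truth_droplets = pd.concat(all_droplets, ignore_index=True)
    truth_cells = pd.concat(all_cells, ignore_index=True)
    truth_droplets.to_csv(out / "truth_droplets.csv", index=False)
    truth_cells.to_csv(out / "truth_cells.csv", index=False)
    calib_d = dataclasses.asdict(calib)
    for key in ("linear_range", "fitted_range"):
        if calib_d.get(key) is not None:
            calib_d[key] = list(calib_d[key])
    snapshot = {
        "synth": dataclasses.asdict(params),
        "acquisition": {
            **dataclasses.asdict(acq),
            "image_shape": list(acq.image_shape),
            "channels": list(acq.channels),
        },
        "calibration": calib_d,
    }
    (out / "synth_config.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=True))
    return GroundTruth(droplets=truth_droplets, cells=truth_cells)
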