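"""Run configuration: acquisition geometry, generator parameters, serialization.

A run is described by a single :class:`RunConfig` that composes the
acquisition geometry, tracker settings, probe calibration, QC thresholds
and (for synthetic runs) the generator parameters.  Configs round-trip
losslessly through YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phquant import CalibrationModel
from .qcstats import QCThresholds
from .tracker import TrackerParams

__all__ = [
    "CHANNELS",
    "LABEL_CHANNELS",
    "PROBE_CHANNELS",
    "AcquisitionConfig",
    "SynthParams",
    "RunConfig",
    "ConfigError",
]

# Ordered channel names: two cell-label channels and the probe's two
# emission channels (600 nm "Cy3" and 667 nm "Cy5").
CHANNELS = ("GREEN", "UV", "CY3_600", "CY5_667")
LABEL_CHANNELS = ("GREEN", "UV")
PROBE_CHANNELS = ("CY3_600", "CY5_667")

# Label dye → emulsion mapping: Calcein AM (green) marks the
# hyperglycolytic arm, CellTrace Violet (UV) the untreated arm.
CHANNEL_EMULSION = {"GREEN": "HG", "UV": "UT"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and cadence of one imaging run (real or synthetic).

    Defaults describe a 13×13 microwell grid per imaging window, 60 µm
    droplets, 5-min frame interval over 3 h (37 frames including t = 0),
    and a desk-scale default of 3 stage positions (a full device has 240).
    """

    grid_rows: int = 13
    grid_cols: int = 13
    n_positions: int = 3
    droplet_diameter_um: float = 60.0
    pixel_size_um: float = 1.0
    frame_interval_min: float = 5.0
    duration_min: float = 180.0
    image_shape: tuple[int, int] = (1024, 1024)
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.n_positions < 1:
            raise ConfigError("grid dimensions and n_positions must be >= 1")
        if self.droplet_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("droplet diameter and pixel size must be positive")
        if self.frame_interval_min <= 0 or self.duration_min < 0:
            raise ConfigError("frame interval must be positive, duration non-negative")
        n = self.duration_min / self.frame_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("duration_min must be a multiple of frame_interval_min")
        # droplets must sit on a non-overlapping regular grid
        h, w = self.image_shape
        if self.droplet_diameter_px >= min(w / self.grid_cols, h / self.grid_rows):
            raise ConfigError("droplet diameter exceeds the grid pitch; droplets would overlap")

    @property
    def n_frames(self) -> int:
        """Frames per stack, inclusive of t = 0."""
        return int(round(self.duration_min / self.frame_interval_min)) + 1

    @property
    def times_min(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval_min

    @property
    def droplet_diameter_px(self) -> float:
        return self.droplet_diameter_um / self.pixel_size_um

    @property
    def droplet_radius_px(self) -> float:
        return self.droplet_diameter_px / 2.0

    def grid_centers(self):
        """(row, col, x, y) centers of the regular well grid in pixels."""
        import numpy as np

        h, w = self.image_shape
        pitch_x = w / self.grid_cols
        pitch_y = h / self.grid_rows
        out = []
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                out.append((r, c, (c + 0.5) * pitch_x, (r + 0.5) * pitch_y))
        return np.array(out, dtype=float)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic two-population droplet experiment.

    The defaults reproduce the study conditions the pipeline targets:
    Poisson occupancy at λ = 1.716 (cell concentration × droplet volume),
    a 1:1 mix of hyperglycolytic (HG, green-labeled) and untreated (UT,
    violet-labeled) emulsions, 3-h mean pH drops of 0.17 (HG single) /
    0.065 (UT single) / 0.021 (empty drift), lognormal per-cell rate
    heterogeneity with CV 0.4, and label-dye photobleaching.
    """

    lambda_cells: float = 1.716
    frac_hg: float = 0.5
    dph_mean_hg_single: float = 0.17
    dph_mean_ut_single: float = 0.065
    dph_empty: float = 0.021
    cell_cv: float = 0.4
    crowding: float = 0.7
    bleach_halflife: float = 90.0
    noise_sigma: float = 100.0
    seed: int = 0
    initial_ph: float = 6.4
    spot_amplitude: float = 20000.0
    spot_sigma_px: float = 2.5
    step_sd_px: float = 2.0
    # Cells sediment toward the droplet's bottom pole, so their lateral
    # excursions project well inside the droplet outline: Brownian motion
    # is reflected at confinement × droplet radius.
    confinement: float = 0.6
    probe_scale: float = 1000.0
    background_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_cells < 0:
            raise ConfigError("lambda_cells must be >= 0")
        if not 0.0 <= self.frac_hg <= 1.0:
            raise ConfigError("frac_hg must be in [0, 1]")
        for name in (
            "dph_mean_hg_single",
            "dph_mean_ut_single",
            "dph_empty",
            "cell_cv",
            "bleach_halflife",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.crowding <= 1:
            raise ConfigError("crowding must be in (0, 1]")
        if not 0 < self.confinement <= 1:
            raise ConfigError("confinement must be in (0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    input_dir: str | None = None
    output_dir: str = "scoph_out"
    synthesize: bool = False
    write_images: bool = False
    seed: int = 0
    log_level: str = "INFO"
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    qc: QCThresholds = field(default_factory=QCThresholds)
    synth: SynthParams | None = None

    @classmethod
    def default_synthetic(cls, seed: int = 0, n_positions: int = 3, **overrides) -> "RunConfig":
        """Default two-population synthetic experiment.

        QC windows use the low-acidification preset scaled to this
        experiment's ΔpH range (~0.2 pH over 3 h) rather than the
        glucose-rich defaults; see :meth:`QCThresholds.low_acidification`.
        """
        acq = overrides.pop("acquisition", AcquisitionConfig(n_positions=n_positions))
        synth = overrides.pop("synth", SynthParams(seed=seed))
        qc = overrides.pop("qc", QCThresholds.low_acidification())
        return cls(
            synthesize=True,
            seed=seed,
            acquisition=acq,
            synth=synth,
            qc=qc,
            **overrides,
        )

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; used for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_asdict(v) for v in obj]
    if isinstance(obj, (list, dict, str, int, float, bool)) or obj is None:
        return obj
    raise TypeError(f"cannot serialize {type(obj)!r}")


_TUPLE_FIELDS = {"image_shape", "channels", "linear_range", "fitted_range"}


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"expected mapping for {cls.__name__}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    nested = {
        "acquisition": AcquisitionConfig,
        "tracker": TrackerParams,
        "calibration": CalibrationModel,
        "qc": QCThresholds,
        "synth": SynthParams,
    }
    for name, value in data.items():
        if name in nested and value is not None:
            kwargs[name] = _from_dict(nested[name], value)
        elif name in _TUPLE_FIELDS and value is not None:
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
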