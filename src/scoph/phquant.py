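"""Ratiometric pH quantification for dual-emission pH probes.

Carboxy SNARF-type probes exist in an acid (AH) and a base (A) form with
distinct emission peaks (600 nm and 667 nm here).  The intensity ratio
``R = F600 / F667`` is a monotone function of pH, and with the endpoint
ratios and a normalization factor it inverts in closed form::

    pH = pKa - log10( (R - R_B) / (R_A - R) * norm_factor )

where ``R_A`` / ``R_B`` are the ratios at the acid/base endpoints and
``norm_factor = F_B(667) / F_A(667)`` is the 667 nm intensity ratio between
the basic and acidic endpoints.  A linear approximation of R vs pH is valid
roughly on pH 5.0-6.5 and is available as an alternative mode.

This module converts per-droplet mean intensities from the two probe
channels into pH time series, normalized traces, and the raw acidification
summary ``ΔpH = pH_initial − pH_final`` (positive = acidification).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

__all__ = [
    "CalibrationModel",
    "probe_intensities",
    "ratio_from_ph",
    "ph_from_ratio",
    "in_linear_range",
    "ratio",
    "droplet_intensity",
    "droplet_intensities",
    "fit_linear_calibration",
    "normalize_trace",
    "delta_ph",
    "bleach_trend",
    "bleach_correct",
]

RATIOMETRIC = "RATIOMETRIC"
LINEAR = "LINEAR"


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """Probe calibration constants for ratiometric or linear pH inversion.

    The defaults describe the synthetic probe model used by the data
    generator.  They are configuration, not instrument facts: real probe
    data needs its own endpoint calibration.

    Parameters
    ----------
    pKa : acid dissociation exponent of the probe.
    R_A, R_B : intensity ratio F600/F667 at the acidic / basic endpoint.
    norm_factor : F_B(667)/F_A(667), the 667 nm endpoint intensity ratio.
    mode : ``"RATIOMETRIC"`` (endpoint equation) or ``"LINEAR"`` (fitted line).
    linear_range : pH interval on which R(pH) is treated as linear.
    linear_slope, linear_intercept : fitted line ``R = slope*pH + intercept``;
        required for LINEAR mode, set by :func:`fit_linear_calibration`.
    residual_sd : residual standard deviation of the linear fit.
    fitted_range : pH range the linear fit was trained on; values outside
        are flagged as extrapolation.
    """

    pKa: float = 6.4
    R_A: float = 3.0
    R_B: float = 0.1
    norm_factor: float = 4.0
    mode: str = RATIOMETRIC
    linear_range: tuple[float, float] = (5.0, 6.5)
    linear_slope: float | None = None
    linear_intercept: float | None = None
    residual_sd: float | None = None
    fitted_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.R_A == self.R_B:
            raise ValueError("endpoint ratios R_A and R_B must differ")
        if not self.norm_factor > 0:
            raise ValueError("norm_factor must be positive")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError("linear_range bounds must be ordered")
        if self.mode not in (RATIOMETRIC, LINEAR):
            raise ValueError(f"unknown calibration mode {self.mode!r}")

    def base_fraction(self, ph):
        """Fraction of the probe in the basic (A) form at ``ph``."""
        ph = np.asarray(ph, dtype=float)
        return 1.0 / (1.0 + 10.0 ** (self.pKa - ph))


def probe_intensities(ph, calib: CalibrationModel, scale: float = 1000.0):
    """Forward optical model: emission intensities (F600, F667) at ``ph``.

    ``scale`` is the 667 nm intensity of the pure acid form in camera
    counts; endpoint intensities follow from the calibration constants
    (F667 basic endpoint = ``norm_factor * scale``, F600 endpoints =
    ``R_A * scale`` and ``R_B * norm_factor * scale``).  The two forms mix
    linearly with the ground-state equilibrium fraction.
    """
    f = calib.base_fraction(ph)
    f667_acid = scale
    f667_base = calib.norm_factor * scale
    f667 = (1.0 - f) * f667_acid + f * f667_base
    f600 = (1.0 - f) * calib.R_A * f667_acid + f * calib.R_B * f667_base
    return f600, f667


def ratio_from_ph(ph, calib: CalibrationModel):
    """Forward ratio model R(pH); inverse of :func:`ph_from_ratio`."""
    f600, f667 = probe_intensities(ph, calib)
    return f600 / f667


def ratio(f600, f667):
    """Emission intensity ratio R = F600 / F667.

    Non-positive denominators yield NaN (flagged missing), not an exception.
    """
    f600 = np.asarray(f600, dtype=float)
    f667 = np.asarray(f667, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(f667 > 0, f600 / np.where(f667 > 0, f667, 1.0), np.nan)
    if r.ndim == 0:
        return float(r)
    return r


def ph_from_ratio(r, calib: CalibrationModel):
    """Invert the measured ratio to pH.

    RATIOMETRIC mode applies the endpoint equation; ratios at or beyond an
    endpoint are saturated and returned as NaN.  LINEAR mode inverts the
    fitted line (requires :func:`fit_linear_calibration` first).  Values
    outside the calibration's linear range are returned as-is; use
    :func:`in_linear_range` to flag them.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if calib.mode == LINEAR:
        if calib.linear_slope is None or calib.linear_intercept is None:
            raise ValueError("LINEAR mode requires a fitted calibration line")
        ph = (r - calib.linear_intercept) / calib.linear_slope
    else:
        lo, hi = sorted((calib.R_A, calib.R_B))
        valid = (r > lo) & (r < hi)
        if not np.all(valid | np.isnan(r)):
            warnings.warn(
                "ratio at or beyond a calibration endpoint; flagged saturated (NaN)",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = (r - calib.R_B) / (calib.R_A - r) * calib.norm_factor
            ph = np.where(valid & (arg > 0), calib.pKa - np.log10(np.where(arg > 0, arg, 1.0)), np.nan)
    return float(ph[0]) if scalar else ph


def in_linear_range(ph, calib: CalibrationModel):
    """Boolean mask of pH values inside the probe's linear range."""
    lo, hi = calib.linear_range
    ph = np.asarray(ph, dtype=float)
    return (ph >= lo) & (ph <= hi)


def droplet_intensity(frame, labels, label: int) -> float:
    """Background-subtracted mean intensity of one droplet.

    Background is the median of non-droplet pixels (``labels == 0``) in the
    same frame; if the mask covers the whole frame no subtraction is done.
    """
    frame = np.asarray(frame, dtype=float)
    sel = labels == label
    if not np.any(sel):
        raise ValueError(f"label {label} is empty in the droplet mask")
    bg_pixels = frame[labels == 0]
    bg = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
    return float(frame[sel].mean()) - bg


def droplet_intensities(frame, labels, index=None):
    """Vectorized :func:`droplet_intensity` over all labels in the mask."""
    frame = np.asarray(frame, dtype=float)
    if index is None:
        index = np.unique(labels)
        index = index[index > 0]
    index = np.asarray(index)
    bg_pixels = frame[labels == 0]
    bg = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
    means = ndimage.mean(frame, labels=labels, index=index)
    return np.asarray(means, dtype=float) - bg


def fit_linear_calibration(ph, r, calib: CalibrationModel | None = None) -> CalibrationModel:
    """Least-squares line R = slope*pH + intercept from calibration pairs.

    Needs at least three pairs inside the probe's linear range; stores the
    residual SD and the fitted pH range (extrapolation beyond it is flagged
    by downstream users).  Returns an updated calibration model.
    """
    ph = np.asarray(ph, dtype=float)
    r = np.asarray(r, dtype=float)
    if calib is None:
        calib = CalibrationModel()
    lo, hi = calib.linear_range
    sel = (ph >= lo) & (ph <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 calibration pairs inside the linear range")
    ph, r = ph[sel], r[sel]
    slope, intercept = np.polyfit(ph, r, 1)
    resid = r - (slope * ph + intercept)
    dof = max(len(ph) - 2, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return dataclasses.replace(
        calib,
        linear_slope=float(slope),
        linear_intercept=float(intercept),
        residual_sd=resid_sd,
        fitted_range=(float(ph.min()), float(ph.max())),
    )


def normalize_trace(ph):
    """Normalize a pH series to its first defined frame (value 1 at anchor).

    Returns ``(normalized, anchor_index)``.  If frame 0 is missing the first
    finite frame is used and its index reported, so provenance can record
    the substitution.
    """
    ph = np.asarray(ph, dtype=float)
    finite = np.flatnonzero(np.isfinite(ph))
    if finite.size == 0:
        raise ValueError("pH series has no defined frames")
    anchor = int(finite[0])
    if ph[anchor] <= 0:
        raise ValueError("anchor pH must be positive for normalization")
    return ph / ph[anchor], anchor


def delta_ph(ph) -> float:
    """Raw ΔpH = pH at first defined frame minus pH at last defined frame.

    Positive values mean acidification.  Returns NaN when fewer than two
    frames are defined.
    """
    ph = np.asarray(ph, dtype=float)
    finite = np.flatnonzero(np.isfinite(ph))
    if finite.size < 2:
        return float("nan")
    return float(ph[finite[0]] - ph[finite[-1]])


def bleach_trend(intensity, times):
    """Monotone exponential photobleaching trend fitted to a label-intensity series.

    Fits ``log I = a - k t`` by least squares on the positive entries and
    returns the trend normalized to 1 at the first time point.
    """
    intensity = np.asarray(intensity, dtype=float)
    times = np.asarray(times, dtype=float)
    if intensity.shape != times.shape:
        raise ValueError("intensity and times must have the same shape")
    if len(intensity) < 3:
        raise ValueError("need at least 3 frames to fit a bleaching trend")
    pos = intensity > 0
    if pos.sum() < 3:
        raise ValueError("bleaching fit needs at least 3 positive intensities")
    k, a = np.polyfit(times[pos], np.log(intensity[pos]), 1)
    trend = np.exp(a + k * times)
    return trend / trend[0]


def bleach_correct(intensity, times):
    """Divide a label-intensity series by its fitted exponential bleaching trend.

    With no bleaching the fitted trend is ~flat and the series is returned
    (numerically) unchanged; pure exponential decay is flattened to its
    initial value.
    """
    intensity = np.asarray(intensity, dtype=float)
    trend = bleach_trend(intensity, times)
    return intensity / trend
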