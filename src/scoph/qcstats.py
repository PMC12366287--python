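"""QC windows, encapsulation statistics, crosstalk checks and group tests.

Image-based occupancy calls are audited against each droplet's measured
acidification: a droplet called "single cell" whose ΔpH falls below the
single-cell window is debris in an empty droplet; one above it is a missed
multi-cell droplet; an "empty" droplet acidifying beyond the empty bound
hides a weakly fluorescent cell.  The module also provides the Poisson
encapsulation design numbers (λ = concentration × droplet volume), droplet
geometry/polydispersity helpers, probe-crosstalk ratios between positive
and negative droplet populations, and two-sample t-tests with the standard
significance-symbol legend.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCThresholds",
    "QCReport",
    "CrosstalkResult",
    "PoissonDesign",
    "apply_qc",
    "rates",
    "crosstalk_ratio",
    "poisson_design",
    "droplet_volume",
    "polydispersity",
    "compare_groups",
    "significance_symbol",
]

# QC actions written into the amended summary table
KEPT = "kept"
RECLASS_EMPTY_DEBRIS = "reclassified_empty_debris"
RECLASS_MULTI = "reclassified_multi"
ERROR_HIDDEN_CELL = "error_hidden_cell"
EXCLUDED_NO_TRACE = "excluded_no_trace"


@dataclass(frozen=True)
class QCThresholds:
    """ΔpH windows for auditing image-based occupancy calls.

    Defaults are the windows derived for a glucose-rich 3-h run
    (single-cell droplets 0.28 ≤ ΔpH ≤ 1.02, empty droplets ΔpH ≤ 0.37).
    They are per-experiment configuration: an experiment on a different
    acidification scale needs windows derived for that scale (see
    :meth:`low_acidification`).
    """

    single_min: float = 0.28
    single_max: float = 1.02
    empty_max: float = 0.37

    def __post_init__(self) -> None:
        if not self.single_min <= self.single_max:
            raise ValueError("single_min must be <= single_max")
        if self.empty_max < 0:
            raise ValueError("empty_max must be >= 0")

    @classmethod
    def low_acidification(cls) -> "QCThresholds":
        """Preset for the oligomycin two-population experiment.

        That run's single-cell ΔpH scale is ~0.07-0.2 over 3 h, so the
        windows sit between the empty-drift level (~0.02) and the
        multi-cell level (~0.23-0.5): singles 0.03 ≤ ΔpH ≤ 0.50, empties
        ΔpH ≤ 0.05.
        """
        return cls(single_min=0.03, single_max=0.50, empty_max=0.05)


@dataclass
class QCReport:
    """Per-class QC tallies. ``counts[cls]`` has kept/excluded/reclassified."""

    counts: dict
    error_rates: dict
    n_input: int

    def total(self, cls: str) -> int:
        c = self.counts.get(cls, {})
        return c.get("kept", 0) + c.get("excluded", 0) + c.get("reclassified", 0)


@dataclass
class CrosstalkResult:
    """Positive/negative droplet intensity ratio over time at one wavelength."""

    times: np.ndarray
    ratio: np.ndarray
    sd: np.ndarray
    n_sample: int
    stable: bool
    max_drift: float


@dataclass(frozen=True)
class PoissonDesign:
    """Encapsulation design: λ and the empty/single/multi probabilities."""

    lam: float
    p_empty: float
    p_single: float
    p_multi: float


def apply_qc(summaries: pd.DataFrame, thresholds: QCThresholds) -> tuple[QCReport, pd.DataFrame]:
    """Audit image-based occupancy classes against measured ΔpH.

    ``summaries`` needs columns ``occ_class`` (EMPTY/SINGLE/MULTI) and
    ``delta_ph``.  Returns the QC report and an amended copy with columns
    ``qc_action`` and ``qc_class`` (the post-QC class; droplets marked as
    errors or without a trace get qc_class ``"EXCLUDED"``).

    Image-classified singles keep their call inside the single window,
    become empty-with-debris below it and multi-cell above it; image-
    classified empties keep their call up to ``empty_max`` and are flagged
    as hidden-cell errors above it.  The windows are applied conditionally
    on the image-derived class, so the partition is exhaustive and
    exclusive.
    """
    required = {"occ_class", "delta_ph"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    df = summaries.copy()
    actions = []
    qc_classes = []
    for occ_class, dph in zip(df["occ_class"], df["delta_ph"]):
        if dph is None or not np.isfinite(dph):
            actions.append(EXCLUDED_NO_TRACE)
            qc_classes.append("EXCLUDED")
        elif occ_class == "SINGLE":
            if dph < thresholds.single_min:
                actions.append(RECLASS_EMPTY_DEBRIS)
                qc_classes.append("EMPTY")
            elif dph > thresholds.single_max:
                actions.append(RECLASS_MULTI)
                qc_classes.append("MULTI")
            else:
                actions.append(KEPT)
                qc_classes.append("SINGLE")
        elif occ_class == "EMPTY":
            if dph > thresholds.empty_max:
                actions.append(ERROR_HIDDEN_CELL)
                qc_classes.append("EXCLUDED")
            else:
                actions.append(KEPT)
                qc_classes.append("EMPTY")
        else:  # MULTI (and anything else) is kept as-is
            actions.append(KEPT)
            qc_classes.append(occ_class)
    df["qc_action"] = actions
    df["qc_class"] = qc_classes

    counts: dict = {}
    error_rates: dict = {}
    for cls, group in df.groupby("occ_class"):
        acts = group["qc_action"]
        kept = int((acts == KEPT).sum())
        reclassified = int(acts.isin([RECLASS_EMPTY_DEBRIS, RECLASS_MULTI]).sum())
        excluded = int(acts.isin([ERROR_HIDDEN_CELL, EXCLUDED_NO_TRACE]).sum())
        n = len(group)
        counts[cls] = {"kept": kept, "reclassified": reclassified, "excluded": excluded}
        n_err = int(acts.isin([RECLASS_EMPTY_DEBRIS, RECLASS_MULTI, ERROR_HIDDEN_CELL]).sum())
        error_rates[cls] = n_err / n if n else float("nan")
    return QCReport(counts=counts, error_rates=error_rates, n_input=len(df)), df


def rates(amended: pd.DataFrame, by_position: bool = True) -> pd.DataFrame:
    """Error and encapsulation rates per position and pooled.

    Encapsulation efficiency = QC-kept single-cell droplets / all droplets;
    empty generation rate analogous; error rate per class = (reclassified +
    error) / class candidate count.  Positions with zero droplets report NaN.
    """
    if "qc_action" not in amended.columns:
        raise ValueError("run apply_qc before computing rates")

    def _one(group: pd.DataFrame, position) -> dict:
        n = len(group)
        singles = group[group["occ_class"] == "SINGLE"]
        empties = group[group["occ_class"] == "EMPTY"]
        kept_single = int((singles["qc_action"] == KEPT).sum())
        kept_empty = int((empties["qc_action"] == KEPT).sum())
        err = [RECLASS_EMPTY_DEBRIS, RECLASS_MULTI, ERROR_HIDDEN_CELL]
        return {
            "position": position,
            "n_droplets": n,
            "single_candidates": len(singles),
            "empty_candidates": len(empties),
            "single_error_rate": (singles["qc_action"].isin(err).mean() if len(singles) else float("nan")),
            "empty_error_rate": (empties["qc_action"].isin(err).mean() if len(empties) else float("nan")),
            "encapsulation_efficiency": kept_single / n if n else float("nan"),
            "empty_rate": kept_empty / n if n else float("nan"),
        }

    rows = []
    if by_position and "position" in amended.columns:
        for pos, group in amended.groupby("position"):
            rows.append(_one(group, pos))
    rows.append(_one(amended, "pooled"))
    return pd.DataFrame(rows)


def crosstalk_ratio(
    positive,
    negative,
    times,
    n_sample: int = 3,
    seed: int | np.random.Generator = 0,
    stability_threshold: float = 0.10,
) -> CrosstalkResult:
    """Probe-retention check: intensity ratio of positive vs negative droplets.

    ``positive`` and ``negative`` are (n_droplets, n_times) intensity
    arrays of probe-loaded and buffer-only droplets at one emission
    wavelength.  ``n_sample`` droplets are drawn from each population
    (seeded); the reported ratio is mean(positive sample)/mean(negative
    sample) per time point, with the SD taken across the sampled positive
    droplets' individual ratios.  The verdict is "stable" (no probe
    leakage) when the relative drift of the ratio over the observation
    window stays below ``stability_threshold``.
    """
    positive = np.atleast_2d(np.asarray(positive, dtype=float))
    negative = np.atleast_2d(np.asarray(negative, dtype=float))
    times = np.asarray(times, dtype=float)
    if positive.shape[0] == 0 or negative.shape[0] == 0:
        raise ValueError("both droplet populations must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pos = min(n_sample, positive.shape[0])
    n_neg = min(n_sample, negative.shape[0])
    pos = positive[rng.choice(positive.shape[0], size=n_pos, replace=False)]
    neg = negative[rng.choice(negative.shape[0], size=n_neg, replace=False)]
    neg_mean = neg.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_droplet = np.where(neg_mean > 0, pos / neg_mean, np.nan)
    ratio = np.nanmean(per_droplet, axis=0)
    sd = np.nanstd(per_droplet, axis=0, ddof=1) if n_pos > 1 else np.zeros_like(ratio)
    finite = np.isfinite(ratio)
    if finite.any() and np.nanmax(np.abs(ratio)) > 0:
        ref = ratio[finite][0]
        max_drift = float(np.nanmax(np.abs(ratio[finite] - ref)) / abs(ref)) if ref else float("inf")
    else:
        max_drift = float("inf")
    return CrosstalkResult(
        times=times,
        ratio=ratio,
        sd=sd,
        n_sample=n_pos,
        stable=max_drift < stability_threshold,
        max_drift=max_drift,
    )


def poisson_design(concentration_per_ml: float, droplet_volume_pl: float) -> PoissonDesign:
    """Encapsulation design numbers from the Poisson loading model.

    λ = cell concentration × droplet volume (1 pL = 1e-9 mL), and the
    droplet-occupancy probabilities P(0) = e^(−λ), P(1) = λe^(−λ),
    P(≥2) = 1 − P(0) − P(1).
    """
    if concentration_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    if droplet_volume_pl <= 0:
        raise ValueError("droplet volume must be > 0")
    lam = concentration_per_ml * droplet_volume_pl * 1e-9
    p0 = float(np.exp(-lam))
    p1 = float(lam * np.exp(-lam))
    return PoissonDesign(lam=lam, p_empty=p0, p_single=p1, p_multi=1.0 - p0 - p1)


def droplet_volume(diameter_um: float) -> float:
    """Sphere volume of a droplet in picoliters (π d³ / 6; 1000 µm³ = 1 pL)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    return float(np.pi * diameter_um**3 / 6.0 / 1000.0)


def polydispersity(diameters) -> float:
    """Coefficient of variation of droplet diameters, in percent."""
    d = np.asarray(diameters, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 diameters")
    mean = d.mean()
    if mean == 0:
        raise ValueError("mean diameter is zero")
    return float(100.0 * d.std(ddof=1) / mean)


def significance_symbol(p: float) -> str:
    """Standard significance legend: ns, *, **, ***."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(values_a, values_b) -> tuple[float, float, str]:
    """Two-tailed two-sample Student's t-test with significance symbol.

    Identical groups (zero pooled variance included) report t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; the
        # degenerate outcome is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):  # zero within-group variance
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    return float(t), float(p), significance_symbol(float(p))
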