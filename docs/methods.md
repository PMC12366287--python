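# Methods

This note documents the models behind `scoph`: what the synthetic generator
emulates, how each pipeline stage works, which parameters matter, and the
numerical and design choices that were genuinely open.

## Ratiometric pH model

The probe is a two-state (acid AH / base A) fluorophore with emission peaks
at 600 nm and 667 nm. With base fraction f(pH) = 1 / (1 + 10^(pKa − pH)),
the emitted intensities mix linearly between the endpoint spectra, and the
ratio R = F₆₀₀/F₆₆₇ inverts exactly:

    pH = pKa − log₁₀( (R − R_B)/(R_A − R) · nf ),   nf = F_B(667)/F_A(667)

where R_A, R_B are the endpoint ratios. `CalibrationModel` defaults
(pKa 6.4, R_A 3.0, R_B 0.1, nf 4.0) describe the *synthetic* probe used by
the generator; they are configuration, not instrument facts, and must be
replaced by a measured endpoint calibration for real probe data. R is
defined as F₆₀₀/F₆₆₇ (the convention of the calibration curve); the
direction is configurable because the opposite quotient also appears in
informal use. A linear mode (least-squares line R vs pH, residual SD
stored, extrapolation flagged) agrees with the endpoint equation within
0.05 pH on pH 5.5–6.5 for the defaults.

pH → intensity round trips are exact to < 1e-9 on the un-quantized optical
model. Rendered images are 16-bit unsigned, so the image-level round trip
is limited by quantization to ~1e-3 pH — far below the ±0.02 recovery
tolerance used for the end-to-end check.

"Normalized pH" is the trace divided by its first defined frame (value 1 at
t = 0); a ratio was chosen over a difference or min–max scaling because it
is the only variant that is invariant under calibration offsets of the
anchor frame and keeps the plotted quantity dimensionless. Raw
ΔpH = pH(first defined frame) − pH(last defined frame); positive values
mean acidification.

## Synthetic scene generator

The generator emulates the study conditions of a two-population droplet
experiment on a microwell array:

- **Geometry.** 13×13 wells per 1024×1024 px imaging window, 60 µm droplets
  at 1 µm/px (the acquisition optics' pixel calibration is not a published
  quantity, so 1 µm/px is a free, round choice); 5-min frames over 3 h
  (37 frames); a desk-scale default of 3 windows stands in for the 240-window
  device.
- **Occupancy.** Cell counts are Poisson(λ), λ default 1.716 (concentration
  × droplet volume). Each droplet is hyperglycolytic (HG) with probability
  0.5, modeling a 1:1 mix of two separately generated emulsions.
- **Acidification.** A droplet's pH declines linearly from pH 6.4 by
  Σ(per-cell drops) + empty drift over the 3-h window. Per-cell 3-h drops
  are lognormal with CV 0.4; their mean is (single-cell mean − drift)
  scaled by crowding^(n−1), crowding 0.7. Defaults: HG single 0.17, UT
  single 0.065, empty drift 0.021 pH units. The crowding factor models
  shared-substrate saturation and reproduces the observed sub-additive
  multi-cell drops (2-cell HG droplets average ≈0.23, not 2×0.17); the
  trajectory function itself is exactly additive in the per-cell rates it
  is given. With CV 0.4 the HG single-cell ΔpH spread is ≈0.06–0.07,
  matching the reported 0.17 ± 0.07.
- **Optics.** Droplets render as uniform disks in the two probe channels
  with intensities from the forward calibration at the simulated pH; cells
  render as Gaussian spots (σ 2.5 px, amplitude 20,000 counts) only in
  their population's label channel (green ↔ HG, violet/UV ↔ UT); label
  intensity bleaches exponentially (half-life 90 min); background is 5% of
  the 16-bit range; additive Gaussian readout noise (σ 100 counts default).
- **Motion.** Confined Brownian motion, step SD 2 px/frame, reflected at
  0.6× droplet radius. Cells in a spherical droplet sediment toward the
  bottom pole, which projects near the droplet center, so lateral
  excursions stay well inside the droplet outline; confinement at the
  droplet rim would put ~⅓ of cells outside the central-area counting
  region and contradict the observed reliability of the central-60% rule.
- **Reproducibility.** All randomness flows from one seed through spawned
  per-position streams; identical parameters give byte-identical TIFFs and
  truth tables.

What the generator does *not* model: optics beyond Gaussian spots (no PSF,
no depth effects), droplet drift/coalescence/shrinkage, probe crosstalk
between droplets, autofluorescent debris, or intensity-dependent cell
detectability. Passing tests therefore demonstrate the pipeline's
correctness on data obeying its stated assumptions, not robustness to
every real-microscope artifact — debris and dim cells, the dominant error
sources in real runs, must be covered by the ΔpH QC stage, which is tested
on constructed confusions instead.

## Tracker

Restoration subtracts a (2r+1) boxcar background estimate from the
σ = 1 px Gaussian-smoothed image. Residuals below 1e-9× the image scale
are snapped to zero so that percentile thresholds on empty noiseless
frames do not promote floating-point ripple to maxima. Detection keeps
local maxima (square (2r+1) footprint; a disk-distance merge afterwards
keeps the brighter of any pair closer than r) whose restored intensity
lies in the upper percentile (default 0.6%, interpretable as an absolute
threshold instead); centroids are refined by the intensity-weighted mean
over the radius neighborhood, where the moments m0 (integrated intensity)
and m2 (spread) are computed. The discrimination step scores each
detection by a kernel density in standardized (m0, m2) space; the default
cutoff 0 passes everything.

Linking solves, per frame, an optimal bipartite assignment (Hungarian
algorithm) between active tracks and detections with cost
d² + Δ(m0/s₀)² + Δ(m2/s₂)², links forbidden beyond
max_displacement × elapsed frames, and gap closing across up to
link_range frames. The moment terms are standardized by their global SDs
before entering the cost — with raw units a unit weight on m0 (∼10⁴
counts) would drown the displacement term. Ties resolve deterministically
(lowest cost, then detection order). Every detection belongs to exactly
one track; unlinkable detections start new tracks.

## Droplet indexing and occupancy

The droplet mask comes from frame 0 of the 667 nm channel (Otsu threshold,
hole filling, removal of components under 25% of the nominal droplet
area); droplets are immobilized in wells, so the mask is reused across
frames (per-frame re-masking is available and indexing is stable to ≥99%
across frames on synthetic data). Grid indexing clusters centroids in y
then x, splitting at gaps larger than half the nominal pitch — robust to
a few pixels of jitter and to missing droplets, and erroring (with the
position named) when components exceed grid slots. Droplets touching the
image border are flagged and excluded from downstream statistics.

A track is assigned to its nearest droplet when its **median** position
lies within radius × √0.6 of the center — the central 60% of the droplet
**area** (the plausible alternative, radius fraction 0.6, is a config
switch). The annulus is discarded because trackers misread high-contrast
droplet rims as cells. Tracks shorter than 5 detections are ignored as
non-persistent (single-frame noise cannot mimic a cell). The per-channel
occupancy is the minimum number of cells consistent with the assigned
tracks: fragments of one cell are temporally disjoint, distinct cells
coexist, so the count is the maximum number of temporally overlapping
track spans (interval max-overlap). Counting raw tracks instead would
double-count cells whose trajectory breaks once — with step SD 2 px and a
5 px displacement limit, ~4% of steps break the link, i.e. more than one
break per 37-frame track on average.

Classification sums both label channels (cross-channel reconciliation):
0 → EMPTY, 1 → SINGLE with the emulsion of its channel, ≥2 → MULTI with
the majority channel (mixed-channel droplets flagged; ties get emulsion
NONE).

## QC and statistics

ΔpH windows audit the image-derived classes conditionally — singles keep
their call inside [single_min, single_max], fall to empty-with-debris
below and to multi above; empties keep their call up to empty_max and are
hidden-cell errors above. Applying the windows *conditionally on the
image class* resolves the overlap between the single-cell lower bound and
the empty upper bound (a ΔpH of 0.3 means debris for an image-single but
a hidden cell for an image-empty). The defaults (0.28 / 1.02 / 0.37) are
the windows derived for a glucose-rich 3-h run; they are per-experiment
configuration because the windows only make sense on that experiment's
acidification scale. The oligomycin two-population experiment runs on a
~0.2-pH scale, so its preset (`QCThresholds.low_acidification`) places
the windows between the empty drift (~0.02) and the multi-cell level:
0.03 / 0.50 / 0.05. Error rate per class = (reclassified + errors) /
candidates; encapsulation efficiency = kept singles / all droplets.

The crosstalk check samples n = 3 droplets (seeded) from probe-loaded and
buffer-only populations and reports the ratio of mean intensities per
time point; a relative drift under 10% over the window is a "stable"
(no-leakage) verdict. Group comparisons use the two-tailed pooled-variance
Student's t-test with the standard symbol legend (ns > 0.05, * ≤ 0.05,
** ≤ 0.01, *** ≤ 0.001); degenerate identical groups report t = 0, p = 1.
No multiplicity correction is applied (single planned contrasts).

## Problem sizes

Unit tests run on 3×3 to 5×5 grids at 256–512 px and 7–13 frames; the
end-to-end recovery and accuracy checks use one full 13×13 window at
1024² px and 37 frames; the acceptance script adds a 3-window noisy
experiment (507 droplets) and 100 trajectory-level significance
replicates at group sizes 21 vs 39. These sizes keep a full run in the
minutes range on one CPU while leaving the statistical checks
well-powered.

## Known limitations

- The tracker supports only Brownian dynamics; no split/merge events.
- Occupancy via interval max-overlap can undercount when two cells merge
  optically for the whole movie, and overcounts nothing by construction;
  at the default conditions residual classification error is ~2–3%,
  dominated by 2-cell droplets read as singles.
- The per-frame re-masking path re-derives droplet identity per frame and
  is slower; it exists for drifting samples but drift itself is not
  modeled or corrected.
- QC windows must be chosen per experiment; there is no automatic window
  derivation from the ΔpH distribution.
- Real-data error sources (debris, dim cells, rim artifacts) enter only
  through the QC model, not the image generator.
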