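# scoph — single-cell optical pH analysis for droplet microwell arrays

`scoph` quantifies the extracellular acidification of single cells that have
been compartmentalized, together with a ratiometric pH probe, in picoliter
water-in-oil droplets immobilized on a 2-D microwell array. It is aimed at
labs running droplet-based metabolic phenotyping (e.g., distinguishing
hyperglycolytic from untreated lymphoma cells by their medium acidification)
who need to turn multi-channel time-lapse TIFF stacks into per-droplet pH
trajectories, occupancy classes, ΔpH statistics and QC reports — and at
method developers, who can exercise every stage on a ground-truthed
synthetic scene generator instead of microscope data.

## What it computes

**Encapsulation design.** Cell loading is Poissonian: with λ = cell
concentration × droplet volume, the droplet occupancy follows
P(X = k) = λ^k e^(−λ) / k!. At the design point λ = 1.716
(1.2×10⁷ cells/mL in 143 pL droplets) this gives 18% empty, ≈31% single-cell
and ≈51% multi-cell droplets.

**Ratiometric pH sensing.** The probe's acid (AH) and base (A) forms emit at
600 and 667 nm; the intensity ratio R = F₆₀₀/F₆₆₇ inverts to pH through the
endpoint equation

    pH = pKa − log₁₀( (R − R_B)/(R_A − R) · F_B(667)/F_A(667) )

with a linear-fit mode available on the probe's linear range (pH 5.0–6.5).
Because R is a ratio, dye concentration, path length and illumination gain
cancel.

**Image pipeline.** Per imaging window (13×13 wells by default): cells are
detected in their label channels by intensity-moment feature-point detection
and linked into Brownian trajectories (radius 10, percentile 0.6, cutoff 0,
link range 4, max displacement 5); droplets are segmented from the 667 nm
channel, indexed onto the well grid, and assigned the tracks whose median
position falls in the central 60% of the droplet area; occupancy is
reconciled across both label channels (a droplet "empty" in green may hold a
violet-labeled cell); per-droplet probe intensities become pH traces,
normalized traces and raw ΔpH = pH_i − pH_f; finally ΔpH windows audit the
image-based calls (singles outside the window are debris or missed
multi-cell droplets, acidifying "empties" hide a cell) and two-tailed
Student's t-tests compare the groups (ns/*/**/***).

## Worked example

```python
from scoph.config import AcquisitionConfig, RunConfig, SynthParams
from scoph.pipeline import run_pipeline

cfg = RunConfig.default_synthetic(seed=1, output_dir="scoph_out")
res = run_pipeline(cfg)                      # 3 windows, 507 droplets
stats = res["group_stats"]
row = stats[(stats.group_a == "HG_single") & (stats.group_b == "UT_single")].iloc[0]
print(f"HG singles: ΔpH = {row.mean_a:.3f} ± {row.sd_a:.3f} (n={row.n_a})")
print(f"UT singles: ΔpH = {row.mean_b:.3f} ± {row.sd_b:.3f} (n={row.n_b})")
print(f"t = {row.t:.1f}, p = {row.p:.2e}  {row.symbol}")
```

prints (seed 1):

```
HG singles: ΔpH = 0.172 ± 0.064 (n=75)
UT singles: ΔpH = 0.067 ± 0.018 (n=79)
t = 14.0, p = 3.26e-29  ***
```

i.e., hyperglycolytic single-cell droplets acidify their 143-pL volume by
~0.17 pH units in 3 h — about 2.6× the untreated drop and ~8× the empty
droplet drift — and the two populations separate at the *** level. The same
run writes `droplets.csv`, `ph_traces.csv`, `droplet_summary.csv`,
`qc_report.json`, `group_stats.csv` and a provenance record to the output
directory.

The command line mirrors the stages:

```bash
scoph simulate sim_dir -c run.yaml     # synthetic stacks + ground truth
scoph track sim_dir tracks.csv -c run.yaml
scoph index sim_dir tracks.csv droplets.csv -c run.yaml
scoph run -c run.yaml                  # everything, end to end
```

## Layout

| module | role |
| --- | --- |
| `scoph.synthgen` | ground-truthed synthetic image stacks (Poisson occupancy, two emulsions, bleaching, confined Brownian cells) |
| `scoph.tracker` | feature-point detection (restoration, moments) and gap-closing Brownian linking |
| `scoph.dropletmap` | droplet mask, grid indexing, central-area cell assignment, occupancy classes |
| `scoph.phquant` | ratiometric/linear calibration, pH traces, ΔpH, bleaching correction |
| `scoph.qcstats` | ΔpH QC windows, error/encapsulation rates, crosstalk ratio, design numbers, t-tests |
| `scoph.config` / `fileio` / `pipeline` / `cli` | run configuration, file sorting, orchestration, CLI |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
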