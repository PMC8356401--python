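# Methods

## The model

The Stroke-Stop index for one patient is

    index = (SDVR × Lp-PLA2) / SF

with SDVR = PSV/EDV measured by Doppler within the internal carotid artery
(both velocities in cm/s, so the ratio is dimensionless and scale-invariant),
Lp-PLA2 the plasma concentration in µg/l, and SF the plaque density
coefficient: 5 for echolucent, 10 for heterogeneous, 15 for echogenic
plaque. Bands are low (< 70 points), medium (70–100, boundaries inclusive)
and high (> 100). The index is an empirical points scale; it carries no
probabilistic calibration to absolute stroke risk and none is implied by a
passing test suite.

Assumptions worth making explicit:

* **SDVR is the within-ICA systolic/diastolic ratio**, not the ICA/CCA
  peak-systolic ratio that some vascular labs use. The two are not
  interchangeable.
* **Units.** The source literature labels the same Lp-PLA2 numbers mg/l,
  ng/ml and µg/l interchangeably. ng/ml ≡ µg/l numerically, and the numbers
  attached to the mg/l label are on the same scale, so the package treats
  all three unit strings as synonyms for one canonical scale (µg/l) and
  never rescales. Converting mg/l → µg/l literally (×1000) would contradict
  every published value.
* **Band edges.** The published prose gives the low band both as
  "50–70 points" and as "< 70 points". The package adopts < 70 with no
  lower bound (indices below 50 are valid and classified low), 70–100
  inclusive as medium, > 100 high. The bundled cohort table (minimum medium
  73, maximum medium 98, minimum high 102) is consistent with either edge
  convention, so the choice is fixed by documentation rather than data.

## Duplex grading

Stenosis severity is graded from PSV and EDV against the consensus velocity
criteria. The consensus cutoffs are not restated in the source study, so the
standard published values are embedded as overridable defaults: PSV 125 and
230 cm/s, EDV 40 and 100 cm/s for the < 50% / 50–69% / ≥ 70% boundaries.
Two conventions are fixed here because the source is silent: a velocity
exactly on a cutoff belongs to the more severe category, and when PSV and
EDV disagree the more severe grade wins — both conservative for a risk
tool. `near_occlusion` and `occlusion` are representable (they can arrive
via input files) but are never produced by velocity grading, which cannot
distinguish them.

## The bundled cohort table

`strokestop/data/table3.csv` transcribes the published 70-patient table:
per patient the printed index, Lp-PLA2, plaque class and stenosis percent.
The symptomatic/asymptomatic flag is omitted because its per-row assignment
is typographically ambiguous in the source; `group` is left unset and any
group-conditional statement is treated as qualitative only. The printed
index is kept in a dedicated `printed_index` field, never overwritten by a
computed value; fixture round-trips (implied SDVR → formula → printed
index) are therefore explicit. A SHA-256 checksum test guards the file
against drift.

Stenosis percents in the table are single printed numbers and are compared
directly by the strict subgroup filters (`stenosis > 70` excludes a row
printed as 70).

## Statistics

Contingency tables use the plain Pearson chi-square without continuity
correction (matching the calculator tool named by the source study's
statistical methods), df = (r−1)(c−1), upper-tail p. Group comparisons use
classical one-way ANOVA, Tukey HSD on the studentized range, and Pearson
correlation; all four delegate to scipy.stats behind the package surface,
and the test suite checks the chi-square against an independent
expected-counts brute force.

Two printed p-values are **not** reproduced by these tests on the printed
counts and are reported as discrepancies rather than reconciled: the
echolucent symptomatic-vs-asymptomatic comparison (printed 0.025; Pearson
chi-square on the printed 3/6/1 vs 0/2/6 counts gives χ² ≈ 8.45, p ≈ 0.015)
and the echogenic comparison (printed 0.352; computed ≈ 0.31). The exact
grouping or test variant behind the printed values is not recoverable.

## Synthetic cohorts

The simulator emulates the study's structure: 30 symptomatic and 40
asymptomatic stenosis patients plus 20 stenosis-free controls. Per group it
draws, independently per patient,

* plaque class from the group's reported mixture (symptomatic
  10/12/8 echolucent/heterogeneous/echogenic of 30; asymptomatic 8/14/18
  of 40),
* a stenosis band (< 60%, 60–< 80%, ≥ 80%) from the group's reported band
  mixture (8/14/8 of 30; 0/14/26 of 40), then a stenosis percent from the
  empirical percents of the bundled table within that band,
* SDVR from the empirical pool of implied SDVRs of the bundled table
  (printed index × SF / Lp-PLA2), stratified by stenosis band — the only
  defensible velocity-ratio data source available, since raw velocities are
  not published,
* Lp-PLA2 from a truncated normal centred on the reported group mean
  (285.30 / 274.35 µg/l). The reported ±2.05 and ±3.38 are read as standard
  errors of the mean: with n = 30/40 that gives sampling SDs of ≈ 11.2 and
  ≈ 21.4 µg/l, consistent with the reported 252.7–328.6 cohort range,
  whereas reading them as SDs would make that range unreachable. Draws are
  truncated to [252.7, 328.6]. The truncated-normal family is a modelling
  choice of this package, not a claim of the source.

Controls draw Lp-PLA2 uniformly from 205–240 µg/l and carry no plaque,
stenosis or velocities; they are never scored. Identical config + seed
yields an identical cohort (one `numpy` Generator stream, fixed draw
order); recorded values are exact at CSV serialization precision (SDVR to
6 decimals, concentrations to 4).

**What the generator does and does not emulate.** It matches the group-level
margins (sizes, plaque mixture, stenosis-band mixture, Lp-PLA2 location,
spread and range) but draws plaque, stenosis and Lp-PLA2 independently
within a group, so it does not reproduce within-patient correlations (e.g.
that echolucent plaques tend to co-occur with higher Lp-PLA2). A passing
recovery test shows the sampler is calibrated to its configured margins —
not that real cohorts look like this joint distribution.

A consequence worth stating: with these margins the simulated symptomatic
group's mean index exceeds the asymptomatic group's by ≈ 9 points on
average (analytically ≈ 135 vs ≈ 126), but the replicate-to-replicate SD of
that difference at n = 30/40 is ≈ 16 points, so the ordering holds in only
about 71% of seeded replicates. The asymptomatic group's much higher
stenosis severity (26 of 40 at ≥ 80%) pulls its SDVR draws up, offsetting
its lower Lp-PLA2 and more stable plaque mix. A stable ordering across
nearly all replicates would require the within-group correlations the
generator deliberately does not invent.

## Numerical choices

* Band edges are closed on the medium band (70 and 100 → medium).
* Risk-map band areas are computed in closed form by integrating the
  clipped iso-risk hyperbola lp = threshold × SF / sdvr over the rectangle;
  the three areas partition the rectangle exactly.
* Index histograms use half-open bins [k·w, (k+1)·w), default width 10
  points from 0 (the published histogram's bin edges are not stated; 10 is
  this package's default and is configurable).
* Validation reports (it never raises); strict-mode readers abort on any
  reported violation. Degenerate inputs (non-positive velocities or
  concentrations, zero-margin tables, constant samples) raise typed errors
  before any library call.
* Chi-square oracle testing: exhaustive over all 2×2 tables with entries
  ≤ 6 plus seeded uniform samples of 2×2 and 2×3 tables with entries ≤ 20
  (exhaustive 2×3 enumeration is ≈ 8.6 × 10⁷ tables and is not attempted).
* Simulation-backed tests use fixed seeds and modest sizes chosen for a
  laptop-scale run: recovery at n = 10,000 draws, ordering rates over
  1,000 replicate cohorts.

## Known limitations

* The index is uncalibrated: no follow-up outcome data exist behind it, so
  nothing here estimates an absolute stroke probability or incidence rate.
* The simulator's independence assumption (above) understates real
  between-variable correlation.
* Velocity grading covers only the PSV/EDV consensus criteria; ICA/CCA
  ratio criteria, waveform analysis and imaging are out of scope.
* The bundled table's symptomatic/asymptomatic labels are unavailable, so
  per-group statements can only be checked on simulated cohorts.
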