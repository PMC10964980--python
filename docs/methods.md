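# Methods

Units everywhere: millimetres, milliseconds, millivolts.  Conduction
velocity (CV) is stored in m/s, numerically equal to mm/ms.  Vertex indices
are 0-based; all times are relative to the pacing-source onset.

## Surface model

The anatomy is a developable "opened RV" sheet — a structured triangulated
rectangle (default spacing 1 mm) with labelled non-conducting regions:
tricuspid annulus, pulmonary annulus, VSD patch, RV incision, surgical
scar.  All quantities of interest (activation times, geodesic radii,
corridor widths) are surface-intrinsic, so a flat sheet loses nothing; a
cylindrical variant exercises wrap-around connectivity.  Structure shapes
are stylized rectangles: the real per-patient patch geometry is not
published, and nothing downstream depends on their outline, only on the
corridors they bound.

## Activation solver

First-arrival activation is computed by Dijkstra shortest paths on an
extended edge stencil: axis edges, both cell diagonals, and knight-move
edges (length sqrt(5)·h).  Edge traversal time is length divided by the
harmonic mean of the endpoint CVs — a first-order eikonal approximation.
The extended stencil matters: with triangle edges alone the graph metric
over-estimates distances by up to tens of percent in unlucky directions and
no amount of refinement fixes it; with 16 directions the worst-case angular
error is 1/cos(13.3°) − 1 ≈ 2.7%, verified in the tests against straight-
line distances at uniform speed.  Knight edges are admitted only when the
two lattice vertices flanking their midpoint are conducting, so they cannot
tunnel through thin non-conducting barriers; ablation-line editing removes
every graph edge whose segment crosses the polyline (flat sheets only —
lines should run between lattice columns, not through vertices).

## Electrogram model

Each mapping site gets `n_bipoles` (default 4) orthogonal bipoles at 3 mm
spacing.  The best-aligned bipole carries the full site amplitude; the
others are attenuated by random orientation factors in [0.3, 0.95].  The
signal is a sum of sharp biphasic Gaussian-derivative wavelets
(sigma 0.8 ms) sampled at 2000 Hz (floor 1000 Hz) plus white noise
(default 0.02 mV in exploratory runs, 0 in the validation cohorts):

* a **primary wavelet** placed so that the time where its |slope| last
  exceeds the annotation threshold (0.1 mV/ms) equals the true LAT of the
  nearest conducting vertex — the last-deflection offset encodes the local
  activation time by construction;
* **fractionation**: when activation within the 5 mm sensing radius spreads
  over ≥ 18 ms (slow zones), up to four low-amplitude wavelets are added at
  7.5 ms spacing before the primary — enough separation to resolve as
  distinct deflections at the default thresholds;
* **split potentials**: when the sensed activation times cluster with an
  isoelectric gap > 25 ms (across a line of block the two sides differ by
  tens of ms), the earlier cluster contributes its own component;
* **amplitudes**: normal myocardium 1.8–6.0 mV peak-to-peak; sites within
  2 mm of a non-conducting structure attenuated ×0.2–0.6; sites over
  scar/patch see only a 0.15–1.0 mV far-field component, below the 1.5 mV
  abnormal-voltage threshold.

Only components at or before the local LAT are synthesized: physically, the
electrode's own myocardium dominates its bipolar signal and later activity
of neighbouring slow tissue is attenuated below the deflection floor.  On
noiseless signals the annotation therefore recovers the true LAT exactly on
myocardial sites; sites over scar carry only far-field timing, and their
"true" local activation is undefined — the recovery guarantee excludes
them.

## Annotation

Deflections are maximal runs with |slope| ≥ 0.1 mV/ms (runs separated by
< 2 ms merge, so the zero-slope instants at wavelet extrema do not split a
deflection) and voltage excursion ≥ 0.05 mV.  LAT = offset of the last
deflection; split potential iff the largest inter-deflection gap strictly
exceeds 20 ms; fractionated iff ≥ 4 deflections.  Voltage classes: < 1.5 mV
abnormal (strict), < 0.5 mV dense scar — the 0.5 mV surrogate replaces the
clinical high-output pacing non-capture test, which has no synthetic
counterpart.  The clinical workflow's manual offline re-annotation is
replaced by deterministic re-annotation under a stricter config.

## Map building

Points project to their nearest vertex (Euclidean, max 5 mm; farther points
are unused).  LAT interpolation is inverse-distance-squared over geodesic
distances within a 5 mm fill radius, exact at point-bearing vertices
(coincident points average).  The mapped LAT range is split into eight
equal-width isochrones over the map's own span — not a fixed window — with
the last bin right-closed; total activation time = LATmax − LATmin.

## Features and isthmus analysis

* **Deceleration zone**: connected component (triangle adjacency) of
  vertices seeing > 3 distinct isochrone indices within a 10 mm geodesic
  radius ("1 cm radius" read literally as a radius; distinct-index counting
  chosen over boundary-crossing counting), minimum area 10 mm² against
  single-vertex speckle.
* **Extreme slowing**: peak count ≥ 6 plus a majority of fractionated
  member sites — the clinical description ("thinner crowding, continuous
  fractionated activity") gives no numbers, so both knobs are exposed.
* **Line of block**: edges with an LAT jump above one bin width flanked by
  a split-potential site within 3 mm, chained into polylines; reversal is
  confirmed when the mean least-squares LAT gradients of the two sides have
  negative inner product.
* **Wave-front collision**: vertices with two earlier neighbours in
  near-opposite directions (inner product < −0.9, drop ≥ 1 ms), components
  of ≥ 3 vertices.  Collisions are reported as warnings, motivating paced
  mapping; zones are not auto-rejected.
* **Isthmus delineation**: for each taxonomy pair present, width = minimal
  boundary-to-boundary distance; the axis runs through the bottleneck
  midpoint perpendicular to the width direction, clipped to the overlap of
  the two structures' footprints.  Conduction time = |median LAT in a 3 mm
  cap at exit − entry| (median resists single-point noise); CV = geodesic
  axis length / conduction time, full precision internally, rounded only in
  reports (1–2 decimals as in clinical tables).  SC-AI iff CV < 0.5
  strictly.  Isochrones/cm counts distinct indices along the axis (the
  area-based alternative is unspecified in the clinical description) per cm
  of axis.

On multi-corridor maps a corridor's far side can be pre-excited through a
parallel corridor, biasing the side-to-side conduction time low and the CV
estimate high (the default map's AI3 reads 0.35 m/s against a planted
0.15).  This is a property of the measurement definition, shared with the
clinical procedure; the controlled single-corridor cohort is therefore the
quantitative validation vehicle, and there CV recovery is within ~8–11%.

## Validation statistics

Confusion metrics report undefined ratios as undefined (never 0); F score
is used because SC-AIs are the minority class.  AUC comes from the
trapezoidal ROC (rank-midpoint ties, equivalent to Mann-Whitney; via
scikit-learn, pair-counting oracle in tests).  Spearman rho is the Pearson
correlation of mid-ranks with a seeded ≥10 000-permutation two-sided
p-value.  Rank-sum tests use the exact null for groups ≤ 10 (normal
approximation above); Fisher's exact for 2×2 tables; two-sided throughout,
alpha 0.05, no multiplicity correction.  The published cohort counts
(11 SC of 27, 10/11 with DZ, 0/16 without) give sensitivity 10/11 ≈ 90.9%,
specificity 100%, and F = 20/21 ≈ 0.952; the 0.94 printed as "accuracy"
for the same counts is not reproducible from them, so the package reports
the full-precision F and treats 0.94 as a lower bound.

## Study conditions of the synthetic cohorts

The single-corridor study plants an 18 mm corridor (the worked-example
isthmus length) of width 12 mm in a 136 × 50 mm sheet, background CV
1.2 m/s (the non-SC isthmus median), left-edge pacing, 20 sites/cm²,
noiseless annotation; 28 corridors with CVs uniform on [0.1, 1.5] m/s.
These are not arbitrary: under the width law the crowding criterion fires
when corridor span/bin ratio exceeds ~2, i.e. when
`18/v > 2·(T₀ + 18/v)/8` with T₀ ≈ 110 ms of background activation —
placing the DZ threshold just above 0.5 m/s, which is the premise of using
">3 isochrones/cm radius" to find SC-AI in the first place.  Measured on
the implementation, the transition sits at ~0.51 m/s: sensitivity is 100%
by construction and the only possible false positives are corridors planted
in (0.50, ~0.52).  With 0.05 mV noise the specificity and the crowding-CV
correlation degrade (≈ 88% and rho ≈ −0.6 on a 12-corridor cohort) because
annotation jitter widens the apparent activation span; this is reported by
`analysis/05_cohort_validation.py`.

What the generator does **not** emulate: 3-D ventricular geometry and
transmural conduction, anisotropic fibre fields, far-field QRS referencing,
respiratory/contact artefacts, catheter-specific interpolation of the
clinical system, and programmed stimulation/inducibility.  Passing the
recovery properties shows the *pipeline logic* is sound under the stated
signal model — not that the thresholds would transfer unchanged to patient
data.

## Numerical choices and degenerate inputs

Equal-LAT maps raise a degenerate-range error; corridors with axis < 5 mm
refuse isochrones-per-cm grading; a zero conduction time refuses a CV;
empty bipole sets, one-class ROC inputs, constant rank vectors and empty
groups raise.  Best-bipole ties resolve to the lowest index.  All
randomness flows from one root seed through named substreams (site
sampling, electrogram draws, cohort CVs), so a fixed seed reproduces every
artifact bit-for-bit; permutation p-values carry their own seed.

## Known limitations

Graph geodesics carry ≤ 2.7% metric error; corridor endpoint caps mix
corridor and background tissue, biasing conduction time slightly low
(≤ ~10% CV error at the defaults); block-line chaining can fragment a
single anatomical line into segments; the cylindrical variant does not
support ablation-line editing; isochrones/cm is quantized (small integer
counts over a 1.8 cm axis), which flattens the crowding-CV correlation on
small cohorts.
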