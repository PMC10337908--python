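# Methods

## Mechano-NPS model

### Channel geometry

The default `ChannelGeometry` is the single-node device used for nuclear
measurements: channel height 9.9 µm; sizing segment 700.4 × 5.9 µm
(L × W); node 80.4 × 50.4 µm; contraction segment 700.4 × 2.9 µm; 6 V DC
drive; 7 kPa non-pulsatile pressure.  All lengths are in micrometres,
currents in nanoamperes, times in seconds.

### Sizing relation

A particle of diameter d in a rectangular segment of width w, height h
and length L blocks a fraction

    ΔI/I = d³ / (D_e² L) · 1 / (1 − 0.8 (d/D_e)³),    D_e = √(4wh/π),

the canonical node-pore relation with the standard large-particle
correction.  The inversion (`size_from_pulse`) solves the strictly
monotone forward relation by bracketed root finding (Brent, tolerance
1e−9 µm) rather than the closed form, so a swapped-in forward relation
(e.g. a recalibrated correction factor) continues to invert correctly.
A multiplicative calibration constant (default 1) absorbs device scale
and is fit by `calibrate_with_beads` so that monodisperse reference
spheres recover their nominal diameter; dispersion of the bead pulse
depths beyond 20 % of their mean raises a `CalibrationWarning`.

### Transit-time model (simulator)

The simulator moves particles at the carrier flow speed v through the
sizing segment (t_s = L_s/v) and node, and slows them in the contraction
segment:

    t_c = (L_c / v) · (1 + k · ε / (1 + softness)),    k = 2.

`softness` is the generator's dimensionless deformability (0 = rigid);
ε is the applied strain.  A rigid particle resists deformation and is
slowed the most; softness strictly shortens t_c toward the unstrained
transit time, and an unstrained particle (d ≤ w_c) is not slowed at all.
This is the simplest monotone map satisfying the assay's qualitative
contract — stiffer nuclei take longer in the contraction — and all wCDI
assertions in the test suite bind only to that ordering, never to the
constant k.

The node's residual blockade in the simulator uses the node's effective
diameter with the full sensing length (L_s + L_node + L_c): the wide node
recovers the current nearly to baseline, which is what the event
segmentation relies on.  Noise is i.i.d. Gaussian; no 1/f or drift term.

### wCDI

The deformability index is instrument-defined and is treated as a
pluggable strategy (`compute_wcdi(..., formula=...)`).  The shipped
default is

    wCDI = L_c · h · t_s / (d_n² · t_c),

a dimensionless, size-normalised inverse contraction transit time,
strictly decreasing in t_c at fixed size.  Any admissible replacement
shares that monotonicity, which is all the suite asserts.  Nuclei with
d_n ≤ w_c carry ε = 0, are flagged `included = False` and excluded from
wCDI summaries.

### Event detection

* Baseline: two-pass estimate.  Pulses only deflect the current
  downward, so the median of the upper mid-range band gives a first
  baseline; a second median restricted to the noise cloud around it
  removes the residual bias from shallow pulse samples caught in the
  band.
* Noise: the median positive deviation above the baseline divided by
  0.6745 (the Gaussian half-sample median).  Positive deviations cannot
  be contaminated by the (downward) pulses, unlike a whole-trace MAD.
* Detection: samples below baseline − k·σ (default k = 5) form runs;
  runs separated by ≤ 50 samples are merged (threshold flicker around a
  marginal node blockade), runs shorter than 10 samples are discarded,
  and nearby runs are clustered into transits when their gap is at most
  half the longest run in the cluster.
* Segmentation: within each transit the sizing and contraction windows
  are the first and last regions whose blockade depth exceeds half the
  25th-percentile depth of the span.  This split keys on the node's
  near-baseline recovery and is insensitive to whether the node itself
  crossed the detection threshold — the failure mode of a pure
  threshold-gap rule at very high SNR.
* ΔI_S is baseline minus the mean over the central 50 % of the sizing
  window (plateau mean, not minimum), for noise robustness.  Events
  truncated by a trace edge or lacking a second sub-pulse are dropped
  with a warning.

With ≥ 20 samples per sub-pulse and SNR ≥ 30 the pipeline recovers
(d_n, t_s, t_c) within 5 % for ≥ 95 % of simulated events and never
miscounts non-overlapping transits; both properties are exercised in the
test suite.

## Synthetic-data generators

The generators emulate the statistical structure of the study's raw
data, with explicit seeds (one `numpy` generator per call, never global
state):

* **Nucleus populations**: Gaussian diameters, default mean 3.41 µm
  (chosen so the average applied strain in the 2.9 µm contraction is
  0.15, the assay's operating point) and SD 0.25 µm, a realistic spread
  for late-prophase meiotic nuclei.  Calibration beads: 2 ± 0.05 µm,
  rigid.
* **NE rings**: a Gaussian radial cross-section (FWHM = ring width)
  modulated by an angular profile of base intensity plus n von Mises
  patches (emulating SUN-1 patches) and one von Mises cap (emulating a
  polarised ZYG-12 cap).  Ground truth is returned on a 1° grid; the
  image integral matches the analytic profile integral to 2 % at zero
  noise.
* **Collapse series**: NE size shrinks linearly at `rate_pre` per frame
  until the contact frame and `rate_post` after; SC size is constant
  until contact, then shrinks.  The default spec makes the NE meet the
  SC exactly at the contact frame (4.0 → 3.0 µm over 20 frames at
  −0.05 µm/frame), at the 10-s cadence used for collapse imaging.
* **Gonad layouts**: nuclei uniform along a 60 a.u. axis split across
  3 animals; collapsed flags Bernoulli per zone; stage labels (TZ, MP,
  LP, Dip) from axial boundaries.
* **Detection tables**: stationary / directed / random-walk 3D motion
  plus a common stage drift, 5-s frame interval, identities withheld
  from the detection table and kept in the truth table.

What the generators do *not* emulate — photobleaching, non-Gaussian
camera noise, baseline drift, overlapping transits, segmentation errors
on crowded nuclei — bounds what passing tests show about real data:
they validate the estimators under the stated statistical structure,
not robustness to every acquisition artefact.

## Imaging quantifications

* **Ring sampling**: mean of 5 bilinear samples across the ring width at
  each angle (1° default grid), background (image mode) subtracted and
  floored at 0.  Coordinates are 0-based pixel centres, x rightward,
  y downward; angles counterclockwise from +x in [0, 360).  Where the
  original workflow traced the periphery by hand, the ring here is
  parameterised (centre/radius, optionally refined by `fit_ring`'s
  small grid search maximising mean ring intensity).
* **Clustering index**: sample (n−1) SD over mean — angular sample
  counts are modest, so the unbiased SD is used; invariant to intensity
  scaling and circular rotation.
* **Polarization**: the peak is found on a 5° circular moving average
  (ties break toward the smallest angle), the raw profile is rotated so
  the peak sits at 180°, and divided by the single raw sample at the
  rotated 0° position.  Folding averages θ with 360° − θ onto [0°, 180°].
  The operation is idempotent and equivariant to input rotation.
* **Tracking**: greedy nearest-neighbour frame-to-frame linking after
  subtracting the known reference drift; links beyond the displacement
  gate start new tracks.  Greedy (not globally optimal) assignment is
  sufficient for sparse patches on a nuclear surface; the gate is the
  config hook if density increases.
* **Volumes**: Otsu threshold, 26-connected 3D components, voxel count ×
  voxel volume; components touching the stack boundary are flagged as
  lower bounds.
* **Collapse alignment**: contact = first frame with NE − SC ≤ tol
  (default 1e−6 for noise-free series).  Because a positive tolerance
  makes the first crossing systematically early under noise, the frames
  up to the crossing — which are all pre-contact — are refit with a
  line and the contact moved to its zero crossing, accepted only when
  the extrapolation stays within half the crossing index; pass
  `refine=False` for the bare rule.  Both series are normalised by
  their final-frame value ("size" of the segmented object is otherwise
  ambiguous — diameter, perimeter and area differ only by scale, which
  normalisation removes).  Shrinkage rates are OLS slopes per frame, fit
  separately on the frames up to and from contact.

## Germline scoring

Zones are equal-length intervals of the distal→proximal axis, half-open
with the last zone closed (a deterministic boundary rule; position
exactly on a boundary belongs to the next zone).  Pairing: ≤ 1 HIM-8
focus = paired; a count of 0 passes the threshold but is flagged for
review.  Synapsis: SYP-1/HTP-3 colocalization fraction ≥ 0.95
(configurable; no published quantification rule exists for "complete"
synapsis, so the threshold is a documented choice, not an assertion).
For real data a collapse call is provided as volume < 0.5 × the zone
median (flagged as a package decision).  Per-zone output reports the
pooled fraction (NaN for empty zones, never 0) and the unweighted
across-animal mean ± sample SD.  Zone-wise proportion comparisons use
the 2×2 chi-square test with continuity correction, falling back to
Fisher's exact test when any expected count is below 5, with BH
adjustment across zones.

## Statistics

Benjamini–Hochberg, Welch's heteroscedastic ANOVA and Games–Howell are
implemented from their published formulas (library coverage for the last
is thin) and cross-checked in the tests against an exhaustive step-up
oracle, statsmodels, and pingouin; the Games–Howell tail uses scipy's
studentized-range distribution with Welch–Satterthwaite degrees of
freedom per pair.  Mann-Whitney (normal approximation with tie
correction), one-way ANOVA, pairwise Welch t tests and two-way ANOVA
dispatch to scipy/statsmodels.  Power for two-sample t tests follows
Cohen's d via the noncentral t distribution.  Note that BH adjustment is
*not* idempotent in general (re-adjusting adjusted values can raise
them further); only dominance and order preservation are guaranteed.

## Problem sizes and determinism

Simulated studies in the tests use 50–100 particles per condition,
600-nucleus gonad layouts, 10,000-replicate nulls for the Welch
calibration and 5,000 for the Games–Howell familywise check (with
critical values interpolated on a degrees-of-freedom grid, since exact
studentized-range quantiles are expensive).  Every simulation takes an
explicit integer seed; identical (spec, seed) yields byte-identical
output, and a pipeline run is a pure function of (config, seed).

## Known limitations

* The wCDI default is a size-normalised inverse transit time with the
  correct units, monotonicity and exclusion rule; absolute wCDI values
  are therefore comparable within this package but not across
  instruments without plugging in the instrument's own formula.
* Event detection assumes non-overlapping transits and a single node;
  multi-node devices and coincident transits are out of scope.
* The tracking linker is greedy; dense fields with crossing
  trajectories would need global assignment.
* Zone scoring takes focus counts and colocalization fractions as
  inputs; detecting them in raw images is out of scope.
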