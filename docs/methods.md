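# Methods

This note documents the models, estimators and numerical choices behind
`ictalmeg`, and what the synthetic validation does and does not establish.

## Forward model

The head is a homogeneous conducting sphere (default radius 96 mm) in a head
frame with origin at the midpoint of the preauricular points, x toward the
right preauricular point, y toward the nasion, z up. The magnetic field of a
current dipole follows the Sarvas closed form; two exact consequences —
radial dipoles and dipoles at the sphere centre are silent — serve as
machine-precision self-tests of the implementation. Sensors are radial
magnetometers on a Fibonacci lattice over the upper hemisphere of a 120 mm
helmet (275 channels by default, mirroring a whole-head axial-gradiometer
layout at the geometry level only; no vendor gradiometer balancing is
modelled).

The scanning grid is a cubic lattice clipped strictly inside the sphere;
6 mm spacing yields ~17,100 voxels. Units: mm for coordinates, tesla for
fields, A·m for dipole moments.

## Inverse solution and accumulated source imaging

Source time courses are estimated with a linearly constrained
minimum-variance (LCMV) scalar beamformer. For voxel r with free-orientation
lead field L (sensors × 3) and regularized data covariance C, the
orientation u is the eigenvector of the smallest *non-null* eigenvalue of
M = LᵀC⁻¹L, restricted to the row space of L so the magnetically silent
radial direction can never be selected; the weights are
w = C⁻¹Lu / (uᵀMu), which satisfy the unit-gain constraint wᵀLu = 1
identically. Diagonal loading defaults to 5% of the mean sensor variance.
Voxels with an entirely silent lead field (the sphere centre) receive zero
weights rather than an error.

Accumulated source imaging sums the source activity over the analyzed
segment. The literal accumulation of signed oscillatory activity cancels to
near zero over whole cycles, so the default accumulates |Q(r, t)| and the
signed sum is retained as an explicit `mode="signed"` flag recorded in every
map. Accumulation is over the whole segment (no sliding sub-windows); the
predominant location is the single arg-max voxel, with exact ties broken by
atlas priority then lowest voxel index.

## Region atlas

No anatomical atlas accompanies a sphere model, so regions are axis-aligned
boxes in the head frame with a priority order (`src/ictalmeg/data/atlas.json`,
a synthetic parcellation versioned with the package). The thirteen labels are
frontal cortex (FC) with nested medial frontal cortex (MFC) and lateral
frontal (LFL), temporal (TC), temporo-parietal junction (TPJ),
parieto-occipito-temporal belt (POT), precuneus (Pc), posterior cingulate
(PCC), parietal lobe (PL), medial occipital (MOC), thalamus (TH), cerebellum
(CE) and a deep-brain catch-all (DBA). Earlier entries win where boxes
overlap and the catch-all guarantees a total, single-valued labelling. Box
extents are anatomy-inspired but make no claim of subject-level fidelity;
they exist to give localization outcomes a deterministic categorical scale.

## Preprocessing

*Artifact rejection.* The recording is tiled into non-overlapping 1-s
windows; any window whose peak absolute field on any channel exceeds 6 pT
(strict) is masked. Data are kept in place; the mask is honoured by segment
detection and exported for audit.

*Band decomposition.* 4th-order Butterworth band-pass applied
forward–backward (zero phase), with a pad of three cycles of the lower band
edge so narrowband edge transients settle outside the retained samples. A
zero-phase 50 Hz notch (Q = 30) is added whenever a band contains the power
line. The six bands tile 1–250 Hz; on white noise the band powers sum to the
broadband power within 15%.

*Seizure segmentation.* Spike candidates are peaks of the 1–4 Hz global
field power (GFP). Baseline statistics come from the quietest 25% of 1-s
windows — not the whole trace — because a discharge can occupy more than
half of a short recording and would otherwise contaminate the median. The
spike threshold is median + 10·MAD of that baseline: the GFP's MAD is narrow
(it pools tens to hundreds of channels), so 10 MAD sits above the
extreme-value tail of pure-noise GFP peaks (empirically z ≈ 5–16 over 25 s)
while remaining an order of magnitude below discharge spikes (z ≈ 30–350).
Peaks form a run when consecutive intervals match the discharge rate ± 1 Hz,
with one missed spike (a double-cycle gap) tolerated inside a run; runs must
begin and end on single-cycle gaps, edge peaks below 0.3× the run's median
spike height are trimmed (they are the acausal filter skirt of a strong
discharge, not spikes), and a run must contain at least
⌈min_duration · (rate − 1)⌉ spikes with a single-cycle median interval.
Segment boundaries extend from the first spike back, and from the last spike
forward, to where the 0.2-s-smoothed GFP envelope crosses
max(baseline threshold, 0.1× run spike height) — operationalizing "first
spike to last slow-wave offset". Segments longer than 3 s (strict) survive;
overlapping expansions merge; segments never overlap rejected windows.
This deterministic detector replaces the expert visual marking used in
clinical practice.

## Synthetic cohort generator

Each simulated seizure is a train of 70 ms biphasic spikes each followed by
a 250 ms half-sine slow wave at 3 Hz, band-passed to the source's declared
band, RMS-normalized, scaled to a 100 nA·m dipole moment and gated by the
seizure window (0.1 s cosine ramps). Background is 1/f (pink, exponent 1)
sensor noise at 100 fT RMS per channel; artifact windows add a Hann bump of
the stated amplitude on all channels. A coupling coefficient c ∈ [0, 1]
mixes a shared train into every source (√(1−c²)·own + c·shared); how
strongly sources couple during generalized discharges is not well
constrained, so it is a parameter rather than a fixed constant, defaulting
to 0.

Each cohort patient carries two sources: a core discharge source (1–6 Hz,
placed uniformly outside the MFC) that drives seizure detection, and an
alpha-band (8–12 Hz) source carrying the group effect. At full effect
strength the alpha source lands in the MFC with probability 0.7 for
nonresponders versus 0.0 for responders — the observed 7/11 vs 0/13
localization split — and the effect-strength parameter interpolates both
groups linearly toward the pooled rate 7/24 (at strength 0 the two groups
share one placement distribution, the null dataset). Clinical covariates
follow the cohort's reported distributions (onset age discrete uniform on
4–10 y; seizure duration ~N(14.1 s, 4.7 s) truncated; follow-up 12–74
months); treatment-outcome fields are generated per group and the group
label is always re-derived through the responder rule, never assigned.

The default simulation rate is 1 kHz (covering the 8–12 Hz contrast and the
1–4 Hz detection band); 6 kHz — the acquisition-grade rate — is a parameter
for full six-band studies. Rates below 500 Hz are rejected.

What the generator does *not* emulate: gradiometer noise correlation
structure, physiological artifacts (cardiac, ocular, muscle), head movement,
realistic cortical geometry or per-subject anatomy, inter-seizure
variability of discharge morphology. Passing recovery tests therefore shows
the estimators are correct under the stated model, not that they are robust
to everything clinical data contains.

## Statistics

The two-sided Fisher exact p sums hypergeometric point probabilities of all
margin-fixed tables whose probability does not exceed the observed one
(relative slack 1 + 1e-7 for float ties); an exhaustive sweep against an
integer-arithmetic enumeration oracle (all row margins ≤ 30) and a
cross-check against an independent library implementation pin it down.
Degenerate margins return p = 1. The Bonferroni gate across the six bands is
0.05/6 ≈ 0.0083. Clinical t-tests are equal-variance Student tests (the
two-tailed variant), with the n−1 sample SD throughout.

Because Fisher's exact test is discrete and conservative, null-calibration
tests compare the empirical rejection rate against the *enumerated* exact
type-I rate under the binomial placement model (~3% at nominal 5% for 11 vs
13 patients at the pooled placement rate), not against the nominal level —
a uniformity test on discrete p-values would fail by construction.

Networks threshold each pair at p < 0.05 with no within-network multiplicity
correction; K is the number of time samples of the analyzed segment and no
autocorrelation correction is applied — a known simplification that inflates
effective degrees of freedom for band-limited signals. Node selection
defaults to the top 1% of ASI strength; `roi-seeded` adds every voxel of a
named region, which is what the MFC analyses use. The group-level network
comparison (a t-test on local-frontal edge counts per patient) is a
pluggable summary statistic, not a claimed reproduction of any published
network contrast.

## Validation scales

Stochastic suites run at desk scale, chosen once as representative rather
than exhaustive: single-dipole localization sweeps use a 80 mm sphere, 6 mm
grid (~9,800 voxels) and 144 sensors at sensor SNR 5 (noise SD = signal
RMS/5), where the arg-max voxel recovers the true voxel across 50 random
tangential dipoles at radius ≥ 15 mm (deep central dipoles approach the
silent regime and are excluded on physical grounds). Pipeline-recovery
studies simulate 24-patient cohorts at 1 kHz with 30 sensors and a 30 mm
grid (147 voxels, ~6 MFC voxels), about one second per study; the exact
Fisher power of the placement model at the Bonferroni gate is 0.92, and the
observed end-to-end recovery rate across 100 studies matches it. Null
network calibration uses 46 independent Gaussian nodes (1,035 pairs), where
the t-threshold is exact.

## Known limitations

- The sphere model and box atlas are deliberately simple; no BEM/FEM, MRI
  segmentation or co-registration is attempted.
- LCMV partially cancels strongly correlated sources; the ROI-seeded node
  rule mitigates this for network recovery, but amplitude bias for coupled
  sources remains.
- The signed ASI mode is faithful to the literal accumulation formula but is
  near-degenerate for oscillatory sources; magnitude mode is the default.
- `K` as raw sample count overstates independent information for narrowband
  signals; comparisons between conditions with equal K are unaffected.
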