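# Methods

`pgcc` re-creates, end to end and fully synthetically, the measurement and
analysis chain of a two-stage pixelated CZT Compton camera observing prompt
gamma (PG) emission during clinical proton pencil-beam delivery, and the
neural-network event processing that turns its heavily piled-up list-mode
data into usable range-verification images.  This note records the models,
the parameters that matter, the numerical conventions, and what the
synthetic data can and cannot establish.

## Coordinate system and units

The beam travels along +z with z = 0 at the target entrance; y is vertical
(the camera hangs below the beam axis); x is lateral.  Energies are in MeV,
positions in cm, times in microseconds from the start of the delivery.

## Camera model

Two detection stages of eight modules each, four 2 × 2-arranged CZT
crystals per module (64 crystals).  Stage-1 crystals are 2.0 × 1.0 × 2.0 cm,
stage-2 crystals 2.0 × 1.5 × 2.0 cm; 0.25 cm between crystals in a module,
1.0 cm between modules, 2.5 cm between the stages, and the stage-1 top face
30 cm below the beam axis.  The 2 × 4 module layout per stage and the
camera center placed under the treatment isocenter (depth 15.6 cm) are
package choices; the reference camera description fixes the module/crystal counts
and dimensions but not the floor plan.  Crystal anodes sit on the lower
(−y) face.

Energy resolution is 0.5% FWHM at 662 keV scaled stochastically as sqrt(E)
(one reference calibration point); position blur is 0.3 mm per axis.

## Beam and emission model

A 150 MeV-class pencil beam, range 15.6 cm in the plastic target,
lateral spread σ = 0.4 cm.  Emission depth density is dose-like: an
entrance plateau at 0.45 of peak, a Gaussian emission peak (amplitude
0.55, width 0.7 cm) just upstream of the range, and a sigmoid distal
falloff of scale 0.1 cm.  The discrete line spectrum carries the carbon
de-excitation lines (718 keV, 2.0 MeV, 4.44 MeV), the 2.22 MeV
neutron-capture line and a 511 keV annihilation component with assumed
relative intensities 0.15 / 0.20 / 0.30 / 0.25 / 0.10.  Delayed positron
activity is not modeled separately; the 511 keV component shares the beam
emission profile.

Dose rate enters through the monitor-unit calibration 1 MU = 3.668 × 10⁶
protons.  The per-proton yield of *detectable* PGs (emitted toward 4π,
after target attenuation) is not a measured reference number; it is set once to
0.07 so that the pileup-driven false-event fractions produced by the
readout at 20 and 180 kMU/min match measured reference detection rates for
this camera class (about one fifth and one half of recorded doubles,
respectively).  All pileup behaviour scales through this single number.

## Photon transport

A deliberately simplified analytic Monte Carlo, not a general-purpose
particle code: exponential attenuation with analytic CZT cross sections
(total and differential Klein–Nishina for Compton scattering, an E⁻³
photoelectric term normalized at 100 keV, and a linear-above-threshold
pair-production term), straight-ray propagation with slab-method
crystal intersections, local deposition of the Compton electron energy,
photoabsorption terminating the history, and pair production depositing
E − 1.022 MeV locally with the two annihilation photons counted as escaping
energy (they are not tracked further, which keeps single-photon event
labels unambiguous).  Energy is conserved exactly for every history.
Doppler broadening, electron transport, neutron transport and target
attenuation are out of scope.

## Readout and event taxonomy

Each module triggers independently: the first interaction opens a 1.5 µs
collection window; everything above the 50 keV threshold in that module and
window is read out as one event, after which the module is dead for the
4 µs pixel reset.  Events with one interaction or more than three are
counted and discarded; any single deposit above 2.7 MeV vetoes the event.
Interactions are recorded in anode-proximity order (closest to the −y anode
first), which is what creates mis-ordered (MO) events.  Ground truth labels
every event as true double / true triple (with the true chronological
order), false (all interactions from distinct photons), or double-in-triple
(a true double riding with an unrelated single, recoverable).

The training-set shuffle rewrites recorded orders to exact balance: half
the true doubles correctly ordered, the six triple orderings equally
represented (one sixth correct), and — a package extension for class
balance — the six double-in-triple variants equally represented.  Labels
are rewritten so "order" always maps recorded slots back to chronology.

## Event classifier

A fully connected residual network (numpy forward/backward, Adam) over the
12-value feature vector (deposit energy and x, y, z per interaction slot,
third slot zero-filled for doubles), with one 16-class softmax: 3 double
classes (two orderings + false) and 13 triple classes (six orderings, six
double-in-triple variants, false).  Classes structurally impossible for an
event's size are masked out of the softmax.  Desk-scale defaults: 10 hidden
layers of width 64, leaky-ReLU slope 0.01, identity skips every 2 layers,
batch 256, learning rate 10⁻³ halved every 12 epochs, 80/20
train/validation split, all seeded and bit-reproducible.

Internally the estimator expands the 12 inputs into deterministic
physics-informed features before the first layer: per-ordering
initial-energy estimates (deposit-sum and nearest-emission-line
hypotheses), Compton-cosine validity margins, the cone's best angular
agreement with the beam axis and the depth where it occurs,
gamma-ray-tracking energies for the six triple orderings, embedded-pair
descriptors for the double-in-triple hypotheses, pairwise distances and
stage flags.  This featurization is a fixed function of the event — no
labels, no randomness — and substitutes for the representational depth of
a production-scale (hundreds-of-layers) network at desk scale.  With raw features only the
same architecture plateaus a few points lower.

A kinematics-only baseline (choose the ordering minimizing
Compton-consistency violations; no notion of false events) is the yardstick
the network must beat, and does: on clean data the baseline orders doubles
at chance-plus-a-little while the network reaches the high 80s.

## Processing and bookkeeping

Predicted labels drive the four-step cleanup: false events removed, true
events re-ordered into predicted chronology, double-in-triple events
reduced to their predicted embedded pair.  Rate summaries count each
category per proton; "usable" = true doubles + true triples + recovered
pairs, and the correctly-ordered and usable fractions follow the reference
bookkeeping conventions (the reference rate table's two "fractions" use
different denominators — CO/usable at the low rate, CO/raw at the high
rate; both are exposed, neither silently corrected).

## Image reconstruction

Every usable event defines a cone of origin: apex at the first interaction,
axis from the second interaction through the first, half-angle from the
Compton formula with the event's initial-energy estimate (deposit sum for
doubles; gamma-ray tracking via the geometric angle at the middle
interaction for triples).  Kinematically forbidden cones are dropped and
counted.  Energy windows 0.6–4.5, 2.0–4.5 and 4.0–4.5 MeV select events by
estimated initial energy.

Backprojection accumulates, per voxel and per event, a Gaussian kernel in
the angular deviation between the voxel direction and the cone half-angle.
The kernel scale is each event's propagated angular uncertainty,
σₑ = sqrt(2 (σ_pos/L)² + 0.01²) for lever arm L (the 0.01 rad floor absorbs
the much smaller energy-resolution term), and the kernel amplitude is
inverse-variance weighted (σₑ⁻³ = unit-integral Gaussian × 1/σₑ²).  This
weighting is the package's reading of "kernel-weighted" backprojection:
intra-module events have millimetre lever arms whose cone axes wobble by
up to ~0.1 rad, and with equal weights their haze buries the image; with
precision weighting the well-measured cones dominate and the beam path,
entrance and distal falloff emerge.  Equal-weight backprojection remains
available (`weight_exponent=1`).

The default grid is the camera's imaging space: 60 x-slices of 3 mm ×
256 × 256 YZ pixels of 2 mm (51.2 cm; the nominal "50 cm" of a 256 × 2 mm
layout is arithmetically 51.2 cm), z spanning −12.8 to 38.4 cm.  Because
voxels are mutually independent sums over events, profile analyses evaluate
only the central slab (3 x-slices nearest the beam axis × the central-y
pixel row × all depths) — exactly equal to cutting those rows from the full
grid, at a tiny fraction of the cost.

## Profiles and range metrics

The depth profile sums the three x-rows nearest x = 0 in the central XZ
plane versus depth z; the crossfield profile mirrors this at a depth of
10 cm.  PGmax is the depth of the profile maximum; PG80/PG60 are the first
distal depths where the profile falls below 80%/60% of the maximum,
linearly interpolated between voxel centers; profiles that never cross
report the metric as undefined.  CNR = |S_peak − S_distal|/σ_distal with
the peak band ±2 cm around PGmax and the distal noise window at 21–25 cm
depth.  Five-number summaries use Tukey (inclusive-median) quartiles;
range-shift uncertainty is quoted as the replicate IQR.  Because a
five-replicate IQR is itself very noisy, shift magnitudes are judged
against the *pooled* replicate IQR (median-centered deviations pooled over
all shift conditions) in the acceptance suite.

The replicated range study (five independent datasets per condition, the
standard replication protocol for this measurement) uses the 2.0–4.5 MeV window: high-energy selection
tightens the cone-range correlation, and the narrower cones give the
cleanest distal falloff.  Replicates simulate 7 × 10⁷ emissions each —
about 10⁹ protons at the assumed yield, i.e. the deepest-energy-layer
delivery scale such measurements image.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the measured problem — discrete
lines, Bragg-like emission, intra-module pileup with dose-rate-dependent
false/mis-ordered/double-in-triple contamination, anode-order scrambling —
and the pipeline demonstrates the intended mechanism: classifier cleanup
raises usable statistics and image contrast severalfold at the highest dose
rate, and median PG60 shifts track imposed millimetre range shifts within
replicate scatter.  It does not reproduce measured-data numbers: no Doppler
broadening, no neutron/room background (so near-empty images lack the
noise floor that collapses measured CNR in the narrowest energy window),
no detector drift, and a desk-scale classifier.  Accuracies, CNR values
and rate magnitudes are therefore properties of this synthetic system,
comparable in trend but not in value to measurements on real hardware.

## Numerical conventions and degenerate inputs

Kinematically forbidden orderings raise (never clamp); collinear triples
raise on the tracking formula; empty event lists reconstruct to zero images
with a warning; profile grids too small for the three-row sum raise; CNR
requires distal coverage and nonzero distal variance; quartiles are Tukey;
voxel cells are half-open with centers at (i + 1/2)·pitch; ties in
"nearest rows" resolve by stable sort.  All randomness flows from one seed
through named substreams (emission, transport, readout, shuffle, train),
so every dataset, fit and image is bit-reproducible.
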