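# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `egflow`. It is the package's own account of its science;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Problem setting

Electrographic flow (EGF) mapping estimates the spatial propagation of
atrial activation wavefronts from 64 simultaneous unipolar electrograms
recorded on a basket catheter (8 splines A–H × 8 electrodes 1–8). During
atrial fibrillation (AF), repetitive focal activations ("sources") are
candidate drivers; EGF mapping aims to detect them as *divergent
singularities* of the reconstructed flow field and to quantify how often
each is active, while rejecting non-propagating electrical activity (e.g.
subthreshold stimulus artifacts) and passive phenomena (rotational or
convergent flow).

## Grid geometry

Splines are circumferential, so the spline axis is periodic: splines A and H
are neighbours. Electrode numbers run along each spline and do not wrap. All
distances are in grid units (1 = inter-electrode spacing). The "one electrode
distance" localization criterion is the Chebyshev distance with row wrap —
i.e. the 8-neighbourhood of an electrode.

The interpolation/analysis pixel grid places `pixels_per_span = 4` pixels per
inter-electrode spacing: 32 rows (8 splines × 4, exactly periodic) × 29
columns (7 spans × 4 + 1, open ends). A periodic row count is what makes
circular-shift equivariance of interpolation and flow exact; a square grid
with a duplicated seam row cannot satisfy it.

## From voltages to intensity frames

1. Band-pass 30–300 Hz (3rd-order Butterworth, zero-phase), absolute value,
   10-ms moving-average smoothing. This makes deflections "bright" regardless
   of polarity; the band rejects baseline wander and most far-field energy.
2. Per-channel min–max normalization over the whole recording. Normalizing
   per channel makes the intensity invariant to per-electrode gain (contact
   quality scales amplitude, not timing), which is the property worth
   preserving; it also means a low-contact electrode contributes noise-shaped
   intensity, which is why contact is scored separately (below).
3. Frames: each 19-ms frame takes the per-channel mean intensity in its
   window. A 2-s segment yields exactly 105 frames. Frame averaging (rather
   than instantaneous sampling) stabilizes the optical-flow data term.
4. Spatial interpolation of each 8×8 frame to 32×29 pixels with a biharmonic
   Green's-function interpolant, kernel g(r) = r²(ln r − 1), with circular
   row distances (period 8 grid units) and a constant polynomial term under a
   sum-to-zero side condition. The interpolant reproduces nodal values and
   constants exactly and is linear in its inputs; it is precomputed once as a
   (pixels × 64) matrix so per-frame interpolation is a single matmul.
   Interpolated values are clipped to [0, 1] (the RBF may overshoot between
   nodes).

## Flow estimation

Horn–Schunck optical flow with brightness-constancy data term and α²-weighted
smoothness, solved by the classical Jacobi fixed point, with two
modifications appropriate to this domain:

* gradients and neighbour averages wrap on the spline axis and reflect on the
  electrode axis;
* the 104 frame-pair flow fields of a segment are smoothed temporally with a
  centred 3-pair moving average before singularity detection. This is what
  cancels the alternating appear/disappear flow transients of non-propagating
  intensity flashes (stimulus artifacts, far-field QRST), which is the core
  of the subthreshold-rejection behaviour.

Defaults: α = 1.0, ≤ 100 iterations, early stop when the largest flow update
falls below 1e−4 px/frame. These were fixed against known-shift oracles
(translated Gaussian blobs: direction within 10°, magnitude monotone in
sub-pixel displacement). The 104 pairs of a segment are solved as one
vectorized stack; a fused numba kernel computes the identical iteration
(cross-checked to 1e−12 against the pure-numpy reference implementation in
the test suite).

The HS objective decreases monotonically over iterations on test fixtures;
energy is exposed (`hs_energy`) for that check.

## Singularity detection and classification

At every interior pixel the eight ring vectors of the 3×3 window are walked
in counter-clockwise ring order. A singularity is declared when (a) every
ring vector exceeds a noise floor (5% of the field's 95th-percentile flow
magnitude — numerical jitter must not vote), and (b) the ring angles sweep a
net full turn, i.e. the Poincaré index of the ring is ±1. A net 360° sweep
necessarily passes through all eight 45° angle sectors, so this is the
"angles around the point cover 360°" criterion in its noise-robust form; the
test suite verifies exact agreement with an independent brute-force winding
computation over ≥ 500 random smooth fields (≈10⁵ ring evaluations).

Classification uses the mean radial and tangential components of the ring
vectors relative to the centre: outward radial flow ⇒ **active divergent**
(candidate driver); inward ⇒ **passive convergent**; dominant tangential
component ⇒ **passive rotational**. Only divergent singularities are ever
"active" in reports. Touching detections in one frame are merged to the
pixel of maximal |divergence| (label components are stitched across the
periodic row seam).

## Source tracking and activity (SAC)

Per-frame detections are clustered over time: a detection joins the cluster
whose running mean position (circular mean on the row axis) lies within one
electrode distance, nearest first, ties broken toward lower row then column;
a final pass fuses clusters whose means drifted within one electrode of each
other, so a source straddling a cell boundary is not split between two
anchors.

Per-segment activity of a source = 100 × (frame pairs in that segment with a
qualifying active-divergent detection) / 104. The summary SAC is the plain
mean over all segments of the recording (segments where the source is silent
count as zeros). The SAC formula itself is an interpretation — the original
is proprietary — and is isolated in `track_sources` for replacement.

Sources below 10% summary SAC are omitted from the summary map but retained
in `all_sources` for diagnostics; the threshold affects display/reporting
only, never the SAC values. Sources whose anchor lies within one electrode
of a low-contact-flagged channel are marked `unreliable_contact` (never
silently dropped).

The summary map's *flow origin* is the interior pixel maximizing the
time-integrated divergence of the per-segment mean flows — in organized
rhythm this is the focal origin of activation (the sinoatrial-node analog).

## Contact scoring

Near-field score per electrode = (median 0.5-s-chunk peak-to-peak outside
ventricular blanking windows) / (median peak-to-peak inside QRST windows,
−50…+250 ms around each ventricular event). Channels scoring strictly below
0.7 are flagged low-contact. Ventricular event times come from annotations
(or, for synthetic data, the generator's QRST schedule); the exact window
construction is a documented default, since only the ratio and the 0.7
threshold are prescribed.

## Synthetic electrogram generator

The generator produces the study conditions with known ground truth; its
defaults are fixed once and are the conditions under which all validation
numbers are computed.

* Sampling 1000 Hz. Unipolar atrial deflection: biphasic (small positive,
  dominant negative lobe), ~20 ms wide — about one frame — with 1.0 mV
  peak-to-peak. Far-field QRST: shared template (sharp biphasic QRS + slow T,
  ~320 ms) at 90 bpm — a ventricularly paced rhythm — 0.4 mV p2p with ±10%
  per-channel gain spread. White noise SD 0.05 mV. Unipolar RA electrograms
  of a few mV with sub-mV ventricular far field are typical of basket
  recordings.
* Wave propagation: activation at electrode e occurs at
  t₀ + dist(e, origin)/cv with wrapped Euclidean distance and conduction
  velocity 30 grid-units/s (≈0.2 m/s at 7-mm spacing — slowed fibrillatory
  conduction; it also keeps inter-frame displacements at the 1–2 px scale
  where single-resolution optical flow is valid).
* Focal pacing: cycle length 100 ms (supra-threshold capture), wavefronts
  reach the whole grid. Sinus-rhythm analog: same centrifugal mechanism at
  1000 ms cycle length.
* Fibrillatory background: transient focal wavelet emitters (Poisson spawn
  1.5/s, exponential lifetimes mean 2 s, per-emitter cycle length
  ~N(180, 20) ms, meandering origins, finite propagation radius U(2, 5) grid
  units standing in for wavefront collision). During capture pacing the
  emitter rate is halved (overdrive suppression analog).
* Dual persistent drivers (spontaneous source mapped while pacing elsewhere):
  each driver's wavefronts reach only electrodes nearer to it than to its
  rival (+0.5 unit margin) — a Voronoi-style collision partition. Naive
  "transparent" superposition of two wave trains is unphysical and
  obliterates both divergence patterns.
* Subthreshold stimulus: 3-ms biphasic 2-mV spike on the single channel
  nearest the site, no propagated deflections, over a fibrillatory (or
  planar/quiescent) background.
* Low contact: the near-field component of listed channels is scaled by an
  attenuation factor; far field untouched. Ground truth records the
  closed-form near/far amplitude ratio.
* Bipolar f-wave generator: organized quasi-sinusoid whose instantaneous
  frequency wanders (control points every ~4 s, SD = the preset's
  frequency SD — each 4-s analysis window sees roughly one frequency offset,
  so the window-to-window DF spread tracks the preset SD), with a per-second
  amplitude envelope, intermittent fractionated salvos (broadband 15–40 Hz
  bursts superposed on a half-amplitude organized component — chaotic
  fractionation has no clean spectral line, and the atrium keeps activating
  near its dominant rate during salvos), and 0.01 mV noise. The envelope
  scale is calibrated by a short fixed-point iteration so the *measured*
  f-wave amplitude of the composite signal equals the preset amplitude: the
  per-animal presets (`animal_A`: 3.92 Hz / 0.47 mV; `animal_B`: 8.4 Hz /
  0.27 mV) fix measured quantities, not internal gains.
* Determinism: every scenario carries an explicit seed; identical scenario +
  seed gives bit-identical recordings. No global random state.

What the generator does **not** emulate: ionic/monodomain tissue dynamics,
anatomic boundaries (crista terminalis, veins), basket deformation and
irregular electrode spacing, electrode drop-out, motion/respiration artifact,
and genuinely re-entrant (rotor) drivers. Passing tests therefore show that
the algorithm chain recovers what this class of kinematic wave model puts in
— focal repetitive drivers vs non-propagating artifact — not that it would
perform identically on in-vivo recordings.

## Spectral metrics and statistics

* Windowing: overlapping 4-s windows at a 2-s step (a 60-s recording gives
  29).
* Dominant frequency: Welch spectrum (2-s sub-windows, 50% overlap, 8×
  zero-padding for peak localization), maximal peak in 3–15 Hz. Pure-tone
  bias is below the 0.25-Hz resolution. A peak carrying < 5% of band power is
  flagged low-confidence; an all-zero window has no DF (reported missing).
* f-wave amplitude: median 0.5-s-chunk peak-to-peak outside ventricular
  blanking. For a pure sinusoid of amplitude a this is 2a; the median makes
  it robust to sparse transients and fractionated salvos.
* SAC pairing: each 4-s window covers two 2-s segments; their activities are
  averaged.
* Regression: OLS line of best fit (statsmodels), reporting r² and the
  F-test p-value of the slope; degenerate zero-variance predictors raise.
  Group comparison: two-tailed Welch t-test (the unequal-variance choice is
  deliberate — per-animal variances differ by an order of magnitude).

## Numerical and degenerate-input choices

* All-equal interpolation inputs short-circuit to a constant image (the
  bordered RBF system would be fine, but the shortcut is exact and cheap).
* Flat (zero-variance) channels normalize to zero intensity rather than NaN.
* Zero ventricular amplitude makes the near-field score +∞ with a warning,
  never a low-contact flag.
* Recordings shorter than 60 s are accepted with a warning and yield
  proportionally fewer segments/windows; shorter than one segment is an
  error.
* Ties in cluster assignment break toward lower row, then lower column.

## Problem sizes

Validation batches run the full pipeline (simulation → intensity → flow →
tracking) on one-minute, 64-channel, 1-kHz recordings: 21 focal-source and
34 subthreshold recordings, ~6–8 s each end to end on one core. These sizes
match the experiment design they emulate; nothing is downscaled.

## Known limitations

* The "modified" elements of the original Horn–Schunck variant are not
  public; wrap-aware gradients + temporal smoothing are this package's
  interpretation (both can be disabled via `FlowConfig`).
* The SAC definition (fraction of frame pairs with a qualifying detection)
  is an interpretation of a proprietary quantity; per-animal SAC
  distributions here should not be compared numerically against clinical
  SAC values.
* Sources sitting exactly on the open column boundaries (electrode columns 1
  and 8) cannot host a full 3×3 detection ring; drivers there are seen as
  flow origins but not as ringed singularities. The circumferential row axis
  has no such blind spot.
* Welch DF at 4-s windows has limited resolution for narrowly separated
  spectral peaks; the 8× zero-padding interpolates but cannot separate them.
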