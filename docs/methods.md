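# Methods

`phototrace` models and measures the photophobic step-up behaviour of
*Euglena gracilis* confined to a shallow circular micro-chamber, reproducing
the full measurement chain of patterned-light behavioural assays: an
agent-based swimming simulator, synthetic bright-field video, swimming-trace
extraction by frame differencing, the trace-momentum (TM) statistic with its
derived ratios, motion-type classification of tracks, and exponential
fitting of the slow adaptation of the population's response.

## The behavioural model

Cells swim in 2-D inside a circular chamber (diameter 2.49 mm; the physical
chamber is 140 µm deep, which confines swimming to a plane). In the dark
every motile cell swims straight with slow rotational diffusion of its
heading (D<sub>θ</sub> = 0.01 rad²/s). Strong blue light triggers one of four
photophobic responses, the cell's *type*:

* **on-site rotation** — the cell spins in place. The body pivots about a
  point near its posterior end, so the centroid gyrates on a circle of
  radius 12 µm while the pivot performs a jittery walk
  (D = 8.5 µm²/s) reflected inside a 40-µm confinement disk around the
  capture point. The resulting 3.9-s trace is a spot.
* **run/tumble** — an immediate avoidance reversal (heading + π ± 60°) at
  light onset, then straight runs interrupted by Poisson tumbles at
  0.125 s⁻¹ (mean 4 per 32-s pulse, matching the observed 3–5 direction
  changes). Each tumble turns the course by ±U[60°, 180°]: a "direction
  change" is a visible turn by construction.
* **circular swimming** — continuous swimming on a circle of diameter
  300–1200 µm.
* **straightforward swimming** — no response (blue-light tolerant).

The response follows a light step-up after a latency drawn from
U[0.05, 0.30] s. The live-cell observation "within 2.0 s" is an upper bound
at the 1.3-s trace-refresh resolution; a sub-second latency is the only
reading compatible with the partial trapping of cells in illuminated
checkerboard squares (with a >1-s latency, cells penetrate ~100 µm into a
square before responding and can never diffuse out again). At light
step-down a responding cell freezes for 2.0 s — the origin of the downward
TM spikes — and then resumes straight swimming. The chamber wall reflects
specularly; track analysis discounts wall turns (below).

**Adaptation.** Each cell carries a fixed propensity rank u ∈ [0, 1). The
population type mixture relaxes as p(t) = p∞ + (p₀ − p∞)·e^(−t/τ) with
τ = 3.0 h; a cell's type is the bucket its rank falls into under the
cumulative mixture ordered rotation → run/tumble → circular → straight, so
cells adapt monotonically toward tolerance. The standard scenario uses
p₀ = (0.90, 0.10, 0, 0) and p∞ = (0.10, 0.55, 0.08, 0.27), which reproduces
the late-cycle mixture (~20 % rotation, 50–60 % run/tumble, <10 % circular,
~25 % straight). Comparative presets encode the evening start (67 %
rotation initially), red-light-only pre-illumination (11 % rotation,
stationary), and nutrient-rich KH culture ((10, 60, 8, 21) %, stationary).

**Speeds.** Initial speeds are drawn uniformly from 50–140 µm/s regardless
of type. Cells that adopt a tolerant type migrate their speed toward that
type's adapted band (run/tumble 50–100, circular/straight 120–180 µm/s) on
the same τ clock; cells still of rotation type retain their initial draw.
This keeps the dark-swimming baseline of the unadapted subpopulation
stationary, so the per-cycle TM decrease ratio is a clean exponential
readout of the mixture; the low speeds of rotating cells seen in real data
are interpreted as a cross-sectional speed–type correlation (slow cells
remain intolerant), not as individual slowing.

## Stimulation protocols

Experiment **A**: 15 uniform pulses of 32 s on / 32 s off, centred in a
26-min segment (5-min dark pads). Experiment **B**: a static checkerboard of
580-µm squares, on for 17 min from segment start, then 9 min dark, 26 min
total. One AB cycle is 55.5 min (a 3.5-min dark pad closes it); the full
protocol alternates A and B eight times. The checkerboard's corner lattice
is anchored at the chamber centre, so a 90° rotation exchanges illuminated
area I and dark area II and the two tile the chamber interior with exactly
equal area.

## Measurement chain

Frames are timed at 3.08 fps (four simulation steps of
dt = 1/12.32 s ≈ 81 ms each), the trace display refreshes at 0.77 Hz (every
fourth frame) and superimposes 3.9 s (12 difference images) per trace.
Traces are |frame difference| > threshold, OR-combined; the default
threshold is 4× the difference-image noise SD (= 4√2 × frame noise SD) when
the noise level is known, else Otsu on the pooled absolute differences.
**TM** is the count of trace pixels inside a region mask (pixels outside
the chamber circle are always excluded). Derived ratios:

* decrease ratio D = (TM_off − TM_on)/TM_off at a pulse, with TM_off taken
  from the adjacent off-phases excluding a 4-s guard after each light-off
  (the freezing spikes would otherwise bias the plateau);
* separation ratio S = mean TM_II / (mean TM_I + mean TM_II), ratio of
  means over the on- and off-durations of experiment B;
* preservation ratio P = mean TM after / before an illumination episode.

**Fast path.** Running the renderer for hours of simulated video is
wasteful, so the pipeline rasterizes trace images directly from simulated
states: swimming cells stamp their oriented body ellipse per frame, rotating
cells stamp the tip-region disk (0.60 × body half-length) that frame
differencing actually leaves of a gyrating body, frozen/stopped cells stamp
nothing. The two free constants of this emulation — the gyration radius
(12 µm) and the rotation stamp radius — were calibrated once on single-cell
rendered stacks so that (a) the fast and full paths give the same spot size
and (b) the spot-to-streak TM ratio matches the published per-cell values
(≈35 : 65 against a 95 µm/s swimmer). On a cycle-1 checkerboard window the
two paths agree on the separation ratio to 0.01–0.03, which is the
pipeline's internal consistency check.

Rendering uses 3 µm/px, a 35 × 10 µm body (within the species range; the
microscope's true magnification is unknown, so absolute pixel quantities
hold only under this documented default calibration), dark cells
(intensity 60) on a bright field (200) with Gaussian noise SD 3.

## Track classification

Detections (connected components of thresholded frames) are linked by
greedy nearest-neighbour assignment gated at 250 µm/s; at assay densities
(20–200 cells per 4.9 mm²) identity switches are rare. Classification over
a 32-s pulse window applies, in order: irregular/excluded (mean speed
< 5 µm/s), rotation (gyration radius < 40 µm), run/tumble (≥ 2 tumble
events), circular (Kåsa circle fit with rms residual < 0.35 × radius,
fitted diameter 150–1500 µm, net signed turning ≥ 3π/2), else straight.

Tumbles are single-step heading changes > 40° relative to the track's
median per-step turn (the detrending keeps smooth circular arcs from
counting); a turn split across two samples is caught by the pairwise sum.
Near the wall (< 70 µm), turns consistent with the specular reflection law
(outgoing = π + 2φ − incoming at contact angle φ, with wall-ward incoming
and inward outgoing) are discounted — wall bounces are not behavioural
direction changes — and net turning is computed from the discounted
increments so chamber-orbiting paths do not read as circles. Tumble
detection looks back 3 s before the pulse so the step-up reversal is
visible against the pre-pulse straight run. These operationalizations were
set against a ≥ 95 % per-type recall requirement on ground-truth cohorts of
each pure type and verified in the test suite.

## Adaptation fitting

Per cycle, the pipeline records D at the 4th pulse of A, type proportions
at the 3rd pulse (classifier on ground-truth tracks), and the B separation
ratios; cycle timestamps are segment midpoints (0.4625 h, 1.3875 h, …).
v(t) = A·e^(−t/τ) + B is fitted by profiled linear least squares with a
multi-start τ grid {0.5, 1, 2, 4, 8} h; the offset is fitted by default
because the decrease ratio plateaus near 0.06 rather than 0. On noiseless
series the fit recovers τ to machine precision; at the observed scatter
(SD ≈ 0.03) the median fitted τ is within 10 % of truth, but a single
8-point fit has an SD of roughly 0.5 h — reporting a median over replicate
runs is essential, and per-run values scatter well beyond the ±0.1 h of the
published 2.9–3.1 h range.

## Problem sizes and protocol decomposition

Measurements use 100 cells for pulse experiments and 200 for checkerboard
experiments, averaged over 8–20 seeded replicates. Because the dark padding
between segments re-mixes cell positions and the adaptation clock is the
only state carried across segments, a standalone segment started from a
uniform population with the clock offset to its in-protocol time is
distribution-identical to the same segment inside a continuous 7.4-h run;
the acceptance computations use this decomposition.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: chamber and checkerboard
geometry, pulse timing, the four motion modes with their published
kinematics, sub-2-s response latency, light-off freezing, and the slow
exponential drift of the type mixture. It does not emulate phototaxis,
flagellar mechanics, intracellular signalling, cell division, 3-D
hydrodynamics, optical point-spread functions, or illumination gradients at
checkerboard square boundaries. Two known consequences for realism:

* **Checkerboard trapping is stronger than in live cells.** Any rotation
  kinematics confined enough to produce the observed 32-s spot traces (and
  hence the D ≈ 0.41 pulse response) traps cells that wander into an
  illuminated square almost irreversibly, so simulated area-I occupancy
  during experiment B saturates near 65 % at cycle 1 and ~43 % at cycle 4,
  above the 57 %/27 % seen in vivo. The live cells evidently escape
  illuminated squares on a ~10-s timescale — short-term habituation under
  sustained light that the four-mode model deliberately omits.
* **The mixture clock is a compromise.** τ = 3.0 h matches the decrease-
  ratio decay, but the published per-cycle type histogram falls faster
  (90 → 40 → 20 % rotation over two cycles); the separation ratios of
  middle cycles therefore correspond to a more-adapted population than the
  standard scenario produces at the same clock time.

Passing tests therefore demonstrate the internal consistency of the
measurement chain and the reproduction of the pulse-experiment quantities;
they do not establish that the B-experiment spatial sorting of live cells
is captured quantitatively.

## Numerical choices

dt ≤ 0.5 s is required; the pipeline locks dt to a quarter frame. Uniform
disk sampling is used for initial positions; reflections fold positions
across the wall once (valid for per-step displacements ≪ radius). The
µm→pixel mapping rounds to nearest pixel centres; translation equivariance
holds for whole-pixel shifts. Degenerate inputs (constant fit series, empty
superimposition windows, zero-TM ratios, empty track tables) raise or are
flagged as documented on each function. All randomness flows from a single
`numpy` Generator per run; identical configurations give bit-identical
outputs.
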