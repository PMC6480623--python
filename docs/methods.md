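# Methods

This note documents the models, assumptions and numerical choices behind
gaitstride, in the spirit of a package's statistical/methods appendix. It
states no empirical result that the test-suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and conventions

Acceleration is in g, force in newtons, time in seconds with
`t = t0 + index/fs` and the first sample at `t0`. Tri-axial samples are
stored column-ordered (ML, AP, VT). The foot sensor keeps its mounting
frame (ML +right, AP +posterior, VT +superior) and is never rotated; its
detector therefore only uses rotation-invariant or sign-stable features.
The raw back frame is (ML +right, AP +posterior, VT +superior); gravity
alignment flips AP into the body convention (+anterior) and applies the
minimal proper rotation (axis–angle) taking the trial-mean acceleration
onto +VT. Heading about VT is left untouched: detection uses only VT and
the ML sign, neither of which depends on heading. The trial mean is used
as the gravity estimate because over whole strides the movement component
averages out; means outside [0.5, 1.5] g abort alignment (the sensor was
plainly not observing ~1 g of gravity). Re-aligning an aligned trial skips
the AP flip and converges to the identity.

Readers accept acceleration in m/s² behind a unit flag (divide by
9.80665). The nominal device rate of ~201 Hz is treated as 200 Hz after
resampling, matching the engine's parameter grid; resampling is polyphase
(`scipy.signal.resample_poly`) so downsampling is anti-aliased.

## Timing assumptions

Steady running between 120 and 240 steps/min bounds the interval between
contralateral ICs to [0.25, 0.50] s and between ipsilateral ICs to
[0.5, 1.0] s; TO occurs no earlier than 0.1 s after the step's IC. These
constants gate both detection-stage containers (`EventTable` refuses
tables violating them) and consolidation.

## Detectors

**Force.** IC = first sample ≥ 10 N following a below-threshold interval;
TO = last sample ≥ 25 N of the stance. Crossing direction conventions
(≥ on the rise, last loaded sample on the fall) are stated explicitly
because thresholds alone do not pin them down. Stances shorter than 0.1 s
are dropped whole (noise, not gait), as are stances whose rise or fall
lies outside the record — their true events are unobservable. Event time
is sample time; no sub-sample interpolation, so force and accelerometer
events share one discrete time base. In whole-trial mode consecutive ICs
below the cadence floor are dropped (configurable off; doubling to 0.5 s
for single-foot plates).

By default the *pipeline* thresholds the force signal unfiltered: the
10/25 N crossings sit two orders of magnitude below stance loads, and a
10 Hz zero-lag filter leaks enough of the stance hump backwards in time to
bias the 10 N crossing earlier by tens of milliseconds. A fully filtered
chain is available via `lowpass_force=True`.

**Accelerometers.** No fixed acceleration threshold appears anywhere.
Candidate peaks are admitted per window by two scale-free rules: (i)
prominence above `k` × a MAD-based spread of the window (k = 1 by
default; the median/MAD pair is used because impact peaks inflate mean and
SD but barely move the median), and (ii) height above the window median of
at least 20 % of the window's maximum excursion above its median. Rule
(ii) exists because zero-lag Butterworth filtering of a narrow impact
transient produces ringing sidelobes whose peak-to-valley prominence is
substantial even though they barely rise above baseline; genuine impact
peaks define the window's excursion while sidelobes reach only a few
percent of it. Both rules are invariant to positive rescaling of the
signal, so candidate times do not depend on sensor gain.

Foot ICs additionally pass a swing-quiescence check: within 0.15 s before
an admitted resultant peak the signal must dip at least the admission
level below the peak, rejecting oscillation peaks riding on a loaded
signal. The check is expressed relative to the peak (not the median) so
that its outcome is robust to which window the peak is seen in.

TO candidates are local minima of VT (peaks of −VT) under the same
admission rules; candidate magnitude conventions are: resultant (foot IC),
VT (back IC), −VT (TO), vGRF (force), matching what consolidation
compares. Detection is deliberately permissive — candidates closer than
the cadence floor are all emitted; arbitration is consolidation's job.

## Sliding windows and consolidation

Windows `[phase + k·shift, phase + k·shift + size)` run until the start
passes the trial end; a final partial window is processed when ≥ 1 s.
Defaults are 200 Hz, 2 s windows, 0.02 s shift; the grid runner sweeps
{50, 100, 200} Hz × {1, 2, 5} s × {0.005, 0.01, 0.02, 0.1, 0.5, 1} s
(54 cells). Candidate uniqueness is keyed on (kind, sample frame) after
snapping times to the grid, so float duplicates from overlapping windows
collapse deterministically.

Consolidation walks IC candidates in time order. A candidate closer than
the cadence floor to an already-retained IC is dropped. For two
consecutive candidates in conflict, "within a reasonable range of the
previously established IC and the next potential IC" is operationalized
as: distance to the previous retained IC and to the next surviving
candidate both within [min, max] separation (a missing neighbour imposes
no constraint). If exactly one candidate is viable it wins; otherwise the
greater magnitude wins, ties to the earlier. The conflict scan advances
one candidate at a time, so chains of close candidates resolve
left-to-right. Per retained IC, TOs at or before IC + 0.1 s are dropped
and the largest-magnitude TO before the next IC is retained (bounded by
the maximum step interval after the last IC); ICs with no admissible TO
are kept as IC-only steps. The procedure is idempotent, which the
property tests assert over randomized pools.

Steps whose IC or TO falls within 0.1 s of a trial edge, or whose stance
could not have completed inside the recording, are marked *provisional*
and excluded from method comparisons (the whole step, not just the edge
event: a half-observable step cannot anchor a timing difference).

`measure_output_rate` reports 1/(wall-time per frame) as a per-frame
distribution; it is hardware dependent and kept out of every pass/fail
decision.

## Comparison statistics

IC matching is greedy nearest-neighbour within ±0.25 s — half the minimum
contralateral interval, which makes assignments unambiguous at any
plausible cadence; ties go to the earlier event. TOs inherit their step's
pairing. A skipped step is charged to the method that failed to find it.
In right-only comparisons (against the foot sensor) left-side steps still
take part in matching — a bilateral method's left steps must not steal a
right match — but unmatched left steps are not charged as skips, and a
matched step assigned "left" counts as a side mismatch. Bland–Altman
summaries use the sample SD (ddof = 1) and 95 % limits mean ± 1.96 SD;
fewer than two pairs flag SD/LoA as undefined. Condition summaries pool
per-step difference arrays across trials of a condition *before* the mean
and SD, so each step carries equal weight.

## The simulator

The generator emulates exactly the structure the detectors assume — it is
a test harness, not a biomechanical model. Defaults describe a typical
steady treadmill run: 170 steps/min (cohorts draw uniformly from the
150–192 steps/min preferred range), GCT 0.25 s, 60 s at 200 Hz with the
plate at 1000 Hz, 0.05 g white sensor noise, ~6 g foot impact peaks
(back peaks half that), 1.5 g TO dips, 0.4 g ML side pulses, 700 N body
weight, and an 8° sagittal tilt of the back sensor emitted in the raw
axis convention so alignment has real work to do. Step times jitter with
SD 1 % of the step period so windows never phase-lock to events; steps
cover the whole duration, as in an excerpt trimmed from continuous
running, and the truth table keeps only complete steps ≥ 0.15 s inside
the record. Stance vGRF uses a two-bump (rearfoot) or single-bump
(forefoot) profile with 35 N boundary samples and zero swing load, which
pins the 10 N up-crossing to the truth IC sample and the last ≥ 25 N
sample to the truth TO sample exactly. All randomness flows from one
seeded generator; identical specs are bit-identical.

What the simulator does *not* model — and hence what passing tests do not
establish about real data: mid-stance foot oscillations, soft-tissue and
harness resonance, gait asymmetries and per-step amplitude variability,
sensor drift/clipping/dropouts, imperfect inter-sensor synchronization,
and any systematic accelerometer-vs-force timing physiology (the real
back sensor feels impacts through the skeleton with its own delay). The
ML side rule in particular is exactly satisfiable here by construction,
whereas on real trunk kinematics it is known to be imperfect.

## Numerical choices

Time comparisons use a 1 µs tolerance; consolidation and validation use
1e-9 s guards. Event CSV times print to 6 decimals (exact on the 5 ms
grid). Trimming rounds `amount × fs` (seconds mode) or `amount × n`
(fraction mode) to whole samples per end; additivity of successive trims
holds exactly for sample-aligned amounts. The Butterworth filter is
designed at order 4 and applied forward–backward (`sosfiltfilt`, even
padding); "order" names the design order, as is common in biomechanics
reporting. Resampled force signals are clipped at zero to preserve the
non-negativity of a magnitude series.

## Problem sizes

The test-suite and acceptance script run at desk scale by design: 1000
randomized force trials for oracle equivalence, 20 (tests) or 10
(acceptance script) trials of 60 s for ground-truth recovery, a 20 s
noise-free triplet for phase invariance and side accuracy, 6-subject
cohorts for offset recovery, and 8–10 s trials in the grid sweep. These
sizes give thousands of steps per check while keeping a full run in
minutes on one CPU.

## Known limitations

The exact per-step operator chain of the original foot/back pattern
descriptions is not fully specified in prose anywhere; the operators here
(resultant impact peak, −VT extremum, ML sign at IC) are declared choices
consistent with the consolidation magnitude conventions, not a
transcription of any reference implementation. The back detector uses VT
only for candidate admission; AP features of trunk-pattern methods are
not used. Left-foot sensors, belt-crossing artifacts, centre-of-pressure
processing and multi-sensor time synchronization are out of scope.
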