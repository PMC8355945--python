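# Methods

## The measurement problem

An echolocating bat in laryngeal flight couples three oscillators: the
wingbeat, respiration, and call emission.  A sound-and-movement tag gives
two views of this system — ultrasonic audio of the calls and heave
(dorso-ventral) acceleration of the wingbeat — and the analysis must join
them at millisecond resolution: which call was emitted at which phase of
which wingbeat, at what source level, in what behavioral context.  This
note documents how each stage does that, what the synthetic data emulate,
and where the design was genuinely open.

## Wingbeat phase from heave acceleration

A flying bat's heave channel oscillates around gravity at the wingbeat
rate.  The sign convention is physical: during the upstroke the wings
push the body down, so acceleration sits **below** g; during the
downstroke it sits above.  We fix g = 9.82 m/s² throughout.

* **Filtering.**  A 255-tap linear-phase FIR (equiripple design, passband
  edge 30 Hz, stopband edge 55 Hz at 1 kHz sampling) applied as a
  centered convolution, so the output is time-aligned with the input
  ("delay-free").  The realized response holds passband ripple < 0.1 dB
  below 25 Hz and > 40 dB attenuation above 60 Hz; taps are normalized to
  exactly unit DC gain so gravity passes unchanged.  Record edges are
  padded by odd reflection, which continues an oscillation smoothly
  instead of folding it back — this keeps the cycle boundary at the very
  first sample detectable.  255 taps (~0.25 s) is steep enough for the
  30 Hz cut while short relative to a behavioral epoch.
* **Cycle detection.**  Downward crossings of g start a cycle (phase 0 =
  start of upstroke), the following upward crossing is phase 180, the
  next downward crossing closes it.  Crossings within 25 ms of the
  previous accepted crossing are rejected (caps the rate at 20 Hz);
  cycles must last 0.05–0.4 s (2.5–20 Hz plausibility) and exceed a
  0.5 m/s² peak-to-trough amplitude, which separates real wingbeats from
  numerical or sensor jitter around gravity.  A record with no crossings
  (bat at rest or on the ground) simply yields no cycles.
* **Phase.**  Interpolated linearly in time, 0→180 between cycle start
  and midpoint, 180→360 to the cycle end.  Among reasonable
  constructions (analytic signal, spectral methods), crossing-anchored
  linear interpolation is the one that *provably* satisfies the mapping
  "acceleration below g ⟺ phase 0–180°" on a clean sinusoid; that
  invariant is tested exhaustively on noise-free synthetic records.
  Other constructions satisfy it only approximately, so this one is the
  package's definition of wingbeat phase.
* **Spectrogram.**  For visual/QC use the stream is anti-alias decimated
  to 100 Hz and short-time transformed (window 128, overlap 100); the
  per-frame peak in 0–50 Hz is tracked and flagged invalid when it does
  not stand well above the frame's median magnitude.

## Call detection and level calibration

* **Front end.**  Causal 4-pole Butterworth high-pass at 10 kHz (a
  physical filter runs forward only), optionally preceded by an FIR
  equalizer built from a measured microphone response CSV.
* **Detector.**  There is no single standard extractor for tag audio, so the detector
  here is an explicit surrogate with all constants exposed: envelope = rectified signal
  smoothed over 0.25 ms; noise floor = median envelope per 10 s block
  (robust because even fast calling is < 3% duty cycle); detections =
  envelope maxima ≥ 20 dB above the floor, separated by ≥ 2 ms.  The
  refractory interval must stay below 4 ms or buzz II trains would merge;
  the guard is enforced at configuration time.  Noisy epochs (wind,
  conspecifics) are excluded via a user-supplied interval mask, not by
  automatic discrimination.
* **Levels.**  Each call's energy flux density (dB re 20 µPa²·s) is
  integrated over the −6 dB window around the envelope peak.  A −6 dB
  window can be read as envelope-based or cumulative-energy-based; both
  are implemented behind one switch and agree to ~1 dB on clean calls;
  envelope is the default.  Windows touching the record edge
  are flagged but measured; windows containing clipped samples are
  flagged so their levels read as lower bounds.  Apparent level → source
  level adds the fixed 14 dB off-axis correction (a scalar: no
  head-movement model).  RMS source level adds 25 dB, the fixed-3 ms
  duration convention (the exact value is −10·log10(0.003) = 25.2 dB;
  the rounded constant is kept for comparability).

## Behavioral segmentation

Call intervals carry the state information.  Default half-open bins
(ms): [4, 7) buzz II, [7, 14) buzz I, [14, 100) multiple calls per
wingbeat, [100, 200) one per wingbeat, [200, 400) one per two,
[400, 600) one per three.  An alternative preset with the 5–7 / 8–14 ms
split used in some figure conventions ships switchable; where the two
sources of bin edges disagree the behavioral definitions win.

* **Captures.**  A buzz is a maximal run of ≥ 5 consecutive calls with
  intervals < 14 ms, extended to the call that starts it; runs separated
  by ≤ 100 ms merge (buzz I pauses should not split an attack).  The
  terminal sub-run with intervals < 7 ms is buzz II; capture time = the
  last buzz call.  By default a buzz I-only run still counts as a capture
  attempt (flag-exposed), since requiring buzz II would silently drop
  aborted attacks.
* **Aerial flag.**  A capture is aerial when wingbeat cycles above an
  amplitude threshold cover ≥ 80% of the half-second before the buzz
  through the capture; without accelerometer overlap the flag is unknown
  rather than false.
* **Commute.**  Maximal buzz-free windows ≥ 100 s in which ≥ 90% of calls
  sit in the wingbeat-locked classes and the median wingbeat frequency is
  6–8 Hz.
* **Approach onset.**  Manual consensus marking of approach onsets by multiple raters is not
  reproducible in code.  The automated surrogate:
  the earliest wingbeat cycle within 5 s of capture from which ≥ 2
  calls/wingbeat holds through to the buzz, with at least two such
  cycles; if never met, the onset degenerates to the buzz start.  Onset
  placement is specified to ±1 cycle.

## Coupling metrics

Calls join cycles by containment of the peak time; calls outside every
cycle land in an "uncycled" bucket — excluded from phase histograms,
retained in interval analyses.  Summed energy per wingbeat adds member
calls in the linear domain, `10·log10(Σ 10^(SL/10))`; empty cycles carry
NaN, never −∞.  Summation uses source-corrected EFD (the +14 dB is a
constant, affecting only the offset).  Capture alignment indexes whole
cycles backward from the cycle containing the capture time; events with
shorter histories contribute missing leading values, and means of summed
EFD are taken in the dB domain.

Circular statistics: the median minimizes the mean circular absolute
deviation — the cost is piecewise linear with knots at the samples and
their antipodes, so the exact minimizer is found over that candidate set
(a 0.25° grid for very large n); a brute-force grid minimizer serves as
the independent oracle in tests.  Quartiles are the 25%/75% cumulative
mass around the median.

The source-level-versus-interval summary bins levels by log-spaced
interval and flags the transition where the bat first backs off its
output: the loud plateau is the median level over ≥ 100 ms bins, and the
flagged pair of bins brackets where the run of weak bins (≥ 6 dB below
plateau) rising from the shortest intervals meets the first loud bin.

## Cross-species arithmetic

Updates per meter = rate / speed; per body length = rate · length /
speed.  The shipped table holds the three printed profiles (tagged bat
0.077 m, 7/150 s⁻¹, 7/2 m/s; sperm whale 16 m, 2/50 s⁻¹, 2/4 m/s; harbor
porpoise 1.5 m, 25/300 s⁻¹, 1/2 m/s).  Ratios are reported unrounded:
whale-vs-bat size-specific search sampling is 16/0.077 ≈ 208 (> 200),
and the bat's capture-vs-search fold is exactly 75 (~70 when rounded).  The allometric regression is evaluated as
printed with mass in kilograms — gram inputs would make it negative for a
34 g bat, so kilograms is the only unit yielding a plausible ~7 Hz.  At
0.034 kg and 7 m/s it evaluates to 7.63 Hz, slightly above the ~7.3 Hz
sometimes associated with these inputs; the formula is implemented as
printed and the residual simply surfaced.

## The synthetic-data generator

The simulator produces the statistical structure the analysis assumes,
not bat biomechanics: no aerodynamic model, no 3-D trajectory, no beam
pattern beyond the scalar 14 dB correction.

* **Accelerometer.**  a_z = g − A(t)·sin φ(t) with per-segment amplitude,
  optional second harmonic at −12 dB (makes spectral peak-tracking
  nontrivial), Gaussian noise, ±8 g clipping.  Wingbeat frequency ramps
  linearly over 0.5 s at segment boundaries, emulating the smooth 6→13 Hz
  rise before a capture.  Records run 20 ms past the behavioral plan —
  a tag keeps logging — so the final wingbeat's closing crossing exists.
* **Audio.**  Each call is a Hann-enveloped linear FM downsweep 80→25 kHz
  (3 ms for search/commute calls per the fixed-duration convention,
  0.5 ms for buzz calls — buzz durations and spectra are not documented
  anywhere, so these are config-exposed choices), scaled so the on-tag
  EFD equals the true source level minus 14 dB, added to a Gaussian noise
  floor, hard-clipped at 121 dB re 20 µPa with the clipped fraction
  reported.
* **Scheduling.**  Wingbeat-locked states place calls at a target
  cumulative phase (center + Gaussian jitter) once per N wingbeats, or
  k ≥ 2 calls per wingbeat spaced 360/k apart; buzz and gleaning states
  place calls by interval (fixed or uniform within a band).  Calls closer
  than 4 ms are pruned — below the fastest interval a bat produces.  One
  master seed drives three independent substreams (schedule, accel noise,
  audio noise); identical seeds give bit-identical truth tables.

### The canonical simulated night

The study conditions are frozen in `echowing.night`: commuting at 7 Hz
with one 82 dB-EFD call per wingbeat (= 107 dB RMS) at phase 176°; 48
aerial captures, each with a three-stage approach (2 calls/wingbeat at
7 Hz and full level → 2/wingbeat at 8.5 Hz, −10 dB → 3/wingbeat at
10 Hz, −16 dB), so the level back-off falls in the ~60–70 ms interval
band; a ~100 ms buzz at 12.5 Hz wingbeat (buzz I at 9 ms intervals, buzz
II at 5 ms, 30 dB below search level).  The full-length night uses
~170 s search bouts, giving ~6×10⁴ calls of which buzz calls are ~1.8%
(< 2%); the audio-rendered round trip condenses search to 2.5 s per
capture so 48 captures of 187.5 kHz audio (~6 min) stay cheap to render
and analyze, which is also the problem size the acceptance script uses.

One deliberate deviation: the per-call phase spread of wingbeat-locked
calls is 30° (white), not wide enough to reproduce the ~135–235°
quartile range of the pooled night by itself.  A white spread that wide
(~74°) would push 17% of commute intervals out of the 100–200 ms class,
contradicting the strict interval-locking of commuting bats; in real
data the wide pooled range comes from mixing tight search calls with
approach and buzz calls spread into the downstroke, and the generator
reproduces it the same way.

### What passing tests do and do not show

Round-trip recovery on this generator exercises the detectors' logic,
calibration arithmetic, and the join between streams under controlled
SNR.  It does not validate performance against echoes, conspecific
calls, wind noise, chewing sounds, tag slippage, or non-sinusoidal
wingbeat waveforms — real-data performance claims need real field
recordings.

## Numerical choices and degenerate inputs

Envelope smoothing 0.25 ms; detection matching tolerance 0.5 ms; empty
call tables and empty cycle lists propagate as empty outputs rather than
errors; phase of a call outside detected flight is NaN; negative
intervals reject the record (time-ordering violation); the interval
histogram's first call is unclassified.  All thresholds named in this
note are keyword arguments or config keys with these defaults.
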