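# echowing

Analysis pipeline for sound-and-movement tag recordings of echolocating
bats, built around one question: how tightly is call emission coupled to
the wingbeat cycle, and how does that coupling break down during prey
capture?

Greater mouse-eared bats (*Myotis myotis*) carrying biologging tags record
ultrasonic audio (187.5 kHz, 16 bit, clip level 121 dB re 20 µPa) and
tri-axial acceleration (1000 Hz, ±8 g).  During commuting and search
flight the bats emit one loud call per wingbeat near the end of the
upstroke; during the terminal buzz of an aerial capture they emit trains
of faint calls at 4–14 ms intervals, decoupled from the ~13 Hz wingbeat.
`echowing` turns the two raw streams into calls, wingbeat cycles,
behavioral states, capture events and coupling metrics — and ships a
ground-truthed tag simulator so the whole chain is testable without any
field data.

## What it computes

**Kinematics** — the heave channel is low-pass filtered (delay-free
linear-phase FIR, 30 Hz cut); wingbeat cycles are delimited by crossings
of g = 9.82 m/s² and mapped to a continuous phase 0–360°, where 0–180°
(acceleration below g) is the upstroke:

```
a_z(t) = g − A(t) · sin φ(t)
```

**Acoustics** — audio is high-pass filtered (4-pole Butterworth, 10 kHz);
calls are detected as envelope peaks ≥ 20 dB above a per-block median
noise floor and measured as energy flux density over the −6 dB envelope
window,

```
EFD = 10 log10( ∫ p²(t) dt / p0² · 1 s ),   p0 = 20 µPa,
SL_EFD = EFD_apparent + 14 dB   (off-axis correction)
SL_RMS = SL_EFD + 25 dB          (3 ms duration convention)
```

**Behavior** — call intervals map onto states: [4, 7) ms buzz II,
[7, 14) ms buzz I, [14, 100) multiple calls per wingbeat (approach),
[100, 600) wingbeat-locked classes.  A capture event is a run of ≥ 5
fast-interval calls; the capture time is the last buzz call.  Commute
segments are ≥ 100 s of buzz-free, wingbeat-locked calling at 6–8 Hz.

**Coupling** — per-call wingbeat phase, per-wingbeat call counts and
summed EFD (energy-domain sum), capture-aligned series over the last ten
wingbeats, circular phase histograms by interval class, and source level
versus call interval.

**Comparative** — sensory updates per meter (rate / speed) and per body
length traveled (rate · length / speed) for bats and toothed whales, plus
the allometric wingbeat-frequency regression
`f = 5.54 − 3.068 log10(mass kg) − 2.857 log10(speed m/s)`.

## Worked example

Simulate a short foraging bout (two aerial captures after commuting
flight) and run the full pipeline on the rendered audio + accelerometer
streams:

```python
from echowing import night

summary, analysis = night.roundtrip_summary(seed=1, n_captures=2, commute_s=30.0)
print(summary["n_detected_captures"], "captures")
print(round(summary["phase_median_deg"], 1), "deg median emission phase")
print(round(summary["commute_sl_rms_db"], 1), "dB re 20 uPa RMS commute source level")
print(round(summary["summed_energy_drop_db"], 1), "dB summed-energy drop in the buzz")
```

prints

```
2 captures
174.0 deg median emission phase
106.7 dB re 20 uPa RMS commute source level
22.8 dB summed-energy drop in the buzz
```

i.e. both buzzes are found, commuting calls sit at the end of the
upstroke (~176°) at ~107 dB RMS source level, and the summed energy per
wingbeat drops ~100-fold in the buzz even though the bat calls ~10× more
often.  The same chain is available from the shell:

```sh
echowing simulate --seed 1 --out sim/        # WAV + accel CSV + truth tables
echowing run --audio sim/audio.wav --accel sim/accel.csv --out results/
echowing compare                             # cross-species update-rate table
```

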