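# mothnav

Moth-inspired olfactory navigation: a puff-based pheromone plume simulator,
a memoryless cast-and-surge flight agent, and a genetic-algorithm
segmentation of 3-D flight trajectories into exploration and exploitation
phases.

## Who this is for

Researchers studying odour-guided navigation — in insects or in bio-inspired
robots — who want to (a) generate realistic plume-tracking trajectories with
known behavioural ground truth, (b) split measured or simulated 3-D flight
paths into casting (exploration) and surging (exploitation) episodes without
hand labelling, and (c) analyse how the exploration–exploitation rate (EER)
depends on distance from the odour source, on the odour pulse rate, and on
flow turbulence.

## The models

**Plume.** Discrete Gaussian puffs ("odour pockets") released from a point
source at frequency *f*, advected by a mean wind (0.25 m/s) plus an
Ornstein–Uhlenbeck fluctuation whose r.m.s. is `turbulence_intensity` times
the mean speed, with per-puff jitter that breaks the train into distinct
pockets.  Concentration is the Gaussian superposition
`c(x) = Σ_j Q_j (2π)^{-3/2} σ_j^{-3} exp(-|x-x_j|²/2σ_j²)`.

**Agent.** A single binary odour sensor (noisy concentration > threshold)
and a noisy local wind vector; the only internal state is a countdown
timer.  Detection ⇒ surge upwind and reset the timer; timer expiry ⇒ cast
crosswind with harmonic sweeps.  Commands pass through an acceleration
limiter, and all sensor inputs carry Gaussian noise with σ = 2% of the
running-average signal.

**Segmentation.**  Five-point-stencil velocities
`v_i = (−l_{i−2} + 8l_{i−1} − 8l_{i+1} + l_{i+2})/12`; per-segment
dispersion score `(1/2π) Σ‖v_i − v̄‖²/(t_e − t_s)`; segments labelled s/o in
strict alternation; the signed sum of scores is maximised over breakpoints
by a genetic algorithm (±1 mutation, one-point crossover,
tournament-with-royalty selection) for each candidate k, and k is chosen at
the elbow of the objective-vs-k curve.  Accuracy against ground truth is
per-sample label agreement; EER is the exploration-sample fraction.

## Worked example

```bash
python examples/03_segment_flight.py
```

```
flight: 459 samples, 4 true mode switches
selected k = 4 segments; objective = 2.554e-05
segments (velocity-sample index ranges and labels):
  [   0,  156)  o
  [ 156,  226)  s
  [ 226,  410)  o
  [ 410,  455)  s
per-sample agreement with ground truth: 0.936
measured exploration fraction (EER): 0.253 vs true 0.248
```

The simulator produced a 6 s flight that surged, lost the plume once, cast,
re-acquired it and surged to the source.  The GA pipeline — which sees only
the positions, not the behavioural state — recovered the four phases with
94% per-sample agreement and an exploration fraction within 0.005 of the
ground truth.  The other examples build a plume snapshot, simulate single
flights, and run reduced-size versions of the frequency sweep, the
turbulence comparison and the simulator-vs-observation fit.

A thin CLI mirrors the library:

```bash
mothnav simulate --n 100 --seed 7 --out flights/
mothnav segment --in flights/flight_0000.csv --seed 0 --out seg.json
mothnav accuracy-benchmark --n 200 --seed 1 --out report.json
mothnav frequency-sweep --n 100 --seed 2 --out sweep.csv
mothnav turbulence-compare --n 40 --seed 5 --out turb.json
```

Trajectory CSVs use columns `t, x, y, z[, mode]` (metres, 75 Hz), so
measured flights can be segmented with the same commands.

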