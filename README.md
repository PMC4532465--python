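# crtscan

Residence-time timescale analysis for passive acoustic telemetry.

Fixed acoustic receivers log discrete detections of tagged animals.
Turning those detections into *continuous residence times* (CRTs —
intervals during which an animal is considered continuously present at
one receiver) requires choosing a **maximum blanking period (MBP)**:
the largest gap between consecutive same-receiver detections that
still counts as continuous presence.  Too small an MBP fragments
residences at every missed transmission (sonic collisions, ambient
noise); too large an MBP fuses genuinely distinct visits.  Historically
the MBP has been picked by expert intuition.

`crtscan` instead treats the MBP as a scanned variable
`MBP_n = n · Δ_MBP` and lets the data reveal the right timescale:

1. For every `MBP_n` in the grid, build the CRT set.  A CRT at
   receiver `R` ends at the last detection at `R` before either a
   detection at a *different* receiver (regardless of the gap length)
   or a same-receiver gap strictly larger than `MBP_n`.
2. For each CRT set, form the empirical survival curve
   `S_MBP_n(t)` = fraction of CRT durations strictly greater than `t`,
   and resample it on a regular grid `t_i = i·Δt` by linear
   interpolation (spans of the raw curve wider than `t_max` are
   discarded, not bridged).
3. Compare consecutive curves through the renormalized sum of squared
   residuals

   `rSSR(MBP_n) = (1/T) Σ_i [S_MBP_n(t_i) − S_MBP_{n+1}(t_i)]²`,

   the mean over the `T` grid points where both curves are defined.
4. The convergence timescale **MBP\*** is the smallest grid value
   beyond which the rSSR profile stays at its floor — from there on,
   residence-time estimates no longer depend on the processing choice.

A stochastic behavioral simulator (independent fish joining/leaving a
receiver array, optionally with a sigmoidal time-dependent rejoining
probability and Bernoulli detection noise) generates synthetic
detection logs with known timescales for validating the scan.

The package is aimed at movement ecologists working with passive
acoustic arrays (e.g. fish aggregating devices), and applies equally to
any discrete presence records — capture–mark–recapture style data
included.

## Worked example

Simulate a memoryless association model (leave probability
θ = 0.0002 per step, join probability μ = 0.0001 per receiver, 1,000
fish, 2 receivers, 100,000 steps) observed through heavy detection
noise (each present fish is logged with probability η = 0.01 per
step), then scan MBP ∈ {1, 100, …, 2000}:

```sh
$ crtscan simulate --scenario 1 --eta 0.01 --seed 42 -o dets.txt
wrote 491322 detections to dets.txt

$ crtscan scan -i dets.txt --preset sim -o scan_out
rSSR profile over 20 pairs; MBP* = 800.0

$ head -6 scan_out/rssr_profile.tsv
mbp     mbp_next        rssr    overlap
1.0     100.0   0.38406457891865065     4
100.0   200.0   0.07260983721301648     1357
200.0   300.0   0.046771373382457876    3895
300.0   400.0   0.022209400280862702    9114
400.0   500.0   0.0070921280790952265   15378
```

Reading the output: at small MBP the survival curves of consecutive
grid values disagree strongly (rSSR ≈ 0.4 between the raw-detection
curve and MBP = 100), because CRTs are still fragmented by missed
detections whose gaps are geometric with mean 1/η = 100 steps.  The
mismatch decays as the MBP overtakes the noise-gap distribution and
reaches its floor at MBP* = 800 steps — close to the point where
`P(gap > MBP)` becomes negligible — after which the curves, and any
residence-time statistic computed from them, are stable.  The
`overlap` column is `T`, the number of jointly defined resampled
points entering each mean.  `scan_out/` also contains the per-MBP
survival curves, a `report.json` with the full parameter set, and
(with `--plot`) semi-log figures.

The same scan on field data uses the named presets `fine`
(Δ_MBP = 10 min, grid 10–120 min) and `diel` (Δ_MBP = 2 h, grid
2–48 h), both with Δt = 10 min and t_max = 4 h, e.g.

```sh
crtscan scan -i S1_File.txt --preset fine -o scad_fine
```

Everything the CLI does is available as a library:

```python
from crtscan import (scenario_config, simulate, compute_mbp_grid,
                     rssr_profile, detect_mbp_star)

table = simulate(scenario_config(1, eta=0.01, seed=42))
grid = compute_mbp_grid(100, 20, include_base=True)   # {1, 100, ..., 2000}
profile = rssr_profile(table, grid, grid_step=1, t_max=100)
print(detect_mbp_star(profile))                       # 800.0
```

## Layout

- `src/crtscan/io_detections.py` — detection-log reading/writing
  (headerless supplementary format and generic delimited text).
- `src/crtscan/crt_builder.py` — MBP grids and vectorized CRT
  construction (gap rule + receiver-switch rule).
- `src/crtscan/survival_rssr.py` — survival curves, gap-aware linear
  resampling, rSSR profiles, MBP* detection.
- `src/crtscan/simulator.py` — the three-scenario behavioral model.
- `src/crtscan/cli.py` — `crtscan simulate | scan | crt | presets`.
- `docs/methods.md` — model details, parameter choices, limitations.
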