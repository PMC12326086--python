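# flocktrace

Flight and flocking analytics for GPS + accelerometry biologging of bird
flocks over heterogeneous landscapes.

`flocktrace` is built for the classic homing-pigeon release design: small
cluster flocks carrying 5 Hz GPS loggers and 100 Hz dorsal z-axis
accelerometers fly repeatedly from a release site back to their home
lofts across a patchwork of open, wooded and urban ground. The package
takes the raw per-bird logger streams to a tidy per-second table of flight
and flocking variables, classifies every position by ground cover, and
fits habitat-conditioned linear mixed models to ask how behaviour changes
over cover types, within flights, and across repeated releases. It is
aimed at movement ecologists working with multi-animal biologging data.

## What it computes

- **Flap (wingbeat) frequency** from z-axis accelerometry — running-mean
  detrending, peak-interval instantaneous frequency over 15-sample
  windows, zero-phase Butterworth smoothing, per-second medians. Flap
  frequency `f` is the oscillation rate (Hz) of the dorsal acceleration
  signal `z(t) ≈ g + A·sin(2π∫f dt)` and proxies flight effort.
- **Trajectory variables** — local-plane projection, ground speed,
  200 m release/home trimming, flight-time and iteration indices.
- **Flock geometry** per second — cohesive membership (largest connected
  component of the 10 m proximity graph), robust centroid (iterative
  ≥40 m exclusion), travel heading, absolute spread (front-back extent +
  left-right extent), distance to centroid, signed front-back and
  left-right offsets.
- **Ground-cover classification** of track points against GeoJSON habitat
  polygons grouped into open / wooded / urban.
- **Model selection** — per response `y` (flap frequency, speed, spread,
  …), linear mixed models `y ~ cover + flight_time + iteration +
  cover:flight_time + cover:iteration + covariates, random intercepts
  loft and bird-in-loft`: generalised-VIF pruning, all-subsets search
  under marginality, ΔAIC < 2 → max marginal r² → parsimony selection,
  Cook's-distance outlier refit, singularity flagging.
- **A seeded flock-flight simulator** that generates landscapes, flights
  and logger streams with known ground truth for all of the above.

## Worked example

Simulate a small campaign and run the pipeline end to end:

```python
from flocktrace import SimConfig, simulate_campaign, PipelineConfig, run_pipeline

campaign = simulate_campaign(SimConfig(seed=1, n_flights=5,
                                       split_probability_per_min=0.0))
cfg = PipelineConfig(responses=("flight_speed", "flap_frequency"),
                     candidate_terms=["habitat", "flight_time", "iteration"])
result = run_pipeline(cfg, campaign)

rep = result["reports"]["flight_speed"]
print(rep["selected"], round(rep["r2"], 3))
coeffs = rep["coefficients"]
print(coeffs[coeffs.term.str.contains("habitat")]
      [["coefficient", "estimate", "se"]].round(3).to_string(index=False))
```

prints (seed 1):

```
['habitat', 'iteration'] 0.097
                            coefficient  estimate    se
 C(habitat, Treatment('open'))[T.urban]     0.645 0.065
C(habitat, Treatment('open'))[T.wooded]    -0.655 0.065
```

The selected flight-speed model keeps ground cover; relative to open
ground the birds fly ~0.65 m/s faster over urban cover and ~0.66 m/s
slower over woodland — recovering the simulator's injected +0.69/−0.67 m/s
offsets within one standard error despite full measurement noise. The
same chain run for flap frequency recovers the injected urban −0.10 Hz
offset (estimate −0.087 ± 0.009) and wooded +0.03 Hz offset (estimate
+0.031 ± 0.009).

A command-line interface wraps the same stages:

```bash
flocktrace simulate --out campaign/ --seed 1
flocktrace run --campaign campaign/ --out results/
flocktrace model --table results/track_subsampled.csv --response flight_speed
```

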