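# Methods

`flocktrace` analyses repeated homing flights of small pigeon flocks over a
heterogeneous landscape: it turns raw biologger streams (5 Hz GPS and
100 Hz dorsal z-axis accelerometry per bird) into per-second flight and
flocking variables, classifies every position by ground cover (open, wooded
or urban), and asks — through linear mixed-model selection — how flap
frequency, flight speed and flock geometry change over the three cover
types, over the course of a flight, and over repeated releases. A seeded
flock-flight simulator provides data with known ground truth so every stage
can be verified by oracle equivalence and parameter recovery.

## Processing chain

**Trajectories.** Fixes are projected onto a local tangent plane about the
home loft with an exactly invertible equirectangular map,
`x = Δlon·cos(lat₀)·111320`, `y = Δlat·111320` (metres). Over the ~9.6 km,
mostly north–south corridor the distance error against a great-circle
oracle stays below 0.1%; the formula is not suitable for continental
extents. Everything within 200 m (inclusive) of the release and home sites
is trimmed to drop the atypical circling at either end, and the retained
time span also clips the accelerometry. Ground speed is the per-fix
displacement over Δt with a 50 m/s implausibility ceiling; the first fix
has no speed. `flight_time` counts seconds from each flight's first
retained record; `iteration` is the 1-based rank of the flight date within
a loft.

**Wingbeat.** The z-axis signal is detrended by a centred 1-s running mean
(long against a ~0.14 s wingbeat, short against drift), band-limited to
20 Hz, and searched for wingbeat peaks: local maxima with prominence above
0.3× the median 1-s rolling SD, at least `fs/20` samples apart, with
sub-sample positions refined by parabolic interpolation (without the
refinement, sample quantisation puts a ~0.2 Hz sawtooth on a 7 Hz
wingbeat). Inter-peak intervals give instantaneous frequencies, averaged
over consecutive 15-sample windows; a zero-phase order-2 Butterworth
low-pass at 1 Hz (on the ~6.7 Hz window-rate series) removes estimator
chatter while passing habitat-scale variation, and per-second medians are
taken last. Missing windows stay missing throughout. On noiseless 4–10 Hz
tones the per-second output is within 0.1 Hz of truth; with 0.2 g white
noise on a unit-amplitude 7 Hz tone, ≥95% of per-second estimates are
within 0.3 Hz.

**Habitat.** Fine land-cover classes are grouped into open, wooded and
urban; points in no polygon are open (mirroring the grouping of
unclassified ground), overlaps resolve urban > wooded > open (the built-up
label is the most specific), and boundary points count as inside.
Containment is evaluated directly in geographic coordinates — at this
extent the plate-carrée map is monotone, so polygon membership is
unchanged by projection.

**Flock geometry.** At each whole second the flock is the largest connected
component of the 10 m proximity graph (chain connectivity allowed; a
component of one is no flock). Ties between equal-sized components go to
the component nearest the previous centroid. The centroid is trimmed
robustly: the farthest member at ≥40 m is dropped and the mean recomputed
until all remaining members are inside; one-at-a-time trimming makes the
majority subgroup dominate after a split, and excluded birds may rejoin at
later seconds. Heading is the unit displacement to the next second's
centroid (steps under 0.5 m carry the previous heading; the first frame
uses the release-to-home axis). Each member's offset decomposes into
front-back (along heading, ahead positive, ties to "front") and left-right
(right positive); absolute spread is the front-back extent plus the
left-right extent of the membership.

**Alignment and subsampling.** All streams reduce to per-second medians
(positions componentwise) and merge onto the GPS-bearing seconds. To blunt
temporal autocorrelation the merged table is subsampled 1-in-15 per bird
and flight, on a per-flight second grid anchored at the flight's first
retained second and shared across the flock so timestamps still match
between members. For a gap-free stream this keeps ceil(n/15) rows, and the
lag-1 autocorrelation of an AR(1) series with coefficient 0.95 falls below
0.95¹⁵ + 0.05.

**Models.** Each response (flap frequency, absolute spread, distance to
centroid, group size, flight speed, front-back, left-right; the two spread
measures square-root transformed) is modelled with fixed effects drawn
from ground cover (3-level factor, open reference), flight time, iteration,
their interactions with cover, and the other flight/flock covariates, with
random intercepts for loft and for bird within loft. Generalised VIF
pruning (threshold 5, the common conservative default; interactions never
tested against their own parents) precedes an exhaustive marginality-
respecting subset search (capped at 2¹⁴ specifications), fitted by maximum
likelihood so AIC compares fixed structures. Among fits within 2 AIC of
the minimum the highest marginal r² (variance of fixed-effect predictions
over fixed + random + residual variance) wins; r² ties at the fifth
decimal go to the fewest terms, then lowest AIC. Observations with Cook's
distance above 4/n — computed in closed form from the fixed-effects
projection of the marginal model, validated against leave-one-out
refitting — are removed once and the selected structure refit by REML for
the reported coefficients. Wald per-term F statistics accompany the
estimates. A multinomial-logistic likelihood-ratio test checks that ground
cover is not confounded with bird or loft identity before they are used as
random effects.

Singular fits are ineligible for selection. Because numerical optimisers
often stall at small positive variances rather than descending to an exact
zero, a fit is declared singular either when a variance falls below 1e-8 of
the residual variance or when refitting without a suspicious component
(variance ratio < 0.02) changes the ML log-likelihood by less than 1e-4 —
the likelihood-flatness signature of a boundary estimate.

## The simulator

The generator reproduces the emulated study's design: three flocks of 6,
10 and 8 birds released 15 times over a ~9.6 km corridor (release
51.500122 N, −0.584229 E; home 51.415368 N, −0.572615 E) tiled with
open/wooded/urban bands of 300–800 m (a fragmented suburban mosaic), each
category covering ≥15% of the corridor. Mean speed is 17.92 m/s and mean
flap frequency 6.93 Hz, with habitat offsets of −0.67/+0.69 m/s (wooded/
urban) on speed and +0.03/−0.10 Hz on flap.

Behaviour: birds steer toward home plus an attractor at the flock centroid
offset by per-bird preferred positions (centred — the flock-mean preferred
displacement is unidentifiable against the centroid); heading noise makes
paths realistically tortuous, with stable per-bird tortuosity multipliers
so weaving birds fly measurably faster while holding station. Station
keeping adjusts speed toward the attractor (gain 0.15 /s, ±2 m/s cap, 5 m
deadband), which is what keeps a cohesive flock from dispersing
along-track — and which makes bird-level ground speeds share a common
flock pace, a property real cluster flocks have too. Per-bird AR(1)
wobble (~3 s timescale) perturbs speed and flap; flight-level offsets
(day-to-day wind and condition) shift a whole flight's pace and effort
without touching within-flight habitat contrasts; loft effects are fixed,
equally spaced values with the configured SD (the three lofts are a fixed
design feature; random draws over three groups would often leave the loft
variance unidentifiable, which the emulated study's non-singular headline
models rule out). Splits send a minority subgroup ≥60 m off-axis for a
fixed duration before rejoining. Wingbeat phase is accumulated
continuously so frequency changes never produce discontinuities; the
z-signal is gravity + 1 g oscillation + slow drift + white noise. GPS
error has a slow drift component (1.5 m, ~30 s) plus white epoch jitter
(0.45 m) — differentiated 5 Hz ground speed is dominated by the jitter,
which is why the speed models' residuals are large, as in real logger
data. Stream clocks start at a uniform random offset (release-box opening
and circling vary per flight). Everything is deterministic given the seed.

What the simulator does not model: wind fields and thermals, altitude,
predators, route learning (no systematic path change across iterations
unless injected), and logger dropouts. Passing recovery tests therefore
show the pipeline recovers effects injected through this behaviour model —
not that the model captures every property of real flights.

## Problem sizes and verification

The recovery experiment (`flocktrace.pipeline.recovery_experiment`, also
run by `scripts/acceptance.py`) uses a scaled campaign — 3 flocks × 5
flights — with measurement noise disabled (GPS drift, accelerometer noise
and drift), behavioural speed wobble reduced to 0.4 m/s, splits disabled,
and injected effects wooded −0.7 / urban +0.7 m/s and urban −0.1 Hz. Ten
replicates run the full pipeline with candidate terms {habitat,
flight_time, iteration}; each injected effect is checked for correct sign
and for the fraction of replicates recovering it within 2 SE of truth
(with calibrated standard errors that fraction is ~95% per effect). These
sizes keep a replicate near twenty seconds; the full-size campaign runs
through the same code path via `flocktrace simulate` / `flocktrace run`.

Known limitations: marginal r² is one of several defensible r² flavours
for mixed models; the Cook's distances approximate mixed-model influence
through the fixed-effects hat matrix (oracle-exact only in the
fixed-effects limit); cross-bird correlation at a shared timestamp (the
common flock pace) is not represented in the models' independence
assumptions, so reported SEs are mildly optimistic for flock-shared
predictors — the subsampling addresses temporal, not cross-member,
correlation, matching the modelling choices the pipeline emulates.
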