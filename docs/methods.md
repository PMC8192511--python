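# Methods

## The estimation problem

A pop-up satellite archival tag (PSAT) on a migrating Atlantic salmon archives
depth, temperature and estimated sunrise/sunset times every 15–60 minutes,
then detaches — on a programmed date, or after 4–5 days at constant depth —
surfaces, and transmits a subset of the archive via Argos together with its
pop-up position. Nothing in the record gives a position directly; the daily
position must be inferred from indirect signals: the timing of twilight (a
noisy longitude and, away from the equinoxes, a noisy latitude), the mean
temperature of near-surface samples matched against a gridded SST field, and
the day's maximum depth, which bounds the water depth from below.

`keltrack` casts this as a hidden Markov model on a discretised ocean. The
hidden state on day *t* is the grid cell occupied by the fish; movement
between days is a diffusion kernel; each day's tag summaries define a
likelihood surface over cells. Filtering and smoothing run the standard
forward–backward recursion; migration routes are reconstructed as the mean of
1000 trajectories drawn from the joint posterior; time-integrated smoothed
surfaces give residency distributions (RDs) whose pairwise Bhattacharyya
affinity, BA(p, q) = Σ√(p·q) ∈ [0, 1], measures the spatial overlap between
populations.

## State space and movement

Two discretisations are implemented, because route reconstructions should not
depend on the grid's structure:

* **latlon** — one state per ocean cell of a regular lat/lon lattice
  (default 1°);
* **distance** — cell centers ~equidistant in km: within each latitude row,
  longitudes are subsampled with stride round(1/cos φ), so longitudinal
  spacing in degrees widens poleward.

Land cells are never states. The daily movement kernel between states is the
one-day solution of isotropic diffusion: weight(i→j) ∝ exp(−d²/(4D))·A_j with
d the great-circle distance (km), D the diffusion coefficient (km²/day) and
A_j the destination cell area — the area factor converts a density into a
per-cell mass so that unequal-area cells (latlon flavour, or the two flavours
side by side) do not produce artificial drift. Weights are truncated at
4·√(2D) km (4 per-axis standard deviations) and each row renormalised over
its ocean destinations, which reflects coastal mass back to sea: fish do not
beach, and probability is conserved to 1e−9 (tested). D defaults to
1000 km²/day (per-axis sd ≈ 45 km/day, consistent with the tens-of-km daily
travel the cohort shows); a profile-likelihood estimate of D by
golden-section search (1% relative tolerance) is available.

## Observation model

Per UTC day with data: maximum depth; "tag SST" = mean temperature of samples
shallower than 20 m (missing if none); light position from twilight times.
Longitude is 15°/h times the offset of apparent noon (the sunrise/sunset
midpoint) from 12:00 UTC; latitude inverts the day length through the
declination/hour-angle equation, solved in closed form, with the hemisphere
chosen by sign(δ)·sign(L − 12 h). The daily likelihood is the cellwise
product of independent components; a missing component contributes a uniform
factor:

| component | form | default | why |
|---|---|---|---|
| light longitude | Gaussian, σ_lon | 0.5° | typical archival light-fix error |
| light latitude | Gaussian, σ_lat | 1.5° | day-length inversion is much noisier |
| SST | Gaussian vs monthly field, σ_sst | 0.7 °C | sensor + climatology mismatch |
| depth | indicator: bathymetry + tol ≥ max depth | tol 10 m | water must be at least that deep; tol absorbs pressure error |

Latitude is dropped (not down-weighted) within ±10 days of an equinox and
whenever the day length is within 10 minutes of 12 h — in that regime the
inversion is degenerate and pretending otherwise injects bias. Monthly SST
fields are indexed by calendar month without temporal interpolation. Release
anchors day 0 as a point mass at the nearest ocean cell; the pop-up position
anchors the final day at Argos scale (σ 10 km). A day whose surface collapses
to all zeros (e.g. an SST value matching nothing feasible) falls back to the
prediction step and is counted in the run report rather than terminating the
track.

## Inference

Recursions run in linear space with per-day renormalisation; the accumulated
normalisers give the data log-likelihood. Route sampling uses
forward-filter/backward-sampling (FFBS), which draws exact joint-posterior
trajectories; sampling per-day marginals independently would break temporal
coherence, and the difference is observable through `compare_tracks`. The
mean track is the per-day spherical mean (unit vectors, dateline-safe) of
1000 samples. Correctness is anchored by an independent oracle: on instances
small enough to enumerate every path, forward–backward marginals agree with
literal path summation to 1e−10 (200 random instances in the test suite).

## What the simulator emulates — and what it does not

The synthetic-data module is the study's ground truth. Its defaults encode
the deployment conditions the analysis assumes:

* **Environment** — monthly SST strictly decreasing poleward
  (0.35 °C/deg from 12 °C at 45° N), seasonal cosine cycle (amplitude
  2.5 °C, peak July), spatial noise 0.3 °C, over a 30°×50° basin with a
  shelf along an eastern coast (3000 m basin, exponential shoaling).
* **Movement** — a biased random walk: each day the heading points at a
  front-like target with probability `bias` (default 0.8), otherwise
  uniform; step length Gaussian (40 ± 8 km/day); land steps are rejected.
* **Depth use** — 80% of samples uniform in the top 10 m; the rest grouped
  into Poisson-count bouts (3/day) with log-normal maximum depths (median
  80 m, log-sd 0.7) and a U-shaped within-bout profile. The sub-surface
  sample count is Binomial per day, so surface occupancy is exactly the
  configured rate.
* **Tag SST** — field value at the true cell plus a *day-correlated* bias
  and per-sample jitter (each sd 0.3 °C by default). A purely i.i.d.
  per-sample error would vanish in the ~40-sample daily mean, leaving the
  configured noise level with no effect on geolocation; the daily bias is
  what a calibration offset or climatology mismatch actually looks like.
* **Twilight** — solar geometry (sun at −0.833°, no equation of time — the
  simulator and the inversion share one closed model, so local noon at
  longitude 0 is exactly 12:00 UTC and the omission cancels end to end)
  plus a dive-skew error: half-normal delays of sunrise and advances of
  sunset (sd 20 min) and a small symmetric clock error (sd 2 min). A
  surface-diving fish sees first light late and last light early, so the
  apparent day shrinks while apparent noon survives — longitude stays good,
  latitude degrades, which is precisely the regime SST-matching
  geolocation exists for. Polar-day/night dates emit no twilight pair.
* **Data recovery** — i.i.d. per-sample dropout, default 0.31 (≈69% of the
  archive recovered). Burst-structured dropout is a noted extension.
* **Release rule** — the record truncates at the programmed pop-up date or
  once the daily depth range stays under 3 m for the configured 4–5-day
  window; the pop-up position gets 5 km Gaussian (Argos-class) noise.

Not emulated: currents and fronts as dynamical objects, prey fields,
behaviour-switching movement, burst dropout, light-curve processing (tags
report twilight estimates directly). Passing tests therefore demonstrate
internal consistency of the inference chain under realistic noise structure,
not performance on any real ocean.

## Numerical and design choices

* Earth is a sphere of radius 6371.0 km; all distances are great-circle
  (haversine). "Straight-line" migration distance means the great-circle arc.
* A "day" is the UTC calendar day; longitudes live in [−180, 180), cell
  centers registered.
* Per-fish RDs are the day-mean of smoothed surfaces; population RDs average
  per-fish RDs with equal weight (a long track should not dominate its
  population), over fish whose migration strictly exceeds 10 days; pooled
  fish-day weighting is available as an option. Overlap is computed on full
  RDs; cumulative-mass contours (default 0.95) are display-only.
* Weekly distance profiles use consecutive 7-day blocks since release; the
  early-migration speed regression is OLS over weeks 1–11. "Post-migration"
  depth use selects samples strictly later than 77 days after release.
  Thermal-niche summaries use all retained samples regardless of depth,
  unlike the <20 m SST filter — they describe where the fish resided.
* One global seed derives per-fish substreams by hashing (seed, fish index),
  so adding a fish never perturbs the others' draws; reruns are
  bit-identical.

## Problem sizes

The shipped analysis and test suite run at desk scale by design: a 1°
30°×50° basin (~1380 ocean states), cohorts of 3–20 fish, deployments of
15–90 days, 100–1000 posterior track samples, and enumeration oracles capped
at 10⁵ paths. All quantities reported by the tests and
`scripts/acceptance.py` are computed at run time at these sizes.

## Known limitations

* The bathymetry likelihood is a hard indicator; a mis-calibrated pressure
  sensor beyond the 10 m tolerance zeroes correct cells (the degenerate-day
  fallback then carries the track).
* Latitude inversion assumes the shared solar model; with real tags the
  twilight-estimation error model would need fitting, and the dive-skew sd
  is a placeholder the config exposes.
* Monthly climatology without interpolation steps the SST field at month
  boundaries.
* The movement kernel is isotropic; advective (current-following) movement
  would bias D upward to compensate.
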