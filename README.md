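# keltrack

Hidden-Markov-model geolocation and space-use analysis for pop-up satellite
archival tags (PSATs) on migrating fish — built around the tag-to-inference
chain used to map ocean migrations of post-spawned Atlantic salmon
(*Salmo salar*).

A PSAT archives depth, temperature and sunrise/sunset estimates every 15–60
minutes, detaches on a programmed date (or after 4–5 days at constant depth),
and reports via Argos. No position is ever measured directly, so `keltrack`
infers daily positions with a grid-based HMM: the hidden state is the ocean
grid cell, movement is a truncated Gaussian diffusion kernel
(weight ∝ exp(−d²/4D), reflected at coasts), and each day's likelihood is the
product of light-longitude/latitude Gaussians, an SST match against a monthly
field, and a maximum-depth bathymetry constraint. Routes are the mean of 1000
forward-filter/backward-sampled posterior tracks; population space use is the
combined residency distribution (RD) of all fish with migrations exceeding
10 days; spatial overlap between populations is Bhattacharyya's affinity
BA(p, q) = Σ√(p·q), with 1 = total overlap and 0 = no overlap.

Because real PSAT archives are not redistributable, the package includes a
first-class simulator that generates the environment fields, true tracks and
tag records with the statistical structure the analysis assumes (80% of
samples in the top 10 m, ~69% data recovery, dive-skewed twilights,
day-correlated SST error), so the whole chain is testable end to end against
known ground truth. See `docs/methods.md` for the model details.

## Worked example

```bash
python analysis/01_simulate.py          # synthetic basin + 6 tagged fish
python analysis/02_geolocate.py         # HMM geolocation, mean-of-1000 routes
python analysis/03_residency_overlap.py # population RDs + overlap matrix
python analysis/04_metrics.py           # speed regression, depth use, thermal niche
```

`02_geolocate.py` prints, per fish, the median daily great-circle error of
the reconstructed route against the simulator's true track:

```
per-fish reconstruction (median daily great-circle error vs truth):
  north-003:   98.3 km over 61 days (recovery 69%, logL -98.5)
  north-004:   77.3 km over 61 days (recovery 68%, logL -112.4)
  ...
cohort median daily error: 164.2 km
```

— i.e. daily positions are recovered to roughly one or two grid cells at 1°
resolution, from light/SST/depth data alone. `03_residency_overlap.py` then
prints the Bhattacharyya overlap between the two simulated populations:

```
       north  south
north    1.0    0.0
south    0.0    1.0
```

Each population overlaps itself completely (diagonal 1.0) while the two
geographically separated cohorts use disjoint ocean areas (off-diagonal 0.0).
`04_metrics.py` reports each fish's early-migration speed from the
weekly-distance regression (weeks 1–11; e.g. ~225 km/week for the southern
cohort released further from its target), the fraction of time spent below
10 m (~0.20, matching the simulator's surface-orientation setting), and the
monthly temperatures occupied by each population.

The same stages are scriptable via the `keltrack` CLI
(`simulate`, `geolocate`, `overlap`, `metrics`, `run-all`), e.g.

```bash
keltrack run-all --seed 7 --out results/run7
```

## Layout

```
src/keltrack/     library: tag_io, synthetic, spatial_grid, observation,
                  hmm, residency, metrics, pipeline, cli
analysis/         numbered narrative drivers writing under results/
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance script
docs/methods.md   model description, simulator design, numerical choices
```
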