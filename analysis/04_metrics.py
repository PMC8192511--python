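"""Migration and behaviour summaries of the reconstructed cohort: weekly
distance from release with the early-migration speed regression, depth use
relative to the 10 m surface layer, and the monthly thermal niche.

Reads results/study/ written by the previous steps and prints the headline
numbers the tables contain.
"""

from pathlib import Path

import pandas as pd

from keltrack.metrics import (
    depth_use,
    distance_regression,
    monthly_thermal_niche,
    weekly_distance_profile,
)
from keltrack.tag_io import read_tag_series, read_track

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"

series = {
    p.stem: read_tag_series(p)
    for p in sorted((STUDY / "tags").glob("*.csv"))
    if not p.name.endswith(".twl.csv")
}

print("early-migration speed (weekly-distance OLS over weeks 1-11):")
for tag_id, s in series.items():
    track = read_track(STUDY / "tracks" / f"{tag_id}.csv")
    prof = weekly_distance_profile(track, s.deployment.release_lat, s.deployment.release_lon)
    try:
        slope, _, r2 = distance_regression(prof, max_week=11)
        print(f"  {tag_id}: {slope:6.1f} km/week (r^2 {r2:.2f})")
    except Exception as exc:
        print(f"  {tag_id}: skipped ({exc})")

print("\ndepth use (fraction of samples deeper than 10 m):")
rows = []
for tag_id, s in series.items():
    du = depth_use(s, threshold_m=10.0)
    rows.append({"tag_id": tag_id, "population": s.deployment.population,
                 "fraction_deeper": du.fraction_below, "max_depth_m": du.max_depth_m})
    print(f"  {tag_id}: {du.fraction_below:.2f} deep "
          f"(max depth {du.max_depth_m:.0f} m, n={du.n_samples})")
pd.DataFrame(rows).to_csv(STUDY / "metrics" / "depth_use.csv", index=False)

by_pop = {}
for s in series.values():
    by_pop.setdefault(s.deployment.population, []).append(s)
niche = monthly_thermal_niche(by_pop)
niche.to_csv(STUDY / "metrics" / "thermal_niche.csv", index=False)
print("\nmonthly thermal niche (median degC by population):")
print(niche.pivot(index="month", columns="group", values="t_median").round(1).to_string())
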