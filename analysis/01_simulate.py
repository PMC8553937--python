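"""Generate the synthetic study and the UK-shaped small-area table.

Emulates the field campaign: 162 sighting-defined sites across five
urban areas with replicated survey and report counts, expert counts at
~64% of sites, plus a 33,988-row small-area statistics table shaped like
the UK's urban census geographies.  Writes everything under results/.
"""

import dataclasses
from pathlib import Path

from catiam import io
from catiam.synthetic import TruthConfig, make_area_table, scatter_sightings, simulate_sites

SEED = 20_250_901
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    truth = TruthConfig(seed=SEED)
    data = simulate_sites(truth)
    sightings = scatter_sightings(data, seed=SEED + 1)
    io.write_table(sightings, OUT / "sightings.csv", seed=SEED, config=truth, overwrite=True)
    reps, summ = io.sites_to_frames(data.sites)
    io.write_table(reps, OUT / "site_replicates.csv", seed=SEED, config=truth, overwrite=True)
    io.write_table(summ, OUT / "site_summary.csv", seed=SEED, config=truth, overwrite=True)

    import pandas as pd

    io.write_table(pd.DataFrame([dataclasses.asdict(truth)]), OUT / "truth_config.csv",
                   seed=SEED, overwrite=True)

    areas = make_area_table(33_988, seed=SEED + 2)
    areas["land_area_km2"] *= 30_724.0 / areas["land_area_km2"].sum()
    io.write_table(areas, OUT / "areas_uk.csv", seed=SEED, overwrite=True)

    n_expert = sum(s.w is not None for s in data.sites)
    print(f"{len(sightings)} sighting records over {truth.n_sites} sites "
          f"({n_expert} with expert counts, {n_expert / truth.n_sites:.0%} coverage)")
    print(f"area table: {len(areas)} small areas, "
          f"{areas['land_area_km2'].sum():,.0f} km^2 urban land")


if __name__ == "__main__":
    main()
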