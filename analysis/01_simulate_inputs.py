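#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Writes the meta-database of yield-change point estimates, the regional
welfare-change table, and the business-as-usual scenario files under
results/inputs/.  All later scripts read these files, so the whole analysis
is reproducible from this single seeded step.
"""

import argparse
from pathlib import Path

from agscc import synthdata as sd

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results/inputs"))
args = ap.parse_args()
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

db = sd.gen_meta_database(sd.MetaGenSpec(seed=args.seed))
db.to_csv(out / "meta_database.csv")
counts = db.records["crop"].value_counts()
print(f"meta-database: {len(db)} point estimates from "
      f"{db.records['study_id'].nunique()} studies "
      f"({', '.join(f'{c}: {n}' for c, n in counts.items())})")

table = sd.gen_welfare_table(seed=args.seed)
table.to_csv(out / "welfare_table.csv")
print(f"welfare table: {len(table)} rows, {len(table.regions)} regions x 3 warming levels")

bau = sd.gen_bau_scenario(seed=args.seed)
bau.to_csv(out / "bau_emissions.csv", out / "bau_regional.csv")
print(f"BAU scenario: {bau.years[0]}-{bau.years[-1]}, "
      f"emissions {bau.emissions[0]:.1f} -> peak {bau.emissions.max():.1f} GtCO2/yr")
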