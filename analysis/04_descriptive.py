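#!/usr/bin/env python
"""Step 4 — descriptive suicide and late-maternal-death tables.

Maternal suicide and late maternal deaths sit outside the modelled
seven-cause simplex: both are summarised directly from observed data (no
uncertainty intervals). Suicide uses specialised (non-CRVS) sources only;
the late analysis reports the ratio of deaths 42 days–1 year after the end
of pregnancy to maternal deaths up to 42 days.
"""

import argparse
import json
from pathlib import Path

from matcod.descriptive import format_ratio, late_ratio_summary, suicide_summary
from matcod.io import read_observations

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data-dir", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

observations = read_observations(args.data_dir / "obs.csv")
region_map = {o.country: o.region for o in observations}
truth = json.loads((args.data_dir / "truth.json").read_text())
region_map.update(truth["country_region"])

suicide = suicide_summary(observations, region_map)
late = late_ratio_summary(observations, region_map)
args.out_dir.mkdir(parents=True, exist_ok=True)
suicide.to_frame().to_csv(args.out_dir / "suicide_report.csv", index=False)
late.to_frame().to_csv(args.out_dir / "late_ratio_report.csv", index=False)

print(f"{suicide.n_countries} countries recorded at least one maternal suicide")
for region, d in sorted(suicide.by_region.items()):
    print(
        f"  {region}: {d['n_countries']} countries, "
        f"average proportion {100 * d['average_proportion']:.1f}%"
    )
print(f"{late.n_countries} countries reported late maternal deaths")
for region, d in sorted(late.by_region.items()):
    print(f"  {region}: mean late-to-early ratio {format_ratio(d['mean_ratio'])}")
print(f"wrote {args.out_dir}/suicide_report.csv, late_ratio_report.csv")
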