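#!/usr/bin/env python
"""Who is in the networks: actor characteristics by role, alters' relation
to their ego by site, and per-network age profiles.

Writes results/descriptives.csv, results/relationships.csv, results/ages.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from egonet.io import read_study
from egonet.reporting import (
    tabulate_ages,
    tabulate_descriptives,
    tabulate_relationships,
)


def main() -> None:
    data = ROOT / "results" / "data"
    collection = read_study(data / "roster.csv", data / "ties.csv")
    desc = tabulate_descriptives(collection)
    rel = tabulate_relationships(collection)
    ages = tabulate_ages(collection)
    desc.to_csv(ROOT / "results" / "descriptives.csv", index=False)
    rel.to_csv(ROOT / "results" / "relationships.csv", index=False)
    ages.to_csv(ROOT / "results" / "ages.csv", index=False)
    print(desc.to_string(index=False))
    eth = desc[(desc.attribute == "ethnicity") & (desc.level == "Hausa")].iloc[0]
    age = desc[(desc.attribute == "age_group") & (desc.level == ">=30")].iloc[0]
    print(f"\n{eth.total_pct}% of actors are Hausa; {age.total_pct}% are 30 or "
          f"older ({age.ego_pct}% of egos)")
    print("wrote results/descriptives.csv, relationships.csv, ages.csv")


if __name__ == "__main__":
    main()
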