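#!/usr/bin/env python
"""Per-network structure: ties, density, degree centrality, normalized
betweenness, Freeman centralization, injectable-user counts.

Reads the simulated data written by 01_simulate.py and writes
results/network_metrics.csv; prints the density/centralization ranges and the
cohesion headline (how many networks are denser than 0.5).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from egonet.io import read_study
from egonet.reporting import tabulate_network_metrics


def main() -> None:
    data = ROOT / "results" / "data"
    collection = read_study(data / "roster.csv", data / "ties.csv")
    df = tabulate_network_metrics(collection)
    out = ROOT / "results" / "network_metrics.csv"
    df.to_csv(out, index=False)
    dense = (df.density > 0.5).sum()
    full = (df.density == 1.0).sum()
    print(df.to_string(index=False))
    print(f"\ndensity range {df.density.min():.2f}-{df.density.max():.2f}; "
          f"{dense}/{len(df)} networks denser than 0.5; {full} at full density")
    print(f"centralization range {df.centralization_pct.min():.1f}-"
          f"{df.centralization_pct.max():.1f}%")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
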