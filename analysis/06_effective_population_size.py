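#!/usr/bin/env python
"""Per-breed effective-population-size trajectories from LD decay.

Bins squared genotype correlations by recombination distance (linear map,
1 cM/Mb) and inverts Sved's expectation per bin. The simulated panels carry
no mutation, so alpha=1 is used here; trajectories are written
Manhattan-ready (one row per bin: t generations ago, Ne).
"""

import argparse
from pathlib import Path

import pandas as pd

from rohpop.io import read_genotype_tsv
from rohpop.ne import ne_trajectory
from rohpop.pipeline import FLOAT_FMT


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    out = Path(args.outdir)

    panel = read_genotype_tsv(out / "genotypes.tsv", out / "markers.tsv")
    parts = []
    for p in panel.population_labels:
        traj = ne_trajectory(panel, p, alpha=1)
        if traj.empty:
            print(f"{p}: no informative bins (LD too strong or too few "
                  f"pairs); skipped")
            continue
        traj.insert(0, "population", p)
        parts.append(traj)
        recent = traj.iloc[-1]
        print(f"{p}: {len(traj)} bins, most recent estimate "
              f"Ne~{recent['ne']:.0f} at t~{recent['t']:.0f} generations")
    if parts:
        pd.concat(parts, ignore_index=True).to_csv(
            out / "ne_trajectory.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
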