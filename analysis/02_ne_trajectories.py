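#!/usr/bin/env python
"""Reconstruct per-population Ne trajectories from linkage-binned LD.

Reads the cohort written by 01_simulate_cohort.py, applies the QC
protocol (duplicate screen, MAF > 0.05), and reconstructs each
population's Ne at the time depths implied by the map-distance bins
(t = 1/2c with a 5-year generation time anchored at 2010).  Writes
<outdir>/ne_trajectories.tsv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from popdecline import genotypes as gt
from popdecline import ldne


def load_cohort(data: Path):
    meta = gt.read_population_meta(data / "population_meta.tsv")
    G = gt.read_genotypes(data / "genotypes.tsv", format="matrix")
    # sample names are "<pop>_indN"; recover the mapping
    G.population_of = {s: s.rsplit("_ind", 1)[0] for s in G.samples}
    lmap, _ = gt.read_linkage_map(data / "linkage_map.tsv")
    return G, lmap, meta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    G, lmap, meta = load_cohort(args.outdir / "data")

    dups, _ = gt.find_duplicate_samples(G)
    drop = {b for _, b, _ in dups}
    if drop:
        G = G.subset_samples([s for s in G.samples if s not in drop])
    G, removed = gt.filter_maf(G, 0.05)
    print(f"QC: {len(drop)} duplicates removed, {len(removed)} loci below MAF 0.05")

    frames = []
    for pop in G.populations:
        traj = ldne.reconstruct_trajectory(
            G.subset_populations([pop]), lmap, population=pop
        )
        frames.append(traj.to_frame())
        unl = next(b for b in traj.bins if b.unlinked)
        deep = traj.bins[0]
        print(
            f"{pop}: Ne({deep.year:.0f}) = {deep.ne_hat:,.0f}  ->  "
            f"Ne(2005) = {unl.ne_hat:,.0f}"
        )
    out = args.outdir / "ne_trajectories.tsv"
    pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
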