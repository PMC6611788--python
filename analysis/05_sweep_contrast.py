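#!/usr/bin/env python
"""Contrast sweep signatures between declining and non-declining groups.

Runs the composite-mu scan (diversity reduction x folded-SFS tail x LD
structure, 20-SNP sliding windows on this panel) on each group's pooled
genotypes at MAF > 0.01, aggregates sliding windows into 1-Mbp bins,
takes delta-mu = non-declining minus declining, flags +-3 SD bins, and
matches any decline-associated RDA loci within 1 Mbp of an outlier
window.  Writes delta_mu.tsv and delta_mu_rda_overlap.tsv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from popdecline import sweeps
from popdecline.genotypes import filter_maf

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

load_cohort = import_module("02_ne_trajectories").load_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--window-snps", type=int, default=20)
    args = ap.parse_args()
    G, lmap, _ = load_cohort(args.outdir / "data")
    panel, _ = filter_maf(G, 0.01)

    truth_pops = pd.read_csv(
        args.outdir / "data" / "truth_populations.tsv", sep="\t"
    ).set_index("pop")["declining"]
    declining = [p for p in panel.populations if truth_pops[p]]
    nondeclining = [p for p in panel.populations if not truth_pops[p]]

    mu_non = sweeps.mu_scan(panel.subset_populations(nondeclining), lmap, W=args.window_snps)
    mu_dec = sweeps.mu_scan(panel.subset_populations(declining), lmap, W=args.window_snps)
    delta = sweeps.flag_delta_outliers(sweeps.aggregate_delta(mu_non, mu_dec))
    ddf = sweeps.delta_windows_to_frame(delta)
    out = args.outdir / "delta_mu.tsv"
    ddf.to_csv(out, sep="\t", index=False)

    n_pos = int((ddf["outlier_class"] == "+dmu").sum())
    n_neg = int((ddf["outlier_class"] == "-dmu").sum())
    print(
        f"{len(ddf)} 1-Mbp bins: {n_pos} +dmu outliers (sweep signal only in "
        f"non-declining) and {n_neg} -dmu outliers (only in declining)"
    )

    rda_path = args.outdir / "rda_scores.tsv"
    if rda_path.exists():
        rdf = pd.read_csv(rda_path, sep="\t")
        rda_out = rdf.loc[rdf["outlier"], "locus"].tolist()
        outliers = [w for w in delta if w.outlier_class != "none"]
        overlap = sweeps.overlap_with_rda(outliers, rda_out, lmap)
        opath = args.outdir / "delta_mu_rda_overlap.tsv"
        overlap.to_csv(opath, sep="\t", index=False)
        print(
            f"{len(overlap)} decline-associated SNPs fall within 1 Mbp of a "
            f"delta-mu outlier window -> {opath}"
        )
    else:
        print("no RDA input (run 04 first): overlap step skipped")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
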