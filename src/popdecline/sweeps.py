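"""Windowed selective-sweep scan and the between-group delta-mu contrast.

A composite sweep statistic mu is computed in sliding windows of W
consecutive panel SNPs (step one SNP) from pooled genotypes of a
population group.  All groups scan the *same* shared SNP panel, so their
windows line up exactly; what differs between groups is what each window
looks like inside a group.  mu is the product of three label-free
factors, each normalised against its genome-wide level so a neutral
genome hovers around 1:

* ``mu_var`` — local diversity reduction: the genome-wide fraction of
  panel SNPs still polymorphic in the group divided by the same fraction
  inside the window (floored at 1/W).  On an array panel with no
  mutation, a completed sweep leaves a desert of group-fixed SNPs, and
  this ratio is its direct signature;
* ``mu_sfs`` — folded-spectrum tail excess: fraction of window SNPs with
  minor-allele count at or below ~2.5% of sampled chromosomes —
  *including* count zero, i.e. SNPs the sweep carried to fixation in the
  group — over the genome-wide fraction.  The tail class rather than
  singletons alone keeps shot noise down at moderate sample sizes;
* ``mu_ld`` — LD structure among the window SNPs still polymorphic in
  the group: mean composite r^2 within each window half over the mean
  r^2 between halves (sweeps leave high LD on each flank but little
  across the swept center); 1 when a half has fewer than two polymorphic
  SNPs.

To contrast groups, sliding-window mu values are averaged into fixed
1-Mbp genomic bins per group and differenced: ``delta_mu =
mean mu(non-declining) - mean mu(declining)``.  Bins more than 3 SD from
the mean delta_mu are outliers; the sign says which group carries the
sweep signal.  Outlier bins are finally intersected with
decline-associated loci (RDA outliers) allowing 1 Mbp of slack on both
window edges, because SNP-driven windows are not pinned to round
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, LinkageMap
from .ldne import pairwise_r2_matrices

MBP = 1_000_000


@dataclass
class MuWindow:
    chrom: str
    bp_start: int        # position of first SNP in window (1-based)
    bp_end: int          # position of last SNP
    n_snps: int
    mu_var: float
    mu_sfs: float
    mu_ld: float
    mu: float
    center_bp: float


@dataclass
class DeltaMuWindow:
    chrom: str
    bp_start: int        # 1-Mbp bin, 1-based inclusive
    bp_end: int
    delta_mu: float
    z: float
    outlier_class: str   # '+dmu' | '-dmu' | 'none'


def _minor_allele_counts(D: np.ndarray) -> np.ndarray:
    """Folded (minor) allele count per locus over non-missing calls."""
    present = D != MISSING
    alt = np.where(present, D, 0).sum(axis=0)
    total = 2 * present.sum(axis=0)
    return np.minimum(alt, total - alt)


def mu_scan(
    G_group: GenotypeMatrix,
    lmap: LinkageMap,
    W: int = 50,
    ld_floor: float = 1e-6,
    sfs_tail_fraction: float = 0.025,
) -> list[MuWindow]:
    """Sliding-window composite mu over the pooled individuals of a group.

    Loci must be mapped; windows are W consecutive panel SNPs per
    chromosome, step one SNP, regardless of whether each SNP still
    segregates in the group (group-fixed SNPs are the sweep signal, not
    something to discard).  Chromosomes with fewer than W SNPs are
    skipped with a warning.
    """
    tab = lmap.table.loc[G_group.loci]
    order = np.lexsort((tab["bp"].to_numpy(), tab["chrom"].to_numpy()))
    loci = [G_group.loci[i] for i in order]
    G = G_group.subset_loci(loci)
    tab = lmap.table.loc[loci]
    chrom_arr = tab["chrom"].to_numpy()
    bp = tab["bp"].to_numpy()

    # genome-wide normalisers over the shared panel, within this group
    mac = _minor_allele_counts(G.dosage)
    n_chrom_sampled = 2 * G.n_samples
    tail_cut = max(1, int(np.floor(sfs_tail_fraction * n_chrom_sampled)))
    tail = mac <= tail_cut           # includes mac == 0: fixed in the group
    poly = mac > 0
    genome_tail_rate = float(tail.mean())
    genome_poly_rate = float(poly.mean())

    r2_mat, _ = pairwise_r2_matrices(G)

    windows: list[MuWindow] = []
    half = W // 2
    for ch in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == ch)
        if idx.size < W:
            warnings.warn(
                f"chromosome {ch} has {idx.size} SNPs < window size {W}; skipped",
                stacklevel=2,
            )
            continue
        for start in range(idx.size - W + 1):
            win = idx[start : start + W]
            b0, b1 = int(bp[win[0]]), int(bp[win[-1]])
            mu_var = genome_poly_rate / max(float(poly[win].mean()), 1.0 / W)
            mu_sfs = (
                float(tail[win].mean()) / genome_tail_rate
                if genome_tail_rate > 0
                else 0.0
            )
            left = win[:half][poly[win[:half]]]
            right = win[half:][poly[win[half:]]]
            if left.size >= 2 and right.size >= 2:
                r_ll = r2_mat[np.ix_(left, left)][np.triu_indices(left.size, k=1)]
                r_rr = r2_mat[np.ix_(right, right)][np.triu_indices(right.size, k=1)]
                r_lr = r2_mat[np.ix_(left, right)].ravel()
                within = 0.5 * (float(np.nanmean(r_ll)) + float(np.nanmean(r_rr)))
                between = max(float(np.nanmean(r_lr)), ld_floor)
                mu_ld = within / between
            else:
                mu_ld = 1.0      # too little polymorphism left to measure LD
            windows.append(
                MuWindow(
                    chrom=str(ch),
                    bp_start=b0,
                    bp_end=b1,
                    n_snps=W,
                    mu_var=mu_var,
                    mu_sfs=mu_sfs,
                    mu_ld=mu_ld,
                    mu=mu_var * mu_sfs * mu_ld,
                    center_bp=0.5 * (b0 + b1),
                )
            )
    return windows


def aggregate_delta(
    mu_nondeclining: list[MuWindow],
    mu_declining: list[MuWindow],
    bin_bp: int = MBP,
    agg: str = "mean",
) -> list[DeltaMuWindow]:
    """Average sliding-window mu into fixed genomic bins and difference groups.

    A window contributes to the bin containing its center; bins with no
    window in either group are dropped.  ``delta_mu = nondeclining -
    declining``; z-scores are over all retained bins.
    """
    if agg not in ("mean", "max"):
        raise ValueError("agg must be 'mean' or 'max'")

    def binned(windows: list[MuWindow]) -> dict[tuple[str, int], list[float]]:
        out: dict[tuple[str, int], list[float]] = {}
        for w in windows:
            key = (w.chrom, int((w.center_bp - 1) // bin_bp))
            out.setdefault(key, []).append(w.mu)
        return out

    nd = binned(mu_nondeclining)
    dc = binned(mu_declining)
    keys = sorted(set(nd) & set(dc))
    dropped = sorted(set(nd) ^ set(dc))
    if dropped:
        warnings.warn(f"{len(dropped)} bins present in only one group dropped", stacklevel=2)
    f = np.mean if agg == "mean" else np.max
    rows = []
    for ch, k in keys:
        delta = float(f(nd[(ch, k)])) - float(f(dc[(ch, k)]))
        rows.append((ch, k * bin_bp + 1, (k + 1) * bin_bp, delta))
    deltas = np.array([r[3] for r in rows])
    mean, sd = (deltas.mean(), deltas.std()) if deltas.size else (0.0, 0.0)
    out = []
    for (ch, lo, hi, d) in rows:
        z = (d - mean) / sd if sd > 0 else 0.0
        out.append(DeltaMuWindow(ch, int(lo), int(hi), d, float(z), "none"))
    return out


def flag_delta_outliers(
    windows: list[DeltaMuWindow], k: float = 3.0
) -> list[DeltaMuWindow]:
    """Classify bins beyond ``k`` SD of delta_mu; sign fixes the class.

    ``+dmu``: sweep signal in non-declining populations only (signal lost
    or never present in decliners); ``-dmu``: the converse.
    """
    if len(windows) < 20:
        raise ValueError("need at least 20 bins to calibrate the outlier rule")
    deltas = np.array([w.delta_mu for w in windows])
    sd = deltas.std()
    if sd == 0:
        warnings.warn("zero delta-mu variance: no outliers flagged", stacklevel=2)
        for w in windows:
            w.outlier_class = "none"
        return windows
    mean = deltas.mean()
    for w in windows:
        z = (w.delta_mu - mean) / sd
        w.z = float(z)
        if z > k:
            w.outlier_class = "+dmu"
        elif z < -k:
            w.outlier_class = "-dmu"
        else:
            w.outlier_class = "none"
    return windows


def overlap_with_rda(
    delta_outliers: list[DeltaMuWindow],
    rda_loci: list[str],
    lmap: LinkageMap,
    tolerance_bp: int = MBP,
) -> pd.DataFrame:
    """Match decline-associated SNPs to delta-mu outlier windows.

    A SNP matches a window when its bp lies in
    ``[window_start - tolerance, window_end + tolerance]`` (closed on
    both ends) on the same chromosome.
    """
    # shared coordinate system: every window chromosome must exist in the
    # linkage map's universe (catches e.g. "1" vs "chr1" naming mismatches)
    known = set(map(str, lmap.table["chrom"].unique()))
    bad = sorted({w.chrom for w in delta_outliers} - known)
    if bad:
        raise ValueError(
            f"chromosome labels do not match the linkage map: {bad} "
            f"(map has {sorted(known)})"
        )
    snp_rows = []
    for l in rda_loci:
        if not lmap.has(l):
            raise ValueError(f"RDA locus {l} missing from the linkage map")
        snp_rows.append((l, str(lmap.table.at[l, "chrom"]), int(lmap.table.at[l, "bp"])))
    rows = []
    for w in delta_outliers:
        for locus, ch, pos in snp_rows:
            if ch == w.chrom and w.bp_start - tolerance_bp <= pos <= w.bp_end + tolerance_bp:
                rows.append(
                    {
                        "chrom": ch,
                        "window_start": w.bp_start,
                        "window_end": w.bp_end,
                        "outlier_class": w.outlier_class,
                        "locus": locus,
                        "bp": pos,
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "window_start", "window_end", "outlier_class", "locus", "bp"]
    )


def mu_windows_to_frame(windows: list[MuWindow]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])


def delta_windows_to_frame(windows: list[DeltaMuWindow]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])
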