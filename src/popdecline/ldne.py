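"""Single-sample reconstruction of historical Ne from linkage-binned LD.

Effective population size leaves a signature in the association (r^2)
between pairs of loci: at drift-recombination equilibrium the expected
squared correlation for a pair with recombination fraction ``c`` is
approximately ``gamma(c)/Ne + 1/S`` where ``S`` is the number of sampled
individuals and

    gamma(c) = ((1 - c)^2 + c^2) / (2 c (2 - c)),

which reduces to 1/3 for unlinked pairs (c = 0.5).  Because LD at
recombination fraction ``c`` turns over on a timescale of roughly
``1/(2c)`` generations, pairs binned by map distance probe Ne at
different depths in the past: ``t = 1/(2 c_bar)`` generations, mapped to
calendar years through a fixed generation time.  Binning locus pairs by
map distance and inverting the expectation bin by bin therefore yields an
Ne *trajectory* from a single contemporary sample.

Pairwise LD is measured with the Burrows composite disequilibrium
computed directly from unphased dosages; sampling bias is handled by
subtracting ``1/S_bar`` from the bin mean r^2 (harmonic-mean sample
size over pairs).  Confidence intervals come from a delete-one-individual
jackknife carried out on the 1/Ne scale, where unbounded upper limits
remain representable (a lower 1/Ne bound at or below zero back-transforms
to an infinite Ne bound).  Individuals, not loci, are the jackknife
unit: every locus pair is computed from the same sampled individuals, so
deleting loci leaves the dominant shared sampling noise invisible and
gives intervals that are far too narrow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, LinkageMap, filter_maf

UNLINKED_C = 0.5


def gamma_c(c) -> np.ndarray | float:
    """Weighting factor linking E[r^2] to 1/Ne at recombination fraction c."""
    c = np.asarray(c, dtype=float)
    out = ((1.0 - c) ** 2 + c**2) / (2.0 * c * (2.0 - c))
    return out if out.ndim else float(out)


def haldane_c(d_morgans) -> np.ndarray | float:
    """Map distance (Morgans) -> recombination fraction, Haldane (no interference)."""
    d = np.asarray(d_morgans, dtype=float)
    out = 0.5 * (1.0 - np.exp(-2.0 * d))
    return out if out.ndim else float(out)


def composite_r2(g_a, g_b) -> float:
    """Burrows composite r^2 between two dosage vectors.

    Samples missing at either locus are dropped.  Returns ``nan`` when a
    locus is monomorphic among the compared samples; requires >= 4
    compared samples.
    """
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    ok = (g_a != MISSING) & (g_b != MISSING)
    a = g_a[ok].astype(float)
    b = g_b[ok].astype(float)
    S = a.size
    if S < 4:
        raise ValueError(f"need >= 4 jointly typed samples, got {S}")
    p_a = a.mean() / 2.0
    p_b = b.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    delta = (a * b).sum() / (2.0 * S) - 2.0 * p_a * p_b
    r2 = delta**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(min(r2, 1.0))


def _pair_sums(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-locus sufficient statistics: shared counts N, sum g_a*g_b, sum g_a."""
    D = G.dosage
    present = (D != MISSING).astype(float)
    X = np.where(D == MISSING, 0, D).astype(float)
    N = present.T @ present          # shared sample counts
    Sxy = X.T @ X                    # sum of g_a * g_b over shared samples
    A = X.T @ present                # sum of g_a over samples typed at both
    return N, Sxy, A


def _r2_from_sums(N: np.ndarray, Sxy: np.ndarray, A: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = A / (2.0 * N)
        p_b = p_a.T
        delta = Sxy / (2.0 * N) - 2.0 * p_a * p_b
        den = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = delta**2 / den
        r2 = np.minimum(r2, 1.0)
        r2[den <= 0] = np.nan
        r2[N < 4] = np.nan
    return r2


def pairwise_r2_matrices(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs composite r^2 and jointly-typed sample counts.

    Returns ``(r2, n)``; ``r2[i, j]`` is nan when either locus is
    monomorphic among the samples typed at both.  Vectorised with a few
    L x L matrix products, so scales to thousands of loci.
    """
    N, Sxy, A = _pair_sums(G)
    return _r2_from_sums(N, Sxy, A), N


@dataclass
class PairBin:
    """One map-distance bin of locus pairs and its Ne estimate."""

    d_low: float                 # Morgans (exclusive lower edge)
    d_high: float                # Morgans (inclusive upper edge); inf for unlinked
    c_bar: float                 # mean recombination fraction over pairs
    n_pairs: int
    n_loci: int
    mean_r2: float
    s_harmonic: float
    r2_adj: float
    ne_hat: float                # may be +inf
    ci_low: float
    ci_high: float
    t: float                     # generations before sampling = 1/(2 c_bar)
    year: float
    low_confidence: bool = False

    @property
    def unlinked(self) -> bool:
        return np.isinf(self.d_high)


@dataclass
class LdNeSettings:
    """Analysis settings; the defaults are the protocol used throughout."""

    bin_width: float = 0.05          # Morgans
    max_distance: float = 0.25       # Morgans; deeper bins rarely have pairs
    maf_cutoff: float = 0.05
    generation_time: float = 5.0     # years
    start_year: int = 2010
    min_pairs: int = 50              # below this a bin is flagged low-confidence
    min_loci_ci: int = 10            # below this the jackknife CI is (0, inf)


@dataclass
class NeTrajectory:
    """Ordered (deep -> recent) per-bin Ne estimates for one population."""

    population: str
    bins: list[PairBin]
    settings: LdNeSettings = field(default_factory=LdNeSettings)
    n_loci_used: int = 0
    excluded_loci: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            rows.append(
                {
                    "population": self.population,
                    "d_low": b.d_low,
                    "d_high": b.d_high,
                    "c_bar": b.c_bar,
                    "n_pairs": b.n_pairs,
                    "n_loci": b.n_loci,
                    "mean_r2": b.mean_r2,
                    "r2_adj": b.r2_adj,
                    "ne_hat": b.ne_hat,
                    "ci_low": b.ci_low,
                    "ci_high": b.ci_high,
                    "t": b.t,
                    "year": b.year,
                    "low_confidence": b.low_confidence,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class _BinShell:
    """Pair bookkeeping for one bin before estimation."""

    d_low: float
    d_high: float
    i_idx: np.ndarray    # locus index of first member of each pair
    j_idx: np.ndarray
    c_vals: np.ndarray


def bin_locus_pairs(
    lmap: LinkageMap,
    loci: list[str],
    bin_width: float = 0.05,
    max_distance: float = 0.25,
) -> list[_BinShell]:
    """Assign locus pairs to map-distance bins.

    Same-chromosome pairs at distance ``d`` in ``((k-1)*w, k*w]`` go to
    linked bin ``k`` (up to ``max_distance``); every different-chromosome
    pair goes to the unlinked bin with c = 0.5 exactly.
    """
    tab = lmap.table.loc[loci]
    chrom = tab["chrom"].to_numpy()
    morg = tab["morgans"].to_numpy()
    L = len(loci)
    iu, ju = np.triu_indices(L, k=1)
    same = chrom[iu] == chrom[ju]
    d = np.abs(morg[iu] - morg[ju])

    shells: list[_BinShell] = []
    n_linked_bins = int(np.ceil(max_distance / bin_width - 1e-9))
    for k in range(n_linked_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        sel = same & (d > lo) & (d <= hi)
        shells.append(
            _BinShell(lo, hi, iu[sel], ju[sel], haldane_c(d[sel]))
        )
    unl = ~same
    shells.append(
        _BinShell(
            np.inf, np.inf, iu[unl], ju[unl], np.full(int(unl.sum()), UNLINKED_C)
        )
    )
    shells[-1].d_low = max_distance  # report: anything beyond the linked range
    return shells


def estimate_ne(mean_r2: float, c_bar: float, s_harmonic: float) -> tuple[float, float]:
    """Point estimate of Ne from a bin's mean r^2.

    Returns ``(ne_hat, r2_adj)``; ``ne_hat`` is +inf when the
    bias-adjusted r^2 is non-positive (no drift signal resolvable).
    """
    if s_harmonic < 4:
        raise ValueError("harmonic-mean sample size < 4: estimator unreliable")
    r2_adj = mean_r2 - 1.0 / s_harmonic
    if r2_adj <= 0:
        return float("inf"), r2_adj
    return gamma_c(c_bar) / r2_adj, r2_adj


def _inv_ne(mean_r2, c_bar, s_harm):
    """1/Ne on the signed scale (may be negative): (r2 - 1/S) / gamma(c)."""
    return (mean_r2 - 1.0 / s_harm) / gamma_c(c_bar)


def _bin_x(
    shell: _BinShell, N: np.ndarray, Sxy: np.ndarray, A: np.ndarray
) -> float:
    """Signed 1/Ne for one bin from the sufficient-statistic matrices."""
    r2 = _r2_from_sums(N, Sxy, A)[shell.i_idx, shell.j_idx]
    n = N[shell.i_idx, shell.j_idx]
    ok = np.isfinite(r2)
    if ok.sum() == 0:
        return float("nan")
    s_harm = ok.sum() / (1.0 / n[ok]).sum()
    return _inv_ne(r2[ok].mean(), shell.c_vals[ok].mean(), s_harm)


def jackknife_ci(
    G: GenotypeMatrix,
    shell: _BinShell,
    min_loci: int = 10,
) -> tuple[float, float]:
    """Delete-one-individual jackknife 95% CI for a bin's Ne.

    Every locus pair is computed from the same sampled individuals, so
    individuals are the exchangeable unit: each one is deleted in turn
    (cheap rank-one downdates of the pair-sum matrices), the bin's 1/Ne
    is re-estimated, and the jackknife variance with normal quantiles
    gives a CI on the 1/Ne scale, back-transformed to Ne.  A lower 1/Ne
    bound <= 0 becomes an infinite upper Ne bound.  Bins drawing on fewer
    than ``min_loci`` loci report (0, inf).
    """
    return _jackknife_all(G, [shell], min_loci)[0]


def _jackknife_all(
    G: GenotypeMatrix, shells: list[_BinShell], min_loci: int = 10
) -> list[tuple[float, float]]:
    N, Sxy, A = _pair_sums(G)
    r2_full = _r2_from_sums(N, Sxy, A)
    S = G.n_samples
    D = G.dosage
    present = (D != MISSING).astype(float)
    X = np.where(D == MISSING, 0, D).astype(float)

    # per-deletion bin estimates on the 1/Ne scale
    x_del = np.empty((S, len(shells)))
    for k in range(S):
        pk, xk = present[k], X[k]
        Nk = N - np.outer(pk, pk)
        Sk = Sxy - np.outer(xk, xk)
        Ak = A - np.outer(xk, pk)
        for b, shell in enumerate(shells):
            x_del[k, b] = _bin_x(shell, Nk, Sk, Ak)

    out: list[tuple[float, float]] = []
    for b, shell in enumerate(shells):
        r2 = r2_full[shell.i_idx, shell.j_idx]
        ok = np.isfinite(r2)
        loci = np.unique(np.concatenate([shell.i_idx[ok], shell.j_idx[ok]]))
        xs = x_del[:, b]
        xs = xs[np.isfinite(xs)]
        if loci.size < min_loci or ok.sum() == 0 or xs.size < 4:
            out.append((0.0, float("inf")))
            continue
        n = N[shell.i_idx, shell.j_idx][ok]
        s_harm = ok.sum() / (1.0 / n).sum()
        x_full = _inv_ne(r2[ok].mean(), shell.c_vals[ok].mean(), s_harm)
        m = xs.size
        var = (m - 1) / m * ((xs - xs.mean()) ** 2).sum()
        se = np.sqrt(var)
        x_lo = x_full - 1.959963984540054 * se
        x_hi = x_full + 1.959963984540054 * se
        ne_high = float("inf") if x_lo <= 0 else 1.0 / x_lo
        ne_low = 0.0 if x_hi <= 0 else 1.0 / x_hi
        out.append((float(ne_low), float(ne_high)))
    return out


def map_bin_to_time(
    c_bar: float, generation_time: float = 5.0, start_year: int = 2010
) -> tuple[float, float]:
    """Generation depth ``t = 1/(2 c_bar)`` and the calendar year it maps to."""
    if c_bar <= 0:
        raise ValueError("mean recombination fraction must be positive")
    t = 1.0 / (2.0 * c_bar)
    return t, start_year - generation_time * t


def reconstruct_trajectory(
    G_pop: GenotypeMatrix,
    lmap: LinkageMap,
    settings: LdNeSettings | None = None,
    population: str | None = None,
) -> NeTrajectory:
    """Full single-sample Ne trajectory for one population sample.

    Applies the MAF cut, drops unmapped loci (with a warning), bins locus
    pairs by map distance, and produces a per-bin Ne estimate with a
    jackknife CI and its time mapping, ordered deep -> recent.
    """
    settings = settings or LdNeSettings()
    if population is None:
        pops = G_pop.populations
        population = pops[0] if len(pops) == 1 else "+".join(pops)

    excluded = lmap.unmapped(G_pop.loci)
    if excluded:
        warnings.warn(
            f"{len(excluded)} loci absent from the linkage map are excluded",
            stacklevel=2,
        )
        G_pop = G_pop.subset_loci([l for l in G_pop.loci if l not in excluded])
    G_f, removed = filter_maf(G_pop, settings.maf_cutoff, scope="global")

    r2_mat, n_mat = pairwise_r2_matrices(G_f)
    shells = bin_locus_pairs(
        lmap, G_f.loci, settings.bin_width, settings.max_distance
    )
    cis = _jackknife_all(G_f, shells, settings.min_loci_ci)
    bins: list[PairBin] = []
    for shell, (ci_low, ci_high) in zip(shells, cis):
        r2_vals = r2_mat[shell.i_idx, shell.j_idx]
        n_vals = n_mat[shell.i_idx, shell.j_idx]
        ok = np.isfinite(r2_vals)
        if ok.sum() == 0:
            continue
        r2, c, n = r2_vals[ok], shell.c_vals[ok], n_vals[ok]
        c_bar = float(c.mean())
        s_harm = float(r2.size / (1.0 / n).sum())
        ne_hat, r2_adj = estimate_ne(float(r2.mean()), c_bar, s_harm)
        t, year = map_bin_to_time(
            c_bar, settings.generation_time, settings.start_year
        )
        n_loci_bin = np.unique(
            np.concatenate([shell.i_idx[ok], shell.j_idx[ok]])
        ).size
        bins.append(
            PairBin(
                d_low=shell.d_low,
                d_high=shell.d_high,
                c_bar=c_bar,
                n_pairs=int(ok.sum()),
                n_loci=int(n_loci_bin),
                mean_r2=float(r2.mean()),
                s_harmonic=s_harm,
                r2_adj=float(r2_adj),
                ne_hat=float(ne_hat),
                ci_low=ci_low,
                ci_high=ci_high,
                t=t,
                year=year,
                low_confidence=bool(ok.sum() < settings.min_pairs),
            )
        )
    if not bins:
        raise ValueError("no usable locus pairs; cannot reconstruct trajectory")
    bins.sort(key=lambda b: -b.t)  # deep -> recent
    return NeTrajectory(
        population=population,
        bins=bins,
        settings=settings,
        n_loci_used=G_f.n_loci,
        excluded_loci=excluded + removed,
    )


def write_trajectory_tsv(traj: NeTrajectory, path) -> None:
    df = traj.to_frame()
    for col in ("ne_hat", "ci_low", "ci_high"):
        df[col] = df[col].map(lambda v: "Inf" if np.isinf(v) else f"{v:.6g}")
    with open(path, "w") as fh:
        s = traj.settings
        fh.write(
            f"# bin_width={s.bin_width} max_distance={s.max_distance} "
            f"maf_cutoff={s.maf_cutoff} generation_time={s.generation_time} "
            f"start_year={s.start_year}\n"
        )
        df.to_csv(fh, sep="\t", index=False)
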