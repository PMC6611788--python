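"""Forward Wright-Fisher simulator of diploid SNP-array genotypes.

Simulates each population independently: ``2*Ne`` haplotypes evolve
forward in time under drift, recombination along a linkage map (Haldane
map function, no interference, free recombination between chromosomes)
and optional multiplicative selection at designated sweep loci.  There is
no mutation: loci segregate from standing variation drawn at generation
zero, matching the SNP-array setting where assayed markers are
pre-ascertained polymorphisms.

Two kinds of signal can be injected for downstream detection tests:

* *decline loci* — a fixed allele-frequency offset applied to designated
  loci in the declining group before simulation starts, giving a
  group-associated polygenic signal;
* *sweeps* — positive selection (fitness 1, 1+s, 1+2s by dosage) at a
  locus in one group only, started at a set generation, optionally
  conditioned on the swept allele reaching a target frequency.

Each population consumes an independent random stream spawned from the
master seed, so adding populations never perturbs existing ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LinkageMap, PopulationMeta

logger = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    """A selective sweep at one locus in one group of populations."""

    locus: str
    s: float  # selection coefficient; fitness 1, 1+s, 1+2s
    start_generation: int = 0
    target_group: str | None = None  # None = all populations
    start_freq: float = 0.05
    condition_on_frequency: float | None = None  # resimulate until final freq exceeds
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class ChromosomeLayout:
    """Evenly spaced loci: ``n_loci`` loci ``spacing_morgans`` apart."""

    name: str
    n_loci: int
    spacing_morgans: float
    bp_per_morgan: float = 1e8  # 1 cM/Mbp


@dataclass
class SimulationConfig:
    """Study conditions for one simulated metapopulation.

    ``ne_schedule`` maps population id -> list of ``(generation, Ne)``
    breakpoints; Ne is constant from each breakpoint until the next.
    ``decline_populations`` marks which populations carry the true decline
    label (used for decline-locus shifts and in the truth record).
    """

    seed: int = 0
    chromosomes: list[ChromosomeLayout] = field(
        default_factory=lambda: [
            ChromosomeLayout(f"chr{k+1}", 30, 0.02) for k in range(10)
        ]
    )
    ne_schedule: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {"pop1": [(0, 500)]}
    )
    n_generations: int = 50
    sample_size: int | dict[str, int] = 50
    init_freq_range: tuple[float, float] = (0.05, 0.5)
    decline_populations: set[str] = field(default_factory=set)
    decline_loci: list[str] = field(default_factory=list)
    decline_shift: float = 0.0
    sweeps: list[SweepSpec] = field(default_factory=list)
    group_of: dict[str, str] = field(default_factory=dict)  # pop -> group label
    latitude_range: tuple[float, float] = (45.0, 60.0)
    sampling_year: int = 2010

    def sample_size_of(self, pop: str) -> int:
        if isinstance(self.sample_size, dict):
            return int(self.sample_size[pop])
        return int(self.sample_size)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the simulated data."""

    ne_schedule: dict[str, list[tuple[int, int]]]
    declining: dict[str, bool]
    locus_role: dict[str, str]  # locus -> neutral | sweep | decline-associated
    final_freq: dict[str, dict[str, float]]    # pop -> locus -> frequency
    initial_freq: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        pops = pd.DataFrame(
            {
                "pop": list(self.declining),
                "declining": [self.declining[p] for p in self.declining],
                "ne_schedule": [
                    ";".join(f"{g}:{n}" for g, n in self.ne_schedule[p])
                    for p in self.declining
                ],
            }
        )
        loci = pd.DataFrame(
            {"locus": list(self.locus_role), "role": list(self.locus_role.values())}
        )
        return pops, loci


# ---------------------------------------------------------------------------

def build_linkage_map(chromosomes: list[ChromosomeLayout]) -> LinkageMap:
    """Lay loci out evenly along each chromosome."""
    rows = []
    for chrom in chromosomes:
        for i in range(chrom.n_loci):
            morgans = i * chrom.spacing_morgans
            rows.append(
                (
                    f"{chrom.name}_{i+1}",
                    chrom.name,
                    int(round(morgans * chrom.bp_per_morgan)) + 1,
                    morgans,
                )
            )
    df = pd.DataFrame(rows, columns=["locus", "chrom", "bp", "morgans"]).set_index(
        "locus"
    )
    return LinkageMap(df)


def _recomb_probs(lmap: LinkageMap) -> np.ndarray:
    """Per-adjacent-interval recombination fraction, Haldane; 0.5 across chromosomes."""
    tab = lmap.table
    d = np.diff(tab["morgans"].to_numpy())
    c = 0.5 * (1.0 - np.exp(-2.0 * np.abs(d)))
    same_chrom = tab["chrom"].to_numpy()[1:] == tab["chrom"].to_numpy()[:-1]
    return np.where(same_chrom, c, 0.5)


def apply_decline_shift(
    freqs: np.ndarray,
    loci: list[str],
    shift_loci: list[str],
    delta: float,
    *,
    lo: float = 0.01,
    hi: float = 0.99,
) -> np.ndarray:
    """Offset initial frequencies of designated loci by ``+delta``.

    Frequencies are clamped to ``[lo, hi]``; clamping is logged because it
    attenuates the injected effect size.
    """
    out = freqs.copy()
    index = {l: j for j, l in enumerate(loci)}
    for l in shift_loci:
        if l not in index:
            raise ValueError(f"decline locus {l} not in the locus panel")
        shifted = out[index[l]] + delta
        clamped = min(max(shifted, lo), hi)
        if clamped != shifted:
            logger.warning("decline shift clamped at locus %s: %.3f -> %.3f", l, shifted, clamped)
            warnings.warn(f"decline shift clamped at locus {l}", stacklevel=2)
        out[index[l]] = clamped
    return out


def _make_gametes(
    H: np.ndarray, parent_idx: np.ndarray, c: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one recombinant gamete from each parent in ``parent_idx``."""
    n, L = len(parent_idx), H.shape[1]
    cross = rng.random((n, L - 1)) < c
    which = np.empty((n, L), dtype=np.int8)
    which[:, 0] = rng.integers(0, 2, size=n)
    # cumulative crossover count determines which parental haplotype each
    # locus is copied from
    which[:, 1:] = (which[:, :1] + np.cumsum(cross, axis=1)) % 2
    h0 = H[2 * parent_idx]
    h1 = H[2 * parent_idx + 1]
    return np.where(which == 0, h0, h1)


def _ne_at(schedule: list[tuple[int, int]], gen: int) -> int:
    ne = schedule[0][1]
    for g, n in schedule:
        if gen >= g:
            ne = n
        else:
            break
    return int(ne)


def _simulate_population(
    pop: str,
    config: SimulationConfig,
    lmap: LinkageMap,
    init_freqs: np.ndarray,
    rng: np.random.Generator,
    extra_sample_generations: tuple[int, ...] = (),
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Run one population forward.

    Returns ``(sampled dosages at the final generation, final allele
    frequencies, extra samples)`` where ``extra samples`` maps each
    requested intermediate generation to a dosage matrix drawn without
    replacement at that generation (used for temporal two-sample
    analyses)."""
    schedule = sorted(config.ne_schedule[pop])
    L = len(lmap.loci)
    c = _recomb_probs(lmap)
    locus_index = {l: j for j, l in enumerate(lmap.loci)}
    group = config.group_of.get(pop, "all")

    sweeps_here = [
        sw
        for sw in config.sweeps
        if sw.target_group is None or sw.target_group == group
    ]
    for sw in sweeps_here:
        if sw.locus not in locus_index:
            raise ValueError(f"sweep locus {sw.locus} not in the locus panel")

    S = config.sample_size_of(pop)
    for attempt in range(max((sw.max_retries for sw in sweeps_here), default=0) + 1):
        ne0 = _ne_at(schedule, 0)
        if any(n < 2 for _, n in schedule):
            raise ValueError("Ne must be >= 2 at all times")
        freqs0 = init_freqs.copy()
        for sw in sweeps_here:
            freqs0[locus_index[sw.locus]] = sw.start_freq
        H = (rng.random((2 * ne0, L)) < freqs0).astype(np.int8)
        realized0 = H.mean(axis=0)  # realized generation-0 frequency
        extra_samples: dict[int, np.ndarray] = {}

        for gen in range(1, config.n_generations + 1):
            ne = _ne_at(schedule, gen)
            n_par = H.shape[0] // 2
            # selection: parent draw weighted by multiplicative sweep fitness
            active = [sw for sw in sweeps_here if gen >= sw.start_generation]
            if active:
                w = np.ones(n_par)
                for sw in active:
                    j = locus_index[sw.locus]
                    dos = H[0::2, j].astype(int) + H[1::2, j].astype(int)
                    w *= 1.0 + sw.s * dos
                w = w / w.sum()
                parents_a = rng.choice(n_par, size=ne, p=w)
                parents_b = rng.choice(n_par, size=ne, p=w)
            else:
                parents_a = rng.integers(0, n_par, size=ne)
                parents_b = rng.integers(0, n_par, size=ne)
            gam_a = _make_gametes(H, parents_a, c, rng)
            gam_b = _make_gametes(H, parents_b, c, rng)
            H_next = np.empty((2 * ne, L), dtype=np.int8)
            H_next[0::2] = gam_a
            H_next[1::2] = gam_b
            H = H_next
            if gen in extra_sample_generations:
                n_ind = H.shape[0] // 2
                if S > n_ind:
                    raise ValueError(
                        f"sample size {S} exceeds Ne {n_ind} at generation {gen}"
                    )
                pick = rng.choice(n_ind, size=S, replace=False)
                extra_samples[gen] = (H[2 * pick] + H[2 * pick + 1]).astype(np.int8)

        final_freq = H.mean(axis=0)
        conditioned = all(
            sw.condition_on_frequency is None
            or final_freq[locus_index[sw.locus]] > sw.condition_on_frequency
            for sw in sweeps_here
        )
        if conditioned:
            break
    else:
        raise RuntimeError(
            f"sweep conditioning failed in population {pop} after retries"
        )

    ne_final = H.shape[0] // 2
    if S > ne_final:
        raise ValueError(
            f"sample size {S} exceeds final Ne {ne_final} in population {pop}"
        )
    picked = rng.choice(ne_final, size=S, replace=False)
    dosage = H[2 * picked] + H[2 * picked + 1]
    return dosage.astype(np.int8), final_freq, extra_samples, realized0


def simulate_metapopulation(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, LinkageMap, PopulationMeta, TruthRecord]:
    """Simulate every population in ``config`` and emit the combined panel.

    Identical config (including seed) always yields identical output.
    """
    from zlib import crc32

    lmap = build_linkage_map(config.chromosomes)
    loci = lmap.loci
    L = len(loci)
    pops = sorted(config.ne_schedule)
    # per-population streams keyed on the population *name*, so adding or
    # removing a population never perturbs the others
    streams = {
        p: np.random.default_rng(
            np.random.SeedSequence([config.seed, crc32(p.encode())])
        )
        for p in pops
    }
    init_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A17]))
    lo, hi = config.init_freq_range
    base_freqs = lo + (hi - lo) * init_rng.random(L)

    locus_role = {l: "neutral" for l in loci}
    for l in config.decline_loci:
        locus_role[l] = "decline-associated"
    for sw in config.sweeps:
        locus_role[sw.locus] = "sweep"

    all_dosage = []
    samples: list[str] = []
    population_of: dict[str, str] = {}
    final_freqs: dict[str, dict[str, float]] = {}
    initial_freqs: dict[str, dict[str, float]] = {}
    lat_lo, lat_hi = config.latitude_range
    meta_rows = []
    for p in pops:
        lat_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x7A7, crc32(p.encode())])
        )
        freqs = base_freqs
        if config.decline_shift and p in config.decline_populations:
            freqs = apply_decline_shift(
                base_freqs, loci, config.decline_loci, config.decline_shift
            )
        dosage, ff, _, f0 = _simulate_population(p, config, lmap, freqs, streams[p])
        all_dosage.append(dosage)
        names = [f"{p}_ind{i+1}" for i in range(dosage.shape[0])]
        samples.extend(names)
        population_of.update({s: p for s in names})
        final_freqs[p] = dict(zip(loci, ff))
        initial_freqs[p] = dict(zip(loci, f0))
        meta_rows.append(
            (
                p,
                "simulated",
                round(float(lat_lo + (lat_hi - lat_lo) * lat_rng.random()), 3),
                config.sampling_year,
                p in config.decline_populations,
            )
        )

    G = GenotypeMatrix(
        samples=samples,
        population_of=population_of,
        loci=list(loci),
        dosage=np.vstack(all_dosage),
    )
    meta = PopulationMeta(
        pd.DataFrame(
            meta_rows, columns=["pop", "continent", "latitude", "year", "declining"]
        ).set_index("pop")
    )
    truth = TruthRecord(
        ne_schedule={p: sorted(config.ne_schedule[p]) for p in pops},
        declining={p: p in config.decline_populations for p in pops},
        locus_role=locus_role,
        final_freq=final_freqs,
        initial_freq=initial_freqs,
    )
    return G, lmap, meta, truth


def simulate_temporal_samples(
    config: SimulationConfig,
    population: str,
    historical_generation: int,
) -> tuple[GenotypeMatrix, GenotypeMatrix, LinkageMap]:
    """One population sampled at two time points of the same realization.

    Returns ``(G_historical, G_recent, linkage_map)`` — a sample drawn at
    ``historical_generation`` and one at the final generation — for
    temporal (two-sample) Ne comparisons.
    """
    from zlib import crc32

    if not 0 < historical_generation < config.n_generations:
        raise ValueError("historical generation must fall inside the simulation")
    lmap = build_linkage_map(config.chromosomes)
    L = len(lmap.loci)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, crc32(population.encode())])
    )
    init_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A17]))
    lo, hi = config.init_freq_range
    freqs = lo + (hi - lo) * init_rng.random(L)
    recent, _, extra, _ = _simulate_population(
        population, config, lmap, freqs, rng, (historical_generation,)
    )
    historical = extra[historical_generation]

    def wrap(dosage: np.ndarray, tag: str) -> GenotypeMatrix:
        names = [f"{population}_{tag}{i+1}" for i in range(dosage.shape[0])]
        return GenotypeMatrix(
            samples=names,
            population_of={s: population for s in names},
            loci=list(lmap.loci),
            dosage=dosage,
        )

    return wrap(historical, "hist"), wrap(recent, "rec"), lmap


# -- canonical scenarios ----------------------------------------------------

#: the default decline history: large and stable, then a recent collapse
DECLINE_NE_HIGH = 2000
DECLINE_NE_LOW = 100


def constant_schedule(ne: int) -> list[tuple[int, int]]:
    return [(0, ne)]


def decline_schedule(
    n_generations: int,
    onset_generations_before_sampling: int = 10,
    ne_high: int = DECLINE_NE_HIGH,
    ne_low: int = DECLINE_NE_LOW,
) -> list[tuple[int, int]]:
    """Constant ``ne_high`` history with a step down to ``ne_low`` shortly
    before sampling (default: 10 generations before)."""
    onset = n_generations - onset_generations_before_sampling
    if onset <= 0:
        raise ValueError("decline onset precedes the start of the simulation")
    return [(0, ne_high), (onset, ne_low)]
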