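"""Benchmark experiments that measure the pipeline under known truth.

Each function runs one calibration or power experiment on simulated data
with the study-condition defaults (constant-Ne panels of 300 mapped SNPs
at S = 50; the decline scenario Ne 2000 -> 100; the two-group sweep
scenario at s = 0.2) and returns plain numbers: estimator medians, CI
coverage, classifier operating rates, oracle agreement, outlier-rule
tail mass, sweep localisation rate, risk-model recovery and the
leave-one-population-out null rate.  The acceptance script and the
acceptance tests both drive these, so the quantities are always
recomputed from scratch.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np

from . import classify as classify_mod
from . import ldne, rda, risk
from . import simulate as sim
from .genotypes import filter_maf
from .pipeline import PipelineConfig, run_pipeline
from .sweeps import aggregate_delta, flag_delta_outliers, mu_scan

#: the constant-Ne study panel: 10 chromosomes x 30 SNPs, 0.02 M spacing
STUDY_CHROMOSOMES = [sim.ChromosomeLayout(f"chr{k+1}", 30, 0.02) for k in range(10)]
STUDY_SAMPLE_SIZE = 50


def _seeds(master_seed: int, tag: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), int(tag)])
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def time_mapping_anchor() -> tuple[float, float]:
    """Generation depth and calendar year of the unlinked bin (c = 0.5)."""
    return ldne.map_bin_to_time(0.5, generation_time=5.0, start_year=2010)


def _constant_ne_trajectory(ne: int, seed: int) -> ldne.NeTrajectory:
    cfg = sim.SimulationConfig(
        seed=seed,
        chromosomes=STUDY_CHROMOSOMES,
        ne_schedule={"p1": [(0, ne)]},
        n_generations=50,
        sample_size=STUDY_SAMPLE_SIZE,
    )
    G, lmap, _, _ = sim.simulate_metapopulation(cfg)
    return ldne.reconstruct_trajectory(G, lmap)


def ne_recovery(ne: int, n_reps: int, master_seed: int) -> dict:
    """Unlinked-bin Ne estimates and jackknife-CI coverage at known truth."""
    estimates, covered = [], 0
    for s in _seeds(master_seed, 100 + ne, n_reps):
        traj = _constant_ne_trajectory(ne, s)
        b = next(x for x in traj.bins if x.unlinked)
        estimates.append(b.ne_hat)
        covered += int(b.ci_low <= ne <= b.ci_high)
    return {
        "true_ne": ne,
        "median_ne": float(np.median(estimates)),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def classifier_rate(scenario: str, n_reps: int, master_seed: int) -> float:
    """Fraction of replicates called declining.

    ``scenario``: 'constant' (Ne 500; the rate is a false-positive rate)
    or 'decline' (the default crash Ne 2000 -> 100 ten generations before
    sampling; the rate is sensitivity).
    """
    if scenario == "constant":
        schedule = sim.constant_schedule(500)
        tag = 300
    elif scenario == "decline":
        schedule = sim.decline_schedule(50, 10)
        tag = 301
    else:
        raise ValueError(scenario)
    n_declining = 0
    for s in _seeds(master_seed, tag, n_reps):
        cfg = sim.SimulationConfig(
            seed=s,
            chromosomes=STUDY_CHROMOSOMES,
            ne_schedule={"p1": schedule},
            n_generations=50,
            sample_size=STUDY_SAMPLE_SIZE,
        )
        G, lmap, _, _ = sim.simulate_metapopulation(cfg)
        call = classify_mod.classify(ldne.reconstruct_trajectory(G, lmap))
        n_declining += call.status == "declining"
    return n_declining / n_reps


def rda_oracle_agreement(master_seed: int, n_instances: int = 5) -> float:
    """Smallest correlation between RDA locus scores and the brute-force
    residualized-covariance oracle over random instances (<= 50 x 50)."""
    worst = 1.0
    for s in _seeds(master_seed, 400, n_instances):
        rng = np.random.default_rng(s)
        n = int(rng.integers(12, 51))
        L = int(rng.integers(10, 51))
        dosage = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        y = np.zeros(n)
        y[: n // 2] = 1.0
        lat = rng.normal(50, 5, n)
        samples = [f"s{i}" for i in range(n)]
        from .genotypes import GenotypeMatrix

        G = GenotypeMatrix(
            samples=samples,
            population_of={s_: ("dec" if y[i] else "non") for i, s_ in enumerate(samples)},
            loci=[f"l{j}" for j in range(L)],
            dosage=dosage,
        )
        res = rda.run_partial_rda(G, y, {"latitude": lat})
        Z = np.column_stack([np.ones(n), lat])
        proj = Z @ np.linalg.pinv(Z)
        X = dosage.astype(float)
        X = X - X.mean(axis=0)
        ref = (y - proj @ y) @ (X - proj @ X)
        worst = min(worst, float(np.corrcoef(ref, res.locus_scores)[0, 1]))
    return worst


def outlier_tail_fraction(master_seed: int, n: int = 10_000) -> float:
    """Fraction of standard-normal scores flagged by the +-3 SD rule."""
    rng = np.random.default_rng(_seeds(master_seed, 500, 1)[0])
    return float(rda.flag_outlier_loci(rng.standard_normal(n), 3.0).mean())


# -- sweep scenario ---------------------------------------------------------

SWEEP_CHROMOSOMES = [
    sim.ChromosomeLayout("chr1", 500, 2e-4),
    sim.ChromosomeLayout("chr2", 500, 2e-4),
]
#: mid-bin locus on chr1 (~5.5 Mbp), so the swept site sits inside a bin
SWEEP_LOCUS_INDEX = 275


def sweep_scenario_config(seed: int) -> sim.SimulationConfig:
    lmap = sim.build_linkage_map(SWEEP_CHROMOSOMES)
    return sim.SimulationConfig(
        seed=seed,
        chromosomes=SWEEP_CHROMOSOMES,
        ne_schedule={p: [(0, 200)] for p in ("a1", "a2", "b1", "b2")},
        group_of={
            "a1": "non-declining", "a2": "non-declining",
            "b1": "declining", "b2": "declining",
        },
        n_generations=40,
        sample_size=30,
        sweeps=[
            # conditioned near fixation: a completed sweep is what leaves
            # the diversity/SFS/LD signature the scan is built to detect
            sim.SweepSpec(
                lmap.loci[SWEEP_LOCUS_INDEX], s=0.2, start_generation=5,
                target_group="non-declining", condition_on_frequency=0.95,
            )
        ],
    )


def sweep_localisation_rate(n_reps: int, master_seed: int) -> float:
    """How often the maximum-|z| 1-Mbp bin falls at the injected sweep.

    A hit is a positive-z maximum bin within 1 Mbp of the sweep position
    (the same slack the window-overlap rule uses, since SNP-driven
    windows blur bin boundaries).
    """
    hits = 0
    for s in _seeds(master_seed, 600, n_reps):
        cfg = sweep_scenario_config(s)
        G, lmap, _, _ = sim.simulate_metapopulation(cfg)
        panel, _ = filter_maf(G, 0.01)
        mu_n = mu_scan(panel.subset_populations(["a1", "a2"]), lmap)
        mu_d = mu_scan(panel.subset_populations(["b1", "b2"]), lmap)
        delta = flag_delta_outliers(aggregate_delta(mu_n, mu_d))
        zmax = max(delta, key=lambda w: abs(w.z))
        sweep_bp = int(lmap.table.iloc[SWEEP_LOCUS_INDEX]["bp"])
        hit = (
            zmax.z > 0
            and zmax.chrom == "chr1"
            and zmax.bp_start - 1_000_000 <= sweep_bp <= zmax.bp_end + 1_000_000
        )
        hits += int(hit)
    return hits / n_reps


def risk_beta_odds_ratio_two() -> float:
    """Log-odds weight recovered from a one-locus 2x2 table with OR = 2."""
    from .genotypes import GenotypeMatrix

    dosage, label = [], []
    dosage += [0] * 300
    label += [1] * 100 + [0] * 200       # odds 0.5 at dosage 0
    dosage += [1] * 300
    label += [1] * 150 + [0] * 150       # odds 1.0 at dosage 1
    samples = [f"s{i}" for i in range(600)]
    G = GenotypeMatrix(
        samples=samples,
        population_of={s: ("dec" if label[i] else "non") for i, s in enumerate(samples)},
        loci=["locus1"],
        dosage=np.array(dosage, np.int8)[:, None],
    )
    model = risk.fit_risk_model(G, np.array(label, float))
    return float(model.beta[0])


def lopo_null_fraction(master_seed: int, n_reps: int = 3) -> float:
    """LOPO significance rate on panels with no causal decline loci.

    Twelve exchangeable constant-Ne populations per replicate, half
    labelled declining; the risk model is fitted to arbitrarily chosen
    loci (there is no signal to find) and every population is tested.
    """
    n_sig = n_tot = 0
    for s in _seeds(master_seed, 700, n_reps):
        chroms = [sim.ChromosomeLayout(f"c{k+1}", 50, 0.002) for k in range(10)]
        pops = [f"d{i}" for i in range(6)] + [f"n{i}" for i in range(6)]
        cfg = sim.SimulationConfig(
            seed=s,
            chromosomes=chroms,
            ne_schedule={p: [(0, 300)] for p in pops},
            n_generations=20,
            sample_size=30,
        )
        G, lmap, _, _ = sim.simulate_metapopulation(cfg)
        labels = np.array(
            [1.0 if G.population_of[x].startswith("d") else 0.0 for x in G.samples]
        )
        loci = G.loci[::25][:20]
        out = risk.lopo_repeatability(G, labels, loci)
        tested = out[~out["skipped"]]
        n_sig += int(tested["significant"].sum())
        n_tot += len(tested)
    return n_sig / n_tot


def pipeline_demo(master_seed: int, outdir: str | Path) -> dict:
    """Run the 12-population demo pipeline twice; report time and identity."""
    outdir = Path(outdir)

    def one(run_dir: Path) -> tuple[float, dict[str, str]]:
        t0 = time.time()
        run_pipeline(PipelineConfig(outdir=str(run_dir), seed=master_seed))
        elapsed = time.time() - t0
        hashes = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(run_dir.glob("*.tsv"))
        }
        return elapsed, hashes

    t1, h1 = one(outdir / "run1")
    t2, h2 = one(outdir / "run2")
    return {
        "runtime_seconds": max(t1, t2),
        "reproducible": h1 == h2 and len(h1) > 0,
        "n_artifacts": len(h1),
    }
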