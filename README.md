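# popdecline

Genomic detection and prediction of population decline for conservation
genetics.  Given diploid SNP-array genotypes from many wild populations,
a sex-averaged linkage map and population metadata, `popdecline`:

1. reconstructs each population's **effective population size (Ne) back
   through time from a single contemporary sample**, by binning locus
   pairs on recombination rate — LD among pairs with recombination
   fraction *c* reflects Ne roughly *t = 1/2c* generations ago, so
   E[r²] ≈ γ(c)/Ne + 1/S inverted bin by bin yields a trajectory;
2. classifies populations as **significantly declining** when the Ne
   estimate nearest 1975 and the one nearest 2005 have non-overlapping
   95% CIs (or when an unbounded historical estimate becomes bounded);
3. finds **decline-associated loci** with a partial redundancy analysis
   of individual genotypes constrained by decline status and conditioned
   on latitude (±3 SD score outliers);
4. contrasts **selective-sweep signatures** between declining and
   non-declining groups with a composite µ statistic (diversity
   reduction × folded-SFS tail × LD structure) in sliding windows,
   differenced in 1-Mbp bins (Δµ) with ±3 SD outliers and 1-Mbp overlap
   matching against the RDA loci;
5. computes **weighted polygenic risk-of-decline scores**
   (score = Σⱼ βⱼ·gⱼ with logistic-model weights on the top 100
   distance-thinned RDA outliers) and tests their repeatability by
   leave-one-population-out refitting with Mann–Whitney comparisons.

A forward Wright–Fisher simulator (drift, linkage-map recombination,
optional sweeps and group-associated frequency shifts) generates
synthetic cohorts with known truth, so every stage is tested end to end
without external data.  See `docs/methods.md` for the models,
assumptions and design choices.

The audience is population and conservation geneticists who want these
analyses as one coherent, reproducible, file-based pipeline — and a
sandbox for asking when the estimators can and cannot work.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort — 12 populations × 30 diploids × 500 mapped SNPs, six
populations crashing from Ne 2000 to 100 ten generations before
sampling, with 20 decline-associated loci shifted by +0.15:

```bash
python analysis/01_simulate_cohort.py --seed 1 --outdir results
python analysis/02_ne_trajectories.py --outdir results
python analysis/03_classify_declines.py --outdir results
python analysis/04_rda_decline_loci.py --outdir results
python analysis/05_sweep_contrast.py --outdir results
python analysis/06_risk_scores.py --outdir results
```

`02_ne_trajectories.py` prints, per population, the deepest-bin estimate
against the most recent (unlinked-bin, "2005") estimate:

```
dec1: Ne(1899) = 236  ->  Ne(2005) = 112
dec2: Ne(1899) = 229  ->  Ne(2005) = 56
...
non1: Ne(1898) = 548  ->  Ne(2005) = 455
non3: Ne(1899) = 588  ->  Ne(2005) = 488
```

The crashed populations' recent estimates sit near 100 and their deep
bins above 230, while constant-Ne populations hover around their true
500 at all depths.  Note the deep bins of the crashed populations read
~250, not 2000: recent drift contaminates historical LD, which is why
the magnitude of a decline is not estimated and why the 1975-vs-2005 CI
rule is conservative on crashes this old (`03_classify_declines.py`
reports the calls together with the truth labels; the mechanism is
quantified in `docs/methods.md`).

`04`–`06` then report, for seed 1:

```
constrained axis explains 1.32% of the conditioned genotype variance;
4 outlier loci (4 of the 20 causal loci on the panel)

70 1-Mbp bins: 1 +dmu outliers ... 1 decline-associated SNP falls
within 1 Mbp of a delta-mu outlier window

risk model: 4 loci, ridge penalty 0
mean score 6.12 in declining vs 2.97 in non-declining populations
LOPO repeatability: 0/12 populations shift significantly at alpha 0.0042
```

— every RDA outlier is a true causal locus, and the risk score separates
the declining group without any population dominating the model.

The same pipeline is available as a single call
(`popdecline.run_pipeline(PipelineConfig(seed=1))`) writing the full
artifact tree with parameter-echoing headers, or stage by stage from
YAML configs.

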