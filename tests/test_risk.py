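"""Risk-locus selection, logistic weights, scores and LOPO repeatability."""

import numpy as np
import pandas as pd
import pytest

from popdecline import simulate as sim
from popdecline.genotypes import LinkageMap
from popdecline.risk import (
    RiskModel,
    compute_scores,
    fit_risk_model,
    lopo_repeatability,
    select_score_loci,
)
from conftest import make_matrix


def map_from_bp(bps, chrom="c1"):
    tab = pd.DataFrame(
        {"chrom": [chrom] * len(bps), "bp": bps, "morgans": [b / 1e8 for b in bps]},
        index=[f"snp{i}" for i in range(len(bps))],
    )
    return LinkageMap(tab)


class TestSelection:
    def test_thinning_keeps_best_per_window(self):
        lmap = map_from_bp([100_000, 500_000])  # same 1-Mbp window, 0.4 Mbp apart
        got = select_score_loci(["snp0", "snp1"], {"snp0": 1.0, "snp1": -2.0}, lmap)
        assert got == ["snp1"]

    def test_fewer_than_n_all_kept(self):
        lmap = map_from_bp([i * 2_000_000 for i in range(60)])
        loci = [f"snp{i}" for i in range(60)]
        scores = {l: float(i) for i, l in enumerate(loci)}
        assert len(select_score_loci(loci, scores, lmap, n=100)) == 60

    def test_matches_brute_force_enumeration(self):
        # 7 outliers over 3 windows
        bps = [100, 200_000, 900_000, 1_200_000, 1_800_000, 2_200_000, 2_900_000]
        lmap = map_from_bp(bps)
        loci = [f"snp{i}" for i in range(7)]
        scores = dict(zip(loci, [0.5, -1.5, 1.0, 2.0, -2.0, 0.3, 0.3]))
        got = select_score_loci(loci, scores, lmap, n=2)
        # brute force: best per window: w0 -> snp1 (1.5), w1 -> snp4 (2.0), w2 -> snp5 (tie, id order)
        window = {l: (int(lmap.table.at[l, "bp"]) - 1) // 10**6 for l in loci}
        best = {}
        for l in loci:
            w = window[l]
            cur = best.get(w)
            if cur is None or (abs(scores[l]), ) > (abs(scores[cur]),) or (
                abs(scores[l]) == abs(scores[cur]) and l < cur
            ):
                best[w] = l
        expected = sorted(best.values(), key=lambda l: (-abs(scores[l]), l))[:2]
        assert got == expected

    def test_empty_outlier_set_errors(self):
        with pytest.raises(ValueError):
            select_score_loci([], {}, map_from_bp([1]))


class TestLogisticFit:
    def test_constant_dosage_gives_zero_beta_and_class_balance_intercept(self):
        d = np.ones((40, 1), np.int8)
        labels = np.array([1.0] * 10 + [0.0] * 30)
        G = make_matrix(d, populations=["dec"] * 10 + ["non"] * 30)
        m = fit_risk_model(G, labels)
        # slope on a constant column is unidentifiable with the intercept;
        # the fitted linear predictor must still equal the class log-odds
        logit = m.intercept + m.beta[0] * 1.0
        assert logit == pytest.approx(np.log(10 / 30), abs=1e-4)

    def test_two_by_two_odds_ratio_recovers_log_or(self):
        dos, lab = [], []
        dos += [0] * 300
        lab += [1] * 100 + [0] * 200   # odds 0.5
        dos += [1] * 300
        lab += [1] * 150 + [0] * 150   # odds 1.0 -> OR 2
        d = np.array(dos, np.int8)[:, None]
        labels = np.array(lab, float)
        pops = ["dec" if v else "non" for v in lab]
        m = fit_risk_model(make_matrix(d, populations=pops), labels)
        assert m.beta[0] == pytest.approx(np.log(2), abs=1e-4)
        assert m.penalty == 0.0

    def test_separation_falls_back_to_ridge(self):
        # perfectly separating locus
        d = np.array([0] * 20 + [2] * 20, np.int8)[:, None]
        labels = np.array([0.0] * 20 + [1.0] * 20)
        pops = ["non"] * 20 + ["dec"] * 20
        m = fit_risk_model(make_matrix(d, populations=pops), labels)
        assert m.converged and m.penalty > 0
        assert np.isfinite(m.beta).all()

    def test_single_class_rejected(self):
        d = np.zeros((10, 1), np.int8)
        with pytest.raises(ValueError, match="both"):
            fit_risk_model(make_matrix(d), np.ones(10))

    def test_causal_beta_sign_tracks_frequency_shift(self):
        chroms = [sim.ChromosomeLayout(f"c{k+1}", 50, 0.002) for k in range(4)]
        lmap = sim.build_linkage_map(chroms)
        causal = lmap.loci[::20][:8]
        cfg = sim.SimulationConfig(
            seed=77, chromosomes=chroms,
            ne_schedule={
                **{f"d{i}": [(0, 300)] for i in range(3)},
                **{f"n{i}": [(0, 300)] for i in range(3)},
            },
            n_generations=15, sample_size=30,
            decline_populations={f"d{i}" for i in range(3)},
            decline_loci=causal, decline_shift=0.15,
        )
        G, _, _, _ = sim.simulate_metapopulation(cfg)
        labels = np.array(
            [1.0 if G.population_of[s].startswith("d") else 0.0 for s in G.samples]
        )
        m = fit_risk_model(G, labels, causal)
        # +delta shift in decliners -> positive mean weight on counted allele
        assert m.beta.mean() > 0


class TestScores:
    def model(self, loci, beta):
        return RiskModel(
            loci=loci, beta=np.asarray(beta, float), intercept=0.3,
            converged=True, penalty=0.0,
        )

    def test_zero_weights_zero_scores(self):
        G = make_matrix(np.random.default_rng(0).integers(0, 3, (5, 3)).astype(np.int8))
        t = compute_scores(G, self.model(G.loci, [0, 0, 0]))
        np.testing.assert_array_equal(t.scores, 0)

    def test_single_locus_arithmetic(self):
        G = make_matrix(np.array([[0], [1], [2]], np.int8))
        t = compute_scores(G, self.model(G.loci, [np.log(2)]))
        np.testing.assert_allclose(t.scores, [0.0, np.log(2), 2 * np.log(2)])

    def test_linearity_in_weights(self):
        G = make_matrix(np.random.default_rng(1).integers(0, 3, (6, 4)).astype(np.int8))
        b = np.array([0.5, -1.0, 0.2, 0.0])
        s1 = compute_scores(G, self.model(G.loci, b)).scores
        s2 = compute_scores(G, self.model(G.loci, 2 * b)).scores
        np.testing.assert_allclose(s2, 2 * s1)

    def test_locus_order_irrelevant(self):
        G = make_matrix(np.random.default_rng(2).integers(0, 3, (6, 3)).astype(np.int8))
        b = [0.5, -0.25, 1.0]
        s1 = compute_scores(G, self.model(G.loci, b)).scores
        m2 = self.model(list(reversed(G.loci)), list(reversed(b)))
        s2 = compute_scores(G, m2).scores
        np.testing.assert_allclose(s1, s2)

    def test_missing_model_locus_errors(self):
        G = make_matrix(np.zeros((4, 2), np.int8))
        with pytest.raises(ValueError, match="absent"):
            compute_scores(G, self.model(["ghost"], [1.0]))


class TestLopo:
    def build_panel(self, seed=0, n_pops=10, per_pop=10, L=10):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, L)
        d = (rng.random((n_pops * per_pop, L)) < p).astype(np.int8) + (
            rng.random((n_pops * per_pop, L)) < p
        ).astype(np.int8)
        pops = sum([[f"p{k}"] * per_pop for k in range(n_pops)], [])
        G = make_matrix(d, populations=pops)
        declining = {f"p{k}" for k in range(n_pops // 2)}
        labels = np.array([1.0 if pop in declining else 0.0 for pop in pops])
        return G, labels

    def test_null_panel_rarely_significant(self):
        G, labels = self.build_panel()
        out = lopo_repeatability(G, labels, G.loci)
        assert len(out) == 10
        assert out["alpha"].iloc[0] == pytest.approx(0.05 / 10)
        # exchangeable populations: excluding one should rarely move scores
        assert out["significant"].sum() <= 1

    def test_tiny_population_skipped(self):
        G, labels = self.build_panel()
        last = [s for s in G.samples if G.population_of[s] == "p9"]
        keep = [s for s in G.samples if G.population_of[s] != "p9"] + last[:1]
        G2 = G.subset_samples(sorted(keep, key=G.samples.index))
        labels2 = np.array(
            [labels[G.samples.index(s)] for s in G2.samples]
        )
        out = lopo_repeatability(G2, labels2, G2.loci)
        row = out[out["population"] == "p9"].iloc[0]
        assert row["skipped"]

    def test_identical_models_give_p_one(self):
        from popdecline.risk import _mwu

        a = np.array([1.0, 2.0, 3.0, 4.0])
        U, p = _mwu(a, a.copy())
        assert p == pytest.approx(1.0)
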