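"""Composite LD, map-distance binning, Ne estimation and time mapping."""

import numpy as np
import pytest

from popdecline import simulate as sim
from popdecline.genotypes import MISSING
from popdecline.ldne import (
    bin_locus_pairs,
    composite_r2,
    estimate_ne,
    gamma_c,
    haldane_c,
    jackknife_ci,
    map_bin_to_time,
    pairwise_r2_matrices,
    reconstruct_trajectory,
)
from conftest import make_matrix


class TestCompositeR2:
    @pytest.mark.parametrize(
        "ga, gb, expected",
        [
            ([0, 1, 1, 2], [0, 1, 1, 2], 1.0),   # perfect coupling
            ([0, 1, 1, 2], [2, 1, 1, 0], 1.0),   # perfect repulsion
            ([0, 0, 2, 2], [0, 2, 0, 2], 0.0),   # independence
        ],
    )
    def test_worked_examples(self, ga, gb, expected):
        assert composite_r2(ga, gb) == pytest.approx(expected, abs=1e-12)

    def test_counted_allele_relabel_invariance(self):
        rng = np.random.default_rng(0)
        ga = rng.integers(0, 3, 30)
        gb = rng.integers(0, 3, 30)
        r = composite_r2(ga, gb)
        assert composite_r2(2 - ga, gb) == pytest.approx(r, abs=1e-12)
        assert composite_r2(ga, 2 - gb) == pytest.approx(r, abs=1e-12)

    def test_monomorphic_locus_gives_nan(self):
        assert np.isnan(composite_r2([0, 0, 0, 0], [0, 1, 2, 0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            composite_r2([0, 1, 2], [0, 1, 2])

    def test_missing_pairs_dropped(self):
        ga = [0, 1, 1, 2, MISSING]
        gb = [0, 1, 1, 2, 2]
        assert composite_r2(ga, gb) == pytest.approx(1.0)

    def test_matrix_path_matches_scalar(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(25, 8)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        G = make_matrix(d)
        r2, n = pairwise_r2_matrices(G)
        for i in range(8):
            for j in range(i + 1, 8):
                expected = composite_r2(d[:, i], d[:, j])
                if np.isnan(expected):
                    assert np.isnan(r2[i, j])
                else:
                    assert r2[i, j] == pytest.approx(expected, abs=1e-12)


class TestGammaAndTime:
    def test_gamma_unlinked_is_one_third(self):
        assert gamma_c(0.5) == pytest.approx(1 / 3)

    def test_gamma_positive_decreasing(self):
        c = np.linspace(0.01, 0.5, 200)
        g = gamma_c(c)
        assert (g > 0).all() and (np.diff(g) < 0).all()

    def test_haldane_examples(self):
        assert haldane_c(0.03) == pytest.approx(0.5 * (1 - np.exp(-0.06)))
        assert haldane_c(0.0) == 0.0

    @pytest.mark.parametrize(
        "c, t, year",
        [
            (0.5, 1.0, 2005.0),
            (0.075, 1 / 0.15, 2010 - 5 / 0.15),
            (0.025, 20.0, 1910.0),
        ],
    )
    def test_time_mapping(self, c, t, year):
        tt, yy = map_bin_to_time(c)
        assert tt == pytest.approx(t) and yy == pytest.approx(year)

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            map_bin_to_time(0.0)


class TestBinning:
    @pytest.fixture
    def lmap(self):
        return sim.build_linkage_map(
            [sim.ChromosomeLayout("c1", 6, 0.03), sim.ChromosomeLayout("c2", 2, 0.03)]
        )

    def test_bin_edges_left_open_right_closed(self, lmap):
        shells = bin_locus_pairs(lmap, lmap.loci, bin_width=0.05, max_distance=0.25)
        # c1 loci at 0, .03, .06, ...: distance 0.03 -> bin 1; 0.06 -> bin 2
        d = {
            (shells[0].d_low, shells[0].d_high): None,
            (shells[1].d_low, shells[1].d_high): None,
        }
        assert (0.0, 0.05) in d and (0.05, 0.10) in d
        idx = {l: i for i, l in enumerate(lmap.loci)}
        pair_03 = (idx["c1_1"], idx["c1_2"])  # 0.03 M apart
        pair_06 = (idx["c1_1"], idx["c1_3"])  # 0.06 M apart
        bin1 = set(zip(shells[0].i_idx, shells[0].j_idx))
        bin2 = set(zip(shells[1].i_idx, shells[1].j_idx))
        assert pair_03 in bin1 and pair_06 in bin2

    def test_cross_chromosome_pairs_unlinked_c_half(self, lmap):
        shells = bin_locus_pairs(lmap, lmap.loci)
        unl = shells[-1]
        assert (unl.c_vals == 0.5).all()
        assert len(unl.c_vals) == 6 * 2  # every c1 x c2 pair

    def test_haldane_c_within_bins(self, lmap):
        shells = bin_locus_pairs(lmap, lmap.loci)
        assert shells[0].c_vals[0] == pytest.approx(0.5 * (1 - np.exp(-0.06)))


class TestEstimateNe:
    def test_unlinked_closed_form(self):
        ne, r2a = estimate_ne(0.0433, 0.5, 30.0)
        assert r2a == pytest.approx(0.0433 - 1 / 30)
        assert ne == pytest.approx((1 / 3) / r2a)
        assert ne == pytest.approx(33.3, rel=0.01)

    def test_unbounded_when_noise_exceeds_signal(self):
        ne, r2a = estimate_ne(0.01, 0.5, 50.0)
        assert np.isinf(ne) and r2a < 0

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match="unreliable"):
            estimate_ne(0.05, 0.5, 3.0)


class TestJackknife:
    def test_degenerate_sample_gives_zero_width(self):
        # perfectly balanced panel: every leave-one-out estimate identical
        block = np.array([[0, 0], [1, 1], [2, 2]], np.int8)
        d = np.tile(block, (8, 6))  # 24 samples x 12 loci
        G = make_matrix(d)
        lmap = sim.build_linkage_map([sim.ChromosomeLayout(f"c{k}", 1, 0.01) for k in range(12)])
        G = make_matrix(d, loci=lmap.loci)
        shells = bin_locus_pairs(lmap, lmap.loci)
        lo, hi = jackknife_ci(G, shells[-1])
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_few_loci_reports_unbounded(self):
        d = np.random.default_rng(0).integers(0, 3, (20, 4)).astype(np.int8)
        lmap = sim.build_linkage_map([sim.ChromosomeLayout(f"c{k}", 1, 0.01) for k in range(4)])
        G = make_matrix(d, loci=lmap.loci)
        shells = bin_locus_pairs(lmap, lmap.loci)
        lo, hi = jackknife_ci(G, shells[-1], min_loci=10)
        assert (lo, hi) == (0.0, float("inf"))


class TestTrajectory:
    def test_deterministic_and_ordered(self):
        cfg = sim.SimulationConfig(
            seed=2,
            ne_schedule={"p1": [(0, 300)]},
            n_generations=30,
            sample_size=40,
        )
        G, lmap, _, _ = sim.simulate_metapopulation(cfg)
        t1 = reconstruct_trajectory(G, lmap)
        t2 = reconstruct_trajectory(G, lmap)
        assert t1.to_frame().equals(t2.to_frame())
        ts = [b.t for b in t1.bins]
        assert ts == sorted(ts, reverse=True)
        assert t1.bins[-1].unlinked and t1.bins[-1].year == pytest.approx(2005.0)

    def test_decline_lowers_recent_bin_relative_to_deep(self):
        hits = 0
        n = 8
        for r in range(n):
            cfg = sim.SimulationConfig(
                seed=700 + r,
                ne_schedule={"p1": sim.decline_schedule(50, 10)},
                n_generations=50,
                sample_size=50,
            )
            G, lmap, _, _ = sim.simulate_metapopulation(cfg)
            traj = reconstruct_trajectory(G, lmap)
            deep, recent = traj.bins[0], traj.bins[-1]
            hits += recent.ne_hat < deep.ne_hat
        assert hits >= int(0.8 * n)

    def test_constant_ne_no_monotone_trend(self):
        # under constant Ne the trajectory should not systematically slope
        signs = []
        for r in range(8):
            cfg = sim.SimulationConfig(
                seed=800 + r,
                ne_schedule={"p1": [(0, 300)]},
                n_generations=50,
                sample_size=50,
            )
            G, lmap, _, _ = sim.simulate_metapopulation(cfg)
            traj = reconstruct_trajectory(G, lmap)
            finite = [b.ne_hat for b in traj.bins if np.isfinite(b.ne_hat)]
            signs.append(np.sign(finite[-1] - finite[0]))
        # replicate-level sign test: both directions occur / no unanimity
        assert abs(sum(signs)) < len(signs)

    def test_unmapped_loci_excluded_with_warning(self):
        d = np.random.default_rng(1).integers(0, 3, (30, 12)).astype(np.int8)
        lmap = sim.build_linkage_map([sim.ChromosomeLayout(f"c{k}", 1, 0.01) for k in range(11)])
        G = make_matrix(d, loci=lmap.loci + ["orphan"])
        with pytest.warns(UserWarning, match="absent from the linkage map"):
            traj = reconstruct_trajectory(G, lmap)
        assert "orphan" in traj.excluded_loci
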