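"""Genotype container, file round-trips, and QC filter behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdecline.genotypes import (
    MISSING,
    EmptyPanelError,
    GenotypeMatrix,
    filter_maf,
    find_duplicate_samples,
    impute_most_frequent,
    read_genotypes,
    read_linkage_map,
    write_genotype_matrix,
)
from conftest import make_matrix

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
chr1\t100\tlocA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\tlocB\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t1/1
"""


class TestReaders:
    def test_vcf_alt_dosage_encoding(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_TEXT)
        G = read_genotypes(p, format="vcf")
        assert G.loci == ["locA", "locB"]
        np.testing.assert_array_equal(G.dosage[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(G.dosage[:, 1], [1, MISSING, 2])
        assert G.counted_allele == {"locA": "G", "locB": "T"}

    def test_multiallelic_vcf_rejected(self, tmp_path):
        bad = VCF_TEXT.replace("chr1\t100\tlocA\tA\tG", "chr1\t100\tlocA\tA\tG,T")
        bad = bad.replace("0/0\t0/1\t1/1\nchr1\t200", "0/0\t0/1\t2/2\nchr1\t200")
        p = tmp_path / "bad.vcf"
        p.write_text(bad)
        with pytest.raises(ValueError, match="locA|multiallelic"):
            read_genotypes(p, format="vcf")

    def test_matrix_missing_token(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tl1\tl2\ns0\t0\tNA\ns1\t2\t1\n")
        G = read_genotypes(p, format="matrix")
        assert G.dosage[0, 1] == MISSING

    def test_matrix_unknown_token_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tl1\ns0\t5\n")
        with pytest.raises(ValueError, match="s0"):
            read_genotypes(p, format="matrix")

    def test_write_read_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "rt.tsv"
        write_genotype_matrix(small_panel, path)
        back = read_genotypes(
            path,
            format="matrix",
            metadata=small_panel.population_of,
        )
        np.testing.assert_array_equal(back.dosage, small_panel.dosage)
        assert back.loci == small_panel.loci
        assert back.samples == small_panel.samples

    def test_linkage_map_sex_average_and_single_column(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("locus\tchrom\tbp\tmale_cM\tfemale_cM\nl1\tc1\t100\t10\t20\n")
        lmap, _ = read_linkage_map(p)
        assert lmap.table.at["l1", "morgans"] == pytest.approx(0.15)
        q = tmp_path / "map2.tsv"
        q.write_text("locus\tchrom\tbp\tmorgans\nl1\tc1\t100\t0.2\n")
        lmap2, _ = read_linkage_map(q)
        assert lmap2.table.at["l1", "morgans"] == pytest.approx(0.2)

    def test_unmapped_locus_listed(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("locus\tchrom\tbp\tmorgans\nl1\tc1\t100\t0.0\n")
        lmap, _ = read_linkage_map(p)
        assert lmap.unmapped(["l1", "l2"]) == ["l2"]


class TestMafFilter:
    def test_strict_cut_removes_exact_threshold(self):
        # 10 diploids, one counted-allele copy in 20 -> MAF exactly 0.05
        col = np.zeros((10, 1), np.int8)
        col[0, 0] = 1
        G = make_matrix(np.hstack([col, np.tile([[0], [1]], (5, 1))]))
        filtered, removed = filter_maf(G, 0.05)
        assert removed == ["l0"]
        assert filtered.loci == ["l1"]

    def test_maf_above_threshold_retained(self):
        # 6/100 counted copies among 50 diploids -> MAF 0.06
        col = np.zeros((50, 1), np.int8)
        col[:6, 0] = 1
        keep = np.tile([[0], [2]], (25, 1))
        G = make_matrix(np.hstack([col, keep]))
        filtered, removed = filter_maf(G, 0.05)
        assert "l0" in filtered.loci and removed == []

    def test_monomorphic_removed_at_any_positive_threshold(self):
        G = make_matrix(np.column_stack([np.zeros(6, np.int8), np.tile([0, 1, 2], 2)]))
        filtered, removed = filter_maf(G, 0.01)
        assert removed == ["l0"]

    def test_all_removed_raises(self):
        G = make_matrix(np.zeros((4, 2), np.int8))
        with pytest.raises(EmptyPanelError):
            filter_maf(G, 0.05)

    def test_idempotent(self, small_panel):
        once, _ = filter_maf(small_panel, 0.1)
        twice, removed = filter_maf(once, 0.1)
        assert twice.loci == once.loci and removed == []

    def test_per_group_scope_stricter_than_global(self):
        # locus polymorphic overall but monomorphic inside population B
        col = np.array([0, 1, 1, 2, 0, 0, 0, 0], np.int8)[:, None]
        other = np.tile([[0], [1]], (4, 1))
        G = make_matrix(
            np.hstack([col, other]), populations=["A"] * 4 + ["B"] * 4
        )
        kept_global, _ = filter_maf(G, 0.05, scope="global")
        assert "l0" in kept_global.loci
        kept_group, removed = filter_maf(G, 0.05, scope="per-group")
        assert "l0" in removed


class TestDuplicates:
    def test_identical_rows_flagged(self):
        base = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], np.int8)
        dups, _ = find_duplicate_samples(make_matrix(base))
        assert [(a, b) for a, b, _ in dups] == [("s0", "s1")]

    def test_one_mismatch_not_flagged(self):
        base = np.array([[0, 1, 2, 1], [0, 1, 2, 2]], np.int8)
        dups, _ = find_duplicate_samples(make_matrix(base))
        assert dups == []

    def test_missing_entries_ignored_and_counted(self):
        a = np.concatenate([np.tile([0, 1], 25), [MISSING]])
        b = np.concatenate([np.tile([0, 1], 25), [2]])
        dups, _ = find_duplicate_samples(make_matrix(np.vstack([a, b])))
        assert dups == [("s0", "s1", 50)]

    def test_zero_comparable_loci_uninformative(self):
        a = np.array([[0, MISSING], [MISSING, 1]], np.int8)
        dups, uninf = find_duplicate_samples(make_matrix(a))
        assert dups == [] and uninf == [("s0", "s1")]

    def test_symmetric_under_sample_order(self, small_panel):
        d = small_panel.dosage.copy()
        d[1] = d[6]  # plant a duplicate
        G = make_matrix(d)
        rev = make_matrix(d[::-1])
        pairs = {frozenset((a, b)) for a, b, _ in find_duplicate_samples(G)[0]}
        n = G.n_samples - 1
        pairs_rev = {
            frozenset((f"s{n - int(a[1:])}", f"s{n - int(b[1:])}"))
            for a, b, _ in find_duplicate_samples(rev)[0]
        }
        assert pairs == pairs_rev and pairs


class TestImputation:
    def test_mode_fill(self):
        col = np.array([0] * 5 + [1] * 3 + [2] + [MISSING], np.int8)[:, None]
        G = impute_most_frequent(make_matrix(col))
        assert G.dosage[-1, 0] == 0

    def test_tie_breaks_to_lowest_class(self):
        col = np.array([0, 0, 1, 1, MISSING], np.int8)[:, None]
        G = impute_most_frequent(make_matrix(col))
        assert G.dosage[-1, 0] == 0

    def test_entirely_missing_locus_errors(self):
        col = np.full((4, 1), MISSING, np.int8)
        with pytest.raises(ValueError, match="l0"):
            impute_most_frequent(make_matrix(col))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_never_changes_observed_entries(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
        mask = rng.random((6, 5)) < 0.3
        d[mask] = MISSING
        if (d == MISSING).all(axis=0).any():
            return  # fully missing column is a documented error case
        G = make_matrix(d.copy())
        out = impute_most_frequent(G)
        obs = d != MISSING
        np.testing.assert_array_equal(out.dosage[obs], d[obs])
        assert not (out.dosage == MISSING).any()


class TestInvariants:
    def test_dosage_validation(self):
        with pytest.raises(ValueError, match="invalid dosage"):
            GenotypeMatrix(
                samples=["a"],
                population_of={"a": "p"},
                loci=["l"],
                dosage=np.array([[3]], np.int8),
            )

    def test_duplicate_locus_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GenotypeMatrix(
                samples=["a"],
                population_of={"a": "p"},
                loci=["l", "l"],
                dosage=np.zeros((1, 2), np.int8),
            )
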