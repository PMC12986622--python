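"""Tests of genotype I/O, variant filtering, LD pruning and panel merging."""

import numpy as np
import pandas as pd
import pytest

from ricegs import (GenotypeMatrix, filter_variants, impute_missing, ld_prune,
                    merge_panels, read_dosage_tsv, read_vcf, write_dosage_tsv,
                    write_vcf)
from ricegs.genio import VARIANT_COLUMNS, VcfParseError


def make_matrix(dosages, ids=None, chrom="1", pos=None, ref="A", alt="C"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 10,
        "id": [f"v{j}" for j in range(m)],
        "ref": ref, "alt": alt,
    })[VARIANT_COLUMNS]
    ids = ids or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(ids, variants, dosages)


NAN = np.nan


class TestVcf:
    VCF_TEXT = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/1\t./.\t1|0
1\t200\tv2\tG\tT\t.\t.\t.\tGT\t1/1\t0/0\t0|0
1\t300\tv3\tA\tC,G\t.\t.\t.\tGT\t0/0\t1/2\t0/1
"""

    def test_gt_coding_table(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(self.VCF_TEXT)
        G = read_vcf(str(path))
        assert G.sample_ids == ["s1", "s2", "s3"]
        # het -> 1, missing -> NaN, phased 1|0 -> 1
        assert G.dosages[0, 0] == 1 and np.isnan(G.dosages[1, 0])
        assert G.dosages[2, 0] == 1
        assert G.dosages[0, 1] == 2 and G.dosages[1, 1] == 0
        # multiallelic record retained with joined alt, flagged non-biallelic
        assert G.variants.loc[2, "alt"] == "C,G"
        assert list(G.is_biallelic_snp()) == [True, True, False]

    def test_round_trip_through_vcf(self, panel, tmp_path):
        path = tmp_path / "panel.vcf"
        write_vcf(panel, str(path))
        back = read_vcf(str(path))
        np.testing.assert_array_equal(panel.dosages, back.dosages)
        assert back.sample_ids == panel.sample_ids
        pd.testing.assert_frame_equal(
            back.variants.astype({"pos": int}),
            panel.variants.astype({"pos": int}))

    def test_round_trip_preserves_missing(self, tmp_path):
        G = make_matrix([[0, NAN], [2, 1]])
        path = tmp_path / "m.vcf"
        write_vcf(G, str(path))
        back = read_vcf(str(path))
        assert np.isnan(back.dosages[0, 1])
        np.testing.assert_array_equal(back.dosages[1], [2, 1])

    def test_malformed_vcf_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(VcfParseError):
            read_vcf(str(path))

    def test_dosage_tsv_round_trip(self, tmp_path):
        G = make_matrix([[0, NAN, 2], [2, 1, 0]])
        path = tmp_path / "d.tsv"
        write_dosage_tsv(G, str(path))
        back = read_dosage_tsv(str(path))
        np.testing.assert_array_equal(np.isnan(G.dosages),
                                      np.isnan(back.dosages))
        assert back.sample_ids == G.sample_ids


class TestFilterVariants:
    def toy(self):
        """10 variants: 2 multiallelic, 3 at 30% missing, 1 at MAF 0.02."""
        n = 10
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(n, 10)).astype(float)
        # columns 0-1 multiallelic / non-SNP
        # columns 2-4: 3 of 10 calls missing (30% > 20%)
        dosages[:3, 2] = NAN
        dosages[:3, 3] = NAN
        dosages[:3, 4] = NAN
        # column 5: complete but rare — one het in 20 alleles, MAF 0.05,
        # below the 0.06 cutoff used in the assertion
        dosages[:, 5] = 0.0
        dosages[0, 5] = 1.0
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, 11) * 10,
            "id": [f"v{j}" for j in range(10)],
            "ref": ["A"] * 10,
            "alt": ["C,G", "CT"] + ["C"] * 8,
        })[VARIANT_COLUMNS]
        G = GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)
        return G

    def test_toy_counts_by_hand(self):
        G = self.toy()
        filtered, rep = filter_variants(G, max_missing_rate=0.20,
                                        min_maf=0.06)
        assert (rep.n_input, rep.n_removed_missing, rep.n_removed_maf,
                rep.n_removed_multiallelic, rep.n_removed_ld,
                rep.n_retained) == (10, 3, 1, 2, 0, 4)
        assert filtered.n_variants == 4

    def test_noop_thresholds_keep_all_biallelic(self):
        G = self.toy()
        filtered, rep = filter_variants(G, max_missing_rate=1.0, min_maf=0.0)
        assert rep.n_removed_multiallelic == 2
        assert rep.n_removed_missing == 0 and rep.n_removed_maf == 0
        assert filtered.n_variants == 8

    def test_all_missing_variant_removed_by_missing_filter(self):
        G = make_matrix([[NAN, 0], [NAN, 1], [NAN, 2]])
        _, rep = filter_variants(G, max_missing_rate=1.0, min_maf=0.0)
        assert rep.n_removed_missing == 1 and rep.n_retained == 1

    def test_idempotent(self, panel):
        first, _ = filter_variants(panel, 0.2, 0.05)
        second, rep = filter_variants(first, 0.2, 0.05)
        assert rep.n_retained == first.n_variants
        np.testing.assert_array_equal(first.dosages, second.dosages)

    def test_empty_matrix_is_legal(self):
        G = make_matrix(np.empty((3, 0)))
        out, rep = filter_variants(G)
        assert out.n_variants == 0 and rep.n_input == 0


def reference_ld_prune(G, window_snps, step_snps, r2_threshold):
    """Exhaustive oracle: re-scan all window placements until no surviving
    pair violates the threshold, applying the same removal rule."""
    removed = set()
    maf = G.maf()
    pos = G.variants["pos"].to_numpy()
    chrom = G.variants["chrom"].to_numpy()

    def r2(a, b):
        x, y = G.dosages[:, a], G.dosages[:, b]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2 or np.var(x[ok]) == 0 or np.var(y[ok]) == 0:
            return 0.0
        return np.corrcoef(x[ok], y[ok])[0, 1] ** 2

    changed = True
    while changed:
        changed = False
        for c in pd.unique(chrom):
            idx = [int(i) for i in np.flatnonzero(chrom == c)]
            for start in range(0, len(idx), step_snps):
                window = idx[start:start + window_snps]
                active = [i for i in window if i not in removed]
                best, best_r2 = None, r2_threshold
                for ii in range(len(active)):
                    for jj in range(ii + 1, len(active)):
                        v = r2(active[ii], active[jj])
                        if v > best_r2:
                            best, best_r2 = (active[ii], active[jj]), v
                if best is not None:
                    a, b = best
                    if (maf[a], -pos[a]) < (maf[b], -pos[b]):
                        removed.add(a)
                    else:
                        removed.add(b)
                    changed = True
                    break
            if changed:
                break
    return [i for i in range(G.n_variants) if i not in removed]


class TestLdPrune:
    def test_duplicated_column_pair_loses_one(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(40, 5)).astype(float)
        dosages = np.column_stack([base, base[:, 0]])  # col 5 == col 0
        G = make_matrix(dosages)
        kept, rep = ld_prune(G, window_snps=6, step_snps=2, r2_threshold=0.9)
        assert rep.n_removed_ld >= 1
        assert not (0 in kept and 5 in kept)

    def test_threshold_one_removes_nothing(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=(30, 8)).astype(float)
        dosages = np.column_stack([base, base[:, 0]])
        G = make_matrix(dosages)
        kept, rep = ld_prune(G, window_snps=5, step_snps=2, r2_threshold=1.0)
        assert rep.n_removed_ld == 0 and len(kept) == 9

    def test_matches_exhaustive_oracle_on_simulated_chromosome(self):
        from ricegs import SimulationConfig, simulate_genotypes
        cfg = SimulationConfig(n_accessions=80, n_snps=100,
                               n_founder_haplotypes=6, recomb_rate=0.02,
                               seed=11)
        G = simulate_genotypes(cfg)
        kept, _ = ld_prune(G, window_snps=10, step_snps=5, r2_threshold=0.5)
        expected = reference_ld_prune(G, 10, 5, 0.5)
        assert list(kept) == expected

    def test_no_surviving_pair_violates_threshold_in_any_window(self):
        from ricegs import SimulationConfig, simulate_genotypes
        cfg = SimulationConfig(n_accessions=60, n_snps=150,
                               n_founder_haplotypes=4, recomb_rate=0.01,
                               seed=3)
        G = simulate_genotypes(cfg)
        kept, _ = ld_prune(G, window_snps=12, step_snps=4, r2_threshold=0.4)
        kept = list(kept)
        for start in range(0, G.n_variants, 4):
            window = [i for i in range(start, min(start + 12, G.n_variants))
                      if i in kept]
            if len(window) < 2:
                continue
            D = G.dosages[:, window]
            r2 = np.corrcoef(D.T) ** 2
            np.fill_diagonal(r2, 0.0)
            assert r2.max() <= 0.4 + 1e-12

    def test_kept_indices_strictly_increasing(self, panel):
        kept, _ = ld_prune(panel, window_snps=10, step_snps=4,
                           r2_threshold=0.3)
        assert (np.diff(kept) > 0).all()

    def test_tiny_window_rejected(self):
        G = make_matrix(np.zeros((5, 4)) + [[0, 1, 2, 0]] * 5)
        with pytest.raises(ValueError):
            ld_prune(G, window_snps=1, step_snps=0)


class TestImputeMissing:
    def test_mean_rounded_examples(self):
        G = make_matrix([[0.0], [2.0], [NAN]])
        out = impute_missing(G, "column_mean_rounded")
        assert out.dosages[2, 0] == 1.0  # mean 1 -> 1

    def test_mean_rounding_tie_goes_to_het(self):
        # mean 0.5 is equidistant from 0 and 1 -> impute the heterozygote
        G = make_matrix([[0.0], [1.0], [NAN], [NAN]])
        out = impute_missing(G, "column_mean_rounded")
        assert out.dosages[2, 0] == 1.0

    def test_mode_example(self):
        G = make_matrix([[0.0], [0.0], [0.0], [2.0], [NAN]])
        out = impute_missing(G, "column_mode")
        assert out.dosages[4, 0] == 0.0

    def test_complete_matrix_returned_unchanged(self, panel):
        assert impute_missing(panel) is panel

    def test_all_missing_column_instructs_filtering(self):
        G = make_matrix([[NAN, 1], [NAN, 2]])
        with pytest.raises(ValueError, match="filter"):
            impute_missing(G)

    def test_output_has_no_missing(self):
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=(20, 15)).astype(float)
        mask = rng.random((20, 15)) < 0.2
        dosages[mask] = NAN
        dosages[0, :] = 1.0  # ensure no all-missing column
        out = impute_missing(make_matrix(dosages))
        assert not np.isnan(out.dosages).any()
        assert np.isin(out.dosages, (0.0, 1.0, 2.0)).all()


class TestMergePanels:
    def test_self_merge_with_relabeled_copy(self, panel):
        sub = panel.take_samples(range(20)).take_variants(range(50))
        other = GenotypeMatrix([f"x_{s}" for s in sub.sample_ids],
                               sub.variants, sub.dosages.copy())
        merged, rep = merge_panels(sub, other)
        assert rep.n_matched == 50 and rep.n_flipped == 0
        assert merged.n_samples == 40 and merged.n_variants == 50

    def test_allele_swap_flips_dosage(self):
        a = make_matrix([[0.0], [1.0]], ids=["a1", "a2"], ref="A", alt="G")
        b = make_matrix([[2.0], [0.0]], ids=["b1", "b2"], ref="G", alt="A")
        merged, rep = merge_panels(a, b)
        assert rep.n_flipped == 1
        # b's dosage 2 of its alt (=A) becomes 0 copies of panel-a's alt
        assert merged.dosages[2, 0] == 0.0 and merged.dosages[3, 0] == 2.0

    def test_strand_ambiguous_swap_dropped(self):
        a = make_matrix([[0.0, 1.0]] * 2, ids=["a1", "a2"],
                        ref="A", alt="T")
        b = make_matrix([[1.0, 1.0]] * 2, ids=["b1", "b2"],
                        ref="T", alt="A")
        merged, rep = merge_panels(a, b)
        assert rep.n_dropped_ambiguous == 2 and merged.n_variants == 0

    def test_planted_overlap_count(self, panel):
        a = panel.take_samples(range(30))
        b_all = panel.take_samples(range(30, 60))
        b = GenotypeMatrix([f"b_{s}" for s in b_all.sample_ids],
                           b_all.variants, b_all.dosages)
        # shift 70% of b's positions away so only 30% overlap is planted
        n_keep = int(0.3 * b.n_variants)
        variants = b.variants.copy()
        variants.loc[n_keep:, "pos"] = variants.loc[n_keep:, "pos"] + 7
        b = GenotypeMatrix(b.sample_ids, variants, b.dosages)
        merged, rep = merge_panels(a, b)
        assert merged.n_variants == n_keep
        assert rep.n_retained == n_keep

    def test_retained_set_symmetric(self):
        a = make_matrix([[0.0, 1.0, 2.0]] * 3, ids=["a1", "a2", "a3"],
                        pos=[10, 20, 30])
        b = make_matrix([[1.0, 1.0]] * 3, ids=["b1", "b2", "b3"],
                        pos=[20, 40])
        m_ab, _ = merge_panels(a, b)
        m_ba, _ = merge_panels(b, a)
        keys = lambda M: set(zip(M.variants["chrom"], M.variants["pos"]))
        assert keys(m_ab) == keys(m_ba) == {("1", 20)}

    def test_duplicate_sample_id_raises(self, panel):
        with pytest.raises(ValueError, match="duplicate"):
            merge_panels(panel, panel)

    def test_maf_invariant_under_allele_flip(self):
        rng = np.random.default_rng(9)
        dosages = rng.integers(0, 3, size=(50, 20)).astype(float)
        G = make_matrix(dosages)
        G_flip = make_matrix(2.0 - dosages, ref="C", alt="A")
        np.testing.assert_allclose(G.maf(), G_flip.maf())
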