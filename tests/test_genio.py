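import numpy as np
import pandas as pd
import pytest

from fearscan import genio, simdata
from fearscan.genio import (
    MISSING, GenotypeMatrix, GenotypeFormatError, fill_sporadic_missing,
    ld_prune, qc_filter, qc_filter_manifest, read_genotypes, write_genotypes,
)


def _toy(dosage, prefix="v"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(dosage, [f"s{i}" for i in range(n)],
                          [f"{prefix}{j}" for j in range(m)])


def _tables(geno, chrom="1"):
    m, n = geno.n_variants, geno.n_samples
    variants = pd.DataFrame({
        "id": geno.variant_ids, "chrom": [chrom] * m,
        "pos": np.arange(1, m + 1) * 1000,
        "allele_minor": ["A"] * m, "allele_major": ["G"] * m,
    })
    samples = pd.DataFrame({"sample_id": geno.sample_ids, "sex": ["F"] * n})
    return variants, samples


class TestPlinkTriplet:
    def test_roundtrip_including_missing(self, tmp_path, small_cohort):
        geno = small_cohort["geno"]
        write_genotypes(geno, small_cohort["variants"], small_cohort["samples"],
                        tmp_path / "cohort")
        g2, v2, s2 = read_genotypes(tmp_path / "cohort.bed")
        assert np.array_equal(geno.dosage, g2.dosage)
        assert g2.sample_ids == geno.sample_ids
        assert g2.variant_ids == geno.variant_ids

    def test_rewrite_is_bit_exact(self, tmp_path, small_cohort):
        geno = small_cohort["geno"]
        write_genotypes(geno, small_cohort["variants"], small_cohort["samples"],
                        tmp_path / "a")
        g2, v2, s2 = read_genotypes(tmp_path / "a.bed")
        write_genotypes(g2, v2, s2, tmp_path / "b")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_handmade_two_bit_decoding(self, tmp_path):
        """4 samples x 2 variants, bytes assembled by hand from the 2-bit
        code table (00=hom A1/minor=2, 01=missing, 10=het, 11=hom A2=0)."""
        # variant 0: samples (2, 1, 0, missing) -> codes 00,10,11,01
        #   byte = 01 11 10 00 (sample 3..0, low bits = sample 0) = 0b01111000
        # variant 1: samples (0, 0, 1, 2) -> codes 11,11,10,00
        #   byte = 00 10 11 11 = 0b00101111
        bed = bytes([0x6C, 0x1B, 0x01, 0b01111000, 0b00101111])
        (tmp_path / "h.bed").write_bytes(bed)
        (tmp_path / "h.bim").write_text("1\tv0\t0\t100\tA\tG\n1\tv1\t0\t200\tC\tT\n")
        (tmp_path / "h.fam").write_text(
            "".join(f"f s{i} 0 0 2 -9\n" for i in range(4))
        )
        geno, variants, _ = read_genotypes(tmp_path / "h.bed")
        expected = np.array([[2, 0], [1, 0], [0, 1], [MISSING, 2]], dtype=np.int8)
        assert np.array_equal(geno.dosage, expected)
        assert list(variants["allele_minor"]) == ["A", "C"]

    def test_dimension_mismatch_raises(self, tmp_path):
        geno = _toy([[0, 1], [1, 2], [2, 0], [0, 0]])
        variants, samples = _tables(geno)
        write_genotypes(geno, variants, samples, tmp_path / "d")
        fam = (tmp_path / "d.fam").read_text()
        (tmp_path / "d.fam").write_text(fam + "f extra 0 0 2 -9\n")
        with pytest.raises(GenotypeFormatError, match="bytes"):
            read_genotypes(tmp_path / "d.bed")

    def test_bad_magic_raises(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x00\x00")
        (tmp_path / "x.bim").write_text("1\tv0\t0\t100\tA\tG\n")
        (tmp_path / "x.fam").write_text("f s0 0 0 2 -9\n")
        with pytest.raises(GenotypeFormatError, match="magic"):
            read_genotypes(tmp_path / "x.bed")


class TestQcFilter:
    def test_study_scale_category_accounting(self):
        mani = simdata.make_variant_manifest(635_984, 15_962, 126_983, seed=0)
        kept, report = qc_filter_manifest(mani)
        assert report.n_removed_nonautosomal == 15_962
        assert report.n_removed_mono_or_indel == 126_983
        assert report.n_retained == len(kept) == 493_039

    def test_maf_exactly_at_threshold_is_removed(self):
        # 10 samples; one variant with minor-allele count 1 -> maf exactly 0.05
        col_maf05 = [1] + [0] * 9
        col_keep = [1, 1, 1, 0, 0, 2, 1, 0, 1, 0]  # maf 0.35
        geno = _toy(np.column_stack([col_maf05, col_keep]))
        variants, _ = _tables(geno)
        kept, var_kept, report = qc_filter(geno, variants, maf_min=0.05)
        assert report.n_removed_maf == 1
        assert kept.variant_ids == ["v1"]

    def test_callrate_filter_matches_direct_count(self, rng):
        d = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        d[:18, 0] = MISSING  # call rate 0.1
        d[:5, 3] = MISSING   # call rate 0.75
        d[:3, 7] = MISSING   # call rate 0.85
        geno = _toy(d)
        variants, _ = _tables(geno)
        kept, _, report = qc_filter(geno, variants, maf_min=0.0, call_rate_min=0.90)
        direct = int((geno.call_rate() <= 0.90).sum())
        assert report.n_removed_callrate == direct == 3
        report.check()

    def test_conservation_on_random_cohorts(self):
        for seed in range(3):
            cfg = simdata.SimConfig(n_breeds=2, n_per_breed=40, n_snps=200,
                                    missing_rate=0.08, seed=seed)
            geno, variants, *_ = simdata.simulate_genotypes(cfg)
            _, _, report = qc_filter(geno, variants)
            report.check()  # raises if removals + retained != input


class TestFillMissing:
    def test_no_missing_is_identity(self):
        geno = _toy([[0, 1], [1, 2], [2, 0]])
        filled = fill_sporadic_missing(geno)
        assert np.array_equal(filled.dosage, geno.dosage)

    def test_mode_fill(self):
        geno = _toy([[0], [0], [2], [MISSING]])
        filled = fill_sporadic_missing(geno)
        assert filled.dosage[3, 0] == 0
        assert not filled.missing_mask().any()

    def test_nonmissing_entries_unchanged(self, small_cohort):
        geno = small_cohort["geno"]
        filled = fill_sporadic_missing(geno)
        keep = ~geno.missing_mask()
        assert np.array_equal(filled.dosage[keep], geno.dosage[keep])

    def test_all_missing_variant_errors(self):
        geno = _toy([[0, MISSING], [1, MISSING]])
        with pytest.raises(ValueError, match="v1"):
            fill_sporadic_missing(geno)


class TestLdPrune:
    def test_duplicate_variants_keep_exactly_one(self, rng):
        x = rng.integers(0, 3, size=500).astype(np.int8)
        geno = _toy(np.column_stack([x, x]))
        kept = ld_prune(geno, window=10, step=5, r2_max=0.6)
        assert len(kept) == 1

    def test_independent_variants_all_retained(self, rng):
        d = rng.integers(0, 3, size=(500, 30)).astype(np.int8)
        geno = _toy(d)
        kept = ld_prune(geno, window=10, step=5, r2_max=0.6)
        assert len(kept) == 30

    def test_toy_matches_bruteforce_greedy(self, rng):
        """20 variants with one correlated triple: the retained set equals an
        exhaustive re-implementation of the greedy rule."""
        d = rng.integers(0, 3, size=(300, 20)).astype(np.int8)
        base = d[:, 4]
        noise = rng.integers(0, 3, size=(300, 2)).astype(np.int8)
        d[:, 5] = np.clip(base + (rng.random(300) < 0.1), 0, 2)
        d[:, 6] = np.clip(base + (rng.random(300) < 0.1), 0, 2)
        geno = _toy(d)
        kept = set(ld_prune(geno, window=20, step=10, r2_max=0.6))

        # brute-force oracle: repeatedly drop the lower-MAF member of the
        # strongest offending pair (equal MAF: the later index)
        maf = geno.maf()
        alive = list(range(20))
        while True:
            r2best, pair = 0.0, None
            for ai in range(len(alive)):
                for bi in range(ai + 1, len(alive)):
                    i, j = alive[ai], alive[bi]
                    r2 = np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
                    if r2 > r2best:
                        r2best, pair = r2, (i, j)
            if pair is None or r2best <= 0.6:
                break
            i, j = pair
            victim = i if maf[i] < maf[j] else j if maf[j] < maf[i] else max(i, j)
            alive.remove(victim)
        assert kept == {f"v{i}" for i in alive}

    def test_idempotent(self, small_cohort):
        geno = fill_sporadic_missing(small_cohort["geno"])
        kept1 = ld_prune(geno, window=50, step=20, r2_max=0.5)
        idx = [i for i, v in enumerate(geno.variant_ids) if v in set(kept1)]
        pruned = geno.subset_variants(idx)
        kept2 = ld_prune(pruned, window=50, step=20, r2_max=0.5)
        assert kept2 == kept1

    def test_window_too_small_errors(self, small_cohort):
        with pytest.raises(ValueError, match="window"):
            ld_prune(small_cohort["geno"], window=1)
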