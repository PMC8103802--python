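import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triorigin.simdata import write_fixture
from triorigin.variants import (
    AlleleDepth,
    GenotypeCall,
    GenotypeCallingConfig,
    call_genotype,
    call_matrix,
    filter_reads_by_kmer,
    read_vcf,
)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (30, 2, GenotypeCall.VARIANT_PRESENT),    # 2 reads at 6.7 %
            (40, 0, GenotypeCall.VARIANT_ABSENT),     # no variant read
            (200, 1, GenotypeCall.VARIANT_ABSENT),    # singleton at 0.5 % < 1 %
            (29, 10, GenotypeCall.MISSING),           # depth below 30
            (100, 2, GenotypeCall.MISSING),           # 2 % — neither rule fires
            (100, 1, GenotypeCall.MISSING),           # singleton at exactly 1 %
        ],
    )
    def test_depth_frequency_rules(self, depth, alt, expected):
        ad = AlleleDepth(ref_count=depth - alt, alt_count=alt, depth=depth)
        assert call_genotype(ad) is expected

    def test_boundary_inclusivity(self):
        # >= 30 depth inclusive; >= 4 % inclusive with >= 2 reads
        assert call_genotype(AlleleDepth(48, 2, 50)) is GenotypeCall.VARIANT_PRESENT
        assert call_genotype(AlleleDepth(28, 2, 30)) is GenotypeCall.VARIANT_PRESENT

    def test_exhaustive_partition(self):
        """Every (alt, depth) cell up to depth 300 gets exactly one call,
        and the vectorized matrix path agrees with the scalar rule."""
        cfg = GenotypeCallingConfig()
        pairs = [(alt, depth) for depth in range(301) for alt in range(depth + 1)]
        alt = np.array([p[0] for p in pairs])[:, None]
        depth = np.array([p[1] for p in pairs])[:, None]
        gm = call_matrix(depth - alt, alt, depth, cfg)
        codes = gm.calls.to_numpy().ravel()
        assert set(np.unique(codes)) <= {-1, 0, 1}
        scalar = np.array(
            [int(call_genotype(AlleleDepth(d - a, a, d), cfg)) for a, d in pairs]
        )
        assert (codes == scalar).all()

    @given(
        depth=st.integers(min_value=30, max_value=300),
        alt=st.integers(min_value=2, max_value=300),
        extra=st.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotonic_in_alt_count(self, depth, alt, extra):
        """Once PRESENT fires, more alt reads never revert the call."""
        alt = min(alt, depth)
        ad = AlleleDepth(depth - alt, alt, depth)
        if call_genotype(ad) is GenotypeCall.VARIANT_PRESENT:
            alt2 = min(alt + extra, depth)
            assert (
                call_genotype(AlleleDepth(depth - alt2, alt2, depth))
                is GenotypeCall.VARIANT_PRESENT
            )

    def test_refalt_denominator_option(self):
        # 2 alt of 10 informative reads is 20 % by ref+alt but 2 % by depth
        ad = AlleleDepth(ref_count=8, alt_count=2, depth=100)
        assert call_genotype(ad) is GenotypeCall.MISSING
        cfg = GenotypeCallingConfig(min_depth=30, freq_denominator="refalt")
        assert call_genotype(ad, cfg) is GenotypeCall.VARIANT_PRESENT


class TestCallMatrix:
    def test_all_zero_alt_high_depth_all_absent(self):
        depth = np.full((4, 3), 50)
        alt = np.zeros((4, 3), dtype=int)
        gm = call_matrix(depth - alt, alt, depth)
        assert (gm.calls.to_numpy() == 0).all()

    def test_zero_depth_all_missing(self):
        z = np.zeros((2, 2), dtype=int)
        gm = call_matrix(z, z, z)
        assert (gm.calls.to_numpy() == -1).all()

    def test_calls_match_dosage_truth_on_clean_fixture(self, clean_sim):
        _, accessions, depths = clean_sim
        gm = call_matrix(
            depths.ref_count, depths.alt_count, depths.depth,
            site_ids=depths.sites["site_id"], sample_ids=depths.sample_ids,
        )
        dos = accessions.dosage_matrix()
        truth = (dos > 0).astype(int)
        calls = gm.calls.to_numpy()
        agree = (calls == truth).mean()
        assert agree >= 0.99


class TestReadVcf:
    def test_fixture_roundtrip_preserves_depths(self, clean_cfg, clean_sim, tmp_path):
        founders, accessions, depths = clean_sim
        paths = write_fixture(founders, accessions, depths, tmp_path, clean_cfg)
        records, refs, alts, deps, samples = read_vcf(paths["vcf"])
        assert samples == depths.sample_ids
        assert [r.pos for r in records] == list(depths.sites["pos"])
        np.testing.assert_array_equal(alts, depths.alt_count)
        np.testing.assert_array_equal(deps, depths.depth)
        np.testing.assert_array_equal(refs, depths.ref_count)

    def test_multiallelic_decomposition(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t7\t.\tC\tA,G\t.\t.\t.\tDP:AD\t60:30,20,10\n"
        )
        records, refs, alts, deps, _ = read_vcf(vcf)
        assert [(r.pos, r.alt_allele) for r in records] == [(7, "A"), (7, "G")]
        assert alts[:, 0].tolist() == [20, 10]
        assert refs[:, 0].tolist() == [30, 30]
        assert deps[:, 0].tolist() == [60, 60]

    def test_empty_vcf_body(self, tmp_path):
        vcf = tmp_path / "e.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        records, refs, alts, deps, samples = read_vcf(vcf)
        assert records == [] and refs.shape == (0, 1)


class TestKmerReadFilter:
    def test_read_matching_target_substring_retained(self, rng):
        target = "".join(rng.choice(list("ACGT"), 100))
        read = target[10:45]
        assert filter_reads_by_kmer([read], [target]) == [read]

    def test_reverse_complement_hit_retained(self, rng):
        target = "".join(rng.choice(list("ACGT"), 80))
        rc = target[5:40].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert filter_reads_by_kmer([rc], [target]) == [rc]

    def test_matches_bruteforce_scan(self, rng):
        """Agreement with an explicit substring-scan oracle on random reads."""
        targets = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(3)]
        reads = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(50)]
        reads += [t[i : i + 25] for t in targets for i in (0, 20)]
        k = 20

        def oracle_hit(read):
            rc = read.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            for strand in (read, rc):
                for t in targets:
                    for i in range(len(t) - k + 1):
                        if t[i : i + k] in strand:
                            return True
            return False

        kept = filter_reads_by_kmer(reads, targets, k=k)
        assert kept == [r for r in reads if oracle_hit(r)]

    def test_empty_targets_and_bad_k(self):
        assert filter_reads_by_kmer(["ACGTACGTACGTACGTACGTA"], []) == []
        with pytest.raises(ValueError):
            filter_reads_by_kmer(["ACGT"], ["ACGT"], k=0)
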