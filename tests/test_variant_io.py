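"""VCF/GFF3/metadata parsing, depth masking, and matrix conversion."""

import numpy as np
import pytest

from svpanel import (
    read_gene_annotation,
    read_metadata,
    read_sv_vcf,
    to_binary_matrix,
    write_sv_vcf,
)
from svpanel.variant_io import ABSENT, MISSING, PRESENT

from conftest import make_record


class TestReadSvVcf:
    def test_depth_below_threshold_masks_call(self, sv_vcf_path):
        # sample 1 is 0/1 at depth 9: the 10-read mask turns it missing,
        # sample 2 carries the same call at depth 10 and stays present
        recs = read_sv_vcf(sv_vcf_path, min_depth=10)
        del1 = recs[0]
        assert del1.svtype == "DEL"
        assert del1.start == 100 and del1.end == 600
        assert del1.length_bp == 501
        assert del1.carriers[0] == MISSING
        assert del1.carriers[1] == PRESENT
        assert del1.carriers[2] == ABSENT

    def test_genotype_states_map_to_carrier_states(self, sv_vcf_path):
        recs = read_sv_vcf(sv_vcf_path, min_depth=10)
        dup1 = recs[1]
        assert dup1.carriers[0] == PRESENT  # 1/1 collapses to present
        assert dup1.carriers[1] == ABSENT
        assert dup1.carriers[2] == MISSING  # ./. uncalled
        assert dup1.length_bp == 300  # |SVLEN| preferred over END-POS+1

    def test_precision_flag_and_pe_support(self, sv_vcf_path):
        recs = read_sv_vcf(sv_vcf_path, min_depth=10)
        assert recs[0].precise and recs[0].pe_support == 5
        assert not recs[2].precise  # IMPRECISE flag
        assert recs[3].svtype == "BND" and recs[3].length_bp is None

    def test_unknown_svtype_retained_and_flagged(self, sv_vcf_path):
        recs = read_sv_vcf(sv_vcf_path, min_depth=10)
        odd = recs[4]
        assert odd.svtype == "unknown" and odd.flagged

    def test_empty_vcf_body_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        assert read_sv_vcf(str(path), min_depth=10) == []

    def test_depth_mask_is_monotone_in_threshold(self, sv_vcf_path):
        low = read_sv_vcf(sv_vcf_path, min_depth=5)
        high = read_sv_vcf(sv_vcf_path, min_depth=20)
        for a, b in zip(low, high):
            newly_missing = (a.carriers != MISSING) & (b.carriers == MISSING)
            resurrected = (a.carriers == MISSING) & (b.carriers != MISSING)
            assert not resurrected.any()
            assert newly_missing.sum() >= 0


class TestBinaryMatrix:
    def test_single_record_three_states(self):
        rec = make_record(carriers=(1, 0, -1), depths=(30, 30, 30))
        m = to_binary_matrix([rec])
        assert m.presence.shape == (1, 3)
        assert m.presence[0, 0] == 1.0
        assert m.presence[0, 1] == 0.0
        assert np.isnan(m.presence[0, 2])

    def test_empty_records_give_empty_matrix(self):
        m = to_binary_matrix([])
        assert m.n_sites == 0

    def test_row_and_column_sums_match_hand_count(self):
        # 5 records x 4 samples; present entries per record: 2,1,0,3,1 = 7
        rows = [(1, 1, 0, 0), (0, -1, 1, 0), (0, 0, 0, 0), (1, 1, 1, -1), (0, 1, -1, 0)]
        recs = [
            make_record(site_id=f"s{i}", carriers=c, depths=(30,) * 4)
            for i, c in enumerate(rows)
        ]
        m = to_binary_matrix(recs)
        assert np.nansum(m.presence) == 7
        assert list(np.nansum(m.presence, axis=1)) == [2, 1, 0, 3, 1]
        assert list(np.nansum(m.presence, axis=0)) == [2, 3, 2, 0]
        # conservation: present entries equal total carriers over records
        assert np.nansum(m.presence) == sum(r.n_present for r in recs)

    def test_inconsistent_panels_rejected(self):
        recs = [
            make_record(carriers=(1, 0, 0)),
            make_record(site_id="other", carriers=(1, 0, 0, 0)),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            to_binary_matrix(recs)


class TestRoundTrip:
    def test_write_then_read_preserves_records(self, tmp_path):
        recs = [
            make_record(site_id="Chr01_100_600_DEL", carriers=(1, 0, -1),
                        depths=(30, 25, 40)),
            make_record(site_id="Chr01_2000_2999_DUP", start=2000, end=2999,
                        svtype="DUP", pe=7, carriers=(0, 1, 1),
                        depths=(12, 15, 18)),
            make_record(site_id="Chr01_5000_5099_INV", start=5000, end=5099,
                        svtype="INV", precise=False, pe=4,
                        carriers=(0, 0, 1), depths=(20, 20, 20)),
        ]
        path = tmp_path / "out.vcf"
        write_sv_vcf(recs, ["s1", "s2", "s3"], path)
        back = read_sv_vcf(str(path), min_depth=10)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.site_id == b.site_id
            assert a.svtype == b.svtype
            assert a.start == b.start and a.end == b.end
            assert a.length_bp == b.length_bp
            assert a.precise == b.precise
            assert a.pe_support == b.pe_support
            assert (a.carriers == b.carriers).all()
            assert (a.depths == b.depths).all()


class TestGeneAnnotation:
    def test_interval_counts_match_hand_count(self, gff3_path):
        feats = read_gene_annotation(gff3_path)
        assert feats.n_genes() == 4
        assert feats.n_cds() == 4
        assert len(feats.genes["Chr01"]) == 2
        assert len(feats.cds["Chr02"]) == 2
        assert feats.cds_outside_gene == []

    def test_single_gene_single_cds(self, tmp_path):
        path = tmp_path / "one.gff3"
        path.write_text(
            "##gff-version 3\n"
            "Chr01\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g\n"
            "Chr01\tsrc\tCDS\t1200\t1500\t.\t+\t0\tID=c;Parent=g\n"
        )
        feats = read_gene_annotation(str(path))
        assert feats.n_genes() == 1 and feats.n_cds() == 1
        iv = next(iter(feats.genes["Chr01"]))
        assert (iv.begin, iv.end) == (1000, 2001)  # 1-based inclusive storage

    def test_empty_file_gives_empty_sets(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        feats = read_gene_annotation(str(path))
        assert feats.n_genes() == 0 and feats.n_cds() == 0


class TestMetadata:
    def test_reads_counts_and_fills_unknown(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "sample_id\tcountry\trace\n"
            "s1\tEthiopia\tdurra\n"
            "s2\tSudan\t\n"
            "s3\tEthiopia\tkafir\n"
        )
        df = read_metadata(str(path))
        assert len(df) == 3
        assert df["country"].value_counts()["Ethiopia"] == 2
        assert df.loc[df.sample_id == "s2", "race"].iloc[0] == "Unknown"
        assert (df["region"] == "Unknown").all()

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sample_id,country\ns1,A\ns1,B\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_metadata(str(path))
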