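"""IO layer: site tables, variants, SNP swapping, CpG discovery, cell QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpgdm import methio
from cpgdm.methio import (
    CellQCRecord,
    CellQCThresholds,
    SiteTableError,
    VariantError,
    cell_qc_filter,
    find_cpg_sites,
    read_site_table,
    swap_snps,
    write_site_table,
)


# ---------------------------------------------------------------- site tables


class TestSiteTable:
    def test_round_trip_preserves_rows_and_bytes(self, tiny_site_table, tmp_path):
        p = tmp_path / "sites.tsv"
        write_site_table(tiny_site_table, p)
        first = p.read_bytes()
        table = read_site_table(p)
        assert len(table) == 4
        pd.testing.assert_frame_equal(table, tiny_site_table)
        write_site_table(table, p)
        assert p.read_bytes() == first  # canonical dialect is byte-stable

    def test_mc_exceeding_cov_rejected_with_row(self, tiny_site_table, tmp_path):
        bad = tiny_site_table.copy()
        bad.loc[1, "b6.mc"] = 9  # cov is 8
        p = tmp_path / "bad.tsv"
        bad.to_csv(p, sep="\t", index=False)
        with pytest.raises(SiteTableError, match="row 1"):
            read_site_table(p)

    def test_header_only_file_is_empty_table(self, tiny_site_table, tmp_path):
        p = tmp_path / "empty.tsv"
        tiny_site_table.iloc[0:0].to_csv(p, sep="\t", index=False)
        table = read_site_table(p)
        assert len(table) == 0
        assert methio.site_table_strains(table) == ["b6", "d2"]

    def test_unknown_context_rejected(self, tiny_site_table, tmp_path):
        bad = tiny_site_table.copy()
        bad.loc[2, "context"] = "CCG"
        p = tmp_path / "bad.tsv"
        bad.to_csv(p, sep="\t", index=False)
        with pytest.raises(SiteTableError, match="context"):
            read_site_table(p)

    def test_collapse_merges_reverse_strand_partner(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [5, 6],
                "strand": ["+", "-"],
                "context": ["CG", "CG"],
                "b6.mc": [3, 2],
                "b6.cov": [10, 6],
            }
        )
        merged = methio.collapse_symmetric_cpgs(table)
        assert len(merged) == 1
        assert merged.loc[0, "pos"] == 5
        assert merged.loc[0, "b6.mc"] == 5
        assert merged.loc[0, "b6.cov"] == 16


# ------------------------------------------------------------------ variants


class TestVariants:
    def test_tsv_round_trip(self, tmp_path):
        v = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [2], "ref": ["C"], "d2": ["T"]}
        )
        p = tmp_path / "v.tsv"
        methio.write_variants_tsv(v, p)
        pd.testing.assert_frame_equal(methio.read_variants(p), v)

    def test_indels_rejected_in_tsv(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("chrom\tpos\tref\td2\nchr1\t2\tCA\tC\n")
        with pytest.raises(VariantError, match="non-SNV"):
            methio.read_variants(p)

    def test_vcf_snvs_read_and_indels_skipped(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td2\tfvb\n"
            "chr1\t5\t.\tC\tT\t.\t.\t.\tGT\t1/1\t0/0\n"
            "chr1\t9\t.\tCA\tC\t.\t.\t.\tGT\t1/1\t0/0\n"
            "chr1\t20\t.\tG\tA\t.\t.\t.\tGT\t0/0\t1/1\n"
        )
        v = methio.read_variants(vcf)
        assert list(v["pos"]) == [5, 20]  # the indel at 9 is skipped
        assert v.loc[0, "d2"] == "T" and v.loc[0, "fvb"] == "C"
        assert v.loc[1, "fvb"] == "A"


# ---------------------------------------------------------------- SNP swap


class TestSwapSnps:
    def test_hand_substitution(self):
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "ref": ["C"], "d2": ["T"]})
        assert swap_snps("ACGT", v, "d2") == "ATGT"

    def test_empty_variants_identity(self):
        v = pd.DataFrame({"chrom": [], "pos": [], "ref": [], "d2": []})
        assert swap_snps("ACGT", v, "d2") == "ACGT"

    def test_ref_mismatch_guards_off_by_one(self):
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "ref": ["G"], "d2": ["T"]})
        with pytest.raises(VariantError, match="mismatch at pos 2"):
            swap_snps("ACGT", v, "d2")

    @given(
        seq=st.text(alphabet="ACGT", min_size=4, max_size=60),
        data=st.data(),
    )
    def test_swap_with_inverted_variants_restores_reference(self, seq, data):
        n_var = data.draw(st.integers(1, min(4, len(seq))))
        positions = data.draw(
            st.lists(
                st.integers(1, len(seq)), min_size=n_var, max_size=n_var, unique=True
            )
        )
        alt = {p: data.draw(st.sampled_from("ACGT")) for p in positions}
        fwd = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "ref": [seq[p - 1] for p in positions],
                "s": [alt[p] for p in positions],
            }
        )
        mutated = swap_snps(seq, fwd, "s")
        back = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "ref": [alt[p] for p in positions],
                "s": [seq[p - 1] for p in positions],
            }
        )
        assert swap_snps(mutated, back, "s") == seq


# ------------------------------------------------------------ CpG discovery


class TestFindCpgs:
    def test_hand_scan(self):
        out = find_cpg_sites("AACGTT")
        ref = out[out["strain"] == "reference"]
        assert list(ref["pos"]) == [3]
        assert ref["context5"].iloc[0] == "AACGT"  # centred on the C

    def test_strain_specific_gain_after_substitution(self):
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [3], "ref": ["A"], "s": ["C"]})
        out = find_cpg_sites("AAAGTT", v, strains=["s"])
        gained = out[(out["strain"] == "s") & out["gained"]]
        assert list(gained["pos"]) == [3]
        assert not out[out["strain"] == "reference"]["in_strain"].any()

    def test_no_cytosine_empty(self):
        out = find_cpg_sites("AAAAAA")
        assert len(out) == 0

    def test_context_padded_at_chromosome_end(self):
        out = find_cpg_sites("CGTACG")
        ref = out[out["strain"] == "reference"]
        assert list(ref["pos"]) == [1, 5]
        assert ref["context5"].tolist() == ["NNCGT", "TACGN"]

    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=80))
    def test_reverse_complement_mirrors_positions(self, seq):
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        fwd = set(find_cpg_sites(seq).query("strain == 'reference'")["pos"])
        rev = set(find_cpg_sites(rc).query("strain == 'reference'")["pos"])
        # the C of a CG maps to its partner G seen from the other strand
        assert rev == {len(seq) - p for p in fwd}


# ------------------------------------------------------------------ cell QC


def _record(cell="c", **overrides):
    base = dict(
        mccc=0.01, mcg=0.8, mch=0.05, mapped_reads=500_000,
        mapping_rate=0.8, coverage_pct=5.0,
    )
    base.update(overrides)
    return CellQCRecord(cell_id=cell, **base)


class TestCellQC:
    def test_boundary_fixture_partitions_exactly(self):
        # strict inequalities: a record sitting exactly on any threshold fails
        boundary = [
            _record("b1", mccc=0.03),
            _record("b2", mcg=0.5),
            _record("b3", mch=0.2),
            _record("b4", mapped_reads=100_000),
            _record("b5", mapping_rate=0.5),
            _record("b6", coverage_pct=2.0),
        ]
        passing = [
            _record("p1"),
            _record("p2", mccc=0.029),
            _record("p3", mcg=0.51),
            _record("p4", mch=0.19),
            _record("p5", mapped_reads=100_001),
        ]
        incomplete = [_record("i1", mcg=None)]
        passed, failed, inc = cell_qc_filter(boundary + passing + incomplete)
        assert [r.cell_id for r in passed] == [r.cell_id for r in passing]
        assert [r.cell_id for r in failed] == [r.cell_id for r in boundary]
        assert [r.cell_id for r in inc] == ["i1"]

    def test_high_mccc_removed(self):
        passed, failed, _ = cell_qc_filter([_record(mccc=0.05)])
        assert passed == [] and len(failed) == 1

    def test_low_mapped_reads_removed(self):
        passed, failed, _ = cell_qc_filter([_record(mapped_reads=50_000)])
        assert passed == [] and len(failed) == 1

    def test_passing_record_retained_unchanged(self):
        rec = _record()
        passed, _, _ = cell_qc_filter([rec])
        assert passed == [rec]

    def test_thresholds_configurable(self):
        rec = _record(mccc=0.05)
        passed, _, _ = cell_qc_filter([rec], CellQCThresholds(max_mccc=0.1))
        assert passed == [rec]


# ------------------------------------------------- genes & chromatin states


class TestAnnotationReaders:
    def test_refgene_flat(self, tmp_path):
        p = tmp_path / "refGene.txt"
        row = ["0", "g1", "chr1", "+", "100", "500"] + ["0"] * 10
        p.write_text("\t".join(row) + "\n")
        genes = methio.read_genes(p)
        assert genes.loc[0, "gene_id"] == "g1"
        assert (genes.loc[0, "txStart"], genes.loc[0, "txEnd"]) == (100, 500)

    def test_gtf(self, tmp_path):
        p = tmp_path / "genes.gtf"
        p.write_text('chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id "g1";\n')
        genes = methio.read_genes(p)
        assert genes.loc[0, "txStart"] == 100  # GTF is 1-based inclusive
        assert genes.loc[0, "txEnd"] == 500

    def test_states_bed_drops_artifacts_and_checks_vocabulary(self, tmp_path):
        p = tmp_path / "states.bed"
        p.write_text(
            "chr1\t0\t100\tActive enhancers\n"
            "chr1\t100\t200\tartifacts\n"
        )
        states = methio.read_states_bed(p)
        assert list(states["state"]) == ["Active enhancers"]
        p.write_text("chr1\t0\t100\tNot a state\n")
        with pytest.raises(ValueError, match="unknown chromatin state"):
            methio.read_states_bed(p)


class TestFasta:
    def test_round_trip(self, tmp_path):
        genome = {"chr1": "ACGTACGT" * 20, "chr2": "TTTT"}
        p = tmp_path / "g.fa"
        methio.write_fasta(genome, p)
        assert methio.read_fasta(p) == genome
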