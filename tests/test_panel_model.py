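"""Domain types, nomenclature and file-format round trips."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mhpanel as mh
from mhpanel.panel_model import LOCUS_ID_PATTERN, MicrohapLocus, DistanceMatrix
from mhpanel.simulate import write_variants_vcf


class TestLocusModel:
    def test_reference_panel_loads_and_spans_match(self, reference_panel):
        loci, stats = reference_panel
        assert len(loci) == 20
        for locus in loci:
            assert LOCUS_ID_PATTERN.match(locus.id)
            assert locus.span_bp == stats.loc[locus.id, "length_bp"]
        by_id = {l.id: l for l in loci}
        assert by_id["mh14zha003"].span_bp == 8
        assert by_id["mh02zha012"].span_bp == 105
        # one locus has no tri-allelic SNP, all others do
        assert sum(l.triallelic_snp is None for l in loci) == 1

    @pytest.mark.parametrize(
        "bad_id",
        ["mh2zha012", "mh02ZHA012", "mh23zha001", "mh02zha12", "mh02zha012A", "xy02zha012"],
    )
    def test_locus_id_pattern_rejects_mutations(self, bad_id):
        assert not LOCUS_ID_PATTERN.match(bad_id)

    @pytest.mark.parametrize(
        "args,expected",
        [((2, "zha", 12, None), "mh02zha012"), ((11, "zha", 6, "a"), "mh11zha006a")],
    )
    def test_make_locus_name(self, args, expected):
        assert mh.make_locus_name(*args) == expected

    @pytest.mark.parametrize(
        "args", [(23, "zha", 1, None), (2, "zha", 0, None), (2, "zha", 1, "A"), (2, "ZHA", 1, None)]
    )
    def test_make_locus_name_rejects(self, args):
        with pytest.raises(ValueError):
            mh.make_locus_name(*args)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        chrom=st.integers(1, 22),
        code=st.text("abcdefghijklmnopqrstuvwxyz", min_size=2, max_size=4),
        serial=st.integers(1, 999),
        suffix=st.sampled_from([None, "a", "b", "z"]),
    )
    def test_generated_names_satisfy_pattern(self, chrom, code, serial, suffix):
        assert LOCUS_ID_PATTERN.match(mh.make_locus_name(chrom, code, serial, suffix))

    def test_single_snp_locus_rejected(self):
        with pytest.raises(ValueError, match="at least 2 SNPs"):
            MicrohapLocus("mh01abc001", 1, (100, 200), ("rs1",))

    def test_non_increasing_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MicrohapLocus("mh01abc001", 1, (200, 100), ("rs1", "rs2"))

    def test_long_span_warns(self):
        with pytest.warns(UserWarning, match="200 bp"):
            MicrohapLocus("mh01abc001", 1, (100, 400), ("rs1", "rs2"))

    def test_parse_rejects_length_mismatch(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "id,chromosome,start,end,length_bp,snp_ids\n"
            "mh01abc001,1,100,150,99,rs1;rs2\n"
        )
        with pytest.raises(ValueError, match="stated length"):
            mh.parse_panel_definition(path)


class TestFrequencyTables:
    def test_roundtrip(self, tmp_path, synthetic_panel):
        path = tmp_path / "freqs.csv"
        mh.write_frequency_table(synthetic_panel[:3], path)
        back = mh.read_frequency_table(path)
        assert [s.locus_id for s in back] == [s.locus_id for s in synthetic_panel[:3]]
        for orig, new in zip(synthetic_panel[:3], back):
            assert new.alleles == orig.alleles
            np.testing.assert_allclose(new.frequencies, orig.frequencies, atol=1e-12)

    def test_near_one_sum_renormalized(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("locus_id,allele,frequency\nL1,ACG,0.5\nL1,ACT,0.5000004\n")
        (fs,) = mh.read_frequency_table(path)
        assert abs(fs.frequencies.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize(
        "rows",
        [
            "L1,ACG,0.5\nL1,ACT,0.6",      # sum violation
            "L1,ACG,-0.1\nL1,ACT,1.1",     # negative
            "L1,ACG,0.5\nL1,ACG,0.5",      # duplicate allele
        ],
    )
    def test_invalid_tables_rejected(self, tmp_path, rows):
        path = tmp_path / "f.csv"
        path.write_text("locus_id,allele,frequency\n" + rows + "\n")
        with pytest.raises(ValueError):
            mh.read_frequency_table(path)


class TestGenotypeTables:
    def test_pair_order_insensitive(self):
        t = mh.GenotypeTable.from_dict({"s1": {"L1": ("ATT", "ACT")}, "s2": {"L1": ("ACT", "ATT")}})
        assert t.genotype("s1", "L1") == t.genotype("s2", "L1") == ("ACT", "ATT")

    def test_roundtrip_synthetic_table(self, tmp_path, synthetic_panel):
        table = mh.hwe_genotype_table(synthetic_panel, 50, seed=3)
        path = tmp_path / "geno.csv"
        mh.write_genotype_table(table, path)
        back = mh.read_genotype_table(path)
        assert back.equals(table)

    def test_missing_marker(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample_id,mh01sim001\ns1,ACG/ACT\ns2,./.\n")
        t = mh.read_genotype_table(path)
        assert t.genotype("s1", "mh01sim001") == ("ACG", "ACT")
        assert t.genotype("s2", "mh01sim001") is None

    def test_allele_length_validated_against_panel(self, tmp_path):
        locus = MicrohapLocus("mh01abc001", 1, (100, 120, 150), ("rs1", "rs2", "rs3"))
        path = tmp_path / "g.csv"
        path.write_text("sample_id,mh01abc001\ns1,AC/AT\n")
        with pytest.raises(ValueError, match="inconsistent"):
            mh.read_genotype_table(path, panel=[locus])

    def test_duo_roundtrip(self, tmp_path, synthetic_panel):
        duos = mh.simulate_duos(synthetic_panel[:4], 6, seed=5)
        path = tmp_path / "duos.csv"
        mh.panel_model.write_duo_table(duos, path)
        back = mh.panel_model.read_duo_table(path)
        assert [d.duo_id for d in back] == [d.duo_id for d in duos]
        for orig, new in zip(duos, back):
            assert new.parent == orig.parent
            assert new.child == orig.child


class TestVcf:
    def test_fixture_roundtrip_count_and_flags(self, tmp_path):
        path = tmp_path / "sim.vcf"
        write_variants_vcf(path, n_variants=200, seed=7)
        variants = mh.read_vcf_candidates(path)
        assert len(variants) == 200
        for v in variants:
            assert v.is_triallelic == (len(v.alts) >= 2)
            assert abs(v.frequencies.sum() - 1.0) < 1e-5
        assert any(v.is_triallelic for v in variants)

    def test_af_complement(self, tmp_path):
        path = tmp_path / "af.vcf"
        path.write_text(
            textwrap.dedent(
                """\
                ##fileformat=VCFv4.2
                ##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
                ##contig=<ID=1>
                #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
                1\t100\trs1\tA\tC,T\t.\t.\tAF=0.6,0.3
                """
            )
        )
        (v,) = mh.read_vcf_candidates(path)
        assert v.is_triallelic
        np.testing.assert_allclose(v.frequencies, [0.1, 0.6, 0.3], atol=1e-6)

    def test_missing_af_and_gt_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\trs1\tA\tC\t.\t.\t.\n"
        )
        with pytest.raises(ValueError, match="no AF"):
            mh.read_vcf_candidates(path)

    def test_region_filter(self, tmp_path):
        path = tmp_path / "sim.vcf"
        write_variants_vcf(path, n_variants=50, seed=7)
        everything = mh.read_vcf_candidates(path)
        lo, hi = everything[10].pos, everything[20].pos
        window = mh.read_vcf_candidates(path, region=f"1:{lo}-{hi}")
        assert len(window) == 11
        assert window[0].pos == lo and window[-1].pos == hi


class TestNewick:
    def test_two_leaf_symmetric_split(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 0.2], [0.2, 0.0]]))
        assert mh.write_newick(mh.nj_tree(dm)) == "(A:0.1,B:0.1);"

    def test_equidistant_three_taxa(self):
        d = np.full((3, 3), 0.4)
        np.fill_diagonal(d, 0.0)
        tree = mh.nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.2, "B": 0.2, "C": 0.2}

    def test_four_taxon_newick_rereads_to_generating_metric(self, tmp_path):
        import io
        from skbio import TreeNode

        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], dtype=float
        )
        newick = mh.write_newick(mh.nj_tree(DistanceMatrix(labels, d)))
        reread = TreeNode.read(io.StringIO(newick))
        tips = {t.name: t for t in reread.tips()}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tips[a].distance(tips[b]) == pytest.approx(d[i, j], abs=1e-9)
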