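import numpy as np
import pytest

from domevol import (
    Alignment,
    DomevolError,
    SequenceRecord,
    annotate_gvgd,
    assign_tiers,
    grantham_distance,
    parse_protein_change,
    parse_variants,
    parse_vcf,
    positional_density,
    tally,
    tier_counts,
    vote_tier,
    write_variants,
)
from domevol.io import Region, RegionMap
from domevol.simulate import simulate_missense_table
from domevol.variants import TIERS, VariantRecord


class TestParsing:
    @pytest.mark.parametrize(
        "text,expect",
        [
            ("p.Arg1008Gln", ("R", 1008, "Q")),
            ("Arg1008Gln", ("R", 1008, "Q")),
            ("R1008Q", ("R", 1008, "Q")),
            ("p.Ser9Ala", ("S", 9, "A")),
        ],
    )
    def test_protein_change_styles(self, text, expect):
        assert parse_protein_change(text) == expect

    def test_malformed_change_rejected(self):
        with pytest.raises(DomevolError, match="malformed"):
            parse_protein_change("c.123A>G")

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(DomevolError, match="ref equals alt"):
            VariantRecord(protein_position=10, ref_aa="A", alt_aa="A")

    def test_score_out_of_range_rejected(self):
        with pytest.raises(DomevolError, match="sift"):
            VariantRecord(protein_position=10, ref_aa="A", alt_aa="G", sift=1.5)

    def test_tsv_bad_rows_logged_not_fatal(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "protein_change\tsift\npoor_text\t0.1\np.Arg10Gln\t0.2\n"
        )
        with pytest.warns(UserWarning, match="rejected"):
            records = parse_variants(p)
        assert len(records) == 1 and records[0].protein_position == 10

    def test_roundtrip(self, tmp_path):
        records, _ = simulate_missense_table(50, seed=3)
        p = tmp_path / "rt.tsv"
        write_variants(records, p)
        back = parse_variants(p)
        assert [(r.ref_aa, r.protein_position, r.alt_aa) for r in back] == [
            (r.ref_aa, r.protein_position, r.alt_aa) for r in records
        ]
        assert [r.sift for r in back] == [r.sift for r in records]
        assert [r.gd for r in back] == [r.gd for r in records]

    def test_vcf_with_csq(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            '##fileformat=VCFv4.2\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
            'Format: Consequence|Protein_position|Amino_acids|SIFT|PolyPhen">\n'
            '##contig=<ID=2>\n'
            '#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n'
            '2\t100\t.\tG\tA\t50\tPASS\tCSQ=missense_variant|1008|R/Q|deleterious(0.01)|probably_damaging(0.95)\n'
            '2\t200\t.\tT\tC\t50\tPASS\tCSQ=intron_variant|||\n'
            '2\t300\t.\tC\tT\t50\tPASS\tCSQ=missense_variant|42|A/V||\n'
        )
        records = parse_vcf(vcf)
        assert len(records) == 2
        first = records[0]
        assert (first.ref_aa, first.protein_position, first.alt_aa) == ("R", 1008, "Q")
        assert first.sift == 0.01 and first.polyphen == 0.95
        assert records[1].sift is None


class TestVoting:
    def test_all_damaging(self):
        assert vote_tier(120, 0.01, 0.95) == "three"

    def test_all_benign(self):
        assert vote_tier(10, 0.5, 0.1) == "none"

    def test_absent_scores_are_nonvotes(self):
        assert vote_tier(None, 0.01, None) == "one"
        with pytest.raises(DomevolError, match="at least one"):
            vote_tier(None, None, None)

    def test_monotone_in_every_score(self, rng):
        # making any score strictly more damaging never lowers the tier
        for _ in range(200):
            gd = float(rng.uniform(0, 215))
            sift = float(rng.uniform(0, 1))
            poly = float(rng.uniform(0, 1))
            base = TIERS.index(vote_tier(gd, sift, poly))
            assert TIERS.index(vote_tier(gd + 20, sift, poly)) >= base
            assert TIERS.index(vote_tier(gd, max(sift - 0.2, 0), poly)) >= base
            assert TIERS.index(vote_tier(gd, sift, min(poly + 0.2, 1))) >= base

    def test_planted_tier_mix_recovered_exactly(self):
        records, truth = simulate_missense_table(
            1000, tier_mix=(0.1, 0.2, 0.3, 0.4), seed=11
        )
        assign_tiers(records)
        assert [r.vote_tier for r in records] == truth
        counts = tier_counts(records)
        assert counts.to_dict() == {"none": 100, "one": 200, "two": 300, "three": 400}


class TestAnnotateGVGD:
    def test_invariant_column_matches_plain_distance(self):
        msa = Alignment(
            [SequenceRecord("ref", "RRAA"), SequenceRecord("s2", "RRWA")]
        )
        rec = VariantRecord(protein_position=1, ref_aa="R", alt_aa="K")
        annotate_gvgd([rec], msa, "ref")
        assert rec.gv == 0.0
        assert rec.gd == pytest.approx(grantham_distance("R", "K"))

    def test_observed_range_zeroes_gd(self):
        msa = Alignment(
            [SequenceRecord("ref", "LA"), SequenceRecord("s2", "FA")]
        )
        rec = VariantRecord(protein_position=1, ref_aa="L", alt_aa="I")
        annotate_gvgd([rec], msa, "ref")
        assert rec.gd == 0.0 and rec.gv > 0

    def test_unalignable_position_falls_back_to_sequence_only(self):
        msa = Alignment(
            [SequenceRecord("ref", "RR"), SequenceRecord("s2", "RR")]
        )
        rec = VariantRecord(protein_position=5, ref_aa="C", alt_aa="W")
        annotate_gvgd([rec], msa, "ref")
        assert rec.gv == 0.0
        assert rec.gd == pytest.approx(grantham_distance("C", "W"))


class TestTallyAndDensity:
    def test_empty_table(self):
        summary = tally([])
        assert summary.n_total == 0
        assert summary.class_counts.empty

    def test_ten_row_hand_count(self):
        records = [
            VariantRecord(protein_position=i + 1, ref_aa="A", alt_aa="G",
                          variant_class=c, consequence=q)
            for i, (c, q) in enumerate(
                [("SNP", "intron_variant")] * 5
                + [("SNP", "missense_variant")] * 2
                + [("insertion", "intron_variant")] * 2
                + [("deletion", "upstream_gene_variant")]
            )
        ]
        summary = tally(records)
        assert summary.n_total == 10
        assert summary.class_counts.to_dict() == {"SNP": 7, "insertion": 2, "deletion": 1}
        assert summary.class_percent["SNP"] == pytest.approx(70.0)
        assert summary.top_consequences.index[0] == "intron_variant"
        assert summary.class_percent.sum() == pytest.approx(100.0, abs=0.1)

    def test_density_enrichment_recovered(self):
        records, _ = simulate_missense_table(2000, seed=8)
        rm = RegionMap(
            "ref",
            [Region("N-terminal", 1, 692), Region("C-terminal", 978, 1104)],
        )
        dens = positional_density(records, rm).set_index("region")["density"]
        ratio = dens["N-terminal"] / dens["C-terminal"]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_out_of_reference_records_skipped(self):
        records = [
            VariantRecord(protein_position=10, ref_aa="A", alt_aa="G"),
            VariantRecord(protein_position=5000, ref_aa="A", alt_aa="G"),
        ]
        rm = RegionMap("ref", [Region("all", 1, 100)])
        with pytest.warns(UserWarning, match="skipped 1"):
            out = positional_density(records, rm, reference_length=1104)
        assert out.iloc[0]["n_missense"] == 1
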