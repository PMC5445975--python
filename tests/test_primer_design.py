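import random

import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from deldesign.genome_index import GenomeSequence, reverse_complement
from deldesign.primer_design import (
    CheckingDesign,
    PlasmidConfig,
    PrimerConstraints,
    PrimerDesignError,
    TmConditions,
    build_hr_template,
    design_checking_primers,
    design_cloning_primers,
    design_hr_primers,
    melting_temperature,
    simulate_cloning_assembly,
)
from deldesign.target_resolution import parse_region

from conftest import random_genome, random_spacer


def _biopython_tm(seq: str) -> float:
    """Independent nearest-neighbor reference (same published tables)."""
    return mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, K=0, Tris=0, Mg=0,
                    dNTPs=0, dnac1=25, dnac2=25, saltcorr=5)


class TestMeltingTemperature:
    def test_m13f_reference_value(self):
        # sequencing primer; expected value frozen from the reference
        # implementation before the main build
        assert melting_temperature("TGTAAAACGACGGCCAGT") == pytest.approx(
            51.143, abs=0.01
        )

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=35))
    def test_agrees_with_reference_implementation(self, seq):
        assert melting_temperature(seq) == pytest.approx(_biopython_tm(seq), abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=30))
    def test_duplex_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(reverse_complement(seq)), abs=1e-9
        )

    def test_gc_rich_melts_higher(self):
        assert melting_temperature("GCGCGCGCGCGCGCGCGCGC") > melting_temperature(
            "ATATATATATATATATATAT"
        )

    def test_too_short_rejected(self):
        with pytest.raises(PrimerDesignError):
            melting_temperature("ACGTACG")

    def test_non_acgt_rejected(self):
        with pytest.raises(PrimerDesignError):
            melting_temperature("ACGTNACGT")

    def test_conditions_shift_tm(self):
        seq = "ACGTACGTACGTACGTACGT"
        low = melting_temperature(seq, TmConditions(monovalent_mM=10))
        high = melting_temperature(seq, TmConditions(monovalent_mM=500))
        assert low < high


class TestHrTemplate:
    def test_homopolymer_lengths(self):
        genome = GenomeSequence({"I": "A" * 300})
        region = parse_region("I", 101, 200, genome)
        template = build_hr_template(genome, region)
        assert template == "A" * 160
        assert len(template) == 160

    def test_flanks_by_construction(self):
        rng = random.Random(13)
        pad = "".join(rng.choice("ACGT") for _ in range(20))
        p = "".join(rng.choice("ACGT") for _ in range(80))
        d = "".join(rng.choice("ACGT") for _ in range(100))
        q = "".join(rng.choice("ACGT") for _ in range(80))
        genome = GenomeSequence({"I": pad + p + d + q + pad})
        region = parse_region("I", 101, 200, genome)  # the D interval
        assert build_hr_template(genome, region) == p + q

    def test_insufficient_upstream_flank(self):
        genome = GenomeSequence({"I": "A" * 300})
        region = parse_region("I", 50, 120, genome)
        with pytest.raises(PrimerDesignError, match="49"):
            build_hr_template(genome, region)

    def test_deletion_round_trip(self):
        # reading across the in-silico deleted junction reproduces the template
        rng = random.Random(17)
        genome = random_genome(rng, 600)
        region = parse_region("I", 250, 380, genome)
        template = build_hr_template(genome, region)
        seq = genome.sequence("I")
        deleted = seq[: region.start - 1] + seq[region.end :]
        junction = region.start - 1  # 0-based length of retained upstream
        assert deleted[junction - 80 : junction + 80] == template


class TestHrPrimers:
    def test_paper_lengths_and_overlap(self):
        rng = random.Random(19)
        template = "".join(rng.choice("ACGT") for _ in range(160))
        fw, rv = design_hr_primers(template)
        assert len(fw.seq) == 100 and len(rv.seq) == 100
        assert fw.seq == template[:100]
        assert rv.seq == reverse_complement(template[-100:])
        # overlap identity over the 40-nt physical overlap
        overlap = 2 * 100 - 160
        assert fw.seq[-overlap:] == reverse_complement(rv.seq)[:overlap][-overlap:]
        assert "overlap 40" in fw.name

    def test_homopolymer_reverse_primer(self):
        fw, rv = design_hr_primers("A" * 160)
        assert rv.seq == "T" * 100

    def test_non_overlapping_rejected(self):
        with pytest.raises(PrimerDesignError, match="not overlap"):
            design_hr_primers("A" * 160, primer_len=80)

    def test_template_shorter_than_primer_rejected(self):
        with pytest.raises(PrimerDesignError):
            design_hr_primers("A" * 90, primer_len=100)

    def test_overlap_region_identical_in_both(self):
        rng = random.Random(23)
        template = "".join(rng.choice("ACGT") for _ in range(150))
        fw, rv = design_hr_primers(template, primer_len=90)
        overlap = 2 * 90 - 150
        assert fw.seq[-overlap:] == reverse_complement(rv.seq[-overlap:])


class TestCloningPrimers:
    TOY = PlasmidConfig("GGGGG" + "TTTTT", insertion_point=5, anneal_len=5)

    def test_ligation_free_toy(self):
        fw, rv = design_cloning_primers("A" * 20, self.TOY, "ligation_free")
        assert fw.seq == "A" * 20 + "TTTTT"
        assert rv.seq == "T" * 20 + "CCCCC"

    def test_ligation_toy(self):
        fw, rv = design_cloning_primers("A" * 20, self.TOY, "ligation")
        assert fw.seq == "A" * 20 + "TTTTT"
        assert rv.seq == "CCCCC"

    @pytest.mark.parametrize("method", ["ligation", "ligation_free"])
    def test_toy_assembly(self, method):
        fw, rv = design_cloning_primers("A" * 20, self.TOY, method)
        circle = simulate_cloning_assembly(fw, rv, self.TOY, method)
        assert circle == "GGGGG" + "A" * 20 + "TTTTT"

    @pytest.mark.parametrize("method", ["ligation", "ligation_free"])
    def test_assembly_on_random_fixtures(self, method):
        rng = random.Random(29)
        for _ in range(50):
            n = rng.randint(40, 120)
            plasmid_seq = "".join(rng.choice("ACGT") for _ in range(n))
            p = rng.randint(1, n)
            plasmid = PlasmidConfig(plasmid_seq, insertion_point=p,
                                    anneal_len=rng.randint(15, 20))
            spacer = random_spacer(rng)
            fw, rv = design_cloning_primers(spacer, plasmid, method)
            circle = simulate_cloning_assembly(fw, rv, plasmid, method)
            assert circle == plasmid.expected_circle(spacer)

    def test_anneal_wraps_circular_origin(self):
        # insertion point at the very end: scaffold anneal wraps to position 1
        plasmid = PlasmidConfig("ACGTACGTACGTACGTACGTGGCC", insertion_point=24,
                                anneal_len=16)
        fw, rv = design_cloning_primers("A" * 20, plasmid, "ligation_free")
        assert fw.seq.endswith(plasmid.sequence[:16])

    def test_mispriming_warning(self, caplog):
        plasmid = PlasmidConfig("G" * 10 + "A" * 20 + "C" * 10,
                                insertion_point=10, anneal_len=15)
        with caplog.at_level("WARNING"):
            design_cloning_primers("A" * 20, plasmid, "ligation")
        assert any("mispriming" in r.message for r in caplog.records)

    def test_bad_spacer_rejected(self):
        with pytest.raises(PrimerDesignError):
            design_cloning_primers("ACGT", self.TOY, "ligation")

    def test_unknown_method_rejected(self):
        with pytest.raises(PrimerDesignError, match="unknown cloning method"):
            design_cloning_primers("A" * 20, self.TOY, "gibson")


class TestCheckingPrimers:
    @pytest.fixture()
    def design(self):
        rng = random.Random(31)
        genome = random_genome(rng, 2000)
        region = parse_region("I", 901, 1100, genome)
        return genome, region, design_checking_primers(genome, region)

    def test_junction_is_500nt_of_joined_flanks(self, design):
        genome, region, out = design
        assert len(out.junction_sequence) == 500
        up = genome.slice("I", region.start - 250, region.start - 1)
        down = genome.slice("I", region.end + 1, region.end + 250)
        assert out.junction_sequence == up + down

    def test_product_size_identity(self, design):
        _, region, out = design
        assert (out.product_size_wildtype - out.product_size_deleted
                == region.length)
        assert out.product_size_deleted <= 500

    def test_primers_are_genomic_and_outside_deletion(self, design):
        genome, region, out = design
        seq = genome.sequence("I")
        fs, fe = out.forward.footprint
        rs, re_ = out.reverse.footprint
        assert seq[fs - 1 : fe] == out.forward.seq
        assert reverse_complement(seq[rs - 1 : re_]) == out.reverse.seq
        assert fe < region.start and rs > region.end

    def test_constraints_respected(self, design):
        _, _, out = design
        c = PrimerConstraints()
        for primer in (out.forward, out.reverse):
            assert c.min_len <= len(primer.seq) <= c.max_len
            assert c.min_tm <= primer.tm_celsius <= c.max_tm
        assert abs(out.forward.tm_celsius - out.reverse.tm_celsius) <= c.max_pair_tm_diff

    def test_insufficient_flank_rejected(self):
        genome = GenomeSequence({"I": "ACGT" * 200})
        region = parse_region("I", 100, 200, genome)
        with pytest.raises(PrimerDesignError, match="99 up"):
            design_checking_primers(genome, region)

    def test_impossible_constraints_name_violation(self):
        genome = GenomeSequence({"I": "AT" * 500})
        region = parse_region("I", 400, 500, genome)
        # an AT-only flank can never reach 20% GC, and that is the closest
        # any window gets to passing
        with pytest.raises(PrimerDesignError, match="forward.*GC below 20%"):
            design_checking_primers(genome, region, flank=250)

    def test_sizes_on_random_fixtures(self):
        rng = random.Random(37)
        for _ in range(20):
            genome = random_genome(rng, 1500)
            start = rng.randint(300, 700)
            end = start + rng.randint(50, 400)
            region = parse_region("I", start, end, genome)
            out = design_checking_primers(genome, region)
            assert (out.product_size_wildtype - out.product_size_deleted
                    == region.length)

    def test_deterministic(self):
        rng = random.Random(41)
        genome = random_genome(rng, 1200)
        region = parse_region("I", 500, 700, genome)
        a = design_checking_primers(genome, region)
        b = design_checking_primers(genome, region)
        assert a == b


class TestPlasmidConfig:
    def test_insertion_point_validated(self):
        with pytest.raises(PrimerDesignError):
            PlasmidConfig("ACGT" * 10, insertion_point=0)

    def test_short_anneal_len_warns(self, caplog):
        with caplog.at_level("WARNING"):
            PlasmidConfig("ACGT" * 10, insertion_point=5, anneal_len=10)
        assert any("anneal_len" in r.message for r in caplog.records)

    def test_anneal_len_longer_than_plasmid_rejected(self):
        with pytest.raises(PrimerDesignError, match="anneal_len"):
            PlasmidConfig("ACGT" * 4, insertion_point=5, anneal_len=17)

    def test_from_fasta(self, tmp_path):
        path = tmp_path / "plasmid.fa"
        path.write_text(">p\nacgtacgtacgtacgtacgtacgt\n")
        plasmid = PlasmidConfig.from_file(path, insertion_point=12, anneal_len=15)
        assert plasmid.sequence == "ACGTACGTACGTACGTACGTACGT"

    def test_expected_circle(self):
        plasmid = PlasmidConfig.toy_default()
        circle = plasmid.expected_circle("T" * 20)
        p = plasmid.insertion_point
        assert circle[p : p + 20] == "T" * 20
        assert len(circle) == len(plasmid.sequence) + 20
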