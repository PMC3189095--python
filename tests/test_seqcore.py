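"""Sequence model, site scanning, digestion and ligation chemistry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bglbrick.seqcore import (
    BGLBRICK_ENZYMES,
    ENZYMES,
    AlphabetError,
    DnaSequence,
    End,
    LigationIncompatibleError,
    NoCutSiteError,
    TopologyError,
    circular_equal,
    circularize,
    digest,
    ends_compatible,
    find_sites,
    ligate,
    ligate_all,
    revcomp,
    revcomp_str,
    rotate,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestRevcomp:
    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_involution(self, s):
        seq = DnaSequence(s)
        assert revcomp(revcomp(seq)).bases == seq.bases

    def test_palindrome(self):
        assert revcomp_str("GAATTC") == "GAATTC"

    def test_quikchange_pair_is_reverse_complement(self):
        # the two strands of the published pSC101 mutagenic oligo pair
        f1 = "gaatttacagatacccagatcAcccgggaaaagg"
        r1 = "ccttttcccgggTgatctgggtatctgtaaattc"
        assert revcomp_str(f1) == r1.upper()

    def test_alphabet_error_names_position(self):
        with pytest.raises(AlphabetError, match="position 2"):
            DnaSequence("ACNGT")


class TestFindSites:
    def test_tailed_primer_carries_one_bglii_site(self):
        rfp_f1 = "aaaAGATCTtttaagaaggagatatacatATGgcgagtagcgaagacgttatc"
        hits = find_sites(DnaSequence(rfp_f1), ENZYMES["BglII"])
        assert [(h.enzyme, h.position) for h in hits] == [("BglII", 3)]

    def test_no_sites_in_homopolymer(self):
        assert find_sites(DnaSequence("AAAAAAAA"), ENZYMES.values()) == []

    def test_site_spanning_circular_origin(self):
        # ...AGA|TCT... across index 0
        seq = DnaSequence("TCTAAACCCAGA", circular=True)
        hits = find_sites(seq, ENZYMES["BglII"])
        assert len(hits) == 1 and hits[0].wraps_origin
        assert hits[0].position == 9

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_doubled_string_oracle(self, seed, random_seq_factory):
        seq = random_seq_factory(300, seed, circular=True)
        got = {(h.enzyme, h.position) for h in find_sites(seq, ENZYMES.values())}
        doubled = seq.bases * 2
        expected = set()
        for enz in ENZYMES.values():
            for p in range(len(seq)):
                if doubled[p : p + 6] == enz.recognition:
                    expected.add((enz.name, p))
        assert got == expected


class TestEnzymeGeometry:
    @pytest.mark.parametrize(
        "name,kind,overhang",
        [
            ("EcoRI", "five_prime", "AATT"),
            ("BglII", "five_prime", "GATC"),
            ("BamHI", "five_prime", "GATC"),
            ("XhoI", "five_prime", "TCGA"),
            ("AvrII", "five_prime", "CTAG"),
            ("SpeI", "five_prime", "CTAG"),
            ("AatII", "three_prime", "ACGT"),
            ("SacI", "three_prime", "AGCT"),
        ],
    )
    def test_overhang_chemistry_table(self, name, kind, overhang):
        enz = ENZYMES[name]
        assert enz.overhang_kind == kind
        assert enz.overhang_seq == overhang
        assert enz.overhang_length == 4

    def test_recognitions_are_palindromic(self):
        for enz in ENZYMES.values():
            assert revcomp_str(enz.recognition) == enz.recognition


class TestDigest:
    def test_two_sites_on_circle_give_two_fragments(self, clean_seq_factory):
        a = clean_seq_factory(200, 1).bases
        b = clean_seq_factory(300, 2).bases
        circ = DnaSequence("GACGTC" + a + "CCTAGG" + b, circular=True)
        frags = digest(circ, [ENZYMES["AatII"], ENZYMES["AvrII"]])
        assert len(frags) == 2

    def test_bglii_cut_offsets_against_oracle(self):
        # oracle: top strand cut at recognition+cut_top, bottom at +cut_bottom
        seq = DnaSequence("TTAGATCTAA")
        left, right = digest(seq, ENZYMES["BglII"])
        enz = ENZYMES["BglII"]
        site = seq.bases.find(enz.recognition)
        top_cut = site + enz.cut_top
        bottom_cut = site + enz.cut_bottom
        expected_overhang = seq.bases[top_cut:bottom_cut]
        assert expected_overhang == "GATC"
        assert right.left_end == End("five_prime", expected_overhang)
        assert left.right_end == End("five_prime", revcomp_str(expected_overhang))
        assert left.bases == "TTA" and right.bases == "GATCTAA"

    def test_no_cut_raises(self):
        with pytest.raises(NoCutSiteError):
            digest(DnaSequence("AAAA"), ENZYMES["BglII"])

    def test_linear_digest_reconstructs_parent(self, random_seq_factory):
        seq = random_seq_factory(3000, 11)
        frags = digest(seq, ENZYMES.values())
        assert len(frags) >= 2
        assert "".join(f.bases for f in frags) == seq.bases

    @pytest.mark.parametrize("seed", range(25))
    def test_circular_digest_ligate_round_trip(self, seed, random_seq_factory):
        seq = random_seq_factory(1500, 100 + seed, circular=True)
        subsets = [
            [ENZYMES["BglII"]],
            [ENZYMES["AatII"], ENZYMES["AvrII"]],
            list(ENZYMES.values()),
        ]
        enz = subsets[seed % len(subsets)]
        try:
            frags = digest(seq, enz)
        except NoCutSiteError:
            return
        assert circular_equal(ligate_all(frags, circular=True), seq)


class TestLigate:
    def test_avrii_spei_junction_destroyed(self):
        up = digest(DnaSequence("AAACCTAGGAAA"), ENZYMES["AvrII"])[0]
        down = digest(DnaSequence("TTTACTAGTTTT"), ENZYMES["SpeI"])[1]
        joined = ligate(up, down)
        assert "CCTAGT" in joined.bases
        junction = DnaSequence(joined.bases)
        assert find_sites(junction, [ENZYMES["AvrII"], ENZYMES["SpeI"]]) == []

    def test_bamhi_bglii_scar(self):
        up = digest(DnaSequence("AAAGGATCCAAA"), ENZYMES["BamHI"])[0]
        down = digest(DnaSequence("TTTAGATCTTTT"), ENZYMES["BglII"])[1]
        joined = ligate(up, down)
        assert "GGATCT" in joined.bases
        assert find_sites(
            DnaSequence(joined.bases), [ENZYMES["BamHI"], ENZYMES["BglII"]]
        ) == []

    def test_aatii_saci_incompatible(self):
        a = digest(DnaSequence("AAAGACGTCAAA"), ENZYMES["AatII"])[0]
        b = digest(DnaSequence("TTTGAGCTCTTT"), ENZYMES["SacI"])[1]
        with pytest.raises(LigationIncompatibleError) as exc:
            ligate(a, b)
        report = exc.value.report
        assert "ACGT" in report["end_a"] and "AGCT" in report["end_b"]

    def test_blunt_joins_blunt_only(self):
        assert ends_compatible(End("blunt"), End("blunt"))
        assert not ends_compatible(End("blunt"), End("five_prime", "GATC"))


class TestCircularEqual:
    @pytest.mark.parametrize("k", [0, 1, 7, 199])
    def test_rotations_equal(self, k, random_seq_factory):
        seq = random_seq_factory(200, 42, circular=True)
        assert circular_equal(seq, rotate(seq, k))

    def test_revcomp_rotation_equal(self, random_seq_factory):
        seq = random_seq_factory(200, 43, circular=True)
        assert circular_equal(seq, rotate(revcomp(seq), 13))

    def test_single_substitution_differs(self, random_seq_factory):
        seq = random_seq_factory(200, 44, circular=True)
        alt = "G" if seq.bases[0] != "G" else "T"
        other = DnaSequence(alt + seq.bases[1:], circular=True)
        assert not circular_equal(seq, other)

    def test_linear_input_is_topology_error(self):
        with pytest.raises(TopologyError):
            circular_equal(DnaSequence("ACGT"), DnaSequence("ACGT", circular=True))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_rotations_oracle(self, seed, random_seq_factory):
        a = random_seq_factory(200, 200 + seed, circular=True)
        r = np.random.default_rng(seed)
        if seed % 2:
            b = rotate(a, int(r.integers(200)))
            if seed % 4 == 3:
                b = revcomp(b)
        else:
            b = random_seq_factory(200, 900 + seed, circular=True)
        oracle = any(
            b.bases == a.bases[k:] + a.bases[:k]
            or b.bases == revcomp_str(a.bases[k:] + a.bases[:k])
            for k in range(len(a))
        )
        assert circular_equal(a, b) == oracle
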