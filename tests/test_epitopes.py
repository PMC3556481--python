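import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoforge import (
    TN_ALPHABET,
    TN_STN_ALPHABET,
    AlphabetLookupError,
    EpitopeSyntaxError,
    EnumerationSpec,
    GlycopeptideEpitope,
    PeptideSequence,
    ValidationError,
    build_library,
    enumerate_glycoforms,
    expand_to_protein,
    extract_windows,
    glycoform_epitope,
    identify_glycosites,
    make_tandem_repeat,
    parse_epitope,
    render_epitope,
    unique_epitopes,
)


class TestRender:
    def test_tn_on_ser6_of_13mer(self):
        e = GlycopeptideEpitope(
            peptide=PeptideSequence("RPAPGSTAPPAHG"),
            annotations={6: "GalNAc"},
        )
        assert render_epitope(e) == "RPAPGS(GalNAc)TAPPAHG"

    def test_tn_on_thr6_of_10mer(self):
        e = GlycopeptideEpitope(
            peptide=PeptideSequence("PAHGVTSAPD"), annotations={6: "GalNAc"}
        )
        assert render_epitope(e) == "PAHGVT(GalNAc)SAPD"

    def test_no_annotations_is_bare_peptide(self):
        e = GlycopeptideEpitope(peptide=PeptideSequence("RPAPGSTAPPAHG"))
        assert render_epitope(e) == "RPAPGSTAPPAHG"

    def test_annotation_on_non_ser_thr_rejected(self):
        with pytest.raises(ValidationError, match="S or T"):
            GlycopeptideEpitope(
                peptide=PeptideSequence("RPAPGSTAPPAHG"),
                annotations={1: "GalNAc"},
            )


class TestParse:
    def test_tn_on_ser7_of_10mer(self):
        e = parse_epitope("PAHGVTS(GalNAc)APD", TN_ALPHABET)
        assert len(e.peptide) == 10
        assert e.annotations == {7: "GalNAc"}
        assert e.peptide[6] == "S"

    def test_bare_string_gives_empty_annotations(self):
        e = parse_epitope("RPAPGSTAPPAHG", TN_ALPHABET)
        assert e.annotations == {}

    def test_unknown_glycan_name(self):
        with pytest.raises(AlphabetLookupError, match="Foo"):
            parse_epitope("RPAPGS(Foo)TAPPAHG", TN_ALPHABET)

    def test_unbalanced_parentheses(self):
        with pytest.raises(EpitopeSyntaxError):
            parse_epitope("RPAPGS(GalNAcTAPPAHG", TN_ALPHABET)
        with pytest.raises(EpitopeSyntaxError):
            parse_epitope("RPAPGS)TAPPAHG", TN_ALPHABET)

    def test_annotation_after_non_site_residue(self):
        with pytest.raises(ValidationError):
            parse_epitope("RP(GalNAc)APGSTAPPAHG", TN_ALPHABET)

    def test_benchmark_strings_round_trip(self):
        from glycoforge import load_benchmark_epitope_strings

        for s in load_benchmark_epitope_strings():
            assert render_epitope(parse_epitope(s, TN_ALPHABET)) == s


# random valid epitopes: a peptide guaranteed to contain sites, with a
# random subset of S/T positions annotated by random alphabet states
@st.composite
def random_epitopes(draw):
    n = draw(st.integers(min_value=5, max_value=25))
    residues = draw(
        st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=n, max_size=n)
    )
    peptide = "".join(residues)
    sites = [i + 1 for i, ch in enumerate(peptide) if ch in "ST"]
    chosen = draw(st.lists(st.sampled_from(sites), unique=True)) if sites else []
    names = [g.name for g in TN_STN_ALPHABET.glycans]
    annotations = {p: draw(st.sampled_from(names)) for p in chosen}
    return GlycopeptideEpitope(
        peptide=PeptideSequence(peptide), annotations=annotations
    )


class TestRoundTripProperty:
    @settings(max_examples=300, derandomize=True)
    @given(random_epitopes())
    def test_parse_inverts_render(self, e):
        assert parse_epitope(render_epitope(e), TN_STN_ALPHABET) == e


class TestWindows:
    def test_centered_window_recovers_13mer(self, muc1_unit):
        # 2-copy repeat; Tn on the Ser at unit position 6; the 13-mer
        # around the first-copy site (clipped at the N-terminus) must
        # reproduce the benchmark epitope (oracle: direct substring
        # arithmetic on the full sequence).
        protein = make_tandem_repeat(muc1_unit, copies=2)
        sites = tuple(identify_glycosites(muc1_unit))
        spec = EnumerationSpec(sites=sites, alphabet=TN_ALPHABET)
        gf = next(
            g for g in enumerate_glycoforms(spec)
            if [s.position for s, _ in g.occupied()] == [6]
        )
        lifted = expand_to_protein(protein, gf)
        windows = extract_windows(protein, lifted, TN_ALPHABET, window_len=13)
        rendered = {render_epitope(w) for w in windows}
        full = muc1_unit.residues * 2
        assert full[0:13] == "RPAPGSTAPPAHG"  # the clipped copy-1 window
        assert "RPAPGS(GalNAc)TAPPAHG" in rendered

    def test_full_length_window_is_whole_protein(self, muc1_unit):
        protein = make_tandem_repeat(muc1_unit, copies=1)
        sites = tuple(identify_glycosites(muc1_unit))
        spec = EnumerationSpec(sites=sites, alphabet=TN_ALPHABET)
        gf = enumerate_glycoforms(spec)[0]
        windows = extract_windows(protein, gf, TN_ALPHABET, window_len=20)
        assert len({w.peptide.residues for w in windows}) == 1
        assert windows[0].peptide.residues == muc1_unit.residues

    def test_centered_mode_one_window_per_occupied_site(self, muc1_unit):
        protein = make_tandem_repeat(muc1_unit, copies=1)
        sites = tuple(identify_glycosites(muc1_unit))
        from glycoforge import Glycoform

        gf = Glycoform(sites=sites, states=(1, 0, 0, 1, 0))
        windows = extract_windows(protein, gf, TN_ALPHABET, window_len=13)
        assert len(windows) == 2

    def test_window_len_out_of_range(self, muc1_unit):
        protein = make_tandem_repeat(muc1_unit, copies=1)
        sites = tuple(identify_glycosites(muc1_unit))
        from glycoforge import Glycoform

        gf = Glycoform(sites=sites, states=(1, 0, 0, 0, 0))
        with pytest.raises(ValidationError):
            extract_windows(protein, gf, TN_ALPHABET, window_len=4)
        with pytest.raises(ValidationError):
            extract_windows(protein, gf, TN_ALPHABET, window_len=21)

    def test_tiled_windows_all_contain_a_site(self, muc1_unit):
        protein = make_tandem_repeat(muc1_unit, copies=1)
        sites = tuple(identify_glycosites(muc1_unit))
        from glycoforge import Glycoform

        gf = Glycoform(sites=sites, states=(0, 1, 0, 0, 0))
        windows = extract_windows(protein, gf, TN_ALPHABET, window_len=6,
                                  mode="tiled")
        # site at position 7; starts 2..7 keep it inside a 6-mer
        assert [w.window_origin for w in windows] == list(range(2, 8))
        assert all(w.annotations for w in windows)


class TestUniqueEpitopes:
    def test_duplicate_windows_across_copies_collapse(self, muc1_unit):
        # Tn on unit site 7: the centered 13-mer lands at the same
        # repeat phase in both copies, so the two windows render
        # identically and collapse to one library entry.
        protein = make_tandem_repeat(muc1_unit, copies=2)
        sites = tuple(identify_glycosites(muc1_unit))
        from glycoforge import Glycoform

        gf = Glycoform(sites=sites, states=(0, 1, 0, 0, 0))
        lifted = expand_to_protein(protein, gf)
        windows = extract_windows(protein, lifted, TN_ALPHABET, window_len=13)
        assert len(windows) == 2  # one per copy
        assert {render_epitope(w) for w in windows} == {
            "RPAPGST(GalNAc)APPAHG"
        }
        assert len(unique_epitopes(windows)) == 1

    def test_interior_windows_independent_of_copy_number(self, muc1_unit):
        # identical unique rendered sets for 3 and 5 copies once
        # boundary-clipped windows are excluded (oracle: brute-force
        # window extraction on both proteins)
        def interior_set(copies):
            protein = make_tandem_repeat(muc1_unit, copies=copies)
            lib = build_library(protein, TN_ALPHABET, window_len=13,
                                mode="centered")
            n = len(protein)
            return {
                render_epitope(e)
                for e in lib
                if 14 <= e.window_origin <= n - 13 - 12
            }

        assert interior_set(3) == interior_set(5)

    def test_epitopes_differing_only_in_glycan_state_both_kept(self):
        p = PeptideSequence("RPAPGSTAPPAHG")
        a = GlycopeptideEpitope(peptide=p, annotations={7: "GalNAc"})
        b = GlycopeptideEpitope(peptide=p, annotations={7: "NeuAc-GalNAc"})
        assert len(unique_epitopes([a, b])) == 2


class TestLibrary:
    def test_whole_unit_window_library_size_is_total(self, muc1_unit):
        # window covering the whole single-copy unit: library = one
        # epitope per glycoform, k^n - 1 of them
        protein = make_tandem_repeat(muc1_unit, copies=1)
        for alphabet, expected in ((TN_ALPHABET, 31), (TN_STN_ALPHABET, 242)):
            lib = build_library(protein, alphabet, window_len=20, mode="tiled")
            assert len(lib) == expected

    def test_glycoform_epitope_annotates_occupied_sites(self, muc1_unit):
        sites = tuple(identify_glycosites(muc1_unit))
        from glycoforge import Glycoform

        gf = Glycoform(sites=sites, states=(1, 0, 0, 0, 2))
        e = glycoform_epitope(muc1_unit, gf, TN_STN_ALPHABET)
        assert e.annotations == {6: "GalNAc", 20: "NeuAc-GalNAc"}
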