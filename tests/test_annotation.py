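"""Signal peptides, cleavage sites, mature peptides, predicates and counting."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_protein
from peptidemine.annotation import (
    AnnotationConfig,
    MaturePeptide,
    SignalPeptideCall,
    annotate_precursor,
    count_peptide_copies,
    derive_mature_peptides,
    find_cleavage_sites,
    parse_predicate,
    parse_signalp_short,
    peptide_notation,
    predict_signal_peptide,
)
from peptidemine.errors import InvalidSites, PredicateSyntaxError
from peptidemine.sequence_io import Alphabet, SequenceRecord
from peptidemine.synthetic import PrecursorSpec, generate_precursor

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=90)


class TestSignalPeptide:
    def test_all_glutamate_has_no_signal(self):
        call = predict_signal_peptide("E" * 30)
        assert not call.present
        assert call.score < 0.34

    def test_designed_boundary_recovered_within_two(self):
        # hand-built signal: Met anchor, hydrophobic core, small-residue context
        rng = random.Random(0)
        for seed in range(50):
            signal = "MKT" + "L" * 10 + "ASA"
            tail = random_protein(random.Random(seed), 40, alphabet="QNDESTHF")
            call = predict_signal_peptide(signal + tail)
            assert call.present
            assert abs(call.cleavage_pos - len(signal)) <= 2

    def test_score_ignores_residues_beyond_window(self):
        base = "MKT" + "L" * 10 + "ASA" + "Q" * 30
        modified = base[:36] + "W" * (len(base) - 36)
        assert predict_signal_peptide(base).score == predict_signal_peptide(modified).score

    def test_short_input_returns_absent(self):
        call = predict_signal_peptide("MKTL")
        assert call == SignalPeptideCall(present=False, cleavage_pos=None, score=0.0)


class TestCleavageSites:
    def test_no_basic_residues(self):
        assert find_cleavage_sites("AAAA") == []

    def test_single_dibasic_site(self):
        sites = find_cleavage_sites("AAKRAA")
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end, sites[0].kind, sites[0].motif) == (2, 4, "dibasic", "KR")

    def test_maximal_run_merges_to_polybasic(self):
        sites = find_cleavage_sites("AKRRA")
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end, sites[0].kind, sites[0].motif) == (1, 4, "polybasic", "KRR")

    def test_monobasic_rules(self):
        # R accepted by default; K not; proline context blocks R
        assert [s.motif for s in find_cleavage_sites("AAGRAA")] == ["R"]
        assert find_cleavage_sites("AAGKAA") == []
        assert find_cleavage_sites("AAPRAA") == []
        assert find_cleavage_sites("AARPAA") == []
        cfg = AnnotationConfig(allow_monobasic_K=True)
        assert [s.motif for s in find_cleavage_sites("AAGKAA", config=cfg)] == ["K"]
        cfg_off = AnnotationConfig(allow_monobasic_R=False)
        assert find_cleavage_sites("AAGRAA", config=cfg_off) == []

    def test_from_pos_restricts_scan(self):
        assert find_cleavage_sites("KRAAKR", from_pos=3)[0].start == 4

    def test_sites_sorted_non_overlapping(self):
        sites = find_cleavage_sites("AKRAGRAAKKA")
        assert all(a.end <= b.start for a, b in zip(sites, sites[1:]))


NO_SIGNAL = SignalPeptideCall(present=False, cleavage_pos=None, score=0.0)


class TestDeriveMaturePeptides:
    def test_amidated_pyroglutamated_tetrapeptide(self):
        protein = "QGPRG" + "KR"
        sites = find_cleavage_sites(protein)
        peptides = derive_mature_peptides(protein, NO_SIGNAL, sites)
        assert len(peptides) == 1
        p = peptides[0]
        assert p.sequence == "QGPR"
        assert p.amidated and p.pyroglutamated
        assert p.notation == "pQGPRamide"

    def test_four_identical_non_amidated_copies(self):
        protein = "LFWVDKR" * 4
        sites = find_cleavage_sites(protein)
        peptides = derive_mature_peptides(protein, NO_SIGNAL, sites)
        assert [p.sequence for p in peptides] == ["LFWVD"] * 4
        assert not any(p.amidated for p in peptides)

    def test_no_sites_yields_single_cterm_fragment(self):
        protein = "QSTENFA"
        peptides = derive_mature_peptides(protein, NO_SIGNAL, [])
        assert len(peptides) == 1
        assert peptides[0].c_terminal_fragment
        assert not peptides[0].amidated

    def test_final_segment_never_amidated(self):
        # trailing G with no downstream site is not a donor
        protein = "AAKRNNG"
        peptides = derive_mature_peptides(protein, NO_SIGNAL, find_cleavage_sites(protein))
        assert peptides[-1].sequence == "NNG"
        assert not peptides[-1].amidated

    def test_overlapping_sites_rejected(self):
        from peptidemine.annotation import CleavageSite

        sites = [
            CleavageSite(2, 4, "dibasic", "KR"),
            CleavageSite(3, 5, "dibasic", "RR"),
        ]
        with pytest.raises(InvalidSites):
            derive_mature_peptides("AAKRRA", NO_SIGNAL, sites)


class TestNotation:
    @pytest.mark.parametrize(
        "sequence,amidated,pyro,expected",
        [
            ("QGPR", True, True, "pQGPRamide"),
            ("LFWVD", False, False, "LFWVD"),
            ("QHP", True, True, "pQHPamide"),
            ("NSFA", True, False, "NSFAamide"),
        ],
    )
    def test_display_notation(self, sequence, amidated, pyro, expected):
        p = MaturePeptide(
            sequence=sequence, start=0, end=len(sequence) + amidated,
            amidated=amidated, pyroglutamated=pyro,
        )
        assert peptide_notation(p) == expected


class TestAnnotatePrecursor:
    def test_deterministic_and_idempotent(self):
        truth = generate_precursor(PrecursorSpec(n_copies=3, peptide_template="QHP", seed=2))
        a1 = annotate_precursor(truth.protein_record)
        a2 = annotate_precursor(truth.protein_record)
        assert a1 == a2

    def test_short_record_is_partial_with_sites_scanned(self):
        rec = SequenceRecord(id="frag", residues="NNAGKRNNA", alphabet=Alphabet.aa)
        ann = annotate_precursor(rec)
        assert ann.partial
        assert len(ann.sites) == 1
        # the G before KR is read as an amidation donor even in fragments
        assert [(p.sequence, p.amidated) for p in ann.peptides] == [("NNA", True), ("NNA", False)]

    @given(AA)
    @settings(deadline=None, max_examples=200)
    def test_reconstruction_equality(self, residues):
        rec = SequenceRecord(id="x", residues=residues, alphabet=Alphabet.aa)
        ann = annotate_precursor(rec)
        assert ann.reconstruct() == residues

    @given(AA)
    @settings(deadline=None, max_examples=100)
    def test_amidation_iff_glycine_donor_in_raw_sequence(self, residues):
        rec = SequenceRecord(id="x", residues=residues, alphabet=Alphabet.aa)
        ann = annotate_precursor(rec)
        site_starts = {s.start for s in ann.sites}
        for p in ann.peptides:
            donor = residues[p.end - 1] == "G" and p.end in site_starts and p.end - p.start >= 2
            assert p.amidated == donor

    def test_disabling_monobasic_r_never_increases_count(self):
        rng = random.Random(4)
        cfg_off = AnnotationConfig(allow_monobasic_R=False)
        everything = parse_predicate("true")
        for _ in range(30):
            rec = SequenceRecord(
                id="x", residues=random_protein(rng, rng.randint(20, 80), "ACDEFGHIKLMNPQRSTVWY"),
                alphabet=Alphabet.aa,
            )
            n_on = count_peptide_copies(annotate_precursor(rec), everything, include_cterm=True)
            n_off = count_peptide_copies(annotate_precursor(rec, cfg_off), everything, include_cterm=True)
            assert n_off <= n_on

    def test_dibasic_only_precursors_unaffected_by_monobasic_flag(self):
        cfg_off = AnnotationConfig(allow_monobasic_R=False)
        for seed in range(10):
            truth = generate_precursor(
                PrecursorSpec(n_copies=5, peptide_template="QHP", separator="KR", seed=seed)
            )
            pred = parse_predicate("contains=QHP")
            on = count_peptide_copies(annotate_precursor(truth.protein_record), pred)
            off = count_peptide_copies(annotate_precursor(truth.protein_record, cfg_off), pred)
            assert on == off == 5


class TestPredicates:
    @pytest.fixture
    def annotation(self):
        truth = generate_precursor(PrecursorSpec(n_copies=2, peptide_template="QGPR", seed=1))
        return annotate_precursor(truth.protein_record)

    def test_atoms_and_conjunction(self, annotation):
        assert count_peptide_copies(annotation, "len=4 & pyroQ & amide") == 2
        assert count_peptide_copies(annotation, "contains=GPR") == 2
        assert count_peptide_copies(annotation, "startswith=Q & endswith=R") == 2

    def test_false_predicate_counts_zero(self, annotation):
        assert count_peptide_copies(annotation, "false") == 0

    def test_negation_or_parens(self, annotation):
        assert count_peptide_copies(annotation, "!amide") == 0
        assert count_peptide_copies(annotation, "(len=4 | len=5) & pyroQ") == 2

    def test_cterm_opt_in(self, annotation):
        # the C-terminal tail is excluded by default, included when asked for
        assert count_peptide_copies(annotation, "true") == 2
        assert count_peptide_copies(annotation, "true", include_cterm=True) == 3
        assert count_peptide_copies(annotation, "cterm") == 1

    def test_minres_atom(self, annotation):
        assert count_peptide_copies(annotation, "minres=G:1") == 2
        assert count_peptide_copies(annotation, "minres=G:3") == 0

    @pytest.mark.parametrize("bad", ["len==4", "unknownatom", "len=4 &", "(amide", "len=x"])
    def test_syntax_errors(self, bad):
        with pytest.raises((PredicateSyntaxError, ValueError)):
            parse_predicate(bad)("ignored")


def test_signalp_short_format_adapter(write_text):
    text = (
        "# SignalP-4.1 euk predictions\n"
        "# name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut Networks-used\n"
        "prec1 0.42 23 0.48 23 0.61 15 0.52 0.50 Y 0.34 SignalP-noTM\n"
        "prec2 0.10 12 0.11 12 0.12 5 0.10 0.11 N 0.34 SignalP-noTM\n"
    )
    calls = parse_signalp_short(write_text("sp.out", text))
    assert calls["prec1"].present and calls["prec1"].cleavage_pos == 22
    assert not calls["prec2"].present
    # the parsed call overrides the built-in heuristic
    rec = SequenceRecord(id="prec1", residues="E" * 22 + "QGPRGKRNN", alphabet=Alphabet.aa)
    ann = annotate_precursor(rec, signal=calls["prec1"])
    assert not ann.partial
    assert ann.signal_end == 22
    assert ann.peptides[0].notation == "pQGPRamide"
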