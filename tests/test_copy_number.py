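"""Copy-number matrices, clade summaries, outliers and knockout explanations."""

import random
import statistics

import pytest

from peptidemine.annotation import annotate_precursor
from peptidemine.copynum import (
    CopyNumberMatrix,
    SiteKnockout,
    build_copy_matrix,
    clade_summary,
    explain_copy_loss,
    flag_outliers,
    order_species_by_tree,
    read_clade_table,
    summarise_site_losses,
    summary_report,
    write_clade_table,
)
from peptidemine.errors import AmbiguousInput, Inconsistent, MissingReference
from peptidemine.sequence_io import Alphabet, SequenceRecord
from peptidemine.synthetic import (
    CladeDatasetSpec,
    PrecursorSpec,
    generate_clade_dataset,
    generate_precursor,
    knockout_cleavage,
)


class TestMatrixConstruction:
    def test_complete_grid(self):
        annotations = []
        for sp in ("sp1", "sp2", "sp3"):
            for fam, copies in (("famA", 2), ("famB", 3)):
                truth = generate_precursor(
                    PrecursorSpec(n_copies=copies, peptide_template="QHP", seed=hash((sp, fam)) % 1000)
                )
                annotations.append((sp, fam, annotate_precursor(truth.protein_record)))
        matrix = build_copy_matrix(annotations, {"famA": "contains=QHP", "famB": "contains=QHP"})
        assert matrix.species == ["sp1", "sp2", "sp3"]
        assert all(matrix.count(sp, "famA") == 2 for sp in matrix.species)
        assert all(matrix.count(sp, "famB") == 3 for sp in matrix.species)

    def test_partial_annotation_is_missing(self):
        truth = generate_precursor(PrecursorSpec(n_copies=2, peptide_template="QHP", seed=1))
        complete = annotate_precursor(truth.protein_record)
        fragment = annotate_precursor(
            SequenceRecord(id="frag", residues="NNAGKRNNA", alphabet=Alphabet.aa)
        )
        assert fragment.partial
        matrix = build_copy_matrix(
            [("sp1", "fam", complete), ("sp2", "fam", fragment), ("sp3", "fam", None)],
            {"fam": "contains=QHP"},
        )
        assert matrix.count("sp1", "fam") == 2
        assert matrix.count("sp2", "fam") is None
        assert matrix.count("sp3", "fam") is None

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(AmbiguousInput):
            CopyNumberMatrix.from_records([("sp1", "fam", 2), ("sp1", "fam", 3)])
        # agreeing duplicates are fine
        m = CopyNumberMatrix.from_records([("sp1", "fam", 2), ("sp1", "fam", 2)])
        assert m.count("sp1", "fam") == 2

    def test_tsv_round_trip_with_missing(self, tmp_path):
        m = CopyNumberMatrix.from_records(
            [("sp1", "famA", 4), ("sp1", "famB", None), ("sp2", "famA", 0), ("sp2", "famB", 7)]
        )
        path = tmp_path / "matrix.tsv"
        m.to_tsv(path)
        assert "NA" in path.read_text()
        assert CopyNumberMatrix.from_tsv(path) == m

    def test_zero_distinct_from_missing(self):
        m = CopyNumberMatrix.from_records([("sp1", "fam", 0), ("sp2", "fam", None)])
        assert m.count("sp1", "fam") == 0
        assert m.count("sp2", "fam") is None


class TestCladeSummary:
    def test_single_species_clade(self):
        m = CopyNumberMatrix.from_records([("sp1", "fam", 7)])
        stats = clade_summary(m, {"sp1": "A"}, "fam")
        assert (stats["A"].mean, stats["A"].median, stats["A"].mode) == (7.0, 7, 7)

    def test_against_brute_force(self):
        rng = random.Random(9)
        records, clades = [], {}
        for i in range(30):
            sp = f"sp{i:02d}"
            clades[sp] = rng.choice("ABC")
            records.append((sp, "fam", rng.choice([None, *range(5, 15)])))
        m = CopyNumberMatrix.from_records(records)
        stats = clade_summary(m, clades, "fam")
        for clade in "ABC":
            values = [
                c for (sp, _, c) in records if clades[sp] == clade and c is not None
            ]
            if not values:
                assert stats[clade].mean is None
                continue
            assert stats[clade].mean == pytest.approx(statistics.mean(values))
            assert stats[clade].median == statistics.median_low(values)
            # smallest among modal ties
            counts = {v: values.count(v) for v in values}
            top = max(counts.values())
            assert stats[clade].mode == min(v for v, n in counts.items() if n == top)
            assert stats[clade].n_species == sum(1 for sp in clades if clades[sp] == clade)

    def test_all_missing_clade_reports_absent(self):
        m = CopyNumberMatrix.from_records([("sp1", "fam", None), ("sp2", "fam", 5)])
        stats = clade_summary(m, {"sp1": "A", "sp2": "B"}, "fam")
        assert stats["A"].mean is None and stats["A"].median is None and stats["A"].mode is None
        assert stats["A"].n_missing == 1

    def test_invariant_to_species_order(self):
        recs = [("sp1", "fam", 3), ("sp2", "fam", 5), ("sp3", "fam", 5)]
        clades = {"sp1": "A", "sp2": "A", "sp3": "A"}
        a = clade_summary(CopyNumberMatrix.from_records(recs), clades, "fam")
        b = clade_summary(CopyNumberMatrix.from_records(list(reversed(recs))), clades, "fam")
        assert a == b


class TestOutliers:
    def test_uniform_clade_has_no_outliers(self):
        m = CopyNumberMatrix.from_records([(f"sp{i}", "fam", 13) for i in range(5)])
        assert flag_outliers(m, {f"sp{i}": "A" for i in range(5)}, "fam") == []

    def test_planted_deviant_flagged_with_mode(self):
        recs = [(f"sp{i}", "fam", 19) for i in range(4)] + [("odd", "fam", 16)]
        clades = {sp: "C" for sp, _, _ in recs}
        m = CopyNumberMatrix.from_records(recs)
        outliers = flag_outliers(m, clades, "fam")
        assert len(outliers) == 1
        assert (outliers[0].species, outliers[0].count, outliers[0].clade_mode) == ("odd", 16, 19)

    def test_stable_under_clade_relabelling(self):
        recs = [("sp1", "fam", 4), ("sp2", "fam", 4), ("sp3", "fam", 3)]
        m = CopyNumberMatrix.from_records(recs)
        a = flag_outliers(m, {"sp1": "A", "sp2": "A", "sp3": "A"}, "fam")
        b = flag_outliers(m, {"sp1": "Z", "sp2": "Z", "sp3": "Z"}, "fam")
        assert [(o.species, o.count, o.clade_mode) for o in a] == [
            (o.species, o.count, o.clade_mode) for o in b
        ]


class TestExplainCopyLoss:
    def _aligned(self, *rows):
        return [
            SequenceRecord(id=f"sp{i}", residues=row, alphabet=Alphabet.aa)
            for i, row in enumerate(rows)
        ]

    def test_identical_rows_report_nothing(self):
        truth = generate_precursor(PrecursorSpec(n_copies=3, peptide_template="QHP", seed=3))
        msa = self._aligned(truth.protein, truth.protein)
        ann = annotate_precursor(truth.protein_record)
        assert explain_copy_loss(msa, "sp0", ann) == []

    def test_single_basic_substitution_reported(self):
        truth = generate_precursor(PrecursorSpec(n_copies=3, peptide_template="QHP", seed=3))
        site = truth.expected_sites[1]
        mutated = truth.protein[: site.start] + "N" + truth.protein[site.start + 1 :]
        msa = self._aligned(truth.protein, mutated)
        ann = annotate_precursor(truth.protein_record)
        knockouts = explain_copy_loss(msa, "sp0", ann)
        assert len(knockouts) == 1
        k = knockouts[0]
        assert (k.species, k.alignment_column, k.observed_residue, k.role) == (
            "sp1", site.start, "N", "cleavage_basic",
        )

    def test_glycine_knockout_costs_one_amidated_peptide(self):
        truth = generate_precursor(PrecursorSpec(n_copies=4, peptide_template="QHP", seed=6))
        mutated = knockout_cleavage(truth, 1, "glycine_to_X", seed=2)
        msa = self._aligned(truth.protein, mutated.protein)
        ann = annotate_precursor(truth.protein_record)
        knockouts = explain_copy_loss(msa, "sp0", ann)
        assert [k.role for k in knockouts] == ["amidation_glycine"]
        n_ref = sum(p.amidated for p in ann.peptides)
        n_mut = sum(
            p.amidated for p in annotate_precursor(mutated.protein_record).peptides
        )
        assert n_mut == n_ref - 1

    def test_gap_reported_as_dash(self):
        truth = generate_precursor(PrecursorSpec(n_copies=2, peptide_template="QHP", seed=8))
        site = truth.expected_sites[0]
        gapped = (
            truth.protein[: site.start] + "--" + truth.protein[site.end :]
        )
        msa = self._aligned(truth.protein, gapped)
        ann = annotate_precursor(truth.protein_record)
        knockouts = explain_copy_loss(msa, "sp0", ann)
        assert {k.observed_residue for k in knockouts} == {"-"}

    def test_missing_reference_and_inconsistent_annotation(self):
        truth = generate_precursor(PrecursorSpec(n_copies=2, peptide_template="QHP", seed=8))
        msa = self._aligned(truth.protein)
        ann = annotate_precursor(truth.protein_record)
        with pytest.raises(MissingReference):
            explain_copy_loss(msa, "nope", ann)
        other = annotate_precursor(
            SequenceRecord(id="sp0", residues="W" + truth.protein[1:], alphabet=Alphabet.aa)
        )
        with pytest.raises(Inconsistent):
            explain_copy_loss(msa, "sp0", other)

    def test_destroyed_vs_weakened_sites(self):
        truth = generate_precursor(PrecursorSpec(n_copies=3, peptide_template="QHP", seed=5))
        s0, s1 = truth.expected_sites[0], truth.expected_sites[1]
        # destroy site 0 entirely, weaken site 1 (one residue left)
        p = list(truth.protein)
        p[s0.start], p[s0.start + 1] = "N", "N"
        p[s1.start] = "S"
        msa = self._aligned(truth.protein, "".join(p))
        ann = annotate_precursor(truth.protein_record)
        knockouts = explain_copy_loss(msa, "sp0", ann)
        status = summarise_site_losses(ann, msa, "sp0", knockouts)
        assert status[("sp1", 0)] == "destroyed"
        assert status[("sp1", 1)] == "weakened"


class TestInterchange:
    def test_clade_table_round_trip(self, tmp_path):
        clades = {"sp1": "A", "sp2": "B"}
        path = tmp_path / "clades.tsv"
        write_clade_table(clades, path)
        assert read_clade_table(path) == clades

    def test_species_ordered_by_newick_leaves(self):
        order = order_species_by_tree(
            ["sp3", "sp1", "sp2", "extra"], "((sp1,sp2),sp3);"
        )
        assert order == ["sp1", "sp2", "sp3", "extra"]

    def test_summary_report_shape(self, tmp_path):
        ds = generate_clade_dataset(
            CladeDatasetSpec(clades=(("A", 2, 3), ("B", 2, 4)), seed=4)
        )
        triples = [
            (sp, ds.spec.family, annotate_precursor(t.protein_record))
            for sp, t in ds.truths.items()
        ]
        matrix = build_copy_matrix(triples, {ds.spec.family: ds.predicate})
        report = summary_report(matrix, ds.clades, tmp_path / "summary.json")
        fam = report["families"][ds.spec.family]
        assert fam["clades"]["A"]["median"] == 3
        assert fam["clades"]["B"]["median"] == 4
        assert (tmp_path / "summary.json").exists()
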