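"""Copy-number evolution across species: matrices, clade summaries, knockouts.

Many precursors carry several tandem copies of related peptides; comparing
copy counts across a phylogeny reveals remarkably stable 'cocktails' with
occasional clade-specific gains and losses. This module builds species x
family count matrices (with an explicit MISSING state for absent or partial
precursors), summarises them per clade, flags per-species deviations from the
clade mode, and explains copy losses mechanistically: substitutions in the
basic residues of a cleavage site or in the amidation glycine donor, read off
a multiple alignment against an annotated reference sequence.

The per-clade central value is reported as mean, median and mode together:
counts are small integers, so the median uses the lower middle value for even
n (integer-preserving) and the mode takes the smallest value among ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import PeptidePredicate, PrecursorAnnotation, count_peptide_copies
from .errors import AmbiguousInput, Inconsistent, MissingReference
from .sequence_io import SequenceRecord

MISSING = None  # cell-level missing marker in the public API; pd.NA internally


class CopyNumberMatrix:
    """Immutable species x family matrix of non-negative counts or MISSING."""

    def __init__(self, df: pd.DataFrame):
        df = df.astype("Int64")
        if (df.fillna(0) < 0).any().any():
            raise ValueError("counts must be non-negative")
        self._df = df
        self._df.index.name = "species"

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int | None]]
    ) -> "CopyNumberMatrix":
        """Build from (species, family, count-or-None) triples.

        Duplicate (species, family) entries are tolerated when they agree and
        raise :class:`AmbiguousInput` when they conflict.
        """
        species: list[str] = []
        families: list[str] = []
        cells: dict[tuple[str, str], int | None] = {}
        for sp, fam, count in records:
            if sp not in species:
                species.append(sp)
            if fam not in families:
                families.append(fam)
            key = (sp, fam)
            if key in cells and cells[key] != count:
                raise AmbiguousInput(
                    f"conflicting counts for {sp!r}/{fam!r}: {cells[key]} vs {count}"
                )
            cells[key] = count
        df = pd.DataFrame(pd.NA, index=species, columns=families, dtype="Int64")
        for (sp, fam), count in cells.items():
            df.loc[sp, fam] = pd.NA if count is None else count
        return cls(df)

    @property
    def species(self) -> list[str]:
        return list(self._df.index)

    @property
    def families(self) -> list[str]:
        return list(self._df.columns)

    def count(self, species: str, family: str) -> int | None:
        v = self._df.loc[species, family]
        return None if pd.isna(v) else int(v)

    def family_counts(self, family: str) -> dict[str, int | None]:
        col = self._df[family]
        return {sp: (None if pd.isna(v) else int(v)) for sp, v in col.items()}

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def reorder_species(self, order: Sequence[str]) -> "CopyNumberMatrix":
        ordered = [s for s in order if s in self._df.index]
        leftover = [s for s in self._df.index if s not in ordered]
        return CopyNumberMatrix(self._df.loc[ordered + leftover])

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CopyNumberMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CopyNumberMatrix) and self._df.equals(other._df)


def build_copy_matrix(
    annotations: Iterable[tuple[str, str, PrecursorAnnotation | None]],
    predicates: Mapping[str, PeptidePredicate | str],
) -> CopyNumberMatrix:
    """Count peptide copies per (species, family) cell.

    A cell is MISSING when the annotation is absent or flagged partial -
    partial transcriptome-derived precursors cannot support a copy count.
    """
    records: list[tuple[str, str, int | None]] = []
    for sp, fam, ann in annotations:
        if ann is None or ann.partial:
            records.append((sp, fam, None))
            continue
        pred = predicates[fam]
        records.append((sp, fam, count_peptide_copies(ann, pred)))
    return CopyNumberMatrix.from_records(records)


@dataclass(frozen=True)
class CladeStats:
    mean: float | None
    median: int | None
    mode: int | None
    n_species: int
    n_missing: int


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def _smallest_mode(values: list[int]) -> int:
    freq: dict[int, int] = {}
    for v in values:
        freq[v] = freq.get(v, 0) + 1
    top = max(freq.values())
    return min(v for v, n in freq.items() if n == top)


def clade_summary(
    matrix: CopyNumberMatrix,
    clades: Mapping[str, str],
    family: str,
) -> dict[str, CladeStats]:
    """Per-clade mean/median/mode of non-MISSING counts for one family.

    A clade with no usable cells reports absent statistics (None), never 0.
    """
    if family not in matrix.families:
        raise KeyError(f"family {family!r} not in matrix")
    counts = matrix.family_counts(family)
    by_clade: dict[str, list[int | None]] = {}
    for sp, count in counts.items():
        clade = clades.get(sp)
        if clade is None:
            continue
        by_clade.setdefault(clade, []).append(count)
    out: dict[str, CladeStats] = {}
    for clade, values in sorted(by_clade.items()):
        present = [v for v in values if v is not None]
        n_missing = len(values) - len(present)
        if not present:
            out[clade] = CladeStats(None, None, None, n_species=len(values), n_missing=n_missing)
        else:
            out[clade] = CladeStats(
                mean=sum(present) / len(present),
                median=_lower_median(present),
                mode=_smallest_mode(present),
                n_species=len(values),
                n_missing=n_missing,
            )
    return out


@dataclass(frozen=True)
class Outlier:
    species: str
    count: int
    clade: str
    clade_mode: int


def flag_outliers(
    matrix: CopyNumberMatrix,
    clades: Mapping[str, str],
    family: str,
) -> list[Outlier]:
    """Species whose count deviates from their clade's modal count.

    Deviation from the mode (not mean +/- sd) matches how near-constant
    integer copy numbers behave: a single species at 16 against a clade of
    19s is the signal of interest.
    """
    stats = clade_summary(matrix, clades, family)
    counts = matrix.family_counts(family)
    out: list[Outlier] = []
    for sp in matrix.species:
        clade = clades.get(sp)
        if clade is None:
            continue
        count = counts[sp]
        mode = stats[clade].mode
        if count is None or mode is None:
            continue
        if count != mode:
            out.append(Outlier(species=sp, count=count, clade=clade, clade_mode=mode))
    return out


@dataclass(frozen=True)
class SiteKnockout:
    """A substitution (or gap) at a functional residue of the reference."""

    species: str
    alignment_column: int
    reference_residue: str
    observed_residue: str
    role: str  # cleavage_basic | amidation_glycine


def _ungapped_to_column(row: str) -> list[int]:
    mapping = []
    for col, res in enumerate(row):
        if res != "-":
            mapping.append(col)
    return mapping


def explain_copy_loss(
    msa: Sequence[SequenceRecord],
    reference_species: str,
    reference_annotation: PrecursorAnnotation,
) -> list[SiteKnockout]:
    """Report substitutions that knock out cleavage sites or amide donors.

    The reference sequence's cleavage-site basic residues and amidation
    glycine donors are mapped to alignment columns; every other sequence is
    checked at those columns. Residues outside the allowed set ({K,R} for
    basic positions, {G} for donors) are reported; gaps are reported with
    observed residue ``-``.
    """
    by_id = {r.id: r for r in msa}
    if reference_species not in by_id:
        raise MissingReference(f"reference {reference_species!r} not in alignment")
    ref_row = by_id[reference_species].residues
    ungapped = ref_row.replace("-", "")
    if ungapped != reference_annotation.record.residues:
        raise Inconsistent(
            f"alignment row for {reference_species!r} does not match the annotated sequence"
        )
    col_of = _ungapped_to_column(ref_row)

    watch: list[tuple[int, str, str]] = []  # (column, reference residue, role)
    for site in reference_annotation.sites:
        for pos in range(site.start, site.end):
            watch.append((col_of[pos], ungapped[pos], "cleavage_basic"))
    for pep in reference_annotation.peptides:
        if pep.amidated:
            donor = pep.end - 1
            watch.append((col_of[donor], "G", "amidation_glycine"))
    watch.sort()

    allowed = {"cleavage_basic": {"K", "R"}, "amidation_glycine": {"G"}}
    knockouts: list[SiteKnockout] = []
    for rec in msa:
        if rec.id == reference_species:
            continue
        for col, ref_res, role in watch:
            obs = rec.residues[col]
            if obs not in allowed[role]:
                knockouts.append(
                    SiteKnockout(
                        species=rec.id,
                        alignment_column=col,
                        reference_residue=ref_res,
                        observed_residue=obs,
                        role=role,
                    )
                )
    knockouts.sort(key=lambda k: (k.species, k.alignment_column))
    return knockouts


def summarise_site_losses(
    reference_annotation: PrecursorAnnotation,
    msa: Sequence[SequenceRecord],
    reference_species: str,
    knockouts: Sequence[SiteKnockout],
) -> dict[tuple[str, int], str]:
    """Classify per (species, site index): 'destroyed' vs 'weakened'.

    A destroyed site has every basic residue substituted; a weakened one
    retains at least one basic residue (and may still cleave under a
    monobasic rule) - the distinction changes the biological conclusion.
    """
    by_id = {r.id: r for r in msa}
    ref_row = by_id[reference_species].residues
    col_of = _ungapped_to_column(ref_row)
    site_cols = {
        idx: {col_of[pos] for pos in range(site.start, site.end)}
        for idx, site in enumerate(reference_annotation.sites)
    }
    hit: dict[tuple[str, int], set[int]] = {}
    for k in knockouts:
        if k.role != "cleavage_basic":
            continue
        for idx, cols in site_cols.items():
            if k.alignment_column in cols:
                hit.setdefault((k.species, idx), set()).add(k.alignment_column)
    return {
        key: ("destroyed" if len(cols) == len(site_cols[key[1]]) else "weakened")
        for key, cols in hit.items()
    }


def read_clade_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: species <TAB> clade label. Lines with '#' are skipped."""
    clades: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            sp, clade = line.split("\t")[:2]
            clades[sp] = clade
    return clades


def write_clade_table(clades: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp, clade in clades.items():
            fh.write(f"{sp}\t{clade}\n")


def order_species_by_tree(species: Sequence[str], newick: str | Path) -> list[str]:
    """Order species rows by leaf order of a Newick tree (display only)."""
    import dendropy

    source = Path(newick)
    if source.exists():
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(newick), schema="newick")
    leaf_order = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
    ordered = [s for s in leaf_order if s in set(species)]
    return ordered + [s for s in species if s not in set(ordered)]


def summary_report(
    matrix: CopyNumberMatrix,
    clades: Mapping[str, str],
    path_json: str | Path | None = None,
) -> dict:
    """Clade summary and outliers for every family, as a JSON-ready dict."""
    report: dict = {"families": {}}
    for fam in matrix.families:
        stats = clade_summary(matrix, clades, fam)
        outliers = flag_outliers(matrix, clades, fam)
        report["families"][fam] = {
            "clades": {
                clade: {
                    "mean": s.mean,
                    "median": s.median,
                    "mode": s.mode,
                    "n_species": s.n_species,
                    "n_missing": s.n_missing,
                }
                for clade, s in stats.items()
            },
            "outliers": [
                {
                    "species": o.species,
                    "count": o.count,
                    "clade": o.clade,
                    "clade_mode": o.clade_mode,
                }
                for o in outliers
            ],
        }
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(report, fh, indent=1)
    return report
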