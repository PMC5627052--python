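"""Synthetic precursors, transcripts and clade datasets with known truth.

The generator emulates preprohormone architecture: an N-terminal signal
peptide (Met + hydrophobic core + a small-residue cleavage context), tandem
peptide copies separated by mono-/dibasic convertase sites, optional glycine
amidation donors, N-terminal glutamines, acidic spacers, and a short
C-terminal tail. Clade datasets add clade-structured copy-number variation,
planted outliers and cleavage-site/amidation-glycine knockout mutations,
together with a by-construction multiple alignment (copies are aligned by
design, so no aligner is needed).

The module's contract - enforced in tests - is that default-config annotation
of any generated protein reproduces the generated truth exactly. Functional
residues (separators, amidation donors, a template's N-terminal Q, its
C-terminal motif) are never touched by background mutation; only the knockout
operations change them, so the truth stays recomputable without re-annotating.

Templates should be broadly hydrophilic, as real secreted peptides are; a
template carrying a long uninterrupted hydrophobic stretch could out-score
the designed signal peptide under the annotation heuristic and void the
truth contract (the tests would catch this loudly).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, replace
from typing import Sequence

from Bio.Data import CodonTable

from .annotation import CleavageSite, MaturePeptide
from .copynum import CopyNumberMatrix, SiteKnockout
from .errors import BadIndex, BadSpec
from .sequence_io import Alphabet, SequenceRecord

_SIGNAL_PREFIX = "MKT"
_SIGNAL_SUFFIX = "ASA"
# hydrophobic, deliberately outside the (-3,-1) small-residue set so the
# designed boundary stays the unique heuristic argmax
_CORE_ALPHABET = "LI"
_TAIL = "SDMTEFA"
_SEPARATORS = {"KR": "dibasic", "RR": "dibasic", "R": "monobasic", "KK": "dibasic"}
_MIXED_CHOICES = ("KR", "RR", "R")
# replacement residues for knockouts / background mutation: no K/R (would
# create sites), no G (could create donors), no Q (could create pyroGlu calls)
_NEUTRAL = "ASTNDEHFP"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in _AA_TO_CODONS.values():
    _codons.sort()
_STOPS = sorted(CodonTable.unambiguous_dna_by_id[1].stop_codons)


@dataclass(frozen=True)
class PrecursorSpec:
    """Recipe for one synthetic precursor."""

    n_copies: int
    peptide_template: str
    separator: str = "KR"  # KR | RR | KK | R | mixed
    amidation: bool = True
    pyroglu: bool | None = None  # None: inferred from the template
    spacer: str | None = None
    signal_core_len: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_copies < 1:
            raise BadSpec("n_copies must be >= 1")
        if not self.peptide_template:
            raise BadSpec("peptide_template must be non-empty")
        self._check_template_basics()
        if not self.amidation and self.peptide_template.endswith("G"):
            raise BadSpec("non-amidated template must not end in G (would be read as a donor)")
        if self.separator not in set(_SEPARATORS) | {"mixed"}:
            raise BadSpec(f"unknown separator {self.separator!r}")
        if self.separator in ("R", "mixed"):
            # a monobasic separator flanked by proline would be guard-rejected
            if self.peptide_template[0] == "P" or (
                not self.amidation and self.peptide_template[-1] == "P"
            ):
                raise BadSpec("template must not place proline next to a monobasic separator")
            if self.spacer is not None and "P" in (self.spacer[0], self.spacer[-1]):
                raise BadSpec("spacer must not place proline next to a monobasic separator")
        starts_q = self.peptide_template.startswith("Q")
        if self.pyroglu is not None and self.pyroglu != starts_q:
            raise BadSpec("pyroglu flag inconsistent with template's first residue")
        if self.spacer is not None:
            if set(self.spacer) & set("KR") or self.spacer.endswith("G") or self.spacer.startswith("Q"):
                raise BadSpec("spacer must be free of K/R, not end in G, not start with Q")
        boundary = len(_SIGNAL_PREFIX) + self.signal_core_len + len(_SIGNAL_SUFFIX)
        if not 15 <= boundary <= 35:
            raise BadSpec("signal_core_len must place the boundary within [15, 35]")

    def _check_template_basics(self) -> None:
        """Basic residues inside a template are allowed only where default
        annotation cannot read them as sites: no K/R runs, no K/R touching a
        separator boundary, and any lone R must sit in a proline context."""
        t = self.peptide_template
        for m in re.finditer(r"[KR]+", t):
            if len(m.group(0)) > 1:
                raise BadSpec("template must not contain adjacent basic residues")
            i = m.start()
            if i == 0:
                raise BadSpec("template must not start with K/R (adjacent to a separator)")
            if i == len(t) - 1 and not self.amidation:
                raise BadSpec("non-amidated template must not end with K/R")
            if m.group(0) == "R":
                left = t[i - 1]
                right = t[i + 1] if i + 1 < len(t) else ("G" if self.amidation else "")
                if left != "P" and right != "P":
                    raise BadSpec(
                        "a lone template R must be flanked by proline (else it would "
                        "be read as a monobasic cleavage site)"
                    )


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated precursor plus the annotation it must receive."""

    id: str
    protein: str
    transcript: SequenceRecord
    signal_boundary: int
    expected_peptides: tuple[MaturePeptide, ...]
    expected_sites: tuple[CleavageSite, ...]
    spec: PrecursorSpec | None = None

    @property
    def protein_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, residues=self.protein, alphabet=Alphabet.aa)


def _site_kind(motif: str) -> str:
    return "monobasic" if len(motif) == 1 else ("dibasic" if len(motif) == 2 else "polybasic")


def _assemble(
    pid: str,
    signal: str,
    parts: Sequence[tuple[str, bool, str]],
    tail: str,
    rng: random.Random,
) -> SyntheticTruth:
    """Assemble (segment, amidated, separator) parts into protein + truth."""
    chunks = [signal]
    pos = len(signal)
    peptides: list[MaturePeptide] = []
    sites: list[CleavageSite] = []
    for seg, amidated, sep in parts:
        raw = seg + ("G" if amidated else "")
        start, end = pos, pos + len(raw)
        peptides.append(
            MaturePeptide(
                sequence=seg,
                start=start,
                end=end,
                amidated=amidated,
                pyroglutamated=seg.startswith("Q"),
                c_terminal_fragment=False,
            )
        )
        chunks.append(raw)
        pos = end
        sites.append(CleavageSite(start=pos, end=pos + len(sep), kind=_site_kind(sep), motif=sep))
        chunks.append(sep)
        pos += len(sep)
    if tail:
        peptides.append(
            MaturePeptide(
                sequence=tail,
                start=pos,
                end=pos + len(tail),
                amidated=False,
                pyroglutamated=tail.startswith("Q"),
                c_terminal_fragment=True,
            )
        )
        chunks.append(tail)
    protein = "".join(chunks)
    transcript = _protein_to_transcript(pid, protein, rng)
    return SyntheticTruth(
        id=pid,
        protein=protein,
        transcript=transcript,
        signal_boundary=len(signal),
        expected_peptides=tuple(peptides),
        expected_sites=tuple(sites),
    )


def _protein_to_transcript(pid: str, protein: str, rng: random.Random) -> SequenceRecord:
    """Back-translate with uniform synonymous codons; UTRs carry an in-frame
    stop just upstream of the CDS so ORF extraction recovers exactly the
    designed protein."""
    utr5 = "".join(rng.choice("ACGT") for _ in range(rng.randint(15, 45))) + "TAA"
    cds = "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in protein) + rng.choice(_STOPS)
    utr3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(15, 45)))
    return SequenceRecord(
        id=f"{pid}_tx", residues=utr5 + cds + utr3, alphabet=Alphabet.nt
    )


def _make_signal(core_len: int, rng: random.Random) -> str:
    core = "".join(rng.choice(_CORE_ALPHABET) for _ in range(core_len))
    return _SIGNAL_PREFIX + core + _SIGNAL_SUFFIX


def _pick_separator(spec_sep: str, rng: random.Random) -> str:
    return rng.choice(_MIXED_CHOICES) if spec_sep == "mixed" else spec_sep


def generate_precursor(spec: PrecursorSpec, pid: str | None = None) -> SyntheticTruth:
    """Generate one precursor and its ground-truth annotation."""
    rng = random.Random(spec.seed)
    pid = pid or f"syn{spec.seed}"
    signal = _make_signal(spec.signal_core_len, rng)
    parts: list[tuple[str, bool, str]] = []
    for i in range(spec.n_copies):
        parts.append((spec.peptide_template, spec.amidation, _pick_separator(spec.separator, rng)))
        if spec.spacer is not None and i < spec.n_copies - 1:
            parts.append((spec.spacer, False, _pick_separator(spec.separator, rng)))
    truth = _assemble(pid, signal, parts, _TAIL, rng)
    return replace(truth, spec=spec)


def knockout_cleavage(truth: SyntheticTruth, site_index: int, mode: str, seed: int = 0) -> SyntheticTruth:
    """Destroy one cleavage site or one copy's amidation donor.

    ``basic_to_X`` replaces every basic residue of the site with a neutral
    residue, merging the two flanking peptides; ``glycine_to_X`` mutates the
    donor glycine of the copy preceding the site, dropping its amidation.
    The expected annotation is recomputed by construction.
    """
    if not 0 <= site_index < len(truth.expected_sites):
        raise BadIndex(f"site_index {site_index} out of range")
    if mode not in ("basic_to_X", "glycine_to_X"):
        raise BadIndex(f"unknown knockout mode {mode!r}")
    rng = random.Random((truth.id, site_index, mode, seed).__repr__())
    site = truth.expected_sites[site_index]
    protein = list(truth.protein)
    peptides = list(truth.expected_peptides)
    sites = list(truth.expected_sites)

    before_idx = next(
        (k for k, p in enumerate(peptides) if p.end == site.start), None
    )
    if mode == "basic_to_X":
        for pos in range(site.start, site.end):
            protein[pos] = rng.choice(_NEUTRAL)
        new_protein = "".join(protein)
        del sites[site_index]
        if before_idx is None:
            raise BadIndex("site has no upstream peptide to merge")
        after_idx = next(
            (k for k, p in enumerate(peptides) if p.start == site.end), None
        )
        if after_idx is None:
            raise BadIndex("site has no downstream peptide to merge")
        before, after = peptides[before_idx], peptides[after_idx]
        merged_end = after.end
        merged = MaturePeptide(
            sequence=new_protein[before.start : merged_end - (1 if after.amidated else 0)],
            start=before.start,
            end=merged_end,
            amidated=after.amidated,
            pyroglutamated=before.pyroglutamated,
            c_terminal_fragment=after.c_terminal_fragment,
        )
        peptides[before_idx : after_idx + 1] = [merged]
    else:  # glycine_to_X
        if before_idx is None or not peptides[before_idx].amidated:
            raise BadIndex("no amidation donor precedes that site")
        donor = site.start - 1
        protein[donor] = rng.choice(_NEUTRAL)
        new_protein = "".join(protein)
        old = peptides[before_idx]
        peptides[before_idx] = MaturePeptide(
            sequence=new_protein[old.start : old.end],
            start=old.start,
            end=old.end,
            amidated=False,
            pyroglutamated=old.pyroglutamated,
            c_terminal_fragment=False,
        )

    transcript = _protein_to_transcript(truth.id, new_protein, rng)
    return SyntheticTruth(
        id=truth.id,
        protein=new_protein,
        transcript=transcript,
        signal_boundary=truth.signal_boundary,
        expected_peptides=tuple(peptides),
        expected_sites=tuple(sites),
        spec=truth.spec,
    )


# ---------------------------------------------------------------------------
# Clade datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeDatasetSpec:
    """Recipe for a clade-structured cross-species dataset.

    ``outliers`` plant a copy-number deviation (clade label, delta) in the
    last species of the clade; ``knockouts`` plant a site or donor knockout
    (clade label, site index, mode) in the first species of the clade.
    """

    clades: tuple[tuple[str, int, int], ...]  # (label, n_species, base copies)
    outliers: tuple[tuple[str, int], ...] = ()
    knockouts: tuple[tuple[str, int, str], ...] = ()
    family: str = "FAM"
    peptide_template: str = "GFNSALMF"
    separator: str = "KR"
    amidation: bool = True
    signal_core_len: int = 12
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.clades:
            raise BadSpec("at least one clade required")
        labels = [c[0] for c in self.clades]
        if len(set(labels)) != len(labels):
            raise BadSpec("duplicate clade labels")
        base = {label: copies for label, _, copies in self.clades}
        for label, _, copies in self.clades:
            if copies < 1:
                raise BadSpec("base_copy_number must be >= 1")
        for label, delta in self.outliers:
            if label not in base:
                raise BadSpec(f"outlier names unknown clade {label!r}")
            if base[label] + delta < 0:
                raise BadSpec("outlier delta would produce a negative count")
        for label, site_index, mode in self.knockouts:
            if label not in base:
                raise BadSpec(f"knockout names unknown clade {label!r}")
            if not 0 <= site_index < base[label]:
                raise BadSpec("knockout site_index outside the clade's copy range")
            if mode not in ("basic_to_X", "glycine_to_X"):
                raise BadSpec(f"unknown knockout mode {mode!r}")
        # validate the per-copy architecture once
        PrecursorSpec(
            n_copies=1,
            peptide_template=self.peptide_template,
            separator=self.separator,
            amidation=self.amidation,
            signal_core_len=self.signal_core_len,
        )
        if self.separator == "mixed":
            raise BadSpec("clade datasets need a fixed separator so columns align")

    @property
    def predicate(self) -> str:
        motif = self.peptide_template[-2:]
        return f"endswith={motif}" + (" & amide" if self.amidation else "")


@dataclass(frozen=True)
class CladeDataset:
    spec: CladeDatasetSpec
    truths: dict[str, SyntheticTruth]
    matrix: CopyNumberMatrix
    clades: dict[str, str]
    alignment: tuple[SequenceRecord, ...]
    predicate: str
    planted_knockouts: tuple[SiteKnockout, ...]

    def clean_species(self, clade: str) -> str:
        """A species of the clade untouched by outliers and knockouts."""
        members = [sp for sp, cl in self.clades.items() if cl == clade]
        touched = {k.species for k in self.planted_knockouts}
        if any(c == clade for c, _ in self.spec.outliers):
            touched.add(members[-1])
        for sp in members:
            if sp not in touched:
                return sp
        raise BadSpec(f"no clean species left in clade {clade!r}")


def _mutate_template(template: str, rng: random.Random, rate: float) -> str:
    """Background substitutions outside functional residues: the first residue
    (possible pyroGlu Q) and the last two (the C-terminal motif the family
    predicate keys on) are immutable."""
    out = list(template)
    for i in range(1, max(1, len(template) - 2)):
        if rng.random() < rate:
            choices = [c for c in _NEUTRAL if c != out[i]]
            out[i] = rng.choice(choices)
    return "".join(out)


def generate_clade_dataset(spec: CladeDatasetSpec) -> CladeDataset:
    """Generate per-species precursors, truth matrix, clade table, alignment.

    Copies are aligned by design: each row is signal + N_max unit slots (a
    missing copy is an all-gap slot, placed before the tail) + tail, so the
    alignment columns coincide with the coordinates of a full-length row.
    """
    sep = spec.separator
    unit_len = len(spec.peptide_template) + (1 if spec.amidation else 0) + len(sep)
    seg_len = len(spec.peptide_template) + (1 if spec.amidation else 0)
    signal_len = len(_SIGNAL_PREFIX) + spec.signal_core_len + len(_SIGNAL_SUFFIX)

    copies_of: dict[str, int] = {}
    clade_of: dict[str, str] = {}
    knockout_of: dict[str, tuple[int, str]] = {}
    species_order: list[str] = []
    for label, n_species, base in spec.clades:
        members = [f"{label}{i + 1:02d}" for i in range(n_species)]
        species_order.extend(members)
        deltas = {m: 0 for m in members}
        for c_label, delta in spec.outliers:
            if c_label == label:
                deltas[members[-1]] += delta
        for c_label, site_index, mode in spec.knockouts:
            if c_label == label:
                knockout_of[members[0]] = (site_index, mode)
        for m in members:
            copies_of[m] = base + deltas[m]
            clade_of[m] = label

    n_max = max(copies_of.values())
    truths: dict[str, SyntheticTruth] = {}
    rows: list[SequenceRecord] = []
    records: list[tuple[str, str, int | None]] = []
    planted: list[SiteKnockout] = []

    for sp_name in species_order:
        rng = random.Random(f"{spec.seed}:{sp_name}")
        n = copies_of[sp_name]
        signal = _make_signal(spec.signal_core_len, rng)
        parts = [
            (_mutate_template(spec.peptide_template, rng, spec.mutation_rate), spec.amidation, sep)
            for _ in range(n)
        ]
        truth = _assemble(sp_name, signal, parts, _TAIL, rng)
        count = n
        if sp_name in knockout_of:
            site_index, mode = knockout_of[sp_name]
            pre = truth
            truth = knockout_cleavage(truth, site_index, mode, seed=spec.seed)
            count = n - 1
            unit_start = signal_len + site_index * unit_len
            if mode == "basic_to_X":
                old_site = pre.expected_sites[site_index]
                for offset, pos in enumerate(range(old_site.start, old_site.end)):
                    planted.append(
                        SiteKnockout(
                            species=sp_name,
                            alignment_column=pos,
                            reference_residue=old_site.motif[offset],
                            observed_residue=truth.protein[pos],
                            role="cleavage_basic",
                        )
                    )
            else:
                donor = unit_start + seg_len - 1
                planted.append(
                    SiteKnockout(
                        species=sp_name,
                        alignment_column=donor,
                        reference_residue="G",
                        observed_residue=truth.protein[donor],
                        role="amidation_glycine",
                    )
                )
        truths[sp_name] = truth
        records.append((sp_name, spec.family, count))
        body = truth.protein[signal_len : len(truth.protein) - len(_TAIL)]
        row = (
            truth.protein[:signal_len]
            + body
            + "-" * ((n_max - n) * unit_len)
            + _TAIL
        )
        rows.append(SequenceRecord(id=sp_name, residues=row, alphabet=Alphabet.aa))

    matrix = CopyNumberMatrix.from_records(records)
    planted.sort(key=lambda k: (k.species, k.alignment_column))
    return CladeDataset(
        spec=spec,
        truths=truths,
        matrix=matrix,
        clades=clade_of,
        alignment=tuple(rows),
        predicate=spec.predicate,
        planted_knockouts=tuple(planted),
    )
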