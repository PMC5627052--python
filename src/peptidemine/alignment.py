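"""Annotate externally computed multiple alignments with feature classes.

Each cell of an alignment is assigned one of six classes derived from the
row's own precursor annotation (not a column consensus): ``signal``,
``peptide``, ``cleavage``, ``amide_glycine``, ``spacer`` or ``gap``. Renderers
use the conventional palette - signal blue, mature peptide red, cleavage site
green, amidation glycine pink - as HTML, ANSI terminal text, or a verbatim
TSV class grid. Manual curation is supported only as an explicit overlay file
of cell-class overrides; alignments themselves are never edited silently.

Alignments are consumed, not computed: run your aligner of choice (e.g.
MAFFT) upstream and feed the result in as aligned FASTA or Clustal.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Sequence

from Bio import AlignIO

from .annotation import (
    ACIDIC,
    AnnotationConfig,
    DEFAULT_CONFIG,
    PrecursorAnnotation,
    annotate_precursor,
)
from .errors import BadFormat, Inconsistent, RaggedAlignment
from .sequence_io import Alphabet, SequenceRecord

CLASSES = ("signal", "peptide", "cleavage", "amide_glycine", "spacer", "gap")

_HTML_COLOURS = {
    "signal": "#4f86f7",       # blue
    "peptide": "#e4572e",      # red
    "cleavage": "#4caf50",     # green
    "amide_glycine": "#f7a8c4",  # pink
    "spacer": "#cccccc",
    "gap": None,
}

_ANSI_CODES = {
    "signal": "\x1b[44m",
    "peptide": "\x1b[41m",
    "cleavage": "\x1b[42m",
    "amide_glycine": "\x1b[45m",
    "spacer": "\x1b[47m",
    "gap": "",
}
_ANSI_RESET = "\x1b[0m"


@dataclass(frozen=True)
class AnnotatedAlignment:
    records: tuple[SequenceRecord, ...]
    cell_classes: tuple[tuple[str, ...], ...]
    annotations: tuple[PrecursorAnnotation, ...] = ()

    def __post_init__(self):
        if len(self.records) != len(self.cell_classes):
            raise Inconsistent("class grid row count does not match alignment")
        for rec, row in zip(self.records, self.cell_classes):
            if len(rec.residues) != len(row):
                raise Inconsistent(f"class grid width mismatch for {rec.id!r}")
            for res, cls in zip(rec.residues, row):
                if (res == "-") != (cls == "gap"):
                    raise Inconsistent(f"gap/class disagreement in {rec.id!r}")


def read_alignment(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read an aligned FASTA or Clustal file; all rows must be equal length."""
    if format not in ("fasta", "clustal"):
        raise BadFormat(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise RaggedAlignment(str(exc)) from exc
    records = [
        SequenceRecord(
            id=rec.id,
            residues=str(rec.seq).upper(),
            alphabet=Alphabet.aa,
            description=rec.description,
        )
        for rec in aln
    ]
    widths = {len(r.residues) for r in records}
    if len(widths) > 1:
        raise RaggedAlignment(f"rows of unequal length: {sorted(widths)}")
    return records


def classes_for_annotation(ann: PrecursorAnnotation, config: AnnotationConfig = DEFAULT_CONFIG) -> list[str]:
    """Per-residue classes for one ungapped, annotated precursor.

    A peptide segment is classed ``spacer`` when its acidic (D/E) fraction
    exceeds the configured maximum - acidic inter-peptide filler rather than
    a bioactive candidate. The amidation donor glycine gets its own class.
    """
    n = len(ann.record.residues)
    classes = ["peptide"] * n
    for i in range(ann.signal_end):
        classes[i] = "signal"
    for site in ann.sites:
        for i in range(site.start, site.end):
            classes[i] = "cleavage"
    for pep in ann.peptides:
        seg = ann.record.residues[pep.start : pep.end]
        acid_fraction = sum(1 for r in seg if r in ACIDIC) / len(seg)
        label = "spacer" if acid_fraction > config.spacer_max_acid_fraction else "peptide"
        for i in range(pep.start, pep.end):
            classes[i] = label
        if pep.amidated:
            classes[pep.end - 1] = "amide_glycine"
    return classes


def annotate_alignment(
    aln: Sequence[SequenceRecord],
    config: AnnotationConfig = DEFAULT_CONFIG,
) -> AnnotatedAlignment:
    """Annotate each row independently and project classes through the gaps."""
    out_rows: list[tuple[str, ...]] = []
    annotations: list[PrecursorAnnotation] = []
    for rec in aln:
        ungapped = SequenceRecord(
            id=rec.id,
            residues=rec.residues.replace("-", ""),
            alphabet=Alphabet.aa,
            description=rec.description,
        )
        ann = annotate_precursor(ungapped, config)
        annotations.append(ann)
        flat = classes_for_annotation(ann, config)
        projected: list[str] = []
        k = 0
        for res in rec.residues:
            if res == "-":
                projected.append("gap")
            else:
                projected.append(flat[k])
                k += 1
        out_rows.append(tuple(projected))
    return AnnotatedAlignment(
        records=tuple(aln), cell_classes=tuple(out_rows), annotations=tuple(annotations)
    )


def apply_overrides(aln: AnnotatedAlignment, overrides: Sequence[tuple[str, int, str]]) -> AnnotatedAlignment:
    """Apply manual curation overrides: (sequence id, column, class) triples."""
    grid = [list(row) for row in aln.cell_classes]
    index = {rec.id: i for i, rec in enumerate(aln.records)}
    for seq_id, col, cls in overrides:
        if cls not in CLASSES:
            raise BadFormat(f"unknown cell class {cls!r}")
        if seq_id not in index:
            raise Inconsistent(f"override names unknown sequence {seq_id!r}")
        row = index[seq_id]
        if (aln.records[row].residues[col] == "-") != (cls == "gap"):
            raise Inconsistent(f"override at {seq_id!r}:{col} conflicts with gap structure")
        grid[row][col] = cls
    return AnnotatedAlignment(
        records=aln.records,
        cell_classes=tuple(tuple(row) for row in grid),
        annotations=aln.annotations,
    )


def read_overrides_tsv(path: str | Path) -> list[tuple[str, int, str]]:
    out: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            seq_id, col, cls = line.split("\t")[:3]
            out.append((seq_id, int(col), cls))
    return out


def render_annotated(aln: AnnotatedAlignment, format: str = "tsv") -> str:
    """Render as ``html``, ``ansi`` or ``tsv`` (verbatim class grid)."""
    if format == "tsv":
        return _render_tsv(aln)
    if format == "html":
        return _render_html(aln)
    if format == "ansi":
        return _render_ansi(aln)
    raise BadFormat(f"unknown render format {format!r}")


def _render_tsv(aln: AnnotatedAlignment) -> str:
    buf = StringIO()
    for rec, row in zip(aln.records, aln.cell_classes):
        buf.write(f"{rec.id}\t{rec.residues}\t{','.join(row)}\n")
    return buf.getvalue()


def parse_rendered_tsv(text: str) -> AnnotatedAlignment:
    """Re-parse the TSV render back into an :class:`AnnotatedAlignment`."""
    records: list[SequenceRecord] = []
    grid: list[tuple[str, ...]] = []
    for line in text.splitlines():
        if not line:
            continue
        seq_id, residues, classes = line.split("\t")
        records.append(SequenceRecord(id=seq_id, residues=residues, alphabet=Alphabet.aa))
        grid.append(tuple(classes.split(",")))
    return AnnotatedAlignment(records=tuple(records), cell_classes=tuple(grid))


def _runs(row: Sequence[str]) -> list[tuple[int, int, str]]:
    runs: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, len(row) + 1):
        if i == len(row) or row[i] != row[start]:
            runs.append((start, i, row[start]))
            start = i
    return runs


def _render_html(aln: AnnotatedAlignment) -> str:
    lines = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><style>",
        "pre { font-family: monospace; }",
        "</style></head><body><pre>",
    ]
    for rec, row in zip(aln.records, aln.cell_classes):
        spans = []
        for start, end, cls in _runs(row):
            chunk = _html.escape(rec.residues[start:end])
            colour = _HTML_COLOURS[cls]
            if colour is None:
                spans.append(f"<span class='gap'>{chunk}</span>")
            else:
                spans.append(f"<span class='{cls}' style='background-color:{colour}'>{chunk}</span>")
        lines.append(f"{_html.escape(rec.id):<30s} " + "".join(spans))
    lines.append("</pre></body></html>")
    return "\n".join(lines) + "\n"


def _render_ansi(aln: AnnotatedAlignment) -> str:
    lines = []
    for rec, row in zip(aln.records, aln.cell_classes):
        parts = []
        for start, end, cls in _runs(row):
            code = _ANSI_CODES[cls]
            chunk = rec.residues[start:end]
            parts.append(f"{code}{chunk}{_ANSI_RESET}" if code else chunk)
        lines.append(f"{rec.id:<30s} " + "".join(parts))
    return "\n".join(lines) + "\n"
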