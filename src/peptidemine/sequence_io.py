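"""Sequence records, FASTA I/O, six-frame translation and ORF extraction.

Coordinates are 0-based, half-open everywhere. Reverse-strand open reading
frames are reported in forward-strand coordinates, with the sign of the frame
carrying the strand. Only the standard genetic code is supported: the taxa
this toolkit targets (echinoderms and other bilaterians) use it, and silently
applying an alternative code would corrupt every downstream cleavage rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, BadFrame, DuplicateId, EmptyInput, InvalidHit, TooShort

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = set(_STANDARD_TABLE.stop_codons)

NT_RESIDUES = frozenset("ACGTN") | {"-"}
AA_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*", "-"}

FRAMES = (1, 2, 3, -1, -2, -3)

_RC = str.maketrans("ACGTN", "TGCAN")


class Alphabet(str, enum.Enum):
    nt = "nt"
    aa = "aa"


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a declared alphabet.

    ``residues`` is uppercase; ``N`` is the only nucleotide ambiguity code
    accepted and ``X`` the only amino-acid one. ``*`` (stop) is permitted only
    in amino-acid records.
    """

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.aa
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise AlphabetError("record id must be non-empty")
        if not self.residues:
            raise EmptyInput(f"record {self.id!r} has no residues")
        allowed = NT_RESIDUES if self.alphabet == Alphabet.nt else AA_RESIDUES
        for pos, res in enumerate(self.residues):
            if res not in allowed:
                raise AlphabetError(
                    f"record {self.id!r}: illegal {self.alphabet.value} residue "
                    f"{res!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OpenReadingFrame:
    """A stop-free translated stretch, located on the forward strand.

    ``protein`` never contains ``*``; the nucleotide interval includes the
    trailing stop codon when one bounds the frame on the right.
    """

    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str

    def __post_init__(self):
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise BadFrame("ORF nucleotide span must be a multiple of 3")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _translate_nt(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _CODON_TO_AA:
            aas.append(_CODON_TO_AA[codon])
        elif codon in _STOP_CODONS:
            aas.append("*")
        else:
            # any ambiguity (N) translates conservatively to X
            aas.append("X")
    return "".join(aas)


def read_fasta(path: str | Path, alphabet: Alphabet | str, strip_gaps: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Accepts unaligned or aligned input; ``-`` gaps are removed only when
    ``strip_gaps`` is set, otherwise they raise :class:`AlphabetError`.
    Both LF and CRLF line endings are accepted.
    """
    alphabet = Alphabet(alphabet)
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise EmptyInput(f"no FASTA records in {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in raw:
        if rec.id in seen:
            raise DuplicateId(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if strip_gaps:
            residues = residues.replace("-", "")
        records.append(
            SequenceRecord(id=rec.id, residues=residues, alphabet=alphabet, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def six_frame_translate(transcript: SequenceRecord) -> dict[int, str]:
    """Translate a transcript in all six frames with the standard code.

    Frames +1..+3 read the forward strand from offsets 0..2; frames -1..-3
    read the reverse complement from offsets 0..2. Stops are rendered ``*``.
    """
    if transcript.alphabet != Alphabet.nt:
        raise AlphabetError("six_frame_translate requires a nucleotide record")
    seq = transcript.residues
    if len(seq) < 3:
        raise TooShort(f"transcript {transcript.id!r} shorter than one codon")
    rc = reverse_complement(seq)
    out: dict[int, str] = {}
    for off in range(3):
        out[off + 1] = _translate_nt(seq[off:])
        out[-(off + 1)] = _translate_nt(rc[off:])
    return out


def extract_orf_containing(
    transcript: SequenceRecord,
    hit_interval: tuple[int, int],
    frame: int,
    require_met: bool = False,
) -> OpenReadingFrame:
    """Extract the maximal stop-free stretch containing an alignment hit.

    ``hit_interval`` is a half-open interval in amino-acid coordinates of the
    stated frame's translation. The stretch is extended to the nearest stop
    (or sequence end) on both sides; nt coordinates are mapped back to the
    forward strand. With ``require_met`` the stretch is trimmed to its first
    methionine, which must not lie beyond the hit start.
    """
    if frame not in FRAMES:
        raise BadFrame(f"frame must be one of {FRAMES}, got {frame}")
    translation = six_frame_translate(transcript)[frame]
    hs, he = hit_interval
    if not (0 <= hs < he <= len(translation)):
        raise InvalidHit(f"hit interval {hit_interval} outside frame {frame} translation")
    if "*" in translation[hs:he]:
        raise InvalidHit(f"hit interval {hit_interval} crosses a stop codon in frame {frame}")

    left = translation.rfind("*", 0, hs)
    aa_start = left + 1  # -1 + 1 == 0 when no stop
    right = translation.find("*", he)
    has_stop = right != -1
    aa_end = right if has_stop else len(translation)

    if require_met:
        met = translation.find("M", aa_start, aa_end)
        if met == -1 or met > hs:
            raise InvalidHit("no initiator methionine at or before the hit start")
        aa_start = met

    protein = translation[aa_start:aa_end]
    off = abs(frame) - 1
    span_start = off + 3 * aa_start
    span_end = off + 3 * (aa_end + (1 if has_stop else 0))
    if frame > 0:
        nt_start, nt_end = span_start, span_end
    else:
        L = len(transcript.residues)
        nt_start, nt_end = L - span_end, L - span_start
    return OpenReadingFrame(
        transcript_id=transcript.id,
        frame=frame,
        nt_start=nt_start,
        nt_end=nt_end,
        protein=protein,
    )
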