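"""Precursor annotation: signal peptide, cleavage sites, mature peptides.

A neuropeptide precursor (preprohormone) is partitioned into an N-terminal
signal peptide, prohormone-convertase cleavage sites (maximal runs of K/R),
and the intervening segments, which are the candidate mature peptides. Two
post-translational modifications are called from sequence alone:

* C-terminal amidation - a segment whose last residue is a glycine donor
  immediately followed by a cleavage site loses the G and is flagged amidated;
* pyroglutamation - any peptide beginning with glutamine is written with the
  conventional ``pQ`` prefix (cyclisation is assumed, not predicted).

Every annotation satisfies an exact reconstruction invariant: concatenating
the signal region, the segments (with amidation glycines restored) and the
site motifs, in order, reproduces the input protein string.

Signal peptides are called by a built-in heuristic with a sensitive default
threshold of 0.34: the score at a candidate cleavage position combines the
mean Kyte-Doolittle hydropathy of the h-region window with the (-3,-1)
small-residue rule. An adapter for external SignalP short-format output can
override the built-in call.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import InvalidSites, PredicateSyntaxError
from .sequence_io import Alphabet, SequenceRecord

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0, "*": 0.0,
}

#: Residues counted as "small" by the (-3,-1) rule.
SMALL_RESIDUES = frozenset("AGSCTV")

BASIC = frozenset("KR")
ACIDIC = frozenset("DE")


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable rules for precursor annotation.

    ``signal_threshold`` of 0.34 is the sensitive default; ``dibasic_motifs``
    are the residue pairs accepted inside a multi-basic run; monobasic R sites
    are accepted by default, monobasic K sites are not.
    """

    signal_threshold: float = 0.34
    dibasic_motifs: frozenset[str] = frozenset({"KR", "RR", "KK", "RK"})
    allow_monobasic_R: bool = True
    allow_monobasic_K: bool = False
    monobasic_proline_guard: bool = True
    min_signal_cleavage: int = 15
    max_signal_cleavage: int = 35
    spacer_max_acid_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.signal_threshold <= 1.0:
            raise ValueError("signal_threshold must be in [0, 1]")
        if not self.min_signal_cleavage < self.max_signal_cleavage:
            raise ValueError("min_signal_cleavage must be < max_signal_cleavage")
        if not 0.0 <= self.spacer_max_acid_fraction <= 1.0:
            raise ValueError("spacer_max_acid_fraction must be in [0, 1]")
        object.__setattr__(self, "dibasic_motifs", frozenset(self.dibasic_motifs))

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationConfig":
        kwargs = dict(d)
        if "dibasic_motifs" in kwargs:
            kwargs["dibasic_motifs"] = frozenset(kwargs["dibasic_motifs"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "signal_threshold": self.signal_threshold,
            "dibasic_motifs": sorted(self.dibasic_motifs),
            "allow_monobasic_R": self.allow_monobasic_R,
            "allow_monobasic_K": self.allow_monobasic_K,
            "monobasic_proline_guard": self.monobasic_proline_guard,
            "min_signal_cleavage": self.min_signal_cleavage,
            "max_signal_cleavage": self.max_signal_cleavage,
            "spacer_max_acid_fraction": self.spacer_max_acid_fraction,
        }


DEFAULT_CONFIG = AnnotationConfig()


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_pos: int | None
    score: float


@dataclass(frozen=True)
class CleavageSite:
    """A maximal run of basic residues, treated as one cleavage site."""

    start: int
    end: int
    kind: str  # monobasic | dibasic | polybasic
    motif: str

    def __post_init__(self):
        if set(self.motif) - BASIC:
            raise InvalidSites(f"site motif {self.motif!r} contains non-basic residues")
        expected = "monobasic" if len(self.motif) == 1 else ("dibasic" if len(self.motif) == 2 else "polybasic")
        if self.kind != expected:
            raise InvalidSites(f"site kind {self.kind!r} does not match motif length {len(self.motif)}")


@dataclass(frozen=True)
class MaturePeptide:
    """One predicted peptide.

    ``sequence`` is the processed form (amidation glycine removed);
    ``start``/``end`` delimit the unprocessed segment in the precursor.
    """

    sequence: str
    start: int
    end: int
    amidated: bool = False
    pyroglutamated: bool = False
    c_terminal_fragment: bool = False

    @property
    def notation(self) -> str:
        core = "pQ" + self.sequence[1:] if self.pyroglutamated else self.sequence
        return core + ("amide" if self.amidated else "")


@dataclass(frozen=True)
class PrecursorAnnotation:
    record: SequenceRecord
    signal: SignalPeptideCall
    sites: tuple[CleavageSite, ...]
    peptides: tuple[MaturePeptide, ...]
    partial: bool
    family: str | None = None

    @property
    def signal_end(self) -> int:
        return self.signal.cleavage_pos if self.signal.present else 0

    def reconstruct(self) -> str:
        """Rebuild the precursor from its parts (exactness is an invariant)."""
        pieces: list[tuple[int, str]] = [(0, self.record.residues[: self.signal_end])]
        for p in self.peptides:
            seg = p.sequence + ("G" if p.amidated else "")
            pieces.append((p.start, seg))
        for s in self.sites:
            pieces.append((s.start, s.motif))
        pieces.sort(key=lambda t: t[0])
        return "".join(seg for _, seg in pieces)


def predict_signal_peptide(protein: str, config: AnnotationConfig = DEFAULT_CONFIG) -> SignalPeptideCall:
    """Heuristic signal-peptide call.

    For each candidate cleavage position p (index of the first mature residue)
    in ``[min_signal_cleavage, max_signal_cleavage]``, the score is
    ``0.7 * H(p) + 0.3 * S(p)`` where H is the mean Kyte-Doolittle hydropathy
    of residues ``[p-13, p-3)`` rescaled from [-4.5, 4.5] to [0, 1], and S is
    the (-3,-1) small-residue rule (1.0 when both of p-3 and p-1 are small,
    0.5 when exactly one is, else 0). The call is present iff the best score
    reaches the threshold; ties go to the earliest position.
    """
    if len(protein) < config.min_signal_cleavage:
        return SignalPeptideCall(present=False, cleavage_pos=None, score=0.0)
    best_score, best_p = -1.0, None
    hi = min(config.max_signal_cleavage, len(protein))
    for p in range(config.min_signal_cleavage, hi + 1):
        window = protein[max(0, p - 13) : p - 3]
        if not window:
            continue
        mean_kd = sum(KYTE_DOOLITTLE.get(r, 0.0) for r in window) / len(window)
        h = min(1.0, max(0.0, (mean_kd + 4.5) / 9.0))
        small = (protein[p - 1] in SMALL_RESIDUES) + (protein[p - 3] in SMALL_RESIDUES)
        s = {0: 0.0, 1: 0.5, 2: 1.0}[small]
        score = 0.7 * h + 0.3 * s
        if score > best_score:
            best_score, best_p = score, p
    if best_p is None:
        return SignalPeptideCall(present=False, cleavage_pos=None, score=0.0)
    present = best_score >= config.signal_threshold
    return SignalPeptideCall(present=present, cleavage_pos=best_p if present else None, score=best_score)


def find_cleavage_sites(
    protein: str, from_pos: int = 0, config: AnnotationConfig = DEFAULT_CONFIG
) -> list[CleavageSite]:
    """Scan maximal K/R runs at or after ``from_pos``.

    A run of length >= 2 is a single site (dibasic or polybasic), accepted iff
    any adjacent residue pair within it is an accepted dibasic motif. Single
    residues are sites only where the matching monobasic flag is enabled, and
    (with the default proline guard) only when neither flanking residue is
    proline: convertases do not process basic residues in a Pro context, which
    is what keeps peptide-internal arginines - e.g. the R of pQGPRamide -
    intact.
    """
    if from_pos > len(protein):
        raise InvalidSites(f"from_pos {from_pos} beyond sequence length {len(protein)}")
    sites: list[CleavageSite] = []
    for m in re.finditer(r"[KR]+", protein[from_pos:]):
        start = from_pos + m.start()
        motif = m.group(0)
        if len(motif) == 1:
            ok = (motif == "R" and config.allow_monobasic_R) or (
                motif == "K" and config.allow_monobasic_K
            )
            if ok and config.monobasic_proline_guard:
                left = protein[start - 1] if start > 0 else ""
                right = protein[start + 1] if start + 1 < len(protein) else ""
                if left == "P" or right == "P":
                    ok = False
            kind = "monobasic"
        else:
            ok = any(motif[i : i + 2] in config.dibasic_motifs for i in range(len(motif) - 1))
            kind = "dibasic" if len(motif) == 2 else "polybasic"
        if ok:
            sites.append(CleavageSite(start=start, end=start + len(motif), kind=kind, motif=motif))
    return sites


def derive_mature_peptides(
    protein: str,
    signal: SignalPeptideCall,
    sites: Sequence[CleavageSite],
    config: AnnotationConfig = DEFAULT_CONFIG,
) -> list[MaturePeptide]:
    """Cut the propeptide at the given sites and flag modifications.

    Segments run between the signal end, the sites and the sequence end; empty
    segments (adjacent sites) are dropped. A segment ending in G immediately
    followed by a site is amidated (G removed); a segment starting with Q is
    flagged pyroglutamated. The final segment, having no downstream site, is a
    C-terminal fragment and can never be amidated. Segments are retained even
    when they look like acidic spacers - classification is the caller's
    predicate's job.
    """
    signal_end = signal.cleavage_pos if signal.present else 0
    prev_end = signal_end
    for s in sites:
        if s.start < prev_end:
            raise InvalidSites(f"site [{s.start},{s.end}) overlaps preceding region ending at {prev_end}")
        prev_end = s.end

    boundaries: list[tuple[int, int, bool]] = []  # (seg_start, seg_end, followed_by_site)
    cursor = signal_end
    for s in sites:
        boundaries.append((cursor, s.start, True))
        cursor = s.end
    boundaries.append((cursor, len(protein), False))

    peptides: list[MaturePeptide] = []
    for seg_start, seg_end, followed in boundaries:
        if seg_end <= seg_start:
            continue
        segment = protein[seg_start:seg_end]
        amidated = followed and len(segment) >= 2 and segment[-1] == "G"
        sequence = segment[:-1] if amidated else segment
        peptides.append(
            MaturePeptide(
                sequence=sequence,
                start=seg_start,
                end=seg_end,
                amidated=amidated,
                pyroglutamated=sequence.startswith("Q"),
                c_terminal_fragment=not followed,
            )
        )
    return peptides


def annotate_precursor(
    record: SequenceRecord,
    config: AnnotationConfig = DEFAULT_CONFIG,
    signal: SignalPeptideCall | None = None,
    family: str | None = None,
) -> PrecursorAnnotation:
    """Full annotation of one precursor protein.

    ``signal`` overrides the built-in heuristic (e.g. a parsed external
    SignalP call). ``partial`` is set when no signal peptide is found: sites
    are then scanned from position 0 and downstream copy-number analysis
    treats the precursor as incomplete.
    """
    if record.alphabet != Alphabet.aa:
        raise InvalidSites("annotate_precursor requires an amino-acid record")
    protein = record.residues
    call = signal if signal is not None else predict_signal_peptide(protein, config)
    from_pos = call.cleavage_pos if call.present else 0
    sites = find_cleavage_sites(protein, from_pos, config)
    peptides = derive_mature_peptides(protein, call, sites, config)
    return PrecursorAnnotation(
        record=record,
        signal=call,
        sites=tuple(sites),
        peptides=tuple(peptides),
        partial=not call.present,
        family=family,
    )


def peptide_notation(p: MaturePeptide) -> str:
    """Display notation: ``pQ`` prefix for pyroglutamate, ``amide`` suffix."""
    return p.notation


# ---------------------------------------------------------------------------
# Peptide predicates (mini-syntax: `len=4 & pyroQ & amide`, `endswith=GW`, ...)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptidePredicate:
    """A pure, serialisable predicate over :class:`MaturePeptide`."""

    text: str
    fn: Callable[[MaturePeptide], bool] = field(compare=False, repr=False)
    uses_cterm: bool = False

    def __call__(self, p: MaturePeptide) -> bool:
        return self.fn(p)


_TOKEN_RE = re.compile(r"\s*(\(|\)|&|\||!|[^\s()&|!]+)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise PredicateSyntaxError(f"cannot tokenize predicate at {text[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _atom(token: str) -> Callable[[MaturePeptide], bool]:
    if token == "amide":
        return lambda p: p.amidated
    if token == "pyroQ":
        return lambda p: p.pyroglutamated
    if token == "cterm":
        return lambda p: p.c_terminal_fragment
    if token == "true":
        return lambda p: True
    if token == "false":
        return lambda p: False
    if "=" in token:
        key, _, value = token.partition("=")
        if key == "len":
            n = int(value)
            return lambda p: len(p.sequence) == n
        if key == "startswith":
            return lambda p: p.sequence.startswith(value)
        if key == "endswith":
            return lambda p: p.sequence.endswith(value)
        if key == "contains":
            return lambda p: value in p.sequence
        if key == "minres":
            res, _, count = value.partition(":")
            n = int(count)
            return lambda p: p.sequence.count(res) >= n
    raise PredicateSyntaxError(f"unknown predicate atom {token!r}")


def parse_predicate(text: str) -> PeptidePredicate:
    """Parse the predicate mini-syntax.

    Grammar: or-expressions of ``|``, and-expressions of ``&``, unary ``!``,
    parentheses, and atoms ``len=N``, ``startswith=S``, ``endswith=S``,
    ``contains=S``, ``minres=R:N``, ``amide``, ``pyroQ``, ``cterm``,
    ``true``, ``false``.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Callable:
        left = parse_and()
        while peek() == "|":
            take()
            right = parse_and()
            left = (lambda l, r: lambda p: l(p) or r(p))(left, right)
        return left

    def parse_and() -> Callable:
        left = parse_unary()
        while peek() == "&":
            take()
            right = parse_unary()
            left = (lambda l, r: lambda p: l(p) and r(p))(left, right)
        return left

    def parse_unary() -> Callable:
        if peek() == "!":
            take()
            inner = parse_unary()
            return lambda p: not inner(p)
        if peek() == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise PredicateSyntaxError("unbalanced parentheses in predicate")
            take()
            return inner
        tok = peek()
        if tok is None or tok in {")", "&", "|"}:
            raise PredicateSyntaxError(f"unexpected token {tok!r} in predicate {text!r}")
        return _atom(take())

    fn = parse_or()
    if pos != len(tokens):
        raise PredicateSyntaxError(f"trailing tokens in predicate {text!r}")
    return PeptidePredicate(text=text, fn=fn, uses_cterm=bool(re.search(r"\bcterm\b", text)))


def count_peptide_copies(
    annotation: PrecursorAnnotation,
    predicate: PeptidePredicate | str,
    include_cterm: bool = False,
) -> int:
    """Number of mature peptides satisfying the predicate.

    C-terminal fragments are excluded unless the predicate mentions ``cterm``
    or ``include_cterm`` is set.
    """
    if isinstance(predicate, str):
        predicate = parse_predicate(predicate)
    allow_cterm = include_cterm or predicate.uses_cterm
    return sum(
        1
        for p in annotation.peptides
        if (allow_cterm or not p.c_terminal_fragment) and predicate(p)
    )


# ---------------------------------------------------------------------------
# SignalP adapter and serialisation
# ---------------------------------------------------------------------------


def parse_signalp_short(path: str | Path) -> dict[str, SignalPeptideCall]:
    """Parse SignalP 4.x short-format output into override calls.

    Expected data columns: name, Cmax, pos, Ymax, pos, Smax, pos, Smean, D,
    ?, Dmaxcut, networks. The Ymax position is 1-based and points at the first
    mature residue, i.e. a 0-based cleavage_pos of ``pos - 1``.
    """
    calls: dict[str, SignalPeptideCall] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            name, ymax_pos, d_score, decision = cols[0], int(cols[4]), float(cols[8]), cols[9]
            present = decision == "Y"
            calls[name] = SignalPeptideCall(
                present=present,
                cleavage_pos=ymax_pos - 1 if present else None,
                score=d_score,
            )
    return calls


def annotation_to_dict(ann: PrecursorAnnotation) -> dict:
    return {
        "id": ann.record.id,
        "residues": ann.record.residues,
        "family": ann.family,
        "partial": ann.partial,
        "signal": {
            "present": ann.signal.present,
            "cleavage_pos": ann.signal.cleavage_pos,
            "score": ann.signal.score,
        },
        "sites": [
            {"start": s.start, "end": s.end, "kind": s.kind, "motif": s.motif} for s in ann.sites
        ],
        "peptides": [
            {
                "sequence": p.sequence,
                "start": p.start,
                "end": p.end,
                "amidated": p.amidated,
                "pyroglutamated": p.pyroglutamated,
                "c_terminal_fragment": p.c_terminal_fragment,
                "notation": p.notation,
            }
            for p in ann.peptides
        ],
    }


def annotation_from_dict(d: dict) -> PrecursorAnnotation:
    record = SequenceRecord(id=d["id"], residues=d["residues"], alphabet=Alphabet.aa)
    signal = SignalPeptideCall(
        present=d["signal"]["present"],
        cleavage_pos=d["signal"]["cleavage_pos"],
        score=d["signal"]["score"],
    )
    sites = tuple(
        CleavageSite(start=s["start"], end=s["end"], kind=s["kind"], motif=s["motif"])
        for s in d["sites"]
    )
    peptides = tuple(
        MaturePeptide(
            sequence=p["sequence"],
            start=p["start"],
            end=p["end"],
            amidated=p["amidated"],
            pyroglutamated=p["pyroglutamated"],
            c_terminal_fragment=p["c_terminal_fragment"],
        )
        for p in d["peptides"]
    )
    return PrecursorAnnotation(
        record=record, signal=signal, sites=sites, peptides=peptides,
        partial=d["partial"], family=d.get("family"),
    )


def write_annotations_json(annotations: Iterable[PrecursorAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([annotation_to_dict(a) for a in annotations], fh, indent=1)


def read_annotations_json(path: str | Path) -> list[PrecursorAnnotation]:
    with open(path) as fh:
        return [annotation_from_dict(d) for d in json.load(fh)]


def peptides_to_tsv(annotations: Iterable[PrecursorAnnotation], path: str | Path) -> None:
    """One row per mature peptide: id, coords, sequence, flags, notation."""
    with open(path, "w") as fh:
        fh.write(
            "precursor_id\tstart\tend\tsequence\tamidated\tpyroglutamated\tc_terminal_fragment\tnotation\n"
        )
        for ann in annotations:
            for p in ann.peptides:
                fh.write(
                    f"{ann.record.id}\t{p.start}\t{p.end}\t{p.sequence}\t"
                    f"{int(p.amidated)}\t{int(p.pyroglutamated)}\t{int(p.c_terminal_fragment)}\t{p.notation}\n"
                )
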