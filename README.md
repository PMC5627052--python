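# peptidemine

Neuropeptide precursor mining, annotation and copy-number evolution.

Neuropeptide precursors (preprohormones) are secreted proteins built from an
N-terminal signal peptide followed by one or more bioactive peptides that are
released by prohormone convertases at mono- and dibasic (K/R) cleavage sites.
Two sequence-predictable modifications matter for bioactivity: C-terminal
**amidation** (a glycine immediately before a cleavage site is converted into
an amide on the preceding residue) and **pyroglutamation** (an N-terminal
glutamine cyclises to pyroglutamate, written `pQ`). Many precursors carry
several tandem copies of related peptides; comparing those copy numbers
across species on a phylogeny shows strikingly stable peptide "cocktails"
with occasional clade-specific gains and losses, usually traceable to single
substitutions that destroy a cleavage site or an amidation donor.

`peptidemine` is a toolkit for that whole analysis, aimed at people mining
transcriptome assemblies for peptide hormone repertoires:

- **sequence_io** — FASTA I/O, six-frame translation, extraction of the open
  reading frame containing a similarity hit (0-based, half-open coordinates;
  reverse-strand ORFs reported on the forward strand).
- **search** — desk-scale translated search: affine-gap Smith–Waterman with a
  deterministic traceback, Karlin–Altschul E-values
  (`E = K·m·n·exp(−λ·S)`), and two cut-off presets: `discovery` (E ≤ 1000)
  and `crossspecies` (E ≤ 1e−6). A reader/writer for BLAST `-outfmt 6`
  tabular files lets an external BLAST stand in for the built-in search.
- **annotation** — the core: signal-peptide call (hydropathy + (−3,−1)
  small-residue heuristic, sensitive threshold 0.34, or an external SignalP
  short-format override), maximal-K/R-run cleavage sites, mature peptides
  with amidation/pyroglutamation flags, display notation (`pQGPRamide`), and
  a composable predicate mini-language (`len=4 & pyroQ & amide`) for counting
  peptide copies.
- **copynum** — species × family copy-number matrices with an explicit
  missing state (partial precursors are never counted), per-clade
  mean/median/mode, outlier flagging against the clade mode, and mechanistic
  copy-loss explanations read off a multiple alignment (substitutions in
  cleavage-site basics or amidation glycines).
- **clustering** — all-vs-all Smith–Waterman (BLOSUM45) similarity graph,
  seeded force-directed embedding with `−log10(p)` attraction, and connected
  components at a p-value cutoff.
- **alignment** — per-row feature classing of externally computed alignments
  (signal blue, peptide red, cleavage green, amidation glycine pink) rendered
  as HTML, ANSI or a TSV class grid, with manual curation supported only as
  an explicit overlay file.
- **synthetic** — a seeded generator of precursors, transcripts, and
  clade-structured cross-species datasets with exact ground truth, used as
  the oracle for every pipeline stage.

## Worked example

Generate a precursor with three copies of the tetrapeptide pQGPRamide and
annotate it:

```sh
peptidemine simulate precursor --copies 3 --template QGPR --seed 4 --out demo
peptidemine annotate demo/protein.fasta --out demo_ann
cat demo_ann/peptides.tsv
```

```
precursor_id  start  end  sequence  amidated  pyroglutamated  c_terminal_fragment  notation
syn4          18     23   QGPR      1         1               0                    pQGPRamide
syn4          25     30   QGPR      1         1               0                    pQGPRamide
syn4          32     37   QGPR      1         1               0                    pQGPRamide
syn4          39     46   SDMTEFA   0         0               1                    SDMTEFA
```

The signal peptide occupies residues 0–17; each `QGPR` segment ended in a
glycine donor (removed from `sequence`, hence `amidated=1`) followed by a
dibasic `KR` site, and starts with Q (hence the `pQ…amide` notation). The
final row is the C-terminal fragment left after the last cleavage site; it
can never be amidated and is excluded from copy counts unless a predicate
asks for it. Counting with the library:

```python
from peptidemine import annotate_precursor, count_peptide_copies, read_fasta

record = read_fasta("demo/protein.fasta", "aa")[0]
annotation = annotate_precursor(record)
count_peptide_copies(annotation, "len=4 & pyroQ & amide")  # -> 3
```

The same chain runs from transcripts: `peptidemine mine queries.fasta
transcripts.fasta --preset crossspecies --out mined` performs the translated
search, extracts the ORF containing each hit, annotates it, and reports how
many candidates were rejected at each stage. `peptidemine simulate clade`,
`count`, `cluster` and `render` cover the cross-species copy-number analysis
and the similarity clustering / alignment-report stages.

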