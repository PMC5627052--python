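# Methods

## The annotation model

A precursor protein is modelled as

```
signal peptide | peptide (G?) | site | peptide (G?) | site | ... | tail
```

where each *site* is a maximal run of basic residues (K/R) and each *peptide*
is a segment between sites. Annotation is a deterministic partition of the
input string; its defining invariant is exact reconstruction — concatenating
the signal region, the segments (with amidation glycines restored) and the
site motifs in order reproduces the input. Every annotated sequence is checked
against this invariant in the test suite, and it is what makes the class grids
of the alignment renderer well defined.

### Signal peptide call

Signal peptides have a hydrophobic h-region ending a few residues before the
cleavage point, and small residues at positions −3 and −1 relative to
cleavage. The built-in score at a candidate cleavage position `p` (the index
of the first mature residue) is

```
score(p) = 0.7 · H(p) + 0.3 · S(p)
H(p) = mean Kyte–Doolittle hydropathy of residues [p−13, p−3),
       rescaled linearly from [−4.5, 4.5] to [0, 1]
S(p) = 1 if both p−3 and p−1 are small (A, G, S, C, T, V);
       0.5 if exactly one is; else 0
```

maximised over `p ∈ [15, 35]` (`min_signal_cleavage`/`max_signal_cleavage`,
both configurable; ties go to the earliest position; the window truncates at
the sequence start if a non-default configuration allows `p < 13`). The call
is positive when the best score reaches `signal_threshold`, default **0.34**
— a deliberately sensitive setting, appropriate when scanning noisy
transcriptome-derived ORFs where a missed signal peptide silently discards a
real precursor. The weights 0.7/0.3 express that the h-region is the
dominant physical signal and the (−3,−1) rule a tie-breaking refinement; the
heuristic is intentionally simple and monotone, not a trained model. Where a
licensed SignalP binary is available, its short-format output can be parsed
and used to override the built-in call per sequence; the rest of the pipeline
is unchanged.

Sequences with no accepted signal peptide are annotated anyway (sites scanned
from position 0) but flagged `partial`; downstream copy-number analysis
treats partial precursors as missing data, never as a count.

### Cleavage sites

Maximal K/R runs are single sites: monobasic (length 1), dibasic (2) or
polybasic (≥ 3). A multi-basic run is accepted iff any adjacent pair within
it belongs to the accepted dibasic motifs (default `{KR, RR, KK, RK}`).
Monobasic R is accepted by default, monobasic K is off by default (the
evidence for K-only processing is weak and accepting it inflates counts);
both are flags. Cleavage is C-terminal to the run and basic residues belong
to no peptide — this matches how annotated alignments colour cleavage sites
separately from mature peptides.

A monobasic site is rejected when either flanking residue is proline
(`monobasic_proline_guard`, default on). Prohormone convertases do not
process single basic residues in a Pro context, and the guard is what keeps
peptide-internal arginines — e.g. the R of pQGPRamide — out of the site
list while still allowing genuine single-R separators between peptide
copies. Without it, any peptide containing R would be split and no
multi-copy repertoire with R-containing peptides could be annotated
correctly.

### Mature peptides and modifications

Segments between the signal end, the sites and the sequence end become
mature-peptide candidates; empty segments (adjacent sites) are dropped. A
segment of length ≥ 2 whose last residue is G and which is immediately
followed by a site is **amidated**: the G is a donor consumed by peptidyl
glycine α-amidating monooxygenase, so it is removed from the reported
sequence. Any peptide starting with Q is flagged **pyroglutamated** — a
convention (cyclisation is assumed possible, not predicted), reflected in the
display notation `pQ…`. The final segment has no downstream site, is flagged
`c_terminal_fragment`, and can never be amidated. Length predicates count the
processed sequence, so a pQXXXamide peptide has length 4 including the pQ.

Acidic spacer segments are *retained* in the peptide list: there is no
principled sequence-only rule separating spacers from bioactive peptides, so
classification is delegated to the caller's predicate (`len=…`, `endswith=…`,
`amide`, …). The alignment renderer uses a display-only heuristic (acidic
fraction > `spacer_max_acid_fraction`, default 0.5) to grey spacers out.

## Search stage

The translated search is a contract-level, desk-scale replacement for a
seeded heuristic search: exact affine-gap Smith–Waterman (gap of length k
scores `gap_open + (k−1)·gap_extend`, defaults −11/−1) against all six frame
translations, with Karlin–Altschul expectation `E = K·m·n·exp(−λS)` using
conventional ungapped BLOSUM62 constants (λ = 0.3176, K = 0.134) and the
total translated database length as `n`. Two presets make the thresholds of
the two use cases first-class: `discovery` (E ≤ 1000) for trawling with
remote homologues and `crossspecies` (E ≤ 1e−6) for mining orthologues with
known queries. One best hit per query × transcript × frame is kept — enough
to anchor ORF extraction, which is the only thing hits are used for. No
attempt is made to reproduce any particular BLAST build's scores; an external
BLAST can be substituted through the `-outfmt 6` adapter.

The traceback is fully deterministic (best end cell earliest in row-major
order; diagonal > up > left on ties) so that identical inputs give
byte-identical outputs everywhere downstream.

ORFs are stop-to-stop stretches; no initiator methionine is required, because
transcriptome assemblies routinely truncate the 5′ end (a `require_met` flag
restores the stricter behaviour). The trailing stop codon is included in the
reported nucleotide interval but never in the protein.

## Copy-number evolution

Counts live in a species × family matrix with an explicit missing state
("NA" in TSV): a cell is missing when the precursor was absent or partial,
which is different from a genuine count of 0. Per-clade central values are
reported as mean, median and mode together; counts are small integers, so the
median uses the lower middle value for even n (integer-preserving) and the
mode the smallest value among ties. Outliers are deviations from the clade
*mode*, not mean ± sd — on near-constant integer data the interesting signal
is "one species at 16 in a clade of 19s", which the mode captures and a
standard-deviation rule does not.

`explain_copy_loss` maps the reference precursor's cleavage-site basic
positions and amidation donor glycines to alignment columns and reports, for
every other row, residues outside the allowed set ({K,R} or {G}); gaps are
reported with observed residue `-`. A separate summary distinguishes
*destroyed* sites (every basic substituted) from *weakened* ones (some basic
left) because a weakened dibasic site may still cleave under the monobasic
rule, which changes the biological conclusion.

## Similarity clustering

All-vs-all Smith–Waterman under BLOSUM45 (more tolerant of deep divergence),
with `p = min(1, E)` per pair. The embedding is a plain force model:
attraction `min(−log10 p, 20) · attract_weight` along edges passing the
p-value cutoff, repulsion `repulse_weight · Δx / max(‖Δx‖², 10⁻⁶)` over all
pairs, displacement damped (0.9) and clipped to `max_step` (0.1), all
coordinates seeded and updated synchronously, so the trajectory is
deterministic and translation-equivariant. The −log10 cap avoids the
singularity of identical pairs, and the distance floor the blow-up of
coincident points. Discrete cluster membership never comes from the
embedding: connected components at a p-value cutoff are computed by
union-find, with labels ordered by smallest member index. Defaults (cutoff
10⁻³, 1000 iterations) are declared configuration, not values inferred from
any external tool.

## The synthetic generator

The generator emulates the architecture the annotation model assumes —
signal peptide (`MKT` + a hydrophobic core + `ASA`), tandem template copies
with optional glycine donors, mono-/dibasic separators, optional acidic
spacers, a short C-terminal tail — plus transcripts (uniform synonymous
codons, random UTRs with an in-frame stop just upstream of the CDS so ORF
extraction is exact) and clade datasets with copy-number structure, planted
outliers and knockouts, and a by-construction alignment (missing copies are
all-gap unit slots, so no aligner is needed).

Its contract is that default-configuration annotation reproduces the
generated truth *exactly*, which requires two design constraints:

- The signal core is drawn from L/I only. These are strongly hydrophobic but
  outside the (−3,−1) small-residue set, which makes the designed boundary
  the unique argmax of the signal score; admitting A/V in the core can create
  score ties one or two positions away from the designed boundary.
- Functional residues — separators, donor glycines, a template's N-terminal
  Q and its last two residues (the motif family predicates key on) — are
  never touched by background mutation, and replacement residues exclude
  K, R, G and Q so mutations cannot create new sites, donors or pyroGlu
  calls. Only the knockout operations change functional residues, and they
  recompute the truth by construction.

Spec validation enforces the same logic (no adjacent basics in templates, no
basic touching a separator boundary, lone template R only in a proline
context, no proline next to a monobasic separator, boundary within the
signal-search window). Templates should be broadly hydrophilic, as secreted
peptides are; a template with a long uninterrupted hydrophobic stretch could
in principle out-score the designed signal peptide, and the truth-contract
tests would fail loudly.

What the generator does **not** emulate: expression levels, read errors,
fragmented or misassembled transcripts, heterogeneous codon usage, alignment
uncertainty (its alignments are exact by construction), or families whose
copies diverge beyond point substitutions. Passing tests therefore
demonstrate correctness of the annotation and counting rules on well-formed
precursors, not robustness to assembly artefacts — on real data, partial
sequences are expected and are handled by the explicit missing state, not by
the generator.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately desk-scale
problems chosen as representative rather than exhaustive: copy-number
recovery over N = 1…25 × three separator regimes × spacer on/off with
multiple seeds; alignment-score verification against an independent
exhaustive oracle on all 4-letter-alphabet pairs of length ≤ 3 plus seeded
samples up to length 6 (the oracle enumerates all increasing match subsets,
at most C(12,6) = 924 per pair, and is also cross-checked against
Bio.Align.PairwiseAligner on longer random pairs); clustering separation on
two 20-member families of 50-mers at 10% divergence; clade analyses on 12–18
species. All randomness is seeded; identical seeds give byte-identical
outputs, including the embedding coordinates.

Degenerate inputs are contracts, not crashes: sequences shorter than the
signal window annotate as partial; empty segments between adjacent sites are
dropped; a clade with no usable counts reports absent statistics rather than
zero; equal-score alignment and layout ties break deterministically as
documented above.

## Known limitations

- The signal heuristic is a two-term physical score, not a trained
  classifier; its absolute scores are not calibrated probabilities and only
  the 0.34 operating point is meaningful. Use the SignalP override for
  publication-grade calls.
- Cleavage calling is rule-based; it knows nothing about convertase
  specificity beyond basic-run structure and the proline guard, and it does
  not model the rare processing at non-basic sites.
- E-values use ungapped Karlin–Altschul constants with gapped alignments, so
  they are comparable within a run but not calibrated against BLAST.
- Disulfide connectivity (e.g. cysteine-knot or N-terminal bridges) is not
  modelled; cysteine counting is available through the `minres=C:n`
  predicate.
- The clustering embedding is for visual grouping; quantitative claims
  should rest on the component structure or the edge list.
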