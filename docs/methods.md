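# Methods

This note documents the models and procedures implemented in `ltrscout`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical and design decisions a maintainer would want
written down.

## The element model

An autonomous LTR retrotransposon is modeled as

```
[TSD] 5'LTR --- internal region (Gag-Pol) --- 3'LTR [TSD]
```

with the two LTRs near-identical direct repeats of 100–3,000 bp whose start
positions lie 1–15 kb apart, terminal 5′-TG…CA-3′ dinucleotides on each LTR,
an optional exact 4–6 bp target-site duplication on both flanks, and an
interior coding for the five Gag-Pol domains: GAG (capsid), AP (aspartic
proteinase), INT (integrase), RT (reverse transcriptase), RH (RNase H). An
element is called **intact** exactly when all five domain types are detected
in its interior; TSD and motif presence are annotation, never filters.

## Detection

**Seeding.** All maximal exact k-mer matches (default k = 20) between
positions i < j on the forward strand with j − i ∈ [1,000, 15,000] bp,
computed from a 2-bit integer encoding and a sort (k-mers containing N never
seed). LTRs of one element are direct repeats regardless of element strand,
so only direct matches are sought; element strand is assigned later from the
domain-hit frames. Exact seeds trade sensitivity to very old, highly
diverged pairs for speed and auditability; sensitivity at moderate
divergence comes from chaining and extension, and at the identity floor of
80 % with dispersed substitutions, clean 20-mers remain frequent.

**Chaining and extension.** Seeds within 50 bp on diagonals within ±30 are
chained; each chain is extended outward by banded (±30) affine-gap dynamic
programming (match +2, mismatch −3, gap open −5, gap extend −2) with an
X-drop of 20: extension stops once the best score in a row falls 20 below
the running maximum, and the boundary is the arg-max cell. The scheme
rewards high-identity repeats (expected score per column is negative below
~71 % identity) and drops off sharply in random flanks. The two repeat
copies are then re-aligned globally with the same scores; identity is
matching columns over all alignment columns (gap columns in the
denominator), and the candidate is kept only if identity > 0.80 strictly
and all length/separation constraints hold. Candidate score = identity ×
mean LTR length.

**Overlap resolution.** Greedy by descending score: a candidate survives if
its span overlaps no kept candidate's LTRs. A candidate strictly inside
another's internal region is therefore kept — nested insertions are real.
Ties break toward the smaller start coordinate, making the stage
deterministic.

**Boundary refinement.** X-drop arg-max boundaries can drift outward by a
few tens of bp when a chance gapped excursion in random flank scores
slightly positive. Refinement therefore first looks for a *jointly
anchored* boundary pair within ±45 bp (`boundary_window`): an element start
on TG, an element end on CA, and an exact 4–6 bp duplication flanking both
— the same boundary-adjustment idea used by the established LTR annotation
tools. The joint requirement has chance probability ~10⁻⁵ per position
pair, so it corrects overshoot far beyond what a plain motif scan could.
When no such pair exists (e.g. the element lost its TSD), the fallback is
the nearest TG within ±10 bp of the 5′ boundary and the nearest CA at the
3′ boundary (`motif_window`), shifting the homologous boundary of the other
LTR by the same offset; equidistant ties prefer the interior side, since
extension errs outward. Any shift that would violate a structural
invariant is reverted and the motif flag left false.

**TSD call.** After refinement, the L bp immediately upstream of the 5′ LTR
are compared with the L bp immediately downstream of the 3′ LTR for
L = 6, 5, 4 (longest first — the most informative exact match). Flanks with
N, or beyond the contig edge, never match.

## Domain annotation

The internal region `[ltr5_end, ltr3_start)` is translated in six frames
with the standard code; codons containing N give X, stop codons are kept as
`*` and score −4 against everything, so local alignments simply avoid them.
Every frame is locally aligned against every library peptide with
affine-gap Smith–Waterman. Defaults:

| parameter | default | rationale |
|---|---|---|
| matrix | BLOSUM80 | high-identity regime of retroelement domains; BLOSUM62 selectable |
| min_score | 80 | raw-score cutoff of the standard screen |
| gap open / extend | 22 / 2 | calibrated to the 1/3-bit-unit BLOSUM80 that Biopython distributes (A/A = 7, W/W = 16). BLAST-style 11/1 belongs to half-bit matrices; at this scale it lets ~30 % of *random* frame-vs-domain comparisons exceed 80, which would void the intactness filter. At 22/2 the measured random maximum over 2,000 comparisons is 76 while genuine domains score ~700+ |
| min_ref_coverage | 0.8 | accepted hits must align over ≥ 80 % of the library peptide — the alignment-length-proportion filter standard in REXdb-style domain annotation. Random near-threshold alignments span < 40 % of a domain |
| max_type_overlap | 10 aa | two accepted hits of one type may overlap by at most 30 nt |

Within one (peptide, frame) pair, local alignment is repeated with segment
splitting around each accepted hit, so tandem copies of a domain in the
same frame are all found (this is what detects multi-cassette elements).
Per domain type, hits are accepted greedily by descending score subject to
the overlap cap. Intactness: all five types present; multi-cassette: some
type with ≥ 2 accepted hits.

## Classification

Superfamily is decided by domain order alone, read 5′→3′ in element
orientation (score-weighted majority strand of the hits, midpoint
comparisons for robustness to slight overlap): INT before RT ⇒ Copia,
INT after RH ⇒ Gypsy. Multi-cassette elements, mixed-strand hit sets, and
orders matching neither pattern are *unclassified* (their lineage is
*unresolved*). Lineage is the arg-max of score-summed library lineage
labels among hits whose superfamily label agrees with the order-based call;
a tie falls to the single best hit, a residual tie to *unresolved*. When
the label vote contradicts the order, order wins — it is the primary
criterion — and the element carries a `conflict` flag preserving the
evidence. The lineage vocabulary is open: any label the library provides
is usable without code changes.

## Divergence and age

The 5′ and 3′ LTR sequences are aligned globally (match +2, mismatch −2,
gap open −10, gap extend −0.5, end gaps penalized; exact DP, deterministic
first-optimal traceback). Columns with a gap or an N are excluded
(pairwise deletion — the treatment is a package choice); among the rest,
A↔G and C↔T count as transitions (proportion P), all other mismatches as
transversions (Q). The Kimura two-parameter distance

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

is evaluated with `log1p` so nearly-identical pairs keep full precision.
Pairs outside the valid domain (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) are reported
as *saturated* and retained, keeping dataset accounting complete. Age
conversion T = d / (2r) is optional and rate-agnostic: no substitution rate
is hardcoded because none is universal; pass `--rate` (per site per year)
to get years/Mya.

## The simulator

`simulate` builds what the detector is specified to find: a random LTR
beginning TG and ending CA; an interior that reverse-translates labeled
library peptides (uniform random synonymous codons) joined by 30-bp random
linkers — long enough to keep neighboring hits apart given the 30-nt
overlap cap; a copy of the LTR mutated site-independently (transition with
probability P_target, else transversion with probability Q_target, mutually
exclusive draws), so realized counts are exactly binomial and recountable
from the emitted sequences; and the TSD duplicated on both flanks. Only the
3′ copy is mutated: the detector and the K2P estimator see pair divergence,
not per-branch history. The terminal TG/CA dinucleotides are exempt from
mutation so motif-built elements keep their motif; the bias on realized
P, Q is ≤ 4/L (0.2 % at L = 2,000), far below the binomial noise the tests
allow for. Indels are off by default so divergence recovery is exactly
binomial; an indel mode (geometric lengths, mean 3 bp) exists for detector
robustness experiments only, and realized P/Q bookkeeping ignores it.

Negatives probe false positives: solo LTRs (single copy with TSD),
truncated elements (1–3 domains deleted), and tandem decoys (80-bp repeats
500 bp apart — below both the length and separation floors). Features are
placed uniformly with ≥ 2 kb spacing on an i.i.d. background (42 % GC);
placement, mutation and assembly all derive from one seeded generator, so a
config + seed reproduces the genome and manifest byte for byte.

What the simulator deliberately does **not** emulate: real genomes' base
composition structure (no Markov background), nested insertion histories,
segmental duplications, soft-masked repeats, sequencing gaps, or domain
divergence from the library (interiors are exact reverse translations).
Passing tests therefore demonstrate the pipeline's logic — boundary
arithmetic, filtering, classification, estimation — under clean conditions,
not its sensitivity on diverged real repeats, where exact-seed detection
and the 0.8 reference-coverage cutoff will be the binding constraints.

### Standard benchmark

The validation roster used by the tests and `scripts/acceptance.py`: a 2 Mb
background carrying 50 intact elements (LTR length uniform in 300–1,500 bp,
transition target uniform in 0.004–0.032 with Q = P/2, giving pair
divergence ≤ 0.05; alternating canonical Copia/Gypsy cassettes; random
strand; random 4–6 bp TSD) plus 7 solo LTRs, 7 truncated elements and 6
tandem decoys. At these sizes a full scan takes well under a minute, so the
whole suite stays fast while every stage is exercised end to end.

## Numerical and interface choices

- Coordinates are 0-based half-open in memory, 1-based inclusive in every
  serialized output (GFF3 convention); the annotation-table `Start`/`End`
  are genomic, and `Length(bp)` is the full element span, constant across
  an element's rows. `Divergence` is raw K2P distance (substitutions/site)
  printed with 6 decimals; saturated elements print `NA`.
- GFF3 parents span all their children; because TSDs flank the element, a
  parent with TSD children is wider than the LTR-to-LTR span (LTR
  coordinates always come from the `long_terminal_repeat` children).
- The library header dialect is strict (`id|domain|superfamily|lineage`);
  a permissive parser for native REXdb headers is out of scope.
- Alignment kernels (protein local, LTR global, identity re-alignment) run
  on Biopython's PairwiseAligner; the test suite cross-checks them against
  independent plain-DP oracles. Tie-breaking among co-optimal alignments
  follows the aligner's first traceback, which is deterministic for fixed
  inputs — the property the pipeline actually needs (byte-identical reruns).
- All randomness flows through explicitly passed `numpy` generators; the
  scan path contains none at all.

## Known limitations

- Exact 20-mer seeding misses LTR pairs so diverged that no 20 bp survives
  unmutated between substitutions; at > 15–20 % divergence, recall decays.
- Domain calls require ≥ 80 % reference coverage, so heavily decayed or
  frameshifted interiors annotate as non-intact (by design — the target is
  the intact complement).
- Solo-LTR and truncated-element *calling* is out of scope; they are
  simulated only as negative controls.
- `Start`/`End` in the annotation table are genomic coordinates; if a
  consumer expects element-relative positions they must subtract the
  element start.
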