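# Methods

This note documents the models, rules and numerical conventions the
package implements, the choices made where several designs were
defensible, and what the synthetic test data can and cannot show.

## Reference-anchored segmentation

Bacterial cytochrome P450s share a conserved fold, so functional
regions occupy approximately fixed positions along the chain. A query
is cut into five regions by mapping fixed cut positions (defaults
92/192/275/395, from a reference P450 with annotated functional
regions) through a **global pairwise alignment** of query and reference
(BLOSUM62, gap open 10, gap extend 1). A pairwise alignment per query
is used instead of one multiple alignment of the whole dataset: the
boundary-mapping semantics are the same, results are independent of
dataset composition and order, and each query is testable in isolation.

When a reference cut falls in a query gap (a deletion in the query),
the boundary anchors at the nearest *aligned* query position to the
left. Left-anchoring is a convention, not a biological claim; it
guarantees the five segments are contiguous and concatenate exactly to
the input sequence, which the test suite asserts as an invariant.
Queries shorter than 50 aa are rejected as unalignable.

## Reduced alphabet

Sequences are recoded into six physico-chemical groups before k-mer
counting: aliphatic {A,V,L,I,M}, aromatic {F,W,Y}, positively charged
{K,R,H}, negatively charged {D,E}, polar {S,T,N,Q,C}, and
conformationally special {G,P}. Grouping by chemistry rather than
identity shrinks the 4-mer space from 20⁴ to 6⁴ and lets features
generalise across family members instead of memorising exact residues
(an overfitting control). The mapping is a default, not a constant:
`ReducedAlphabet` accepts any total mapping, so an alternative grouping
can be dropped in without code changes. The wildcard `X` maps to a
dedicated symbol that occurs in no feature k-mer, so ambiguous residues
can never contribute to a count.

## Dereplication

Training sets are reduced with greedy longest-first clustering: a
sequence joins the first cluster whose representative it matches at
≥ 95% identity, where identity = matches / length of the shorter
sequence under the global alignment above (the convention of
CD-HIT-style tools). The word size (default 5) is only a candidate
prefilter — pairs sharing no common 5-mer are skipped, which cannot
change membership because such pairs cannot reach 95% identity.
Idempotence and coverage (every input within threshold of some
representative) are property-tested against an all-pairs oracle.

## Classifier

The feature space is defined by the positive class only: a reduced
4-mer is a feature of a region iff it occurs in ≥ ceil(n/2) positive
training sequences in that region (presence per sequence, occurrences
within one sequence counted once). Features are ordered
lexicographically within regions for deterministic serialization. Any
P450 is then vectorized as overlapping occurrence counts.

Classes are balanced by seeded random oversampling of the minority
class (every original sample kept, the deficit drawn with replacement),
then split 60:40 into training and internal validation. The split is
stratified — at the small positive-class sizes typical for this
problem an unstratified split can lose a class entirely. The Random
Forest uses 100 trees (a conventional default; scores at a 0.15
threshold are granular enough at 100 trees), maximum depth 10 for the
first training round and 14 for the refinement round, and minimum one
sample per leaf. A query's score is the fraction of trees voting
positive — the only score definition under which a 0.15 cutoff on a
forest is meaningful — and the positive call is strict (score must
*exceed* 0.15). The low threshold trades precision for recall
deliberately: stage 2 validates every hit by requiring a rule-passing
precursor ORF, so false positives are cheap, while a missed P450 is
unrecoverable.

Validation metrics are computed on the held-out 40%: recall,
specificity, precision, positive-class F1, and balanced accuracy
= (recall + specificity)/2. Model persistence is by re-derivation: the
feature space JSON plus training data and seed reproduce the forest
exactly, so no binary model artifact is needed.

The refinement round (`P450ClassifierModel.refine`) merges newly
accepted positives into the training set (dereplicating the union),
rebuilds the feature space from the enlarged positive class, and
retrains at depth 14.

## Precursor ORF discovery

The neighborhood is the anchor gene's span extended 3000 nt on each
side (measured from the gene boundaries, not its midpoint) and
truncated at record edges. All six frames are scanned; an ORF is a
start codon (ATG/GTG/TTG — the common bacterial set; configurable)
followed by its nearest in-frame stop under translation table 11, both
fully inside the window, translating to 10–40 residues. The initiator
is translated literally (GTG→V, TTG→L) rather than forced to Met; the
selection rules read internal and C-terminal residues, so this choice
is low-impact, and a flag forces Met for users who prefer CDS
convention.

Selection rules:

* **aromatic-core** (first round): the C-terminal six residues must
  contain two consecutive residues from {F, W, Y}. Histidine is
  excluded from the aromatic set — characterized family cores anchor
  their crosslinks on W/Y/F, and His-based bridges belong to a related
  but distinct family. The window is the C-terminal six residues even
  for longer cores; longer (hepta/octapeptide) cores are reachable via
  the motif rule, which scans the whole precursor.
* **leader-motif** (second round): the precursor must contain one of
  KSLK, RSLK, ESLK, KSRK, KPLK, PSLK; the leftmost occurrence is
  reported. The motif's expected position (residues 17–20) is
  informational and deliberately not enforced.

ORFs sharing ≥1 nt with an annotated CDS on either strand are
discarded, except CDSs whose product/note contains "tryptorubin family
RiPP precursor" (case-insensitive) — those are the genes being looked
for. Among ORFs with the same strand and stop codon (alternative
starts of one gene), the shortest rule-satisfying variant is kept and
the longer variants' start coordinates are recorded as metadata, since
the true start cannot be resolved when several start codons are in
frame.

Coordinates are 0-based half-open internally and 1-based inclusive in
GenBank output; region files re-base the window to start at 1 and
carry over clipped original annotations. A GC-content utility
((G+C)/(A+C+G+T) with ambiguous bases excluded, plus a signed delta
against a genome mean) supports screening clusters for horizontal
transfer signatures.

## Mass prediction

Peptide formulas are residue-composition sums plus one water; each
oxidative crosslink (biaryl C–C, C–N or aryl-ether C–O) subtracts H₂
regardless of bond type, matching the proton-loss reasoning used to
interpret HR-MS of modified cores. [M+H]⁺ is the neutral monoisotopic
mass plus the proton mass, i.e. **with** electron-mass correction —
the convention that reproduces the calcd values printed for the
characterized compounds to four decimals. (Literature values computed
without the correction differ by ~0.0005; both conventions circulate,
which is why the correction is stated explicitly here.) Candidate
grids enumerate N-terminal truncations × crosslink counts, reflecting
the common exoproteolytic trimming of mature cores; per-modification
mass deltas other than −2 H can be supplied for future chemistry.
Output precision is four decimals; ppm error is signed,
(obs − calc)/calc × 10⁶.

## Synthetic data generators

`generate_family` emulates the training situation: a positive family
sharing region-localized reduced-alphabet 4-mer signatures, against a
background family. Defaults: 40 positives vs 40 negatives, 400-aa
backbones (inside the 300–450 aa classification window), two 4-mer
signatures planted in the substrate-binding-1 and core regions, and 5%
per-site substitution noise for within-family diversity. Signatures
are planted after mutation, so every positive carries them; negatives
are generated on an independent backbone (distinct protein families,
as in the real task of separating atropopeptide P450s from unrelated
P450s) and scrubbed of chance signature occurrences anywhere in the
sequence. What this does **not** emulate: real P450 homology
structure, phylogenetic correlation between and within classes, or the
heavy class imbalance of a genuine negative set — so a perfect F1 on
fixtures demonstrates the pipeline's correctness on separable data,
not expected performance on real proteins.

`generate_neighborhood` emits a nucleotide record (default 60% GC,
actinobacteria-like) containing an annotated anchor P450 CDS, one
unannotated truth precursor (leader with a KSLK-family motif at
residues 17–20, six-residue core), and five decoys each violating
exactly one rule: too short (9 aa), too long (41 aa), no motif, no
aromatic core pair, and CDS-overlapping. Planted peptides are
reverse-translated with a fixed codon per amino acid (the
lexicographically first table-11 codon), so output is deterministic
and only Met encodes a start codon — planted peptides therefore avoid
internal Met to preclude nested in-frame starts. Because random DNA
contains short ORFs that can pass the rules by chance, the generator
scans its own background and knocks out every unplanned rule-passing
ORF by single-base edits (start-codon break, premature stop, or
stop-codon break); edits in overlapping frames can interact, so the
scrubber walks through alternative edits per ORF until the
neighborhood is clean. Planted elements keep a 30-nt margin from each
other so a bridging ORF always leaves an editable codon. Both
generators are pure functions of their spec: identical seeds give
byte-identical output.

## Problem sizes and tolerances in the test suite

The suite verifies ORF scanning against a brute-force six-frame oracle
on 500 random sequences up to 5 kb, vectorization against a
sliding-window oracle on 1000 random strings, the feature quorum rule
exhaustively on ≤10-sequence sets, dereplication against an all-pairs
oracle at n ≤ 30, and precursor recovery (precision = recall = 1) on
50 random neighborhood specs; the classifier reaches F1 = 1.0 on the
default family across 5 seeds and chance-level balanced accuracy
(0.35–0.65) on label-shuffled data across 10 seeds. Printed mass
values are asserted to ±0.0002 and ppm errors to ±0.01. Mass
constants are CODATA/AME monoisotopic values; the mass module is
cross-checked against an independent proteomics library to 1e-4.

## Known limitations

* The reduced alphabet is a defensible physico-chemical default, not a
  uniquely determined grouping; results depend on it, which is why it
  is injectable.
* Segment boundaries inherit any pathology of the pairwise alignment;
  for highly divergent queries the mapped regions may drift from the
  structural regions.
* The precursor finder enumerates ORFs only; it performs no coding
  potential or conservation scoring, by design.
* Crosslink mass deltas assume purely oxidative (−2 H) chemistry;
  modifications that are mass-neutral or add atoms need explicit
  per-modification deltas.
* The pipeline operates on local files only; retrieving records from
  NCBI is the user's responsibility.
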