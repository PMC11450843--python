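# atropomine

Genome mining for **atropopeptide** biosynthetic gene clusters (BGCs).

Atropopeptides are ribosomally synthesized and posttranslationally
modified peptides (RiPPs) whose mature products — rigid, often
atropisomeric mono- to tetracyclic peptides such as tryptorubin A — are
produced from a short ribosomal precursor by a single family-defining
cytochrome P450 that installs biaryl (C–C), carbon–nitrogen and
aryl-ether crosslinks between side chains. Their BGCs are tiny (a
precursor gene of 10–40 codons plus a P450 gene) and the precursor genes
are almost never annotated, so conventional BGC detectors miss them.
`atropomine` is aimed at natural-product genome miners who want to find
these clusters in local sequence data and screen culture extracts for
the corresponding metabolites.

## Method

The pipeline inverts the usual RiPP-mining order: it first recognises
the *tailoring enzyme* with a classifier, then confirms the BGC by
finding the precursor gene with deterministic rules.

**Stage 1 — P450 classification.** Each candidate P450 (300–450 aa) is
globally aligned to an annotated reference P450 and cut at reference
positions 92/192/275/395 into five functional regions (N-terminus, two
substrate-binding regions, core, C-terminus). Sequences are recoded
into a six-group physico-chemical alphabet (aliphatic / aromatic /
positive / negative / polar / conformational) and each region is
described by counts of overlapping 4-mers; a 4-mer is a feature iff it
occurs in ≥ half of the positive training sequences in that region.
Training sets are dereplicated at 95% identity (greedy, CD-HIT-style);
classes are balanced by random oversampling; a Random Forest
(100 trees, depth 10 in round 1 / 14 in round 2, min 1 sample per leaf)
is trained on a stratified 60:40 split. A query's score is the fraction
of trees voting positive, and a hit requires score > 0.15 — a
deliberately permissive threshold, since stage 2 discards false
positives cheaply.

**Stage 2 — precursor ORF discovery.** In the ±3 kb neighborhood of
each positive P450 gene, all six reading frames are scanned for ORFs of
10–40 codons (starts ATG/GTG/TTG, translation table 11). Candidates
must either contain two consecutive aromatic residues (F/W/Y) in the
six C-terminal residues — the core peptide anchoring the crosslinks —
(round 1), or carry one of the leader motifs KSLK / RSLK / ESLK / KSRK
/ KPLK / PSLK (round 2). ORFs overlapping annotated CDS features are
dropped (except features already labeled as tryptorubin-family
precursors), and nested ORFs sharing a stop codon are collapsed to the
shortest rule-satisfying variant.

**Mass screening.** For a predicted core peptide, each oxidative
crosslink removes 2 H from the elemental formula. The package computes
electron-mass-corrected monoisotopic [M+H]⁺ values over a grid of
N-terminal truncations × crosslink counts and matches observed HR-MS
features in ppm:

m([M+H]⁺) = Σᵢ nᵢ·mᵢ − 2·n_xlink·m(H) + m(H⁺)

## Worked example

Generate a synthetic workspace (a planted-signature P450 family and a
GenBank neighborhood with an embedded precursor), train, and mine:

```
$ atropomine simulate --out-dir fixtures --seed 7
$ atropomine train --reference fixtures/reference.fasta \
      --positives fixtures/positives.fasta \
      --negatives fixtures/negatives.fasta --out-dir model --seed 1
Atropopeptide P450 classifier — held-out validation
=====================================================
trees: 100   max depth: 10   min samples/leaf: 1
features: 368 reduced-alphabet 4-mers over 5 functional regions (from 40 positives)
score threshold: > 0.15
-----------------------------------------------------
TP    16   FP     0   TN    16   FN     0
recall              1.0000
specificity         1.0000
precision           1.0000
f1 (positive)       1.0000
balanced accuracy   1.0000
```

The held-out confusion counts (16 + 16 sequences of the 40:40 balanced
set) are perfect because the generated positives carry separable
region-localized 4-mer signatures. Precursor search around the
annotated P450 in the simulated record recovers the planted precursor
— leader, KSLK-family motif and six-residue core — exactly:

```
$ atropomine corefind --genbank fixtures/neighborhood_000.gbk \
      --anchor SYNP450_000007.1 --out region.gbk --rule-mode both
SYNTH_000007  7058  7138  -  MSDTELINAFREKVSAPSLK  SWYQWL  PSLK  both
```

Mass screening of that core against two observed ions:

```
$ printf 'core\tmax_crosslinks\tallow_n_truncations\nSWYQWL\t2\t1\n' > cores.tsv
$ atropomine masses --cores cores.tsv --observed 793.3655 --observed 791.3540
core    peptide  truncation  n_crosslinks  formula     mz_calc   mz_obs    ppm
SWYQWL  WYQWL    1           2             C42H46N8O8  791.3511  791.354   3.66
SWYQWL  WYQWL    1           1             C42H48N8O8  793.3668  793.3655  -1.64
SWYQWL  WYQWL    1           0             C42H50N8O8  795.3824
SWYQWL  SWYQWL   0           2             C45H51N9O10 878.3832
SWYQWL  SWYQWL   0           1             C45H53N9O10 880.3988
SWYQWL  SWYQWL   0           0             C45H55N9O10 882.4145
```

Reading the table: the observed *m/z* 791.3540 matches the pentapeptide
WYQWL (serine removed by host peptidases) carrying **two** crosslinks
(−4 H, calcd 791.3511), and 793.3655 matches the singly crosslinked
variant (−2 H, calcd 793.3668) — i.e. one BGC, two products differing
in modification count.

The same functionality is available as a library; the classifier
follows a model/results idiom:

```python
from atropomine import P450ClassifierModel, ClassifierConfig
model = P450ClassifierModel.from_sequences(positives, negatives, scheme)
results = model.fit(ClassifierConfig(seed=1))
print(results.summary())
labels, scores = results.classify_proteins(queries, scheme)
```

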