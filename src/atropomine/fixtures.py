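"""Seeded generators of synthetic test data with known embedded truth.

Two generators stand in for the data the mining pipeline consumes in
production (curated P450 training sets and NCBI nucleotide records):

* :func:`generate_family` emits a positive protein family carrying
  planted, segment-localized reduced-alphabet 4-mer signatures on a
  shared backbone, against a background family built on an independent
  backbone and scrubbed of the signatures — emulating atropopeptide
  P450s amid unrelated P450s.
* :func:`generate_neighborhood` emits a GenBank-style nucleotide record
  embedding an annotated anchor P450 gene and an unannotated precursor
  ORF with a configurable leader motif and core, plus decoy ORFs each
  violating exactly one selection rule. The generator verifies that no
  unplanned ORF in the neighborhood passes the selection rules, editing
  the random background until the planted truth is the only candidate.

Both generators are deterministic functions of their spec (seed
included): identical specs yield byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from atropomine.neighborhood import (
    CdsAnnotation,
    DEFAULT_MOTIFS,
    GenomicNeighborhood,
    MotifSet,
    OrfCandidate,
    apply_core_rule,
    apply_motif_rule,
    extract_neighborhood,
    filter_cds_overlap,
    scan_orfs,
)
from atropomine.seqprep import (
    AMINO_ACIDS,
    DEFAULT_ALPHABET,
    ProteinSeq,
    ReducedAlphabet,
    ReferenceScheme,
)

# ---------------------------------------------------------------------------
# protein family generator

#: One representative residue per reduced-alphabet group symbol, used to
#: spell a reduced k-mer signature as concrete amino acids.
GROUP_REPRESENTATIVE = {
    "a": "A",  # aliphatic
    "r": "F",  # aromatic
    "p": "K",  # positively charged
    "n": "D",  # negatively charged
    "h": "S",  # polar
    "c": "G",  # conformationally special
}


@dataclass(frozen=True)
class FamilySpec:
    """Conditions for a planted-signature protein family.

    The defaults emulate a desk-scale version of the mining study's
    training sets: 40 positives vs 40 negatives, backbone length within
    the 300-450 aa window of full-length bacterial P450s, two 4-mer
    signatures localized to the substrate-binding and core regions, and
    5% per-site substitution noise for within-family diversity.
    """

    n_positive: int = 40
    n_negative: int = 40
    seed: int = 0
    backbone_length: int = 400
    signature: tuple[tuple[int, str], ...] = ((1, "rphr"), (3, "anra"))
    mutation_rate: float = 0.05
    cut_positions: tuple[int, int, int, int] = (92, 192, 275, 395)

    def __post_init__(self) -> None:
        if self.n_positive < 2 or self.n_negative < 1:
            raise ValueError("need >= 2 positives and >= 1 negative")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        for seg_idx, kmer in self.signature:
            if not 0 <= seg_idx <= 4:
                raise ValueError(f"segment index {seg_idx} out of range")
            if any(sym not in GROUP_REPRESENTATIVE for sym in kmer):
                raise ValueError(f"signature {kmer!r} has unknown symbols")


@dataclass(frozen=True)
class FamilyFixture:
    positives: tuple[ProteinSeq, ...]
    negatives: tuple[ProteinSeq, ...]
    scheme: ReferenceScheme
    alphabet: ReducedAlphabet


def _segment_bounds(cuts: Sequence[int], length: int) -> list[tuple[int, int]]:
    edges = [0, *cuts, length]
    return [(edges[i], edges[i + 1]) for i in range(5)]


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)]


def _mutate(
    rng: np.random.Generator, residues: list[str], rate: float
) -> list[str]:
    out = list(residues)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    return out


def _signature_residues(kmer: str) -> str:
    return "".join(GROUP_REPRESENTATIVE[sym] for sym in kmer)


def _scrub_signatures(
    rng: np.random.Generator,
    residues: list[str],
    spec: FamilySpec,
    alphabet: ReducedAlphabet,
) -> list[str]:
    """Destroy chance occurrences of any signature anywhere in the
    sequence (segment boundaries of negatives are alignment-dependent,
    so scrubbing is sequence-wide to be safe)."""
    from atropomine.seqprep import reduce_sequence

    changed = True
    while changed:
        changed = False
        for _seg_idx, kmer in spec.signature:
            reduced = reduce_sequence("".join(residues), alphabet)
            idx = reduced.find(kmer)
            if idx >= 0:
                # replace one residue with one from a different group
                pos = idx + int(rng.integers(0, len(kmer)))
                current_group = alphabet.mapping[residues[pos]]
                choices = [
                    aa for aa in AMINO_ACIDS
                    if alphabet.mapping[aa] != current_group
                ]
                residues[pos] = choices[int(rng.integers(0, len(choices)))]
                changed = True
    return residues


def generate_family(
    spec: FamilySpec, alphabet: ReducedAlphabet = DEFAULT_ALPHABET
) -> FamilyFixture:
    """Labeled positive/negative families with planted k-mer signatures.

    Every positive carries every signature in its designated segment
    (planted after mutation, so presence is guaranteed regardless of the
    mutation rate); negatives are generated on an independent backbone
    and scrubbed of chance signature occurrences.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.backbone_length <= spec.cut_positions[-1]:
        raise ValueError("backbone must extend past the last cut position")
    bounds = _segment_bounds(spec.cut_positions, spec.backbone_length)
    for seg_idx, kmer in spec.signature:
        lo, hi = bounds[seg_idx]
        if hi - lo < len(kmer):
            raise ValueError(
                f"segment {seg_idx} too short to plant {kmer!r}"
            )

    pos_backbone = _random_protein(rng, spec.backbone_length)
    neg_backbone = _random_protein(rng, spec.backbone_length)

    positives = []
    for i in range(spec.n_positive):
        residues = _mutate(rng, pos_backbone, spec.mutation_rate)
        for seg_idx, kmer in spec.signature:
            lo, hi = bounds[seg_idx]
            at = lo + int(rng.integers(0, hi - lo - len(kmer) + 1))
            planted = _signature_residues(kmer)
            residues[at:at + len(planted)] = list(planted)
        positives.append(ProteinSeq(f"pos_{i:03d}", "".join(residues)))

    negatives = []
    for i in range(spec.n_negative):
        residues = _mutate(rng, neg_backbone, spec.mutation_rate)
        residues = _scrub_signatures(rng, residues, spec, alphabet)
        negatives.append(ProteinSeq(f"neg_{i:03d}", "".join(residues)))

    scheme = ReferenceScheme(
        reference=ProteinSeq("backbone", "".join(pos_backbone)),
        cut_positions=spec.cut_positions,
    )
    return FamilyFixture(
        positives=tuple(positives),
        negatives=tuple(negatives),
        scheme=scheme,
        alphabet=alphabet,
    )


# ---------------------------------------------------------------------------
# genomic neighborhood generator

#: Fixed codon per amino acid: the lexicographically first table-11 codon.
#: Only methionine encodes as a start codon (ATG), so planted peptides
#: without internal Met cannot spawn nested in-frame start variants.
CODON_OF = {
    "A": "GCA", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAA", "E": "GAA", "G": "GGA", "H": "CAC", "I": "ATA",
    "L": "CTA", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "AGC", "T": "ACA", "W": "TGG", "Y": "TAC", "V": "GTA",
}
STOP_FOR_PLANT = "TAA"

DEFAULT_LEADER_PREFIX = "MSDTELINAFREKVSA"  # 16 aa, no internal Met
DEFAULT_CORE = "SWYQWL"

#: Decoy peptides, each violating exactly one selection rule when the
#: other planted features are intact.
DECOY_TOO_SHORT = "MKSLKASWWY"[:9]  # 9 aa: below the 10 aa bound
DECOY_TOO_LONG = (
    "MSDTELINAFREKVSA" + "KSLK" + "GAEDTSALNEGADST" + "SWYQWL"
)  # 41 aa: above the 40 aa bound
DECOY_NO_MOTIF = "MSDTELINAFREGVSAGTLE" + "SWYQWL"  # aromatic core, no motif
DECOY_NO_AROMATIC = "MSDTELINAFREKVSA" + "KSLK" + "ASGIGL"  # motif, dull core


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Conditions for a synthetic P450 neighborhood.

    The anchor P450 gene is annotated as a CDS; the truth precursor is
    planted as plain (unannotated) sequence at ``truth_offset`` nt from
    the anchor boundary (positive: downstream of the anchor end;
    negative: upstream of the anchor start). Background composition
    defaults to 60% GC, actinobacteria-like.
    """

    seed: int = 0
    record_length: int = 12000
    anchor_start: int = 5400
    anchor_length: int = 1200
    anchor_strand: int = 1
    leader_prefix: str = DEFAULT_LEADER_PREFIX
    motif: str = "KSLK"
    core: str = DEFAULT_CORE
    truth_strand: int = 1
    truth_offset: int = 500
    decoys: tuple[str, ...] = (
        "too_short", "too_long", "no_motif", "no_aromatic", "cds_overlap",
    )
    gc_fraction: float = 0.60

    def __post_init__(self) -> None:
        if "M" in self.precursor[1:]:
            raise ValueError(
                "internal Met would plant a nested in-frame start codon"
            )
        if len(self.precursor) < 10 or len(self.precursor) > 40:
            raise ValueError("truth precursor must be 10-40 aa")
        if self.truth_strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        if abs(self.truth_offset) + len(self.precursor) * 3 + 3 > 3000:
            raise ValueError("truth precursor outside the 3 kb flank")

    @property
    def precursor(self) -> str:
        return self.leader_prefix + self.motif + self.core

    @classmethod
    def random(cls, seed: int) -> "NeighborhoodSpec":
        """A randomized spec: placement, strands, motif and core vary."""
        rng = np.random.default_rng(seed)
        cores = ("SWYQWL", "AWGWYE", "TDAWFS", "SWYIWY", "NWAFYG")
        motifs = DEFAULT_MOTIFS.motifs
        record_length = int(rng.integers(9000, 15000))
        anchor_length = int(rng.integers(900, 1400)) // 3 * 3
        anchor_start = int(
            rng.integers(3200, record_length - anchor_length - 3200)
        )
        offset_side = 1 if rng.random() < 0.5 else -1
        return cls(
            seed=seed,
            record_length=record_length,
            anchor_start=anchor_start,
            anchor_length=anchor_length,
            anchor_strand=1 if rng.random() < 0.5 else -1,
            motif=str(motifs[rng.integers(0, len(motifs))]),
            core=str(cores[rng.integers(0, len(cores))]),
            truth_strand=1 if rng.random() < 0.5 else -1,
            truth_offset=offset_side * int(rng.integers(200, 2500)),
        )


@dataclass(frozen=True)
class PlantedOrf:
    """Ground truth for one planted element (record coordinates)."""

    kind: str  # "truth" or a decoy name
    start: int
    end: int
    strand: int
    aa_seq: str


@dataclass(frozen=True)
class NeighborhoodFixture:
    record: SeqRecord
    anchor: CdsAnnotation
    truth: PlantedOrf
    decoys: tuple[PlantedOrf, ...]

    @property
    def neighborhood(self) -> GenomicNeighborhood:
        return extract_neighborhood(self.record, self.anchor)


def _encode_orf(peptide: str) -> str:
    return "".join(CODON_OF[aa] for aa in peptide) + STOP_FOR_PLANT


def _random_background(
    rng: np.random.Generator, length: int, gc: float
) -> list[str]:
    bases = []
    for _ in range(length):
        if rng.random() < gc:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "T")
    return bases


def _passes_any_rule(orf: OrfCandidate, motifs: MotifSet) -> bool:
    return apply_core_rule(orf) or apply_motif_rule(orf, motifs) is not None


def generate_neighborhood(
    spec: NeighborhoodSpec, motifs: MotifSet = DEFAULT_MOTIFS
) -> NeighborhoodFixture:
    """Build a record whose only rule-passing candidate is the truth ORF.

    Decoys are planted so that each violates exactly one rule; the
    random background is then edited (start/stop codon knockouts) until
    no unplanned ORF in the anchor neighborhood passes either the
    aromatic-core or the leader-motif rule.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_background(rng, spec.record_length, spec.gc_fraction)

    anchor = CdsAnnotation(
        start=spec.anchor_start,
        end=spec.anchor_start + spec.anchor_length,
        strand=spec.anchor_strand,
        label="cytochrome P450 monooxygenase",
    )

    protected: list[tuple[int, int]] = [(anchor.start, anchor.end)]

    # keep planted elements apart so an ORF bridging one element into
    # background always leaves an editable in-frame codon for scrubbing
    margin = 30

    def collides(start: int, nt_len: int) -> bool:
        return any(
            start < hi + margin and lo - margin < start + nt_len
            for lo, hi in protected
        )

    def place(nt_len: int, offset: int | None) -> int:
        """Record start coordinate for a planted element."""
        if offset is not None:
            start = (
                anchor.end + offset
                if offset >= 0
                else anchor.start + offset - nt_len
            )
            if start < 0 or start + nt_len > spec.record_length:
                raise ValueError("planted element outside the record")
            if collides(start, nt_len):
                raise ValueError("planted elements collide")
            return start
        for _ in range(200):  # decoys: rng placement with rejection
            side = 1 if rng.random() < 0.5 else -1
            off = int(rng.integers(100, 2600))
            start = anchor.end + off if side > 0 else anchor.start - off - nt_len
            if start < 0 or start + nt_len > spec.record_length:
                continue
            if collides(start, nt_len):
                continue
            return start
        raise ValueError("could not place a decoy without collision")

    def plant(peptide: str, strand: int, start: int) -> tuple[int, int]:
        nt = _encode_orf(peptide)
        if strand == -1:
            nt = str(Seq(nt).reverse_complement())
        seq[start:start + len(nt)] = list(nt)
        span = (start, start + len(nt))
        protected.append(span)
        return span

    truth_pep = spec.precursor
    truth_nt_len = 3 * len(truth_pep) + 3
    t0 = place(truth_nt_len, spec.truth_offset)
    t_span = plant(truth_pep, spec.truth_strand, t0)
    truth = PlantedOrf(
        kind="truth",
        start=t_span[0],
        end=t_span[1],
        strand=spec.truth_strand,
        aa_seq=truth_pep,
    )

    decoy_peptides = {
        "too_short": DECOY_TOO_SHORT,
        "too_long": DECOY_TOO_LONG,
        "no_motif": DECOY_NO_MOTIF,
        "no_aromatic": DECOY_NO_AROMATIC,
    }
    decoys: list[PlantedOrf] = []
    # the CDS-straddling decoy has a fixed slot; plant it first so the
    # rng-placed decoys reject collisions against it
    ordered_decoys = sorted(spec.decoys, key=lambda k: k != "cds_overlap")
    for kind in ordered_decoys:
        if kind == "cds_overlap":
            # a valid precursor ORF straddling the anchor CDS boundary
            pep = spec.leader_prefix + spec.motif + spec.core
            nt_len = 3 * len(pep) + 3
            start = anchor.end - 30
            if any(
                start < hi + margin and lo - margin < start + nt_len
                for lo, hi in protected[1:]  # anchor overlap is the point
            ):
                raise ValueError("cds_overlap decoy collides with the truth")
            nt = _encode_orf(pep)
            seq[start:start + nt_len] = list(nt)
            protected.append((start, start + nt_len))
            decoys.append(
                PlantedOrf(kind, start, start + nt_len, 1, pep)
            )
            continue
        pep = decoy_peptides[kind]
        strand = 1 if rng.random() < 0.5 else -1
        nt_len = 3 * len(pep) + 3
        start = place(nt_len, None)
        span = plant(pep, strand, start)
        decoys.append(PlantedOrf(kind, span[0], span[1], strand, pep))

    # ORFs exempt from scrubbing: every planted element by exact span,
    # plus longer in-frame variants of the truth (same stop codon) which
    # deduplication collapses onto the truth as alternative starts.
    planted_spans = {
        (p.start, p.end, p.strand) for p in (truth, *decoys)
    }
    truth_stop_key = (
        truth.strand, truth.end if truth.strand == 1 else truth.start
    )

    def build_record() -> SeqRecord:
        record = SeqRecord(
            Seq("".join(seq)),
            id=f"SYNTH_{spec.seed:06d}",
            name=f"SYNTH{spec.seed:06d}",
            description="synthetic atropopeptide neighborhood fixture",
            annotations={"molecule_type": "DNA"},
        )
        record.features.append(
            SeqFeature(
                FeatureLocation(anchor.start, anchor.end, strand=anchor.strand),
                type="CDS",
                qualifiers={
                    "product": [anchor.label],
                    "protein_id": [f"SYNP450_{spec.seed:06d}.1"],
                },
            )
        )
        return record

    def is_protected(pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in protected)

    def _edit_options(orf: OrfCandidate) -> list[tuple[int, str] | tuple[int, str, str]]:
        """Ordered single edits that each kill the ORF.

        An edit may interact with overlapping reading frames (killing
        one ORF can enable another on the opposite strand), so callers
        walk this list across scrub rounds rather than always retrying
        the first entry.
        """
        options: list = []
        if orf.strand == 1:
            stop_first = orf.end - 3
            # 'C' at any start-codon position breaks ATG/GTG/TTG
            for p in (orf.start, orf.start + 1, orf.start + 2):
                if not is_protected(p):
                    options.append((p, "C"))
        else:
            stop_first = orf.start + 2
            # complement logic: 'G' at any position of the record
            # triplet breaks the minus-strand start codon
            for p in (orf.end - 1, orf.end - 2, orf.end - 3):
                if not is_protected(p):
                    options.append((p, "G"))
        # premature in-frame stop codons, nearest the start first
        n_codons = (orf.end - orf.start) // 3
        for k in range(1, n_codons - 1):
            if orf.strand == 1:
                p = orf.start + 3 * k
                codon = "TAA"
            else:
                p = orf.end - 3 * (k + 1)
                codon = "TTA"  # revcomp of TAA
            if all(not is_protected(p + j) for j in range(3)):
                options.append((p, codon, "codon"))
        # last resort: knock out the stop codon (extends the ORF)
        if not is_protected(stop_first):
            options.append((stop_first, "C" if orf.strand == 1 else "G"))
        return options

    # background scrub: knock out unplanned rule-passing ORFs; edits can
    # interact across frames, so per-ORF attempt counters advance through
    # alternative edits instead of cycling on the first one
    attempts: dict[tuple[int, int, int], int] = {}
    for _ in range(500):
        nb = extract_neighborhood(build_record(), anchor)
        orfs = filter_cds_overlap(
            scan_orfs(nb), nb.annotations
        )
        spurious = [
            o for o in orfs
            if (o.start, o.end, o.strand) not in planted_spans
            and o.stop_key != truth_stop_key
            and _passes_any_rule(o, motifs)
        ]
        if not spurious:
            break
        # pick the first spurious ORF with an untried edit; interacting
        # frames can resurrect an already-edited ORF, in which case a
        # different edit (possibly on a different ORF) must break the tie
        choice = None
        for orf in spurious:
            key = (orf.start, orf.end, orf.strand)
            options = _edit_options(orf)
            idx = attempts.get(key, 0)
            if idx < len(options):
                choice = (key, options, idx)
                break
        if choice is None:
            raise ValueError(
                "unable to scrub spurious ORFs nested in planted sequence"
            )
        key, options, idx = choice
        attempts[key] = idx + 1
        option = options[idx]
        if len(option) == 3:
            p, codon, _ = option
            seq[p:p + 3] = list(codon)
        else:
            p, base = option
            seq[p] = base
    else:
        raise ValueError("background scrubbing did not converge")

    return NeighborhoodFixture(
        record=build_record(),
        anchor=anchor,
        truth=truth,
        decoys=tuple(decoys),
    )
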