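"""Precursor-ORF discovery around atropopeptide-modifying P450 genes.

Atropopeptide precursor genes are short (10-40 codons), unannotated, and
sit within ~3 kb of the family-defining cytochrome P450 gene. This
module extracts that genomic neighborhood from a GenBank record,
enumerates candidate ORFs in all six reading frames (bacterial table 11;
start codons ATG/GTG/TTG), and applies the family's selection rules:

* aromatic-core rule (first mining round): the six C-terminal residues
  of the precursor — the core peptide — must contain two consecutive
  aromatic residues (F, W or Y), the anchor points of the P450-installed
  crosslinks;
* leader-motif rule (second round): the precursor must contain one of
  the KSLK-family leader motifs (KSLK, RSLK, ESLK, KSRK, KPLK, PSLK)
  that thread the precursor into the P450's substrate tunnel.

ORFs overlapping annotated CDS features are discarded (except features
already labeled as tryptorubin-family RiPP precursors), and nested ORFs
sharing a stop codon are collapsed to the shortest rule-satisfying one,
with discarded alternative starts kept as metadata since the true start
cannot be resolved when several start codons are in frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
AROMATIC = frozenset("FWY")
CORE_LENGTH = 6
DEFAULT_FLANK = 3000
EXEMPT_CDS_PHRASE = "tryptorubin family ripp precursor"

TRANSLATION_TABLE = 11


@dataclass(frozen=True)
class MotifSet:
    """Allowed leader motifs; typically found at precursor residues
    17-20 (informational only, position is not enforced)."""

    motifs: tuple[str, ...] = ("KSLK", "RSLK", "ESLK", "KSRK", "KPLK", "PSLK")

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) != 4 or m != m.upper():
                raise ValueError(f"motif {m!r} must be an uppercase 4-mer")


DEFAULT_MOTIFS = MotifSet()


@dataclass(frozen=True)
class CdsAnnotation:
    """A CDS feature in record coordinates (0-based half-open)."""

    start: int
    end: int
    strand: int
    label: str = ""


@dataclass(frozen=True)
class GenomicNeighborhood:
    """A window of <= ``flank`` nt on each side of an anchor gene."""

    record_id: str
    sequence: str  # full record sequence
    anchor: CdsAnnotation
    window: tuple[int, int]  # record coordinates, 0-based half-open
    annotations: tuple[CdsAnnotation, ...] = ()

    def __post_init__(self) -> None:
        w0, w1 = self.window
        if not (0 <= w0 < w1 <= len(self.sequence)):
            raise ValueError("window outside the record")
        if not (w0 <= self.anchor.start and self.anchor.end <= w1):
            raise ValueError("window must contain the anchor gene")

    @property
    def window_seq(self) -> str:
        return self.sequence[self.window[0]:self.window[1]]


@dataclass(frozen=True)
class OrfCandidate:
    """A short ORF; coordinates are 0-based half-open record coordinates
    spanning start codon through stop codon inclusive."""

    start: int
    end: int
    strand: int
    aa_seq: str
    start_codon: str

    def __post_init__(self) -> None:
        span = self.end - self.start
        if span % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if len(self.aa_seq) != span // 3 - 1:
            raise ValueError("translation length inconsistent with span")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def stop_key(self) -> tuple[int, int]:
        """Identity of the stop codon: (strand, 3'-end coordinate)."""
        return (self.strand, self.end if self.strand == 1 else self.start)

    @property
    def core(self) -> str:
        return self.aa_seq[-CORE_LENGTH:]


@dataclass(frozen=True)
class PrecursorCandidate:
    """An ORF accepted as a putative atropopeptide precursor."""

    orf: OrfCandidate
    rule_mode: str  # "aromatic-core" | "leader-motif" | "both"
    matched_motif: str | None = None
    alternative_starts: tuple[int, ...] = ()

    @property
    def core(self) -> str:
        return self.orf.core

    @property
    def leader(self) -> str:
        return self.orf.aa_seq[:-CORE_LENGTH]


def find_anchor(record: SeqRecord, key: str) -> CdsAnnotation:
    """Locate a CDS in a GenBank record by protein_id or locus_tag."""
    for feat in record.features:
        if feat.type != "CDS":
            continue
        ids = feat.qualifiers.get("protein_id", []) + feat.qualifiers.get(
            "locus_tag", []
        )
        if key in ids:
            return CdsAnnotation(
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=feat.location.strand or 1,
                label=";".join(feat.qualifiers.get("product", [])),
            )
    raise ValueError(f"no CDS with protein_id/locus_tag {key!r} in {record.id}")


def _cds_annotations(record: SeqRecord) -> list[CdsAnnotation]:
    out = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        label = ";".join(
            feat.qualifiers.get("product", [])
            + feat.qualifiers.get("note", [])
        )
        out.append(
            CdsAnnotation(
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=feat.location.strand or 1,
                label=label,
            )
        )
    return out


def extract_neighborhood(
    record: SeqRecord,
    anchor: CdsAnnotation | str,
    flank: int = DEFAULT_FLANK,
) -> GenomicNeighborhood:
    """Window of ``flank`` nt either side of the anchor gene boundaries,
    truncated at record edges; CDS annotations intersecting the window
    are retained in original record coordinates."""
    if isinstance(anchor, str):
        anchor = find_anchor(record, anchor)
    seq = str(record.seq).upper()
    w0 = max(0, anchor.start - flank)
    w1 = min(len(seq), anchor.end + flank)
    annotations = tuple(
        a for a in _cds_annotations(record) if a.start < w1 and a.end > w0
    )
    if not any(
        a.start == anchor.start and a.end == anchor.end for a in annotations
    ):
        annotations = annotations + (anchor,)
    return GenomicNeighborhood(
        record_id=record.id,
        sequence=seq,
        anchor=anchor,
        window=(w0, w1),
        annotations=annotations,
    )


def _translate(nt: str) -> str:
    return str(Seq(nt).translate(table=TRANSLATION_TABLE))


def _scan_strand(
    seq: str, min_aa: int, max_aa: int, starts: Sequence[str],
    force_met: bool,
) -> list[tuple[int, int, str, str]]:
    """All (start, end, aa, start_codon) on the forward strand of seq."""
    out = []
    n = len(seq)
    for frame in range(3):
        stop_positions = [
            i for i in range(frame, n - 2, 3) if seq[i:i + 3] in STOP_CODONS
        ]
        stop_iter = iter(stop_positions)
        next_stop = next(stop_iter, None)
        for i in range(frame, n - 2, 3):
            while next_stop is not None and next_stop < i:
                next_stop = next(stop_iter, None)
            codon = seq[i:i + 3]
            if codon not in starts:
                continue
            if next_stop is None:
                break  # no in-frame stop downstream in the window
            start, end = i, next_stop + 3
            aa_len = (end - start) // 3 - 1
            if not min_aa <= aa_len <= max_aa:
                continue
            aa = _translate(seq[start:end - 3])
            if force_met:
                aa = "M" + aa[1:]
            out.append((start, end, aa, codon))
    return out


def scan_orfs(
    neighborhood: GenomicNeighborhood,
    min_aa: int = 10,
    max_aa: int = 40,
    starts: Sequence[str] = START_CODONS,
    force_met: bool = False,
) -> list[OrfCandidate]:
    """Enumerate short ORFs in all six frames of the window.

    An ORF is a start codon followed by its nearest in-frame stop, both
    fully inside the window; the initiator is translated literally
    unless ``force_met`` is set. Returns candidates sorted by
    (start, strand).
    """
    w0, w1 = neighborhood.window
    window_seq = neighborhood.window_seq
    if len(window_seq) < 3 * (min_aa + 2):
        return []
    cands: list[OrfCandidate] = []
    for s, e, aa, codon in _scan_strand(
        window_seq, min_aa, max_aa, starts, force_met
    ):
        cands.append(
            OrfCandidate(
                start=w0 + s, end=w0 + e, strand=1, aa_seq=aa,
                start_codon=codon,
            )
        )
    rc = str(Seq(window_seq).reverse_complement())
    L = len(window_seq)
    for s, e, aa, codon in _scan_strand(rc, min_aa, max_aa, starts, force_met):
        cands.append(
            OrfCandidate(
                start=w0 + L - e, end=w0 + L - s, strand=-1, aa_seq=aa,
                start_codon=codon,
            )
        )
    cands.sort(key=lambda c: (c.start, -c.strand))
    return cands


def apply_core_rule(orf: OrfCandidate) -> bool:
    """True iff the 6-residue core holds two consecutive aromatics."""
    core = orf.core
    return any(
        core[i] in AROMATIC and core[i + 1] in AROMATIC
        for i in range(len(core) - 1)
    )


def apply_motif_rule(
    orf: OrfCandidate, motifs: MotifSet = DEFAULT_MOTIFS
) -> str | None:
    """Leftmost occurrence of any allowed leader motif, or None."""
    best: tuple[int, str] | None = None
    for motif in motifs.motifs:
        idx = orf.aa_seq.find(motif)
        if idx >= 0 and (best is None or idx < best[0]):
            best = (idx, motif)
    return best[1] if best else None


def filter_cds_overlap(
    orfs: Iterable[OrfCandidate],
    annotations: Iterable[CdsAnnotation],
    exempt_phrase: str = EXEMPT_CDS_PHRASE,
) -> list[OrfCandidate]:
    """Drop ORFs sharing >= 1 nt with a non-exempt CDS on either strand."""
    blocking = [
        a for a in annotations
        if exempt_phrase not in a.label.lower()
    ]
    kept = []
    for orf in orfs:
        if any(orf.start < a.end and a.start < orf.end for a in blocking):
            continue
        kept.append(orf)
    return kept


def deduplicate_nested(orfs: Sequence[OrfCandidate]) -> list[
    tuple[OrfCandidate, tuple[int, ...]]
]:
    """Collapse ORFs sharing a (strand, stop) to the shortest one.

    Returns (kept ORF, alternative start coordinates) pairs; the
    alternatives record the longer in-frame variants whose true start
    cannot be distinguished.
    """
    groups: dict[tuple[int, int], list[OrfCandidate]] = {}
    order: list[tuple[int, int]] = []
    for orf in orfs:
        key = orf.stop_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(orf)
    out = []
    for key in order:
        group = sorted(groups[key], key=lambda o: o.end - o.start)
        shortest = group[0]
        alternatives = tuple(
            o.start if o.strand == 1 else o.end for o in group[1:]
        )
        out.append((shortest, alternatives))
    return out


def find_precursors(
    neighborhood: GenomicNeighborhood,
    rule_mode: str = "leader-motif",
    motifs: MotifSet = DEFAULT_MOTIFS,
    min_aa: int = 10,
    max_aa: int = 40,
    starts: Sequence[str] = START_CODONS,
    force_met: bool = False,
) -> list[PrecursorCandidate]:
    """Full selection pipeline: scan, CDS filter, rules, deduplicate."""
    if rule_mode not in ("aromatic-core", "leader-motif", "both"):
        raise ValueError(f"unknown rule mode {rule_mode!r}")
    orfs = scan_orfs(neighborhood, min_aa, max_aa, starts, force_met)
    orfs = filter_cds_overlap(orfs, neighborhood.annotations)
    passing: list[tuple[OrfCandidate, str | None]] = []
    for orf in orfs:
        motif = apply_motif_rule(orf, motifs)
        ok = True
        if rule_mode in ("aromatic-core", "both"):
            ok = ok and apply_core_rule(orf)
        if rule_mode in ("leader-motif", "both"):
            ok = ok and motif is not None
        if ok:
            passing.append((orf, motif))
    motif_by_orf = {id(orf): m for orf, m in passing}
    deduped = deduplicate_nested([orf for orf, _ in passing])
    return [
        PrecursorCandidate(
            orf=orf,
            rule_mode=rule_mode,
            matched_motif=motif_by_orf[id(orf)],
            alternative_starts=alts,
        )
        for orf, alts in deduped
    ]


def write_region_genbank(
    neighborhood: GenomicNeighborhood,
    kept: Sequence[PrecursorCandidate],
    out,
) -> None:
    """Write the window as a GenBank record with precursors annotated.

    Coordinates are re-based so the window starts at 1; carried-over
    CDS annotations are clipped to the window.
    """
    w0, w1 = neighborhood.window
    record = SeqRecord(
        Seq(neighborhood.window_seq),
        id=neighborhood.record_id,
        name=neighborhood.record_id[:16].replace("|", "_"),
        description=(
            f"neighborhood {w0 + 1}..{w1} of {neighborhood.record_id}"
        ),
        annotations={"molecule_type": "DNA"},
    )
    for ann in neighborhood.annotations:
        loc = FeatureLocation(
            max(ann.start, w0) - w0, min(ann.end, w1) - w0, strand=ann.strand
        )
        qualifiers = {"product": [ann.label]} if ann.label else {}
        record.features.append(SeqFeature(loc, type="CDS", qualifiers=qualifiers))
    for cand in kept:
        orf = cand.orf
        if not (w0 <= orf.start and orf.end <= w1):
            raise ValueError("precursor candidate outside the window")
        qualifiers = {
            "product": ["putative atropopeptide precursor"],
            "translation": [orf.aa_seq],
            "core_peptide": [cand.core],
            "rule_mode": [cand.rule_mode],
        }
        if cand.matched_motif:
            qualifiers["leader_motif"] = [cand.matched_motif]
        if cand.alternative_starts:
            qualifiers["alternative_starts"] = [
                ",".join(str(a - w0 + 1) for a in cand.alternative_starts)
            ]
        loc = FeatureLocation(orf.start - w0, orf.end - w0, strand=orf.strand)
        record.features.append(
            SeqFeature(loc, type="CDS", qualifiers=qualifiers)
        )
    try:
        if hasattr(out, "write"):
            SeqIO.write(record, out, "genbank")
        else:
            SeqIO.write(record, str(out), "genbank")
    except OSError as exc:
        raise OSError(f"failed writing GenBank region to {out}: {exc}") from exc


def gc_content(nt_seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases excluded from both sides."""
    seq = nt_seq.upper()
    gc = sum(seq.count(b) for b in "GC")
    total = gc + sum(seq.count(b) for b in "AT")
    if total == 0:
        raise ValueError("no unambiguous bases in sequence")
    return gc / total


def gc_delta(gene_gc: float, genome_mean_gc: float) -> float:
    """Signed difference between a gene's GC fraction and the genome mean."""
    return gene_gc - genome_mean_gc
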