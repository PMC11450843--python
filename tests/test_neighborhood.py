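"""Neighborhood extraction, ORF scanning, selection rules, GenBank I/O."""

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from atropomine.fixtures import CODON_OF, NeighborhoodSpec, generate_neighborhood
from atropomine.neighborhood import (
    CdsAnnotation,
    GenomicNeighborhood,
    MotifSet,
    OrfCandidate,
    START_CODONS,
    STOP_CODONS,
    apply_core_rule,
    apply_motif_rule,
    deduplicate_nested,
    extract_neighborhood,
    filter_cds_overlap,
    find_precursors,
    gc_content,
    gc_delta,
    scan_orfs,
    write_region_genbank,
)

BASES = "ACGT"


def _record(seq, anchor_start, anchor_end, strand=1, rec_id="R1"):
    record = SeqRecord(Seq(seq), id=rec_id,
                       annotations={"molecule_type": "DNA"})
    from Bio.SeqFeature import FeatureLocation, SeqFeature

    record.features.append(
        SeqFeature(
            FeatureLocation(anchor_start, anchor_end, strand=strand),
            type="CDS",
            qualifiers={"product": ["cytochrome P450"],
                        "protein_id": ["ANCHOR.1"]},
        )
    )
    return record


def _random_nt(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _orf(aa, strand=1, start=0):
    """Build an OrfCandidate for a peptide (fixture codon table)."""
    nt_len = 3 * len(aa) + 3
    return OrfCandidate(
        start=start, end=start + nt_len, strand=strand, aa_seq=aa,
        start_codon="ATG",
    )


class TestExtractNeighborhood:
    def test_window_arithmetic(self, rng):
        record = _record(_random_nt(rng, 20000), 5000, 6200)
        nb = extract_neighborhood(record, "ANCHOR.1")
        assert nb.window == (2000, 9200)

    def test_left_truncation_at_record_edge(self, rng):
        record = _record(_random_nt(rng, 20000), 1000, 2200)
        nb = extract_neighborhood(record, "ANCHOR.1")
        assert nb.window == (0, 5200)

    def test_strand_independent(self, rng):
        seq = _random_nt(rng, 20000)
        plus = extract_neighborhood(_record(seq, 5000, 6200, 1), "ANCHOR.1")
        minus = extract_neighborhood(_record(seq, 5000, 6200, -1), "ANCHOR.1")
        assert plus.window == minus.window

    def test_missing_anchor_rejected(self, rng):
        record = _record(_random_nt(rng, 2000), 500, 800)
        with pytest.raises(ValueError, match="NOPE"):
            extract_neighborhood(record, "NOPE")


def brute_force_orfs(nb, min_aa=10, max_aa=40):
    """Independent oracle: test every in-frame start/stop pair directly."""
    w0, w1 = nb.window
    found = set()
    for strand in (1, -1):
        seq = nb.window_seq if strand == 1 else str(
            Seq(nb.window_seq).reverse_complement()
        )
        L = len(seq)
        for i in range(L - 2):
            if seq[i:i + 3] not in START_CODONS:
                continue
            j = i + 3
            while j + 3 <= L:
                if seq[j:j + 3] in STOP_CODONS:
                    aa_len = (j - i) // 3
                    if min_aa <= aa_len <= max_aa:
                        if strand == 1:
                            found.add((w0 + i, w0 + j + 3, 1))
                        else:
                            found.add((w0 + L - j - 3, w0 + L - i, -1))
                    break
                j += 3
    return found


class TestScanOrfs:
    def test_planted_orf_recovered_with_translation(self, rng):
        peptide = "MTEALDNKVSARWYSTQELD"  # 20 aa
        nt = "".join(CODON_OF[a] for a in peptide) + "TAA"
        background = _random_nt(rng, 3000)
        seq = background[:1200] + nt + background[1200:]
        record = _record(seq, 100, 400)
        nb = extract_neighborhood(record, "ANCHOR.1")
        hits = [
            o for o in scan_orfs(nb)
            if o.start == 1200 and o.end == 1200 + len(nt)
        ]
        assert len(hits) == 1
        assert hits[0].aa_seq == peptide and hits[0].strand == 1

    @pytest.mark.parametrize("n_aa,expected", [(9, False), (10, True),
                                               (40, True), (41, False)])
    def test_length_bounds(self, rng, n_aa, expected):
        peptide = "M" + "A" * (n_aa - 1)
        nt = "".join(CODON_OF[a] for a in peptide) + "TAA"
        pad = "C" * 600  # GC-only padding: no start or stop codons
        seq = pad + nt + pad
        record = _record(seq, 0, 60)
        nb = extract_neighborhood(record, CdsAnnotation(0, 60, 1))
        found = any(
            o.start == 600 and o.end == 600 + len(nt) for o in scan_orfs(nb)
        )
        assert found == expected

    def test_tiny_window_yields_nothing(self, rng):
        record = _record("ATGAAATAA" * 3, 0, 9)
        nb = GenomicNeighborhood(
            record_id="r", sequence=str(record.seq), window=(0, 27),
            anchor=CdsAnnotation(0, 9, 1),
        )
        assert scan_orfs(nb) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_nt(rng, int(rng.integers(200, 5000)))
        nb = GenomicNeighborhood(
            record_id="r", sequence=seq, window=(0, len(seq)),
            anchor=CdsAnnotation(0, min(30, len(seq)), 1),
        )
        got = {(o.start, o.end, o.strand) for o in scan_orfs(nb)}
        assert got == brute_force_orfs(nb)


class TestCoreRule:
    @pytest.mark.parametrize("core,expected", [
        ("SWYQWL", True),   # W-Y adjacent
        ("WFIWYS", True),   # W-F and W-Y adjacent
        ("ASGIGL", False),  # no aromatic pair
        ("AWAWAW", False),  # aromatics never adjacent
    ])
    def test_consecutive_aromatics(self, core, expected):
        orf = _orf("MSDTELINAFREKVSAKSLK" + core)
        assert apply_core_rule(orf) == expected

    def test_rule_sees_only_last_six_residues(self):
        # aromatic pair in the leader must not satisfy the core rule
        orf = _orf("MSDWWLINAFREKVSAKSLK" + "ASGIGL")
        assert apply_core_rule(orf) is False


class TestMotifRule:
    def test_canonical_motif_at_17(self):
        orf = _orf("MSDTELINAFREKVSA" + "KSLK" + "SWYQWL")
        assert apply_motif_rule(orf) == "KSLK"
        assert orf.aa_seq.index("KSLK") == 16  # residues 17-20

    def test_near_miss_not_matched(self):
        orf = _orf("MSDTELINAFREGVSA" + "KSLR" + "SWYQWL")
        assert apply_motif_rule(orf) is None

    def test_leftmost_occurrence_wins(self):
        orf = _orf("MSDT" + "PSLK" + "ELINAFRE" + "KSLK" + "SWYQWL")
        assert apply_motif_rule(orf) == "PSLK"


class TestCdsOverlapFilter:
    def test_overlapping_removed_exempt_kept_intergenic_kept(self):
        orfs = [_orf("M" + "A" * 19, start=s) for s in (100, 300, 900)]
        annotations = [
            CdsAnnotation(0, 130, 1, "cytochrome P450"),
            CdsAnnotation(310, 400, 1, "tryptorubin family RiPP precursor CDS"),
        ]
        kept = filter_cds_overlap(orfs, annotations)
        assert [o.start for o in kept] == [300, 900]

    def test_any_strand_overlap_counts(self):
        orf = _orf("M" + "A" * 19, strand=1, start=100)
        kept = filter_cds_overlap(
            [orf], [CdsAnnotation(150, 250, -1, "something else")]
        )
        assert kept == []


class TestDeduplication:
    def test_shortest_per_stop_kept_with_alternatives(self):
        long = _orf("MAAAAA" + "MSDTELINAFREKVSAKS", start=282)
        short = _orf("MSDTELINAFREKVSAKS", start=300)
        assert long.end == short.end
        kept = deduplicate_nested([long, short])
        assert len(kept) == 1
        orf, alternatives = kept[0]
        assert orf is short and alternatives == (282,)

    def test_single_candidate_unchanged(self):
        orf = _orf("M" + "A" * 12)
        assert deduplicate_nested([orf]) == [(orf, ())]

    def test_opposite_strands_not_merged(self):
        a = _orf("M" + "A" * 12, strand=1, start=100)
        b = _orf("M" + "A" * 12, strand=-1, start=100)
        kept = deduplicate_nested([a, b])
        assert len(kept) == 2


class TestRuleComposition:
    def test_core_then_motif_equals_motif_then_core(self, neighborhood_fixture):
        nb = neighborhood_fixture.neighborhood
        orfs = scan_orfs(nb)
        motifs = MotifSet()
        one = [o for o in orfs if apply_core_rule(o)
               and apply_motif_rule(o, motifs)]
        other = [o for o in orfs if apply_motif_rule(o, motifs)
                 and apply_core_rule(o)]
        assert one == other


class TestGenBankOutput:
    def test_round_trip_coordinates_and_translation(
        self, neighborhood_fixture, tmp_path
    ):
        nb = neighborhood_fixture.neighborhood
        kept = find_precursors(nb, rule_mode="both")
        assert kept
        out = tmp_path / "region.gbk"
        write_region_genbank(nb, kept, out)
        back = next(SeqIO.parse(str(out), "genbank"))
        assert str(back.seq) == nb.window_seq
        w0 = nb.window[0]
        precursor_feats = [
            f for f in back.features
            if f.qualifiers.get("product") == ["putative atropopeptide precursor"]
        ]
        assert len(precursor_feats) == len(kept)
        for feat, cand in zip(precursor_feats, kept):
            assert int(feat.location.start) == cand.orf.start - w0
            assert int(feat.location.end) == cand.orf.end - w0
            assert feat.qualifiers["translation"] == [cand.orf.aa_seq]

    def test_rebased_coordinates(self, rng):
        # candidate at record [2100, 2160) in a window starting at 2000
        # must appear as feature 101..160 (1-based inclusive)
        seq = _random_nt(rng, 10000)
        nb = GenomicNeighborhood(
            record_id="r", sequence=seq, window=(2000, 9000),
            anchor=CdsAnnotation(3000, 4000, 1, "cytochrome P450"),
        )
        orf = OrfCandidate(
            start=2100, end=2160, strand=1,
            aa_seq="X" * 19, start_codon="ATG",
        )
        from atropomine.neighborhood import PrecursorCandidate

        cand = PrecursorCandidate(orf=orf, rule_mode="both")
        import io

        out = io.StringIO()
        write_region_genbank(nb, [cand], out)
        text = out.getvalue()
        assert "101..160" in text

    def test_empty_candidate_list_is_valid(self, neighborhood_fixture, tmp_path):
        nb = neighborhood_fixture.neighborhood
        out = tmp_path / "empty.gbk"
        write_region_genbank(nb, [], out)
        back = next(SeqIO.parse(str(out), "genbank"))
        assert len(back.seq) == nb.window[1] - nb.window[0]
        assert any(f.type == "CDS" for f in back.features)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5),
    ])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_delta(self):
        assert gc_delta(gc_content("GCAT"), 0.70) == pytest.approx(-0.20)

    def test_ambiguous_excluded(self):
        assert gc_content("GCNNAT") == pytest.approx(0.5)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complement_invariant(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_nt(rng, 200)
        rc = str(Seq(seq).reverse_complement())
        assert gc_content(seq) == pytest.approx(gc_content(rc))
        assert 0.0 <= gc_content(seq) <= 1.0
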