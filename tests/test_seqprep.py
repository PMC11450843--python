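"""Segmentation, reduced-alphabet recoding, and dereplication."""

import numpy as np
import pytest

from atropomine.seqprep import (
    DEFAULT_ALPHABET,
    DereplicationParams,
    ProteinSeq,
    ReducedAlphabet,
    ReferenceScheme,
    dereplicate,
    read_fasta,
    reduce_sequence,
    segment_by_reference,
    write_fasta,
)
from conftest import random_protein


class TestProteinSeq:
    def test_uppercased_on_ingestion(self):
        assert ProteinSeq("a", "mktay").residues == "MKTAY"

    @pytest.mark.parametrize("bad", ["", "MKT1AY", "MKT-AY", "MKUZAY"])
    def test_rejects_invalid_residues(self, bad):
        with pytest.raises(ValueError):
            ProteinSeq("a", bad)


class TestSegmentation:
    def test_reference_against_itself(self, reference_scheme):
        sp = segment_by_reference(
            reference_scheme.reference, reference_scheme
        )
        assert sp.query_boundaries == (92, 192, 275, 395)
        L = len(reference_scheme.reference)
        assert [len(s) for s in sp.segments] == [92, 100, 83, 120, L - 395]

    def test_leading_insertion_shifts_boundaries(self, reference_scheme):
        ref = reference_scheme.reference
        query = ProteinSeq("q", "A" * 10 + ref.residues)
        sp = segment_by_reference(query, reference_scheme)
        assert sp.query_boundaries == (102, 202, 285, 405)

    def test_cut_in_deletion_anchors_left(self, reference_scheme):
        # remove reference residues 90-95: the 92 cut falls inside the
        # deletion and must anchor at the query position aligned to
        # reference position 89
        ref = reference_scheme.reference
        query = ProteinSeq("q", ref.residues[:89] + ref.residues[95:])
        sp = segment_by_reference(query, reference_scheme)
        assert sp.query_boundaries[0] == 89
        assert sp.query_boundaries[1:] == (186, 269, 389)

    @pytest.mark.parametrize("seed", range(6))
    def test_concatenation_identity_and_monotonicity(
        self, reference_scheme, seed
    ):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(120, 500))
        query = random_protein(rng, length, f"q{seed}")
        sp = segment_by_reference(query, reference_scheme)
        assert "".join(sp.segments) == query.residues
        b = sp.query_boundaries
        assert list(b) == sorted(b)
        assert b[-1] <= len(query)

    def test_rejects_short_query(self, reference_scheme):
        with pytest.raises(ValueError, match="minimum alignable"):
            segment_by_reference(ProteinSeq("q", "MKTAY" * 8), reference_scheme)


class TestReducedAlphabet:
    def test_empty_identity(self):
        assert reduce_sequence("") == ""

    def test_aromatics_collapse(self):
        out = reduce_sequence("WYF")
        assert len(set(out)) == 1 and out[0] == DEFAULT_ALPHABET.mapping["W"]

    def test_positives_collapse(self):
        out = reduce_sequence("KRH")
        assert len(set(out)) == 1 and out[0] == DEFAULT_ALPHABET.mapping["K"]

    def test_length_preserving_and_deterministic(self, rng):
        seq = random_protein(rng, 200, "r").residues
        out = reduce_sequence(seq)
        assert len(out) == len(seq)
        assert out == reduce_sequence(seq)

    def test_wildcard_has_its_own_symbol(self):
        sym = reduce_sequence("X")
        assert sym == DEFAULT_ALPHABET.wildcard_symbol
        assert sym not in set(DEFAULT_ALPHABET.mapping.values())

    def test_mapping_must_be_total(self):
        with pytest.raises(ValueError):
            ReducedAlphabet(mapping={"A": "a"})


def _mutate_at(seq: str, positions, rng):
    out = list(seq)
    from atropomine.seqprep import AMINO_ACIDS

    for p in positions:
        choices = [aa for aa in AMINO_ACIDS if aa != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


class TestDereplication:
    def test_identical_pair_collapses(self):
        seqs = [ProteinSeq("a", "MKTAYIAKQR" * 6), ProteinSeq("b", "MKTAYIAKQR" * 6)]
        assert len(dereplicate(seqs)) == 1

    def test_ten_percent_divergence_splits(self, rng):
        base = random_protein(rng, 100, "a")
        other = ProteinSeq("b", _mutate_at(base.residues, range(0, 100, 10), rng))
        reps = dereplicate([base, other])
        assert len(reps) == 2

    def test_single_sequence_is_its_own_representative(self, rng):
        seq = random_protein(rng, 80, "solo")
        assert dereplicate([seq]) == [seq]

    def test_idempotence_and_coverage_oracle(self, rng):
        # three cluster centers, each with a few 1-2 substitution copies
        from atropomine.seqprep import _identity, _make_aligner

        centers = [random_protein(rng, 60, f"c{i}") for i in range(3)]
        pool = list(centers)
        for i, c in enumerate(centers):
            for j in range(1 + i):
                mutated = _mutate_at(c.residues, [5 * j + 3], rng)
                pool.append(ProteinSeq(f"c{i}_m{j}", mutated))
        assert len(pool) <= 30
        reps = dereplicate(pool)
        reps2 = dereplicate(reps)
        assert [r.id for r in reps2] == [r.id for r in reps]
        # all-pairs oracle: every input is within threshold of some rep
        aligner = _make_aligner()
        for seq in pool:
            assert any(
                _identity(seq.residues, rep.residues, aligner) >= 0.95
                for rep in reps
            )

    def test_length_filter(self, rng):
        short = random_protein(rng, 100, "short")
        ok = random_protein(rng, 350, "ok")
        params = DereplicationParams(length_filter=(300, 450))
        assert dereplicate([short, ok], params) == [ok]


def test_fasta_round_trip(tmp_path, rng):
    seqs = [random_protein(rng, 60, f"s{i} some description") for i in range(3)]
    path = tmp_path / "x.fasta"
    write_fasta(seqs, path)
    back = read_fasta(path)
    assert [s.residues for s in back] == [s.residues for s in seqs]
    assert back[0].id.split()[0] == "s0"
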