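"""Segment-wise reduced-alphabet k-mer features for P450 classification.

The feature space is defined entirely by the positive training class: a
4-mer (over the reduced alphabet) becomes a feature of a functional
region when it occurs in that region in at least half of the positive
training sequences. Any P450 is then vectorized as the overlapping
occurrence counts of each retained k-mer in the corresponding region.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from atropomine.seqprep import (
    DEFAULT_ALPHABET,
    ReducedAlphabet,
    SegmentedProtein,
    reduce_sequence,
)

N_SEGMENTS = 5


def count_overlapping(text: str, pattern: str) -> int:
    """Number of (possibly overlapping) occurrences of pattern in text."""
    if not pattern or len(pattern) > len(text):
        return 0
    n = 0
    start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


@dataclass(frozen=True)
class KmerFeatureSpace:
    """Per-segment retained k-mers defining the classifier's feature axes.

    ``per_segment_features`` holds, for each of the five regions, the
    lexicographically sorted list of reduced-alphabet k-mers that passed
    the at-least-half-of-positives rule; ``n_positives`` records how
    many positive sequences defined the space.
    """

    k: int
    min_positive_fraction: float
    per_segment_features: tuple[tuple[str, ...], ...]
    n_positives: int

    def __post_init__(self) -> None:
        if len(self.per_segment_features) != N_SEGMENTS:
            raise ValueError("feature space must cover five segments")
        for kmers in self.per_segment_features:
            for kmer in kmers:
                if len(kmer) != self.k:
                    raise ValueError(f"feature {kmer!r} is not a {self.k}-mer")

    @property
    def n_features(self) -> int:
        return sum(len(f) for f in self.per_segment_features)

    def feature_names(self) -> list[str]:
        return [
            f"seg{i}:{kmer}"
            for i, kmers in enumerate(self.per_segment_features)
            for kmer in kmers
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "min_positive_fraction": self.min_positive_fraction,
                "n_positives": self.n_positives,
                "per_segment_features": [
                    list(f) for f in self.per_segment_features
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "KmerFeatureSpace":
        obj = json.loads(text)
        return cls(
            k=obj["k"],
            min_positive_fraction=obj["min_positive_fraction"],
            n_positives=obj["n_positives"],
            per_segment_features=tuple(
                tuple(f) for f in obj["per_segment_features"]
            ),
        )


@dataclass(frozen=True)
class FeatureVector:
    source_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("feature counts must be non-negative")


def reduce_segments(
    protein: SegmentedProtein, alphabet: ReducedAlphabet = DEFAULT_ALPHABET
) -> tuple[str, ...]:
    """Recode each functional region of a segmented protein."""
    return tuple(reduce_sequence(seg, alphabet) for seg in protein.segments)


def build_feature_space(
    positive_segments: Sequence[Sequence[str]],
    k: int = 4,
    min_positive_fraction: float = 0.5,
) -> KmerFeatureSpace:
    """Retain per-segment k-mers present in >= ceil(fraction * n) positives.

    ``positive_segments`` holds one five-tuple of reduced segment strings
    per positive training sequence. Presence is per sequence (a k-mer
    occurring twice in one sequence counts once toward the quorum).
    """
    n = len(positive_segments)
    if n < 2:
        raise ValueError(
            "feature construction requires at least two positive sequences"
        )
    for segs in positive_segments:
        if len(segs) != N_SEGMENTS:
            raise ValueError("every positive must have five segments")
    quorum = math.ceil(min_positive_fraction * n)
    per_segment: list[tuple[str, ...]] = []
    for seg_idx in range(N_SEGMENTS):
        counts: dict[str, int] = {}
        for segs in positive_segments:
            seg = segs[seg_idx]
            seen = {seg[i:i + k] for i in range(len(seg) - k + 1)}
            for kmer in seen:
                counts[kmer] = counts.get(kmer, 0) + 1
        retained = sorted(km for km, c in counts.items() if c >= quorum)
        per_segment.append(tuple(retained))
    return KmerFeatureSpace(
        k=k,
        min_positive_fraction=min_positive_fraction,
        per_segment_features=tuple(per_segment),
        n_positives=n,
    )


def vectorize(
    segments: Sequence[str],
    space: KmerFeatureSpace,
    source_id: str = "",
) -> FeatureVector:
    """Count each retained k-mer (overlapping) in its segment."""
    if len(segments) != N_SEGMENTS:
        raise ValueError(
            f"expected {N_SEGMENTS} segments, got {len(segments)}"
        )
    values = [
        count_overlapping(segments[i], kmer)
        for i in range(N_SEGMENTS)
        for kmer in space.per_segment_features[i]
    ]
    return FeatureVector(
        source_id=source_id, values=np.asarray(values, dtype=np.int64)
    )
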