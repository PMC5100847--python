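"""Core in-memory containers shared across the package.

Sequences are plain Python strings over the uppercase alphabet {A,C,G,T,N};
k-mer machinery re-encodes them to 2-bit arrays on demand (see
:mod:`hapspec._kmers`).  Coordinates are 0-based, half-open everywhere in
code; human-readable reports convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (contig or scaffold).

    ``sequence`` must be non-empty and uppercase over {A,C,G,T,N}; parsers in
    :mod:`hapspec.seqio` enforce this on read.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read with Sanger-encoded base qualities."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class KmerHistogram:
    """Histogram of k-mer multiplicities: multiplicity m -> n(m) distinct k-mers.

    ``total_mass`` is the total number of k-mer instances counted,
    sum_m m * n(m); ``distinct`` is the number of distinct k-mers, sum_m n(m).
    ``k`` and ``canonical`` are metadata and may be absent when the histogram
    was loaded from a bare two-column file.
    """

    counts: dict[int, int] = field(default_factory=dict)
    k: int | None = None
    canonical: bool = True

    def __post_init__(self) -> None:
        for m, n in self.counts.items():
            if m < 1:
                raise ValueError(f"multiplicity {m} < 1 in histogram")
            if n < 0:
                raise ValueError(f"negative count n({m}) = {n}")

    @property
    def total_mass(self) -> int:
        return sum(m * n for m, n in self.counts.items())

    @property
    def distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts) if self.counts else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerHistogram):
            return NotImplemented
        return {m: n for m, n in self.counts.items() if n} == {
            m: n for m, n in other.counts.items() if n
        }

    def __len__(self) -> int:
        return len(self.counts)
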