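"""Synthetic diploid genomes, reads and assemblies with known truth.

The generator emulates the situation a short-read assembler faces in a
highly heterozygous outcrossing diploid: two haplotypes differing by i.i.d.
substitutions at a per-site rate H (~1.25% in valley oak), uniform read
coverage of each haplotype, and a draft assembly that mixes three kinds of
contig:

* ``COLLAPSED``   — a homozygous region represented once;
* ``SPLIT_A/B``   — a heterozygous region the assembler failed to collapse,
  so both haplotypes appear as separate contigs ("haplotigs");
* ``TRUE_DUPLICATE`` — a genuine segmental duplication, present twice in
  each haplotype.

All randomness derives from the config seed; the same config is
byte-reproducible.  Heterozygosity is substitution-only (no indels), which
is the divergence mode the downstream estimators are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kmers
from .records import ReadRecord, SequenceRecord


@dataclass
class DiploidSimConfig:
    """Parameters of the diploid genome to synthesise.

    ``heterozygosity`` is the per-site probability that the two haplotypes
    differ.  Segmental duplications are modelled by copying
    ``duplication_length``-bp segments of the genome and appending the copies,
    identically in both haplotypes, so each duplication adds its length to
    the haploid genome size.
    """

    genome_length: int = 500_000
    heterozygosity: float = 0.0125
    n_duplications: int = 0
    duplication_length: int = 5_000
    gc: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1_000:
            raise ValueError("genome_length must be >= 1000 bp")
        if not 0.0 <= self.heterozygosity <= 0.05:
            raise ValueError("heterozygosity must be in [0, 0.05]")
        if self.n_duplications < 0:
            raise ValueError("n_duplications must be >= 0")
        if self.n_duplications and not 0 < self.duplication_length < self.genome_length:
            raise ValueError("duplication_length must be in (0, genome_length)")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")


@dataclass
class DiploidTruth:
    """A simulated diploid with full ground truth."""

    hapA: SequenceRecord
    hapB: SequenceRecord
    variant_positions: np.ndarray  # sorted, hapA coordinates
    duplication_intervals: list[tuple[int, int]]  # copy locations, hapA coords
    config: DiploidSimConfig = field(repr=False, default=None)

    @property
    def haploid_length(self) -> int:
        return len(self.hapA.sequence)

    @property
    def n_het_sites(self) -> int:
        return int(self.variant_positions.size)


@dataclass
class ReadSimConfig:
    """Uniform single-end read sampling per haplotype with i.i.d. base errors."""

    read_length: int = 150
    depth_per_haplotype: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.depth_per_haplotype <= 0:
            raise ValueError("depth_per_haplotype must be > 0")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")


@dataclass
class AssemblySimConfig:
    """Fragmentation model for the synthetic draft assembly.

    Fragment lengths are exponential with mean ``mean_fragment`` and a
    200-bp floor (degenerate slivers are not informative).  A heterozygous
    fragment yields two haplotype contigs with probability
    ``split_probability``, else one collapsed contig.
    """

    mean_fragment: float = 8_000.0
    split_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_fragment <= 0:
            raise ValueError("mean_fragment must be > 0")
        if not 0.0 <= self.split_probability <= 1.0:
            raise ValueError("split_probability must be in [0, 1]")


_MIN_FRAGMENT = 200


def simulate_diploid(cfg: DiploidSimConfig) -> DiploidTruth:
    """Draw a diploid genome: random base sequence, optional segmental
    duplications, then haplotype B as A plus i.i.d. substitutions.

    Duplicated copies are kept identical between haplotypes (no het sites
    inside the copy), so they behave as the homozygous two-copy repeats the
    coverage classifiers are meant to recognise.
    """
    rng = np.random.default_rng(cfg.seed)
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    base = rng.choice(4, size=cfg.genome_length, p=p).astype(np.uint8)

    pieces = [base]
    dup_intervals: list[tuple[int, int]] = []
    offset = cfg.genome_length
    for _ in range(cfg.n_duplications):
        src = int(rng.integers(0, cfg.genome_length - cfg.duplication_length + 1))
        pieces.append(base[src : src + cfg.duplication_length].copy())
        dup_intervals.append((offset, offset + cfg.duplication_length))
        offset += cfg.duplication_length
    hap_a = np.concatenate(pieces)

    het_mask = rng.random(hap_a.size) < cfg.heterozygosity
    for s, e in dup_intervals:
        het_mask[s:e] = False
    variant_positions = np.flatnonzero(het_mask)
    hap_b = hap_a.copy()
    if variant_positions.size:
        shift = rng.integers(1, 4, size=variant_positions.size).astype(np.uint8)
        hap_b[variant_positions] = (hap_b[variant_positions] + shift) % 4

    return DiploidTruth(
        hapA=SequenceRecord("hapA", _kmers.decode(hap_a)),
        hapB=SequenceRecord("hapB", _kmers.decode(hap_b)),
        variant_positions=variant_positions,
        duplication_intervals=dup_intervals,
        config=cfg,
    )


def _sample_reads_from(
    hap: np.ndarray, hap_name: str, cfg: ReadSimConfig, rng: np.random.Generator
) -> tuple[list[str], pd.DataFrame]:
    L, rl = hap.size, cfg.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds haplotype length {L}")
    n_reads = int(round(cfg.depth_per_haplotype * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    mat = hap[starts[:, None] + np.arange(rl)]
    if cfg.error_rate > 0:
        err = rng.random(mat.shape) < cfg.error_rate
        shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)
    blob = _kmers._CODE_BASE[mat].tobytes().decode("ascii")
    seqs = [blob[i * rl : (i + 1) * rl] for i in range(n_reads)]
    truth = pd.DataFrame(
        {
            "read_id": [f"{hap_name}_r{i}" for i in range(n_reads)],
            "haplotype": hap_name,
            "start": starts,
        }
    )
    return seqs, truth


def simulate_reads(
    truth: DiploidTruth, cfg: ReadSimConfig
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Sample error-bearing reads uniformly from each haplotype.

    Returns the reads and a truth table mapping every read id to its source
    haplotype and 0-based start.
    """
    rng = np.random.default_rng(cfg.seed)
    qual = "I" * cfg.read_length
    reads: list[ReadRecord] = []
    tables = []
    for rec in (truth.hapA, truth.hapB):
        hap = _kmers.encode(rec.sequence)
        seqs, tab = _sample_reads_from(hap, rec.id, cfg, rng)
        reads.extend(
            ReadRecord(rid, s, qual) for rid, s in zip(tab["read_id"], seqs)
        )
        tables.append(tab)
    return reads, pd.concat(tables, ignore_index=True)


def simulate_assembly(
    truth: DiploidTruth, cfg: AssemblySimConfig
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Fragment the diploid into a draft assembly with truth labels.

    The hapA coordinate axis is partitioned into exponential fragments with
    breaks forced at duplication-copy boundaries.  Duplication copies emit one
    ``TRUE_DUPLICATE`` contig each; heterozygous fragments emit a SPLIT_A /
    SPLIT_B haplotig pair with probability ``split_probability``; everything
    else emits one ``COLLAPSED`` contig (hapA sequence).

    Returns the contigs and a label table with columns
    ``id, label, start, end, length``.
    """
    rng = np.random.default_rng(cfg.seed)
    hap_a = _kmers.encode(truth.hapA.sequence)
    hap_b = _kmers.encode(truth.hapB.sequence)
    variants = truth.variant_positions

    # segments of the axis between forced (duplication) boundaries
    bounds = sorted(truth.duplication_intervals)
    segments: list[tuple[int, int, bool]] = []  # (start, end, is_duplicate)
    pos = 0
    for s, e in bounds:
        if pos < s:
            segments.append((pos, s, False))
        segments.append((s, e, True))
        pos = e
    if pos < hap_a.size:
        segments.append((pos, hap_a.size, False))

    contigs: list[SequenceRecord] = []
    rows = []
    idx = 0

    def emit(seq_arr: np.ndarray, label: str, start: int, end: int) -> None:
        nonlocal idx
        idx += 1
        cid = f"ctg{idx:05d}"
        contigs.append(SequenceRecord(cid, _kmers.decode(seq_arr)))
        rows.append((cid, label, start, end, end - start))

    for seg_start, seg_end, is_dup in segments:
        if is_dup:
            emit(hap_a[seg_start:seg_end], "TRUE_DUPLICATE", seg_start, seg_end)
            continue
        pos = seg_start
        while pos < seg_end:
            frag = max(_MIN_FRAGMENT, int(rng.exponential(cfg.mean_fragment)))
            end = min(pos + frag, seg_end)
            if seg_end - end < _MIN_FRAGMENT:  # absorb a trailing sliver
                end = seg_end
            lo = np.searchsorted(variants, pos)
            hi = np.searchsorted(variants, end)
            heterozygous = hi > lo
            if heterozygous and rng.random() < cfg.split_probability:
                emit(hap_a[pos:end], "SPLIT_A", pos, end)
                emit(hap_b[pos:end], "SPLIT_B", pos, end)
            else:
                emit(hap_a[pos:end], "COLLAPSED", pos, end)
            pos = end

    labels = pd.DataFrame(rows, columns=["id", "label", "start", "end", "length"])
    return contigs, labels
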