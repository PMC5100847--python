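"""Assembly redundancy removal.

Two procedures operate on a draft assembly of a heterozygous diploid:

* :func:`collapse_haplotigs` — iterative haplotype-redundancy collapse: all
  contigs longer than a participation floor are aligned all-vs-all, and for
  every overlapping pair in which at least ``min_overlap_frac`` (default
  20%) of the smaller contig aligns at ``min_identity`` or better, the
  smaller contig is removed.  Rounds repeat until a fixpoint.
* :func:`clean_scaffolds` — single-pass removal of short scaffolds that are
  completely contained in, and nearly identical to, a strictly longer
  scaffold.

Overlap evidence comes from a native seed-and-extend aligner: shared-k-mer
seeds on both strands, chained by diagonal, scored by exact column
comparison with X-drop extension.  It is gap-free, which matches the
substitution-style divergence between haplotypes this module targets.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import canonical_window_codes, encode, window_codes
from .records import SequenceRecord

_XDROP = 30  # score drop (match +1 / mismatch -1) ending an extension
_MAX_CODE_OCCURRENCES = 16  # positions kept per seed code within one record
_MAX_CODE_RECORDS = 32  # records sharing a code before it is deemed repetitive


@dataclass
class OverlapHit:
    """Best gap-free overlap between an unordered pair of sequences.

    Spans are 0-based half-open on each sequence's forward strand;
    ``frac_small`` is the aligned span as a fraction of the smaller
    sequence; ``contained`` means the entire smaller sequence aligned.
    """

    id_small: str
    id_large: str
    span_small: tuple[int, int]
    span_large: tuple[int, int]
    identity: float
    frac_small: float
    contained: bool
    strand: str = "+"


@dataclass
class CollapseConfig:
    """Parameters of the iterative haplotig collapse."""

    min_participant_len: int = 600
    min_overlap_frac: float = 0.20
    min_identity: float = 0.95
    seed_k: int = 21
    max_rounds: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must be in (0, 1]")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class CleanConfig:
    """Parameters of the contained-scaffold cleaning pass."""

    max_candidate_len: int = 50_000
    min_identity: float = 0.99
    seed_k: int = 21

    def __post_init__(self) -> None:
        if self.max_candidate_len <= 0:
            raise ValueError("max_candidate_len must be positive")


def _xdrop_extend(match: np.ndarray, s0: int, s1: int) -> tuple[int, int]:
    """Extend seed span [s0, s1) over a boolean match array with X-drop."""
    # right
    best, cur, end = 0, 0, s1
    for i in range(s1, match.size):
        cur += 1 if match[i] else -1
        if cur > best:
            best, end = cur, i + 1
        elif cur < best - _XDROP:
            break
    # left
    best, cur, start = 0, 0, s0
    for i in range(s0 - 1, -1, -1):
        cur += 1 if match[i] else -1
        if cur > best:
            best, start = cur, i
        elif cur < best - _XDROP:
            break
    return start, end


def _best_oriented_hit(
    small: np.ndarray,
    large_index: dict[int, list[int]],
    large: np.ndarray,
    k: int,
    min_identity: float,
) -> tuple[float, float, tuple[int, int], tuple[int, int]] | None:
    """Best gap-free hit of ``small`` (one orientation) against ``large``.

    Returns (frac_small, identity, span_small, span_large) or None.
    """
    codes, _, starts = window_codes(small, k)
    diag_votes: Counter[int] = Counter()
    diag_span: dict[int, list[int]] = {}
    for code, spos in zip(codes.tolist(), starts.tolist()):
        for lpos in large_index.get(code, ()):
            d = lpos - spos
            diag_votes[d] += 1
            span = diag_span.setdefault(d, [spos, spos])
            if spos < span[0]:
                span[0] = spos
            if spos > span[1]:
                span[1] = spos
    if not diag_votes:
        return None
    diag = max(diag_votes, key=lambda d: (diag_votes[d], -abs(d)))

    # window of small positions p with 0 <= p + diag < len(large)
    lo = max(0, -diag)
    hi = min(small.size, large.size - diag)
    if hi <= lo:
        return None
    match = small[lo:hi] == large[lo + diag : hi + diag]

    # containment first: the whole small sequence fits on this diagonal
    if lo == 0 and hi == small.size:
        ident = float(match.mean())
        if ident >= min_identity:
            return 1.0, ident, (0, small.size), (diag, diag + small.size)

    s0, s1 = diag_span[diag]
    s0 = max(s0, lo) - lo
    s1 = min(s1 + k, hi) - lo
    if s1 <= s0:
        return None
    a, b = _xdrop_extend(match, s0, s1)
    if b <= a:
        return None
    ident = float(match[a:b].mean())
    span_small = (lo + a, lo + b)
    span_large = (lo + a + diag, lo + b + diag)
    return (span_small[1] - span_small[0]) / small.size, ident, span_small, span_large


def _pair_hit(
    rec_small: SequenceRecord,
    rec_large: SequenceRecord,
    large_arr: np.ndarray,
    large_index: dict[int, list[int]],
    seed_k: int,
    min_identity: float,
) -> OverlapHit | None:
    small_fwd = encode(rec_small.sequence)
    n = small_fwd.size
    # reverse complement in code space
    small_rc = (np.uint8(3) - small_fwd)[::-1].copy()
    small_rc[small_rc > 3] = 4  # N stays invalid (3 - 4 wraps, reset)

    best: tuple | None = None
    for strand, arr in (("+", small_fwd), ("-", small_rc)):
        hit = _best_oriented_hit(arr, large_index, large_arr, seed_k, min_identity)
        if hit is None:
            continue
        frac, ident, span_s, span_l = hit
        if strand == "-":
            span_s = (n - span_s[1], n - span_s[0])
        key = (frac, ident)
        if best is None or key > (best[0], best[1]):
            best = (frac, ident, span_s, span_l, strand)
    if best is None:
        return None
    frac, ident, span_s, span_l, strand = best
    if ident < min_identity:
        return None
    return OverlapHit(
        id_small=rec_small.id,
        id_large=rec_large.id,
        span_small=span_s,
        span_large=span_l,
        identity=ident,
        frac_small=frac,
        contained=frac >= 1.0,
        strand=strand,
    )


def _build_index(arr: np.ndarray, k: int) -> dict[int, list[int]]:
    codes, _, starts = window_codes(arr, k)
    index: dict[int, list[int]] = defaultdict(list)
    for code, pos in zip(codes.tolist(), starts.tolist()):
        lst = index[code]
        if len(lst) < _MAX_CODE_OCCURRENCES:
            lst.append(pos)
    return dict(index)


def _candidate_pairs(
    records: list[SequenceRecord], k: int, min_shared: int = 3
) -> list[tuple[int, int]]:
    """Unordered record-index pairs sharing at least ``min_shared`` seed codes."""
    owners: dict[int, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        codes, _ = canonical_window_codes(encode(rec.sequence), k)
        for code in np.unique(codes).tolist():
            lst = owners[code]
            if len(lst) <= _MAX_CODE_RECORDS:
                lst.append(i)
    shared: Counter[tuple[int, int]] = Counter()
    for members in owners.values():
        if len(members) < 2 or len(members) > _MAX_CODE_RECORDS:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                shared[(members[a], members[b])] += 1
    return [pair for pair, cnt in shared.items() if cnt >= min_shared]


def find_overlaps(
    records: list[SequenceRecord],
    seed_k: int = 21,
    min_identity: float = 0.95,
) -> list[OverlapHit]:
    """All-vs-all overlap detection; at most one (best) hit per unordered pair.

    For each pair the shorter sequence plays the query on both strands; ties
    in length are broken so the lexicographically earlier id is the "large"
    side, keeping output deterministic.
    """
    if len(records) < 2:
        return []
    by_pos = {i: rec for i, rec in enumerate(records)}
    arrays: dict[int, np.ndarray] = {}
    indexes: dict[int, dict[int, list[int]]] = {}
    hits: list[OverlapHit] = []
    for i, j in sorted(_candidate_pairs(records, seed_k)):
        a, b = by_pos[i], by_pos[j]
        if (len(a), b.id) < (len(b), a.id):  # a is smaller (tie -> later id is small)
            small, large, li = a, b, j
        else:
            small, large, li = b, a, i
        if li not in arrays:
            arrays[li] = encode(by_pos[li].sequence)
            indexes[li] = _build_index(arrays[li], seed_k)
        hit = _pair_hit(small, large, arrays[li], indexes[li], seed_k, min_identity)
        if hit is not None:
            hits.append(hit)
    return hits


@dataclass
class DedupResult:
    """Outcome of a redundancy-removal pass: kept + removed = input."""

    kept: list[SequenceRecord]
    removed: pd.DataFrame  # id, length, removed_by, frac_small, identity, round
    rounds: int = 1
    converged: bool = True
    nonparticipants: list[str] = field(default_factory=list)

    @property
    def removed_records(self) -> list[str]:
        return self.removed["id"].tolist()


_REMOVED_COLUMNS = ["id", "length", "removed_by", "frac_small", "identity", "round"]


def collapse_haplotigs(
    records: list[SequenceRecord], cfg: CollapseConfig | None = None
) -> DedupResult:
    """Iteratively remove the smaller contig of every qualifying overlap.

    A pair qualifies when at least ``min_overlap_frac`` of the smaller contig
    aligns to the larger at ``min_identity`` or better (the 20% boundary is
    inclusive).  Within a round all removals are decided against the
    round-start contig set, so the outcome is order-independent; rounds
    repeat until none removes anything.  Contigs at or below
    ``min_participant_len`` never participate but are retained in the output
    and listed in ``nonparticipants``.
    """
    cfg = cfg or CollapseConfig()
    current = list(records)
    removed_rows: list[tuple] = []
    rounds = 0
    converged = False
    while rounds < cfg.max_rounds:
        rounds += 1
        participants = [r for r in current if len(r) > cfg.min_participant_len]
        hits = find_overlaps(participants, cfg.seed_k, cfg.min_identity)
        doomed: dict[str, tuple] = {}
        for h in hits:
            if h.frac_small >= cfg.min_overlap_frac and h.identity >= cfg.min_identity:
                prev = doomed.get(h.id_small)
                if prev is None or (h.frac_small, h.identity) > (prev[3], prev[4]):
                    doomed[h.id_small] = (
                        h.id_small,
                        None,
                        h.id_large,
                        h.frac_small,
                        h.identity,
                        rounds,
                    )
        if not doomed:
            converged = True
            break
        lengths = {r.id: len(r) for r in current}
        for rid, row in doomed.items():
            removed_rows.append((rid, lengths[rid], *row[2:]))
        current = [r for r in current if r.id not in doomed]
    removed = pd.DataFrame(removed_rows, columns=_REMOVED_COLUMNS)
    nonparticipants = [r.id for r in current if len(r) <= cfg.min_participant_len]
    return DedupResult(
        kept=current,
        removed=removed,
        rounds=rounds,
        converged=converged,
        nonparticipants=nonparticipants,
    )


def clean_scaffolds(
    records: list[SequenceRecord], cfg: CleanConfig | None = None
) -> DedupResult:
    """Remove scaffolds completely contained in a longer, nearly identical one.

    Single pass: a scaffold is removed iff it is shorter than
    ``max_candidate_len``, its entire length aligns within a strictly longer
    scaffold, and the alignment identity is at least ``min_identity``.
    """
    cfg = cfg or CleanConfig()
    hits = find_overlaps(records, cfg.seed_k, cfg.min_identity)
    lengths = {r.id: len(r) for r in records}
    doomed: dict[str, tuple] = {}
    for h in hits:
        if (
            h.contained
            and h.identity >= cfg.min_identity
            and lengths[h.id_small] < cfg.max_candidate_len
            and lengths[h.id_small] < lengths[h.id_large]
        ):
            prev = doomed.get(h.id_small)
            if prev is None or h.identity > prev[4]:
                doomed[h.id_small] = (
                    h.id_small,
                    lengths[h.id_small],
                    h.id_large,
                    h.frac_small,
                    h.identity,
                    1,
                )
    kept = [r for r in records if r.id not in doomed]
    removed = pd.DataFrame(list(doomed.values()), columns=_REMOVED_COLUMNS)
    return DedupResult(kept=kept, removed=removed, rounds=1, converged=True)
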