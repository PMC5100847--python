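"""Assembly summary statistics: N50 against a stated genome size, scaffold
count/total/mean tables, gap (N-run) accounting, GC content and repeat-mask
percentage summaries.

Two deliberate reporting conventions:

* mean scaffold size truncates (floor), it does not round — the convention
  used in draft-genome report tables;
* percentages round half-up to two decimals, so 10.4446% prints as 10.44
  and 6.3397% as 6.34.

The N50 here takes an *external* genome size G (what some communities call
NG50): the largest length L such that scaffolds of length >= L together
cover at least G/2.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .records import SequenceRecord

logger = logging.getLogger(__name__)


def n50(lengths: Sequence[int], genome_size: int) -> int:
    """Length at which the descending running sum first reaches genome_size/2.

    Returns 0 (with a warning) when the assembly covers less than half the
    stated genome size.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if not lengths:
        raise ValueError("lengths must be non-empty")
    half = genome_size / 2
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if running >= half:
            return int(length)
    logger.warning(
        "n50: total assembly length %d is below half the genome size %d",
        running,
        genome_size,
    )
    return 0


def mean_size(total_bp: int, count: int) -> int:
    """Mean sequence size, truncated to an integer (floor division)."""
    if count <= 0:
        raise ValueError("count must be positive")
    return total_bp // count


def percent_of(part_bp: int, total_bp: int, decimals: int = 2) -> float:
    """Percentage of ``total_bp``, rounded half-up to ``decimals`` places."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100 * part_bp) / Decimal(total_bp)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def scaffold_stats(
    assembly: Iterable[SequenceRecord] | Sequence[int],
    thresholds: Sequence[int] = (0, 2000),
    genome_size: int = 0,
) -> pd.DataFrame:
    """One summary row per minimum-length threshold.

    Columns: ``subset, count, total_bp, n50_bp, mean_bp``; N50 is computed
    against ``genome_size`` over the subset's lengths.
    """
    lengths = [
        len(x) if isinstance(x, SequenceRecord) else int(x) for x in assembly
    ]
    if not lengths:
        raise ValueError("assembly must be non-empty")
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    rows = []
    for t in thresholds:
        sub = [x for x in lengths if x >= t]
        label = "All scaffolds" if t <= 0 else f"Scaffolds >= {t} bp"
        if not sub:
            rows.append((label, 0, 0, 0, 0))
            continue
        total = sum(sub)
        rows.append((label, len(sub), total, n50(sub, genome_size), mean_size(total, len(sub))))
    return pd.DataFrame(rows, columns=["subset", "count", "total_bp", "n50_bp", "mean_bp"])


def gap_stats(assembly: Iterable[SequenceRecord]) -> tuple[int, int, int]:
    """Count maximal N-runs: returns (run count, total N bp, total non-N bp)."""
    runs = 0
    n_bp = 0
    total = 0
    for rec in assembly:
        seq = rec.sequence
        total += len(seq)
        in_run = False
        for c in seq:
            if c == "N":
                n_bp += 1
                if not in_run:
                    runs += 1
                    in_run = True
            else:
                in_run = False
    return runs, n_bp, total - n_bp


def gc_content(assembly: Iterable[SequenceRecord]) -> float:
    """GC fraction over non-N bases: (G + C) / (A + C + G + T)."""
    gc = 0
    acgt = 0
    for rec in assembly:
        seq = rec.sequence
        gc += seq.count("G") + seq.count("C")
        acgt += len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("no non-N bases in assembly")
    return gc / acgt


def _union_bp(intervals: list[tuple[str, int, int]]) -> int:
    """Total bases covered by the union of (chrom, start, end) intervals."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def mask_summary(mask: pd.DataFrame, assembly_total: int) -> pd.DataFrame:
    """Per-class masked-base summary with a TOTAL row over all classes.

    ``mask`` needs columns ``chrom, start, end`` and a class label column
    (``name``).  Overlapping intervals within a class are unioned, never
    double-counted; the TOTAL row unions across classes.  Percentages are
    of ``assembly_total``, rounded half-up to 2 decimals.
    """
    if assembly_total <= 0:
        raise ValueError("assembly_total must be positive")
    label_col = "name" if "name" in mask.columns else "class"
    rows = []
    all_ivs: list[tuple[str, int, int]] = []
    for label, group in mask.groupby(label_col, sort=True):
        ivs = list(zip(group["chrom"], group["start"].astype(int), group["end"].astype(int)))
        bp = _union_bp(ivs)
        rows.append((label, len(group), bp, percent_of(bp, assembly_total)))
        all_ivs.extend(ivs)
    total_bp = _union_bp(all_ivs) if all_ivs else 0
    rows.append(("TOTAL", len(mask), total_bp, percent_of(total_bp, assembly_total)))
    return pd.DataFrame(rows, columns=["class", "n_elements", "bp_occupied", "percent"])
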