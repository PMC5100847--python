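"""Read-depth computation and coverage-bimodality classification.

In an assembly of a heterozygous diploid, contigs that represent a single
haplotype of a region attract roughly half the read depth of contigs
representing a collapsed (homozygous) region, because the reads of the
other haplotype map elsewhere.  The per-region mean-depth distribution is
therefore bimodal at 0.5x and 1x of the expected depth, and that
bimodality drives three estimators here:

* :func:`classify_coverage` — haplotig vs collapsed labels per contig;
* :func:`estimate_size_from_coverage` — genome size as half the haplotig
  length plus the full collapsed length;
* :func:`classify_duplicate_genes` — for genes present twice in the
  assembly, split-haplotype (0.5x) vs true duplicate (1x) calls.

Mapping is a lightweight k-mer vote scheme, not a full aligner: each read
is assigned to the contig sharing the most seed k-mers, which is adequate
because every estimator downstream consumes only mean depth ratios.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import canonical_window_codes, encode
from .records import ReadRecord, SequenceRecord

logger = logging.getLogger(__name__)

HAPLOID_LEVEL = "HAPLOID_LEVEL"
DIPLOID_LEVEL = "DIPLOID_LEVEL"
SPLIT_HAPLOTYPE = "SPLIT_HAPLOTYPE"
TRUE_DUPLICATE = "TRUE_DUPLICATE"


@dataclass
class DepthProfile:
    """Per-base depth arrays per contig, plus mapping bookkeeping."""

    depth: dict[str, np.ndarray]
    assigned: int = 0
    unmapped: int = 0
    ambiguous: int = 0

    def total_depth(self) -> int:
        return int(sum(a.sum() for a in self.depth.values()))


def pseudo_map(
    reads: list[ReadRecord],
    contigs: list[SequenceRecord],
    seed_k: int = 21,
    min_votes: int = 3,
) -> DepthProfile:
    """Assign each read to the contig sharing the most seed k-mers.

    Votes are canonical k-mer matches, so orientation is free.  Reads with
    fewer than ``min_votes`` matches anywhere stay unmapped; reads whose top
    two contigs tie are discarded as ambiguous.  Depth is incremented over
    the read span inferred from the seed diagonals, clipped to contig bounds.
    """
    index: dict[int, list[tuple[int, int]]] = defaultdict(list)
    names = [c.id for c in contigs]
    lengths = [len(c) for c in contigs]
    for ci, contig in enumerate(contigs):
        codes, starts = canonical_window_codes(encode(contig.sequence), seed_k)
        for code, pos in zip(codes.tolist(), starts.tolist()):
            lst = index[code]
            if len(lst) < 8:
                lst.append((ci, pos))
    index = dict(index)

    depth = {c.id: np.zeros(len(c), dtype=np.int32) for c in contigs}
    profile = DepthProfile(depth=depth)

    for read in reads:
        codes, starts = canonical_window_codes(encode(read.sequence), seed_k)
        votes: dict[int, int] = defaultdict(int)
        positions: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for code, rpos in zip(codes.tolist(), starts.tolist()):
            entry = index.get(code)
            if not entry:
                continue
            seen = set()
            for ci, cpos in entry:
                if ci in seen:
                    continue
                seen.add(ci)
                votes[ci] += 1
                positions[ci].append((rpos, cpos))
        if not votes:
            profile.unmapped += 1
            continue
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][1] < min_votes:
            profile.unmapped += 1
            continue
        if len(ranked) > 1 and ranked[1][1] == ranked[0][1]:
            profile.ambiguous += 1
            continue
        ci = ranked[0][0]
        pairs = positions[ci]
        # strand from diagonal consistency: forward -> cpos - rpos constant
        fwd_diags = [c - r for r, c in pairs]
        rev_diags = [c + r for r, c in pairs]
        if _spread(fwd_diags) <= _spread(rev_diags):
            start = int(np.median(fwd_diags))
        else:
            start = int(np.median(rev_diags)) - (len(read) - seed_k)
        lo = max(0, start)
        hi = min(lengths[ci], start + len(read))
        if hi > lo:
            depth[names[ci]][lo:hi] += 1
            profile.assigned += 1
        else:
            profile.unmapped += 1

    if profile.unmapped or profile.ambiguous:
        logger.info(
            "pseudo_map: %d assigned, %d unmapped, %d ambiguous",
            profile.assigned,
            profile.unmapped,
            profile.ambiguous,
        )
    return profile


def _spread(values: list[int]) -> int:
    return max(values) - min(values) if values else 0


def mean_depth(
    profile: DepthProfile, regions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean per-base depth per region (whole contigs when no regions given).

    ``regions`` follows the BED3(+name) frame from :func:`hapspec.seqio.read_bed3`;
    a region out of contig bounds raises a ``ValueError`` naming it.
    Returns a frame with columns ``region, length, mean_depth``.
    """
    rows = []
    if regions is None:
        for cid, arr in profile.depth.items():
            rows.append((cid, arr.size, float(arr.mean()) if arr.size else 0.0))
    else:
        for _, row in regions.iterrows():
            cid, start, end = row["chrom"], int(row["start"]), int(row["end"])
            name = row.get("name") or f"{cid}:{start}-{end}"
            if cid not in profile.depth:
                raise ValueError(f"region {name}: unknown contig {cid!r}")
            arr = profile.depth[cid]
            if start < 0 or end > arr.size or end <= start:
                raise ValueError(
                    f"region {name}: [{start}, {end}) out of bounds for "
                    f"{cid!r} (length {arr.size})"
                )
            rows.append((name, end - start, float(arr[start:end].mean())))
    return pd.DataFrame(rows, columns=["region", "length", "mean_depth"])


@dataclass
class BimodalClassification:
    """HAPLOID_LEVEL / DIPLOID_LEVEL labels against an expected depth."""

    expected_depth: float
    threshold: float
    table: pd.DataFrame = field(repr=False)  # region, length, mean_depth, label

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("region")["label"]

    def summary(self) -> str:
        n_hap = int((self.table["label"] == HAPLOID_LEVEL).sum())
        n_dip = len(self.table) - n_hap
        return (
            f"Coverage classification: expected depth {self.expected_depth:g}x, "
            f"threshold {self.threshold:g}x; {n_hap} haploid-level, "
            f"{n_dip} diploid-level regions"
        )


def classify_coverage(
    table: pd.DataFrame,
    expected_depth: float,
    threshold: float | None = None,
    refine: bool = False,
) -> BimodalClassification:
    """Label regions haploid-level (mean depth < threshold) or diploid-level.

    The default threshold is 0.75x the expected depth — the midpoint of the
    0.5x and 1x modes — with strict-below semantics.  With ``refine`` the
    threshold moves to the empirical valley between the two modes when both
    are detectable in the data.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be > 0")
    t = threshold if threshold is not None else 0.75 * expected_depth
    if refine:
        t = _refined_threshold(table["mean_depth"].to_numpy(), expected_depth, t)
    out = table.copy()
    out["label"] = np.where(out["mean_depth"] < t, HAPLOID_LEVEL, DIPLOID_LEVEL)
    return BimodalClassification(expected_depth=expected_depth, threshold=t, table=out)


def _refined_threshold(means: np.ndarray, d: float, default: float) -> float:
    """Move the cut to the empirical valley between the 0.5x and 1x modes."""
    sel = means[(means > 0.25 * d) & (means < 1.25 * d)]
    if sel.size < 10:
        return default
    hist, edges = np.histogram(sel, bins=24)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo_mode = hist[centers < 0.75 * d]
    hi_mode = hist[centers >= 0.75 * d]
    if lo_mode.size == 0 or hi_mode.size == 0 or not lo_mode.any() or not hi_mode.any():
        return default
    i_lo = int(np.argmax(np.where(centers < 0.75 * d, hist, -1)))
    i_hi = int(np.argmax(np.where(centers >= 0.75 * d, hist, -1)))
    if i_hi <= i_lo + 1:
        return default
    valley = i_lo + 1 + int(np.argmin(hist[i_lo + 1 : i_hi]))
    return float(centers[valley])


def estimate_size_from_coverage(classification: BimodalClassification) -> float:
    """Genome size = half the haploid-level length + the diploid-level length.

    Haploid-level regions are haplotigs, two per genomic locus, so their
    total length double-counts the genome and is halved.
    """
    t = classification.table
    hap_len = int(t.loc[t["label"] == HAPLOID_LEVEL, "length"].sum())
    dip_len = int(t.loc[t["label"] == DIPLOID_LEVEL, "length"].sum())
    return 0.5 * hap_len + dip_len


@dataclass
class DuplicateCall:
    """Split-haplotype vs true-duplicate calls over two-copy genes."""

    expected_depth: float
    threshold: float
    table: pd.DataFrame = field(repr=False)  # gene, mean_depth, label
    excluded: list[str] = field(default_factory=list)

    @property
    def fraction_true_duplicate(self) -> float:
        if len(self.table) == 0:
            return float("nan")
        return float((self.table["label"] == TRUE_DUPLICATE).mean())

    def summary(self) -> str:
        return (
            f"Two-copy genes: {len(self.table)} called, "
            f"{100 * self.fraction_true_duplicate:.1f}% in the 1x (true-duplicate) "
            f"peak at threshold {self.threshold:g}x"
        )


def classify_duplicate_genes(
    table: pd.DataFrame,
    expected_depth: float,
    copy_counts: dict[str, int] | pd.Series | None = None,
) -> DuplicateCall:
    """Classify two-copy genes by read depth: 0.5x = split haplotype, 1x = true duplicate.

    ``table`` needs columns ``gene`` and ``mean_depth`` (one row per gene
    copy or per gene; copies are averaged).  Copy counts come from
    ``copy_counts`` or a ``copy_count`` column; genes without exactly two
    copies are excluded with a warning.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be > 0")
    df = table.copy()
    if "gene" not in df.columns:
        raise ValueError("table must have a 'gene' column")
    if copy_counts is not None:
        cc = pd.Series(copy_counts)
        df["copy_count"] = df["gene"].map(cc)
    if "copy_count" not in df.columns:
        df["copy_count"] = df.groupby("gene")["gene"].transform("size")
    per_gene = df.groupby("gene").agg(
        mean_depth=("mean_depth", "mean"), copy_count=("copy_count", "first")
    )
    excluded = per_gene.index[per_gene["copy_count"] != 2].tolist()
    if excluded:
        logger.warning(
            "classify_duplicate_genes: excluded %d genes without exactly 2 copies",
            len(excluded),
        )
    called = per_gene[per_gene["copy_count"] == 2].reset_index()
    t = 0.75 * expected_depth
    called["label"] = np.where(
        called["mean_depth"] < t, SPLIT_HAPLOTYPE, TRUE_DUPLICATE
    )
    return DuplicateCall(
        expected_depth=expected_depth,
        threshold=t,
        table=called[["gene", "mean_depth", "label"]],
        excluded=excluded,
    )


def median_expected_depth(table: pd.DataFrame, min_length: int = 5_000) -> float:
    """Estimate the expected (diploid-level) depth as the median of long regions."""
    sel = table.loc[table["length"] >= min_length, "mean_depth"]
    if sel.empty:
        sel = table["mean_depth"]
    return float(sel.median())
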