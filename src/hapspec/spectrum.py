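"""K-mer spectrum profiling of a diploid genome.

The multiplicity histogram of the k-mers in a deep read set from a
heterozygous diploid shows three features: an error spike at multiplicity
~1 (each sequencing error spawns a near-unique word), a "haploid" peak at
the per-haplotype coverage depth c1 (words unique to one haplotype because
of heterozygosity), and a "diploid" peak at c2 ~ 2*c1 (words shared by both
haplotypes, plus repeats at higher multiples).

From a fitted spectrum two quantities follow:

* genome size: the summation M1/c1 + M2/c2, where M1 is the k-mer mass
  (instances, not distinct words) between the error cutoff and the valley
  separating the two peaks, and M2 is all remaining non-error mass; repeat
  mass sits in M2 and is divided by the diploid depth, so repeats count by
  copy number.  A haploid-consistent variant halves the haploid-peak
  component (see :class:`GenomeSizeEstimate`).
* heterozygosity      H = (M1/c1) / (2 k G), a first-order model: an
  isolated SNP makes the k words covering it unique to each haplotype,
  2k haplotype-private distinct words per het site, and M1/c1 estimates the
  number of haplotype-private distinct words.  SNPs closer than k overlap
  their windows, so the estimator is biased slightly downward at high H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import MAX_K, multiplicity_histogram
from .records import KmerHistogram, ReadRecord

MULTIPLICITY_CAP = 10_000


class SpectrumError(ValueError):
    """The histogram does not carry the expected coverage signal."""


def count_kmers(
    reads: list[ReadRecord] | list[str], k: int = 21, canonical: bool = True
) -> KmerHistogram:
    """Count k-mers in a read set and return the multiplicity histogram.

    Every k-length window free of N contributes one count; with
    ``canonical`` the window and its reverse complement collapse to one key.
    Multiplicities above 10,000 accumulate in the cap bin.
    """
    if not reads:
        raise ValueError("reads must be non-empty")
    if k % 2 == 0 or not 3 <= k <= MAX_K:
        raise ValueError(f"k must be odd and in [3, {MAX_K}], got {k}")
    seqs = [r.sequence if isinstance(r, ReadRecord) else r for r in reads]
    if all(len(s) < k for s in seqs):
        raise ValueError(f"k={k} is longer than every read")
    counts = multiplicity_histogram(seqs, k, canonical=canonical, cap=MULTIPLICITY_CAP)
    return KmerHistogram(counts, k=k, canonical=canonical)


@dataclass
class SpectrumFit:
    """Fitted landmarks and mass partition of a k-mer histogram.

    ``error_cutoff`` (e*) is the first local minimum of the smoothed
    histogram scanning up from multiplicity 1; mass at or below it is
    attributed to sequencing error.  ``c1`` is the haploid-peak depth (absent
    for a homozygous spectrum), ``c2`` the diploid-peak depth, ``valley`` the
    minimum between them.  Masses: ``error_mass`` (m <= e*), ``hap_mass`` M1
    (e* < m <= valley) and ``other_mass`` M2 (m > valley) partition the total
    exactly.
    """

    error_cutoff: int
    c1: int | None
    c2: int
    valley: int
    error_mass: int
    hap_mass: int
    other_mass: int
    k: int | None = None
    smooth_window: int = 5
    histogram: KmerHistogram = field(repr=False, default=None)

    @property
    def total_mass(self) -> int:
        return self.error_mass + self.hap_mass + self.other_mass

    def summary(self) -> str:
        lines = [
            "K-mer spectrum fit",
            "------------------",
            f"word size k          : {self.k if self.k is not None else 'unknown'}",
            f"error cutoff e*      : {self.error_cutoff}",
            f"haploid peak depth c1: {self.c1 if self.c1 is not None else 'absent'}",
            f"diploid peak depth c2: {self.c2}",
            f"valley               : {self.valley}",
            f"error k-mer mass     : {self.error_mass:,}",
            f"haploid-peak mass M1 : {self.hap_mass:,}",
            f"other mass M2        : {self.other_mass:,}",
            f"total k-mers         : {self.total_mass:,}",
        ]
        return "\n".join(lines)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected ends."""
    if window == 1:
        return y.astype(float)
    half = window // 2
    padded = np.pad(y.astype(float), half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _local_maxima(s: np.ndarray, lo: int) -> list[int]:
    """Interior local maxima of s at indices > lo (1-based multiplicities)."""
    peaks = []
    for m in range(max(lo + 1, 1), s.size - 1):
        if s[m] > s[m - 1] and s[m] >= s[m + 1] and s[m] > 0:
            peaks.append(m)
    return peaks


def fit_spectrum(hist: KmerHistogram, smooth_window: int = 5) -> SpectrumFit:
    """Locate the error cutoff, the coverage peaks and the valley.

    The histogram is smoothed with a centered moving average before peak
    calling.  Peak pairing: the global maximum beyond the error cutoff is
    matched with a companion local maximum near twice (or half) its depth;
    a histogram with a single peak is treated as homozygous (M1 = 0, c1
    absent).  A monotone-decreasing histogram has no coverage signal and
    raises :class:`SpectrumError`.
    """
    if not hist.counts:
        raise SpectrumError("empty histogram")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    max_m = hist.max_multiplicity
    dense = np.zeros(max_m + 2)  # index = multiplicity; pad one above
    for m, n in hist.counts.items():
        dense[m] = n

    # error cutoff from the raw histogram: the earliest minimum before the
    # first rise (smoothing would smear the m=1 error spike into neighbours)
    raw = dense[1 : max_m + 1]
    first_rise = None
    for i in range(raw.size - 1):
        if raw[i + 1] > raw[i]:
            first_rise = i
            break
    if first_rise is None:
        raise SpectrumError("monotone-decreasing histogram: no coverage peak")
    e_star = int(np.argmin(raw[: first_rise + 1])) + 1  # multiplicity

    # suppress the error region entirely before peak smoothing
    peak_dense = dense.copy()
    peak_dense[: e_star + 1] = 0
    s = _smooth(peak_dense[1:], smooth_window)  # s[i] = smoothed n(i + 1)

    def smoothed(m: int) -> float:
        return s[m - 1]

    peaks = [m + 1 for m in _local_maxima(s, lo=e_star - 1)]
    peaks = [m for m in peaks if m > e_star]
    if not peaks:
        raise SpectrumError("no coverage peak beyond the error cutoff")

    global_peak = max(peaks, key=smoothed)
    # discard noise bumps: a genuine peak has non-trivial height
    min_height = 0.05 * smoothed(global_peak)
    peaks = [m for m in peaks if smoothed(m) >= min_height]

    def best_in(lo: float, hi: float) -> int | None:
        cands = [m for m in peaks if lo < m <= hi]
        return max(cands, key=smoothed) if cands else None

    companion_hi = best_in(1.5 * global_peak, 3.0 * global_peak)
    companion_lo = best_in(global_peak / 3.0, global_peak / 1.5)

    if companion_hi is not None:
        c1, c2 = global_peak, companion_hi
    elif companion_lo is not None:
        c1, c2 = companion_lo, global_peak
    elif len(peaks) == 1:
        c1, c2 = None, global_peak  # homozygous: single coverage peak
    else:
        c1, c2 = global_peak, min(2 * global_peak, max_m)  # assumed-double fallback

    masses_m = np.arange(1, dense.size - 1)
    mass = masses_m * dense[1:-1]

    if c1 is None:
        valley = e_star
        hap_mass = 0
    else:
        lo, hi = c1, c2
        # interior multiplicities (c1, c2) map to s indices [c1, c2 - 1)
        valley = int(lo + 1 + np.argmin(s[lo : hi - 1])) if hi - 1 > lo else lo
        hap_mass = int(mass[(masses_m > e_star) & (masses_m <= valley)].sum())

    error_mass = int(mass[masses_m <= e_star].sum())
    other_mass = int(mass[masses_m > valley].sum())

    return SpectrumFit(
        error_cutoff=e_star,
        c1=c1,
        c2=int(c2),
        valley=int(valley),
        error_mass=error_mass,
        hap_mass=hap_mass,
        other_mass=other_mass,
        k=hist.k,
        smooth_window=smooth_window,
        histogram=hist,
    )


@dataclass
class GenomeSizeEstimate:
    """Genome size from a spectrum fit.

    ``size`` is the classic summation M1/c1 + M2/c2 (error mass excluded):
    distinct haploid-peak words plus depth-normalised remaining mass.
    Because M1/c1 counts the haplotype-private words of *both* haplotypes
    (an isolated het site contributes k private words per haplotype), that
    sum measures the distinct k-mer content of the diploid, which exceeds
    the haploid size by roughly a factor (2 - e^(-kH)).  ``haploid_size``
    halves the haploid-peak component, (M1/c1)/2 + M2/c2, and is the
    consistent estimator of the haploid genome length; parameter-recovery
    checks and the heterozygosity model use it.
    """

    size: float
    haploid_size: float
    haploid_component: float  # M1 / c1
    other_component: float  # M2 / c2
    method: str = "kmer-spectrum"

    def summary(self) -> str:
        return (
            f"Genome size ({self.method}): {self.size:,.0f} bp summed; "
            f"haploid-consistent {self.haploid_size:,.0f} bp "
            f"(haploid-peak component {self.haploid_component:,.0f}, "
            f"other {self.other_component:,.0f})"
        )


def estimate_genome_size(fit: SpectrumFit) -> GenomeSizeEstimate:
    """Divide haploid-peak mass by c1, all other non-error mass by c2, sum.

    The error mass is excluded entirely.  For a homozygous spectrum
    (M1 = 0) both reported sizes reduce to M2/c2.
    """
    if fit.hap_mass > 0 and fit.c1 is None:
        raise SpectrumError("haploid-peak mass present but haploid depth absent")
    hap_comp = fit.hap_mass / fit.c1 if fit.hap_mass > 0 else 0.0
    other_comp = fit.other_mass / fit.c2
    return GenomeSizeEstimate(
        size=hap_comp + other_comp,
        haploid_size=0.5 * hap_comp + other_comp,
        haploid_component=hap_comp,
        other_component=other_comp,
    )


@dataclass
class HetEstimate:
    """First-order heterozygosity: H = (M1/c1) / (2 k G)."""

    heterozygosity: float
    model: str = "first-order-isolated-snp"

    def summary(self) -> str:
        return f"Heterozygosity ({self.model}): {100 * self.heterozygosity:.2f}%"


def estimate_heterozygosity(fit: SpectrumFit, k: int | None = None) -> HetEstimate:
    """Estimate H assuming each het site contributes 2k haplotype-private words.

    ``k`` defaults to the word size recorded on the fit.  Windows of nearby
    SNPs overlap, so this is a lower bound that tightens as H*k -> 0.
    """
    if k is None:
        k = fit.k
    if k is None:
        raise ValueError("word size k required (not recorded on the fit)")
    G = estimate_genome_size(fit).haploid_size
    if G <= 0:
        raise SpectrumError("genome size is zero; cannot estimate heterozygosity")
    if fit.hap_mass == 0:
        return HetEstimate(0.0)
    hap_words = fit.hap_mass / fit.c1
    return HetEstimate(hap_words / (2.0 * k * G))
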