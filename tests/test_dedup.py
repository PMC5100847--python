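"""Overlap detection and redundancy removal, checked against a full
dynamic-programming local-alignment oracle on desk-size fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

import hapspec as hs
from hapspec._kmers import revcomp
from hapspec.dedup import CleanConfig, CollapseConfig, find_overlaps
from hapspec.records import SequenceRecord

from conftest import mutate, random_seq


# ---------------------------------------------------------------- oracle ---

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -6
_aligner.extend_gap_score = -6


def _oracle_one_strand(small: str, large: str):
    alns = _aligner.align(small, large)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    qspan = aln.aligned[0]
    span = int(qspan[-1][1] - qspan[0][0])
    matches = sum(
        1
        for (qs, qe), (ts, te) in zip(*aln.aligned)
        for a, b in zip(small[qs:qe], large[ts:te])
        if a == b
    )
    cols = sum(qe - qs for qs, qe in aln.aligned[0])
    return span / len(small), matches / cols


def oracle_overlap(small: str, large: str):
    """Best (frac_small, identity) by exhaustive local alignment, both strands."""
    best = None
    for s in (small, revcomp(small)):
        hit = _oracle_one_strand(s, large)
        if hit and (best is None or hit > best):
            best = hit
    return best


def oracle_qualifies(a: SequenceRecord, b: SequenceRecord, min_frac, min_id):
    small, large = (a, b) if (len(a), b.id) < (len(b), a.id) else (b, a)
    hit = oracle_overlap(small.sequence, large.sequence)
    if hit is None:
        return None
    frac, ident = hit
    if frac >= min_frac and ident >= min_id:
        return small.id
    return None


def oracle_collapse_removed(records, cfg: CollapseConfig) -> set[str]:
    """Fixpoint of the removal rule with oracle alignments (simultaneous rounds)."""
    current = list(records)
    removed: set[str] = set()
    for _ in range(cfg.max_rounds):
        parts = [r for r in current if len(r) > cfg.min_participant_len]
        doomed = set()
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                victim = oracle_qualifies(
                    parts[i], parts[j], cfg.min_overlap_frac, cfg.min_identity
                )
                if victim:
                    doomed.add(victim)
        if not doomed:
            break
        removed |= doomed
        current = [r for r in current if r.id not in doomed]
    return removed


def redundant_fixture(seed: int, n_contigs: int = 10):
    """Random contigs with planted containments, partial overlaps and decoys."""
    rng = np.random.default_rng(seed)
    records = []
    base = random_seq(rng, 2_000)
    records.append(SequenceRecord("big0", base))
    # contained copies at 0 or ~1% divergence, some reverse-complemented
    for i in range(3):
        s = int(rng.integers(0, 800))
        ln = int(rng.integers(700, 1_200))
        sub = mutate(rng, base[s : s + ln], rate=float(rng.choice([0.0, 0.01])))
        if rng.random() < 0.5:
            sub = revcomp(sub)
        records.append(SequenceRecord(f"contained{i}", sub))
    # partial overlaps: shared prefix well above the 20% rule, random tail
    for i in range(2):
        ln = int(rng.integers(900, 1_400))
        shared = int(0.5 * ln)
        s = int(rng.integers(0, 400))
        seq = mutate(rng, base[s : s + shared], 0.005) + random_seq(rng, ln - shared)
        records.append(SequenceRecord(f"overlap{i}", seq))
    # unrelated decoys
    for i in range(n_contigs - len(records)):
        records.append(SequenceRecord(f"decoy{i}", random_seq(rng, int(rng.integers(700, 2_000)))))
    return records


# ----------------------------------------------------------------- tests ---


class TestFindOverlaps:
    def test_identical_pair(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 1_000)
        hits = find_overlaps([SequenceRecord("a", seq), SequenceRecord("b", seq)])
        assert len(hits) == 1
        (h,) = hits
        assert h.identity == 1.0 and h.contained and h.frac_small == 1.0

    def test_exact_substring_contained(self):
        rng = np.random.default_rng(1)
        big = random_seq(rng, 2_000)
        small = big[600:1_000]
        hits = find_overlaps([SequenceRecord("A", big), SequenceRecord("B", small)])
        (h,) = hits
        assert h.id_small == "B" and h.contained and h.frac_small == 1.0
        assert h.span_large == (600, 1_000)

    def test_reverse_complement_containment(self):
        rng = np.random.default_rng(2)
        big = random_seq(rng, 2_000)
        small = revcomp(big[300:900])
        (h,) = find_overlaps([SequenceRecord("A", big), SequenceRecord("B", small)])
        assert h.contained and h.strand == "-"

    def test_partial_overlap_fraction_vs_oracle(self):
        rng = np.random.default_rng(3)
        big = random_seq(rng, 2_000)
        # 100-bp shared block in a 500-bp contig, mismatching flanks
        small = random_seq(rng, 200) + big[500:600] + random_seq(rng, 200)
        (h,) = find_overlaps(
            [SequenceRecord("A", big), SequenceRecord("B", small)], min_identity=0.5
        )
        frac_o, ident_o = oracle_overlap(small, big)
        assert h.frac_small == pytest.approx(frac_o, abs=0.05)
        assert h.frac_small == pytest.approx(0.20, abs=0.05)

    def test_no_hit_between_unrelated_sequences(self):
        rng = np.random.default_rng(4)
        recs = [SequenceRecord("a", random_seq(rng, 1_000)),
                SequenceRecord("b", random_seq(rng, 1_000))]
        assert find_overlaps(recs) == []


class TestCollapse:
    def test_identical_equal_length_pair_removes_later_id(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 1_000)
        res = hs.collapse_haplotigs(
            [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        )
        assert [r.id for r in res.kept] == ["a"]
        assert res.removed["id"].tolist() == ["b"]

    def test_twenty_percent_boundary_is_inclusive(self):
        # exactly 200 aligned bp of a 1,000-bp contig: frac_small = 0.200
        rng = np.random.default_rng(6)
        big = random_seq(rng, 3_000)
        block = big[1_000:1_200]
        # flanks that cannot extend the gap-free alignment
        left = "".join("A" if b != "A" else "C" for b in big[600:1_000])
        right = "".join("A" if b != "A" else "C" for b in big[1_200:1_600])
        small = left + block + right
        res = hs.collapse_haplotigs([SequenceRecord("A", big), SequenceRecord("B", small)])
        assert res.removed["id"].tolist() == ["B"]
        assert res.removed["frac_small"].iloc[0] == pytest.approx(0.200, abs=0.01)

    def test_nested_chain_keeps_largest(self):
        rng = np.random.default_rng(7)
        c = random_seq(rng, 3_000)
        b = c[500:2_500]
        a = c[800:1_900]
        res = hs.collapse_haplotigs(
            [SequenceRecord("A", a), SequenceRecord("B", b), SequenceRecord("C", c)]
        )
        assert [r.id for r in res.kept] == ["C"]
        assert res.rounds <= 2 + 1  # fixpoint confirmation round at most

    def test_short_contigs_do_not_participate(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 500)  # below the 600-bp participation floor
        res = hs.collapse_haplotigs(
            [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        )
        assert len(res.kept) == 2
        assert set(res.nonparticipants) == {"a", "b"}

    def test_conservation_and_idempotence(self):
        records = redundant_fixture(seed=9)
        res = hs.collapse_haplotigs(records)
        assert {r.id for r in res.kept} | set(res.removed["id"]) == {r.id for r in records}
        assert not (set(res.removed["id"]) & {r.id for r in res.kept})
        again = hs.collapse_haplotigs(res.kept)
        assert len(again.removed) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_decisions_match_alignment_oracle(self, seed):
        records = redundant_fixture(seed=100 + seed)
        cfg = CollapseConfig()
        res = hs.collapse_haplotigs(records, cfg)
        assert set(res.removed["id"]) == oracle_collapse_removed(records, cfg)

    def test_split_assembly_collapses_to_haploid_length(self):
        truth = hs.simulate_diploid(
            hs.DiploidSimConfig(genome_length=60_000, heterozygosity=0.0125, seed=40)
        )
        contigs, labels = hs.simulate_assembly(
            truth, hs.AssemblySimConfig(mean_fragment=5_000, split_probability=1.0, seed=41)
        )
        res = hs.collapse_haplotigs(contigs)
        kept_len = sum(len(r) for r in res.kept)
        assert abs(kept_len / truth.haploid_length - 1) <= 0.10
        # >= 90% of participating split pairs reduced to one member
        # (contigs at or below the 600-bp floor are retained by design)
        pairs = labels[labels["length"] > 600].groupby(["start", "end"]).filter(
            lambda g: len(g) == 2
        )
        kept_ids = {r.id for r in res.kept}
        reduced = sum(
            1
            for _, g in pairs.groupby(["start", "end"])
            if len(set(g["id"]) & kept_ids) == 1
        )
        assert reduced / (len(pairs) // 2) >= 0.90


class TestClean:
    def test_contained_short_scaffold_removed(self):
        rng = np.random.default_rng(10)
        big = random_seq(rng, 60_000)
        small = big[20_000:30_000]
        res = hs.clean_scaffolds([SequenceRecord("big", big), SequenceRecord("small", small)])
        assert res.removed["id"].tolist() == ["small"]

    def test_candidate_length_boundary_exclusive(self):
        rng = np.random.default_rng(11)
        big = random_seq(rng, 120_000)
        small = big[10_000:60_000]  # exactly 50 kb: not "shorter than 50 kb"
        res = hs.clean_scaffolds([SequenceRecord("big", big), SequenceRecord("small", small)])
        assert len(res.removed) == 0

    def test_low_identity_containment_kept(self):
        rng = np.random.default_rng(12)
        big = random_seq(rng, 20_000)
        small = mutate(rng, big[5_000:10_000], rate=0.10)  # identity ~0.90 < 0.99
        res = hs.clean_scaffolds([SequenceRecord("big", big), SequenceRecord("small", small)])
        assert len(res.removed) == 0

    def test_conservation(self):
        records = redundant_fixture(seed=13)
        res = hs.clean_scaffolds(records, CleanConfig(min_identity=0.99))
        assert {r.id for r in res.kept} | set(res.removed["id"]) == {r.id for r in records}
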