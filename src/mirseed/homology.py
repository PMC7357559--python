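"""Homology search: map reference pre-miRNAs onto a genome.

The scan is an exact k-mer seeded, ungapped comparison evaluated on every
candidate diagonal (seed diagonal +- ``shift``), both strands.  Percent
identity is computed over the full precursor length; under the
gaps-count-as-mismatches scoring of the banded model, the best placement is
always one of the shifted ungapped diagonals, so the scan is equivalent to a
brute-force slide of each precursor over every genome position at the same
identity floor (a property the test suite checks).

Sensitivity note: a hit with m mismatches over length L is guaranteed to be
seeded only when k <= L // (m + 1); :func:`guaranteed_k` computes the largest
such k for a given identity floor.

Candidate filtering applies the three homology criteria: full-length
similarity > 93%, at most one seed-region (positions 2-8) mismatch and at
most two non-seed mismatches per annotated mature arm, and one reference per
genomic locus (paralogous loci of one reference are kept).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .types import GenomicInterval, ReferenceMirna, SequenceRecord, dna, revcomp

#: seed region of a mature miRNA: positions 2-8, 1-based, 5'->3'
SEED_START = 2
SEED_END = 8


@dataclass
class RawHit:
    """An ungapped full-length placement of a reference precursor."""

    ref: ReferenceMirna
    locus: GenomicInterval
    genome_subseq: str  # genome slice, revcomp'd on '-', DNA alphabet, 5'->3' of the ref
    similarity_pct: float


@dataclass
class CandidateLocus:
    ref: ReferenceMirna
    locus: GenomicInterval
    genome_subseq: str
    similarity_pct: float
    seed_mm_5p: Optional[int] = None
    nonseed_mm_5p: Optional[int] = None
    seed_mm_3p: Optional[int] = None
    nonseed_mm_3p: Optional[int] = None

    def mature_subseq(self, arm: str) -> Optional[str]:
        """Genome sub-sequence under the reference's mature-arm span."""
        a = self.ref.mature5p if arm == "5p" else self.ref.mature3p
        if a is None:
            return None
        return self.genome_subseq[a.start - 1 : a.end]


def percent_identity(ref_seq: str, genome_subseq: str) -> float:
    """100 x matches / alignment length over two equal-length sequences.

    U and T compare equal; N never matches.
    """
    a, b = dna(ref_seq), dna(genome_subseq)
    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return 100.0 * matches / len(a)


def mature_mismatches(ref_mature: str, candidate_mature: str) -> tuple[int, int]:
    """Hamming mismatches in and outside the seed (positions 2-8) of a mature."""
    a, b = dna(ref_mature), dna(candidate_mature)
    if len(a) != len(b):
        raise ValueError(f"mature length mismatch: {len(a)} vs {len(b)}")
    seed_mm = nonseed_mm = 0
    for pos, (x, y) in enumerate(zip(a, b), start=1):
        if x != y or x == "N":
            if SEED_START <= pos <= SEED_END:
                seed_mm += 1
            else:
                nonseed_mm += 1
    return seed_mm, nonseed_mm


def guaranteed_k(min_length: int, min_identity: float) -> int:
    """Largest seed length that cannot miss a hit at the identity floor."""
    max_mm = int(min_length * (1.0 - min_identity / 100.0))
    return max(1, min_length // (max_mm + 1))


def _index_genome(contigs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((chrom, i))
    return index


def scan_genome(
    genome: list[SequenceRecord],
    reference_set: list[ReferenceMirna],
    k: int = 12,
    min_identity: float = 85.0,
    max_hits_per_ref: int = 200,
    shift: int = 3,
) -> list[RawHit]:
    """Seeded full-length scan of every reference precursor, both strands.

    Every placement (diagonal within ``shift`` of a shared exact k-mer) with
    identity >= ``min_identity`` is reported; if a reference exceeds
    ``max_hits_per_ref`` placements, only the highest-identity ones are kept.
    """
    shortest = min(len(r.precursor) for r in reference_set)
    if k > shortest:
        raise ValueError(f"k={k} longer than shortest precursor ({shortest} nt)")
    contigs = {rec.id: dna(rec.sequence) for rec in genome}
    index = _index_genome(contigs, k)

    hits: list[RawHit] = []
    for ref in reference_set:
        prec = dna(ref.precursor)
        L = len(prec)
        found: dict[tuple[str, str, int], RawHit] = {}
        for strand in ("+", "-"):
            query = prec if strand == "+" else revcomp(prec)
            starts: set[tuple[str, int]] = set()
            for off in range(L - k + 1):
                for chrom, gpos in index.get(query[off : off + k], ()):
                    base = gpos - off
                    for d in range(-shift, shift + 1):
                        starts.add((chrom, base + d))
            for chrom, s in starts:
                seq = contigs[chrom]
                if s < 0 or s + L > len(seq):
                    continue
                window = seq[s : s + L]
                subseq = window if strand == "+" else revcomp(window)
                sim = percent_identity(prec, subseq)
                if sim < min_identity:
                    continue
                locus = GenomicInterval(chrom, s + 1, s + L, strand)
                found[(chrom, strand, s)] = RawHit(ref, locus, subseq, sim)
        ordered = sorted(
            found.values(), key=lambda h: (-h.similarity_pct, str(h.locus))
        )[:max_hits_per_ref]
        hits.extend(ordered)
    return hits


def brute_force_scan(
    genome: list[SequenceRecord],
    reference_set: list[ReferenceMirna],
    min_identity: float = 85.0,
) -> list[RawHit]:
    """Slide every precursor over every position and strand (test oracle)."""
    contigs = {rec.id: dna(rec.sequence) for rec in genome}
    hits = []
    for ref in reference_set:
        prec = dna(ref.precursor)
        L = len(prec)
        for chrom, seq in contigs.items():
            for s in range(len(seq) - L + 1):
                window = seq[s : s + L]
                for strand in ("+", "-"):
                    subseq = window if strand == "+" else revcomp(window)
                    sim = percent_identity(prec, subseq)
                    if sim >= min_identity:
                        hits.append(
                            RawHit(ref, GenomicInterval(chrom, s + 1, s + L, strand), subseq, sim)
                        )
    return hits


def _arm_mismatches(hit: RawHit) -> dict[str, tuple[int, int]]:
    out = {}
    for arm, span in hit.ref.arms():
        ref_mat = hit.ref.mature_seq(arm)
        cand_mat = hit.genome_subseq[span.start - 1 : span.end]
        out[arm] = mature_mismatches(ref_mat, cand_mat)
    return out


def _conflicts(a: GenomicInterval, b: GenomicInterval, min_frac: float) -> bool:
    """Two hits compete for one locus: same strand, overlap >= min_frac of the shorter."""
    if a.strand != b.strand or a.chrom != b.chrom:
        return False
    ov = a.overlap_length(b)
    return ov >= min_frac * min(len(a), len(b))


def filter_candidates(
    hits: list[RawHit],
    min_similarity: float = 93.0,
    max_seed_mm: int = 1,
    max_nonseed_mm: int = 2,
    overlap_frac: float = 0.5,
) -> list[CandidateLocus]:
    """Apply the three homology criteria and de-duplicate loci.

    Similarity must strictly exceed ``min_similarity``; every annotated arm
    must show <= ``max_seed_mm`` seed and <= ``max_nonseed_mm`` non-seed
    mismatches.  Overlapping same-strand hits are resolved greedily so each
    locus is assigned to a single reference (highest similarity first, ties
    to the lexicographically smallest reference name); non-overlapping hits
    of one reference all survive (paralogs).
    """
    passing: list[tuple[RawHit, dict[str, tuple[int, int]]]] = []
    for hit in hits:
        if hit.similarity_pct <= min_similarity:
            continue
        arm_mm = _arm_mismatches(hit)
        if any(s > max_seed_mm or n > max_nonseed_mm for s, n in arm_mm.values()):
            continue
        passing.append((hit, arm_mm))

    passing.sort(key=lambda t: (-t[0].similarity_pct, t[0].ref.name, str(t[0].locus)))
    accepted: list[tuple[RawHit, dict[str, tuple[int, int]]]] = []
    for hit, arm_mm in passing:
        if any(_conflicts(hit.locus, acc.locus, overlap_frac) for acc, _ in accepted):
            continue
        accepted.append((hit, arm_mm))

    out = []
    for hit, arm_mm in accepted:
        cand = CandidateLocus(
            ref=hit.ref,
            locus=hit.locus,
            genome_subseq=hit.genome_subseq,
            similarity_pct=hit.similarity_pct,
        )
        if "5p" in arm_mm:
            cand.seed_mm_5p, cand.nonseed_mm_5p = arm_mm["5p"]
        if "3p" in arm_mm:
            cand.seed_mm_3p, cand.nonseed_mm_3p = arm_mm["3p"]
        out.append(cand)
    out.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.locus.strand, c.ref.name))
    return out
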