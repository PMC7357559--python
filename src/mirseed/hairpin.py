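"""Thermodynamic hairpin validation of candidate pre-miRNA loci.

Candidates are extended by 10 nt of genomic flank on each side, folded to
their minimum-free-energy (MFE) secondary structure under the Turner
nearest-neighbor model at 37 degC (ViennaRNA), and accepted as stem-loop
hairpins when (1) every annotated mature arm lies on one arm of the stem
without spanning the terminal loop, (2) no internal loop or bulge in the stem
leaves 6 or more unpaired nucleotides on its larger side, and (3) the MFE is
no more than -15 kcal/mol.  A structurally acceptable candidate is
high-confidence when its reference additionally carries homolog evidence
(annotated in another species, experimental support, or previously reported
in macaque).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import RNA

from .homology import CandidateLocus
from .types import GenomicInterval, SequenceRecord, rna, revcomp

MFE_THRESHOLD = -15.0  # kcal/mol, pass when mfe <= threshold
MAX_BULGE = 6  # pass when the largest one-sided internal loop is < this
DEFAULT_FLANK = 10


@dataclass
class FlankedSequence:
    """A locus sequence with genomic flanks, in RNA alphabet, 5'->3'."""

    sequence: str
    flank5: int  # realized 5' flank length (may be clipped at a contig end)
    flank3: int
    clipped: bool


@dataclass
class FoldResult:
    sequence: str
    dot_bracket: str
    mfe: float  # kcal/mol


@dataclass
class HairpinFeatures:
    """Stem/loop anatomy of a single-hairpin fold (1-based spans)."""

    is_single_hairpin: bool
    arm5p: Optional[tuple[int, int]] = None  # outermost 5' paired base .. innermost
    arm3p: Optional[tuple[int, int]] = None
    loop: Optional[tuple[int, int]] = None
    n_stem_pairs: int = 0
    max_internal_bulge: int = 0


@dataclass
class ValidatedPreMirna:
    candidate: CandidateLocus
    fold: FoldResult
    features: HairpinFeatures
    passes_mature_in_arm: bool
    passes_bulge: bool
    passes_mfe: bool

    @property
    def passes_structure(self) -> bool:
        return self.passes_mature_in_arm and self.passes_bulge and self.passes_mfe

    @property
    def high_confidence(self) -> bool:
        ref = self.candidate.ref
        evidence = (
            ref.annotated_elsewhere
            or ref.experimentally_supported
            or ref.previously_reported_in_macaque
        )
        return self.passes_structure and evidence


def extract_with_flanks(
    genome: list[SequenceRecord] | dict[str, str],
    locus: GenomicInterval,
    flank: int = DEFAULT_FLANK,
) -> FlankedSequence:
    """Locus sequence plus up to ``flank`` nt each side, clipped at contig ends.

    Minus-strand loci are reverse-complemented, so the returned sequence reads
    5'->3' on the transcribed strand; output is RNA alphabet.
    """
    contigs = genome if isinstance(genome, dict) else {r.id: r.sequence for r in genome}
    if locus.chrom not in contigs:
        raise ValueError(f"unknown contig {locus.chrom!r}")
    contig = contigs[locus.chrom]
    if locus.end > len(contig):
        raise ValueError(f"locus {locus} outside contig of length {len(contig)}")
    up = min(flank, locus.start - 1)
    down = min(flank, len(contig) - locus.end)
    raw = contig[locus.start - 1 - up : locus.end + down]
    if locus.strand == "-":
        raw = revcomp(raw)
        up, down = down, up
    return FlankedSequence(rna(raw), up, down, clipped=(up < flank or down < flank))


def fold_mfe(sequence: str) -> FoldResult:
    """Minimum-free-energy structure under the Turner model at 37 degC.

    Accepts RNA (or DNA, mapped T->U) with N treated as unpairable;
    deterministic for a given sequence.
    """
    seq = rna(sequence)
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)}")
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} nt)")
    structure, mfe = RNA.fold_compound(seq).mfe()
    return FoldResult(seq, structure, round(float(mfe), 2))


def pair_table(dot_bracket: str) -> list[Optional[int]]:
    """0-based partner index per position (None if unpaired)."""
    stack: list[int] = []
    partner: list[Optional[int]] = [None] * len(dot_bracket)
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch != ".":
            raise ValueError(f"bad dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return partner


def hairpin_features(fold: FoldResult) -> HairpinFeatures:
    """Anatomy of the fold's stem-loop.

    Structures whose paired positions do not form a single nested chain
    (multiloops, two separate hairpins) are flagged non-hairpin.  For a single
    hairpin, the arms run from the outermost to the innermost paired base on
    each side, ``loop`` is the unpaired span closed by the innermost pair, and
    ``max_internal_bulge`` is the largest number of unpaired nucleotides on
    the larger side of any internal loop or bulge within the stem.
    """
    partner = pair_table(fold.dot_bracket)
    pairs = sorted((i, j) for i, j in enumerate(partner) if j is not None and i < j)
    if not pairs:
        raise ValueError("no stem: structure has no base pairs")

    # single hairpin <=> pairs are totally ordered by nesting:
    # sorted by 5' position, each pair must enclose the next
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            return HairpinFeatures(is_single_hairpin=False, n_stem_pairs=len(pairs))

    outer_i, outer_j = pairs[0]
    inner_i, inner_j = pairs[-1]
    max_bulge = 0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        left = i2 - i1 - 1
        right = j1 - j2 - 1
        max_bulge = max(max_bulge, max(left, right))
    return HairpinFeatures(
        is_single_hairpin=True,
        arm5p=(outer_i + 1, inner_i + 1),
        arm3p=(inner_j + 1, outer_j + 1),
        loop=(inner_i + 2, inner_j),  # 1-based span strictly inside the innermost pair
        n_stem_pairs=len(pairs),
        max_internal_bulge=max_bulge,
    )


def _mature_in_one_arm(
    mature_span: tuple[int, int], features: HairpinFeatures
) -> bool:
    """True if the mature lies wholly 5' or wholly 3' of the terminal loop."""
    if not features.is_single_hairpin or features.loop is None:
        return False
    m_start, m_end = mature_span
    loop_start, loop_end = features.loop
    # the innermost paired bases delimit the two arms
    return m_end < loop_start or m_start > loop_end


def validate_hairpin(
    candidate: CandidateLocus,
    fold: FoldResult,
    features: HairpinFeatures,
    flank5: int = 0,
    mfe_threshold: float = MFE_THRESHOLD,
    max_bulge: int = MAX_BULGE,
) -> ValidatedPreMirna:
    """Apply the three structural criteria to a folded candidate.

    ``flank5`` is the realized 5' flank length of the folded sequence; mature
    spans annotated on the precursor are offset by it.
    """
    mature_ok = True
    for arm, span in candidate.ref.arms():
        mspan = (span.start + flank5, span.end + flank5)
        if not _mature_in_one_arm(mspan, features):
            mature_ok = False
    return ValidatedPreMirna(
        candidate=candidate,
        fold=fold,
        features=features,
        passes_mature_in_arm=mature_ok,
        passes_bulge=features.max_internal_bulge < max_bulge,
        passes_mfe=fold.mfe <= mfe_threshold,
    )


def validate_candidates(
    genome: list[SequenceRecord] | dict[str, str],
    candidates: list[CandidateLocus],
    flank: int = DEFAULT_FLANK,
    mfe_threshold: float = MFE_THRESHOLD,
    max_bulge: int = MAX_BULGE,
) -> list[ValidatedPreMirna]:
    """Fold every candidate with flanks and validate it (pipeline stage)."""
    out = []
    for cand in candidates:
        flanked = extract_with_flanks(genome, cand.locus, flank)
        fold = fold_mfe(flanked.sequence)
        try:
            features = hairpin_features(fold)
        except ValueError:  # all-dot fold: no stem at all
            features = HairpinFeatures(is_single_hairpin=False)
        out.append(
            validate_hairpin(
                cand, fold, features, flank5=flanked.flank5,
                mfe_threshold=mfe_threshold, max_bulge=max_bulge,
            )
        )
    return out


def write_dot_bracket(folds: list[tuple[str, FoldResult]], path) -> None:
    """RNAfold-style output: name, sequence, structure with ``(mfe)`` suffix."""
    with open(path, "w") as fh:
        for name, fold in folds:
            fh.write(f">{name}\n{fold.sequence}\n{fold.dot_bracket} ({fold.mfe:.2f})\n")
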