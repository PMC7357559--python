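"""Shared coordinate and sequence types.

Coordinates are 1-based and inclusive on both ends throughout the package,
with the strand appended when printed (``chr1:128814989-128815918+``).  BED
export is the only place the 0-based half-open convention appears.

Sequences may be stored in DNA (T) or RNA (U) alphabet as read from disk;
every comparison in the package goes through :func:`dna`, which maps U to T,
so the two alphabets are interchangeable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

VALID_STRANDS = ("+", "-")

#: genomic feature classes the annotation model knows about; ``intron`` is
#: deliberately absent — intron space is derived as gene-minus-exon.
FEATURE_CLASSES = ("exon", "UTR", "gene", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


def dna(seq: str) -> str:
    """Uppercase and map U->T so RNA and DNA spellings compare equal."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement; U is complemented like T, output is DNA alphabet."""
    return dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic locus with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 1 <= start <= end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}{self.strand}"

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end<strand>`` notation."""
        body, strand = text[:-1], text[-1]
        chrom, span = body.rsplit(":", 1)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        """Containment irrespective of strand."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_bed(self) -> tuple[str, int, int, str]:
        """(chrom, 0-based start, half-open end, strand)."""
        return (self.chrom, self.start - 1, self.end, self.strand)

    @classmethod
    def from_bed(cls, chrom: str, start0: int, end0: int, strand: str) -> "GenomicInterval":
        return cls(chrom, start0 + 1, end0, strand)


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTUN")
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred scores (already decoded)."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA annotated on one arm of a precursor.

    ``start``/``end`` are 1-based inclusive offsets into the precursor.
    """

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceMirna:
    """A reference precursor with optional mature-arm annotations.

    ``species`` holds the comma-separated set of species in which homologs of
    this miRNA are annotated (used for age assignment); the support flags feed
    the high-confidence evidence rule.
    """

    name: str
    species: str
    precursor: str
    mature5p: Optional[MatureArm] = None
    mature3p: Optional[MatureArm] = None
    experimentally_supported: bool = False
    annotated_elsewhere: bool = False
    previously_reported_in_macaque: bool = False

    def __post_init__(self) -> None:
        if self.mature5p is None and self.mature3p is None:
            raise ValueError(f"reference {self.name!r}: no mature arm annotated")
        for label, arm in (("m5p", self.mature5p), ("m3p", self.mature3p)):
            if arm is None:
                continue
            if arm.start < 1 or arm.end > len(self.precursor) or arm.start > arm.end:
                raise ValueError(
                    f"reference {self.name!r}: {label} span {arm.start}-{arm.end} "
                    f"outside 1-{len(self.precursor)} precursor"
                )

    @property
    def species_list(self) -> list[str]:
        return [s.strip() for s in self.species.split(",") if s.strip()]

    def mature_seq(self, arm: str) -> Optional[str]:
        """Mature sub-sequence for arm '5p' or '3p', in the precursor alphabet."""
        a = self.mature5p if arm == "5p" else self.mature3p
        if a is None:
            return None
        return self.precursor[a.start - 1 : a.end]

    def arms(self) -> list[tuple[str, MatureArm]]:
        out = []
        if self.mature5p is not None:
            out.append(("5p", self.mature5p))
        if self.mature3p is not None:
            out.append(("3p", self.mature3p))
        return out


@dataclass(frozen=True)
class AnnotationFeature:
    interval: GenomicInterval
    feature_class: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature class {self.feature_class!r} not in {FEATURE_CLASSES}"
            )
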