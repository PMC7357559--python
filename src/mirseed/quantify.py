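"""Small-RNA library QC, tag mapping, miRNA assignment and TPM normalization.

A read survives QC unless (in this order) it is an adapter/primer artifact,
has >10% unknown bases, has >50% low-quality bases, or its insert is shorter
than 18 nt; the 3' adapter is trimmed before the length check.  Surviving
reads are collapsed to unique tags, kept only when they match the genome
perfectly over their full length, dropped when any placement overlaps
rRNA/tRNA/snRNA/snoRNA/repeat features or exons, and assigned to mature
miRNAs allowing up to two non-seed mismatches (none in the seed).  A mature
is called expressed when it has >= 10 reads summed over samples and is
detected in >= 3 individuals; expression is normalized to tags per million
clean reads (TPM).

Adapter semantics: a match requires the complete adapter within the read with
at most ``adapter_mm`` (default 2) mismatches; the read is trimmed at the
leftmost such match.  A read is an adapter/primer artifact (rule 1) when its
trimmed insert is empty or itself matches the adapter prefix with at most
``adapter_mm`` mismatches.  Because detection needs the full adapter, these
rules are idempotent; partial adapter overhang at the 3' end of a read is not
trimmed (the read then simply keeps its tail and will fail genome matching).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .homology import SEED_END, SEED_START
from .types import AnnotationFeature, GenomicInterval, ReadRecord, SequenceRecord, dna, revcomp

QC_RULES = ("adapter", "high_n", "low_quality", "too_short")

#: feature classes whose overlap disqualifies a tag from miRNA assignment;
#: UTRs are exonic sequence and are treated like exons here.
DISCARD_CLASSES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "UTR"})


@dataclass
class QcParams:
    min_length: int = 18
    max_n_fraction: float = 0.10
    low_quality_phred: int = 20  # a base is low-quality when its score is below this
    max_low_quality_fraction: float = 0.50
    adapter_mm: int = 2


@dataclass
class QcResult:
    clean: list[ReadRecord]
    tally: dict[str, int]

    @property
    def n_removed(self) -> int:
        return sum(self.tally.values())


@dataclass
class TagPlacements:
    sequence: str
    count: int
    placements: list[GenomicInterval]


@dataclass
class Library:
    sample_id: str
    clean_reads: int
    unique_tags: dict[str, int]
    mapped_tags: list[TagPlacements] = field(default_factory=list)


@dataclass
class MatureRecord:
    """A mature miRNA sequence to quantify against (genome-validated)."""

    name: str
    sequence: str
    precursors: list[str]


@dataclass
class MirnaExpression:
    mature_name: str
    precursor_names: list[str]
    raw_counts: dict[str, int]  # sample -> count
    tpm: dict[str, float] = field(default_factory=dict)
    mean_tpm: float = 0.0

    @property
    def total_count(self) -> int:
        return sum(self.raw_counts.values())

    @property
    def n_detected(self) -> int:
        return sum(1 for c in self.raw_counts.values() if c > 0)


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _find_adapter(seq: str, adapter: str, max_mm: int) -> Optional[int]:
    """Leftmost start of a full-length adapter match (<= max_mm), or None."""
    alen = len(adapter)
    exact = seq.find(adapter)
    # only positions left of an exact occurrence can host an earlier fuzzy match
    limit = exact if exact != -1 else max(0, len(seq) - alen + 1)
    for pos in range(limit):
        mm = 0
        for x, y in zip(seq[pos : pos + alen], adapter):
            if x != y:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return pos
    return exact if exact != -1 else None


def qc_filter(
    reads: Iterable[ReadRecord],
    adapter: str,
    params: QcParams | None = None,
) -> QcResult:
    """Trim 3' adapters and drop reads failing any of the four QC rules.

    The tally attributes each removed read to the first rule that fires, in
    rule order (adapter, high-N, low-quality, too-short).
    """
    params = params or QcParams()
    adapter = dna(adapter)
    if len(adapter) < 8:
        raise ValueError(f"adapter too short ({len(adapter)} nt, need >= 8)")
    clean: list[ReadRecord] = []
    tally = {rule: 0 for rule in QC_RULES}
    for read in reads:
        seq = dna(read.sequence)
        pos = _find_adapter(seq, adapter, params.adapter_mm)
        if pos is not None:
            insert, quals = seq[:pos], read.qualities[:pos]
        else:
            insert, quals = seq, list(read.qualities)
        # rule 1: the read is adapter/primer material
        if not insert or _mismatches(insert, adapter[: len(insert)]) <= params.adapter_mm:
            tally["adapter"] += 1
            continue
        n = len(insert)
        if insert.count("N") / n > params.max_n_fraction:
            tally["high_n"] += 1
            continue
        if sum(1 for q in quals if q < params.low_quality_phred) / n > params.max_low_quality_fraction:
            tally["low_quality"] += 1
            continue
        if n < params.min_length:
            tally["too_short"] += 1
            continue
        clean.append(ReadRecord(read.id, insert, quals))
    return QcResult(clean, tally)


_INDEX_K = 18  # minimum clean-read length, so every tag has a full first k-mer


class GenomeIndex:
    """Exact k-mer index over the contigs; shared across samples."""

    def __init__(self, contigs: dict[str, str], k: int = _INDEX_K):
        self.contigs = {c: dna(s) for c, s in contigs.items()}
        self.k = k
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[i : i + k], []).append((chrom, i))

    def occurrences(self, tag: str) -> list[GenomicInterval]:
        """All perfect full-length placements of a tag, either strand."""
        placements = []
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            if len(query) < self.k:
                continue
            for chrom, i in self.kmers.get(query[: self.k], ()):
                if self.contigs[chrom][i : i + len(query)] == query:
                    placements.append(
                        GenomicInterval(chrom, i + 1, i + len(query), strand)
                    )
        return placements


def collapse_and_map(
    sample_id: str,
    clean_reads: Sequence[ReadRecord],
    genome: list[SequenceRecord] | dict[str, str] | GenomeIndex,
) -> Library:
    """Collapse identical reads to tags and keep perfect full-length matches.

    Multi-mapping tags retain every placement.  Tags shorter than the index
    k-mer (18 nt, the minimum clean-read length) cannot be placed.
    """
    if isinstance(genome, GenomeIndex):
        index = genome
    else:
        contigs = genome if isinstance(genome, dict) else {r.id: r.sequence for r in genome}
        index = GenomeIndex(contigs)
    counts = Counter(dna(r.sequence) for r in clean_reads)
    mapped = []
    for tag, count in sorted(counts.items()):
        placements = index.occurrences(tag)
        if placements:
            mapped.append(TagPlacements(tag, count, placements))
    return Library(
        sample_id=sample_id,
        clean_reads=len(clean_reads),
        unique_tags=dict(counts),
        mapped_tags=mapped,
    )


def classify_annotation(
    tags: Sequence[TagPlacements],
    annotations: Sequence[AnnotationFeature],
) -> list[TagPlacements]:
    """Drop tags with any placement overlapping structural RNA, repeats or exons."""
    filtering = [f for f in annotations if f.feature_class in DISCARD_CLASSES]
    by_chrom: dict[str, list[AnnotationFeature]] = {}
    for f in filtering:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    kept = []
    for tag in tags:
        discard = any(
            p.overlaps(f.interval)
            for p in tag.placements
            for f in by_chrom.get(p.chrom, ())
        )
        if not discard:
            kept.append(tag)
    return kept


def _tag_matches_mature(
    tag: str, mature: str, max_len_diff: int = 2, max_nonseed_mm: int = 2
) -> bool:
    """5'-anchored comparison: seed (2-8) exact, <= 2 non-seed mismatches,
    length within +-2 nt of the mature (3' trimming tolerance)."""
    if abs(len(tag) - len(mature)) > max_len_diff:
        return False
    n = min(len(tag), len(mature))
    if n < SEED_END:
        return False
    seed_mm = nonseed_mm = 0
    for pos in range(1, n + 1):
        if tag[pos - 1] != mature[pos - 1]:
            if SEED_START <= pos <= SEED_END:
                seed_mm += 1
            else:
                nonseed_mm += 1
    return seed_mm == 0 and nonseed_mm <= max_nonseed_mm


def assign_reads_to_mirnas(
    libraries: Sequence[Library],
    matures: Sequence[MatureRecord],
    kept_tags: Optional[dict[str, list[TagPlacements]]] = None,
) -> list[MirnaExpression]:
    """Count tags per mature miRNA per sample.

    ``kept_tags`` maps sample_id to its annotation-filtered tag list; when
    omitted, each library's mapped tags are used unfiltered.  A tag is counted
    once per distinct mature name it matches; matures sharing one name (the
    same sequence from several precursors) form a single record listing all
    precursors.
    """
    merged: dict[str, MatureRecord] = {}
    for m in matures:
        if m.name in merged:
            merged[m.name].precursors = sorted(set(merged[m.name].precursors) | set(m.precursors))
        else:
            merged[m.name] = MatureRecord(m.name, dna(m.sequence), list(m.precursors))

    samples = [lib.sample_id for lib in libraries]
    counts: dict[str, dict[str, int]] = {name: {s: 0 for s in samples} for name in merged}
    for lib in libraries:
        tags = kept_tags[lib.sample_id] if kept_tags is not None else lib.mapped_tags
        for tag in tags:
            for name, mat in merged.items():
                if _tag_matches_mature(tag.sequence, mat.sequence):
                    counts[name][lib.sample_id] += tag.count
    return [
        MirnaExpression(name, merged[name].precursors, counts[name])
        for name in sorted(merged)
        if any(c > 0 for c in counts[name].values())
    ]


def call_known_mirnas(
    expressions: Sequence[MirnaExpression],
    min_reads: int = 10,
    min_individuals: int = 3,
    n_samples: Optional[int] = None,
) -> list[MirnaExpression]:
    """Keep matures with >= min_reads total and detection in >= min_individuals."""
    if expressions:
        n = len(next(iter(expressions)).raw_counts)
    else:
        n = n_samples or 0
    if n < min_individuals:
        raise ValueError(
            f"only {n} samples: the >= {min_individuals}-individual threshold is unsatisfiable"
        )
    return [
        e for e in expressions
        if e.total_count >= min_reads and e.n_detected >= min_individuals
    ]


def tpm(raw_counts: dict[str, int], clean_reads: dict[str, int]) -> dict[str, float]:
    """Tags per million clean reads, per sample."""
    out = {}
    for sample, count in raw_counts.items():
        total = clean_reads[sample]
        if total <= 0:
            raise ValueError(f"sample {sample!r}: clean read count is zero")
        out[sample] = count / total * 1e6
    return out


def add_tpm(
    expressions: Sequence[MirnaExpression], libraries: Sequence[Library]
) -> None:
    """Fill in per-sample TPM and mean TPM in place."""
    clean = {lib.sample_id: lib.clean_reads for lib in libraries}
    for e in expressions:
        e.tpm = tpm(e.raw_counts, clean)
        e.mean_tpm = sum(e.tpm.values()) / len(e.tpm)
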