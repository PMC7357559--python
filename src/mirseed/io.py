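"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Biopython's SeqIO; GFF3 and the flat TSV report
tables are read line-by-line so that errors can carry line numbers and the
feature-type mapping stays a plain, user-configurable dictionary.  All readers
accept gzip-compressed input (detected by the ``.gz`` suffix).

Reference miRNA sets use a flat FASTA-header dialect (miRBase EMBL parsing is
out of scope)::

    >mir-21 species=hsa,mmu,dre|m5p=9-30|m3p=47-68|exp=1|ann=1|mfas=0
    UAGCUUAUCAGACUGAUGUUGA...

Header fields after the record name are ``|``-separated ``key=value`` pairs:
``species`` (comma-separated species codes of annotated homologs), ``m5p`` /
``m3p`` (1-based inclusive mature spans on the precursor, at least one
required), and the 0/1 evidence flags ``exp`` (homolog has experimental
support), ``ann`` (annotated as miRNA in another species) and ``mfas``
(previously reported in cynomolgus macaque).
"""
from __future__ import annotations

import gzip
import logging
from collections import Counter
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import SeqIO

from .types import (
    AnnotationFeature,
    GenomicInterval,
    MatureArm,
    ReadRecord,
    ReferenceMirna,
    SequenceRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: default mapping from GFF3 ``type`` column to the closed feature-class set
DEFAULT_GFF_TYPE_MAP = {
    "exon": "exon",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "UTR": "UTR",
    "gene": "gene",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat_region": "repeat",
    "repeat": "repeat",
    "dispersed_repeat": "repeat",
}


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Sequences are whitespace-stripped and uppercased; U/T are preserved as
    read.  Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dupes: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                dupes.add(rec.id)
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {sorted(dupes)}")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------

def parse_fastq(path: PathLike) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records with Phred+33 qualities."""
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield ReadRecord(
                    rec.id,
                    str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attr(attrs: str, key: str) -> str:
    for part in attrs.strip().split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return ""


def parse_gff3(
    path: PathLike,
    type_map: Optional[dict[str, str]] = None,
) -> list[AnnotationFeature]:
    """Read GFF3 features, mapping types into the closed feature-class set.

    Types absent from ``type_map`` are skipped; the per-type skip counts are
    logged.  ``start > end`` is an error reported with its line number.
    """
    if type_map is None:
        type_map = DEFAULT_GFF_TYPE_MAP
    features: list[AnnotationFeature] = []
    skipped: Counter[str] = Counter()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand = cols[:7]
            if ftype not in type_map:
                skipped[ftype] += 1
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            if strand not in ("+", "-"):
                strand = "+"  # GFF3 '.' / '?' features: strand is irrelevant downstream
            name = _gff_attr(cols[8], "ID") if len(cols) > 8 else ""
            features.append(
                AnnotationFeature(
                    GenomicInterval(chrom, start_i, end_i, strand), type_map[ftype], name
                )
            )
    if skipped:
        logger.info("parse_gff3(%s): skipped unmapped types %s", path, dict(skipped))
    return features


def write_gff3(
    features: Iterable[AnnotationFeature],
    path: PathLike,
    source: str = "mirseed",
) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            attrs = f"ID={feat.name}" if feat.name else "."
            fh.write(
                f"{iv.chrom}\t{source}\t{feat.feature_class}\t{iv.start}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def write_bed(intervals: Iterable[tuple[str, GenomicInterval]], path: PathLike) -> None:
    """Write named loci as 6-column BED (0-based half-open)."""
    with _open_text(path, "wt") as fh:
        for name, iv in intervals:
            chrom, start0, end0, strand = iv.to_bed()
            fh.write(f"{chrom}\t{start0}\t{end0}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Reference miRNA sets
# ---------------------------------------------------------------------------

def _parse_span(text: str, name: str, key: str) -> MatureArm:
    try:
        start, end = text.split("-")
        return MatureArm(int(start), int(end))
    except ValueError as exc:
        raise ValueError(f"reference {name!r}: bad {key} span {text!r}") from exc


def parse_reference_set(path: PathLike) -> list[ReferenceMirna]:
    """Read a reference pre-miRNA FASTA in the key=value header dialect."""
    out: list[ReferenceMirna] = []
    for rec in parse_fasta(path):
        fields: dict[str, str] = {}
        for part in rec.description.split("|"):
            part = part.strip()
            if "=" in part:
                key, value = part.split("=", 1)
                fields[key.strip()] = value.strip()
        m5p = _parse_span(fields["m5p"], rec.id, "m5p") if "m5p" in fields else None
        m3p = _parse_span(fields["m3p"], rec.id, "m3p") if "m3p" in fields else None
        out.append(
            ReferenceMirna(
                name=rec.id,
                species=fields.get("species", ""),
                precursor=rec.sequence,
                mature5p=m5p,
                mature3p=m3p,
                experimentally_supported=fields.get("exp", "0") == "1",
                annotated_elsewhere=fields.get("ann", "0") == "1",
                previously_reported_in_macaque=fields.get("mfas", "0") == "1",
            )
        )
    return out


def write_reference_set(refs: Iterable[ReferenceMirna], path: PathLike) -> None:
    records = []
    for ref in refs:
        parts = [f"species={ref.species}"]
        if ref.mature5p:
            parts.append(f"m5p={ref.mature5p.start}-{ref.mature5p.end}")
        if ref.mature3p:
            parts.append(f"m3p={ref.mature3p.start}-{ref.mature3p.end}")
        parts.append(f"exp={int(ref.experimentally_supported)}")
        parts.append(f"ann={int(ref.annotated_elsewhere)}")
        parts.append(f"mfas={int(ref.previously_reported_in_macaque)}")
        records.append(SequenceRecord(ref.name, ref.precursor, "|".join(parts)))
    write_fasta(records, path)


# ---------------------------------------------------------------------------
# Locus tables (loci printed as chrom:start-end<strand>)
# ---------------------------------------------------------------------------

def read_locus_table(path: PathLike) -> list[tuple[str, GenomicInterval, dict[str, str]]]:
    """Read a TSV with columns ``name``, ``locus`` and any extra columns.

    ``locus`` uses the ``chrom:start-end<strand>`` notation.  Returns
    (name, interval, extra-columns) triples; used for externally supplied
    locus lists such as the published per-locus supplementary table.
    """
    rows = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "name" not in header or "locus" not in header:
            raise ValueError(f"{path}: expected 'name' and 'locus' columns, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            vals = dict(zip(header, line.split("\t")))
            try:
                iv = GenomicInterval.from_string(vals["locus"])
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: bad locus {vals['locus']!r}") from exc
            rows.append((vals["name"], iv, {k: v for k, v in vals.items() if k not in ("name", "locus")}))
    return rows
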