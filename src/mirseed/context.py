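"""Genomic characterization of validated miRNA loci.

Covers the locus-level analyses: genomic context classes (intergenic /
intronic / exonic / UTR / splice-site-overlapping), antisense (mirror) pairs,
same-strand 10-kb clusters with homo/hetero seed classes, seed-identity
family grouping, conservation-age categories, and the rank correlation
between age and mean expression.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .types import AnnotationFeature, GenomicInterval, dna

CONTEXT_CLASSES = ("intergenic", "intronic", "exonic", "UTR", "splice_site_overlapping")

#: ordinal age categories, oldest first (rank 1 = vertebrate)
AGE_CATEGORIES = ("vertebrate", "mammal", "primate", "cercopithecidae")

#: default species-code -> clade table used by age assignment.  Clades:
#: ``vertebrate`` = non-mammal vertebrate, ``mammal`` = non-primate mammal,
#: ``primate`` = primate outside Cercopithecidae, ``cercopithecidae``.
DEFAULT_SPECIES_CLADES = {
    # non-mammal vertebrates
    "dre": "vertebrate", "gga": "vertebrate", "xtr": "vertebrate", "aca": "vertebrate",
    # non-primate mammals
    "mmu": "mammal", "rno": "mammal", "bta": "mammal", "cfa": "mammal",
    "ssc": "mammal", "oar": "mammal",
    # primates outside Cercopithecidae
    "hsa": "primate", "ptr": "primate", "ggo": "primate", "ppy": "primate",
    "cja": "primate", "sla": "primate",
    # Cercopithecidae (Old-world monkeys)
    "mml": "cercopithecidae", "mfa": "cercopithecidae", "mne": "cercopithecidae",
    "pha": "cercopithecidae", "sbq": "cercopithecidae",
}

DEFAULT_CLUSTER_GAP = 10_000


@dataclass
class MirnaLocusAnnotation:
    name: str
    locus: GenomicInterval
    context: str
    host_gene: Optional[str] = None
    mirror_partner: Optional[str] = None


@dataclass
class Cluster:
    members: list[str]  # locus names ordered by start
    span: GenomicInterval
    strand: str
    seed_class: Optional[str] = None  # homo | hetero


def classify_context(
    name: str,
    locus: GenomicInterval,
    annotations: Sequence[AnnotationFeature],
) -> MirnaLocusAnnotation:
    """Assign exactly one context class to a locus.

    Exonic when fully inside an exon (sub-classed UTR when inside a UTR
    feature); splice-site-overlapping when crossing an exon boundary interior
    to a gene; intronic when inside a gene but not an exon; intergenic
    otherwise.  Host strand is ignored for containment but the host gene is
    recorded.
    """
    genes = [f for f in annotations if f.feature_class == "gene"]
    exons = [f for f in annotations if f.feature_class == "exon"]
    utrs = [f for f in annotations if f.feature_class == "UTR"]

    host = next((g for g in genes if g.interval.contains(locus)), None)
    host_name = host.name or str(host.interval) if host else None

    if any(u.interval.contains(locus) for u in utrs):
        return MirnaLocusAnnotation(name, locus, "UTR", host_name)
    if any(e.interval.contains(locus) for e in exons):
        return MirnaLocusAnnotation(name, locus, "exonic", host_name)
    if host is not None:
        touching = [e for e in exons if host.interval.contains(e.interval) and e.interval.overlaps(locus)]
        if touching:
            return MirnaLocusAnnotation(name, locus, "splice_site_overlapping", host_name)
        return MirnaLocusAnnotation(name, locus, "intronic", host_name)
    # partial gene overlap without containment is rare; treat boundary-crossing
    # loci that overlap an exon edge as splice-site-overlapping as well
    part = next((g for g in genes if g.interval.overlaps(locus)), None)
    if part is not None and any(e.interval.overlaps(locus) for e in exons):
        return MirnaLocusAnnotation(name, locus, "splice_site_overlapping", part.name or None)
    if part is not None:
        return MirnaLocusAnnotation(name, locus, "intronic", part.name or None)
    return MirnaLocusAnnotation(name, locus, "intergenic", None)


def find_mirror_pairs(
    loci: Sequence[tuple[str, GenomicInterval]],
) -> list[tuple[str, str]]:
    """Pairs of loci overlapping by >= 1 nt on opposite strands of one chrom.

    Pairs are reported once, ordered by name; the relation is symmetric.
    """
    pairs = []
    for i, (name_a, a) in enumerate(loci):
        for name_b, b in loci[i + 1 :]:
            if a.chrom == b.chrom and a.strand != b.strand and a.overlap_length(b) >= 1:
                pairs.append(tuple(sorted((name_a, name_b))))
    return sorted(set(pairs))


def detect_clusters(
    loci: Sequence[tuple[str, GenomicInterval]],
    max_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[Cluster]:
    """Chain same-strand neighbors with edge-to-edge gaps <= ``max_gap``.

    Per chromosome and strand, loci sorted by start are chained transitively
    whenever ``next.start - prev.end - 1 <= max_gap`` (overlapping loci chain
    too); chains of >= 2 become clusters.  Output is independent of input
    order and partitions the clustered loci.
    """
    names = [n for n, _ in loci]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate locus names: {dupes}")
    groups: dict[tuple[str, str], list[tuple[str, GenomicInterval]]] = {}
    for name, iv in loci:
        groups.setdefault((iv.chrom, iv.strand), []).append((name, iv))
    clusters = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda t: (t[1].start, t[1].end, t[0]))
        chain: list[tuple[str, GenomicInterval]] = []
        chain_end = None
        for name, iv in members + [("", None)]:  # sentinel flushes the last chain
            if iv is not None and chain and iv.start - chain_end - 1 <= max_gap:
                chain.append((name, iv))
                chain_end = max(chain_end, iv.end)
            else:
                if len(chain) >= 2:
                    span = GenomicInterval(
                        chrom, min(m[1].start for m in chain), max(m[1].end for m in chain), strand
                    )
                    clusters.append(Cluster([m[0] for m in chain], span, strand))
                if iv is not None:
                    chain = [(name, iv)]
                    chain_end = iv.end
    clusters.sort(key=lambda c: (c.span.chrom, c.span.start, c.strand))
    return clusters


def classify_cluster_seed(
    cluster: Cluster, seeds: dict[str, str]
) -> str:
    """homo when every member's seed (mature positions 2-8) is identical."""
    member_seeds = []
    for name in cluster.members:
        if name not in seeds or not seeds[name]:
            raise ValueError(f"cluster member {name!r} has no mature seed")
        member_seeds.append(dna(seeds[name]))
    return "homo" if len(set(member_seeds)) == 1 else "hetero"


def group_families(seeds: dict[str, str]) -> dict[str, list[str]]:
    """Group miRNAs into families by exact seed identity.

    Family keys are the shared seed sequence (DNA alphabet).  Seed-identity
    grouping is a proxy for curated family tables.
    """
    fams: dict[str, list[str]] = {}
    for name, seed in seeds.items():
        fams.setdefault(dna(seed), []).append(name)
    return {k: sorted(v) for k, v in fams.items()}


def assign_age(
    species: Sequence[str],
    clade_table: Optional[dict[str, str]] = None,
) -> str:
    """Broadest clade among a miRNA's homolog species set.

    vertebrate if any non-mammal vertebrate homolog exists; else mammal if
    any non-primate mammal; else primate if any primate outside
    Cercopithecidae; else cercopithecidae.
    """
    table = clade_table or DEFAULT_SPECIES_CLADES
    unknown = sorted(set(species) - set(table))
    if unknown:
        raise ValueError(f"unknown species labels: {unknown}")
    clades = {table[s] for s in species}
    for cat in AGE_CATEGORIES:
        if cat in clades:
            return cat
    return "cercopithecidae"


def age_rank(category: str) -> int:
    """Ordinal rank, oldest = 1 (vertebrate) .. youngest = 4."""
    return AGE_CATEGORIES.index(category) + 1


def spearman_age_expression(
    ages: Sequence[str], mean_tpm: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho between miRNA age and mean expression, two-sided p.

    Age is coded so that older categories score higher (vertebrate = 4 ...
    cercopithecidae = 1); a positive rho therefore means older miRNAs are
    higher-expressed.  Ties get average ranks; p comes from the
    t-approximation.
    """
    if len(ages) != len(mean_tpm):
        raise ValueError("ages and expression differ in length")
    if len(ages) < 4:
        raise ValueError(f"need >= 4 observations, got {len(ages)}")
    scores = [len(AGE_CATEGORIES) + 1 - age_rank(a) for a in ages]
    rho, p = stats.spearmanr(scores, list(mean_tpm))
    return float(rho), float(p)
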