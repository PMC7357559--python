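"""Synthetic study generator: toy genome, planted pre-miRNA loci, reference
set, annotations and multi-individual small-RNA libraries with known truth.

The generator emulates the study design this pipeline targets: a primate
genome carrying conserved pre-miRNA loci in diverse genomic contexts
(intergenic, intronic, exonic, UTR, splice-site-overlapping), same-strand
clusters with inter-locus gaps <= 10 kb, antisense (mirror) pairs, and four
unrelated individuals sequenced for small RNAs.  Planted loci are designed
stem-loop hairpins (a 22-bp stem around a short loop); the 10 nt immediately
flanking each planted precursor use a C/A-only alphabet, which cannot base
pair with itself, so the flank-extended sequence the pipeline folds keeps a
single-hairpin topology.  Reference records represent the homologs of other
species and differ from the genome copy by a configurable number of
substitutions placed outside both seed regions.

Locus expression follows the age-stratified model in which older miRNAs are
higher expressed — vertebrate : mammal : primate mean expression scales
160 : 10 : 1 by default, with Cercopithecidae-specific loci below primate
level — and per-sample counts are negative-binomial.  Exon-overlapping loci
(exonic/UTR/splice-site) are silent, since their tags cannot survive the
exon-overlap annotation filter.

Non-cluster loci are separated by > 10 kb so the planted clusters are exactly
the clusters recoverable from the locus coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as mio
from .types import (
    AnnotationFeature,
    GenomicInterval,
    MatureArm,
    ReadRecord,
    ReferenceMirna,
    SequenceRecord,
    dna,
    revcomp,
)

DEFAULT_SEED = 1455
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

_AGE_SPECIES = {
    "vertebrate": "dre,gga,mmu,hsa,mml",
    "mammal": "mmu,bta,hsa,mml",
    "primate": "hsa,ptr,mml",
    "cercopithecidae": "mml,mfa",
}

_FLANK_LEN = 10  # planted C/A flank on each side of a precursor


@dataclass
class SimulationConfig:
    """Study-design knobs; the defaults are the conditions the tests run under."""

    n_contigs: int = 2
    contig_length: int = 220_000
    # standalone locus counts per context class
    n_intergenic: int = 7
    n_intronic: int = 9
    n_exonic: int = 2
    n_utr: int = 2
    n_splice: int = 2
    # (size, seed_class) per same-strand cluster; members are intergenic
    clusters: tuple[tuple[int, str], ...] = ((3, "homo"), (2, "hetero"))
    n_mirror_pairs: int = 1  # each pair = two overlapping intronic loci, opposite strands
    # conservation-age composition over all planted loci
    age_counts: dict[str, int] = field(
        default_factory=lambda: {
            "vertebrate": 8, "mammal": 8, "primate": 8, "cercopithecidae": 5,
        }
    )
    # expression model: mean TPM = base_tpm * age_fold[age_category]
    base_tpm: float = 300.0
    age_fold: dict[str, float] = field(
        default_factory=lambda: {
            "vertebrate": 160.0, "mammal": 10.0, "primate": 1.0, "cercopithecidae": 0.3,
        }
    )
    nb_dispersion: float = 0.2
    arm3p_fraction: float = 0.25  # share of a locus's reads from the 3p arm
    # hairpin geometry
    stem_length: int = 22
    loop: str = "CAACAACAA"
    # reference (homolog) vs genome substitutions, drawn uniformly per locus
    divergence_range: tuple[int, int] = (0, 2)
    n_decoy_refs: int = 3  # references with no locus in the genome
    # spacing between blocks / between cluster members (nt)
    interlocus_gap: tuple[int, int] = (11_000, 13_000)
    intracluster_gap: tuple[int, int] = (200, 3_000)
    rng_seed: int = DEFAULT_SEED

    def total_loci(self) -> int:
        return (
            self.n_intergenic + self.n_intronic + self.n_exonic + self.n_utr
            + self.n_splice + sum(size for size, _ in self.clusters)
            + 2 * self.n_mirror_pairs
        )


@dataclass
class PlantedLocus:
    ref: ReferenceMirna
    locus: GenomicInterval
    genome_precursor: str  # transcribed-strand sequence actually in the genome
    age_category: str
    context_class: str
    cluster_id: Optional[int] = None
    mirror_partner: Optional[str] = None
    mean_tpm: float = 0.0


@dataclass
class TruthSet:
    genome: list[SequenceRecord]
    annotations: list[AnnotationFeature]
    planted_loci: list[PlantedLocus]
    reference_set: list[ReferenceMirna]
    expression_model: dict[str, float]  # locus name -> mean TPM
    config: SimulationConfig
    rng_seed: int = DEFAULT_SEED


@dataclass
class LibrarySpec:
    sample_id: str
    n_reads: int = 100_000
    adapter: str = DEFAULT_ADAPTER
    noise_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "adapter": 0.05, "high_n": 0.02, "low_quality": 0.03,
            "short": 0.05, "rfrag": 0.10,
        }
    )

    def __post_init__(self) -> None:
        if sum(self.noise_fractions.values()) >= 1.0:
            raise ValueError("noise fractions must sum to < 1")


@dataclass
class SimulatedLibraries:
    reads: dict[str, list[ReadRecord]]  # sample -> shuffled reads
    truth_counts: dict[str, dict[str, int]]  # mature name -> sample -> emitted count
    specs: list[LibrarySpec]


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.55) -> str:
    p_each = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p_each))


def _ca_flank(rng: np.random.Generator, length: int = _FLANK_LEN) -> str:
    """C/A-only flank: cannot pair with itself (no G or T/U)."""
    return "".join(rng.choice(list("CA"), size=length, p=[0.5, 0.5]))


def _design_precursor(rng: np.random.Generator, cfg: SimulationConfig,
                      seed7: Optional[str] = None, stem_mismatches: int = 0) -> str:
    """arm5 + loop + revcomp(arm5); optionally with a shared seed (homo-seed
    clusters) or internal stem mismatches (mirror-pair hosts, so the two
    strands yield distinguishable matures)."""
    arm5 = _random_seq(rng, cfg.stem_length)
    if seed7 is not None:
        arm5 = arm5[0] + seed7 + arm5[8:]
    arm3 = revcomp(arm5)
    if stem_mismatches:
        # mutate arm3 at mature positions 9-20 (outside the 3p seed)
        positions = rng.choice(np.arange(8, 20), size=stem_mismatches, replace=False)
        arm3_l = list(arm3)
        for p in positions:
            arm3_l[p] = str(rng.choice([b for b in "ACGT" if b != arm3_l[p]]))
        arm3 = "".join(arm3_l)
    return arm5 + cfg.loop + arm3


def _diverge(rng: np.random.Generator, precursor: str, n_subs: int,
             stem_length: int, loop_len: int) -> str:
    """Homolog divergence: substitutions outside both seed regions."""
    seed5 = set(range(1, 8))  # 0-based indices of 5p-mature positions 2-8
    m3_start = stem_length + loop_len  # 0-based start of the 3p mature
    seed3 = set(range(m3_start + 1, m3_start + 8))
    allowed = [i for i in range(len(precursor)) if i not in seed5 and i not in seed3]
    seq = list(precursor)
    if n_subs:
        for i in rng.choice(allowed, size=n_subs, replace=False):
            seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
    return "".join(seq)


def _make_reference(name: str, precursor: str, age: str, cfg: SimulationConfig) -> ReferenceMirna:
    m3_start = cfg.stem_length + len(cfg.loop) + 1
    return ReferenceMirna(
        name=name,
        species=_AGE_SPECIES[age],
        precursor=precursor,
        mature5p=MatureArm(1, cfg.stem_length),
        mature3p=MatureArm(m3_start, m3_start + cfg.stem_length - 1),
        experimentally_supported=True,
        annotated_elsewhere=True,
        previously_reported_in_macaque=False,
    )


def _passes_validation(genome_precursor: str, ref: ReferenceMirna) -> bool:
    """Generation-time check that a planted hairpin clears the structural
    criteria with margin (MFE <= -17, largest bulge < 5, matures in arms)."""
    from .hairpin import fold_mfe, hairpin_features

    fold = fold_mfe(genome_precursor)
    try:
        feats = hairpin_features(fold)
    except ValueError:
        return False
    if not feats.is_single_hairpin or fold.mfe > -17.0 or feats.max_internal_bulge >= 5:
        return False
    loop_start, loop_end = feats.loop
    for _arm, span in ref.arms():
        if not (span.end < loop_start or span.start > loop_end):
            return False
    return True


# ---------------------------------------------------------------------------
# truth-set generation
# ---------------------------------------------------------------------------

class _ContigBuilder:
    def __init__(self, name: str, rng: np.random.Generator):
        self.name = name
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0  # length so far

    def append(self, seq: str) -> int:
        """Append sequence; return the 1-based start of the appended part."""
        start = self.cursor + 1
        self.parts.append(seq)
        self.cursor += len(seq)
        return start

    def spacer(self, lo: int, hi: int) -> None:
        self.append(_random_seq(self.rng, int(self.rng.integers(lo, hi + 1)), gc=0.4))

    def sequence(self) -> str:
        return "".join(self.parts)


def generate_truth_set(config: SimulationConfig | None = None,
                       rng_seed: Optional[int] = None) -> TruthSet:
    """Build the toy genome with planted loci; deterministic given the seed."""
    cfg = config or SimulationConfig()
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)

    if sum(cfg.age_counts.values()) != cfg.total_loci():
        raise ValueError(
            f"age_counts sum {sum(cfg.age_counts.values())} != total loci {cfg.total_loci()}"
        )

    ages = [a for a, n in cfg.age_counts.items() for _ in range(n)]
    rng.shuffle(ages)
    age_iter = iter(ages)

    contigs = [_ContigBuilder(f"chr{i+1}", rng) for i in range(cfg.n_contigs)]
    annotations: list[AnnotationFeature] = []
    planted: list[PlantedLocus] = []
    refs: list[ReferenceMirna] = []
    counter = 0
    block = 0

    def new_hairpin(age: str, seed7: Optional[str] = None, stem_mm: int = 0,
                    max_tries: int = 50) -> tuple[str, str, ReferenceMirna]:
        nonlocal counter
        counter += 1
        name = f"syn-mir-{counter:03d}"
        for _ in range(max_tries):
            prec = _design_precursor(rng, cfg, seed7=seed7, stem_mismatches=stem_mm)
            n_subs = int(rng.integers(cfg.divergence_range[0], cfg.divergence_range[1] + 1))
            ref_prec = _diverge(rng, prec, n_subs, cfg.stem_length, len(cfg.loop))
            ref = _make_reference(name, ref_prec, age, cfg)
            if _passes_validation(prec, ref):
                return name, prec, ref
        raise RuntimeError(f"could not design a valid hairpin for {name}")

    def plant(builder: _ContigBuilder, prec: str, strand: str) -> GenomicInterval:
        """Write flank5+precursor+flank3 on the requested strand; the interval
        covers the precursor only."""
        body = _ca_flank(rng) + prec + _ca_flank(rng)
        seq = body if strand == "+" else revcomp(body)
        start = builder.append(seq)
        return GenomicInterval(builder.name, start + _FLANK_LEN,
                               start + _FLANK_LEN + len(prec) - 1, strand)

    def next_contig() -> _ContigBuilder:
        nonlocal block
        b = contigs[block % cfg.n_contigs]
        block += 1
        b.spacer(*cfg.interlocus_gap)
        return b

    # --- standalone intergenic loci
    for _ in range(cfg.n_intergenic):
        b = next_contig()
        age = next(age_iter)
        _name, prec, ref = new_hairpin(age)
        iv = plant(b, prec, str(rng.choice(["+", "-"])))
        refs.append(ref)
        planted.append(PlantedLocus(ref, iv, prec, age, "intergenic"))

    # --- clusters (same strand, gaps <= 10 kb), intergenic placement
    for cid, (size, seed_class) in enumerate(cfg.clusters, start=1):
        b = next_contig()
        strand = str(rng.choice(["+", "-"]))
        shared = _random_seq(rng, 7) if seed_class == "homo" else None
        for m in range(size):
            if m:
                b.spacer(*cfg.intracluster_gap)
            age = next(age_iter)
            _name, prec, ref = new_hairpin(age, seed7=shared)
            iv = plant(b, prec, strand)
            refs.append(ref)
            planted.append(PlantedLocus(ref, iv, prec, age, "intergenic", cluster_id=cid))

    # --- gene-hosted loci
    def host_gene(builder: _ContigBuilder, kind: str, age: str):
        gene_strand = str(rng.choice(["+", "-"]))
        locus_strand = str(rng.choice(["+", "-"]))
        gene_start = builder.append(_random_seq(rng, 150, gc=0.45))
        exon1_end = builder.cursor

        if kind == "splice":
            _name, prec, ref = new_hairpin(age)
            iv = plant(builder, prec, locus_strand)
            exon1_end = iv.start + 19  # exon 1 ends 20 nt into the precursor
            builder.append(_random_seq(rng, 120, gc=0.4))
            ctx = "splice_site_overlapping"
        elif kind in ("exonic", "utr"):
            _name, prec, ref = new_hairpin(age)
            iv = plant(builder, prec, locus_strand)
            builder.append(_random_seq(rng, 60, gc=0.45))
            exon1_end = builder.cursor  # exon 1 spans the locus entirely
            if kind == "utr":
                annotations.append(
                    AnnotationFeature(
                        GenomicInterval(builder.name, iv.start - 5, iv.end + 5, gene_strand),
                        "UTR",
                    )
                )
            ctx = "UTR" if kind == "utr" else "exonic"
        else:  # intronic locus or mirror host, inside the intron
            builder.append(_random_seq(rng, 100, gc=0.4))
            _name, prec, ref = new_hairpin(age, stem_mm=3 if kind == "mirror" else 0)
            iv = plant(builder, prec, locus_strand)
            builder.append(_random_seq(rng, 100, gc=0.4))
            ctx = "intronic"

        exon2_start = builder.append(_random_seq(rng, 150, gc=0.45))
        gene_end = builder.cursor
        gname = f"GENE{len(annotations):03d}"
        giv = GenomicInterval(builder.name, gene_start, gene_end, gene_strand)
        annotations.append(AnnotationFeature(giv, "gene", gname))
        annotations.append(AnnotationFeature(
            GenomicInterval(builder.name, gene_start, exon1_end, gene_strand), "exon", gname + ".e1"))
        annotations.append(AnnotationFeature(
            GenomicInterval(builder.name, exon2_start, gene_end, gene_strand), "exon", gname + ".e2"))
        return prec, ref, iv, ctx

    for kind, count in (("intronic", cfg.n_intronic), ("exonic", cfg.n_exonic),
                        ("utr", cfg.n_utr), ("splice", cfg.n_splice)):
        for _ in range(count):
            b = next_contig()
            age = next(age_iter)
            prec, ref, iv, ctx = host_gene(b, kind, age)
            refs.append(ref)
            planted.append(PlantedLocus(ref, iv, prec, age, ctx))

    # --- mirror pairs: the partner is the reverse-complement strand of the
    # host locus (the reverse complement of a hairpin is itself a hairpin;
    # the 3 planted stem mismatches make the four matures distinguishable)
    for _ in range(cfg.n_mirror_pairs):
        b = next_contig()
        age_a, age_b = next(age_iter), next(age_iter)
        prec_a, ref_a, iv_a, _ctx = host_gene(b, "mirror", age_a)
        prec_b = revcomp(prec_a)
        counter += 1
        name_b = f"syn-mir-{counter:03d}"
        n_subs = int(rng.integers(cfg.divergence_range[0], cfg.divergence_range[1] + 1))
        ref_b = _make_reference(
            name_b, _diverge(rng, prec_b, n_subs, cfg.stem_length, len(cfg.loop)), age_b, cfg
        )
        if not _passes_validation(prec_b, ref_b):
            raise RuntimeError("mirror partner failed hairpin validation")
        iv_b = GenomicInterval(iv_a.chrom, iv_a.start, iv_a.end,
                               "-" if iv_a.strand == "+" else "+")
        refs.extend([ref_a, ref_b])
        planted.append(PlantedLocus(ref_a, iv_a, prec_a, age_a, "intronic",
                                    mirror_partner=name_b))
        planted.append(PlantedLocus(ref_b, iv_b, prec_b, age_b, "intronic",
                                    mirror_partner=ref_a.name))

    # --- structural-RNA features feeding the annotation-filter noise class
    for b in contigs:
        b.spacer(*cfg.interlocus_gap)
        start = b.append(_random_seq(rng, 500, gc=0.5))
        annotations.append(AnnotationFeature(
            GenomicInterval(b.name, start, b.cursor, "+"), "rRNA", f"rRNA-{b.name}"))
        b.spacer(2000, 3000)
        start = b.append(_random_seq(rng, 200, gc=0.5))
        annotations.append(AnnotationFeature(
            GenomicInterval(b.name, start, b.cursor, "+"), "tRNA", f"tRNA-{b.name}"))

    # --- decoy references absent from the genome
    for _ in range(cfg.n_decoy_refs):
        counter += 1
        prec = _design_precursor(rng, cfg)
        refs.append(_make_reference(f"syn-mir-{counter:03d}", prec, "primate", cfg))

    # --- finalize contigs
    for b in contigs:
        if b.cursor > cfg.contig_length:
            raise ValueError(
                f"genome too small: contig {b.name} needs {b.cursor} nt "
                f"> contig_length {cfg.contig_length}"
            )
        b.append(_random_seq(rng, cfg.contig_length - b.cursor, gc=0.4))
    genome = [SequenceRecord(b.name, b.sequence()) for b in contigs]

    # --- expression model
    expression: dict[str, float] = {}
    for p in planted:
        silent = p.context_class in ("exonic", "UTR", "splice_site_overlapping")
        p.mean_tpm = 0.0 if silent else cfg.base_tpm * cfg.age_fold[p.age_category]
        expression[p.ref.name] = p.mean_tpm

    truth = TruthSet(genome, annotations, planted, refs, expression, cfg, seed)
    _check_truth_invariants(truth)
    return truth


def _check_truth_invariants(truth: TruthSet) -> None:
    contigs = {r.id: r.sequence for r in truth.genome}
    by_name = {p.ref.name: p for p in truth.planted_loci}
    for p in truth.planted_loci:
        raw = contigs[p.locus.chrom][p.locus.start - 1 : p.locus.end]
        if p.locus.strand == "-":
            raw = revcomp(raw)
        if dna(raw) != dna(p.genome_precursor):
            raise AssertionError(f"planted precursor not retrievable at {p.locus}")
        if p.mirror_partner is not None:
            q = by_name[p.mirror_partner]
            assert q.mirror_partner == p.ref.name
            assert p.locus.strand != q.locus.strand and p.locus.overlaps(q.locus)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def default_library_specs(n_samples: int = 4, n_reads: int = 100_000) -> list[LibrarySpec]:
    """Four unrelated individuals by default."""
    return [LibrarySpec(sample_id=f"CE{i+1:02d}", n_reads=n_reads) for i in range(n_samples)]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def truth_matures(truth: TruthSet) -> list[tuple[str, str, float]]:
    """(mature name, genome tag sequence, mean TPM) per planted mature arm."""
    out = []
    f3 = truth.config.arm3p_fraction
    for p in truth.planted_loci:
        for arm_label, span, share in (("5p", p.ref.mature5p, 1.0 - f3),
                                       ("3p", p.ref.mature3p, f3)):
            if span is None:
                continue
            tag = dna(p.genome_precursor[span.start - 1 : span.end])
            if not 18 <= len(tag) <= 30:
                raise ValueError(
                    f"mature tag length {len(tag)} outside 18-30 for {p.ref.name}-{arm_label}"
                )
            out.append((f"{p.ref.name}-{arm_label}", tag, share * p.mean_tpm))
    return out


def simulate_libraries(
    truth: TruthSet,
    specs: Optional[list[LibrarySpec]] = None,
    rng_seed: Optional[int] = None,
) -> SimulatedLibraries:
    """Draw per-sample reads: exact mature-arm tags plus the four QC-removable
    noise classes and rRNA/tRNA fragments that survive QC but fail the
    annotation filter.  Deterministic given the seed."""
    specs = specs or default_library_specs()
    seed = truth.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed + 7919)  # decoupled from genome generation
    contigs = {r.id: r.sequence for r in truth.genome}
    dispersion = truth.config.nb_dispersion

    rfrag_sources = [
        contigs[f.interval.chrom][f.interval.start - 1 : f.interval.end]
        for f in truth.annotations
        if f.feature_class in ("rRNA", "tRNA")
    ]
    matures = truth_matures(truth)

    truth_counts: dict[str, dict[str, int]] = {}
    reads: dict[str, list[ReadRecord]] = {}
    for spec in specs:
        sample_reads: list[ReadRecord] = []
        adapter = dna(spec.adapter)
        nf = spec.noise_fractions
        removable = sum(nf.get(k, 0) for k in ("adapter", "high_n", "low_quality", "short"))
        clean_target = spec.n_reads * (1 - removable)
        rid = 0

        def emit(seq: str, quals: Optional[list[int]] = None) -> None:
            nonlocal rid
            rid += 1
            sample_reads.append(
                ReadRecord(f"{spec.sample_id}.{rid}", seq, quals or [40] * len(seq))
            )

        for name, tag, mean_tpm in matures:
            count = _nb_draw(rng, mean_tpm / 1e6 * clean_target, dispersion)
            if count > 0:
                truth_counts.setdefault(name, {})[spec.sample_id] = count
            for _ in range(count):
                emit(tag + adapter)

        for _ in range(int(nf.get("rfrag", 0) * spec.n_reads)):
            src = rfrag_sources[int(rng.integers(len(rfrag_sources)))]
            flen = int(rng.integers(18, 26))
            start = int(rng.integers(0, len(src) - flen + 1))
            frag = dna(src[start : start + flen])
            if rng.random() < 0.5:
                frag = revcomp(frag)
            emit(frag + adapter)
        for _ in range(int(nf.get("adapter", 0) * spec.n_reads)):
            emit(adapter + _random_seq(rng, 8))
        for _ in range(int(nf.get("high_n", 0) * spec.n_reads)):
            insert = list(_random_seq(rng, 22))
            for pos in rng.choice(22, size=4, replace=False):  # 4/22 > 10% N
                insert[pos] = "N"
            emit("".join(insert) + adapter)
        for _ in range(int(nf.get("low_quality", 0) * spec.n_reads)):
            insert = _random_seq(rng, 22)
            quals = [8] * 14 + [40] * 8 + [40] * len(adapter)  # 14/22 > 50% low-quality
            emit(insert + adapter, quals)
        for _ in range(int(nf.get("short", 0) * spec.n_reads)):
            emit(_random_seq(rng, int(rng.integers(10, 18))) + adapter)

        order = rng.permutation(len(sample_reads))
        reads[spec.sample_id] = [sample_reads[i] for i in order]

    return SimulatedLibraries(reads=reads, truth_counts=truth_counts, specs=specs)


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------

def write_truth_set(truth: TruthSet, libs: SimulatedLibraries, out_dir) -> None:
    """Write genome.fa, annotations.gff3, reference.fa, FASTQs and truth TSVs."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    mio.write_fasta(truth.genome, out / "genome.fa")
    mio.write_gff3(truth.annotations, out / "annotations.gff3")
    mio.write_reference_set(truth.reference_set, out / "reference.fa")
    for spec in libs.specs:
        mio.write_fastq(libs.reads[spec.sample_id], out / f"{spec.sample_id}.fastq.gz")
    with open(out / "truth" / "planted_loci.tsv", "w") as fh:
        fh.write("name\tlocus\tage\tcontext\tcluster_id\tmirror_partner\tmean_tpm\n")
        for p in truth.planted_loci:
            fh.write(
                f"{p.ref.name}\t{p.locus}\t{p.age_category}\t{p.context_class}\t"
                f"{p.cluster_id if p.cluster_id is not None else ''}\t"
                f"{p.mirror_partner or ''}\t{p.mean_tpm:g}\n"
            )
    samples = [s.sample_id for s in libs.specs]
    with open(out / "truth" / "counts.tsv", "w") as fh:
        fh.write("mature\t" + "\t".join(samples) + "\n")
        for name in sorted(libs.truth_counts):
            row = libs.truth_counts[name]
            fh.write(name + "\t" + "\t".join(str(row.get(s, 0)) for s in samples) + "\n")
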