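"""End-to-end orchestration: homology -> hairpin -> quantify -> annotate.

`run_analysis` is the in-memory engine the tests and acceptance script use;
`run_pipeline` wraps it with file IO, report tables and a run manifest.
Re-running with the same config and inputs is byte-identical (no timestamps
are written).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from math import floor
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import context as ctx
from . import hairpin as hp
from . import homology as hom
from . import io as mio
from . import quantify as qt
from .types import AnnotationFeature, ReadRecord, ReferenceMirna, SequenceRecord, dna


@dataclass
class PipelineConfig:
    """Paths and thresholds; threshold defaults are the published criteria."""

    genome: str = ""
    annotations: str = ""
    reference_set: str = ""
    fastqs: tuple[str, ...] = ()
    out_dir: str = "mirseed_out"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"

    min_identity: float = 93.0      # full-precursor similarity, strict >
    max_seed_mm: int = 1
    max_nonseed_mm: int = 2
    mfe_threshold: float = -15.0    # kcal/mol, pass when <=
    max_bulge: int = 6              # pass when largest bulge < this
    cluster_gap: int = 10_000
    min_reads: int = 10
    min_individuals: int = 3
    flank: int = 10
    scan_k: int = 12
    scan_floor: float = 85.0
    rng_seed: int = 1455

    def validate(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ValueError(f"identity threshold {self.min_identity} outside 0-100")
        if not 0 <= self.scan_floor <= 100:
            raise ValueError(f"scan floor {self.scan_floor} outside 0-100")
        if self.scan_floor > self.min_identity:
            raise ValueError("scan floor must not exceed the identity threshold")
        for name in ("max_seed_mm", "max_nonseed_mm", "max_bulge", "cluster_gap",
                     "min_reads", "min_individuals", "flank", "scan_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AnalysisResult:
    candidates: list[hom.CandidateLocus]
    validated: list[hp.ValidatedPreMirna]
    high_confidence: list[hp.ValidatedPreMirna]
    locus_names: dict[int, str]                      # index into high_confidence -> name
    libraries: list[qt.Library] = field(default_factory=list)
    qc_tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    kept_tags: dict[str, list[qt.TagPlacements]] = field(default_factory=dict)
    expressions: list[qt.MirnaExpression] = field(default_factory=list)
    called: list[qt.MirnaExpression] = field(default_factory=list)
    contexts: list[ctx.MirnaLocusAnnotation] = field(default_factory=list)
    mirror_pairs: list[tuple[str, str]] = field(default_factory=list)
    clusters: list[ctx.Cluster] = field(default_factory=list)
    ages: dict[str, str] = field(default_factory=dict)               # locus name -> age
    spearman: Optional[tuple[float, float]] = None
    stage_counts: dict[str, int] = field(default_factory=dict)


def _unique_locus_names(validated: Sequence[hp.ValidatedPreMirna]) -> dict[int, str]:
    """One stable name per genomic locus; paralogs get -1, -2 suffixes."""
    by_ref: dict[str, int] = {}
    for v in validated:
        by_ref[v.candidate.ref.name] = by_ref.get(v.candidate.ref.name, 0) + 1
    seen: dict[str, int] = {}
    names = {}
    for i, v in enumerate(validated):
        ref = v.candidate.ref.name
        if by_ref[ref] == 1:
            names[i] = ref
        else:
            seen[ref] = seen.get(ref, 0) + 1
            names[i] = f"{ref}-{seen[ref]}"
    return names


def _dominant_seed(v: hp.ValidatedPreMirna, expr_by_precursor: dict[str, dict[str, int]]) -> str:
    """Seed (mature positions 2-8) of the more abundant arm; 5p on ties."""
    ref = v.candidate.ref
    arms = [a for a, _ in ref.arms()]
    if len(arms) > 1 and expr_by_precursor:
        totals = {
            arm: sum(expr_by_precursor.get(f"{ref.name}-{arm}", {}).values())
            for arm in arms
        }
        arms.sort(key=lambda a: (-totals.get(a, 0), a))
    mature = v.candidate.mature_subseq(arms[0])
    return dna(mature[1:8])


def run_analysis(
    genome: list[SequenceRecord],
    annotations: list[AnnotationFeature],
    reference_set: list[ReferenceMirna],
    reads_by_sample: Optional[dict[str, list[ReadRecord]]] = None,
    config: Optional[PipelineConfig] = None,
) -> AnalysisResult:
    """Run homology search, hairpin validation, quantification (when reads
    are given) and genomic characterization over in-memory inputs."""
    cfg = config or PipelineConfig()
    cfg.validate()

    # --- homology
    hits = hom.scan_genome(genome, reference_set, k=cfg.scan_k, min_identity=cfg.scan_floor)
    candidates = hom.filter_candidates(
        hits, min_similarity=cfg.min_identity,
        max_seed_mm=cfg.max_seed_mm, max_nonseed_mm=cfg.max_nonseed_mm,
    )

    # --- hairpin validation
    validated = hp.validate_candidates(
        genome, candidates, flank=cfg.flank,
        mfe_threshold=cfg.mfe_threshold, max_bulge=cfg.max_bulge,
    )
    high_conf = [v for v in validated if v.high_confidence]
    names = _unique_locus_names(high_conf)

    result = AnalysisResult(
        candidates=candidates, validated=validated,
        high_confidence=high_conf, locus_names=names,
    )
    result.stage_counts = {
        "references": len(reference_set),
        "raw_hits": len(hits),
        "candidates": len(candidates),
        "validated_structures": sum(1 for v in validated if v.passes_structure),
        "high_confidence": len(high_conf),
    }

    # --- quantification
    expr_by_mature: dict[str, dict[str, int]] = {}
    if reads_by_sample:
        matures: list[qt.MatureRecord] = []
        for i, v in enumerate(high_conf):
            for arm, _span in v.candidate.ref.arms():
                seq = v.candidate.mature_subseq(arm)
                matures.append(qt.MatureRecord(f"{v.candidate.ref.name}-{arm}", seq, [names[i]]))
        index = qt.GenomeIndex({r.id: r.sequence for r in genome})
        for sample, reads in reads_by_sample.items():
            qc = qt.qc_filter(reads, cfg.adapter)
            lib = qt.collapse_and_map(sample, qc.clean, index)
            result.qc_tallies[sample] = qc.tally
            result.libraries.append(lib)
            result.kept_tags[sample] = qt.classify_annotation(lib.mapped_tags, annotations)
        result.expressions = qt.assign_reads_to_mirnas(result.libraries, matures, result.kept_tags)
        result.called = qt.call_known_mirnas(
            result.expressions, min_reads=cfg.min_reads, min_individuals=cfg.min_individuals,
            n_samples=len(result.libraries),
        )
        qt.add_tpm(result.called, result.libraries)
        expr_by_mature = {e.mature_name: e.raw_counts for e in result.expressions}
        result.stage_counts["clean_reads"] = sum(l.clean_reads for l in result.libraries)
        result.stage_counts["expressed_matures"] = len(result.called)

    # --- genomic characterization of high-confidence loci
    loci = [(names[i], v.candidate.locus) for i, v in enumerate(high_conf)]
    result.contexts = [ctx.classify_context(n, iv, annotations) for n, iv in loci]
    result.mirror_pairs = ctx.find_mirror_pairs(loci)
    partner = {a: b for a, b in result.mirror_pairs} | {b: a for a, b in result.mirror_pairs}
    for c in result.contexts:
        c.mirror_partner = partner.get(c.name)
    result.clusters = ctx.detect_clusters(loci, max_gap=cfg.cluster_gap)
    seeds = {names[i]: _dominant_seed(v, expr_by_mature) for i, v in enumerate(high_conf)}
    for cluster in result.clusters:
        cluster.seed_class = ctx.classify_cluster_seed(cluster, seeds)
    result.ages = {
        names[i]: ctx.assign_age(v.candidate.ref.species_list)
        for i, v in enumerate(high_conf)
    }
    result.stage_counts["clusters"] = len(result.clusters)
    result.stage_counts["mirror_pairs"] = len(result.mirror_pairs)

    # --- age vs expression
    if result.called:
        age_by_ref = {v.candidate.ref.name: ctx.assign_age(v.candidate.ref.species_list)
                      for v in high_conf}
        pts = [(age_by_ref[e.mature_name[:-3]], e.mean_tpm)
               for e in result.called if e.mature_name[:-3] in age_by_ref]
        if len(pts) >= 4:
            result.spearman = ctx.spearman_age_expression(
                [a for a, _ in pts], [t for _, t in pts]
            )
    return result


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    return floor(x + 0.5)


def summarize_library_stats(
    libraries: Sequence[qt.Library],
    mature_seqs: Sequence[str],
    kept_tags: Optional[dict[str, list[qt.TagPlacements]]] = None,
) -> pd.DataFrame:
    """Per-sample summary: clean reads, unique sRNAs, clean reads for miRNAs,
    unique sRNAs for miRNAs, plus an Average column rounded to the nearest
    integer.  A tag counts toward miRNAs when it matches any of the given
    mature sequences under the assignment rule."""
    if not libraries:
        raise ValueError("no libraries to summarize")
    matures = [dna(m) for m in mature_seqs]
    samples = [lib.sample_id for lib in libraries]
    rows = {
        "Clean reads": [lib.clean_reads for lib in libraries],
        "Unique sRNAs": [len(lib.unique_tags) for lib in libraries],
    }
    reads_mir, uniq_mir = [], []
    for lib in libraries:
        tags = kept_tags[lib.sample_id] if kept_tags else lib.mapped_tags
        n_reads = n_uniq = 0
        for tag in tags:
            if any(qt._tag_matches_mature(tag.sequence, m) for m in matures):
                n_reads += tag.count
                n_uniq += 1
        reads_mir.append(n_reads)
        uniq_mir.append(n_uniq)
    rows["Clean reads for miRNAs"] = reads_mir
    rows["Unique sRNAs for miRNAs"] = uniq_mir
    df = pd.DataFrame(rows, index=samples).T
    df["Average"] = [round_half_up(v) for v in df.mean(axis=1)]
    return df


def summarize_counts_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the Average column of a per-sample integer summary table."""
    samples = [c for c in table.columns if c != "Average"]
    out = table[samples].copy()
    out["Average"] = [round_half_up(v) for v in out[samples].mean(axis=1)]
    return out


# ---------------------------------------------------------------------------
# file-level orchestration
# ---------------------------------------------------------------------------

def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Load inputs, run the analysis, write report tables and a manifest."""
    config.validate()
    for label, path in (("genome", config.genome),
                        ("annotations", config.annotations),
                        ("reference set", config.reference_set),
                        *((f"fastq {p}", p) for p in config.fastqs)):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing {label}: {path!r}")

    genome = mio.parse_fasta(config.genome)
    annotations = mio.parse_gff3(config.annotations)
    refs = mio.parse_reference_set(config.reference_set)
    reads = {
        Path(p).name.split(".")[0]: list(mio.parse_fastq(p)) for p in config.fastqs
    }
    result = run_analysis(genome, annotations, refs, reads or None, config)
    write_reports(result, config)
    return result


def write_reports(result: AnalysisResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cand_rows = [
        {
            "ref": c.ref.name, "chrom": c.locus.chrom, "start": c.locus.start,
            "end": c.locus.end, "strand": c.locus.strand,
            "similarity": round(c.similarity_pct, 2),
            "seed_mm_5p": c.seed_mm_5p, "nonseed_mm_5p": c.nonseed_mm_5p,
            "seed_mm_3p": c.seed_mm_3p, "nonseed_mm_3p": c.nonseed_mm_3p,
        }
        for c in result.candidates
    ]
    pd.DataFrame(cand_rows).to_csv(out / "candidates.tsv", sep="\t", index=False)
    mio.write_gff3(
        [AnnotationFeature(c.locus, "gene", c.ref.name) for c in result.candidates],
        out / "candidates.gff3",
    )

    val_rows = [
        {
            "ref": v.candidate.ref.name, "locus": str(v.candidate.locus),
            "mfe": v.fold.mfe, "n_stem_pairs": v.features.n_stem_pairs,
            "max_internal_bulge": v.features.max_internal_bulge,
            "mature_in_arm": v.passes_mature_in_arm, "bulge_ok": v.passes_bulge,
            "mfe_ok": v.passes_mfe, "high_confidence": v.high_confidence,
        }
        for v in result.validated
    ]
    pd.DataFrame(val_rows).to_csv(out / "validation.tsv", sep="\t", index=False)
    hp.write_dot_bracket(
        [(v.candidate.ref.name, v.fold) for v in result.validated],
        out / "structures.txt",
    )

    if result.libraries:
        samples = [lib.sample_id for lib in result.libraries]
        expr_rows = []
        for e in result.called:
            row = {"mature": e.mature_name,
                   "precursors": ",".join(e.precursor_names)}
            row |= {f"count_{s}": e.raw_counts.get(s, 0) for s in samples}
            row |= {f"tpm_{s}": round(e.tpm.get(s, 0.0), 3) for s in samples}
            row["mean_tpm"] = round(e.mean_tpm, 3)
            expr_rows.append(row)
        pd.DataFrame(expr_rows).to_csv(out / "expression.tsv", sep="\t", index=False)
        library_summary(result).to_csv(out / "library_summary.tsv", sep="\t")

    ctx_rows = [
        {"name": c.name, "locus": str(c.locus), "context": c.context,
         "host_gene": c.host_gene or "", "mirror_partner": c.mirror_partner or "",
         "age": result.ages.get(c.name, "")}
        for c in result.contexts
    ]
    pd.DataFrame(ctx_rows).to_csv(out / "contexts.tsv", sep="\t", index=False)

    cl_rows = [
        {"cluster": str(c.span), "n_members": len(c.members),
         "members": "/".join(c.members), "seed_class": c.seed_class}
        for c in result.clusters
    ]
    pd.DataFrame(cl_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)

    if result.spearman is not None:
        rho, p = result.spearman
        with open(out / "age_correlation.tsv", "w") as fh:
            fh.write("spearman_rho\tp_value\tn\n")
            fh.write(f"{rho:.4f}\t{p:.3g}\t{len(result.called)}\n")

    manifest = {
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "stage_counts": result.stage_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def library_summary(result: AnalysisResult) -> pd.DataFrame:
    """Table-1-style per-sample summary computed from the analysis result."""
    mature_seqs = [
        dna(v.candidate.mature_subseq(arm))
        for v in result.high_confidence
        for arm, _span in v.candidate.ref.arms()
    ]
    return summarize_library_stats(result.libraries, mature_seqs, result.kept_tags or None)
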