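# Methods

## Scope and assumptions

`mirseed` annotates *conserved* miRNA genes: loci recognizable by sequence
homology to already-annotated pre-miRNAs. It assumes ungapped conservation
over the full precursor length (indel-containing orthologs are out of
reach), a canonical single stem-loop precursor (multiloop structures are
rejected), and small-RNA libraries in which mature miRNAs appear as exact
genomic substrings after adapter removal. De-novo discovery of
non-conserved miRNAs, isomiR sub-classification, target prediction and
enrichment analysis are deliberately out of scope.

## Homology search

The scan seeds with exact k-mers (default k = 12) shared between a reference
precursor and either genome strand, then evaluates every full-length
placement on the seeded diagonals and the ±3 shifted diagonals. Percent
identity is 100 × matches / precursor length over the ungapped placement;
U ≡ T, and N never matches. This realizes a banded alignment in which gaps
are scored as mismatches: under that scoring a gapped placement can never
beat the best shifted ungapped diagonal, so the scan is exactly equivalent
to a brute-force slide of the precursor over every genome position — an
equivalence the test suite asserts. Seeding is guaranteed lossless when
k ≤ L/(m+1) for precursor length L and the maximum mismatch count m implied
by the identity floor (`homology.guaranteed_k`); the default floor is 85 %,
below which hits are discarded before filtering.

Candidate filtering applies, in order: similarity strictly > 93 %; per
annotated mature arm, ≤ 1 mismatch in the seed (mature positions 2–8,
1-based, on either arm) and ≤ 2 outside it; locus de-duplication. Two hits
conflict when they share a strand and overlap by ≥ 50 % of the shorter
locus; conflicts are resolved greedily by similarity, ties by
lexicographically smallest reference name, so each locus carries exactly one
reference while one reference may keep several non-overlapping (paralogous)
loci. Opposite-strand overlaps never conflict — that is what lets antisense
(mirror) pairs through.

## Hairpin validation

Candidates are extended by `flank = 10` nt of genomic sequence per side
(clipped at contig ends, and the realized 5′ flank length offsets the
mature-arm coordinates). Folding uses the ViennaRNA 2.x MFE fold (Turner
2004 nearest-neighbor parameters, 37 °C); N is treated as unpairable and the
result is deterministic. The independent check of the folding route
enumerates *every* non-crossing structure of short random sequences
(canonical + GU pairs, hairpin loops ≥ 3 nt) and scores each with the same
energy evaluator; the enumeration minimum must equal the DP minimum exactly
(tolerance 0.01 kcal/mol, the printed precision).

Stem-loop anatomy is read off the dot-bracket string: the structure is a
single hairpin iff its base pairs form one nested chain; the terminal loop
is the unpaired span inside the innermost pair, the arms run from the
outermost to the innermost paired base on each side, and the bulge metric of
an internal loop/bulge is the unpaired count on its *larger* side (the
published criterion "n < 6" does not say which side; the larger-side
convention is the stricter documented choice). The three acceptance criteria
are: every mature arm wholly 5′ or wholly 3′ of the terminal loop (a mature
may extend below the stem into the flank, but must not span the loop);
largest bulge < 6; MFE ≤ −15.0 kcal/mol exactly ("no more than −15").
Multi-hairpin folds fail the mature-in-arm criterion by definition.
High confidence additionally requires reference-side evidence: annotated as
miRNA in another species, experimental support for a homolog, or previous
report in the target species.

## Small-RNA quantification

Adapter handling is deliberately conservative so that QC is idempotent by
construction: an adapter is detected only when the *complete* adapter
sequence matches within the read with ≤ 2 mismatches (leftmost match wins);
the read is trimmed there, and a read whose trimmed insert is empty or
itself matches the adapter prefix with ≤ 2 mismatches is removed as
adapter/primer material. Partial adapter overhang at the 3′ end of a read is
not trimmed — such reads keep their tail and simply fail perfect genome
matching later. Re-applying QC to its own output is then a no-op, which the
suite asserts on simulated noisy libraries.

The four removal rules run in fixed order (adapter; > 10 % N; > 50 % bases
below Phred 20, the configurable definition of "low-quality"; insert
< 18 nt) and the rejection tally attributes each read to the first rule that
fires, so tallies sum to input − clean. Boundary conventions: exactly 10 % N
and exactly 50 % low-quality are kept (both rules are strict inequalities).

Clean reads collapse to unique tags; a tag survives only with a perfect
full-length genome match (either strand, all placements kept; placement uses
an exact 18-mer index, 18 nt being the minimum clean-read length). Tags with
any placement overlapping rRNA, tRNA, snRNA, snoRNA, repeat features or
exons (UTRs count as exonic sequence) are discarded. Assignment to a mature
miRNA requires: length within ± 2 nt (3′ trimming tolerance), seed identical,
≤ 2 non-seed mismatches over the compared prefix. Matures with identical
sequence share one mature name and their record lists all source precursors;
a tag matching several distinct mature names is counted once per name
(counts are not fractionally split — the field's per-mature count tables are
not fractional). The expressed call needs ≥ 10 reads total across samples
and detection in ≥ 3 individuals (applied per mature, the stricter of the
two possible readings); with < 3 samples the threshold is unsatisfiable and
an error. TPM = count / clean-reads × 10⁶ per sample; mean TPM is the
arithmetic mean over samples.

## Genomic characterization

Context classes are mutually exclusive and assigned in priority order: UTR
(locus inside a UTR feature), exonic (inside an exon), splice-site-
overlapping (inside a gene and overlapping an exon boundary),
intronic (inside a gene, outside exons — introns are derived, never stored),
else intergenic. Containment ignores the host strand; the host gene is
recorded. Mirror pairs are opposite-strand overlaps of ≥ 1 nt. Clusters
chain same-strand neighbors with edge-to-edge gap (next.start − prev.end − 1)
≤ 10 000 nt, extended transitively — published clusters of dozens of genes
spanning > 40 kb only arise under chaining; the equivalence with the
brute-force transitive closure of the pairwise relation is asserted for
random locus sets. Gap is edge-to-edge rather than start-to-start ("within
10 kb" read as separation); the parameter is configurable. Seed classes:
homo iff all members' seeds (positions 2–8 of the dominant mature — the more
abundant arm when expression is available, else 5p) are identical. Family
grouping uses exact seed identity, a proxy for curated family tables, and is
labeled as such.

Age assignment maps each reference's homolog species set through a
configurable species → clade table and returns the broadest clade present
(vertebrate ⊃ mammal ⊃ primate ⊃ Cercopithecidae). For the correlation, age
is coded ordinally with older = higher (vertebrate 4 … Cercopithecidae 1) so
a positive Spearman ρ reads "older miRNAs, higher expression"; ρ uses
average ranks for ties and the two-sided t-approximation for p (scipy), and
needs ≥ 4 points.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a small
primate-like genome (2 × 220 kb by default) carrying 29 planted pre-miRNA
loci — intergenic and intronic singletons, a 3-member homo-seed and a
2-member hetero-seed cluster, exonic/UTR/splice-site placements, one
antisense mirror pair — plus gene models, rRNA/tRNA features, and four
individuals' small-RNA libraries (100 k reads each by default; the real
study's libraries are ~100× larger, a pure scale choice).

Planted precursors are designed hairpins: a 22-nt arm, a 9-nt loop, and the
arm's reverse complement, giving 22-bp stems whose matures are the two arms.
The 10 nt flanking each planted precursor use a C/A-only alphabet, which
cannot base-pair with itself, so the flank-extended sequence the pipeline
folds keeps single-hairpin topology; every design is additionally verified
at generation time against stricter-than-pipeline criteria (MFE ≤ −17,
bulge < 5) and redrawn if it fails — a planted "true" miRNA must be a real
hairpin by construction. Mirror hosts get 3 stem mismatches outside both
seeds so the two strands (a hairpin's reverse complement is again a hairpin)
yield mutually distinguishable matures. Reference records model the other-
species homolog: 0–2 substitutions (uniform) placed outside both seeds,
plus a homolog species set encoding the intended age category and three
decoy references with no genomic locus.

Expression follows the conservation-age gradient: mean TPM =
base (300) × fold, with folds 160 : 10 : 1 : 0.3 for vertebrate : mammal :
primate : Cercopithecidae — the 160× and 10× gaps are the study conditions,
Cercopithecidae set below primate. Per-sample counts are negative binomial
(dispersion 0.2; no published count model exists, NB is the field's default
for sRNA counts), split 75/25 between 5p and 3p arms. Exon-overlapping loci
are silent, since their tags could never survive the exon-overlap filter.
Noise classes per library (adapter dimers 5 %, high-N 2 %, low-quality 3 %,
short 5 %, rRNA/tRNA fragments 10 %) are constructed to fail exactly their
targeted QC rule, except the structural-RNA fragments, which survive QC and
die at annotation filtering. All randomness flows from one integer seed
(default 1455, an arbitrary fixed value); identical seeds give byte-identical
truth sets and libraries.

What the generator does **not** emulate: sequencing errors inside miRNA tags
(an optional substitution rate exists for the reference divergence, not the
reads), ligation/GC bias, isomiR end-heterogeneity, precursor loop
fragments, partial adapters, and genome-scale repeat structure. Passing the
end-to-end tests therefore demonstrates the pipeline's logic is correct
under clean, fully-specified conditions — not that its thresholds are
optimal for real libraries.

## Numerical choices and degenerate inputs

Energies are compared at 0.01 kcal/mol (the printed precision); MFE values
are rounded to 2 decimals. Percent-identity thresholds are strict
inequalities (> 93), MFE and count thresholds inclusive (≤ −15, ≥ 10).
Unfoldable sequences return the all-dot structure at 0.0 kcal/mol; an
all-dot fold has no stem and errors in feature extraction, which the
validation stage converts into a non-hairpin failure. Empty candidate sets,
zero-expression loci and single-placement tags are all legal; zero clean
reads, < 3 samples for the expression call and < 4 points for the
correlation are errors. Cluster detection on duplicate locus names is an
error (names key the partition).

## Problem sizes

Default test/acceptance sizes: 2 × 220 kb genome, 29 loci, 4 × ~55 k reads
after noise, 500 random 15–25-mers for the folding oracle, 100 random locus
sets (≤ 200 loci) for the cluster oracle, 25 kb genomes for the scan oracle.
These sizes keep the full suite around a minute while exercising every code
path; all are configuration, not limits.

## Known limitations

Ungapped homology misses indel-bearing orthologs; the one-locus-one-miRNA
rule collapses genuinely ambiguous paralog assignments by similarity alone;
multi-mapped tags are counted once per mature name, slightly inflating
summed counts relative to fractional assignment; adapter detection requires
the full adapter within the read; seed-identity families under-merge
relative to curated family tables; and the age table ships only common
miRBase species codes (unknown codes are a deliberate error, not a guess).
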