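# Methods

## Scope and data model

The pipeline computes annotation-level statistics of long non-coding RNA
genes (lncGs) against protein-coding genes (PCGs) from five standard
inputs: a gene annotation GTF (GENCODE dialect), a transcript FASTA, a
polyA feature GTF, a VCF of SNVs with clinical-significance flags, and two
TSV snapshots (subcellular localization; validated variant coordinates).
All in-memory coordinates are 1-based inclusive — the native convention of
GTF and VCF — and are converted to 0-based half-open only at BED export.
This keeps the two primary input conventions aligned and confines
off-by-one risk to a single function.

Gene "length" is the genomic span (end − start + 1); transcript length for
sequence analyses is the mature (spliced) sequence length. The two scales
differ by orders of magnitude (tens of kb vs ~1 kb) and both are reported,
never mixed. When a dedicated lncRNA-only GTF lacking `gene_type` is
supplied, all of its genes are treated as lncRNA; chromosome labels with
and without the `chr` prefix are unified against the assembly; records on
unknown sequences (scaffolds/patches) are dropped and counted.

## Density track and peak calling

Each gene is assigned to exactly one fixed window (default 1 Mb) by its
leftmost genomic coordinate, strand-ignored; a midpoint anchor is available
as an option. The trailing partial window is kept so window counts sum to
the chromosome total. Counts per 1-Mb window are numerically identical to
densities in genes/Mb, and the raw counts are what the threshold sees — no
kernel smoothing is applied. A window is a TRUE peak when its density is at
or above the 95th percentile of the window-density distribution of its
gene class, computed genome-wide per class over all windows, zero windows
included (a per-chromosome threshold is available behind a flag). The
quantile estimator is the linear-interpolation (Hyndman–Fan type-7) rule,
the default of the numerical environments this kind of analysis is usually
run in, so thresholds are reproducible elsewhere. Ties at the threshold are
all flagged TRUE (≥ comparison); with all windows equal, every window is a
TRUE peak — the degenerate case is deliberate and tested.

## Positional GC profiles

GC fraction is (G+C)/(A+C+G+T); ambiguity codes leave the denominator. The
positional profile slides a 10-nt window with step 1 (no step is standard,
1 nt is the finest and the default here), then maps window *i* of *m* to
chunk ⌊i·20/m⌋ and averages within chunks. Sequences shorter than the
window contribute one whole-sequence value in chunk 1; sequences with fewer
than 20 windows leave empty chunks, which are excluded from group means
rather than zero-filled. Group profiles average chunk-wise across members.
For subtype profiles the taxonomically ambiguous classes (novel,
name-assigned) are pooled as "Others" or excluded, since those labels say
nothing about genomic context. Note the quantity profiled is positional GC
*content*; true strand skew (G−C)/(G+C) is a separate optional statistic
and never substitutes for it.

Localization calls use fixed term lists (nuclear: Nucleoplasm, Nucleus,
Chromatin, Nuclear, Nuclear speckle, Paraspeckles in the nucleus;
cytoplasmic: Cytosol, Cytoplasm, Ribosome, Ribosome-free cytosol,
Mitochondrion, Endoplasmic reticulum), matched case-insensitively on the
exact terms. A molecule with evidence on both sides, or with no matching
term, is "other" and excluded from the two-group GC comparison; the
comparison itself is a one-way ANOVA, with Benjamini–Hochberg adjustment
applied only when more than two groups are compared (for two groups the
raw p is the honest number).

## Subtype classification

Classification is a pure function of (gene name, accession), evaluated in
fixed order: no curated symbol (name missing, equal to the accession, or
itself an `ENSG…` string) → novel; `LINC` prefix → intergenic; suffixes
`-AS`, `-DT`, `-IT`, `-HG`, `-OT`, each with optional trailing digits →
antisense, divergent, intronic, microRNA-host, overlapping; fallback →
name-assigned. Precedence matters for chimeric names (`LINC…-AS1` is
intergenic because the prefix rule fires first) and is pinned by tests.
Real microRNA host genes are often named without the hyphen (`MIR17HG`);
the hyphenated rule is the documented default and an optional extra rule
captures the unhyphenated form — neither behavior is asserted as canonical.
The rule set is loadable from a 3-column TSV so taxonomy updates need no
code change. No coordinate-based verification against PCGs is attempted:
the classification is lexical by design.

## Architecture and polyadenylation

Exons-per-gene aggregates exon records across all isoforms without
deduplicating shared exons — the only convention under which a gene with
~8.5 isoforms of ~8 exons each averages ~70 exons, as the human PCG
catalog does. A monoexonic gene is one all of whose isoforms are
single-exon (an "any isoform" mode exists for sensitivity analysis). Ties
for extreme genes break on the lexicographically smallest accession.

PolyA features are assigned to every same-strand gene whose span they
overlap (an id-linked mode is the natural alternative when the feature GTF
carries transcript ids). Each site is paired with the nearest upstream
signal in the same gene within 100 nt — the canonical signal sits ~10–30
nt upstream of the cleavage site, so 100 nt is permissive without
cross-gene capture. Spacing is strand-aware: (site 5′ − signal 3′ − 1) on
+, mirrored on −; unpaired sites are excluded from means. Gene-level polyA
presence uses annotated features only; motif scanning (AATAAA / CA, exact,
overlapping matches allowed) is a separate operation and its output is
never mixed into the presence flag.

## Variants

A variant hits a gene when its position lies inside the gene span,
inclusive on both ends, strand-ignored. A variant inside k genes yields k
hits; per-chromosome totals deduplicate by variant id, while subtype
tables count the variant once per gene — so subtype rows can sum to
slightly more than the deduplicated total when genes of different subtypes
overlap. Transitions are exactly {A↔G, C↔T} on single-base ref/alt pairs;
indels and MNVs are "other" and leave the Ti/Tv denominator. Multi-allelic
records contribute one classification per alt. Clinical flags resolve to
the highest-priority true flag (pathogenic > likely_pathogenic > VUS >
likely_benign > benign); flag-free variants are "unclassified" and excluded
from pathogenicity fractions. The χ² goodness-of-fit test compares
observed per-subtype counts per chromosome against expected weights —
per-subtype gene counts on that chromosome by default, with per-subtype
genomic bp and genome-wide subtype shares as alternative weight modes
surfaced in the output metadata. Validated-variant cross-referencing joins
on exact (chromosome, position); duplicate rows in the validated list
collapse to one.

## Synthetic data: what it emulates, and what it does not

The generator emits a 3 × 10 Mb genome by default with, per chromosome,
100 lncGs and 80 PCGs, plus one 30-gene hotspot in window 3 of chr1.
Defaults and the reasoning behind them:

| parameter | default | rationale |
|---|---|---|
| gene spans | log-normal, lncG median 10 kb (σ=1.2), PCG median 30 kb (σ=1.0), truncated to [200, L/10] | reproduces the heavy-tailed span distributions and the lncG < PCG ordering of the human catalog at toy-chromosome scale |
| isoforms/gene | 1 + geometric; means 3.1 (lncG), 8.5 (PCG) | the catalog's mean isoform counts |
| monoexonic fraction | 0.156 (lncG), 0.045 (PCG), applied per gene | the catalog's monoexonic gene shares; gene-level application matches the all-isoforms definition |
| exons/transcript | 1 + geometric(p), p = 0.30 / 0.133 for multi-exon genes | gives overall means ≈ 3.8 and 8.2 exons per transcript |
| GC gradient | (0.60, 0.36) lncG, (0.64, 0.44) PCG | the observed 5′-high/3′-low positional GC decline, with the 3′ floor near 36% |
| polyA | 28% of genes, spacing ~ Poisson(20) nt | the catalog's ~28% polyA-element share and ~20 nt signal→site distance |
| subtype name mix | novel .705, intergenic .112, antisense .091, name-assigned .051, divergent .030, intronic .006, host .004, overlapping .001 | the genome-wide subtype proportions |
| variants | 30,000 SNVs, P(transition) = 2/3, five clinical flags drawn independently (.06/.05/.04/.02/.02), 30% validated, half placed inside lncGs | large enough to pin shares tightly; independent flags deliberately produce multi-flag variants to exercise the priority resolver |

Sequences are generated base-by-base with P(G or C) interpolated linearly
from the 5′ to the 3′ target, so the gradient is recoverable structure,
not an artifact of any analysis choice. Randomness comes from one root
seed split hierarchically (per chromosome, then per stage), making bundles
byte-identical for identical configurations — a manifest JSON records the
configuration and per-file checksums.

What the generator does **not** emulate: realistic human sequence
composition (repeats, CpG islands, splice-site motifs), inter-chromosomal
heterogeneity of counts (each toy chromosome gets the same gene budget, so
cross-class count correlations are degenerate on the bundle), length–GC
coupling, and linkage between clinical flags and position. Passing the
synthetic-recovery tests therefore demonstrates that the *computations*
are correct and that planted aggregate structure is recovered — not that
any biological claim about real annotation holds. Real-release analysis
runs through `analysis/07_real_annotation.py` on files the user supplies.

## Numerical choices and degenerate inputs

- Quantile of a single window equals that window: it is a TRUE peak.
- Pearson correlation on a zero-variance vector raises a typed error
  rather than returning NaN; callers report "undefined".
- GC of a sequence with no unambiguous bases raises; windows that are all
  ambiguity codes propagate NaN and are excluded from chunk means.
- Fisher's exact test is two-sided by summation of table probabilities ≤
  the observed one; tests pin it against full hypergeometric enumeration
  for all margins ≤ 12.
- χ² expected weights are rescaled to the observed total; a zero weight is
  an error (the category should be excluded upstream instead).
- KDE mode detection uses Silverman bandwidth on a 2048-point grid;
  plateau edges count once.
- Ties for extremes and at peak thresholds resolve deterministically
  (lexicographic id; inclusive ≥), so repeated runs are byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
bundles: the shared test bundle uses 80 lncGs + 50 PCGs per chromosome
with 6,000 variants; the recovery conditions use the generator defaults
(330 lncGs, 240 PCGs, 30,000 variants); hotspot detection is measured over
100 replicates of a single-chromosome 20-gene background with a 30-gene
injection (an excess far beyond 5σ of the Poisson-scale background). These
sizes were chosen as the smallest at which the binomial/regression checks
have comfortable margins.

## Known limitations

- Subtype assignment is purely lexical; genes with curated names that
  ignore the suffix conventions are "name-assigned" regardless of their
  true genomic context, and novel genes are never disambiguated.
- The polyA pairing rule (nearest upstream within 100 nt) is a modeling
  choice; annotation releases do not state one.
- The per-chromosome GC figures weight transcripts equally, not by length.
- Variant intersection is position-only; it does not distinguish exonic
  from intronic positions within a gene.
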