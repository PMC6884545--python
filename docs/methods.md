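# Methods

This note documents the models, parameter choices and numerical decisions
behind grcscan, and what the synthetic-data validation does and does not
demonstrate.

## The detection model

A germline-restricted chromosome (GRC) carries paralogs of single-copy
A-chromosomal genes. Let *f* be the number of GRCs per haploid A-genome set
in the sequenced germline tissue and *c* the number of copies of a gene per
GRC. Mapping germline reads onto the somatic reference superimposes all GRC
copies onto the single A locus, giving an expected germline/soma depth ratio
of 1 + f·c over the gene and an expected GRC-allele fraction of
f·c / (1 + f·c) among germline reads at sites where the GRC paralog has
diverged. Both signals vanish in soma, which is the basis of the two
detection channels (coverage excess and germline-specific SNVs) and of both
negative controls (tissue-swap).

*f* is estimated cytogenetically as f = 2G / (4G + 2S) from G FISH-positive
cells (tetraploid germline cells carrying two GRCs) and S FISH-negative
diploid somatic cells in a testis preparation. With the default
parameterisation f = 0.364. The underlying cell counts are not published; the
estimator is validated on reconstructed integer counts (G=67, S=50 gives
0.3641) and on its analytic bounds (f ∈ [0, 0.5]). Physical GRC size is the
synaptonemal-complex length ratio against chromosome 2 multiplied by the
chromosome 2 assembly size: 1.07 × 156.41 Mb = 167.36 Mb.

## Coverage calling cascade

Mean depth is computed in fixed windows (5 kb for calling; 1 kb retained for
fine-scale reporting). The cascade:

1. **Library normalisation** — germline windows are multiplied by the
   soma/germline total-depth ratio.
2. **Outlier-excluded slope correction** — germline windows above
   mean + 2 SD are excluded from a zero-intercept OLS fit of germline on
   soma depth; *all* germline windows are then divided by the fitted slope.
   The excluded windows remain callable: they are precisely the amplified
   ones, and removing them from calling would defeat the method. The zero
   intercept is a deliberate choice — depth is proportional to copy number
   through the origin, and the procedure's estimator was otherwise open.
3. **Filters** — windows below the 5th percentile of germline depth or with
   zero soma depth are flagged `low_coverage` (no pseudo-counts; undefined
   ratios are simply not callable); windows with GC outside 30–60% are
   flagged `gc_fail`. Flagged windows are never called.
4. **Centring** — the log₂ ratio distribution is centred on the mode of its
   histogram (bin width 0.05). The mode rather than mean/median pins the 1:1
   peak even when amplified windows are abundant; the published procedure
   states only that the distribution was centred on zero.
5. **Threshold** — log₂ ≥ 2 is called, inclusively (the boundary value
   counts; inclusivity was unspecified).
6. **Blocks** — adjacent called windows merge; runs ≥ 10 kb are blocks,
   shorter runs singletons. Genes overlapping any called window (half-open
   interval overlap) form the amplified gene set.
7. **Negative control** — the identical directional rule with tissue roles
   swapped counts soma-excess windows; on clean data this is zero.

The interaction order (normalise, then outlier removal, then slope) follows
the text order of the published procedure and is fixed.

## Germline-specific SNVs

A site is called when some non-reference base has ≥ 10 supporting germline
reads, zero supporting soma reads, and soma depth ≥ 10 at the site.
"≥10 read coverage" is interpreted as alt-supporting reads, not total site
depth — total depth alone would admit error alleles; the alternative reading
is available as `count_mode="site"`. Soma sites below the depth floor are
skipped rather than called (absence of evidence is not absence); the floor
defaults to 10 and is configurable. Multi-allelic sites yield at most one
call per (locus, alt); indels are out of scope. Per-sample call sets can be
intersected on (locus, alt) across germline replicates.

High confidence is the union rule: ≥ 5 intersected germline-specific SNVs,
or membership in the coverage-amplified gene set. Consensus pairs substitute
called alt bases into the reference gene sequence ('ref' vs 'alt', equal
length). RNA verification requires ≥ 100 RNA reads at the site and an
alt/ref read ratio strictly above 1%.

## Copy number

`CN = depth × genome_size / library_bases`, exact arithmetic. Library size is
measured in sequenced bases (the same units as depth × positions). For
germline libraries the genome size adds the content of f GRCs to the
assembly size. Note a documented inconsistency in the published
parameterisation: 1223 Mb + 0.364 × 167.3 Mb = 1283.9 Mb, whereas 1329 Mb is
printed (0.634 × 167.3 would give 1329.1 — consistent with a digit
transposition). The formula is implemented as written and the pipeline config
accepts an explicit `germline_genome_size_bp` override; the discrepancy is
documented, not resolved. On simulated data the effective germline genome
size (assembly + f·Σc·gene_length) makes the estimator exact in expectation.

Transcripts with a depth coefficient of variation above 0.5 are split into
contiguous high/low segments by exact 1-D 2-means on per-position depth
(threshold minimising within-class SSE — deterministic, no initialisation),
with runs shorter than 50 bp absorbed into their neighbour to suppress
single-position noise; copy number is then reported per segment.

## Expression enrichment

Background genes are labelled by tissue of maximal expression over the panel
(default: brain, heart, kidney, liver, testis, ovary); genes expressed in no
tissue are excluded, and arg-max ties break by fixed column order. The test
draws `n_reps = 10,000` samples of the query size without replacement from
the full background (query genes included in the pool — whether the
published sampling excluded them is unstated, and including them is the
conservative default) and reports one-tailed empirical p-values: fraction of
draws with a testis/ovary count ≥ observed, and with an "other" count ≤
observed. Raw fractions are reported alongside the (r+1)/(n_reps+1)
convention, which avoids exactly-zero p-values. A Bonferroni factor is
carried for optional family-wise reporting but never applied by default.
The exact hypergeometric tail P(X ≥ k), computed by direct integer
summation of binomial coefficients, is kept as an independent oracle; at the
chicken-panel configuration (N=7918, K=1376, n=65, k=22) it equals
9.663 × 10⁻⁴ and the randomisation p agrees to Monte Carlo error.

## Evolutionary strata

Assignment is purely topological. After rooting on the deepest sampled
lineage (corvid outgroup), the divergence set D is every ref species inside
the MRCA of the GRC ('alt') clade and the focal subspecies ref tip. The
stratum is the innermost ladder level whose cumulative species set contains
D. The stem-versus-within ambiguity at the estrildid level is resolved by
completeness: D equal to all sampled estrildids means the alt lineage
diverged on the estrildid stem (S2); a proper subset means divergence within
estrildids (S3). This is one consistent reading of an under-specified rule
and is stated as such. Multiple alt tips must be monophyletic; otherwise the
tree is unassigned. Trees whose alt-attachment node has bootstrap support
below 50 are unassigned, mirroring the practice of not ranking poorly
resolved trees. Branch lengths never influence assignment.

## Synthetic data generator

The generator emulates the data structure the method consumes, not the
sequencing process: per-position pileup columns per tissue (GRC reads map to
their A-paralog by construction, so no aligner is involved), Poisson depths,
binomially thinned GRC read fractions, divergence sites uniform within gene
bodies, errors uniform over the three non-reference bases, and a smooth
lognormal depth modulation (CV 0.1 per 200 bp, unit mean) shared by both
tissues to emulate the GC/mappability structure that makes real germline and
soma window depths tightly correlated. Genes are placed in equal slots with
jitter confined to half the slot slack so inter-gene gaps never collapse.
Truth tables (per-site GRC alleles, per-gene copies, library sizes) are
emitted alongside as TSV/JSON.

Defaults follow the studied system: f = 0.364, GRC size 167.3 Mb, per-gene
copies up to 308, divergence rate 1% per site, soma depth 15–20×
(re-sequencing-scale), error < 1%, GC spanning 0.32–0.58 so the GC filter is
exercised. Fixed seeds make every output byte-identical across runs.

What it does **not** emulate: read fragments and insert sizes, mapping
ambiguity and mappability bias, indels, linked-read barcodes, real GC-depth
response curves, population polymorphism. Passing the recovery suites
therefore shows the cascade's logic and arithmetic are correct under the
stated dosage model — not that the thresholds are optimal on real libraries,
where mapping artefacts and assembly errors add failure modes the generator
does not produce.

## Validation problem sizes

The recovery suites run at deliberately modest scale: a 4.8-Mb chromosome
with two hundred 12-kb genes (twenty GRC-amplified at f·c between 3.64 and
112) at 15× soma depth for coverage/SNV recovery; 12-kb genes at 20× for
copy number (tolerance 10% of 1 + f·c); 10,000 randomisation draws against
the exact tail (3 Monte Carlo SE); 250 clean trees (50 per stratum) for
strata. Recovery simulations use error-free sequencing because the checks
assert exhaustive guarantees (every adequately covered truth site called,
zero control calls); error behaviour is exercised separately, where even at
an error rate of 10⁻³ the ≥10-read rule yields zero spurious tissue-specific
calls across seeds. Genes span at least two calling windows (12 kb vs 5 kb)
so that a window lies fully inside an amplified gene — the regime the
method targets, where amplified blocks extend over tens to hundreds of kb.

## Known limitations

* Windowed ratio calling, not segmentation (no HMM/CBS), no mappability or
  GC *correction* of depth (GC is only a filter), no sex-chromosome dosage
  model.
* SNV calling has no base-quality model or genotype likelihoods; it is a
  counting rule, faithful to the original but not a general-purpose caller.
* The transcriptome-clustering step of the original copy-number protocol is
  replaced by non-redundant annotated intervals; segment splitting uses
  2-means where the original "split" rule was unspecified.
* Stratum assignment assumes the ladder's taxon sampling; trees missing many
  ref tips should be filtered upstream.
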