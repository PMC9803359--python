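# Methods

`splicegrammar` implements a sequence-grammar analysis of 5' splice-site
(5'SS) selection, the statistics used to study how splicing changes when U6
snRNA loses its ACAGA-box m6A modification, and the bulked-segregant scan
used to map such a mutant in the first place. Everything runs on standard
text formats (FASTA, GFF3/GTF, TSV, VCF) and all fixtures are produced by
seed-deterministic simulators, so the full pipeline is testable without any
sequencing data.

## Coordinates and splice-site windows

Internally all intervals are 0-based half-open; GFF3/GTF 1-based inclusive
coordinates are converted only at the I/O boundary. A donor window covers
positions −3..−1 (exonic) and +1..+5 (intronic), with no position 0; an
acceptor window covers −5..−1 (intronic) and +1..+2 (exonic). Windows are
reported in transcription sense in the RNA alphabet, so minus-strand windows
are reverse complements of the genomic slice. Windows that would run off a
chromosome end are discarded with a logged count rather than padded — a
scoring matrix must never contain placeholder bases. Windows containing N
are excluded from matrix building but are retained elsewhere and score as
missing. Non-GU donors are never silently dropped; they are counted and
logged.

## PSSM scoring of U5 and U6 snRNA interaction potential

A position-specific scoring matrix stores log2 of pseudocounted base
frequencies, `f(b, i) = (count + k) / (n + 4k)` with pseudocount `k = 1` per
base per position by default. The pseudocount prevents −inf scores for
unobserved bases; because all downstream comparative statistics are
rank-based (Spearman), results are insensitive to `k` in (0, 2] (a property
the test suite asserts). Log base 2 is a convention; ranks are invariant to
the base.

The U5 snRNA loop 1 interaction is scored over the exonic −2..−1 positions;
the U6 snRNA ACAGA-box interaction over the intronic +3..+5 positions. A
site's log-likelihood is the sum of log2 frequencies of its observed bases.
Matrices are built from junction-deduplicated sites (one count per unique
genomic donor) so that genes with many isoforms do not dominate the
frequencies; transcript-weighted building is available by skipping the
dedup step. For pairs of alternative donors ordered upstream/downstream
along the transcription direction, the log-odds ratio uses the downstream
site as the denominator: positive values mean the upstream site has the
greater PSSM score.

## Discrete U5/U6 classes and the two major donor classes

The U5 class of a donor is the Hamming distance of its −2..−1 bases from
the consensus AG (0–2); the U6 class is the distance of +3..+5 from RAG
with the degenerate R matching either purine at zero cost (0–3). N counts
as one edit — a conservative choice for the rare ambiguous windows, which
are logged. Two exact flags mark the major classes: `is_aggu` (AG exon end
plus GU intron start) and `is_gurag` (+1..+5 matches GURAG); they are not
mutually exclusive, and a doubly perfect AG//GURAG site carries both. Where
a single partition is needed (class-recovery checks, Fig-7-style splits),
`major_class` compares the two distances on their normalised scales and
breaks ties with the exact flags; the `is_gurag` flag is the primary split
for the "GURAG vs all other" style of comparison, with the complement as
background.

For a pair of alternative donors oriented lost → gained (the site with
reduced usage first), the switch category at +4 is the most specific of
A→U, A→B, S→U, B→A, same, other (IUPAC sets B={C,G,U}, S={C,G}); positions
+5 and −1 support G→H / H→G. Contingency-table axes order classes by the
mean PSSM log-likelihood of their members, strongest first, with ties
broken by class value.

## Alternative-splicing events and PSI

Events are extracted pairwise from the exon chains of each gene's
transcripts: A5/A3 from intron pairs sharing an acceptor/donor boundary, RI
from an exon strictly spanning another transcript's intron, SE from an
internal exon whose flanking junctions coexist with a direct skip junction.
A boundary-sharing intron pair whose difference is bridged by an exon and a
second junction is an exon-skipping configuration, not a genuine
alternative-site shift, and is suppressed from A5/A3 calls. Multi-way
alternative donors decompose into all pairs. Mutually exclusive exons and
alternative first/last exons are outside the analysed classes.

The inclusion form is defined deterministically and strand-symmetrically:
the shorter-intron form for A5/A3, the retained form for RI, the
exon-included form for SE. PSI is inclusion abundance over total event-form
abundance from the supplied transcript TPM table, and is missing when the
total falls below the expression floor (default 1.0 TPM summed over event
forms, which prevents 0/0 PSIs from unexpressed genes). No read-level
counting is performed; abundances are taken as given.

## Differential-splicing models

Each event's PSI row is fitted by OLS as
`PSI ~ genotype + temperature + genotype:temperature` with genotype a
two-level factor (wild type as reference) and temperature categorical with
the 20 °C growth temperature as reference — four unevenly spaced levels do
not justify a linear trend. Gaussian-identity on raw PSI keeps effect sizes
on the PSI scale on which they are interpreted; a logit transform is
available behind a flag. Per-term p-values come from partial F-tests on
nested model pairs (each main effect against the additive model, the
interaction against the additive model). Rows need at least `min_obs = 3`
non-missing PSIs per genotype; missing PSIs are dropped per event
(complete-case, no imputation). Zero residual variance or a rank-deficient
full design flags the event degenerate with missing p-values. BH q-values
are computed within term across events and thresholded at 5% FDR by
default. Delta PSI is the mutant − wild-type mean, per temperature and
pooled; for alternative-site pairs its sign orients the lost (sensitive)
and gained sites and the direction of the usage shift (negative distances
= shift toward the upstream site).

## Composition statistics

Logo-input frequency matrices are empirical probabilities without
pseudocount, built from deduplicated sites. Composition differences between
two site sets are tested per position with a groups × bases G-test
(`G = 2 * sum O ln(O/E)`, expectations from pooled margins), summed with
their degrees of freedom over the −2..+5 donor positions by default;
pooling all positions into one table is available as an option. Zero
observed cells contribute nothing and base columns absent from both sets
are dropped from the df, which avoids inflated df on small skewed fixtures;
a Williams correction is available behind a flag but off by default, as the
intended use is large site sets. Correlations of scores and of pair
log-odds ratios are tie-corrected Spearman coefficients with the
large-sample p-value approximation (minimum three complete pairs).

## Bulked-segregant scan

Variants are filtered to EMS-consistent transitions: G>A plus, by default,
C>T as the reverse-strand representation of G:C→A:T (strict G>A-only mode
is available). Each SNP's pool × allele 2×2 depth table gives a G
statistic; per-chromosome the statistics are smoothed at SNP positions with
a tri-cube kernel `w(d) = (1 − (|d|/h)^3)^3`, total window 2 Mb (half-width
h = 1 Mb; a flag reinterprets the figure as the half-width). Evaluating at
SNP positions keeps the track overlayable on per-SNP allele fractions. The
candidate interval is the contiguous run of SNPs with smoothed G at or
above 95% of the global maximum containing that maximum; tied maxima
resolve to the widest run, and a flat track returns the whole chromosome
with a warning. Functional-impact annotation of candidate SNPs is out of
scope; externally produced labels can be joined onto the variant table.

## Synthetic data: what it emulates and what it does not

`simulate_sites` draws donors from a two-class mixture (default weight 0.5)
with per-position emissions: the AG//GU-like class has A at −2 and G at −1
with probability 0.9 and uniform +3..+5; the //GURAG-like class has uniform
exonic bases, R (A or G in equal parts) at +3 and A, G at +4, +5 each with
probability 0.9; both classes fix G,U at +1..+2 with probability 0.98 and a
uniform −3. Sites are realised as identical-size two-exon genes on the plus
strand of one toy chromosome built from fixed spacer blocks, so every
coordinate is hand-checkable and extraction round-trips exactly. The 0.9 /
0.98 emission strengths are a stylised, clearly separated two-class
population; real donor sets have graded class memberships and positional
dependencies the generator deliberately omits, so the anticorrelation
magnitude measured here (|rho| ≈ 0.6) characterises the generator, not any
real genome — real annotations give weaker values. Passing tests
demonstrate the statistics recover planted structure, not that any
particular genome shows a particular effect size.

`simulate_psi` plants genotype effects (default: 20% of events, |delta
PSI| = 0.2 with random sign) and optional per-temperature interaction
profiles on uniform baselines in [0.2, 0.8], adds N(0, 0.05) noise, and
clips to [0, 1] (clip rate logged, <1% under defaults). The design mirrors
six replicates of two genotypes at 4/12/20/28 °C. Real PSI noise is
mean-dependent and bounded; the Gaussian approximation is adequate away
from the boundaries, which the baseline range enforces.

`simulate_bsa` models a recessive causal locus in an F2 from a backcross:
the mutant pool is homozygous at the causal SNP (marker allele fraction
1 − c at recombination fraction c) and the aphenotypic pool segregates 1:2,
giving 1/3 + c/3; c = min(0.5, 0.04 × distance in Mb), a typical
plant-genome recombination density. Per-SNP pool allele counts are binomial
over 2 × 50 chromosomes, read depths Poisson(50), alt reads binomial within
pools. Allele identities are independent across SNPs (no within-individual
haplotype correlation), which slightly understates the noise correlation of
real pools but leaves marginal expectations exact. Default scale: one 20 Mb
chromosome, 2000 SNPs, causal position drawn uniformly from the central
80% when unspecified.

Each generator consumes draws from a single `numpy.random.default_rng(seed)`
in a fixed order, so equal seeds give byte-identical output files.

## Numerical choices and problem sizes

Tolerances: PSSM frequency normalisation to 1e−9; zero-residual-variance
detection at SSR < 1e−12; interval-calling peak ties at 1e−12 of the
maximum. The test and acceptance runs use the defaults above (10,000 sites
with a 100,000-site re-simulation for rank-correlation stability, 1000
events per differential-splicing run, 20 bulked-segregant replicates),
sizes at which every check completes in seconds while keeping Monte-Carlo
error well inside the asserted bounds.

## Known limitations

No higher-order or maximum-entropy splice models (positions are treated
independently); no free-energy duplex scoring of snRNA:5'SS helices; no
read-level quantification or junction counting; no NMD/productivity
classification; no motif discovery; linkage between alternative 3'SS choice
and 5'SS events is reported as within-gene co-occurrence only, without a
causal model. Plotting is not included; all outputs are TSV/JSON tables
suitable for any logo or heatmap tool.
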