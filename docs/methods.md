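# Methods

## Cohort definition

Tumors are partitioned from the sample metadata alone. *Cases* carry a
bi-allelic BRCA1 or BRCA2 inactivation (`brca_status` ∈ {bBRCA1,
bBRCA2}); *controls* are BRCA1/2 wild type (no mono-allelic alteration
either) with little evidence of HR deficiency — SBS signature 3 is not
the tumor's dominant signature and the LST count is strictly below 12.
All other tumors are excluded. "Dominant" means signature 3 has the
largest exposure among the tumor's decomposed signatures; decomposition
itself is an input, not computed here. The two control conditions are
applied as independent filters. Case groups smaller than 10 (config
`min_group`) are skipped with a logged reason.

The BRCAness flag used in the single-gene loss-of-function analysis is
LST-high **and** signature-3 exposure strictly above 20%.
Loss-of-function classes are the truncating events: nonsense, frameshift
insertion/deletion, canonical splice site; missense is excluded. Odds
ratios apply the Haldane–Anscombe 0.5 correction whenever a cell of the
2×2 table is zero.

## Coordinates and formats

Internally every interval is 0-based, half-open, "chr"-prefixed.
SEG-dialect segment tables are treated as 1-based inclusive and
converted on ingestion (start−1, end); BED files pass through unchanged.
Chromosome Y is excluded throughout (the bundled hg19 cytoband table has
851 bands after that exclusion); mitochondrial and unplaced contigs are
dropped with a warning, any other chromosome token is a fatal error.
Result tables serialize floats at 17 significant digits and are re-read
with round-trip float parsing, so a seeded run is byte-reproducible and
`read(write(x)) == x` holds exactly.

## Cytoband copy number

A band's copy number is assigned from the segments overlapping it: if
the union of overlaps covers ≤ 50% of the band the cell is *missing*
(excluded from all downstream numerators and denominators — absence of
evidence, not neutrality). Otherwise the copy number whose segments
contribute the greatest total overlapped length wins; exact length ties
take the **lower** copy number, a deliberate conservative choice toward
the deletion-focused analysis. The assignment is invariant to splitting
any segment at an interior point. Ploidy is used as a real number,
without rounding: deleted iff CN ≤ ψ − 1, amplified iff CN ≥ ψ + 3
(offsets configurable). The fraction of genome altered is the
length-weighted fraction of segments whose CN differs from round(ψ).

## Enrichment and the fixed-margin null

Per band and direction (deletion / amplification as separate FDR
families), a two-sided Fisher exact test on evaluable cells, BH-adjusted
across bands. "Enriched" requires both q < α (default 0.05) and a higher
alteration frequency in cases; bands missing in more than half of either
group are flagged low-coverage but still tested.

The permutation null preserves each band's total alteration count (row
sums) and each tumor's alteration burden (column sums). States are
sampled by a seeded checkerboard-swap Markov chain: burn-in of 10 × nnz
attempted swaps, thinning of 1 × nnz between samples (both
configurable); constant rows/columns are immutable fixed points, so
degenerate matrices are returned unchanged. Missing cells enter the
binary matrix as unaltered, matching the 0/1 coding of the test. Because
margins are fixed, a band's Fisher p depends only on its altered-case
count; per-band margin-conditional lookup tables therefore replace per-
iteration Fisher calls, and BH is re-run inside every permuted matrix
(`recompute_bh=False` reuses the observed BH threshold instead — the
re-computation is the default because the statistic "number of
significant bands" is otherwise not well defined per permutation). The
empirical p uses add-one smoothing, (1 + #{perm ≥ obs}) / (1 + B).
Desk-scale runs use B ≤ 1000; the statistic is cheap enough that larger
B is purely a time trade-off.

## Transcriptional consistency score

Dichotomization is at the per-gene median FPKM over **all** tumors;
"low" means strictly below, so ties at the median count as high — the
conservative reading when tie handling is unspecified. A gene inherits
the deletion call of the cytoband containing its midpoint (configurable
in principle to direct segment overlap; the midpoint rule keeps gene-
and band-level analyses consistent). TCS is computed only when at least
5 case tumors carry the deletion. The normalization control set is
**non-deleted control-group tumors** (not all non-deleted tumors): the
score asks whether the deletion, rather than cohort-wide factors,
explains the down-regulation. When the control proportion is exactly 0
with a positive case proportion, the normalized score is reported as
infinity and the thresholds are applied as usual. Pass criteria are
strict inequalities: TCS > 0.7 and normalized TCS > 1.5.

## CRISPR screens

Bayes-factor tables are inputs (BAGEL-style, one row per gene); the
package starts where the screen analysis ends. RPS = BF_KO − BF_WT,
computed over the shared gene set. Categories per background:
non-essential = the ceil-half of negative-BF genes with lowest BF,
essential = the ceil-half of positive-BF genes with highest BF, the rest
(including BF = 0) neutral; ties break by gene symbol so the split is
deterministic. The proliferation evidence used by the integration step
is the category *switch* (essential → neutral/non-essential, neutral →
non-essential) — the gene-level rule for "promoting proliferation in the
knockout"; requiring membership in the top 50% of negative-RPS genes in
addition is available via `require_top_negative`. The DepMap filter
averages gene effects across the selected bi-allelic BRCA1 cell lines
(mean, configurable in spirit to all-lines-exceed) and keeps genes with
mean effect > −0.5, strict.

## Synthetic cohorts

The generator emulates the ovarian study scale: 90 cases vs 140
controls, 200 cytobands tiling a toy genome contiguously (1 Mb bands, 25
per chromosome), 1000 genes placed inside the bands. Twenty planted
bands delete with probability 0.6 in cases versus 0.15 everywhere else;
deletions are realized as segments spanning the band at CN = ψ − 1
(neutral elsewhere at CN = ψ) for per-tumor ploidies drawn from
{2, 3, 4}, which exercises the ploidy-relative thresholds. A "ragged"
mode jitters segment boundaries by up to ±20% of the band length to
exercise the majority-overlap rule (jitter is capped below 25% so the
planted call is always recoverable).

Expression is log-normal around per-gene baselines (log2 μ ~ N(3,1),
noise sd 0.5); half the genes inside enriched bands are *coupled* —
shifted down by 2 log2 units in any tumor whose covering band is
deleted. Bayes factors follow the class ranges essential [5,15],
non-essential [−15,−5], neutral [−1,1]; non-switch genes share one
concordant base value across both screens, while the 40 planted switch
genes are essential in wild type and non-essential in the knockout.
Per-screen Gaussian noise defaults to sd 0.2: the neutral band is only 2
units wide, so noise must stay well below the 4-unit class gap for the
ceil-half category rule to remain stable — "clear separation with
tunable difficulty", with difficulty raised explicitly via
`bf_noise_sd`. Half the switch genes are drawn from the coupled set;
these form the planted viable genes (the three-way truth intersection).
Mutations occur at a uniform 10% rate per gene and sample across both
groups (null co-mutation structure), and a small DepMap-style effect
table places switch genes above the −0.5 threshold.

What the generator does **not** emulate: realistic segmentation noise
and focal events, signature decomposition from trinucleotide spectra,
expression dosage gradients (coupling is a fixed shift), correlated
gene–gene structure, or sgRNA-level screen noise. Passing tests
demonstrate correct recovery of the planted statistical structure under
these idealized conditions, not performance on real cohorts.

## Numerical choices and degenerate inputs

Fisher p-values use the minimum-likelihood two-sided rule (all tables
with point probability ≤ observed, within 1e-7 relative slack), matching
the exact rational-enumeration oracle to 1e-10 on all small-margin
tables. BH is implemented directly from the step-up definition and
cross-checked against statsmodels. Empty mutation universes, samples
without segments, genes with midpoints outside every band, all-constant
expression rows and zero-negative-RPS screens all degrade to defined
results (p = 1, missing columns, warnings) rather than errors; truly
unusable inputs — duplicate sample ids, inverted intervals, unknown
chromosomes, empty group assignments — fail fast with the offending
record named.

## Problem sizes

Default test and demonstration runs use 200 bands × 230 samples × 1000
genes with 200–1000 permutations; multi-seed calibration suites use 20
(recovery) and 40 (null calibration) seeds. These sizes make every
distributional claim testable in seconds while keeping the per-band
counts in the regime the published cohorts occupy.

## Known limitations

Real cytoband analyses face segmental aneuploidy patterns and purity /
ploidy estimation error that the generator sidesteps; the >50% overlap
rule is resolved as fraction-of-band (the quantity assigned is the
band's CN), and the multi-segment dominance rule is one defensible
choice among several — both are configurable points for sensitivity
analysis. The permutation chain's mixing is adequate for the matrix
sizes tested (verified empirically by state-change rates); very sparse
or near-degenerate matrices may need longer burn-in. Differential
expression, deconvolution and pathway enrichment are deliberately out of
scope; their outputs can be supplied as drop-in gene lists or expression
tables.
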