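# Methods

This note documents the models, conventions and numerical choices behind
`teregulon`, and what the synthetic cohorts do and do not establish about
real data.

## Coordinates and interval semantics

All intervals are 0-based half-open internally (BED convention); GFF3 input
is converted on read and report tables print insertion ranges 1-based
inclusive. "Within *w* bp" always means a gap of at most *w* between the
closest interval ends, with any overlap counting as distance 0 — the
behaviour of standard genome-arithmetic windowing tools. Boundaries are
inclusive: a gap of exactly *w* qualifies.

## TE consensus calling

**Reference insertions** (annotated in the reference assembly) are retained
for a population only when the genotyping caller reports them present or
polymorphic in *every* replicate sample. A missing or duplicated status for
any (TE, sample) pair excludes that TE with a logged warning rather than an
error, since upstream genotypers routinely drop uncallable loci.

**Non-reference insertions** are called per sample by two independent
callers. Within each caller, same-family calls (family labels compared
case-folded and whitespace-trimmed; no alias dictionary) whose intervals lie
within the merge distance (default 25 bp) are merged across samples into
union intervals, pooling sample support. A consensus insertion is emitted
where a merged call from one caller lies within the merge distance of a
same-family merged call from the other and each caller supports it in at
least `min_samples` (default 2) of the replicates; the output interval is
the union of the paired intervals, and overlapping outputs of one family
are re-merged so the final set is exhaustive. Note that consensus counts
are *not* monotone in the merge distance: a larger distance can pair
caller-A and caller-B calls (and pool sample support) that a smaller one
could not. Monotonicity does hold within-caller and for the support
threshold, and the tests assert exactly those forms.

**Cross-population uniqueness** marks an insertion population-unique when
the other population's consensus set has no same-family insertion within a
match distance (default 25 bp, mirroring the merge rule) on the same
chromosome; matching is symmetric. This identity rule is a package
convention — how cross-population identity of insertions "present only in
one population" should be decided is genuinely open, and the 25 bp/family
choice simply reuses the within-population merge semantics.

**Gene linking** is windowing, not nearest-gene assignment: every
(TE, gene) pair within 1 kb produces a link, so one TE may annotate several
genes and vice versa, and equidistant ties produce both links. Relative
positions are strand-aware: containment (or spanning the whole gene) is
`genic`; crossing exactly the 5′ or 3′ boundary is `us_ovlp` / `ds_ovlp`;
otherwise `upstream` / `downstream` with the gap as distance. Synthetic
genes carry no exon structure, so `genic` stands in for finer intragenic
labels such as "intronic".

## Differential-result processing

Significance is `p_adj ≤ alpha` with `alpha = 0.05`; the threshold is
inclusive (the boundary convention is not universal among upstream tools,
so it is configurable) and a missing adjusted p — an upstream-filtered
gene — is never significant. Genes present in only one population's table
count as not significant where absent rather than being dropped, since the
two populations are filtered independently upstream.

Shared/unique classes partition the union of genes: shared when significant
in both populations, unique when significant in exactly one. DE/DA genes
are significant in both assays *within* one population; the shared DE/DA
set is the intersection of the two populations' DE/DA sets.

Concordance classes come solely from the signs of the RNA and ATAC LFCs.
An exact zero has no sign: the gene is classed `undefined` and leaves the
denominator. Shrunken LFCs are almost surely nonzero, so this matters only
for degenerate inputs. Proportion summaries report pct = 100·k/n with the
plain binomial proportion standard error 100·√(p(1−p)/n); this SE
convention reproduces published percentage ± SE tables of this design to
the printed precision at both n = 114 and n = 312.

The concordance regression fits `rna_lfc ~ atac_lfc * C(declass)` by OLS
with the population-local DE class (shared / unique / not significant) and
reports per-term partial F tests with Type II sums of squares (the
analysis-of-deviance convention of the R ecosystem this analysis style
comes from; Type III is switchable via `anova_type`). With a single class
present the model collapses to the simple regression.

Promoter aggregation defines the promoter as the strand-aware window
running 1 kb from the 5′ gene end away from the gene body, weights each
overlapping peak by its overlap length, and takes the weighted-mean LFC;
the adjusted p is carried from the largest-overlap peak (leftmost on ties).
Zero total overlap weight falls back to equal weighting with a warning.
The exact weighting used by upstream integration tools is not specified,
so this is a documented package choice.

## TE–regulation association

Genes collapse to a three-level TE factor with precedence
non-reference > reference > none; non-reference insertions are the recent,
likely-polymorphic ones, hence the precedence. Five characteristics are
tested per population: DE class, DA class, direction of significant
expression change, direction of significant accessibility change, and the
joint expression/accessibility direction over all genes. The omnibus test
is Pearson's χ² without continuity correction (uniform across table sizes;
configurable upstream tools differ only for 2×2). Zero-margin rows or
columns are dropped with a warning; a characteristic with fewer than two
observed levels skips the test. When the omnibus p ≤ 0.05, each cell gets
a standardized residual z = (O−E)/√(E(1−r/N)(1−c/N)) and a two-sided
normal p, Bonferroni-adjusted across the cells of that table only (the
convention of the dedicated post-hoc packages). Exact tests for sparse
tables are out of scope — a documented limitation for very small cohorts.

## Transgenerational classification

Control-drift exclusion removes genes significant in the
control-vs-control generation contrast from the descendant (G6) responder
list only — the direct (G3) list is left intact, matching how such
filtering is applied in practice. TEI candidates are the intersection of
the G3 responders with the filtered G6 responders. Direction consistency
is sign agreement of the two generations' LFCs; zero LFCs leave the
denominator (logged), and the reported percentage is rounded to the
nearest integer while full precision is retained internally. The
cross-generation regression is OLS of G6 LFC on G3 LFC. Keyword flags use
case-insensitive *substring* matching (so "epigen" hits "epigenetic");
token-based matching would miss exactly the intended morphological
variants.

## Synthetic cohorts

The generator emulates the statistical structure of a two-population,
two-generation stress experiment at desk scale: 2,000 genes on 4
chromosomes, 3 replicate samples per population, 500 reference and 350
non-reference insertions (70% within 1 kb of a gene), 25% shared and 10%
per-population unique responders, log2 effects of mean 1.5 (spread 0.75)
with RNA/ATAC correlation 0.7, observation noise 0.25 (heteroscedastic,
scaled per gene by U(0.5, 1.5)), caller detection probability 0.95 with
2–3 bp coordinate jitter, 5% control-drift genes, and a cross-generation
coefficient of 0.34 for half of each population's responders
(`g6 = 0.34·g3 + N(0, 0.5)`). TE density per gene is deliberately higher
than in a real fly genome so that TE-linked gene classes remain well
populated at 2,000 genes; at genome scale the density is lower but the
absolute counts are larger. The planted TE–regulation association pushes
genes hosting a non-reference insertion in population 1 toward
down-regulation with odds `te_assoc_odds` (default 3; odds 1 plants
nothing), mirroring a cold-population expression association; population 2
carries no planted direction effect.

P-values are two-sided normal tails of observed LFC over its per-gene sd,
Benjamini–Hochberg adjusted within each table, mirroring per-contrast
adjustment upstream. At `lfc_noise_sd = 0` the emitter returns the exact
truth with p_adj 0/1 by non-nullness — the degenerate limit used by the
exact round-trip tests, since a z-statistic is undefined at zero sd.
Placement is slot-based: chromosomes are cut into equal slots with >1 kb
margins, each gene or intergenic TE owns one slot, and near-gene TEs share
their host gene's slot — deterministic, collision-free and O(n), with an
explicit feasibility check replacing iterative rejection sampling.
`easy_config()` (perfect detection, zero jitter, effects of mean 3, noise
0.05) is the high-signal regime in which recovery invariants are checked:
consensus sets match truth exactly and class/TEI recovery exceeds 95%/99%.

What the cohorts do *not* emulate: read-level evidence, count
distributions and shrinkage, exon structure, correlated genes, TE
family-specific behaviour, or upstream gene filtering. Passing recovery
tests therefore validates the inference chain's logic and calibration, not
the upstream measurement process.

Two observed properties worth knowing: (i) the cross-generation slope
fitted over *significance-selected* TEI candidates exceeds the planted
population-wide coefficient, because conditioning on descendant
significance selects larger inherited effects — planted-slope recovery is
therefore checked on the planted transgenerational subset; (ii) BH false
positives keep realistic shared/unique classification just below perfect
even at high signal, which is why exact-equality checks use the zero-noise
limit.

## Determinism

Every emitter and the pipeline itself are pure functions of
(configuration, seed): seeds derive from a root seed via independent
sequence spawns per emitter, tables are written with fixed float
formatting, and the run manifest records per-file SHA-256 digests so
repeated runs can be verified byte-identical.
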