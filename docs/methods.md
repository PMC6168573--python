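# Methods

`mirnet` implements a system-level integration of bulk mRNA and miRNA
sequencing data from a case/control disease time-course — the motivating
system is a mouse myocardial-infarction (MI) model sampled at an early (1
day), middle (1 week) and late (8 week) stage against stage-matched sham
controls — and selects miRNA families whose expression moves consistently
against a sufficiently large set of their predicted targets at every stage.
This note records the model, the parameter choices, the numerical
conventions, and what the synthetic validation does and does not show.

## Normalization model

Both layers start from raw read counts. mRNA abundance is quantified as
FPKM (count / (feature length in kb × column total in millions)) using the
annotated feature length directly; no effective-length correction is
applied, since the pipeline starts from a count matrix rather than from an
assembler's transcript models. miRNA abundance is RPM (count / column total
× 10⁶), so each column sums to 10⁶ before row filtering. Features that are
exactly zero in every sample are removed; remaining values receive a +1
pseudocount, are log2-transformed, and are quantile-normalized across all
samples jointly (a flag stops the chain after the log step). Each matrix
carries an explicit transform state (`linear → log2p1 → log2p1_quantile`)
and every stage checks its precondition, so a half-normalized matrix cannot
flow downstream.

Quantile normalization replaces the rank-r value of every column by the
mean of the r-th order statistics across columns. Within-column ties share
the mean of the substituted values over the tied span. Two consequences are
worth stating plainly: on tie-free columns the operation leaves every column
with the identical sorted value vector and is exactly idempotent; on columns
containing ties (equal counts are common in the low-abundance tail) the
averaged tie values deviate from the common multiset, and re-application can
shift them slightly. This matches the dominant implementation of the
convention (e.g. limma's `normalizeQuantiles` with tie averaging). The
contract tests therefore assert exactness on tie-free rows and pin the tie
behaviour separately.

## Differential expression

Per stage, each feature is tested MI vs sham with an independent two-sample
t-test on the log2 normalized values — Welch by default, pooled variance
behind a flag, since with 3 replicates per group neither choice is
well-powered to detect variance inequality and Welch is the safer default.
When both groups have zero variance the test is degenerate; the documented
contract returns p = 1 for equal means and p = 0 otherwise. Fold change is
computed on the linear means of the back-transformed (2^x) values, i.e. on
the pseudocounted linear scale, and reported with the signed convention
(−4 for a 4-fold drop). P-values are Benjamini–Hochberg adjusted across all
features within each stage. A feature is called `up` iff adjusted p < 0.05
**and** log2FC > 1 (`down` symmetrically); the joint rule means a large fold
change with poor support, or strong support for a small shift, both yield
`ns`. Thresholds are stored with the table.

One practical consequence of the +1 pseudocount: fold changes of barely
expressed features are compressed toward 1, so a true 5.7-fold change in a
gene whose FPKM is ~1 will not clear the |FC| > 2 rule. This is intended
behaviour (it suppresses noise-driven calls in the low-expression regime)
and it shapes the synthetic-data design below.

## Integration cascade

Differentially expressed miRNAs are aggregated to seed families via a
family registry: a family is DE at a stage if at least one member is DE
there, its direction is the sign shared by all DE members, and internally
conflicting families are treated as not significant at that stage. Five
filters are applied in order, and the surviving family count after each is
recorded:

1. **top-k & stage-robust DE** — the family has a member among the top k
   (default 50) most highly expressed DEmiRs, ranked by mean RPM across all
   samples (global ranking; a per-stage mode exists behind a flag), and is
   DE with one consistent sign at every stage;
2. **conservation** — the family is conserved in mouse, rat and human (all
   registry members must carry all three flags);
3. **target filter** — at least one predicted target with weighted context++
   score percentile (WCSP) strictly greater than 50 and ≥ 1 seed site;
4. **anti-correlation** — at every stage, at least one filtered target is a
   DEG moving opposite to the family;
5. **minimum conserved targets** — at every stage, at least `min_targets`
   (default 10, inclusive) of those anti-correlated targets carry a
   conserved site (the site-level TargetScan-style flag, distinct from the
   species conservation of the miRNA itself).

Per-stage target sets are counted independently — the robustness rule does
not require the *same* ten genes at every stage, only ten at each. Both
boundary conventions are deliberate: WCSP strictly > 50, target count
≥ 10. Families eliminated at the combined first filter carry a fine-grained
reason (`top_k` vs `de_all_stages`) in the elimination record so each
negative control can be attributed to exactly one filter. Edges are unique
per (family, gene, stage); multiple prediction rows collapse to one edge
that is conserved-site if any row is. Every emitted edge is validated
against the opposite-direction invariant at construction.

## Candidate cascade

For a selected family, candidate effectors are narrowed in four steps: all
predicted targets → WCSP/seed filter → intersection with DEGs moving
opposite to the family (union over stages by default; the per-stage mode is
a flag, since a stage-pooled DEG list is the natural reading of a
stage-robust family) → intersection with an apoptosis GO term chosen by
direction: a down-regulated family is intersected with *positive regulation
of apoptotic process* (its de-repressed targets are pro-apoptotic) and an
up-regulated family with *negative regulation of apoptotic process*. GO
matching is by exact term label with no term-tree propagation. Counts are
asserted non-increasing.

## Enrichment statistics

**GSEA.** Genes are ranked per stage by signal-to-noise,
(μ_MI − μ_sham)/(σ_MI + σ_sham), with each group's σ floored at
max(0.2·|μ|, 0.2) so the denominator never vanishes; ties are broken by
gene id. The enrichment score is the signed maximum deviation of the
weighted Kolmogorov–Smirnov running sum (hits add |metric|^p normalized
over hits, default p = 1; misses subtract 1/(N−K)). When the positive and
negative extremes tie exactly in magnitude (possible only at p = 0 on
symmetric layouts) the positive extreme is returned. A set covering the
whole universe is degenerate (miss decrement undefined) and returns ES = 1
with a warning. Significance uses gene-set permutation — n_perm (default
1,000) random same-size sets from the ranked universe — with the +1
correction, p = (1 + #{|ES₀| ≥ |ES|})/(1 + n_perm), so p is never zero;
NES divides ES by the mean |ES₀| of matching sign, and q is BH across the
collection. The permutation path computes ES from sorted hit positions in
closed form; its exact equivalence to the running-sum evaluation is covered
by tests.

**GO.** Right-sided hypergeometric test: p = P(X ≥ k) for k annotated genes
in a query of n from a universe of N with K annotated, BH-corrected across
terms. The implementation delegates the tail probability to
`scipy.stats.hypergeom`; tests verify it against exact binomial-coefficient
enumeration over every realizable (N ≤ 12, K, n, k).

## Synthetic-data generator

The generator writes a complete study — seven data files (mRNA counts with
lengths, miRNA counts, design, target predictions, family registry, GO
annotations, GMT gene sets) plus a planted-truth document — from one seed.
All randomness flows through a fixed stream-splitting scheme (one
`SeedSequence` child per artifact), so each artifact is bit-identical across
runs and independent of the others.

Counts are negative binomial (gamma–Poisson, var = μ + φμ²) with a shared
dispersion φ = 0.005, the regime of well-behaved biological replicates; at
the default depths this yields within-group replicate correlations of log2
values above 0.99, emulating the tight replicate scatter typical of bulk
heart RNA-seq. Library sizes are 5×10⁶ (mRNA) and 2×10⁶ (miRNA) reads with
5% log-normal variation — deliberately smaller than a production sequencing
run (tens of millions) so that a full study generates in about a second;
the filter logic under test is insensitive to depth once counts are
comfortably above the pseudocount regime. Gene baseline abundances are
log-normal (σ = 1.5); genes designated as planted targets have their
baseline floored at the median abundance, because (see above) the +1
pseudocount makes anti-correlation undetectable by design for silent genes.

miRNA abundances follow a truncated power law i^−α whose exponent is
calibrated by bisection so that the expected top-50 share of mean RPM
(planted fold changes included) equals the configured target, default 0.96
— the concentration regime in which a handful of miRNA species dominates
the tissue's miRNA pool. Differential effects multiply the MI group mean by
2^±2.5 at the planted stages. The DE programs cover 15%/20%/2% of genes at
the three stages, reproducing the characteristic collapse of the
differential signal at end stage.

Two planted families (one down-regulated four-member family, one
up-regulated singleton, mirroring the archetypes miR-30-5p and miR-142a-5p)
satisfy every filter, each with 12 disjoint opposite-direction DE targets
per stage and a planted candidate subset (9 and 4 genes) annotated with the
direction-matched apoptosis term; background members of the apoptosis terms
are drawn away from all planted target blocks so the final intersection has
a unique right answer. Five decoy families each violate exactly one filter:
not conserved in human; all predictions at WCSP ≤ 50; not DE at the last
stage; only 4 conserved-site targets at the middle stage; parked at
abundance rank n−20 so it falls below the top-50 DEmiR cut (60 background
DEmiRs at higher abundance, each DE at only one or two stages, guarantee the
cut is binding). Replicate count defaults to 3 per condition per stage — a
choice, not a measured value, as pooled-sample designs often leave the
effective replication unstated.

**What passing tests show, and what they do not.** Exact recovery of the
planted families and candidates demonstrates that every filter implements
its stated rule with the stated boundary conventions and that the cascade
attributes eliminations correctly. It does not demonstrate biological
recall on real tissue: the generator plants effects far above the detection
threshold, uses a single shared dispersion, and omits batch effects,
isoform structure, cross-mapping between miRNA paralogs, and correlated
gene programs. The null-simulation checks show the t-test/BH chain is
calibrated under the generator's noise model, not under arbitrary real
noise.

## Echo metrics

Fractional shortening, FS(%) = (LVEDD − LVESD)/LVEDD × 100, and ejection
fraction, EF(%) = (EDV − ESV)/EDV × 100, are provided as validated utility
functions (and a CLI subcommand) for the phenotyping side of an MI study.
Inputs are validated (positive, end-systolic ≤ end-diastolic) but not
unit-converted.

## Problem sizes and determinism

The reference study is 2,000 genes × 300 miRNAs × 18 libraries; a full
generate-plus-analyse cycle (including 1,000-permutation GSEA over the
bundled gene-set collection) takes a few seconds on one core, and the whole
test suite runs in well under a minute. All pipeline outputs are
byte-identical across runs given the same inputs, configuration and seed;
the acceptance script verifies this by hashing two independent end-to-end
runs.
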