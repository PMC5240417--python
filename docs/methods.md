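# Methods

This note documents the statistical model, the defaults and the design
choices behind `triodiff`, in the order the pipeline runs.

## Count model

Counts are modelled as negative binomial with the mean–dispersion
parameterization **Var = μ + αμ²** (α ≥ 0; α = 0 is Poisson). The
parameterization is stated explicitly because NB "size/probability"
conventions are a common source of ambiguity: throughout the package the
NB size parameter is r = 1/α and the success probability p = r/(r+μ).
One dispersion per gene is shared across species and tissues — the
simplest structure the estimator can recover from a two- or six-replicate
design; nothing in the pipeline requires it to be true of real data, only
that the estimator is fed replicates from groups it treats as homogeneous.

## Unigene selection

A transcript survives iff FPKM > 2 (strict inequality, so a transcript at
exactly 2.0 is dropped) **or** it has an ortholog in another assembly.
Within a cluster, ortholog-linked transcripts take priority as the
representative, because downstream ortholog groups admit at most one gene
per species and the ortholog-linked isoform is the one the cross-species
evidence actually points at; among candidates of equal standing the longest
wins, with ties broken by lexicographically smallest transcript id for
determinism. FPKM is interpreted per pooled species library (tissue reads
combined before assembly); `fpkm_cutoff` is exposed for per-tissue tables.
N50 is the standard definition: the length at which the descending
cumulative length first reaches half the assembly total.

## Ortholog groups

Groups are connected components of the pairwise ortholog graph (hand-rolled
union–find with deterministic root selection). Components holding two genes
of one species — many-to-many orthology — keep the lexicographically first
gene of that species and demote the rest to singleton groups; the pipeline
needs exactly one expression value per species per group, and with no
support weights on pairs the lexicographic rule is the deterministic
choice. Counts of species absent from a group are structural zeros; the
Venn tallies and the hybrid-specific fraction (hybrid-unique groups over
the union of groups) follow directly from the group table.

## Normalization and dispersion

Size factors are median-of-ratios: for genes expressed in every sample,
the median over genes of count/geometric-mean, rescaled to geometric mean 1.
The median is taken on the ratio scale (not the log scale, which would
geometrically interpolate at even gene counts). **Assumption**: a majority
of genes are not differential between samples. Simulations in which *every*
gene changes (e.g. a pure-additive trio with no conserved background)
violate this and visibly bias the hybrid's factors; the recovery tests
therefore include a conserved majority, as real transcriptomes do.

Dispersion is estimated per gene by pooled method of moments,
α̂ = Σ df·(s²−m) / Σ df·m² over design groups with ≥ 2 replicates, clipped
at 0, then shrunk toward the 20%-trimmed mean of all gene estimates with
weight 1/(mean replicates per group) — full weight on the gene's own
estimate as replication grows, half-and-half at n = 2. This is a
deliberately simple estimator; it recovers α to within a factor of ~1.5 at
n = 5 replicates in the test suite, which is sufficient for the test
statistics that consume it.

## The two tests and the consensus rule

*Exact conditional test.* Under equal group means the group sums are
NB(n·r, p) with a shared p, so the conditional law of one group's sum given
the grand total is negative hypergeometric — independent of the unknown
mean. The two-sided p-value is the probability mass of all splits of the
total at most as likely as the observed one (relative tie tolerance 1e-8,
so exactly symmetric outcomes fall in both tails). Below α = 1e-6 the
conditional law is replaced by its binomial (Poisson) limit, which is exact
there to well below the tie tolerance; above a grand total of 10,000 the
lattice sum is replaced by a continuity-corrected normal approximation to
bound runtime (the switch is a documented constant,
`dge.EXACT_TOTAL_CUTOFF`). The test conditions on rounded normalized
counts when size factors differ from 1.

*Wald test.* z = (log(m̄_B + c) − log(m̄_A + c)) / SE with c = 0.5 and the
delta-method SE from the NB moment variance of each group mean,
Var(m̄) = n⁻² Σ_j (μ/s_j + αμ²). Under a null simulation (μ ≥ 50, α = 0.1,
n = 4) its raw p-values are KS-indistinguishable from uniform.

*Fixed-null (MPV) variant.* The hybrid mean is tested against the fixed
value (m̄₁ + m̄₂)/2 on the linear scale, with variance Var(m̄_H) +
(Var(m̄₁) + Var(m̄₂))/4 so parental estimation uncertainty is not ignored.
Only the Wald form applies — there is no exact conditional analogue for a
fixed-value null.

A gene is a **DEG** when BH-adjusted p < 0.001 for *both* tests and
|log2FC| > 1 (pseudo-count 0.5 on normalized means, which keeps fold
changes finite for structural-zero singleton groups). Requiring two
differently-shaped tests to agree mirrors the both-methods-agree practice
of running two DE packages and intersecting their calls. The adjusted-p
threshold is applied to each test independently. Whether the fold-change
gate should see shrunken or raw fold changes is an open choice; raw
(pseudo-counted) fold changes are used.

## Inheritance classification

Entry set: DEGs between the parents, per tissue. Each entrant is judged
against P1, P2 and the MPV with the dual-test adjusted-p rule but *without*
the fold-change gate — equality judgments would be masked by a fold-change
requirement, since genuinely intermediate hybrids sit well within 2-fold of
both parents. The decision order is fixed: transgression first (hybrid
significantly beyond both parents is never mislabeled dominant), then
complete dominance (non-significance against exactly one parent), then the
between-parents split into additive (MPV test does not reject) versus
incomplete dominance. "Hybrid = MPV" is therefore read as non-rejection,
a lenient criterion by construction — an equivalence test would be
stricter; the recovery tests quantify what the lenient reading delivers.
Genes non-significant against both parents while the parents differ are
`ambiguous` and excluded from summary denominators. The overall row counts
each group once, preferring the corolla call on cross-tissue conflicts
(the floral phenotype is the analysis' focus) and flagging the conflict.

## Synthetic data generator

The generator emulates the design the analysis assumes: per-gene modes
drawn from configurable proportions; per-tissue, per-gene base means of
2^U(3, 9) expected counts; parental log2 divergence U(min, min+spread) with
default min 2 (comfortably above the DEG threshold of 1); hybrid means
placed exactly at the MPV (F1a, linear scale — expression abundance is the
trait, so the additive value is the arithmetic parental mean), at a parent
(F1b), a full margin below the MPV but inside the parental range (F1c,
feasibility of which forces min > log2(2^(margin+1) − 1), validated), or
beyond the range by 2^(margin + U(0,1)) (F1d); per-sample size factors
U(0.7, 1.3); singleton genes present in one species only; two tissues with
independent means (tissues are analysed separately, so no shared tissue
effect is modelled); dispersion default 0.05, a moderate bulk-RNA-seq
value, exposed as a free parameter because within-species variability is
not otherwise constrained at two replicates. Defaults put 70% of trio
genes in the conserved mode and split the rest with complete dominance
dominating, the qualitative spectrum interspecific F1 comparisons report.

What the generator does **not** emulate: GC/length biases, isoform-level
quantification noise, correlated dispersion–mean trends, allele-specific
expression, or assembly artifacts. Passing recovery tests therefore shows
the statistical machinery is correct under its own model, not that real
libraries meet that model.

## Problem sizes in the test and acceptance runs

Recovery checks run the full pipeline at 5,000 genes × 2 tissues × 6
replicates per species (seeds 1–5 in the tests; the acceptance script runs
the seed it is given) — a size chosen to make class-level recall estimates
stable to a few percent while keeping a complete suite run in the low
minutes. Smaller unit fixtures (hundreds of genes, 2–3 replicates) cover
the plumbing.

## Known limitations

- The exact conditional test assumes the dispersion is known; it is fed the
  shrunken estimate, so its nominal exactness is conditional on that
  estimate (the Wald test shares the plug-in).
- Method-of-moments dispersion at n = 2 leans heavily on the cross-gene
  prior; per-gene dispersion differences are then barely identifiable.
- The MPV test's non-rejection reading means low power *favors* additive
  calls; F1a/F1c confusion dominates the recovery error, as the decision
  tree predicts.
- Median-of-ratios normalization requires a non-differential majority of
  genes (see above).
- Two-group contrasts only; no GLM designs, no cross-tissue interaction
  testing.
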