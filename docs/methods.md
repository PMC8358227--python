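# Methods

`hybridome` analyses expression data from a reciprocal crossing design
between two wild tomato species with near-complete hybrid seed failure:
*Solanum peruvianum* (P) and *S. chilense* (C). Four cross types are
compared — the within-species crosses PP and CC ("normal" seeds) and the
reciprocal hybrids PC and CP (maternal species written first) — using two
assays: endosperm mRNA counts and whole-seed small-RNA (sRNA) cluster
counts. The pipeline answers four questions: which features change
expression in hybrids, where sRNA clusters sit relative to genes, how hybrid
expression relates to the two parental levels (inheritance mode), and which
genes show the concomitant sRNA-loss/expression-gain signature.

## Differential expression

Counts are modelled as negative binomial with Var = μ + αμ². Libraries are
normalized by median-of-ratios size factors (factor_j = median over
all-positive features of count/geometric-mean). The tested contrast pools
both normal crosses against both hybrid crosses on the log scale:

    L = ½(log μ_PC + log μ_CP) − ½(log μ_PP + log μ_CC)

Per-cross means μ̂_g are means of size-factor-normalized counts — the NB-GLM
maximum-likelihood estimate under a log link when size factors are equal
within a cross, and a quasi-likelihood estimating-equation solution
otherwise. This choice (rather than a full IRLS fit with per-library
offsets) makes every log2FC *exactly* invariant to rescaling any single
library's counts, which we treat as a defining property of a
normalization-respecting estimator. Per-feature dispersion α̂ is a pooled
within-cross method-of-moments estimate, α̂ = Σ_g w_g(s²_g − μ̂_g·mean(1/s_j)) /
Σ_g w_g μ̂_g² with w_g = n_g − 1, floored at 1e-8; there is no shrinkage
across features, keeping the estimator fully specified and testable.

The Wald statistic L/SE(L) uses a delta-method standard error,
Var(log μ̂_g) = (μ̂_g·Σ 1/s_j + α̂ μ̂_g² n_g) / (n_g μ̂_g)², and is referred to
a Student t distribution with df = libraries − crosses (8 in the default
design). The t reference is deliberate: with a plug-in moment dispersion
estimated from 8 residual degrees of freedom, a normal reference is
anti-conservative (measured raw-p type-I ≈ 0.09 at nominal 0.05 on null
simulations), while the t reference calibrates to 0.048–0.06 across seeds.
A feature is called DE when |log2FC| exceeds the class threshold — 2.5 for
genes, 2.0 for sRNA clusters, in log2 units — and the Bonferroni-corrected
p (divisor = number of features actually tested) is below 0.05. BH-FDR q
values are emitted as an extra column but never drive the flag. All-zero or
sub-`min_total_count` features are reported untested with p = 1 and
log2FC = 0. The pseudocount (default 0.5) acts as a *floor* on normalized
cross means before logs, not an additive shift, again to preserve exact
scale invariance for expressed features; it only matters when a cross is
essentially silent. Before sRNA testing, clusters classed as structural or
housekeeping RNA (antisense, rRNA, tRNA, snoRNA, snRNA, SRP RNA) are
removed; miRNA-annotated and clean clusters are kept.

Replication note: matching DESeq2 (the common engine for such designs)
bit-for-bit is a non-goal; the analysis is defined by its contrast,
thresholds and correction, and a statsmodels NB-GLM is used as an
independent cross-check in the test suite (log2FC agreement within 0.15,
correlation > 0.999 on seeded data).

## Genomic context

Coordinates are 0-based half-open everywhere internally; GFF3 input/output
converts at the boundary. An sRNA cluster is linked to every protein-coding
gene whose body extended by the flank window (default 2,500 bp, clipped at
0) it intersects on the same chromosome. The window is symmetric and
strand-agnostic (`bedtools window` semantics); a cluster near several genes
yields several links (no nearest-gene tie-break), and the gene body counts
as "within boundaries". The reported distance is 0 for overlap, else the
gap to the gene body; upstream/downstream labels follow gene orientation
when stranded. Physical gene clusters are maximal runs of ≥ 3 genes sharing
an annotation label whose consecutive end-to-start gaps are ≤ 5,000 bp
("within 5 kb of genomic space" read as the gap between gene bodies;
configurable). Size classes: miRNA flag takes precedence, then DicerCall
21/22 → 21–22 nt, 24 → 24 nt, else other.

## Inheritance modes

For one hybrid direction H ∈ {PC, CP}, two log ratios are computed from
per-cross normalized means with a 0.5 pseudocount: r_P = log2((μ_H+ε)/(μ_PP+ε))
and r_C likewise against CC. With threshold t (1.0 log2 units for genes,
0.5 for sRNA clusters — "x-fold change" interpreted on the log2 scale, as a
literal linear reading of "< 1-fold" would make every feature conserved),
the (r_P, r_C) plane partitions exhaustively: near both parents →
conserved; near exactly one → dominant for that species; beyond both with
agreeing signs → over/underdominant; beyond both with opposing signs →
additive. Boundary values |r| = t fall on the near side — a deterministic
tie-break. "Similar to one parent" is operationalized as within-threshold of
exactly that parent; conservation requires closeness to *both* parents,
which in turn implies the parents are similar — the alternative reading
(closeness to the maternal cross only) would not yield a disjoint partition.
Dominance is labelled by species, not parental role, so reciprocal hybrids
are directly comparable. Classification runs on all features regardless of
DE status, with an optional subset restriction. An all-zero feature has
r_P = r_C = 0 and is conserved by convention. There is no significance test
on mode membership.

## Synthetic studies

The generator is the test bed for every stage; its defaults are the study
conditions. Design: 3 replicate libraries per cross and assay (12 per
assay), the sRNA replication of the emulated design, with the maternal
plants 1616A (P) and 4329B (C) attached to their crosses. Defaults: 2,000
genes and 2,000 sRNA clusters (a desk-scale stand-in for the tens of
thousands in a real study), NB dispersion α = 0.05, baseline means drawn
log-uniformly from 10² to 10³ (moderately expressed features, where mode
classification is well-posed), library depth 10⁶ with ±30% per-library
variation (exercising normalization), 7% of genes and 1.2% of sRNA clusters
DE at |log2FC| = 4 (genes 66% up; sRNA clusters 90% down, matching the
hybrid sRNA loss the pipeline is built to detect), half of all clusters
planted inside gene flanks, 8% of clusters tagged structural, ten planted
3-gene physical clusters, ~1.5% of clean linked clusters planted as joint
sRNA-down/gene-up pairs, and five silent target genes.

Annotation geometry guarantees unambiguous truth: genes sit on two
chromosomes with inter-gene gaps of 8–12 kb (> 2 × flank), planted gene
clusters use intra-run gaps of 0.8–4 kb, flank-planted sRNA clusters sit
within 2.5 kb of a single isolated host gene (30% in the body, the rest in
either flank), and far clusters are centered in wide gaps > 2.5 kb plus
margin from every gene. Requests that cannot be placed raise a geometry
error rather than degrading silently.

Counts are drawn per library as NB(μ·depth-scale, α) (Poisson in the α→0
limit). Per-cross means encode both the DE truth and the mode truth
consistently: planted-DE features have equal parents and both hybrids
shifted by ±4 log2 (hence over/underdominant); non-DE features carry
contrast-neutral geometries — conserved and additive have hybrid-vs-normal
contrast exactly 0; dominant features carry the small dominance shift
(kept ≥ 0.5 log2 below the DE threshold); non-DE transgressive features use
a shift capped at threshold − 0.5. Every planted placement keeps a
0.5-log2 guard margin beyond the classification boundary it must clear, so
the noiseless mean vectors classify to their planted mode with 100%
agreement, and recovery under noise is a meaningful statistic rather than a
coin flip. The same planted mode is used for both hybrid directions.

What the generator does *not* emulate: mapping artefacts and multimapping
ambiguity, gene-specific dispersion, correlated features, library-specific
GC or length biases, partially overlapping annotations, and
maternal-tissue contamination of whole-seed sRNA. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not robustness to everything real data can do.

## Joint signatures

A joint signature is a gene called DE-over whose ≥ 1 linked cluster is
called DE-under, both under the combined contrast; per-direction sign
consistency (gene up in PC vs PP *and* CP vs CC; clusters down in both) is
reported as a boolean flag, never used as a filter, since no per-direction
test is defined. DE invariants of every reported gene and cluster are
re-checked at assembly time. Silent targets are genes with ≥ 1 DE-linked
cluster and total raw endosperm count below `detection_min` (default 1,
i.e. fully undetected). The gene and sRNA count tables come from different
tissues (endosperm vs whole seed) and are never combined numerically —
only joined through links. The distribution report compares CPM of DE
features between each maternal plant's normal and hybrid libraries with the
Wilcoxon rank-sum test (exact enumeration when n+m ≤ 12 and tie-free,
normal approximation with tie correction otherwise) and emits compact
letters at the 0.01 level plus a long-format table for violin plots.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script (2,000 features, 3
replicates per cross, ≤ 20 random interval instances) are chosen so the
whole suite completes in seconds while keeping every recovery statistic
away from its acceptance boundary; they are desk-scale choices of this
package. Known limitations: the moment dispersion estimator is noisy at 2
replicates per cross (the t reference compensates on average, not per
feature); Bonferroni across tens of thousands of real features is far more
conservative than across 2,000 synthetic ones; and the mode classifier
inherits the pseudocount's compression of ratios for very low-expressed
features.
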