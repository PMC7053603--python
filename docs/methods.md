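# Methods

This note documents the statistical models, the synthetic-data design, the
numerical conventions, and the known limitations of `cernet`.

## Differential expression

Each dataset is a log2-scale feature × sample matrix with paired
tumor/normal samples per subject (or two independent groups). Paired
designs test the within-pair differences d_i: logFC = mean(d), residual
variance s² = var(d) with d = n−1 degrees of freedom and unscaled standard
error u = 1/√n. Group designs use the pooled two-sample formulation
(df = n₁+n₂−2, u = √(1/n₁+1/n₂)).

Variance moderation follows the standard empirical-Bayes treatment: the
per-feature variances are modeled as draws from a scaled inverse-chi-square
prior (s₀², d₀), estimated by moment matching on log s² through
digamma/trigamma identities (with a Newton solve for the trigamma inverse).
The posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) replaces s² in the t
statistic, which then has d + d₀ degrees of freedom (capped at the pooled
residual df; an infinite d₀ falls back to the normal reference). With
moderation disabled the statistic reduces exactly to the ordinary t. The
implementation was verified against limma's `eBayes` on a blocked paired
fit: logFC, t, p and BH-adjusted p agree to at least 8 decimals (the
frozen reference values live in the test suite).

Degenerate case: zero residual variance with moderation disabled yields
p = 0 when |logFC| > 0 and p = 1 when logFC = 0, with a logged warning.

Benjamini–Hochberg adjustment is the step-up rule
adj_(i) = min_{j≥i}(p_(j)·n/j) capped at 1, returned in input order.

Up/down calls use strict inequalities (p-value strictly below the gate,
|logFC| strictly above), applied to the raw or adjusted p as configured.
Presets for five public accession datasets ship in
`diffexpr.THRESHOLD_PRESETS`. Cross-dataset consensus requires significance
in *every* dataset of a molecule kind; features whose significant
directions disagree are flagged inconsistent.

## Coexpression

Pearson r over the full shared sample list (tumor and normal; a
tumor-only analysis can be run by subsetting the datasets first — the
all-samples default deliberately lets the shared condition effect
contribute, which is what makes synergistic DE pairs separable).
Significance is the exact transform t = r√((n−2)/(1−r²)) on n−2 df, with
|r| = 1 mapped to p = 0. lncRNA–mRNA pairs pass at r > 0.7 and p < 0.05
(strict) in every dataset; miRNA–mRNA pairs pass at r < 0 with no p gate
by default (an optional gate exists in `screen_negative`). Correlations
are computed only among consensus differentially expressed features.

## Target evidence

Predictions are ingested as one 0/1 column per source (default 12 names
mirroring the common aggregator: miRWalk, MicroT4, miRanda, miRBridge,
miRDB, miRMap, miRNAMap, PICTAR2, PITA, RNA22, RNAhybrid, Targetscan).
A pair counts as predicted with support ≥ min_sources (default 6,
inclusive). The predicted set is intersected with the negative-correlation
pairs; both the support count and r are carried forward.

## Duplex scanning

Local alignment of the reversed miRNA against the target under
complementarity scoring: A:U and G:C score `match_score` (+5), G:U scores
`gu_wobble_score` (+1), other combinations `mismatch_score` (−3); columns
whose miRNA position lies in the seed window (2–8 from the 5′ end) are
multiplied by `seed_scale` (4). Gaps are affine: the first gapped column
costs `gap_open` (−9), each further column `gap_extend` (−4). The
dynamic program is a three-state Smith–Waterman (numba-compiled); maximal
non-overlapping local optima are reported greedily by score, blocking the
accepted target interval and rescanning. A brute-force enumeration oracle
in the test suite confirms optimality on all tiny random instances tried.

Hit energies come from a nearest-neighbor stacking model: Watson–Crick
stack free energies (Turner-style ΔG°37 values, kcal/mol) are summed over
consecutive paired columns; any stack involving a G:U wobble contributes a
flat −0.5; every maximal stacked segment pays a +4.09 helix-initiation
penalty, and loop entropies between segments are otherwise ignored. Charging
the initiation per segment is what keeps scattered chance complementarity
(several short helices) from accumulating a spuriously stable energy; a
contiguous 22-nt site still reaches ≈ −40 kcal/mol. This is a deterministic
desk-scale approximation — absolute agreement with Vienna-style ensemble
energies or with the original miRanda binary is *not* claimed, and the
score/energy gates (score > 140, energy < −20, both strict) should be
read as operating on this model's scale.

## Assembly, network, ranking

A triple (l, m, g) is emitted iff (m,l) has a passing duplex site, (m,g)
passes evidence ∩ negative correlation, (l,g) passes the synergy screen in
all datasets, directions[l] = directions[g] ∈ {up, down}, and the miRNA
direction is undetermined or opposite. Direction policy is per molecule
kind: inconsistent mRNAs/lncRNAs are excluded from assembly, inconsistent
miRNAs are retained as "undetermined" (they appear in the network without
an arrow); both policies are configurable.

The network has one node per molecule and three edge kinds (mir_lnc,
mir_mrna, lnc_mrna_coexpr). Degree is the unweighted incident-edge count,
coexpression edges included by default (configurable), matching an
unweighted connectivity analysis of the drawn network.

The core-axis score is a convex combination (default equal thirds) of:
mean min-max-normalized degree of the triple's nodes; mean (over members
and datasets) min-max-normalized |logFC|; and the mean fraction of
datasets in which each member is significant with its consensus direction.
The composite is this package's own ranking device — the upstream screening
criteria (connectivity, effect size, reproducibility) are combined
quantitatively rather than by inspection, and literature priors are out of
scope. Ties break lexicographically, so ranking is deterministic.

## Downstream statistics

Enrichment: p = P(X ≥ k), X ~ Hypergeometric(N, K, n) with every gene set
intersected with the universe before sizing; the EASE variant (default)
replaces k by max(k−1, 0), which is conservative by construction. BH is
applied within each category. The universe defaults to the union of the
supplied collections plus the query. Published DAVID p-values are not
reproducible without the original background universe, so none are
asserted anywhere.

ROC: the curve is swept over distinct thresholds (ties collapse to one
step), AUC by trapezoid — provably equal to the Mann–Whitney
U/(n₊·n₋) with half credit for ties, which the tests verify. Direction is
explicit (`positive_is_high`), never auto-flipped. Stage grouping maps
T1/T2 → early, T3 → advanced, and rejects anything else.

qPCR: ΔCt = Ct_target − Ct_reference per group, ΔΔCt = ΔCt_case −
ΔCt_control, fold = 2^−ΔΔCt; the group-level variant averages ΔCt within
each group before differencing.

## Synthetic data

The generator emulates a multi-accession paired design. Defaults — 200
mRNAs, 50 lncRNAs, 20 miRNAs, two pseudo-datasets of 10 tumor/normal
pairs, 10 planted triples, 5 planted DE singletons per kind,
|log2FC| = 2, noise sd 0.5 (log2 units), coupling 0.9, 12 evidence sources
at sensitivity 0.9 / false-positive rate 0.02 with 5× decoys, 300-nt
lncRNAs, 22-nt miRNAs — are calibration choices representing a clean
array experiment of the scale such studies use; the source datasets
publish no effect-size or variance figures to copy.

Expression is log2-normal around per-feature baselines (uniform 6–12):
value = baseline + δ·1[tumor] + σ·z. Planted triples use a Gaussian
structural chain — z_mRNA = −c·z_miRNA + √(1−c²)·ε and z_lncRNA = c·z_mRNA
+ √(1−c²)·ε′ — so that corr(miRNA, mRNA) = −c and corr(lncRNA, mRNA) = +c
in the residuals, on top of the shared (opposite for the miRNA) condition
effect. Triple directions alternate down/up deterministically; the miRNA
always takes the opposite sign. In the noise-free limit every planted
logFC equals ±effect exactly.

Evidence flags are Bernoulli draws in a fixed order (true-pair flags,
decoy selection, decoy flags) from a dedicated stream, so tests can replay
the stream. Sequences are uniform-random ACGU; each planted (miRNA,
lncRNA) site embeds the reverse complement of the full miRNA ("strong") or
of seed positions 2–8 only ("weak") at a recorded 1-based interval.
Validation tables plant a configurable group ΔΔCt (default 2.0 → fold
0.25), T1/T2/T3 labels, and class-separated scores (separation 3.0 sd;
infinity gives disjoint supports).

All streams derive from one master seed via named `SeedSequence` children;
identical configs produce identical bundles.

What the generator does *not* emulate: probe-level artifacts, batch
effects, missing values, heavy-tailed or intensity-dependent noise,
correlated null genes, isoform complexity, or realistic miRNA seed-family
structure. Passing recovery tests therefore demonstrates the pipeline's
correctness under its own assumptions, not performance on real arrays,
where normalization and probe-collapse conventions dominate
reproducibility (for real accessions a probe map can be supplied; the
collapse rule keeps the probe with the highest mean expression).

## Problem sizes and determinism

The shipped tests and the acceptance script run the full pipeline on 100
independent seeds of the default configuration (≈0.4 s per run) and the
DE-rate measurement on 25 seeds; these sizes give stable aggregate rates
while keeping a full run around a minute. Every stage is deterministic
given its inputs; sorted outputs and lexicographic tie-breaks make reruns
byte-identical.

## Known limitations

- The duplex energy model is a stacking-sum approximation; no ensemble
  folding, loop entropies, or conservation filtering.
- Consensus requires significance in *all* datasets of a kind; there is no
  soft-voting mode.
- Enrichment ignores the GO DAG (no term propagation).
- The miRNA–mRNA correlation source is a single dataset (the first, by
  default) rather than an intersection, mirroring the single-accession
  situation it models; configure `mir_mrna_dataset` to change it.
- No survival modeling, batch correction, or array preprocessing.
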