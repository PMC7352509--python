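# Methods

`astropair` implements a patient-matched tumor-pair progression analysis:
given initial and recurrent tumors from the same patients, plus normal
references, it characterizes how copy number, expression, molecular subtype
and somatic mutations change between diagnosis and relapse. Because cohorts
of this kind are institutional and rarely shareable, the package ships a
first-class synthetic-cohort generator with planted ground truth, and every
guarantee the test suite makes is a statement about recovery of that truth.

## The core model: a chromosome-aware three-state Gaussian HMM

For each patient the per-gene expression change is summarized as
x_g = log2(recurrent) − log2(initial), ordered along the genome. Segmental
DNA gains and losses shift the expression of *runs* of neighboring genes
coherently, so the hidden expression state of a gene (underexpressed,
unchanged, overexpressed) is locally persistent along the chromosome. A
first-order hidden Markov model with three Gaussian emission components
captures exactly this persistence:

- hidden states k ∈ {under, unchanged, over} with initial distribution π and
  a 3×3 row-stochastic transition matrix A;
- emissions x_g | k ~ N(μ_k, σ²_k) with the ordering constraint
  μ_under < μ_unchanged < μ_over, re-imposed by state relabeling after every
  M-step so the states keep their meaning throughout training.

One model is trained across *all* pair profiles (pooled Baum–Welch with
expected-count pooling over profiles and chromosomes). Each chromosome is
treated as an independent sequence restarting from π — the dependency being
modeled is local chromosomal proximity, and there is no biological reason
for the last gene of one chromosome to inform the first gene of the next.
A `concat_genome` switch chains the whole profile instead. Per-gene state
calls come from forward–backward posterior decoding; exact posterior ties
resolve to "unchanged", the conservative call.

Numerical choices: all recursions run in log space (log-sum-exp); the
E-step is batched across equal-length sequences so training on a cohort of
tens of profiles × thousands of genes takes about a second; emission
variances are floored at 1e-4 (with a warning) to prevent collapse onto a
single observation; convergence is declared when the log-likelihood gain
drops below 1e-4 (max 200 iterations). Defaults: means initialized at
(−3, 0, 3) log2 units, self-transitions 0.9, unit variances, uniform π.
π and A are re-estimated by default and emission variances are per-state;
both behaviors are switchable (`update_startprob`, `update_transmat`,
`tied_variance`).

## Surrounding pipeline stages

**Preprocessing.** Raw counts are filtered (genes with zero reads, then
genes with CPM < 1 in strictly more than half the samples — the boundary
case of exactly half is kept), transformed to
log2((c + 0.5) / (lib + 1) · 1e6), and normalized by cyclic loess: for every
unordered sample pair an M-vs-A lowess trend (span 0.7, tricube-weighted
local linear fit via statsmodels) is split half-and-half between the two
samples; three full cycles by default. The transform preserves each pair's
A values exactly and removes between-sample trends. Whether tumors and
normals are normalized jointly or separately is a genuinely open design
point; the pipeline normalizes jointly (one matrix), and the functions
accept any column subset. Row z-scores (n−1 denominator, constant rows
flagged and zeroed) are provided for heatmap display.

**Copy number.** Segment files (SEG-style, read as 1-based inclusive and
converted to the package-wide 0-based half-open convention) are mapped to
genes by the midpoint rule: a gene takes the mean log2-ratio of the segment
containing its midpoint — deterministic and unambiguous for genes
straddling a boundary; genes in no segment are missing, not zero.
Chromosome/arm event calls use thresholds loss ≤ −0.3, gain ≥ +0.3, with at
least 70% of the scope's genes qualifying; when both directions qualify the
larger fraction wins and exact ties are neutral. These thresholds are this
package's own operationalization of whole-chromosome events (conventional
aCGH practice) and are config-exposed. Without a centromere table, arms are
split at the chromosome's coordinate midpoint.

**Clustering.** Samples are compared by d = 1 − Pearson r and agglomerated
with Ward's criterion in the ward.D2 dialect (squared dissimilarities inside
the Lance–Williams update). The implementation delegates to scipy's linkage,
which the test suite verifies against a hand-written naive Lance–Williams
agglomerator on all small random instances; ties between equal merge
heights follow scipy's nearest-neighbor-chain order (ties have measure zero
on continuous profiles). Matched pairs are classified as
direct / same-cluster / different-cluster: "direct" means some internal
node's leaf set is exactly the two samples. Node stability is plain
bootstrap probability — features resampled with replacement, support = the
fraction of replicate trees containing the node's exact leaf set. The
multiscale AU correction of the original stability software is deliberately
omitted: plain BP is sufficient for the planted-structure guarantees made
here, and the difference is documented rather than hidden.

**Differential expression.** Cluster-vs-normal (and any two-group) testing
uses an empirical-Bayes moderated t-statistic: per-gene pooled variances
s²_g on d degrees of freedom are shrunk toward a prior fitted across genes
by moments of the marginal s² ~ s0²·F(d, d0) distribution
(v/m² = 2(d + d0 − 2)/(d(d0 − 4)), with d0 = ∞ when the observed spread is
at or below pure sampling spread). The moderated statistic is referred to a
t distribution on d0 + d df. This is a self-contained moment-based variant
of the standard moderated-t approach; d0 → 0 reduces to the ordinary
t-test and d0 → ∞ to a pooled z-like test, both verified numerically.
BH-FDR uses the step-up procedure (via statsmodels) at q ≤ 0.01 by default.
Category over-representation uses one-sided ("greater") Fisher exact tests;
no multiplicity correction is applied across categories — callers see raw
enrichment p-values.

**Subtype assignment.** Tumor profiles are reduced to per-gene log2 ratios
against the mean of the normal references. G-CIMP positivity requires a
strictly positive Pearson correlation with the G-CIMP signature centroid
over shared genes (r = 0 exactly is negative). Four-class assignment picks
the class centroid with the greatest correlation, requiring it to exceed
`min_r` (default 0); exact ties or no positive correlation yield
"unclassifiable", and such pairs are excluded from (and reported alongside)
the initial→recurrent transition table. Signature genes missing from the
measured universe are dropped, not imputed — the remaining panel genes are
strongly correlated with the missing ones and act as a redundant backup.
Centroids are accepted from any supplied table (weighted GMT or per-class
TSV).

**Progression aggregation.** Decoded states are tallied per progression
group (A2→A3, A2→G4, A3→G4). A gene is frequently altered in a direction if
called so in at least 50% of the group's pairs — "at least" is inclusive,
so exactly half qualifies, which also means a gene can sit in both
directions' frequent sets at exactly 0.5 but never above it. Direction is
the decoded label only; magnitude is ignored. Cross-group comparisons
enumerate all Venn regions per direction plus opposite-direction overlaps.
Average alteration profiles take, for each frequent gene, the mean
log-ratio over exactly the pairs carrying that call. When a patient has
multiple relapses the (initial, last recurrent) comparison is used by
default. Pathway profiles report the fraction of each pathway's measured
genes in each frequent set with a Fisher enrichment p.

**Mutation summaries.** Variant identity is (chrom, pos, ref, alt).
Shared/private partitions are set operations on these keys. Gene-level
recurrence supports two scopes as first-class options, because pairs can
carry mutations in the same gene at different positions: `shared-in-pair`
requires an identical key in both tumors; `any-sample` counts a pair if
either tumor carries any variant in the gene. Functional tallies report
nonsynonymous / stop / synonymous / intronic / other, with
exonic = nonsynonymous + stop + synonymous. VCF 4.2 files are parsed with
cyvcf2; annotation itself (gene, class, VAF) is consumed, never computed.

## The synthetic cohort generator

The generator defines the study conditions; it is deliberately not a tuning
knob. Defaults: 21 patient-matched pairs in three progression groups
(6 A2→A3, 5 A2→G4, 10 A3→G4), four normal brain references, 2,000 genes
evenly spaced over 10 chromosomes (a desk-scale stand-in for ~14k genes
over 23 chromosomes), expression noise sd 0.5 log2 units with a
patient-level shared component of sd 0.25 (within-pair expression
correlation beyond copy-number coupling is exposed as `within_pair_sd`
rather than fixed), and a planted HMM with means (−3, 0, 3), emission sd
0.7 and self-transitions 0.9.

Planted structure:

- **Copy-number subgroups** (three, cyclic over patients) carry
  whole/half-chromosome events; every pair shares its segmentation and a
  patient-level segment-noise component (sd 0.1, plus a per-sample third of
  that), so matched pairs resemble each other the way real pairs do. One
  deletion of the last chromosome is planted only in the *recurrent* tumors
  of one subgroup — the chromosome-10-like progression event: initial
  tumors are never called loss there, and pairs of that subgroup stop
  co-clustering directly while the others remain direct neighbors.
- **CNA→expression coupling** is additive in log2 with attenuation 0.5
  (dosage effects on expression are damped relative to the DNA ratio);
  attenuation 1.0 reproduces DNA shifts exactly in the zero-noise limit.
- **Expression subgroups** (three, assigned independently of the
  copy-number subgroups) shift disjoint 150-gene marker blocks by 2 log2
  units.
- **Subtype structure**: class centroids (neural, proneural, classical,
  mesenchymal, plus a G-CIMP panel) are Gaussian weight vectors (sd 2.0)
  over disjoint 50-gene panels at the gene-map tail. Patients cycle through
  the three observed classes; planted transitions send proneural initials
  to mesenchymal recurrences and keep the others, and classical pairs play
  the IDH-wild-type role: planted G-CIMP negative (their profiles subtract
  the G-CIMP centroid), everyone else positive. The neural class exists in
  the signature set but is never planted.
- **Variants**: per-pair shared / initial-private / recurrent-private
  counts are Poisson around means (60, 106, 173); three marker genes carry
  a shared variant at one fixed position in planted fractions 12/17, 10/17
  and 6/17 of pairs, echoing the frequencies of the classic recurrently
  mutated glioma genes.

Randomness uses numpy PCG64 streams spawned from `SeedSequence(seed,
spawn_key=(stream, index))`, one named substream per sample/pair, so a
fixed seed is bit-reproducible across platforms and adding samples does not
perturb earlier ones. Integer counts are Poisson draws around
2^(log2 expression) at a 5e6 library size, so log-CPM preprocessing
approximately inverts the generator.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level sampling and mapping artifacts,
batch/run effects between sequencing runs, tumor purity and subclonal
mixtures, realistic mutational signatures or hypermutation, methylation,
and gene-length or GC biases. Recovery guarantees are statements about the
planted generative structure at the stated signal-to-noise, not about
clinical cohorts.

## Problem sizes used by the checks

The acceptance suite and `scripts/acceptance.py` run: HMM oracle equality
on 100 random sequences of length ≤ 6 against full 3^T path enumeration
(tolerance 1e-8); parameter recovery on 25 profiles × 2,000 genes (fitted
means within ±0.15, transition diagonal within ±0.03, decoding accuracy
≥ 95%); ward.D2 equality with the naive Lance–Williams oracle for n ≤ 6;
exact planted-subgroup recovery and bootstrap support ≥ 0.95 at B = 100 on
the default 21-pair cohort; BH and Fisher oracle equality (1e-12) and null
false-discovery proportion ≤ 5% over 200 replicates at q ≤ 0.01; exact
subtype/G-CIMP recovery over 20 seeds; inclusive-boundary frequent sets and
Venn regions against set algebra; exact variant round trips over 20 seeds;
and byte-identical manifests for two same-seed pipeline runs. These sizes
were chosen as the package's standard demonstration scale.

## Known limitations

- The moderated test's moment-based prior fit is less efficient than a
  likelihood-based fit of log-variances; for small gene counts d0 is noisy
  (it only affects moderation strength, not test validity under the null).
- Plain bootstrap probabilities understate support for nodes deep in the
  tree relative to multiscale-corrected values.
- Arm-level event calls without a centromere table split chromosomes at the
  coordinate midpoint, which is wrong for strongly acrocentric chromosomes.
- Cyclic loess is O(samples²) lowess fits per cycle; for hundreds of
  samples reduce `n_cycles` or span granularity.
- The Venn region enumeration is exponential in the number of compared
  sets; it is intended for the three progression groups / clusters.
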