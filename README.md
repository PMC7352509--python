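# astropair

Patient-matched tumor-pair progression analysis for astrocytoma-like
cohorts: when initial and recurrent tumors are available from the same
patients, `astropair` characterizes what changed on the way to relapse —
in gene copy number, genome-wide expression, molecular subtype, and somatic
mutations — and aggregates per-patient calls into progression groups
(A2→A3, A2→G4, A3→G4, i.e., WHO-grade transitions toward secondary
glioblastoma).

The package is aimed at computational cancer-genomics researchers who have
(or want to emulate) a paired cohort: gene annotation, expression counts,
copy-number segments, subtype signature panels, and somatic variant calls.
Because such cohorts are institutional and rarely public, a first-class
synthetic-data module generates cohorts with planted ground truth, and the
whole pipeline is validated by recovering that truth.

## The core method

Per patient, expression changes are summarized as a chromosomally ordered
log-ratio profile x_g = log2(recurrent_g / initial_g). Segmental DNA gains
and losses shift *runs* of neighboring genes coherently, so the hidden
expression state of a gene is locally persistent along the chromosome. A
three-state first-order Gaussian HMM exploits this:

- states k ∈ {under, unchanged, over}, initial distribution π, transition
  matrix A, emissions x_g | k ~ N(μ_k, σ²_k) with μ₁ < μ₂ < μ₃
  (initialized at −3, 0, +3 log2 units);
- one model trained by pooled Baum–Welch across all pair profiles, each
  chromosome an independent sequence;
- per-gene states assigned by forward–backward posterior decoding,
  γ_g(k) = P(state_g = k | x), label = argmax_k γ_g(k).

A gene is a frequent progression-group alteration if it is called in the
same direction in at least 50% of the group's pairs. Around this core sit:
1 − Pearson / ward.D2 hierarchical clustering with bootstrap stability and
matched-pair adjacency; an empirical-Bayes moderated t-test
(s̃² = (d₀s₀² + d s²)/(d₀ + d)) with BH-FDR at q ≤ 0.01; Fisher
over-representation tests; centroid-correlation G-CIMP and four-class
subtype assignment; and shared/private somatic-variant summaries with
gene-level mutation frequencies. See `docs/methods.md` for the full model
account.

## Worked example

```python
import numpy as np
from astropair import CohortSpec, simulate_cohort, simulate_pair_profiles
from astropair.hmm import fit_hmm, posterior_decode
from astropair.synthetic_data import build_gene_map

spec = CohortSpec(seed=1)              # 21 pairs, 2000 genes, 10 chromosomes
gene_map = build_gene_map(spec)
profiles, truth = simulate_pair_profiles(spec, gene_map)

chrom = gene_map["chrom"].to_numpy()
params, trace = fit_hmm(profiles, chrom)
print("fitted means:", params.means.round(3))
print("self-transitions:", np.diag(params.transmat).round(3))

_, labels = posterior_decode(profiles, chrom, params)
acc = (labels.to_numpy() == truth.hmm_states.to_numpy()).mean()
print(f"decoding accuracy: {acc:.4f}")
```

Output:

```
fitted means: [-3.011 -0.018  3.002]
self-transitions: [0.899 0.897 0.898]
decoding accuracy: 0.9967
```

The planted chain had means (−3, 0, 3) and self-transitions 0.9: training
recovers the emission means to ~0.01 log2 units and the transition diagonal
to ~0.003, and posterior decoding assigns 99.7% of the 42,000 gene-level
states correctly.

The full pipeline (simulate → preprocess → copy number → clustering → DE →
HMM → subtype → progression → mutations) runs from the shell and writes
plain-text artifacts plus a checksum manifest:

```bash
astropair run --out demo_run --seed 1
astropair simulate --out demo_cohort --seed 1   # cohort files only
```

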