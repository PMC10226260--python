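# neuro17q

Chromosome-17q imbalance calling, MYCN-amplification-context essentiality
screening and multi-evidence oncogene prioritization for neuroblastoma
cohorts.

Gains on chromosome arm 17q are the most frequent chromosomal aberration in
neuroblastoma and, together with *MYCN* amplification (MNA) on 2p, mark
high-risk disease. This package implements, as a tested and reusable
pipeline, the computational analyses used to nominate 17q oncogenes (such
as *IGF2BP1* and *BIRC5*) from tumor copy-number profiles, CRISPR dependency
screens, tumor expression and survival data. A seeded synthetic-cohort
generator with known ground truth makes every stage testable without access
to patient data.

## What it computes

**17q balance value.** From per-sample binned shallow-WGS log2 ratios, each
tumor is classified as *balanced* or *unbalanced* 17q by

```
bv = −median(IMP1-ter) + median(17p) + 0.2
```

where `17p` is the median log2 ratio over the whole p arm and `IMP1-ter`
the median over the segment from the *IGF2BP1* locus to the q terminus;
`bv ≤ 0` calls the sample unbalanced. Gain/loss states use log2-ratio
thresholds of +0.3 / −0.4; MNA is called when copy number at the *MYCN*
locus exceeds 4.

**MNA-context essentiality screen.** Over a pan-cancer dependency panel
(13 MNA vs 607 other cell lines in the reference conditions): expression
filter (log2 TPM > 2 in ≥ ~85% of MNA lines), median-dependency filter
(MNA median < −0.2 and other median > −0.3), common-essential exclusion,
then a per-gene empirical-Bayes moderated t-test. Per-gene variances s²_g
on d_g degrees of freedom are shrunk toward a scaled inverse-chi-square
prior (d₀, s₀²) fitted by moment matching on log s²_g:

```
s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),   t_g = Δ_g / (s̃_g·√(1/n₁+1/n₂))
```

with d₀ + d_g reference degrees of freedom, followed by Benjamini–Hochberg
FDR (hits at FDR < 0.05).

**Chromosome enrichment.** Upper-tail hypergeometric test P(X ≥ k) of a
gene list's distribution over autosomal protein-coding genes, computed in
log space (chromosome-17 enrichment of neuroblastoma essential genes
reaches p ~ 5e-22).

**Expression association.** Spearman correlation-of-correlations between
two genes' genome-wide co-expression signatures, knockdown-logFC
concordance, ADRN/MES signature scoring, and E-box (CANNTG) motif scanning.

**Survival.** Kaplan–Meier curves and two-group log-rank tests with
median-split or best-cutoff expression dichotomization (best-cutoff
p-values are flagged as optimization-biased).

**Ranking.** Evidence rows (dependency, tumor fold changes, hazard,
co-expression, knockdown response, ChIP/CLIP scores) min-max scaled to
[0, 1] or [−1, 1], oriented, and averaged into a composite oncogene score.

## Worked example

```python
from neuro17q import (SimulationConfig, simulate_cohort, balance_call,
                      toy_regions, simulate_dependency_screen, run_screen)

cfg = SimulationConfig(seed=1)                 # 100-tumor synthetic cohort
ann, profiles, expr, meta, truth = simulate_cohort(cfg)
regions = toy_regions(cfg)

call = balance_call(profiles[0], regions["17p"], regions["imp1_ter"])
print(call.median_17p, call.median_imp1_ter, call.bv, call.label)
# 0.567 0.589 0.178 balanced      (a whole-17 gain: both arms up, bv > 0)

screen, gt = simulate_dependency_screen(SimulationConfig(seed=1, n_genes=2000))
res = run_screen(screen)
print(len(res.hits))
# 40        (all 40 planted MNA-essential genes recovered, no false hits)
```

The first sample carries a balanced whole-chromosome-17 gain: both arm
medians sit near +0.58 (one extra copy), so the balance value stays at
~0.2 and the sample is called balanced. On the default screen conditions
the cascade tests 40 genes and recovers all 40 planted MNA-selective
dependencies at FDR < 0.05.

The same pipeline is scriptable from the shell:

```
neuro17q simulate --seed 1 --n-samples 100 --out-prefix cohort
neuro17q cn --bins cohort.cn.tsv --regions regions.tsv --out calls.tsv
neuro17q enrich --counts counts.tsv --out enrichment.tsv
```

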