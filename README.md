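# cytodm

Association analysis between tissue cytokine profiles and mucosal microbiota
composition, for paired tumor / healthy-mucosa study designs.

Given a 16S genus-level count table, a Luminex-style cytokine panel (pg/ml,
with lower/upper limits of quantification) and a patient pairing table,
`cytodm` answers the question *which cytokines are associated with which
dominant genera, and in which direction?* in two steps:

1. **Screening (sure independence screening).** Each cytokine is scored
   alone: a Dirichlet regression with concentrations
   `α_ij = exp(β_0j + x_i β_1j)` is tested against the intercept-only model
   by a likelihood-ratio test on J degrees of freedom. Cytokines are ranked
   by p-value and the top *m* advance.
2. **Bayesian variable selection (BVS) in Dirichlet-multinomial
   regression.** Counts `y_i ~ DM(exp(x_i'θ), N_i)` with a hard-thresholding
   prior `θ_kj = b_kj·1[|b_kj| ≥ t]`, `b_kj ~ N(0, σ²)`, `t ~ U(0, t_max)`,
   sampled by Metropolis-within-Gibbs. The output is a posterior probability
   of inclusion (PPI) and a posterior mean for every cytokine–category pair
   — the probability that the association is nonzero, and its estimated
   sign and magnitude on the log-concentration scale.

The response is compositional: the top-k most abundant genera (default 3 —
in colorectal mucosa typically *Bacteroides*, *Prevotella* and
*Escherichia/Shigella*) plus a pooled `residual` category. The package also
provides the standard per-sample community statistics (richness, Shannon,
Pielou evenness, Chao1, Good's coverage, exact rarefaction curves with a
saturation flag), a dendrogram-based check that paired samples cluster
together, paired Wilcoxon signed-rank tests, and a fully ground-truthed
synthetic study generator so every stage can be validated without external
data. See `docs/methods.md` for models, defaults and design rationale.

## Worked example

Simulate a study at the default conditions (40 patients with paired
tumor/healthy samples, 8 cytokines of which 2 truly affect a category with
log-link magnitude 1.5), then run both steps on the tumor tissue:

```python
from cytodm import (StudyConfig, generate_paired_study, aggregate_to_rank,
                    build_composition_response, screen_cytokines, run_bvs,
                    BvsConfig, render_association_tables,
                    standardize_covariates, apply_loq)
from cytodm.synthetic import default_loq

study = generate_paired_study(StudyConfig(n_patients=40, seed=3))
print("true active pairs:", sorted(study.truth.active_set))
# true active pairs: [(1, 2), (2, 1)]   # CYT01 -> category 2, CYT02 -> category 1

tumor = study.pairing.tumor_samples()
genus = aggregate_to_rank(study.otu_table.select_samples(tumor), "genus")
response = build_composition_response(genus, top_k=3)
panel = apply_loq(study.cytokine_panel.select_samples(tumor),
                  default_loq(study.cytokine_panel.cytokine_names))

screen = screen_cytokines(panel, response, m=3)
print(screen.to_frame().round(4))
```

```
          statistic  p_value  converged  rank  selected
cytokine
CYT01       63.0108   0.0000       True     2      True
CYT02       68.9207   0.0000       True     1      True
CYT03       11.1049   0.0254       True     3      True
CYT04        4.4237   0.3517       True     5     False
...
```

The two truly active cytokines dominate the ranking. Step 2 on all eight
cytokines:

```python
result = run_bvs(standardize_covariates(panel), response, BvsConfig(seed=3))
ppi, coef = render_association_tables(result)
print(ppi); print(coef)
```

```
           Escherichia/Shigella  Bacteroides  Prevotella  residual
intercept                   1.0          1.0         1.0       1.0
CYT01                       1.0          0.0         0.0       0.0
CYT02                       0.0          0.0         1.0       0.0
...
           Escherichia/Shigella  Bacteroides  Prevotella  residual
intercept                  1.75         1.68        1.25      2.31
CYT01                      1.35         0.00        0.00      0.00
CYT02                      0.00         0.00       -1.42      0.00
...
```

Reading the tables: CYT01–*Escherichia/Shigella* and CYT02–*Prevotella* are
included with posterior probability 1.00; every null pair has PPI 0.00. The
posterior means 1.35 and −1.42 recover the true coefficients (+1.5 and
−1.5): one standard deviation more of CYT01 multiplies the
*Escherichia/Shigella* concentration by e^1.35 ≈ 3.9, and CYT02 suppresses
*Prevotella* correspondingly.

The same analysis is available from the shell:

```sh
cytodm simulate --outdir study --seed 3
cytodm screen --counts study/counts.tsv --taxonomy study/taxonomy.tsv \
    --cytokines study/cytokines.csv --pairing study/pairing.tsv \
    --tissue tumor --out screening.csv
cytodm bvs --counts study/counts.tsv --taxonomy study/taxonomy.tsv \
    --cytokines study/cytokines.csv --pairing study/pairing.tsv \
    --tissue tumor --seed 3 --outdir bvs_out
cytodm run --config pipeline.yaml     # full pipeline from a YAML config
```

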