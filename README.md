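# pathflux

Pathway flux analysis of bulk transcriptomes and the **IM-Index**, a
composite diagnostic score over signaling and energy-metabolism
pathways.

## The problem

Peripheral-blood leukocyte RNAseq carries a readout of the host immune
state, which shifts as disease progresses (for example across healthy
controls, benign pulmonary nodules and malignant tumors). Single-gene
differential expression often fails to separate such groups, but the
*pathway-level* flow of molecular activity can. `pathflux` scores each
sample by propagating its expression profile through a curated
knowledge network — genes, molecular species (RNAs, proteins,
complexes, compounds), reactions with typed participant roles, and
pathways with crosstalk links — using mass-action kinetics, and
condenses the result into a single index for group discrimination.

It is aimed at computational biologists who have (a) a gene-by-sample
expression matrix on a linear scale (TPM or similar) and (b) a network
definition file, and want per-pathway fluxes, a per-sample index, and
the statistics to judge it against group labels and competing
biomarkers.

## The model

For a reaction *R* with rate constant *k* and participants in roles
`e` (enzyme), `g` (gene), `s` (substrate), `tr_a` (transcriptional
activator) — activating — and `i` (inhibitor), `tr_r` (transcriptional
repressor) — inhibitory:

```
flux(R) = k · ∏ c(activating participants) / ∏ (1 + c(inhibitory participants))
```

The concentration `c` of a species is the product of its constituent
genes' expression values; declared-constant species (H2O, O2) keep a
fixed value. A pathway *P* with *N(P)* reactions has

```
flux(P) = ( Σ_{R∈P} flux(R) ) / N(P)  −  mean base flux of crosstalk(P)
```

where the crosstalk term is evaluated one level deep (base fluxes
only). The diagnostic score is

```
IM-Index = α · Σ_{P ∈ signaling transduction} flux(P) + β · Σ_{P ∈ energy metabolism} flux(P)
```

with α = β = 1 by default. The statistical battery evaluates the index
with midrank Mann–Whitney AUC and stratified-bootstrap confidence
intervals, a one-sided bootstrap comparison against competing
biomarkers (2000 replications by default), Kruskal–Wallis / Wilcoxon
group tests, univariate logistic odds ratios, Spearman correlations
and Bonferroni-corrected per-pathway differential flux.

Because no suitable public cohort ships with the package, a synthetic
module generates miniature networks and three-group cohorts in which
the genes feeding designated *driver pathways* are multiplicatively
up-shifted (malignant ≥ benign ≥ control) over a lognormal baseline —
enough structure to exercise and calibrate every stage end to end.

## Worked example

```python
from pathflux import (
    NetworkSpec, CohortSpec, generate_network, generate_cohort,
    compute_flux_matrix, compute_im_index, kruskal_wallis, roc_with_bootstrap,
)

net = generate_network(NetworkSpec(n_genes=30, n_pathways=5, seed=1))
mat, labels, truth = generate_cohort(
    net,
    CohortSpec(group_sizes={"malignant": 30, "benign": 30, "control": 30}, seed=1),
)

fm = compute_flux_matrix(mat, net)
table = compute_im_index(fm, labels=labels)   # alpha = beta = 1
print(table.data.groupby("group")["im_index"].median().round(1))

h, p = kruskal_wallis(table.scores, dict(zip(table.data.index, table.data["group"])))
print(f"Kruskal-Wallis: H = {h:.1f}, p = {p:.2e}")

mb = table.data[table.data["group"] != "control"]
roc = roc_with_bootstrap(
    mb["im_index"], mb["group"], n_boot=2000, seed=7, pos_label="malignant"
)
print(f"AUC = {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")
```

Output:

```
group
benign        3990142.4
control       1471512.5
malignant    13481609.4
Name: im_index, dtype: float64
Kruskal-Wallis: H = 78.3, p = 9.77e-18
AUC = 0.992 (95% CI 0.973-1.000)
```

The medians order malignant > benign > control because driver-pathway
genes were up-shifted 2.0× / 1.4× / 1.0× in the three groups and flux
is multiplicative in expression; the index separates malignant from
benign nodules with AUC 0.992 on this synthetic cohort. (Raw index
magnitudes are arbitrary — they scale with expression units and
network size; only comparisons between samples scored on the same
network are meaningful.)

## Command line

Every stage is independently invokable:

```sh
pathflux simulate --out-dir demo              # synthetic network + cohort
pathflux validate demo/network.json           # check + summarize a network
pathflux run --network demo/network.json --expression demo/expression.tsv \
             --labels demo/labels.tsv --out-dir demo/out --seed 1
```

`run` writes `flux_matrix.tsv`, `pathway_klass.tsv`, `im_index.tsv`,
`stats.json` and `run_metadata.json` (config, seed scheme, input
checksums). Exit codes: 0 success, 2 validation error, 3 I/O error.
A flat `key = value` config file can replace the flags (`--config`),
with flags taking precedence.

## Layout

| module | contents |
| --- | --- |
| `pathflux.network` | network data model, JSON I/O, validation, summaries |
| `pathflux.flux` | concentrations, reaction/pathway fluxes, flux matrix |
| `pathflux.stats` | IM-Index, rank tests, ROC/bootstrap, logistic OR, differential flux |
| `pathflux.simulate` | synthetic networks, cohorts, fixture bundles, brute-force oracle |
| `pathflux.pipeline` / `pathflux.cli` | end-to-end orchestration and the `pathflux` command |

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
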