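# Methods

## Network model

The knowledge network has four layers — genes, species, reactions,
pathways — stored in one JSON document. Species concentrations are
functions of gene expression only: the concentration of a species is
the **product** of its constituent genes' expression values on the
linear (TPM-like) scale. A complex of two proteins therefore has a
concentration quadratic in expression, which is the mass-action view
of complex formation under the simplifying assumption that protein
abundance tracks transcript abundance. Compounds that the analysis
treats as environmentally buffered (water, oxygen) are declared
constant and keep a fixed value — our convention is 1.0, which makes
them neutral factors in reaction products.

Regulatory feedback from pathways to genes is not a separate edge
type: transcriptional activation/repression enters as ordinary
reactions with `tr_a`/`tr_r` participants, and microRNA-style
repression is likewise representable as a `tr_r` participant. The flux
semantics below never need a dedicated regulation layer.

Validation is total: a file either loads into a network satisfying
every invariant (resolvable references, disjoint id namespaces, known
roles and pathway classes, at least one activating participant per
reaction, positive rate constants, no self-crosstalk) or loading fails
with a message listing *every* violation found. Writing is canonical —
entity order preserved, sets sorted, keys sorted — so equal networks
serialize to identical bytes.

## Flux semantics

Reaction flux is mass action over activating participants with
divisive attenuation by inhibitory participants:

    flux(R) = k_R · ∏_{act} c · ∏_{inh} 1/(1 + c)

The divisive form is a deliberate modelling choice: a plain product
over all participants would make a *larger* inhibitor concentration
*increase* flux, contradicting the role's meaning, while `1/(1+c)`
leaves flux unchanged at zero inhibitor and keeps it nonnegative. The
`g` (gene) role is activating with concentration equal to that gene's
expression; it exists so transcription reactions can reference genes
directly.

Pathway flux is the mean reaction flux minus the mean **base** flux of
the pathway's crosstalk partners. The subtraction is evaluated one
level deep only: the crosstalk pathways' own crosstalk is never
expanded. The recursive definition is otherwise circular (crosstalk
partners may list each other), and one-level evaluation is the unique
terminating reading. Consequences accepted as-is: pathway flux can be
negative after subtraction (no clamping — the IM-Index sums raw
values), and crosstalk influence is local.

Missing genes: a network gene absent from the expression input
contributes a configurable floor concentration (default 0, silencing
any reaction that requires it); each missing gene is logged once and
the overall coverage fraction is reported as a warning. Zero coverage
is an error. A global `scale` factor can rescale all expression values
before flux computation; no log transform is applied anywhere, since
mass action is multiplicative in concentrations.

The production path (`compute_flux_matrix`) is vectorized across
samples; a deliberately naive per-entry evaluator
(`pathflux.simulate.naive_flux_matrix`, plain Python floats, re-walks
the network for every sample × pathway entry) serves as an independent
oracle in the test suite and generates the fixture bundle's expected
fluxes. The suite requires agreement to 1e-9 relative tolerance on
randomly generated networks.

## IM-Index and statistics

IM-Index = α·Σ flux(P) over signaling-transduction pathways +
β·Σ flux(P) over energy-metabolism pathways, α = β = 1 by default (the
weights are recorded alongside the scores). The index is linear in
(α, β), which the tests assert via additivity of the class partial
sums. Index magnitudes are arbitrary: they scale with expression units
and with network size, so only within-network comparisons are
meaningful — all downstream tests are rank-based for exactly this
reason.

Statistical conventions:

- **Rank tests.** Kruskal–Wallis (≥3 groups) and the Wilcoxon rank-sum
  test (2 groups) use midranks with tie correction (scipy
  implementations). When every observation is identical the tie
  correction degenerates to 0/0; we return H = 0, p = 1 (no evidence
  of difference). The Wilcoxon p-value is exact for small tie-free
  samples, tie-corrected normal approximation otherwise (scipy's
  `method="auto"`).
- **AUC.** Midrank Mann–Whitney estimator, U/(n_pos·n_neg); ties count
  one half. Confidence intervals are 2.5/97.5 percentile bootstrap
  with resampling stratified by class, preserving class counts so the
  AUC is defined in every replicate. Default 2000 replications.
- **Classifier comparison.** One-sided bootstrap with null "the other
  marker classifies as well or better": each replicate resamples
  *samples* (stratified), scores the same resample with both markers,
  and computes d\* = AUC_index\* − AUC_other\*;
  p = (1 + #{d\* ≤ 0}) / (n_boot + 1). The add-one convention avoids
  p = 0 at finite replication counts. Under two pure-noise markers the
  procedure rejects at roughly the nominal rate (checked ≤ 10% at the
  5% level over 200 simulated datasets).
- **Logistic odds ratio.** Single-predictor logistic regression
  (statsmodels Newton/IRLS, tolerance 1e-8, ≤ 100 iterations), 95%
  Wald CI, complete observations only. Because the per-unit OR of a
  continuous index depends on its arbitrary units, the per-SD OR is
  reported alongside. Complete separation is detected up front and
  flagged with an infinite-OR sentinel rather than allowed to diverge;
  constant scores are flagged degenerate.
- **Differential pathway flux.** Per-pathway Kruskal–Wallis (or
  Wilcoxon for two groups) with Bonferroni correction
  (p_bonf = min(1, m·p_raw) over the m pathways tested), rows sorted
  by raw p. Bonferroni, not FDR, is used to match the reporting
  convention of this analysis family.

## Synthetic data

The generator stands in for a real diagnostic cohort and defines the
conditions under which the pipeline is validated.

**Network.** Each generated reaction has a substrate and an enzyme
species whose constituents are sampled without replacement from the
gene pool (`genes_per_species` each, default 2), an optional inhibitor
(probability `inhibitor_fraction`, default 0.2), and occasionally a
constant compound (water/oxygen) as an extra substrate. Pathways are
split signaling/metabolism by `klass_fractions` (default 0.6/0.4,
banker's rounding of the signaling count) and crosstalk links are
Bernoulli per ordered pathway pair (`crosstalk_density`, default 0.1).
Defaults give 30 genes / 5 pathways / 20 reactions — miniature, but
structurally complete.

**Cohort.** Expression of gene *g* in a sample of group *G* is

    baseline_g · multiplier_G^[g feeds a driver pathway] · exp(N(0, noise_log_sd))

with `baseline_g ~ exp(N(baseline_log_mean, baseline_log_sd))` drawn
once per gene and shared across samples (gene-specific baselines,
per-cell lognormal noise). Defaults: baseline_log_mean 3.0 (natural
log; ≈ 20 TPM for a typical gene), baseline_log_sd 1.0, noise_log_sd
0.3 — values chosen as a plausible bulk-RNAseq-like spread, since no
distributional description of a real cohort is available; lognormality
is an assumption, not a fitted fact. Default group sizes are
78 malignant / 21 benign / 40 control, mirroring a malignant-heavy
diagnostic study; default multipliers 2.0 / 1.4 / 1.0 with control as
reference. "Feeds a driver pathway" means the gene is a constituent of
a species participating in an *activating* role in any reaction of
that pathway — inhibitor-feeding genes are excluded because shifting
them would invert the intended effect direction.

What the generator does **not** emulate: count noise and library-size
effects (no negative-binomial model), gene–gene correlation beyond
shared pathway membership, batch effects, or covariate structure
(age/sex/biomarkers). Passing tests therefore demonstrate the
machinery's correctness and calibration, not clinical performance on
real RNAseq.

## Determinism

Every stochastic component takes an explicit seed. The pipeline
derives per-purpose child seeds as
`SeedSequence([seed, crc32(purpose)])`, so bootstrap streams for
different contrasts are independent yet reproducible; the scheme and
all effective parameters are recorded in `run_metadata.json` together
with SHA-256 checksums of the inputs. Fixed-seed runs are
byte-identical, which the test suite asserts on whole artifact files.
Floats in JSON reports are serialized at 12 significant digits.

## Problem sizes used in validation

The test and acceptance runs use miniature networks (≈ 5–25 genes per
species pool ≤ 26, ≤ 50 reactions) and cohorts of 90–140 samples, with
2000 bootstrap replications where bootstrap is involved; the whole
suite runs in seconds. These sizes were chosen because the engine's
correctness properties (oracle equivalence, rank-statistic identities,
calibration) are scale-free: they hold per entry and per test, so
small instances verify the same code paths a production-scale network
would execute.

## Known limitations

- Rate constants default to 1; the engine accepts per-reaction
  constants but ships no kinetic database integration, so absolute
  fluxes are unitless scores, not physical rates.
- No time-course simulation: fluxes are instantaneous functions of one
  expression profile (steady-state snapshot view).
- One-level crosstalk is a modelling truncation, not an exact solution
  of the circular definition.
- Species concentrations assume transcript abundance is a valid proxy
  for protein/complex abundance; no translation or degradation
  modelling.
- The equal-weight IM-Index (α = β = 1) is a default, not an
  optimized choice; the weights are exposed for tuning.
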