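# Methods

This note documents the models and procedures implemented in
`lupus_stratify`, the synthetic cohort generator that exercises them, the
numerical choices made where the design was genuinely open, and the limits
of what the passing test suite demonstrates.

## Statistical primitives

All categorical comparisons run through two conventions. The
clinical-characteristics convention applies the continuity-corrected
chi-squared on every 2×2 table,
χ² = N·(max(0, |ad−bc| − N/2))² / (r₁r₂c₁c₂) with 1 df and the correction
term floored at zero (equal-proportion tables give χ² = 0, p = 1; a zero
margin gives p = 1 directly). The benefit-comparison convention
(`expected_lt5_fisher`) uses the two-sided Fisher exact test when any
expected cell count r_i·c_j/N falls below 5 and the corrected chi-squared
otherwise. Fisher's two-sided p follows the probability-mass rule — the sum
of hypergeometric masses of all tables with the observed margins whose mass
does not exceed the observed table's (relative tolerance 1e−7) — which is
also what full enumeration over the support gives; the two are tested for
exact agreement on all tables up to N = 40. One pragmatic note: the
calcineurin-style table [[10,1],[3,12]] has minimum expected count 5.5
and therefore lands on the chi-squared branch; both tests round to the same
3-decimal p there, so the policy is insensitive for that comparison.

Mann–Whitney U uses midrank ties, exact enumeration when min(n_x, n_y) ≤ 8
and the data are tie-free, and otherwise the normal approximation with tie
and continuity corrections. Spearman's ρ is the Pearson correlation of
midranks with a t-approximation at n−2 df; perfectly monotone inputs are
flagged `exact-monotone` with p reported as 0. Benjamini–Hochberg q-values
are step-up adjusted and order-preserving. BH is *not* idempotent —
re-adjusting adjusted values inflates them by m/rank again — so the tested
invariants are q ∈ [0,1], q ≥ p, and monotonicity in the sorted order.

P-values are reported raw and, following clinical-table convention, rounded
to three decimals where tables are reproduced.

## Differential expression

Per gene, ordinary least squares of log2 expression on an intercept, a group
indicator, age, sex, one-hot sequencing batch, and RIN. The group
coefficient is the log2 fold change; two-sided p-values use the t
distribution at the residual df; BH controls FDR across genes at 0.05
(the significance level is a package decision). No empirical-Bayes variance
moderation is applied: OLS is deterministic, exact on the synthetic
log-normal noise model, and the acceptance surface does not depend on
small-sample shrinkage. Samples missing any covariate are dropped per
analysis with a warning (per-variable complete-case, mirroring per-row N
reporting in clinical tables). A rank-deficient design raises an error
naming the collinear columns. The specificity filter is a strict
|log2FC| > 0.58 (≈1.5-fold); 0.58 itself is excluded.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) for a query of n genes against each term
of size K (after intersection with the background) in a universe of N;
BH across tested terms; gene ratio = k/K. The background is all genes in the
expression matrix (a package decision — the universe is otherwise
unspecified in this kind of analysis). Terms outside [5, 2000] genes after
intersection are skipped and recorded.

## Co-expression modules

Unsigned adjacency |cor|^β by default (signed `((1+cor)/2)^β` by flag),
Pearson correlation. The scale-free criterion (smallest β with model fit
R² ≥ 0.8 of log p(k) vs log k over 10 connectivity bins) is implemented and
tested, but the pipeline default is the conventional unsigned β = 6: at 26
samples the scale-free fit is unstable (the chosen β ranged from 2 to 20
across synthetic seeds, and β = 2 collapses the network into one module).

TOM follows the standard formula with the diagonal treated as 0 in the
connectivity and neighbour sums and set to 1 in the output. Genes are
clustered by average linkage on 1 − TOM. The static cut height is chosen by
a deterministic scan: among candidate heights (quantiles 0.5–0.999 of the
merge heights, capped at 0.99), the one yielding the most branches of at
least `min_module_size` genes wins, ties to the lower height. A fixed
absolute cut does not transfer across network scales because the noise
connectivity — and with it the whole TOM scale — grows with the gene
universe; the scan adapts without randomness. Candidate modules are then
refined by the field's standard eigengene post-processing: modules whose
eigengenes correlate ≥ 0.8 are merged, and every gene is re-assigned to its
best-correlated module eigengene when that kME reaches 0.5, iterated to a
fixed point (≤ 4 rounds). This replaces dynamic tree cutting with a simpler
deterministic procedure; planted two-block structure (within-correlation
0.8) is recovered at Jaccard ≥ 0.9, which is what the tests demonstrate —
weaker planted correlation (~0.5, the regime the generator produces at
realistic dysregulation amplitudes) recovers modules only partially, though
downstream stratification is robust to that impurity.

The module eigengene is the first principal component of the standardized
member expression, scaled to unit variance and oriented so its correlation
with the mean member expression is positive (making downstream signs
reproducible). Cross-cohort replication tests each module pair by
hypergeometric overlap (BH-corrected); a module replicates when its best
partner has q < 0.05 and the overlap covers ≥ 30% of the smaller module.
Module meta-clusters come from Ward clustering on 1 − cor(eigengenes) cut at
k = 5, each cluster labelled by the annotation signature set with the
smallest hypergeometric overlap p — an automated stand-in for manual
annotation.

## Matching and dysregulation scores

Greedy nearest-age, same-sex matching without replacement at a 1:5 ratio,
patients in ascending id order, control ties broken by id: deterministic and
reproducible; globally optimal matching is out of scope. 26 patients pool
exactly 130 distinct controls. Per-gene z uses the pooled reference mean and
SD (n−1); constant-reference genes are excluded with a warning. The module
dysregulation score is the unweighted mean of member-gene z — not an
eigengene projection — because it is orientation-free and deterministic.
Patients are Ward-clustered on module z-vectors and cut at k = 2; subgroup 1
is the cluster with the higher mean interferon z. In the pipeline the
orientation anchor is an explicit per-patient interferon signature score
(mean gene z over the packaged interferon annotation genes) rather than the
annotated module's mean: a merged detected module can mix up- and
down-regulated genes and flip the module-mean sign even when the split is
correct. Subgroup 2 is re-cut at k = 2 into nested subsets 2a/2b.

## Deconvolution

Expression is un-logged (2^x − 1) and each sample's marker-gene vector is
regressed on the 22-column signature by non-negative least squares;
coefficients are renormalized to sum to 1 (compositional closure by
construction). NNLS is deterministic and dependency-light; support-vector
regression variants would add tuning without changing what the synthetic
tests can show. NLR = neutrophil fraction / (B + T + NK + plasma fractions),
infinite when the lymphoid total is zero with non-zero neutrophils. Group
comparisons are pairwise Mann–Whitney per cell type with BH across cell
types.

## Serology associations

Spearman per module × marker with pairwise deletion (≥ 5 paired
observations); Mann–Whitney of module z by binary status with direction =
sign(median difference). Significance is flagged at uncorrected p < 0.05 —
small-cohort serology panels are conventionally reported uncorrected — and a
BH-corrected q column is emitted alongside for users who want it.

## Regulator enrichment and drug response

Genes are ranked by descending |mean z| within the chosen subgroup (stable
id tie-break). For each regulon the recovery curve accumulates target hits
over the top 3% of the ranking; AUC = Σ_ranks cumulative hits / (window ×
regulon size). NES standardizes AUC across all regulons (mean 0, SD 1,
population SD); the chief regulator is the top NES, and the conventional
NES ≥ 3 notability bar is reported, not enforced. Note the null of this AUC
is strongly right-skewed (hit counts in a 3% window are sparse), so the
*maximum* NES across a couple dozen random regulons crosses 3 in an
appreciable fraction of seeds; the typical (median) null maximum stays
below 3, and the planted chief regulator separates cleanly (NES ≈ 4–5).

The anticipated-response score is R_pd = mean over drug targets of
s_g · z_pg with s = +1 for inhibited and −1 for stimulated targets:
inhibiting an overexpressed gene or stimulating an underexpressed one scores
positive. The benefit threshold τ = 0.5 (configurable) requires targets to
be meaningfully dysregulated, not merely positive. Benefit proportions are
compared per drug under the expected-count policy.

## The synthetic cohort generator

The generator emulates the study design, not any real dataset: three
cohorts (26 CNS lupus patients planted as subgroups of 11 and 15, 38 active
non-NP SLE, 497 HC), with ages from 18-truncated normals at the published
per-group means/SDs, sex at the published female frequencies, three
sequencing batches, and RIN ~ N(8, 0.8) clipped to (5, 10].

Expression is built in four layers, genes × samples on the log2 scale:

1. **Cell mixing.** A 22-cell-type signature with 6 exclusive markers per
   type; per-sample fractions are Dirichlet draws whose concentration
   vectors shift by group (subgroup 1: neutrophils ×1.35, plasma cells ×3,
   lymphoid ×0.55 — the myeloid-shifted, lymphopenic profile). Non-marker
   genes are flat across cell types, so mixing adds no variance to them and
   the planted module effects stay analytic.
2. **Module activity.** Ten planted modules (interferon, B cell, T cell,
   cytotoxic/NK, two inflammation modules, plasma cells/ubiquitination,
   cell cycle, transcription regulation, mitochondria-associated). Each
   sample carries a latent activity per module: group effect δ plus
   N(0, 0.75) heterogeneity, applied additively (× noise SD) to all member
   genes. Defaults plant the study's qualitative pattern: interferon +2.5 SD
   in subgroup 1 (the prominent module), inflammation +1.5…+2, lymphoid
   modules −2, subgroup 2 attenuated (|δ| ≤ 0.5), non-NP SLE intermediate
   for shared axes. Because members share the activity latent, the realized
   patient z is (δ + u)/√(1 + 0.75²) ≈ 0.8·δ — dysregulation amplitudes and
   within-module correlation trade off through the same knob.
3. **CNS-specific genes.** 30 standalone genes (no activity latent) shifted
   +1 SD in both CNS subgroups only; these seed the packaged
   chromosome-segregation-style gene set and drive the DEG set logic.
4. **Covariates and noise.** Per-gene age slopes (SD 0.002/yr), a +0.2
   male shift on a random 10% of genes, per-gene per-batch shifts
   (SD 0.15, random sign — a global same-sign batch shift would add a
   shared per-patient offset to every module z and act as an artificial
   clustering axis), per-gene RIN slopes (SD 0.05), and N(0, 0.4) log2
   noise (log-normal in linear space).

Serum markers tied to module activities (CXCL10 and IL-1RA ↔ interferon,
CXCL13 ↔ cell cycle, CCL4 and GDF15 ↔ inflammation, IgM anti-PC ↔ T cell)
are Gaussian-copula calibrated to Spearman ρ ≈ 0.6 with the planted
activity (Pearson r = 2·sin(πρ_s/6)); six decoy markers are independent.
Anti-dsDNA positivity (titre ≥ 40 U/mL) is planted only in subgroup 1
(4 of 9 with measured data; 0 of 12 in subgroup 2), and clinical flags are
planted at the published case-mix frequencies, so the subgroup
characterization tables reproduce structurally when stratification recovers
the planted labels. Fixture databases — ~50 GO-like sets, the signature, 25
TF regulons (IRF9's targets 90% inside the interferon module, so the
planted chief regulator is recoverable by construction), and the
drug→target/action table (anifrolumab→IFNAR/ISGs, C3 inhibitor→C3,
calcineurin inhibitors→PPP3 subunits, SYK inhibitor→SYK,
bortezomib→PSMB family, memantine→NMDAR subunits; all inhibitory) — are
regenerated from the same seed.

Everything is deterministic given the config seed; each stage derives its
own generator stream, so metadata are identical regardless of whether
expression is generated.

**What the generator does not emulate:** count-level sequencing noise
(negative-binomial mean–variance), gene-length and library-size artefacts,
correlated module structure beyond the shared activity latent, real marker
biology, longitudinal sampling, or any property of real patient data.
Passing tests demonstrate the pipeline's correctness and calibration on
this generative model — planted effects recovered, exact statistics exact,
type-I error nominal — not clinical validity of subgroups or response
calls on real cohorts.

## Problem sizes and defaults

The default synthetic run uses 5000 genes × 561 samples and completes in
about half a minute on one CPU; tests use scaled-down cohorts (400–2000
genes, 120–200 HC) chosen to keep every planted structure detectable while
the suite stays fast. `min_module_size` defaults to 30 at full scale and 10
in test-scale configurations. Calibration and recovery studies
(subgroup-recovery ARI at 1.5-SD planted contrasts, DGE type-I on a null
cohort with HC-like mixing for all groups, anifrolumab benefit ordering) use
20 seeds each.

## Known limitations

- Static-cut-plus-refinement module detection is deliberately simpler than
  dynamic tree cutting; at planted within-module correlation ~0.5 and 26
  samples it fragments or misses weak modules (mean Jaccard ~0.5 against
  planted truth), though patient stratification downstream is insensitive.
- The matching is greedy, not optimal, and can propagate early choices; with
  a large control pool this is immaterial.
- The NES null is skewed (see above); NES magnitudes should be compared
  within a run, not across regulon collections of different sizes.
- Response scores are linear in z and ignore dose, pharmacokinetics, and
  target interactions; benefit calls are in-silico constructs with no
  claim of clinical validity.
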