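# lupus-stratify

Whole-blood transcriptome stratification of active CNS lupus
(neuropsychiatric systemic lupus erythematosus with active central-nervous-
system involvement), built for researchers who want to reproduce, probe, or
extend module-based patient stratification on bulk RNA-seq cohorts.

Active CNS lupus is clinically heterogeneous, and attributing
neuropsychiatric symptoms to lupus rather than other causes is a major
challenge. One productive approach stratifies patients molecularly: discover
co-expressed gene modules in whole blood, score each patient's module
dysregulation against matched healthy controls, cluster patients on those
scores, and ask whether the resulting subgroups differ in immune-cell
composition, serology, and anticipated response to targeted therapies. This
package implements that full analysis chain as a tested library plus a thin
CLI, exercised end to end on a seeded synthetic cohort generator that
emulates the study design it targets: 26 active CNS lupus patients (planted
subgroups of 11 and 15), 38 active non-neuropsychiatric SLE patients, and
497 healthy controls (HC).

## The methods at its core

- **Covariate-adjusted differential expression**: per gene, OLS of log2
  expression on a group indicator plus age, sex, sequencing batch and RIN;
  Benjamini–Hochberg FDR across genes; the specificity filter keeps genes
  with |log2FC| > 0.58 (~1.5-fold).
- **Co-expression modules (WGCNA core)**: adjacency `a_ij = |cor(x_i, x_j)|^β`,
  topological overlap
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  average-linkage clustering on `1 − TOM`, a static cut selected from the
  merge-height distribution, and eigengene-based refinement (merging close
  modules, kME re-assignment). Module eigengene = first principal component
  of the standardized member expression.
- **Dysregulation z-scores**: each patient is matched to 5 same-sex,
  nearest-age HC without replacement (26 patients → a pooled reference of
  130 controls); per-gene `z = (x − μ_ref)/σ_ref`, module score = mean
  member-gene z. Patients are stratified by Ward clustering on module
  z-vectors; subgroup 1 is the cluster with the higher interferon z.
- **Immune deconvolution**: non-negative least squares of the un-logged
  marker-gene vector on a 22-cell-type signature matrix, renormalized to
  proportions; neutrophil-to-lymphocyte ratio (NLR) = neutrophil fraction /
  summed B, T, NK and plasma-cell fractions.
- **Serology associations**: Spearman correlation of module z with serum
  marker levels; Mann–Whitney of module z by autoantibody status.
- **Regulator enrichment**: genes ranked by |mean z|; per TF regulon, the
  recovery-curve AUC over the top 3% of the ranking, standardized across
  regulons into a normalized enrichment score (NES); the chief regulator is
  the top NES.
- **Anticipated drug response**: reversal score
  `R_pd = mean_g s_g · z_pg` over drug d's targets (s = +1 for inhibited,
  −1 for stimulated targets); a patient benefits when `R ≥ τ` (default 0.5);
  subgroup benefit proportions are compared with Fisher's exact test when
  any expected cell count is below 5, otherwise the Yates-corrected χ².

## Worked example

Run the whole pipeline on a scaled-down synthetic cohort (600 genes,
170 HC; full cohort structure otherwise):

```bash
cat > cfg.yaml <<EOF
sim:
  n_genes: 600
  module_size: 20
  n_hc: 170
min_module_size: 10
EOF
lupus-stratify all --config cfg.yaml --seed 4 --outdir out/
python - <<'PY'
import json
r = json.load(open("out/report.json"))
d = r["stages"]
print("pooled matched controls:", d["dysreg"]["pooled_controls"])
print("subgroup sizes:", d["dysreg"]["subgroup_sizes"])
print("chief regulator:", d["regnet"]["chief_regulator"])
print("anifrolumab benefit:", d["drugs"]["per_drug"]["anifrolumab"])
PY
```

prints

```
pooled matched controls: 130
subgroup sizes: {'1': 11, '2': 15}
chief regulator: IRF9
anifrolumab benefit: {'method': 'fisher', 'p': 0.014349172163144434,
                      'prop1': 0.9090909090909091, 'prop2': 0.4}
```

Reading: the 26 synthetic CNS lupus patients were each matched to 5 same-sex
nearest-age controls (pooling 130 of the 170 HC), Ward clustering on module
dysregulation z-scores recovered the planted 11/15 subgroup split, the
planted IRF9 regulon tops the NES ranking of the regulator enrichment, and
the interferon-high subgroup 1 shows a significantly higher proportion of
patients with an anticipated benefit from the IFNAR-blocking antibody
(91% vs 40%, Fisher p = 0.014 at this reduced scale).

Every stage is also a library call (`lupus_stratify.dge.fit_dge`,
`coexpr.detect_modules`, `dysreg.module_z`, `deconv.estimate_fractions`,
`regnet.nes_scores`, ...) operating on pandas objects, and the per-stage CLI
subcommands (`simulate`, `dge`, `ora`, `modules`, `dysreg`, `deconv`,
`assoc`, `regnet`, `drugs`) run any prefix of the chain.

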