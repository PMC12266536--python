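"""Configuration, orchestration, file I/O and the machine-readable report.

``run_pipeline`` executes the stages in topological order (simulate ->
dge / modules -> dysreg -> deconv / assoc / regnet / drugs -> report), each
stage writing its TSV outputs into the output directory and appending a
parameter echo, input hashes, shapes and headline results to the
schema-versioned run report.  All randomness flows from the single config
seed; regenerating with an identical config and seed yields an identical
report body.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, deconv, dge, dysreg, io, ora, regnet, serology
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "STAGES", "STAGE_DEPS"]

log = logging.getLogger("lupus_stratify")

SCHEMA_VERSION = "1.0"

STAGES = ["simulate", "dge", "ora", "modules", "dysreg", "deconv",
          "assoc", "regnet", "drugs", "report"]

STAGE_DEPS = {
    "simulate": [],
    "dge": ["simulate"],
    "ora": ["dge"],
    "modules": ["simulate"],
    "dysreg": ["modules"],
    "deconv": ["dysreg"],
    "assoc": ["dysreg"],
    "regnet": ["dysreg"],
    "drugs": ["dysreg"],
    "report": [],
}

_SEROLOGY_MARKERS = ["CXCL10", "IL1RA", "CXCL13", "CCL4_serum", "GDF15",
                     "IgM_anti_PC", "CRP", "IL6", "TNFa", "BAFF",
                     "MMP8", "FasL"]
_FLAG_COLUMNS = ["renal", "haematologic", "vascular", "musculoskeletal",
                 "dermal", "serosal", "immunologic", "constitutional",
                 "anti_dsdna_pos"]


@dataclass
class RunConfig:
    """Paths, per-stage parameters and the global seed."""

    outdir: str = "results"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)       # SimulationConfig overrides

    dge_fdr: float = 0.05
    lfc_threshold: float = 0.58
    ora_min_size: int = 5
    ora_max_size: int = 2000
    # conventional unsigned-network default; None = scale-free auto-pick,
    # which is unstable at ~26 samples
    soft_power: int | None = 6
    signed_network: bool = False
    min_module_size: int = 30
    module_clusters: int = 5
    match_ratio: int = 5
    subgroups_k: int = 2
    top_fraction: float = 0.03
    tau: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def expand_stages(self) -> list:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage name(s): {unknown}")
        wanted = set()

        def add(s):
            for dep in STAGE_DEPS[s]:
                add(dep)
            wanted.add(s)

        for s in self.stages:
            add(s)
        return [s for s in STAGES if s in wanted]


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(
            f"stage {needed_by!r} needs output of stage {stage!r} "
            f"({key}), which has not run")
    return state[key]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages end to end; returns the run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    report = {"schema_version": SCHEMA_VERSION, "seed": cfg.seed,
              "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
              "stages": {}, "warnings": []}
    state: dict = {}
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for stage in cfg.expand_stages():
                log.info("running stage %s", stage)
                _STAGE_FUNCS[stage](cfg, state, report, out)
            report["warnings"] = sorted({str(w.message) for w in caught})
    finally:
        log.removeHandler(fh)
        fh.close()
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_simulate(cfg: RunConfig, state, report, out: Path):
    sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.sim)
    cohort = simulate_cohort(sim_cfg)
    state["cohort"] = cohort
    io.write_expression(cohort.expr, out / "expression.tsv")
    io.write_metadata(cohort.meta, out / "metadata.tsv")
    io.write_gmt(cohort.genesets, out / "genesets.gmt")
    io.write_gmt(cohort.regulons, out / "regulons.gmt")
    cohort.signature.to_csv(out / "signature.tsv", sep="\t")
    cohort.drug_targets.to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    report["stages"]["simulate"] = {
        "params": dataclasses.asdict(sim_cfg),
        "n_genes": int(cohort.expr.shape[0]),
        "n_samples": int(cohort.expr.shape[1]),
        "cohort_sizes": cohort.meta["cohort"].value_counts().to_dict(),
        "hashes": {f.name: _md5(f) for f in
                   [out / "expression.tsv", out / "metadata.tsv"]},
    }


def _stage_dge(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "dge")
    cns = dge.fit_dge(cohort.expr, cohort.meta, group="CNS_LUPUS",
                      fdr=cfg.dge_fdr, lfc_threshold=cfg.lfc_threshold)
    sle = dge.fit_dge(cohort.expr, cohort.meta, group="SLE_NONNP",
                      fdr=cfg.dge_fdr, lfc_threshold=cfg.lfc_threshold)
    sets = dge.deg_sets(cns, sle, fdr=cfg.dge_fdr)
    specific_lfc = dge.lfc_filter(cns.loc[sorted(sets["specific_a"])],
                                  cfg.lfc_threshold)
    state.update(dge_cns=cns, dge_sle=sle, deg_sets=sets,
                 cns_specific=sorted(sets["specific_a"]),
                 cns_specific_lfc=list(specific_lfc.index))
    cns.to_csv(out / "deg_cns.tsv", sep="\t")
    sle.to_csv(out / "deg_sle.tsv", sep="\t")
    report["stages"]["dge"] = {
        "fdr": cfg.dge_fdr, "lfc_threshold": cfg.lfc_threshold,
        "counts": sets["counts"],
        "n_specific_lfc": int(len(specific_lfc)),
    }


def _stage_ora(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "ora")
    query = _require(state, "cns_specific", "dge", "ora")
    background = list(cohort.expr.index)
    if not query:
        report["stages"]["ora"] = {"note": "empty query, skipped"}
        return
    table, skipped = ora.run_ora(query, background, cohort.genesets,
                                 min_size=cfg.ora_min_size,
                                 max_size=cfg.ora_max_size)
    table.to_csv(out / "ora_table.tsv", sep="\t", index=False)
    top = table.iloc[0] if len(table) else None
    report["stages"]["ora"] = {
        "n_terms_tested": int(len(table)), "n_skipped": len(skipped),
        "top_term": None if top is None else
        {"term": top["term"], "p": float(top["p"]), "q": float(top["q"]),
         "gene_ratio": float(top["gene_ratio"])},
    }
    state["ora_table"] = table


def _stage_modules(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "modules")
    meta = cohort.meta
    cns_ids = meta.index[meta["cohort"] == "CNS_LUPUS"]
    sle_ids = meta.index[meta["cohort"] == "SLE_NONNP"]
    expr_cns = cohort.expr[cns_ids]
    if cfg.soft_power is None:
        params = coexpr.pick_soft_threshold(expr_cns, signed=cfg.signed_network)
    else:
        params = coexpr.CoexpressionParams(beta=cfg.soft_power,
                                           scale_free_r2=float("nan"),
                                           signed=cfg.signed_network)
    params.min_module_size = cfg.min_module_size
    adj = coexpr.adjacency(expr_cns, params.beta, signed=params.signed)
    tom = coexpr.compute_tom(adj)
    modules = coexpr.detect_modules(tom, expr_cns,
                                    min_module_size=cfg.min_module_size)
    annotation_sets = {k: v for k, v in cohort.genesets.items()
                       if k.startswith("sig_")}
    k = min(cfg.module_clusters, max(1, len(modules.labels)))
    if modules.labels:
        coexpr.cluster_modules(modules, k=k, annotation_sets=annotation_sets,
                               universe=cohort.expr.index)
    # replication in the non-NP SLE cohort
    adj_b = coexpr.adjacency(cohort.expr[sle_ids], params.beta,
                             signed=params.signed)
    modules_b = coexpr.detect_modules(coexpr.compute_tom(adj_b),
                                      cohort.expr[sle_ids],
                                      min_module_size=cfg.min_module_size)
    overlap = coexpr.replicate_modules(modules, modules_b, cohort.expr.index)
    state.update(modules=modules, modules_sle=modules_b, module_overlap=overlap)
    io.write_gmt(dict(modules.modules), out / "modules.gmt")
    modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    (out / "coexpr_params.json").write_text(json.dumps(
        {"beta": params.beta, "scale_free_r2": params.scale_free_r2,
         "signed": params.signed, "min_module_size": params.min_module_size}))
    n_repl = (int(overlap.groupby("module_a")["replicated"].any().sum())
              if len(overlap) else 0)
    report["stages"]["modules"] = {
        "beta": params.beta, "scale_free_r2": params.scale_free_r2,
        "n_modules": len(modules.labels),
        "n_unassigned": len(modules.unassigned),
        "annotation": modules.annotation,
        "n_replicated_in_sle": n_repl,
    }


def _stage_dysreg(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "dysreg")
    modules = _require(state, "modules", "modules", "dysreg")
    meta = cohort.meta
    patients = meta[meta["cohort"] == "CNS_LUPUS"]
    hc = meta[meta["cohort"] == "HC"]
    match = dysreg.match_controls(patients, hc, ratio=cfg.match_ratio)
    gz = dysreg.gene_z(cohort.expr, match.pooled, list(patients.index))
    d = dysreg.module_z(gz, modules)
    anchor = _anchor_module(modules)
    anchor_scores = None
    ifn_sig = [g for g in cohort.genesets.get("sig_interferon", [])
               if g in gz.index]
    if ifn_sig:
        anchor_scores = gz.loc[ifn_sig].mean(axis=0)
    assignment = dysreg.cluster_patients(d, k=cfg.subgroups_k,
                                         anchor_module=anchor,
                                         anchor_scores=anchor_scores)
    table = dysreg.characterize_subgroups(
        assignment, meta,
        categorical=_FLAG_COLUMNS,
        continuous=["age", "sledai", "disease_duration", "anti_dsdna",
                    "C3c", "C4"])
    state.update(match=match, gene_z=gz, dysregulation=d,
                 assignment=assignment, subgroup_table=table)
    d.to_csv(out / "dysregulation.tsv", sep="\t")
    pd.DataFrame({"subgroup": assignment.labels,
                  "nested": assignment.nested}).to_csv(
        out / "subgroups.tsv", sep="\t", na_rep="NA")
    pd.DataFrame([(p, c) for p, cs in match.mapping.items() for c in cs],
                 columns=["patient", "control"]).to_csv(
        out / "matches.tsv", sep="\t", index=False)
    table.to_csv(out / "subgroup_characteristics.tsv", sep="\t", index=False)
    extra = {}
    if "planted_subgroup" in meta.columns:
        from sklearn.metrics import adjusted_rand_score
        truth = meta.loc[assignment.labels.index, "planted_subgroup"]
        extra["planted_ari"] = float(
            adjusted_rand_score(truth, assignment.labels))
    report["stages"]["dysreg"] = {
        "ratio": cfg.match_ratio, "pooled_controls": len(match.pooled),
        "anchor_module": anchor,
        "subgroup_sizes": {str(k): int(v)
                           for k, v in assignment.sizes.items()},
        **extra,
    }


def _anchor_module(modules) -> str | None:
    ifn = [m for m, name in modules.annotation.items() if name == "interferon"]
    if ifn:
        return max(ifn, key=lambda m: len(modules.modules[m]))
    return modules.labels[0] if modules.labels else None


def _stage_deconv(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "deconv")
    assignment = _require(state, "assignment", "dysreg", "deconv")
    match = state["match"]
    meta = cohort.meta
    ids = list(meta.index[meta["cohort"] != "HC"]) + list(match.pooled)
    fr = deconv.estimate_fractions(cohort.expr[ids], cohort.signature)
    groups = pd.Series("HC_matched", index=fr.index)
    groups[meta.loc[fr.index, "cohort"] == "SLE_NONNP"] = "SLE_NONNP"
    for pid, lab in assignment.labels.items():
        groups[pid] = f"subgroup_{lab}"
    comp = deconv.compare_fractions(fr, groups)
    fr.to_csv(out / "fractions.tsv", sep="\t")
    comp.to_csv(out / "fraction_comparisons.tsv", sep="\t", index=False)
    state.update(fractions=fr, fraction_groups=groups)
    nlr = fr["nlr"].groupby(groups).median()
    report["stages"]["deconv"] = {
        "n_samples": int(len(fr)),
        "median_nlr": {str(k): float(v) for k, v in nlr.items()},
    }


def _stage_assoc(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "assoc")
    d = _require(state, "dysregulation", "dysreg", "assoc")
    markers = [m for m in _SEROLOGY_MARKERS if m in cohort.meta.columns]
    corr = serology.correlate_modules_markers(d, cohort.meta, markers)
    frames = [corr]
    if "anti_dsdna_pos" in cohort.meta.columns:
        try:
            frames.append(serology.modules_by_status(d, cohort.meta,
                                                     "anti_dsdna_pos"))
        except ValueError as e:
            report["stages"].setdefault("assoc", {})["status_note"] = str(e)
    assoc = pd.concat(frames, ignore_index=True)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    state["associations"] = assoc
    sig = corr[corr["significant"] == True]  # noqa: E712
    report["stages"].setdefault("assoc", {}).update({
        "n_pairs": int(len(corr)), "n_significant": int(len(sig))})


def _stage_regnet(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "regnet")
    gz = _require(state, "gene_z", "dysreg", "regnet")
    assignment = state["assignment"]
    g1 = assignment.labels.index[assignment.labels == 1]
    mean_z = gz[list(g1)].mean(axis=1)
    ranked = regnet.rank_genes(mean_z)
    scores = regnet.nes_scores(ranked, cohort.regulons,
                               top_fraction=cfg.top_fraction)
    scores.to_csv(out / "regulators.tsv", sep="\t", index=False)
    state.update(regulators=scores, ranked_genes=ranked)
    top = scores.iloc[0]
    report["stages"]["regnet"] = {
        "top_fraction": cfg.top_fraction,
        "chief_regulator": top["tf"], "chief_nes": float(top["nes"]),
        "n_regulons": int(len(scores)),
    }


def _stage_drugs(cfg: RunConfig, state, report, out: Path):
    cohort = _require(state, "cohort", "simulate", "drugs")
    gz = _require(state, "gene_z", "dysreg", "drugs")
    assignment = state["assignment"]
    calls = regnet.response_table(gz, cohort.drug_targets, tau=cfg.tau)
    comparison = regnet.compare_benefit(calls, assignment)
    calls.to_csv(out / "response_calls.tsv", sep="\t", index=False)
    comparison.to_csv(out / "benefit_comparison.tsv", sep="\t", index=False)
    state.update(response_calls=calls, benefit_comparison=comparison)
    report["stages"]["drugs"] = {
        "tau": cfg.tau,
        "per_drug": {
            r["drug"]: {"prop1": float(r["prop1"]), "prop2": float(r["prop2"]),
                        "p": float(r["p"]), "method": r["method"]}
            for _, r in comparison.iterrows()},
    }


def _stage_report(cfg: RunConfig, state, report, out: Path):
    report["stages"]["report"] = {"outputs": sorted(
        p.name for p in out.iterdir() if p.is_file())}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "dge": _stage_dge,
    "ora": _stage_ora,
    "modules": _stage_modules,
    "dysreg": _stage_dysreg,
    "deconv": _stage_deconv,
    "assoc": _stage_assoc,
    "regnet": _stage_regnet,
    "drugs": _stage_drugs,
    "report": _stage_report,
}
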