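"""Seeded generator of a synthetic PRECISESADS-like cohort.

Emulates the design of the study population this pipeline targets: three
cohorts (26 active CNS lupus patients split 11/15 into two planted molecular
subgroups, 38 active non-neuropsychiatric SLE patients, 497 healthy
controls), with

* whole-blood expression built as a cell-type mixture (signature matrix x
  Dirichlet cell fractions) plus additive planted module effects on the log2
  scale, covariate effects (age, sex, batch, RIN) and Gaussian log2 noise
  (log-normal in linear space);
* co-expression structure induced by a shared per-sample "module activity"
  latent variable, so module discovery has something real to find;
* serological markers calibrated to a target Spearman correlation with the
  planted module activities (CXCL10/IL-1RA with interferon, CXCL13 with cell
  cycle, CCL4/GDF15 with inflammation, IgM anti-PC with the T-cell module);
* autoantibody positivity (anti-dsDNA at the >=40 U/mL cut-off) concentrated
  in planted subgroup 1, and clinical flags planted at the case-mix
  frequencies of the emulated tables;
* fixture databases: a GO-like gene-set collection (including a
  "chromosome segregation"-style set holding the planted CNS-specific DEGs),
  a 22-cell-type marker signature, a TF regulon collection whose IRF9
  regulon overlaps the interferon module, and a drug->target/action table.

Everything is deterministic under the config seed.  All module effect sizes
are expressed in healthy-control standard-deviation units of a single gene,
which makes the expected dysregulation z-scores analytic:
z = (delta + u) / sqrt(1 + activity_sd^2) with u the per-sample activity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "CELL_TYPES",
    "LYMPHOID_PREFIXES",
    "simulate_metadata",
    "build_signature",
    "simulate_expression",
    "simulate_serology",
    "build_fixtures",
    "simulate_cohort",
    "mix_expression",
]

# The 22 immune cell types of the classic whole-blood deconvolution panel.
CELL_TYPES = [
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
]

LYMPHOID_PREFIXES = ("B cells", "T cells", "NK cells", "Plasma cells")

# Typical whole-blood mean fractions (renormalised); neutrophils dominate.
_BASE_FRACTIONS = {
    "B cells naive": 0.030, "B cells memory": 0.012, "Plasma cells": 0.003,
    "T cells CD8": 0.080, "T cells CD4 naive": 0.070,
    "T cells CD4 memory resting": 0.070, "T cells CD4 memory activated": 0.012,
    "T cells follicular helper": 0.008, "T cells regulatory (Tregs)": 0.015,
    "T cells gamma delta": 0.012,
    "NK cells resting": 0.045, "NK cells activated": 0.010,
    "Monocytes": 0.080, "Macrophages M0": 0.004, "Macrophages M1": 0.004,
    "Macrophages M2": 0.004, "Dendritic cells resting": 0.006,
    "Dendritic cells activated": 0.004, "Mast cells resting": 0.003,
    "Mast cells activated": 0.002, "Eosinophils": 0.026, "Neutrophils": 0.510,
}

# Named member genes anchoring each planted co-expression module; the rest
# of each module is filled with synthetic ids.  Memberships are a synthetic
# emulation chosen so the packaged drug-target table lands on meaningfully
# dysregulated genes (IFNAR in the interferon module, calcineurin subunits
# in inflammation, PSMB genes in plasma cells/ubiquitination, SYK in the
# mitochondria-associated module).
_MODULE_SEEDS = {
    "interferon": ["IFNAR1", "IFNAR2", "ISG15", "IFI44", "MX1", "OAS1",
                   "IRF9", "IFI6", "IFI27", "IFI44L", "IFIT1", "IFIT3",
                   "MX2", "OAS2", "OAS3", "RSAD2", "USP18", "STAT1",
                   "STAT2", "IRF7"],
    "b_cell": ["CD19", "MS4A1", "CD79A", "CD79B", "BLK", "BLNK", "PAX5",
               "TCL1A", "FCRL1"],
    "t_cell": ["CD3D", "CD3E", "CD3G", "CD2", "CD28", "LCK", "ZAP70",
               "IL7R", "CCR7"],
    "nk_cytotoxic": ["NKG7", "GNLY", "KLRD1", "PRF1", "GZMB", "GZMH",
                     "KLRK1", "FGFBP2", "ELF1"],
    "inflammation_ii": ["PPP3CA", "PPP3CB", "PPP3R1", "TNF", "IL1B",
                        "IL6R", "NFKB1", "C3", "TLR5"],
    "inflammation_iv": ["CCL4", "CCL3", "CXCL2", "NLRP3", "S100A8",
                        "S100A9", "FPR1"],
    "plasma_ubiq": ["PSMB1", "PSMB2", "PSMB5", "PSMB8", "PSMB9", "PSMB10",
                    "XBP1", "PRDM1", "MZB1"],
    "cell_cycle": ["CDC20", "CCNB1", "CDK1", "CDK2", "MKI67", "BUB1",
                   "TOP2A", "AURKB"],
    "reg_transcription": ["ZNF143", "TAF1", "GTF2B", "POLR2A", "MED12",
                          "SP1"],
    "mitochondrial": ["SDHA", "UQCRC1", "NDUFA1", "COX5A", "ATP5F1A",
                      "SYK", "MTOR"],
}

# Standalone CNS-lupus-specific DEGs (planted in both CNS subgroups, absent
# in non-NP SLE); seeds the "chromosome segregation"-style fixture set.
_CNS_SEED_GENES = ["PRTN3", "CTSC", "GRIN1", "GRIN2A", "GRIN2B", "ACE",
                   "TOP1", "NPEPPS"]

# Per-module planted effects in HC-SD units: (subgroup 1, subgroup 2,
# non-NP SLE).  Subgroup 1 carries prominent interferon/inflammation
# upregulation and lymphoid downregulation; subgroup 2 is attenuated.
_DEFAULT_EFFECTS = {
    "interferon":        (2.5, 0.5, 1.5),   # the prominent module
    "b_cell":            (-2.0, -0.3, -0.5),
    "t_cell":            (-2.0, -0.3, -0.3),
    "nk_cytotoxic":      (-2.0, -0.3, -0.3),
    "inflammation_ii":   (2.0, 0.3, 0.5),
    "inflammation_iv":   (1.5, 0.2, 0.3),
    "plasma_ubiq":       (1.5, 0.2, 0.5),
    "cell_cycle":        (1.2, 0.3, 0.2),
    "reg_transcription": (1.0, 0.2, 0.2),
    "mitochondrial":     (1.2, 0.2, 0.2),
}

# Serological markers tied to a planted module activity; None = decoy,
# independent of every module.
_MARKER_MODULES = {
    "CXCL10": "interferon",
    "IL1RA": "interferon",
    "CXCL13": "cell_cycle",
    "CCL4_serum": "inflammation_iv",
    "GDF15": "inflammation_iv",
    "IgM_anti_PC": "t_cell",
    "CRP": None, "IL6": None, "TNFa": None, "BAFF": None,
    "MMP8": None, "FasL": None,
}

# Clinical-flag case-mix frequencies (positives / group size) emulating the
# study's subgroup and comparator tables.
_FLAG_FREQS = {
    # flag: (S1 of 11, S2 of 15, SLE of 38)
    "renal": (2 / 11, 3 / 15, 20 / 38),
    "haematologic": (4 / 11, 0 / 15, 9 / 38),
    "vascular": (2 / 11, 1 / 15, 11 / 38),
    "musculoskeletal": (3 / 11, 2 / 15, 17 / 38),
    "dermal": (6 / 11, 9 / 15, 27 / 38),
    "serosal": (0.0, 0.0, 3 / 38),
    "immunologic": (8 / 11, 8 / 15, 31 / 38),
    "constitutional": (1 / 11, 0.0, 2 / 38),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-design defaults."""

    n_subgroup1: int = 11
    n_subgroup2: int = 15
    n_sle: int = 38
    n_hc: int = 497
    match_ratio: int = 5

    n_genes: int = 5000
    module_size: int = 60
    markers_per_type: int = 6
    n_cns_deg: int = 30          # CNS-specific standalone DEGs
    cns_deg_delta: float = 1.0   # planted in both CNS subgroups, SD units

    module_effects: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    noise_sd: float = 0.4        # per-gene log2 noise SD
    activity_sd: float = 0.75    # per-sample module activity SD (noise-SD units)

    age_coef_sd: float = 0.002   # per-gene log2 slope per year
    sex_effect: float = 0.2      # shift on a random 10% of genes for males
    n_batches: int = 3
    batch_sd: float = 0.15       # per-gene per-batch log2 shift SD
    rin_slope_sd: float = 0.05   # per-gene log2 slope SD per RIN unit

    sero_rho: float = 0.6        # target Spearman with planted activity
    dirichlet_conc_hc: float = 150.0
    dirichlet_conc_patient: float = 60.0
    null_fractions: bool = False  # True: all cohorts mix like HC (null runs)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subgroup1", "n_subgroup2", "n_sle", "n_hc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_genes < 1 or self.module_size < 1:
            raise ValueError("non-positive dimensions")

    @property
    def n_cns(self) -> int:
        return self.n_subgroup1 + self.n_subgroup2

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCohort:
    """Bundle of everything the generator produced, plus the planted truth."""

    meta: pd.DataFrame                 # samples x metadata, indexed by sample_id
    expr: pd.DataFrame                 # genes x samples, log2 scale
    signature: pd.DataFrame            # marker genes x 22 cell types, linear
    genesets: dict                     # GO-like term -> gene list
    regulons: dict                     # TF -> target gene list
    drug_targets: pd.DataFrame         # columns drug, gene, action
    modules_truth: dict                # module -> planted member gene list
    activity_truth: pd.DataFrame       # samples x modules planted activity (SD units)
    fractions_truth: pd.DataFrame      # samples x 22 planted cell fractions
    config: SimulationConfig = None


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.seed])


def _planted_positives(rng, ids, n_pos):
    """Choose exactly n_pos of ids, seeded."""
    chosen = rng.choice(len(ids), size=min(n_pos, len(ids)), replace=False)
    mask = np.zeros(len(ids), dtype=bool)
    mask[chosen] = True
    return mask


def simulate_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample records for the three cohorts.

    Ages are truncated normal (>= 18) with per-cohort means/SDs matching the
    emulated case mix; sex is Bernoulli at the cohort female frequencies;
    anti-dsDNA positivity is planted only in subgroup 1 (4 of 9 with
    measured data); clinical flags at the emulated per-group frequencies.
    """
    rng = _rng(cfg, 1)
    rows = []

    def ages(n, mean, sd):
        a = rng.normal(mean, sd, size=n)
        while np.any(a < 18):
            a[a < 18] = rng.normal(mean, sd, size=int(np.sum(a < 18)))
        return np.round(a, 1)

    def sexes(n, f_freq):
        n_f = int(round(f_freq * n))
        s = np.array(["F"] * n_f + ["M"] * (n - n_f))
        rng.shuffle(s)
        return s

    groups = [
        ("CNS_LUPUS", "S1", cfg.n_subgroup1, 43.7, 15.1, 1.0),
        ("CNS_LUPUS", "S2", cfg.n_subgroup2, 46.8, 14.6, 14 / 15),
        ("SLE_NONNP", "none", cfg.n_sle, 48.0, 14.3, 35 / 38),
        ("HC", "none", cfg.n_hc, 47.1, 13.0, 393 / 497),
    ]
    idx = 0
    for cohort, sub, n, age_mu, age_sd, f_freq in groups:
        age = ages(n, age_mu, age_sd)
        sex = sexes(n, f_freq)
        for i in range(n):
            rows.append({
                "sample_id": f"{'P' if cohort != 'HC' else 'H'}{idx:04d}",
                "cohort": cohort, "planted_subgroup": sub,
                "age": age[i], "sex": sex[i],
                "batch": f"B{rng.integers(cfg.n_batches)}",
                "rin": float(np.clip(np.round(rng.normal(8.0, 0.8), 2), 5.0, 10.0)),
            })
            idx += 1
    meta = pd.DataFrame(rows).set_index("sample_id")

    # clinical flags at emulated frequencies (exact planted counts)
    for flag, (f1, f2, fsle) in _FLAG_FREQS.items():
        col = np.zeros(len(meta), dtype=bool)
        for label, freq in (("S1", f1), ("S2", f2)):
            sel = np.flatnonzero((meta["cohort"] == "CNS_LUPUS").values
                                 & (meta["planted_subgroup"] == label).values)
            col[sel] = _planted_positives(rng, sel, int(round(freq * len(sel))))
        sel = np.flatnonzero((meta["cohort"] == "SLE_NONNP").values)
        col[sel] = _planted_positives(rng, sel, int(round(fsle * len(sel))))
        meta[flag] = col

    # anti-dsDNA: measured for 9/11 in S1 (4 positive), 12/15 in S2 (0
    # positive), 30/38 in SLE (15 positive); HC all measured, rare positives.
    measured = np.ones(len(meta), dtype=bool)
    titre = rng.exponential(8.0, size=len(meta))
    titre[titre >= 39.0] = 38.0
    pos = np.zeros(len(meta), dtype=bool)
    plan = {"S1": (9 / 11, 4 / 9), "S2": (12 / 15, 0.0)}
    for label, (meas_f, pos_f) in plan.items():
        sel = np.flatnonzero((meta["cohort"] == "CNS_LUPUS").values
                             & (meta["planted_subgroup"] == label).values)
        m = _planted_positives(rng, sel, int(round(meas_f * len(sel))))
        measured[sel] = m
        meas_ids = sel[m]
        pos[meas_ids] = _planted_positives(rng, meas_ids,
                                           int(round(pos_f * len(meas_ids))))
    sel = np.flatnonzero((meta["cohort"] == "SLE_NONNP").values)
    m = _planted_positives(rng, sel, int(round(30 / 38 * len(sel))))
    measured[sel] = m
    pos[sel[m]] = _planted_positives(rng, sel[m], int(round(0.5 * int(m.sum()))))
    titre[pos] = 40.0 + rng.exponential(40.0, size=int(pos.sum()))
    titre = np.round(titre, 1)
    titre[~measured] = np.nan
    meta["anti_dsdna"] = titre
    meta["anti_dsdna_pos"] = np.where(measured, titre >= 40.0, np.nan)

    # complement (g/L), mildly lower C4 in subgroup 1
    c3 = rng.normal(1.1, 0.25, len(meta))
    c4 = rng.normal(0.22, 0.07, len(meta))
    s1 = ((meta["cohort"] == "CNS_LUPUS")
          & (meta["planted_subgroup"] == "S1")).values
    c4[s1] -= 0.07
    meta["C3c"] = np.round(np.clip(c3, 0.2, None), 2)
    meta["C4"] = np.round(np.clip(c4, 0.03, None), 2)

    dur = rng.normal(15.5, 9.9, len(meta)).clip(0.5)
    dur[(meta["cohort"] == "HC").values] = np.nan
    meta["disease_duration"] = np.round(dur, 1)
    sledai = rng.normal(15.7, 7.2, len(meta)).clip(8)
    sledai[(meta["cohort"] == "SLE_NONNP").values] = \
        rng.normal(13.6, 4.1, int((meta["cohort"] == "SLE_NONNP").sum())).clip(8)
    sledai[(meta["cohort"] == "HC").values] = np.nan
    meta["sledai"] = np.round(sledai, 0)
    return meta


def _gene_universe(cfg: SimulationConfig):
    """Module memberships, marker names, CNS DEGs and filler gene ids."""
    modules = {}
    for name, seeds in _MODULE_SEEDS.items():
        members = list(seeds[: cfg.module_size])
        j = 1
        while len(members) < cfg.module_size:
            members.append(f"{name.upper()}_{j:03d}")
            j += 1
        modules[name] = members
    markers = [f"MRK{t:02d}_{j}" for t in range(len(CELL_TYPES))
               for j in range(cfg.markers_per_type)]
    cns = list(_CNS_SEED_GENES[: cfg.n_cns_deg])
    j = 1
    while len(cns) < cfg.n_cns_deg:
        cns.append(f"CNSG_{j:03d}")
        j += 1
    used = sum(len(m) for m in modules.values()) + len(markers) + len(cns)
    if used > cfg.n_genes:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for {used} structured genes")
    filler = [f"G{j:05d}" for j in range(cfg.n_genes - used)]
    genes = [g for m in modules.values() for g in m] + cns + markers + filler
    return modules, markers, cns, filler, genes


def build_signature(cfg: SimulationConfig) -> pd.DataFrame:
    """Marker-gene x 22-cell-type reference profiles (linear scale).

    Each cell type gets ``markers_per_type`` exclusive markers with high
    expression in its own column and a low basal level elsewhere.
    """
    rng = _rng(cfg, 2)
    n_types = len(CELL_TYPES)
    markers = [f"MRK{t:02d}_{j}" for t in range(n_types)
               for j in range(cfg.markers_per_type)]
    sig = np.full((len(markers), n_types), 2.0)
    for t in range(n_types):
        for j in range(cfg.markers_per_type):
            sig[t * cfg.markers_per_type + j, t] = rng.uniform(300.0, 700.0)
    return pd.DataFrame(sig, index=markers, columns=CELL_TYPES)


def _dirichlet_alpha(cfg: SimulationConfig, label: str) -> np.ndarray:
    base = np.array([_BASE_FRACTIONS[c] for c in CELL_TYPES])
    base = base / base.sum()
    mult = np.ones_like(base)
    if label == "S1":
        # myeloid shift: more neutrophils and plasma cells, fewer lymphoid
        for i, c in enumerate(CELL_TYPES):
            if c == "Neutrophils":
                mult[i] = 1.35
            elif c == "Plasma cells":
                mult[i] = 3.0
            elif c.startswith(LYMPHOID_PREFIXES):
                mult[i] = 0.55
    elif label in ("S2", "SLE"):
        for i, c in enumerate(CELL_TYPES):
            if c == "Neutrophils":
                mult[i] = 1.05
            elif c.startswith(LYMPHOID_PREFIXES):
                mult[i] = 0.9
    mean = base * mult
    mean = mean / mean.sum()
    conc = cfg.dirichlet_conc_hc if label == "HC" else cfg.dirichlet_conc_patient
    return mean * conc


def mix_expression(signature: pd.DataFrame, fractions: pd.DataFrame,
                   gene_base: pd.Series) -> pd.DataFrame:
    """Noise-free mixture expression in log2(x + 1).

    Marker genes follow ``signature @ fractions``; all other genes are flat
    across cell types at their basal level (so mixing adds no variance and
    planted module effects stay analytic).
    """
    frac = fractions[signature.columns].to_numpy().T    # types x samples
    mixed = signature.to_numpy() @ frac                 # markers x samples
    out = pd.DataFrame(
        np.tile(gene_base.to_numpy()[:, None], (1, fractions.shape[0])),
        index=gene_base.index, columns=fractions.index)
    out.loc[signature.index] = mixed
    return np.log2(out + 1.0)


def simulate_expression(meta: pd.DataFrame, signature: pd.DataFrame,
                        cfg: SimulationConfig):
    """Expression matrix plus planted truth.

    Returns ``(expr, activity, fractions)`` where ``expr`` is genes x
    samples log2, ``activity`` holds per-sample planted module activities in
    HC-SD units (group effect + latent activity), and ``fractions`` the
    planted cell-type proportions.
    """
    rng = _rng(cfg, 3)
    modules, marker_names, cns_genes, filler, genes = _gene_universe(cfg)
    n_s = len(meta)

    # planted cell fractions
    frac = np.zeros((n_s, len(CELL_TYPES)))
    for i, (sid, row) in enumerate(meta.iterrows()):
        label = row["planted_subgroup"] if row["cohort"] == "CNS_LUPUS" else (
            "SLE" if row["cohort"] == "SLE_NONNP" else "HC")
        if cfg.null_fractions:
            label = "HC"
        frac[i] = rng.dirichlet(_dirichlet_alpha(cfg, label))
    fractions = pd.DataFrame(frac, index=meta.index, columns=CELL_TYPES)

    # basal levels: flat across cell types for non-marker genes
    base = pd.Series(np.exp(rng.uniform(np.log(3.0), np.log(300.0), len(genes))),
                     index=genes)
    expr = mix_expression(signature, fractions, base)

    # planted module activity: group delta + per-sample latent
    activity = pd.DataFrame(0.0, index=meta.index, columns=list(modules))
    group_col = np.where(meta["cohort"] == "CNS_LUPUS",
                         meta["planted_subgroup"],
                         np.where(meta["cohort"] == "SLE_NONNP", "SLE", "HC"))
    for m, members in modules.items():
        d1, d2, dsle = cfg.module_effects.get(m, (0.0, 0.0, 0.0))
        delta = np.select([group_col == "S1", group_col == "S2",
                           group_col == "SLE"], [d1, d2, dsle], default=0.0)
        u = rng.normal(0.0, cfg.activity_sd, n_s)
        activity[m] = delta + u
        # per-gene shift: activity (in per-gene SD units) x per-gene HC SD
        shift = (activity[m].to_numpy() * cfg.noise_sd)[None, :]
        expr.loc[members] = expr.loc[members].to_numpy() + shift

    # CNS-specific standalone DEGs, planted in both CNS subgroups; these
    # genes carry no activity latent, so their HC SD is exactly noise_sd
    is_cns = (meta["cohort"] == "CNS_LUPUS").to_numpy()
    expr.loc[cns_genes] = (expr.loc[cns_genes].to_numpy()
                           + cfg.cns_deg_delta * cfg.noise_sd
                           * is_cns[None, :])

    # covariates: per-gene age slope, male shift on 10% of genes, per-gene
    # per-batch shifts (random sign, so module means are not confounded by
    # a global batch direction), per-gene RIN slope
    age = (meta["age"] - meta["age"].mean()).to_numpy()
    age_coef = rng.normal(0.0, cfg.age_coef_sd, len(genes))
    expr += np.outer(age_coef, age)
    male = (meta["sex"] == "M").to_numpy().astype(float)
    sex_genes = rng.random(len(genes)) < 0.10
    expr += np.outer(sex_genes * cfg.sex_effect, male)
    batch_idx = meta["batch"].str[1:].astype(int).to_numpy()
    batch_eff = rng.normal(0.0, cfg.batch_sd, (len(genes), cfg.n_batches))
    expr += batch_eff[:, batch_idx]
    rin_coef = rng.normal(0.0, cfg.rin_slope_sd, len(genes))
    expr += np.outer(rin_coef, (meta["rin"] - 8.0).to_numpy())

    if cfg.noise_sd > 0:
        expr += rng.normal(0.0, cfg.noise_sd, expr.shape)
    return expr, activity, fractions


def simulate_serology(meta: pd.DataFrame, activity: pd.DataFrame,
                      cfg: SimulationConfig) -> pd.DataFrame:
    """Add serum marker columns correlated with planted module activities.

    Each linked marker is built as ``r * standardized activity +
    sqrt(1-r^2) * noise`` with the Pearson r chosen so the Spearman
    correlation with the planted activity is approximately ``sero_rho``
    (Gaussian-copula inversion r = 2 sin(pi * rho_s / 6)).  Decoy markers
    are independent noise.
    """
    rng = _rng(cfg, 4)
    meta = meta.copy()
    r = 2.0 * np.sin(np.pi * cfg.sero_rho / 6.0) if cfg.sero_rho else 0.0
    for marker, module in _MARKER_MODULES.items():
        noise = rng.normal(0.0, 1.0, len(meta))
        if module is not None and r != 0.0:
            if module not in activity.columns:
                raise KeyError(f"unknown module {module!r} for marker {marker!r}")
            a = activity[module].to_numpy()
            a = (a - a.mean()) / a.std()
            z = r * a + np.sqrt(1.0 - r * r) * noise
        else:
            z = noise
        # log-normal-ish positive levels
        meta[marker] = np.round(np.exp(3.0 + 0.8 * z), 2)
    return meta


def build_fixtures(cfg: SimulationConfig, outdir=None):
    """Fixture databases: gene sets, signature, regulons, drug table.

    Returns ``(genesets, signature, regulons, drug_targets)``; writes the
    standard-format files (GMT / TSV) when ``outdir`` is given.
    """
    rng = _rng(cfg, 5)
    modules, marker_names, cns_genes, filler, genes = _gene_universe(cfg)
    signature = build_signature(cfg)

    genesets = {}
    # the planted CNS-specific signature, chromosome-segregation style
    genesets["chromosome_segregation"] = sorted(set(cns_genes) | {"CDC20", "C3"})
    # annotation signature sets, one per module meta-cluster
    half = max(3, cfg.module_size // 2)
    genesets["sig_interferon"] = modules["interferon"][:half]
    genesets["sig_inflammation"] = (modules["inflammation_ii"][: half // 2]
                                    + modules["inflammation_iv"][: half // 2])
    genesets["sig_lymphocyte_signalling"] = (modules["b_cell"][: half // 2]
                                             + modules["t_cell"][: half // 2])
    genesets["sig_nk_platelets"] = modules["nk_cytotoxic"][:half]
    genesets["sig_plasma_ubiquitination"] = modules["plasma_ubiq"][:half]
    genesets["sig_cell_cycle"] = modules["cell_cycle"][:half]
    genesets["sig_mitochondrial"] = modules["mitochondrial"][:half]
    # decoy GO-like terms drawn from the whole universe
    pool = np.array(genes)
    for j in range(45):
        size = int(rng.integers(8, 120))
        genesets[f"GO_decoy_{j:02d}"] = sorted(
            rng.choice(pool, size=size, replace=False).tolist())

    # regulons: IRF9 concentrated in the interferon module, decoys random
    regulons = {}
    ifn = modules["interferon"]
    n_irf9 = 20
    n_from_ifn = max(1, int(np.ceil(0.9 * n_irf9)))
    irf9 = list(rng.choice(np.array(ifn), size=min(n_from_ifn, len(ifn)),
                           replace=False))
    others = [g for g in genes if g not in set(irf9)]
    irf9 += list(rng.choice(np.array(others), size=n_irf9 - len(irf9),
                            replace=False))
    regulons["IRF9"] = sorted(irf9)
    for j in range(24):
        size = int(rng.integers(15, 30))
        regulons[f"TF_decoy_{j:02d}"] = sorted(
            rng.choice(pool, size=size, replace=False).tolist())

    drug_rows = []
    def add(drug, targets, action="inhibits"):
        for g in targets:
            drug_rows.append({"drug": drug, "gene": g, "action": action})
    add("anifrolumab", ["IFNAR1", "IFNAR2", "ISG15", "IFI44", "MX1", "OAS1"])
    add("C3_inhibitor", ["C3"])
    add("calcineurin_inhibitor", ["PPP3CA", "PPP3CB", "PPP3R1"])
    add("SYK_inhibitor", ["SYK"])
    add("bortezomib", ["PSMB1", "PSMB2", "PSMB5", "PSMB8", "PSMB9"])
    add("memantine", ["GRIN1", "GRIN2A", "GRIN2B"])
    drug_targets = pd.DataFrame(drug_rows)

    universe = set(genes)
    for name, members in {**genesets, **regulons}.items():
        if not members or not set(members) <= universe:
            raise AssertionError(f"fixture set {name} breaks referential integrity")
    # small gene universes may truncate module seed lists; keep only targets
    # that exist, but never lose a drug entirely
    drug_targets = drug_targets[drug_targets["gene"].isin(universe)]
    lost = set(r["drug"] for r in drug_rows) - set(drug_targets["drug"])
    if lost:
        raise AssertionError(f"drug(s) without any target in the universe: {sorted(lost)}")

    if outdir is not None:
        from . import io as lio
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        lio.write_gmt(genesets, out / "genesets.gmt")
        lio.write_gmt(regulons, out / "regulons.gmt")
        signature.to_csv(out / "signature.tsv", sep="\t")
        drug_targets.to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    return genesets, signature, regulons, drug_targets


def simulate_cohort(cfg: SimulationConfig | None = None) -> SyntheticCohort:
    """Run every generator stage and return the assembled cohort."""
    cfg = cfg or SimulationConfig()
    meta = simulate_metadata(cfg)
    genesets, signature, regulons, drug_targets = build_fixtures(cfg)
    expr, activity, fractions = simulate_expression(meta, signature, cfg)
    meta = simulate_serology(meta, activity, cfg)
    modules, *_ = _gene_universe(cfg)
    return SyntheticCohort(meta=meta, expr=expr, signature=signature,
                           genesets=genesets, regulons=regulons,
                           drug_targets=drug_targets, modules_truth=modules,
                           activity_truth=activity, fractions_truth=fractions,
                           config=cfg)
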