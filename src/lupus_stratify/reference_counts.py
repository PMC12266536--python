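"""Published 2x2 counts from the emulated study's clinical tables.

Each entry reconstructs a categorical comparison from the printed counts and
per-variable Ns: positives and group sizes for both comparator groups, the
reported (3-decimal) p-value, and the test convention that reproduces it —
``always_yates`` for the clinical-characteristics tables,
``expected_lt5_fisher`` for the anticipated-benefit comparisons.

These counts are inputs (study data), used to recompute the reported
p-values from scratch; the reported value is never asserted without
recomputation.
"""

from .stats import ContingencyTable2x2, select_categorical_test

# (name, positives_1, n_1, positives_2, n_2, reported_p, policy)
# Group 1 / group 2 are: active CNS lupus / active non-NP SLE for the
# cohort-characteristics rows, and CNS lupus subgroup 1 / subgroup 2 for the
# subgroup-characteristics and anticipated-benefit rows.
PRINTED_TABLES = [
    # cohort characteristics: active CNS lupus (n=26) vs active non-NP SLE (n=38)
    ("cohort_female_sex", 25, 26, 35, 38, 0.895, "always_yates"),
    ("cohort_seizure", 2, 20, 0, 37, 0.229, "always_yates"),
    ("cohort_psychosis", 3, 21, 0, 38, 0.076, "always_yates"),
    ("cohort_organic_brain_syndrome", 2, 21, 0, 38, 0.236, "always_yates"),
    ("cohort_visual_disturbance", 6, 21, 0, 38, 0.002, "always_yates"),
    ("cohort_cranial_nerve_disorder", 1, 21, 0, 38, 0.762, "always_yates"),
    ("cohort_lupus_headache", 7, 21, 0, 38, 0.001, "always_yates"),
    ("cohort_cva", 3, 21, 0, 38, 0.076, "always_yates"),
    ("cohort_vascular", 3, 26, 11, 38, 0.178, "always_yates"),
    ("cohort_musculoskeletal", 5, 26, 17, 38, 0.065, "always_yates"),
    ("cohort_renal", 5, 26, 20, 38, 0.015, "always_yates"),
    ("cohort_dermal", 15, 26, 27, 38, 0.402, "always_yates"),
    ("cohort_serosal", 0, 26, 3, 38, 0.387, "always_yates"),
    ("cohort_immunologic", 16, 26, 31, 38, 0.135, "always_yates"),
    ("cohort_constitutional", 1, 26, 2, 38, 1.000, "always_yates"),
    ("cohort_haematologic", 4, 26, 9, 38, 0.621, "always_yates"),
    ("cohort_anti_dsdna_pos", 4, 21, 15, 30, 0.050, "always_yates"),
    ("cohort_anti_sm_pos", 0, 20, 2, 28, 0.625, "always_yates"),
    ("cohort_anti_b2gpi_igg_pos", 3, 21, 2, 29, 0.702, "always_yates"),
    ("cohort_anti_b2gpi_igm_pos", 2, 21, 1, 29, 0.772, "always_yates"),
    ("cohort_acl_igg_pos", 3, 21, 3, 30, 0.979, "always_yates"),
    ("cohort_acl_igm_pos", 3, 21, 1, 30, 0.367, "always_yates"),
    ("cohort_low_c3c", 7, 21, 15, 30, 0.371, "always_yates"),
    ("cohort_low_c4", 9, 21, 12, 30, 1.000, "always_yates"),
    ("cohort_antimalarials", 18, 26, 28, 38, 0.915, "always_yates"),
    ("cohort_azathioprine", 2, 21, 8, 38, 0.443, "always_yates"),
    ("cohort_methotrexate", 4, 21, 3, 38, 0.396, "always_yates"),
    ("cohort_mycophenolic_acid", 1, 21, 12, 38, 0.040, "always_yates"),
    # subgroup characteristics: CNS lupus subgroup 1 (n=11) vs subgroup 2 (n=15)
    ("subgroup_female_sex", 11, 11, 14, 15, 1.000, "always_yates"),
    ("subgroup_seizure", 2, 9, 0, 11, 0.369, "always_yates"),
    ("subgroup_psychosis", 0, 9, 3, 12, 0.322, "always_yates"),
    ("subgroup_organic_brain_syndrome", 0, 9, 2, 12, 0.592, "always_yates"),
    ("subgroup_visual_disturbance", 2, 9, 4, 12, 0.944, "always_yates"),
    ("subgroup_cranial_nerve_disorder", 0, 9, 1, 12, 1.000, "always_yates"),
    ("subgroup_lupus_headache", 2, 9, 5, 12, 0.640, "always_yates"),
    ("subgroup_cva", 2, 9, 1, 12, 0.787, "always_yates"),
    ("subgroup_vascular", 2, 11, 1, 15, 0.774, "always_yates"),
    ("subgroup_musculoskeletal", 3, 11, 2, 15, 0.698, "always_yates"),
    ("subgroup_renal", 2, 11, 3, 15, 1.000, "always_yates"),
    ("subgroup_dermal", 6, 11, 9, 15, 1.000, "always_yates"),
    ("subgroup_immunologic", 8, 11, 8, 15, 0.551, "always_yates"),
    ("subgroup_constitutional", 1, 11, 0, 15, 0.874, "always_yates"),
    ("subgroup_haematologic", 4, 11, 0, 15, 0.047, "always_yates"),
    ("subgroup_anti_dsdna_pos", 4, 9, 0, 12, 0.045, "always_yates"),
    ("subgroup_anti_b2gpi_igg_pos", 2, 9, 1, 12, 0.787, "always_yates"),
    ("subgroup_anti_b2gpi_igm_pos", 1, 9, 1, 12, 1.000, "always_yates"),
    ("subgroup_acl_igg_pos", 2, 9, 1, 12, 0.787, "always_yates"),
    ("subgroup_acl_igm_pos", 1, 9, 2, 12, 1.000, "always_yates"),
    ("subgroup_low_c3c", 4, 9, 3, 12, 0.640, "always_yates"),
    ("subgroup_low_c4", 6, 9, 3, 12, 0.143, "always_yates"),
    ("subgroup_antimalarials", 8, 11, 10, 15, 1.000, "always_yates"),
    ("subgroup_azathioprine", 1, 9, 1, 12, 1.000, "always_yates"),
    ("subgroup_methotrexate", 2, 9, 2, 12, 1.000, "always_yates"),
    ("subgroup_mycophenolic_acid", 1, 9, 0, 12, 0.882, "always_yates"),
    # anticipated drug benefit: subgroup 1 vs subgroup 2
    ("benefit_anifrolumab", 8, 11, 3, 15, 0.015, "expected_lt5_fisher"),
    ("benefit_c3_inhibitor", 8, 11, 3, 15, 0.015, "expected_lt5_fisher"),
    ("benefit_calcineurin_inhibitor", 10, 11, 3, 15, 0.001, "expected_lt5_fisher"),
    ("benefit_syk_inhibitor", 8, 11, 4, 15, 0.054, "expected_lt5_fisher"),
]


def recompute(entry):
    """Recompute one printed comparison; returns (raw_p, rounded_p)."""
    name, a, n1, c, n2, reported, policy = entry
    res = select_categorical_test(
        ContingencyTable2x2(a, n1 - a, c, n2 - c), policy=policy)
    return res.p_value, res.p_round
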