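{
  "description": "Re-encoding of the published fetal-CNS-anomaly WGS cohort tables. Diagnosed-sample rows reproduce the printed variant tables; undiagnosed-sample attributes beyond the printed marginals (sex 81/81, subgroups 114/48, QC failure counts) are synthetic.",
  "n_samples": 162,
  "n_diagnosed": 62,
  "accounting_by_patient": {
    "aneuploidy": 18,
    "cnv_gt_100kb": 17,
    "small_cnv": 3,
    "snv": 24
  },
  "accounting_by_event": {
    "aneuploidy": 18,
    "cnv_gt_100kb": 21,
    "small_cnv": 3,
    "snv": 26
  },
  "accounting_note": "The abstract counts patients (18+17+3+24=62); the results text counts events (21 CNVs >100 kb, 26 SNVs). Which rows a 17-CNV patient accounting excludes is not stated; both tallies are kept.",
  "subgroups": {
    "CNS_only": 114,
    "CNS_plus": 48
  },
  "diagnosed_by_subgroup": {
    "CNS_only": 28,
    "CNS_plus": 34
  },
  "tier_order": [
    "chromosomal",
    "submicroscopic",
    "snv",
    "intragenic"
  ],
  "qc": {
    "cnv_calling_failed": 3,
    "small_cnv_qc_failed": 4,
    "lowpass_only_samples": 26,
    "deep_wgs_samples": 136
  },
  "burden_cohort": {
    "n_cases": 136,
    "n_controls": 200
  },
  "pcp_panel_note": "13 planar-cell-polarity genes screened; 2 NTD-case hits, 0 control hits"
}
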