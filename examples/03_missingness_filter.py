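"""Classify missingness (MAR vs MNAR) and apply the two-step filter.

Step 1 removes proteins observed in fewer than half of all samples; step 2
runs a per-protein G-test of observation counts against compartment and
flags proteins whose non-detections are compartment-dependent (MNAR, the
signature of limit-of-detection censoring) without removing them.
"""

from lcmproteo import SimConfig, generate_dataset, two_step_filter

cfg = SimConfig(n_proteins=2000, n_kidneys=9, lod=22.0, seed=3)
matrix, metadata, _ = generate_dataset(cfg)

filtered, report = two_step_filter(matrix, metadata, min_frac=0.5, alpha=0.05)
print(f"input proteins:            {report.n_input}")
print(f"removed (<50% observed):   {report.n_removed_low_observation}")
print(f"flagged MNAR (retained):   {report.n_flagged_mnar}")
print(f"analysis matrix:           {filtered.n_proteins} proteins")
print(f"pooled dataset-level G:    {report.pooled.g_stat:.2f} "
      f"(p={report.pooled.p_value:.3g}, {report.pooled.classification})")
# MNAR flags concentrate among low-abundance and compartment-skewed
# proteins; they stay in the matrix but downstream complete-case summaries
# can treat them with caution.
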