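"""Simulate a small sorted-cell cohort with a spiked somatic clone.

Two patients, three subpopulations each, ~400x depth over a 1 kb region;
one clone at 3% allelic fraction confined to CD8+ cells of each patient.
"""

from clonecall import SimulationConfig, simulate_patient_cohort

config = SimulationConfig(
    n_patients=2,
    subpopulations=("CD4+", "CD8+", "CD19+"),
    target_region_length=1000,
    depth_mean=400,
    error_rate=1e-4,
    clone_spec=[("CD8+", 0.03, 1)],
    seed=42,
)

reads, truth, ref = simulate_patient_cohort(config)

print(f"simulated {len(reads)} read records over {reads.sample_id.nunique()} samples")
print("\nground truth (true_af is the allelic fraction, clone size = 2 x AF):")
print(truth.to_string(index=False))
# Germline hets (true_af 0.5) appear in every subpopulation of a patient;
# somatic clones appear in exactly one, which is what the screen exploits.
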