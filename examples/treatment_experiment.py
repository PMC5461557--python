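"""Full pipeline: simulated unilateral-treatment experiment.

Simulates a treatment cohort (treated hemisphere loses half its puncta) and
a sham cohort of 6 animals each — two sections x three sites per hemisphere,
with lognormal inter-animal variability — then aggregates sites to animals,
normalizes each treated hemisphere to the same animal's control hemisphere,
and compares the cohorts with the normality-gated test.
"""

import tempfile

import punctakit as pk
from punctakit.pipeline import RunConfig, run_pipeline

config = RunConfig(
    seed=7,
    volume=pk.VolumeSpec(50.0, 50.0, 10.0),
    thomas=pk.ThomasParams(parent_intensity=0.002, mean_offspring=8.0, offspring_sigma_um=0.5),
    design=pk.ExperimentDesign(n_animals=6, treatment_effect_count=0.5),
    fof=pk.FOFParams(linking_length_um=2.0),
)

with tempfile.TemporaryDirectory() as tmp:
    report = run_pipeline(config, tmp)
    for metric, entry in report.summary["metrics"].items():
        comp = entry["comparison"]
        means = entry["normalized_treated_mean"]
        print(f"{metric}:")
        print(f"  normalized treated mean, treatment cohort: {means['treatment']:.3f}")
        print(f"  normalized treated mean, sham cohort:      {means['sham']:.3f}")
        print(f"  {comp['test_used']} p = {comp['p_value']:.4g}")

print(
    "\nA normalized mean of ~0.5 in the treatment cohort recovers the simulated\n"
    "halving of puncta density; the sham cohort stays at ~1. The p-value tests\n"
    "treatment vs sham on the per-animal normalized values."
)
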