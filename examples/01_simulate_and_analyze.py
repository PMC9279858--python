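"""Simulate a study collection and run the full analysis pipeline.

Six case-control studies are drawn at a true allele odds ratio of 1.5
(control MAF 0.30, 1000-2000 subjects per arm), then pooled under the
allele model with heterogeneity assessment, the bias battery, and
credibility grading.
"""

from credmeta import (
    AnalysisConfig,
    SimulationConfig,
    report_frame,
    run_pipeline,
    simulate_association,
)

cfg = SimulationConfig(
    n_studies=6,
    true_or=1.5,
    control_maf=0.30,
    cases_range=(1000, 2000),
    controls_range=(1000, 2000),
    seed=11,
)
dataset = simulate_association(cfg, variant_id="rs0000001", disease="example disease")
reports = run_pipeline(dataset, AnalysisConfig(grouping=("overall",)))

print(report_frame(reports).to_string(index=False))
rep = reports[0]
print()
print(
    f"The pooled OR estimates the simulated allele odds ratio ({cfg.true_or}); "
    f"model '{rep.meta.model}' was chosen by the P_Q < 0.1 rule, and the "
    f"credibility call combines the Venice letters with the FPRP."
)
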