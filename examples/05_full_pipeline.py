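"""Run the whole pipeline end-to-end from one seeded configuration.

Equivalent to `toxmir run --outdir out --seed 1` from a shell: simulate,
normalize, call DEMs, classify trends, enrich targets, score
histopathology AUC, and render the summary report.
"""

from toxmir.pipeline import PipelineConfig, make_report, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1))
print(make_report(bundle))
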