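#!/usr/bin/env python
"""Two-class parameter-recovery study (10 seeds x 2,000 respondents).

Checks that the 2-class latent-class logit with 20 random starts recovers
the generating class shares and the published switch odds ratios; writes
per-seed estimates to results/recovery_study.csv and medians to
results/recovery_medians.json.
"""
import json
from pathlib import Path

from trialpref.recovery import recovery_study

ROOT = Path(__file__).resolve().parents[1] / "results"
ROOT.mkdir(parents=True, exist_ok=True)

table, medians = recovery_study(seed=1)
table.to_csv(ROOT / "recovery_study.csv", index=False)
(ROOT / "recovery_medians.json").write_text(json.dumps(medians, indent=1))
print(table.round(3).to_string(index=False))
print("\nMedians over 10 seeds (generating values: 36.1%, 11.83, 13.89):")
for k, v in medians.items():
    print(f"  {k}: {v:.3f}")
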