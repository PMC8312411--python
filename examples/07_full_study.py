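"""Run the full synthetic-study pipeline end to end.

Simulates a five-group cohort with FI (deficit-derived), BMI and education,
then produces descriptives, the correlation table, the univariate model
comparison, bivariate fits, moderation, and sensitivity analyses.  All
outputs are TSV/JSON in the output directory and reproducible from the
seed alone.  Expect a few minutes of runtime at this size.
"""

import json
import twinkin as tk

cfg = tk.StudyConfig(n_pairs=500, seed=9, output_dir="study_out",
                     n_restarts=1, grid_points=9)
bundle = tk.run_study(cfg)
print(json.dumps(bundle["status"], indent=1))
print("outputs in", cfg.output_dir)
# table3_univariate.tsv lists AIC per model; with the default generating
# truth the ADE quantitative sex-limitation model should rank best, and
# sensitivity.json shows sqrt-FI shares within a few points of the raw fit.
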