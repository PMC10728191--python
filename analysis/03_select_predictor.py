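"""Exhaustive AICc model selection over the 11 microbial dissimilarity
predictors of pairwise feedback.

Expect the three pathogen groups (soil fungal pathogen, soil oomycete, root
fungal pathogen) to carry the top importances (>= 0.7 cutoff) and the final
predictor's slopes to be negative: more dissimilar pathogen communities,
more negative feedback.
"""

import json
from pathlib import Path

import pandas as pd

from psfdilution.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    cfg = PipelineConfig(seed=0, out_dir=str(OUT), stages=("predict",))
    report = run_pipeline(cfg)
    imp = pd.Series(report["predict"]["importance"]).sort_values(ascending=False)
    print("predictor importances (sum of Akaike weights):")
    print(imp.round(3).to_string())
    print("\nimportant (>= 0.7):", report["predict"]["important_predictors"])
    spec = json.loads((OUT / "predictor.json").read_text())
    print("\nfitted predictor:", {k: round(v, 3) for k, v in spec["coefficients"].items()},
          "intercept", round(spec["intercept"], 3))
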