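"""Generate the synthetic study: designs, dissimilarities, pots, plots, reads.

Writes all stage inputs under results/run/ and prints the design counts
(expected: 18 species, 81 pairwise feedback tests, 702 pots, 240 plots of
which 168 are mixtures).
"""

from pathlib import Path

from psfdilution.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    cfg = PipelineConfig(seed=0, out_dir=str(OUT), stages=("simulate",))
    run_pipeline(cfg)
    import pandas as pd

    design = pd.read_csv(OUT / "plots.tsv", sep="\t")
    pots = pd.read_csv(OUT / "pots.tsv", sep="\t")
    pairs = pd.read_csv(OUT / "pairing_design.tsv", sep="\t")
    print(f"plots: {len(design)} ({(design.richness >= 2).sum()} mixtures)")
    print(f"pots: {len(pots)}; pairwise feedback tests: {len(pairs)}")
    print(f"inputs written to {OUT}")
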