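"""Paired Wilcoxon comparisons across the two analysis grids.

Produces the four comparison tables — best classifier vs the other three
(per game), roadrunner vs maze (per classifier), best level subset vs the
other six, and feature-family contrasts at the best subset — each for
accuracy and F1 at alpha = .05, from the fold-wise grids written by the
previous steps.
"""

import sys
from pathlib import Path

from sensortoy import io as stio
from sensortoy.compare import compare_tables

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    grid_one = stio.read_grid_json(RESULTS / "grid_one.json")["grid_one"]
    grid_two = stio.read_grid_json(RESULTS / "grid_two.json")["grid_two"]
    tables = compare_tables(grid_one, grid_two)
    for name, df in tables.items():
        df.to_csv(RESULTS / f"comparison_{name}.csv", index=False)
        n_sig = int(df["significant"].sum())
        print(f"{name}: {len(df)} comparisons, {n_sig} significant at alpha=.05")
        for rec in df[df["significant"]].itertuples():
            print(f"   {rec.metric:9s} {rec.config_a} vs {rec.config_b}: p={rec.p_value:.4g}")
    print(f"wrote 4 comparison tables -> {RESULTS}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
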