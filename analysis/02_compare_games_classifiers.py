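"""First analysis: four classifiers on the full features of each game.

Evaluates KNN, logistic regression, decision tree and SVM with the
minority-driven stratified cross-validation on the roadrunner and maze
feature tables written by 01_simulate_cohort.py, reports fold-mean accuracy
and F1 per configuration, and stores the fold-wise grid for the statistical
comparison step.
"""

import sys
from pathlib import Path

from sensortoy import io as stio
from sensortoy.evaluate import build_fold_plan, run_analysis_one
from sensortoy.games import MAZE, ROADRUNNER

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    tables = {
        ROADRUNNER: stio.read_feature_csv(RESULTS / "features_roadrunner.csv"),
        MAZE: stio.read_feature_csv(RESULTS / "features_maze.csv"),
    }
    plan = build_fold_plan(dict(zip(tables[ROADRUNNER]["id"], tables[ROADRUNNER]["label"])),
                           SEED)
    print(f"fold plan: {plan.n_folds} folds, {len(plan.reuse_ids)} reused label-0 children")
    grid, _ = run_analysis_one(tables, SEED, plan=plan)

    print(f"{'game':12s} {'classifier':20s} {'accuracy':>9s} {'f1':>7s} {'recall':>7s}")
    best = max(grid, key=lambda k: grid[k].mean_accuracy)
    for (game, kind), r in sorted(grid.items()):
        mark = "  <- best" if (game, kind) == best else ""
        print(f"{game:12s} {kind:20s} {r.mean_accuracy:9.3f} {r.mean_f1:7.3f} "
              f"{r.mean_recall:7.3f}{mark}")
    stio.write_grid_json({"grid_one": grid}, RESULTS / "grid_one.json", extra={"seed": SEED})
    print(f"wrote fold-wise grid -> {RESULTS / 'grid_one.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
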