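"""Second analysis: difficulty-level subsets x feature families.

Takes the best classifier from the game/classifier grid and re-evaluates it
on roadrunner features restricted to each of the 7 level subsets and each
feature family (sensor only, game only, both; age and gender always
included).  Sessions are regenerated deterministically from the cohort seed,
so the grid is evaluated on exactly the recordings analysis one used.
"""

import sys
from pathlib import Path

from sensortoy import io as stio
from sensortoy.compare import best_classifier, best_level_subset
from sensortoy.evaluate import build_fold_plan, classifier_specs, run_analysis_two, selector_grid
from sensortoy.games import ROADRUNNER
from sensortoy.pipeline import cohort_feature_tables
from sensortoy.players import sample_cohort

SEED = 1
N = 95
PREVALENCE = 0.5
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    payload = stio.read_grid_json(RESULTS / "grid_one.json")
    grid_one = payload["grid_one"]
    best = best_classifier(grid_one)
    print(f"best classifier from analysis one: {best}")

    children = sample_cohort(N, PREVALENCE, SEED)
    tables = cohort_feature_tables(children, SEED, {ROADRUNNER: selector_grid()})
    plan = build_fold_plan({c.id: c.label for c in children}, SEED)
    grid_two, _ = run_analysis_two(tables[ROADRUNNER], classifier_specs()[best], SEED,
                                   plan=plan)

    print(f"{'levels':8s} {'family':8s} {'accuracy':>9s} {'f1':>7s}")
    for (levels, family), r in sorted(grid_two.items()):
        print(f"{levels:8s} {family:8s} {r.mean_accuracy:9.3f} {r.mean_f1:7.3f}")
    subset = best_level_subset(grid_two)
    cell = grid_two[(subset, "both")]
    print(f"best level subset (family=both): {{{','.join(subset)}}} "
          f"with accuracy {cell.mean_accuracy:.3f}, f1 {cell.mean_f1:.3f}")
    stio.write_grid_json({"grid_two": grid_two}, RESULTS / "grid_two.json",
                         extra={"seed": SEED, "classifier": best})
    print(f"wrote fold-wise grid -> {RESULTS / 'grid_two.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
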