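"""End-to-end study pipeline over a synthetic cohort.

Glue with no science of its own: simulate every child's two sessions once,
extract every feature table the two analyses need in the same pass (so both
grids see the identical recorded sessions), then run the classifier grids
and the comparison tables.  Seeds are spawned hierarchically from one cohort
seed, so the whole study is reproducible from (n, prevalence, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compare import best_classifier, best_level_subset, compare_tables
from .cube import CubeTopology, build_topology
from .evaluate import (
    FoldPlan,
    RunResult,
    build_fold_plan,
    classifier_specs,
    run_analysis_one,
    run_analysis_two,
    selector_grid,
)
from .features import FeatureSelector, aggregate_features, compute_signals, feature_table
from .games import (
    MAZE,
    ROADRUNNER,
    LevelSchedule,
    enumerate_roadrunner_permutations,
    maze_schedule,
    roadrunner_schedule,
)
from .players import ChildProfile, CohortConfig, SensorStream, sample_cohort
from .games import SessionLog

GAMES = (ROADRUNNER, MAZE)

#: full-table selectors of the game/classifier analysis
ANALYSIS_ONE_SELECTORS: dict[str, FeatureSelector] = {
    ROADRUNNER: FeatureSelector(frozenset({0, 1, 2}), "both"),
    MAZE: FeatureSelector(frozenset({0, 1}), "both"),
}


def levels_key(selector: FeatureSelector) -> str:
    return "".join(str(l) for l in sorted(selector.levels))


def session_seed(cohort_seed: int, child_index: int, game: str) -> int:
    """Deterministic per-session seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(cohort_seed), int(child_index), GAMES.index(game)])
    return int(ss.generate_state(1)[0] % (2**31))


def assign_permutation(child_index: int) -> int:
    """Round-robin roadrunner level order, as in the original deployment."""
    return child_index % len(enumerate_roadrunner_permutations())


def simulate_child(
    child: ChildProfile,
    child_index: int,
    cohort_seed: int,
    *,
    topology: Optional[CubeTopology] = None,
) -> dict[str, tuple[SensorStream, SessionLog]]:
    """Both sessions (roadrunner + maze) of one child."""
    from .players import simulate_session  # local import keeps module load light

    topo = topology or build_topology()
    perm_id = assign_permutation(child_index)
    perm = enumerate_roadrunner_permutations()[perm_id]
    out = {}
    out[ROADRUNNER] = simulate_session(
        child, ROADRUNNER, roadrunner_schedule(perm),
        session_seed(cohort_seed, child_index, ROADRUNNER),
        topology=topo, permutation_id=perm_id,
    )
    out[MAZE] = simulate_session(
        child, MAZE, maze_schedule(),
        session_seed(cohort_seed, child_index, MAZE),
        topology=topo,
    )
    return out


def cohort_feature_tables(
    children: Sequence[ChildProfile],
    cohort_seed: int,
    selectors: Mapping[str, Sequence[FeatureSelector]],
    *,
    topology: Optional[CubeTopology] = None,
) -> dict[str, dict[tuple[str, str], pd.DataFrame]]:
    """Simulate each child once and aggregate every requested feature table.

    ``selectors`` maps game -> selectors wanted for that game.  Returns
    ``tables[game][(levels, family)]`` with one row per child.  Streams are
    discarded as soon as their derived signals are aggregated, so memory
    stays flat in cohort size.
    """
    topo = topology or build_topology()
    rows: dict[str, dict[tuple[str, str], list[dict]]] = {
        g: {(levels_key(s), s.family): [] for s in sels} for g, sels in selectors.items()
    }
    for i, child in enumerate(children):
        sessions = simulate_child(child, i, cohort_seed, topology=topo)
        for game, sels in selectors.items():
            stream, log = sessions[game]
            signals = compute_signals(stream, log, topo)
            for s in sels:
                rows[game][(levels_key(s), s.family)].append(
                    aggregate_features(signals, log, s, child)
                )
    return {
        g: {key: feature_table(r) for key, r in per_game.items()}
        for g, per_game in rows.items()
    }


@dataclass
class StudyResult:
    """Everything the two analyses produce for one synthetic cohort."""

    children: list[ChildProfile]
    plan: FoldPlan
    grid_one: dict[tuple[str, str], RunResult]
    grid_two: dict[tuple[str, str], RunResult]
    best_classifier: str
    best_subset: str
    tables: dict[str, pd.DataFrame]
    feature_tables: dict[str, dict[tuple[str, str], pd.DataFrame]] = field(repr=False, default_factory=dict)


def run_study(
    n: int = 95,
    prevalence: float = 0.5,
    seed: int = 0,
    *,
    cohort_config: CohortConfig = CohortConfig(),
    topology: Optional[CubeTopology] = None,
    with_analysis_two: bool = True,
) -> StudyResult:
    """Simulate a cohort and run the full two-grid comparison study."""
    topo = topology or build_topology()
    ss = np.random.SeedSequence([int(seed), 101])
    cohort_seed, plan_seed, eval_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    children = sample_cohort(n, prevalence, cohort_seed, config=cohort_config)
    wanted: dict[str, list[FeatureSelector]] = {
        ROADRUNNER: selector_grid() if with_analysis_two else [ANALYSIS_ONE_SELECTORS[ROADRUNNER]],
        MAZE: [ANALYSIS_ONE_SELECTORS[MAZE]],
    }
    tables = cohort_feature_tables(children, cohort_seed, wanted, topology=topo)

    one_inputs = {
        ROADRUNNER: tables[ROADRUNNER][("012", "both")],
        MAZE: tables[MAZE][("01", "both")],
    }
    plan = build_fold_plan({c.id: c.label for c in children}, plan_seed)
    grid_one, _ = run_analysis_one(one_inputs, eval_seed, plan=plan)
    best = best_classifier(grid_one)

    grid_two: dict[tuple[str, str], RunResult] = {}
    subset = ""
    cmp_tables: dict[str, pd.DataFrame] = {}
    if with_analysis_two:
        grid_two, _ = run_analysis_two(tables[ROADRUNNER], classifier_specs()[best],
                                       eval_seed, plan=plan)
        subset = best_level_subset(grid_two)
        cmp_tables = compare_tables(grid_one, grid_two)

    return StudyResult(
        children=children,
        plan=plan,
        grid_one=grid_one,
        grid_two=grid_two,
        best_classifier=best,
        best_subset=subset,
        tables=cmp_tables,
        feature_tables=tables,
    )
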