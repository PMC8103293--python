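"""Simulate the synthetic study cohort and write its observable records.

Draws 95 virtual children (prevalence 0.5 of likely fine-motor problems),
has each of them play one roadrunner and one maze session, and writes what
the real deployment recorded: the cohort manifest, per-child game-event
logs, and the per-game feature tables used by every later step.  Raw
110 Hz sensor streams are written only for the first two children as format
examples — a full cohort of streams is ~0.5 GB of CSV and is regenerated
from the seed on demand.
"""

import sys
from pathlib import Path

import numpy as np

from sensortoy import io as stio
from sensortoy.cube import build_topology
from sensortoy.features import aggregate_features, compute_signals, feature_table
from sensortoy.games import MAZE, ROADRUNNER
from sensortoy.pipeline import ANALYSIS_ONE_SELECTORS, simulate_child
from sensortoy.players import sample_cohort

SEED = 1
N = 95
PREVALENCE = 0.5
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    children = sample_cohort(N, PREVALENCE, SEED)
    stio.write_manifest_csv(children, OUT / "manifest.csv")
    n_pos = sum(c.label for c in children)
    print(f"cohort: {N} children, {n_pos} label-1 / {N - n_pos} label-0 (seed {SEED})")

    topo = build_topology()
    rows = {ROADRUNNER: [], MAZE: []}
    for i, child in enumerate(children):
        sessions = simulate_child(child, i, SEED, topology=topo)
        for game, (stream, log) in sessions.items():
            stio.write_session_jsonl(log, OUT / f"{child.id}_{game}.jsonl")
            if i < 2:
                stio.write_sensor_csv(stream, OUT / f"{child.id}_{game}.csv")
            signals = compute_signals(stream, log, topo)
            rows[game].append(
                aggregate_features(signals, log, ANALYSIS_ONE_SELECTORS[game], child)
            )

    for game, game_rows in rows.items():
        table = feature_table(game_rows)
        stio.write_feature_csv(table, OUT.parent / f"features_{game}.csv")
        by_label = table.groupby("label")["game_mean"].mean()
        print(f"{game}: mean game feature by label: "
              f"0 -> {by_label[0]:.3f}, 1 -> {by_label[1]:.3f}")
    print(f"wrote manifest, {2 * N} event logs, 4 example streams, 2 feature tables -> {OUT.parent}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
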