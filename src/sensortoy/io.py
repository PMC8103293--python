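"""On-disk formats: sensor CSV, event JSONL, manifest/feature CSV, result JSON.

All formats are plain text.  Floats in CSVs are written with 9 significant
digits (below sensor noise, above float32 round-off); JSON keeps full
double precision.  Event logs are JSON Lines with a header record carrying
the session identity, then one record per event.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .evaluate import RunResult
from .games import (
    MAZE,
    ROADRUNNER,
    GameEvent,
    SessionLog,
    enumerate_roadrunner_permutations,
    maze_schedule,
    roadrunner_schedule,
)
from .players import ChildProfile, SensorStream

PathLike = Union[str, Path]
CSV_FLOAT_FORMAT = "%.9g"

SENSOR_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
MANIFEST_COLUMNS = ("id", "age", "gender", "percentile", "label")


# -- sensor streams ---------------------------------------------------------

def write_sensor_csv(stream: SensorStream, path: PathLike) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.acc, stream.gyro]), columns=SENSOR_COLUMNS
    )
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_sensor_csv(path: PathLike, rate: float = 110.0) -> SensorStream:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sensor stream file not found: {path}")
    df = pd.read_csv(path)
    missing = set(SENSOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed sensor CSV, missing columns {sorted(missing)}")
    return SensorStream(
        t=df["t"].to_numpy(float),
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        rate=rate,
    )


# -- session logs -----------------------------------------------------------

def write_session_jsonl(log: SessionLog, path: PathLike) -> None:
    header = {
        "child_id": log.child_id,
        "game": log.game,
        "permutation_id": log.permutation_id,
        "lods": [lod for lod, _ in log.schedule.segments],
        "seed": log.seed,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for e in log.events:
            fh.write(json.dumps({"t": e.t, "kind": e.kind, "cell": e.cell, "lod": e.lod}) + "\n")


def read_session_jsonl(path: PathLike) -> SessionLog:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"session log file not found: {path}")
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty session log")
    try:
        header = json.loads(lines[0])
        records = [json.loads(ln) for ln in lines[1:]]
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSONL ({exc})") from exc
    game = header["game"]
    if game == ROADRUNNER:
        if header.get("lods") is not None:
            schedule = roadrunner_schedule(header["lods"])
        else:
            schedule = roadrunner_schedule(
                enumerate_roadrunner_permutations()[header["permutation_id"]]
            )
    elif game == MAZE:
        schedule = maze_schedule()
    else:
        raise ValueError(f"{path}: unknown game {game!r}")
    events = [GameEvent(t=r["t"], kind=r["kind"], cell=r.get("cell"), lod=r.get("lod"))
              for r in records]
    return SessionLog(
        child_id=header["child_id"], game=game, schedule=schedule,
        seed=header.get("seed", 0), events=events,
        permutation_id=header.get("permutation_id"),
    )


# -- cohort manifest --------------------------------------------------------

def write_manifest_csv(children: Iterable[ChildProfile], path: PathLike) -> None:
    df = pd.DataFrame(
        [{"id": c.id, "age": c.age, "gender": c.gender,
          "percentile": c.percentile, "label": c.label} for c in children]
    )
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_manifest_csv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed manifest, missing columns {sorted(missing)}")
    return df


# -- feature tables ---------------------------------------------------------

def write_feature_csv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_feature_csv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table file not found: {path}")
    return pd.read_csv(path, dtype={"levels": str})


# -- run results ------------------------------------------------------------

def run_result_to_dict(result: RunResult) -> dict:
    return {
        "config": result.config,
        "folds": {
            "accuracy": result.accuracy.tolist(),
            "f1": result.f1.tolist(),
            "recall": result.recall.tolist(),
        },
        "means": {
            "accuracy": result.mean_accuracy,
            "f1": result.mean_f1,
            "recall": result.mean_recall,
        },
    }


def run_result_from_dict(d: Mapping) -> RunResult:
    return RunResult(
        config=dict(d["config"]),
        accuracy=np.asarray(d["folds"]["accuracy"], float),
        f1=np.asarray(d["folds"]["f1"], float),
        recall=np.asarray(d["folds"]["recall"], float),
    )


def write_grid_json(grids: Mapping[str, Mapping[tuple, RunResult]], path: PathLike,
                    extra: Optional[Mapping] = None) -> None:
    """Serialize one or more analysis grids keyed by joined config keys."""
    payload: dict = dict(extra or {})
    for name, grid in grids.items():
        payload[name] = {"|".join(map(str, key)): run_result_to_dict(r)
                         for key, r in grid.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_grid_json(path: PathLike) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"results file not found: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for name, value in payload.items():
        if isinstance(value, dict) and value and all(
            isinstance(v, dict) and "folds" in v for v in value.values()
        ):
            out[name] = {tuple(k.split("|")): run_result_from_dict(v)
                         for k, v in value.items()}
        else:
            out[name] = value
    return out
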