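"""Per-session feature extraction: filtering, derived signals, aggregation.

The pipeline mirrors standard movement-science practice: each raw axis is
low-pass filtered (zero-phase 4th-order Butterworth, 4 Hz cut-off), axes are
combined into total-magnitude signals, and smoothness proxies are their time
derivatives:

==========  =====================================================  ========
signal      meaning                                                units
==========  =====================================================  ========
a           total acceleration magnitude (gravity included)        m/s^2
omega       total angular velocity magnitude                       rad/s
jerk        derivative of a — translational smoothness             m/s^3
alpha       derivative of omega — rotational smoothness            rad/s^2
cos_sim     dot-to-up cosine (roadrunner only), in [-1, 1]         —
maze_ok     on-track indicator (maze only), in {0, 1}              —
==========  =====================================================  ========

The first 60 s (warm-up) are always discarded.  Features are the mean and
standard deviation of each applicable signal over the pooled samples of the
selected difficulty levels (both occurrences of a level pooled before
aggregating), giving 8 sensor features + 2 game features per game, plus age
and gender as general features.

The cube's up direction is estimated from the accelerometer alone — the
negated, normalised low-passed acceleration — which is drift-free and uses
only recorded channels.  Gravity is deliberately not removed from ``a``:
orientation changes then remain visible in the acceleration magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .cube import CubeTopology, build_topology
from .games import MAZE, ROADRUNNER, SessionLog
from .players import ChildProfile, SensorStream

FILTER_CUTOFF_HZ = 4.0
FILTER_ORDER = 4

SENSOR_FEATURES = ("a_mean", "a_sd", "w_mean", "w_sd",
                   "jerk_mean", "jerk_sd", "alpha_mean", "alpha_sd")
GAME_FEATURES = ("game_mean", "game_sd")
GENERAL_FEATURES = ("age", "gender")
GENDER_CODE = {"girl": 0, "boy": 1}

FAMILIES = ("sensor", "game", "both")


@dataclass(frozen=True)
class FeatureSelector:
    """Which difficulty levels and which feature family feed the classifier."""

    levels: frozenset[int]
    family: str = "both"

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("selector needs at least one level")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    def feature_columns(self) -> tuple[str, ...]:
        cols: tuple[str, ...] = ()
        if self.family in ("sensor", "both"):
            cols += SENSOR_FEATURES
        if self.family in ("game", "both"):
            cols += GAME_FEATURES
        return cols + GENERAL_FEATURES


def lowpass(signal: np.ndarray, rate: float, *, cutoff: float = FILTER_CUTOFF_HZ,
            order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0."""
    if rate <= 2 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz too low for a {cutoff} Hz cut-off")
    x = np.asarray(signal, dtype=float)
    b, a = butter(order, cutoff, btype="low", fs=rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[0] <= padlen:
        raise ValueError(f"signal too short for filtering: {x.shape[0]} <= padlen {padlen}")
    return filtfilt(b, a, x, axis=0)


def magnitude(xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a (n, 3) signal."""
    return np.linalg.norm(np.asarray(xyz, dtype=float), axis=-1)


def differentiate(signal: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference derivative (one-sided at the ends), same length."""
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(x, 1.0 / rate, axis=0)


def estimate_up(stream: SensorStream) -> np.ndarray:
    """World-up in the body frame from the accelerometer (unit rows).

    The simulator writes gravity as ``-g * up``, so up is the negated,
    normalised low-passed acceleration.
    """
    filt = lowpass(stream.acc, stream.rate)
    return -filt / np.linalg.norm(filt, axis=1, keepdims=True)


def alignment_signal(stream: SensorStream, log: SessionLog,
                     topology: Optional[CubeTopology] = None) -> np.ndarray:
    """Per-sample cosine between the dot's cell direction and estimated up."""
    if log.game != ROADRUNNER:
        raise ValueError("alignment is a roadrunner quantity")
    topo = topology or build_topology()
    cells = log.cell_at_times(stream.t)
    up = estimate_up(stream)
    return np.einsum("ij,ij->i", topo.centers[cells], up)


def maze_ok_signal(log: SessionLog, times: Optional[np.ndarray] = None,
                   rate: float = 110.0) -> np.ndarray:
    """On-track indicator on the sampling grid; its mean is time-on-path."""
    if log.game != MAZE:
        raise ValueError("maze correctness is a maze quantity")
    if times is None:
        times = np.arange(int(round(log.schedule.total_duration * rate))) / rate
    return log.on_path_at_times(times)


@dataclass(frozen=True)
class DerivedSignals:
    """All per-sample derived signals of one session, on the 110 Hz grid."""

    t: np.ndarray
    a: np.ndarray
    w: np.ndarray
    jerk: np.ndarray
    alpha: np.ndarray
    game_signal: np.ndarray   # cos_sim (roadrunner) or maze_ok (maze)
    game: str


def compute_signals(stream: SensorStream, log: SessionLog,
                    topology: Optional[CubeTopology] = None) -> DerivedSignals:
    """Filter, combine and differentiate one session's channels."""
    acc_f = lowpass(stream.acc, stream.rate)
    gyr_f = lowpass(stream.gyro, stream.rate)
    a = magnitude(acc_f)
    w = magnitude(gyr_f)
    if log.game == ROADRUNNER:
        game_sig = alignment_signal(stream, log, topology)
    else:
        game_sig = maze_ok_signal(log, stream.t)
    return DerivedSignals(
        t=stream.t,
        a=a,
        w=w,
        jerk=differentiate(a, stream.rate),
        alpha=differentiate(w, stream.rate),
        game_signal=game_sig,
        game=log.game,
    )


def _selection_mask(signals: DerivedSignals, log: SessionLog, levels: frozenset[int]) -> np.ndarray:
    mask = np.zeros(signals.t.shape, dtype=bool)
    for start, end, lod, is_warm in log.schedule.intervals():
        if is_warm or lod not in levels:
            continue
        mask |= (signals.t >= start) & (signals.t < end)
    return mask


def aggregate_features(signals: DerivedSignals, log: SessionLog,
                       selector: FeatureSelector, child: ChildProfile) -> dict:
    """Pool the selected segments and compute mean/SD of each signal."""
    mask = _selection_mask(signals, log, selector.levels)
    if not mask.any():
        raise ValueError(f"no samples left after selecting levels {sorted(selector.levels)}")
    row: dict = {"id": child.id}
    series = {"a": signals.a, "w": signals.w, "jerk": signals.jerk, "alpha": signals.alpha}
    if selector.family in ("sensor", "both"):
        for name, x in series.items():
            row[f"{name}_mean"] = float(np.mean(x[mask]))
            row[f"{name}_sd"] = float(np.std(x[mask]))
    if selector.family in ("game", "both"):
        row["game_mean"] = float(np.mean(signals.game_signal[mask]))
        row["game_sd"] = float(np.std(signals.game_signal[mask]))
    row["age"] = float(child.age)
    row["gender"] = GENDER_CODE[child.gender]
    row["label"] = int(child.label)
    row["levels"] = "".join(str(l) for l in sorted(selector.levels))
    row["game"] = signals.game
    return row


def extract_features(stream: SensorStream, log: SessionLog,
                     selector: FeatureSelector, child: ChildProfile,
                     topology: Optional[CubeTopology] = None) -> dict:
    """One child's feature vector for one session (warm-up dropped)."""
    return aggregate_features(compute_signals(stream, log, topology), log, selector, child)


def feature_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-child rows into the cohort feature table."""
    df = pd.DataFrame(list(rows))
    meta = [c for c in ("id", "label", "levels", "game") if c in df.columns]
    ordered = [c for c in df.columns if c not in meta]
    return df[["id"] + ordered + [c for c in meta if c != "id"]]


def design_matrix(table: pd.DataFrame, selector: FeatureSelector) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) for the classifiers; general features are always included."""
    cols = list(selector.feature_columns())
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy(dtype=int)
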