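"""Paired Wilcoxon signed-rank comparisons over fold-wise scores.

Fold-wise metrics from a shared fold plan are paired observations, so
configurations are compared with the two-sided Wilcoxon signed-rank test at
alpha = .05 (no multiple-testing correction — each comparison is read at its
own level).  Fold scores on two-sample test sets are coarse (accuracy is 0,
0.5 or 1), which makes zero and tied differences the norm rather than the
exception; the implementation therefore commits to an explicit policy:

* zero differences are discarded before ranking (classic treatment; the
  Pratt variant is selectable), and a comparison with no nonzero
  differences is maximally insignificant, p = 1;
* with at most 25 nonzero differences the exact null distribution of the
  signed-rank sum is computed by dynamic programming over the (possibly
  tied, hence half-integer) ranks — doubling the ranks makes them integers,
  so ties are handled exactly rather than approximately;
* with more the usual normal approximation is used, with tie and continuity
  corrections.

Four comparison tables are produced from the two analysis grids: best
classifier vs the others (per game), roadrunner vs maze (per classifier),
best level subset vs the other subsets (family = both), and feature-family
comparisons at the best subset — each for accuracy and F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import CLASSIFIER_KINDS, LEVEL_SUBSETS, RunResult

ALPHA = 0.05
EXACT_MAX_N = 25
METRICS = ("accuracy", "f1")


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    config_a: str
    config_b: str
    p_value: float
    significant: bool

    @staticmethod
    def from_p(metric: str, a: str, b: str, p: float) -> "ComparisonResult":
        return ComparisonResult(metric, a, b, float(p), bool(p < ALPHA))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by DP over doubled ranks (ties handled exactly).

    Under H0 each |difference| carries its rank with an independent fair
    sign.  ``dist[s]`` counts sign assignments whose doubled positive-rank
    sum is ``s``; the two-sided p doubles the smaller tail (point included
    in both tails), capped at 1.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def _approx_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mu
    if diff == 0:
        return 1.0
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.sf(abs(z))))


def wilcoxon_paired(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    *,
    zero_method: str = "wilcox",
    method: str = "auto",
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired fold scores.

    ``method``: 'auto' picks the exact null for <= 25 nonzero differences
    and the corrected normal approximation above; 'exact'/'approx' force a
    path.  ``zero_method='pratt'`` keeps zeros in the ranking (delegated to
    scipy's approximate implementation).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired score vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 5:
        raise ValueError("need at least 5 paired folds")
    d = a - b
    if not np.any(d != 0):
        return 1.0
    if zero_method == "pratt":
        return float(stats.wilcoxon(a, b, zero_method="pratt", method="approx").pvalue)
    if zero_method != "wilcox":
        raise ValueError(f"unknown zero_method: {zero_method}")
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "exact" or (method == "auto" and len(d) <= EXACT_MAX_N):
        return _exact_signed_rank_p(ranks, w_plus)
    if method not in ("auto", "approx"):
        raise ValueError(f"unknown method: {method}")
    return _approx_signed_rank_p(ranks, w_plus)


def compare_pair(res_a: RunResult, res_b: RunResult, metric: str,
                 label_a: str, label_b: str) -> ComparisonResult:
    p = wilcoxon_paired(res_a.scores(metric), res_b.scores(metric))
    return ComparisonResult.from_p(metric, label_a, label_b, p)


# ---------------------------------------------------------------------------
# the four comparison tables
# ---------------------------------------------------------------------------

def best_classifier(grid_one: Mapping[tuple[str, str], RunResult]) -> str:
    """Classifier with the highest mean accuracy averaged over the games."""
    games = sorted({g for g, _ in grid_one})
    return max(
        CLASSIFIER_KINDS,
        key=lambda kind: np.mean([grid_one[(g, kind)].mean_accuracy for g in games]),
    )


def best_level_subset(grid_two: Mapping[tuple[str, str], RunResult]) -> str:
    """Level subset (family=both) with the highest mean accuracy."""
    both = [(levels, r) for (levels, fam), r in grid_two.items() if fam == "both"]
    return max(both, key=lambda lr: lr[1].mean_accuracy)[0]


def _rows_to_frame(rows: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"metric": r.metric, "config_a": r.config_a, "config_b": r.config_b,
          "p_value": r.p_value, "significant": r.significant} for r in rows]
    )


def table_best_vs_other_classifiers(grid_one: Mapping[tuple[str, str], RunResult],
                                    best: str) -> pd.DataFrame:
    """Best classifier against the other three, per game and metric."""
    rows = []
    for game in sorted({g for g, _ in grid_one}):
        for other in CLASSIFIER_KINDS:
            if other == best:
                continue
            for metric in METRICS:
                rows.append(compare_pair(grid_one[(game, best)], grid_one[(game, other)],
                                         metric, f"{game}/{best}", f"{game}/{other}"))
    return _rows_to_frame(rows)


def table_game_comparison(grid_one: Mapping[tuple[str, str], RunResult]) -> pd.DataFrame:
    """Roadrunner against maze for every classifier and metric."""
    rows = []
    for kind in CLASSIFIER_KINDS:
        for metric in METRICS:
            rows.append(compare_pair(grid_one[("roadrunner", kind)], grid_one[("maze", kind)],
                                     metric, f"roadrunner/{kind}", f"maze/{kind}"))
    return _rows_to_frame(rows)


def table_best_subset_vs_others(grid_two: Mapping[tuple[str, str], RunResult],
                                best_subset: str) -> pd.DataFrame:
    """Best level subset (family=both) against the other six subsets."""
    rows = []
    for levels in ["".join(str(l) for l in sorted(s)) for s in LEVEL_SUBSETS]:
        if levels == best_subset:
            continue
        for metric in METRICS:
            rows.append(compare_pair(grid_two[(best_subset, "both")], grid_two[(levels, "both")],
                                     metric, f"levels {best_subset}", f"levels {levels}"))
    return _rows_to_frame(rows)


def table_family_comparison(grid_two: Mapping[tuple[str, str], RunResult],
                            best_subset: str) -> pd.DataFrame:
    """Both-vs-sensor, both-vs-game, sensor-vs-game at the best subset."""
    rows = []
    for fam_a, fam_b in (("both", "sensor"), ("both", "game"), ("sensor", "game")):
        for metric in METRICS:
            rows.append(compare_pair(grid_two[(best_subset, fam_a)], grid_two[(best_subset, fam_b)],
                                     metric, f"{fam_a} features", f"{fam_b} features"))
    return _rows_to_frame(rows)


def compare_tables(
    grid_one: Mapping[tuple[str, str], RunResult],
    grid_two: Mapping[tuple[str, str], RunResult],
) -> dict[str, pd.DataFrame]:
    """All four comparison tables from the paired analysis grids."""
    best = best_classifier(grid_one)
    subset = best_level_subset(grid_two)
    return {
        "best_vs_other_classifiers": table_best_vs_other_classifiers(grid_one, best),
        "game_comparison": table_game_comparison(grid_one),
        "best_subset_vs_others": table_best_subset_vs_others(grid_two, subset),
        "family_comparison": table_family_comparison(grid_two, subset),
    }
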