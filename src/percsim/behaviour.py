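"""Scoring of the category-exemplar 1-back task and similarity-slope analyses.

Same-category catch trials are the analytically interesting ones: pressing
the same-exemplar key there is a confusion error whose probability should
rise with the perceived similarity of the (previous, current) exemplar
pair. Error rates and correct-response RTs are binned by the similarity
level of the trial pair under an observer's level partition, and the linear
slope over levels quantifies similarity sensitivity. Re-binning the same
trials under every OTHER observer's partition (n - 1 iterations, averaged)
tests whether behaviour is specifically coupled to the observer's own
perceived structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design
from .rdm import EXCLUDED, LEVELS

LEVEL_INDEX = {"low": 1, "medium": 2, "high": 3}


class ScoringError(ValueError):
    """Behaviour log does not align with the trial sequence."""


@dataclass(frozen=True)
class SlopeStats:
    """Group-level slope inference."""

    slopes: pd.Series  # per observer
    mean_slope: float
    t: float
    p: float  # one-sided, H1: mean slope > 0
    df: int


@dataclass(frozen=True)
class OwnOtherStats:
    """Own-partition vs other-partition slope comparison."""

    own: pd.Series  # per observer
    other_mean: pd.Series  # per observer, mean over n-1 iterations
    t: float
    p: float  # one-sided, H1: own > other
    df: int
    n_iterations: int


def score_oneback(log: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Score a behaviour log against its trial sequence.

    Returns one row per trial with the trial pair (for same-category
    catches), correctness, confusion flag (same-exemplar press on a
    same-category catch), false alarms on no-response trials, and the RT.
    """
    trials = trials.sort_values(["run", "position"]).reset_index(drop=True)
    log = log.sort_values(["run", "position"]).reset_index(drop=True)
    if len(log) != len(trials) or not (
        (log["run"].to_numpy() == trials["run"].to_numpy()).all()
        and (log["position"].to_numpy() == trials["position"].to_numpy()).all()
    ):
        raise ScoringError("behaviour log does not match the trial sequence")

    rows = []
    prev: tuple[int, int] | None = None
    prev_run = None
    for t, l in zip(trials.itertuples(), log.itertuples()):
        if t.run != prev_run:
            prev, prev_run = None, t.run
        pair_i = pair_j = 0
        correct = confusion = miss = false_alarm = False
        if t.trial_type == design.SAME_CATEGORY_CATCH:
            if prev is None:
                raise ScoringError(
                    f"run {t.run} position {t.position}: catch without predecessor"
                )
            pair_i, pair_j = sorted((prev[1], t.exemplar))
            correct = l.response == "same_category_key"
            confusion = l.response == "same_exemplar_key"
            miss = l.response == "none"
        elif t.trial_type == design.SAME_EXEMPLAR_CATCH:
            correct = l.response == "same_exemplar_key"
            miss = l.response == "none"
        else:
            correct = l.response == "none"
            false_alarm = l.response != "none"
        rows.append(
            (
                t.run,
                t.position,
                t.category,
                t.exemplar,
                t.trial_type,
                pair_i,
                pair_j,
                l.response,
                l.rt,
                correct,
                confusion,
                miss,
                false_alarm,
            )
        )
        prev = (t.category, t.exemplar)
    return pd.DataFrame(
        rows,
        columns=[
            "run",
            "position",
            "category",
            "exemplar",
            "trial_type",
            "pair_i",
            "pair_j",
            "response",
            "rt",
            "correct",
            "confusion",
            "miss",
            "false_alarm",
        ],
    )


def _pair_levels(partition: pd.DataFrame) -> dict[tuple[int, int, int], str]:
    return {
        (r.category, r.exemplar_i, r.exemplar_j): r.level
        for r in partition.itertuples()
    }


def performance_table(
    scored: pd.DataFrame, partition: pd.DataFrame
) -> pd.DataFrame:
    """Error rate and mean correct RT per similarity level.

    Same-category catch trials are keyed by the level of their (previous,
    current) exemplar pair under ``partition``; pairs the gap rule excluded
    are dropped. The error rate is the fraction of same-category trials
    answered with the same-exemplar key (confusions), matching the
    confusion-focused reading of 1-back errors.
    """
    levels = _pair_levels(partition)
    sc = scored[scored["trial_type"] == design.SAME_CATEGORY_CATCH].copy()
    sc["level"] = [
        levels.get((r.category, r.pair_i, r.pair_j), EXCLUDED)
        for r in sc.itertuples()
    ]
    sc = sc[sc["level"] != EXCLUDED]
    rows = []
    for level in LEVELS:
        grp = sc[sc["level"] == level]
        n = len(grp)
        err = float(grp["confusion"].mean()) if n else np.nan
        rts = grp.loc[grp["correct"], "rt"]
        rows.append((level, n, err, float(rts.mean()) if len(rts) else np.nan))
    return pd.DataFrame(rows, columns=["level", "n_trials", "error_rate", "mean_rt"])


def similarity_slope(perf: pd.DataFrame, measure: str = "error_rate") -> float:
    """OLS slope of a performance measure against level index (low=1..high=3)."""
    col = {"error": "error_rate", "error_rate": "error_rate", "rt": "mean_rt"}[
        measure
    ]
    valid = perf.dropna(subset=[col])
    valid = valid[valid["n_trials"] > 0]
    if len(valid) < 3:
        raise ScoringError(
            f"need all 3 levels with trials to fit a slope, got {len(valid)}"
        )
    x = valid["level"].map(LEVEL_INDEX).to_numpy(dtype=float)
    y = valid[col].to_numpy(dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def group_slopes(
    scored_by_observer: dict[int, pd.DataFrame],
    partitions: dict[int, pd.DataFrame],
    measure: str = "error_rate",
) -> SlopeStats:
    """Per-observer own-partition slopes with a one-sided group t-test."""
    slopes = {}
    for o, scored in scored_by_observer.items():
        perf = performance_table(scored, partitions[o])
        try:
            slopes[o] = similarity_slope(perf, measure)
        except ScoringError:
            continue  # observer lacks a level; excluded from the group test
    ser = pd.Series(slopes).sort_index()
    t, p = stats.ttest_1samp(ser.to_numpy(), 0.0, alternative="greater")
    return SlopeStats(
        slopes=ser,
        mean_slope=float(ser.mean()),
        t=float(t),
        p=float(p),
        df=len(ser) - 1,
    )


def own_vs_other(
    scored_by_observer: dict[int, pd.DataFrame],
    partitions: dict[int, pd.DataFrame],
    measure: str = "error_rate",
) -> OwnOtherStats:
    """Own-rating vs other-rating similarity slopes, paired across observers.

    Each observer's trials are re-binned under every other observer's level
    partition; the resulting n - 1 slopes are averaged and compared with the
    own-partition slope by a paired t-test (one-sided, own > other).
    """
    import warnings

    ids = sorted(scored_by_observer)
    if len(ids) < 3:
        raise ScoringError("own-vs-other comparison needs at least 3 observers")
    own, other = {}, {}
    for o in ids:
        try:
            own_slope = similarity_slope(
                performance_table(scored_by_observer[o], partitions[o]), measure
            )
        except ScoringError:
            warnings.warn(
                f"observer {o}: missing level under own partition; excluded"
            )
            continue
        iters = []
        for o2 in ids:
            if o2 == o:
                continue
            try:
                iters.append(
                    similarity_slope(
                        performance_table(scored_by_observer[o], partitions[o2]),
                        measure,
                    )
                )
            except ScoringError:
                warnings.warn(
                    f"observer {o}: missing level under observer {o2}'s "
                    "partition; iteration dropped"
                )
        if not iters:
            continue
        own[o] = own_slope
        other[o] = float(np.mean(iters))
    own_s = pd.Series(own).sort_index()
    other_s = pd.Series(other).sort_index()
    diff = own_s.to_numpy() - other_s.to_numpy()
    if np.allclose(np.std(diff), 0.0) and np.allclose(diff.mean(), 0.0):
        t, p = 0.0, 0.5
    else:
        t, p = stats.ttest_rel(
            own_s.to_numpy(), other_s.to_numpy(), alternative="greater"
        )
        t, p = float(t), float(p)
    return OwnOtherStats(
        own=own_s,
        other_mean=other_s,
        t=t,
        p=p,
        df=len(own_s) - 1,
        n_iterations=len(ids) - 1,
    )
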