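"""Pairwise linear decoding of exemplars with leave-one-run-out folds.

For every within-category exemplar pair a linear maximum-margin classifier
(SVC, C = 1) is trained on run-wise mean patterns from all runs but one and
tested on the held-out run; accuracies are averaged over folds, then over
the pairs a level partition retains, and tested against chance (0.5) with
a one-tailed group t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from . import design
from .neural import PatternDataError
from .rdm import LEVELS
from .synthetic import NeuralPatternSet

CHANCE = 0.5


@dataclass(frozen=True)
class DecodingGroupStats:
    region: str
    level: str
    mean_accuracy: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    n_tests: int


def runwise_patterns(pset: NeuralPatternSet) -> pd.DataFrame:
    """Per (run, category, exemplar) mean pattern over no-response trials.

    Every exemplar must appear in every run; with fewer than 2 runs
    leave-one-run-out folds are impossible.
    """
    trials = pset.trials
    runs = sorted(trials["run"].unique())
    if len(runs) < 2:
        raise PatternDataError("leave-one-run-out needs at least 2 runs")
    mask = (trials["trial_type"] == design.NO_RESPONSE).to_numpy()
    idx = trials.loc[mask, ["run", "category", "exemplar"]]
    frame = pd.DataFrame(pset.data[mask], index=pd.MultiIndex.from_frame(idx))
    means = frame.groupby(level=[0, 1, 2]).mean()
    expected = pd.MultiIndex.from_product(
        [
            runs,
            sorted(trials["category"].unique()),
            sorted(trials["exemplar"].unique()),
        ],
        names=["run", "category", "exemplar"],
    )
    missing = expected.difference(means.index)
    if len(missing):
        raise PatternDataError(
            f"missing (run, exemplar) cells for decoding: {list(missing)[:5]}"
        )
    return means.reindex(expected)


def pairwise_accuracy(
    runwise: pd.DataFrame,
    category: int,
    exemplar_i: int,
    exemplar_j: int,
    c: float = 1.0,
) -> float:
    """Leave-one-run-out accuracy for one exemplar pair.

    Features are standardized with training-fold statistics only. If the two
    classes are identical in the training data the fold is undecidable and
    scored at chance (with a warning).
    """
    runs = runwise.index.get_level_values("run").unique()
    xi = runwise.loc[(slice(None), category, exemplar_i), :].to_numpy()
    xj = runwise.loc[(slice(None), category, exemplar_j), :].to_numpy()
    accs = []
    for k, _ in enumerate(runs):
        ti = np.delete(xi, k, axis=0)
        tj = np.delete(xj, k, axis=0)
        if np.allclose(ti, tj):
            warnings.warn("identical training classes; fold scored at chance")
            accs.append(CHANCE)
            continue
        train = np.r_[ti, tj]
        y_train = np.r_[
            np.zeros(len(ti), dtype=int), np.ones(len(tj), dtype=int)
        ]
        test = np.vstack([xi[k], xj[k]])
        y_test = np.array([0, 1])
        mu = train.mean(axis=0)
        sd = train.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=c)
        clf.fit((train - mu) / sd, y_train)
        accs.append(float(np.mean(clf.predict((test - mu) / sd) == y_test)))
    return float(np.mean(accs))


def observer_level_accuracies(
    pset: NeuralPatternSet, partition: pd.DataFrame, c: float = 1.0
) -> pd.DataFrame:
    """Mean pairwise accuracy per similarity level for one observer x region.

    ``partition`` is the observer's stratified behaviour RDM; excluded pairs
    are dropped. Levels with no retained pairs come back as NaN (with a
    warning downstream).
    """
    runwise = runwise_patterns(pset)
    rows = []
    for level in LEVELS:
        pairs = partition[partition["level"] == level]
        accs = [
            pairwise_accuracy(runwise, r.category, r.exemplar_i, r.exemplar_j, c)
            for r in pairs.itertuples()
        ]
        rows.append(
            (
                pset.observer,
                pset.region,
                level,
                len(accs),
                float(np.mean(accs)) if accs else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["observer", "region", "level", "n_pairs", "accuracy"]
    )


def level_decoding(
    accuracies: pd.DataFrame, n_tests: int
) -> list[DecodingGroupStats]:
    """One-tailed group t-tests of level accuracies against chance.

    ``accuracies`` stacks `observer_level_accuracies` frames over observers
    (and possibly regions); ``n_tests`` is the Bonferroni family size
    (regions x levels).
    """
    out = []
    for (region, level), grp in accuracies.groupby(["region", "level"], sort=False):
        vals = grp["accuracy"].dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"{region}/{level}: no retained pairs, level skipped")
            continue
        if np.allclose(np.std(vals), 0.0):
            t = 0.0 if np.allclose(vals.mean(), CHANCE) else np.sign(
                vals.mean() - CHANCE
            ) * np.inf
            p = 0.5 if t == 0 else (np.finfo(float).tiny if t > 0 else 1.0)
        else:
            t, p = stats.ttest_1samp(vals, CHANCE, alternative="greater")
            t, p = float(t), float(p)
        out.append(
            DecodingGroupStats(
                region=region,
                level=level,
                mean_accuracy=float(vals.mean()),
                t=t,
                df=len(vals) - 1,
                p_raw=p,
                p_bonferroni=min(1.0, p * n_tests),
                n_tests=n_tests,
            )
        )
    return out
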