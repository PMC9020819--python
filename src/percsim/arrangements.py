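"""Behaviour RDMs from circular-arena arrangements.

Observers express perceived visual similarity by dragging the four
exemplars of a category around a unit-radius arena: closer means more
similar. The six pairwise distances per category, pooled over the
observer's ten categories and converted to dissimilarity percentiles, form
the observer's behaviour-based RDM. Each category's six pairs are further
stratified into low / medium / high perceived-similarity levels (two pairs
each), with a minimum percentile gap enforced between successive levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rdm import (
    EXCLUDED,
    LEVELS,
    PAIR_KEY,
    RDMError,
    make_rdm_frame,
    restrict_to_level,
)

ARENA_RADIUS = 1.0
_ARENA_TOL = 1e-6

ARRANGEMENT_COLUMNS = ["observer", "category", "exemplar", "x", "y"]


class ArrangementError(ValueError):
    """Invalid arena arrangement input."""


@dataclass(frozen=True)
class IntersubjectStats:
    """Leave-one-out intersubject agreement over a set of behaviour RDMs."""

    per_observer_r: pd.Series
    mean_r: float
    min_r: float
    max_r: float
    t: float
    p: float  # one-sided, H1: mean Fisher-z > 0


def validate_arrangement(points: pd.DataFrame) -> None:
    if points["exemplar"].duplicated().any():
        raise ArrangementError("duplicate exemplar ids in arrangement")
    radii = np.hypot(points["x"], points["y"])
    if (radii > ARENA_RADIUS + _ARENA_TOL).any():
        raise ArrangementError("arrangement coordinates fall outside the arena")


def distances_from_arrangement(points: pd.DataFrame) -> pd.DataFrame:
    """Six raw pairwise Euclidean distances of one category's arrangement.

    ``points`` has columns (exemplar, x, y); the result has canonical rows
    (exemplar_i < exemplar_j, lexicographic) with a ``raw`` distance column.
    Works on any planar point set; the arena-bounds invariant is enforced
    where study arrangements are ingested (`build_behaviour_rdm`).
    """
    if points["exemplar"].duplicated().any():
        raise ArrangementError("duplicate exemplar ids in arrangement")
    pts = points.sort_values("exemplar")
    ids = pts["exemplar"].to_numpy()
    xy = pts[["x", "y"]].to_numpy(dtype=float)
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            rows.append(
                (int(ids[a]), int(ids[b]), float(np.linalg.norm(xy[a] - xy[b])))
            )
    return pd.DataFrame(rows, columns=["exemplar_i", "exemplar_j", "raw"])


def build_behaviour_rdm(arrangements: pd.DataFrame) -> pd.DataFrame:
    """Behaviour RDM of one observer from their per-category arrangements.

    ``arrangements`` holds one arrangement per category (columns
    observer, category, exemplar, x, y). Percentiles are pooled over all of
    the observer's within-category pairs (60 under the default design), so
    that the resulting RDM is comparable across categories and observers.
    """
    observers = arrangements["observer"].unique()
    if len(observers) != 1:
        raise ArrangementError(
            f"expected a single observer's arrangements, got {sorted(observers)}"
        )
    categories = set(arrangements["category"])
    missing = sorted(set(range(1, max(categories) + 1)) - categories)
    if missing:
        raise ArrangementError(f"missing arrangements for categories {missing}")
    n_exemplars = arrangements.groupby("category")["exemplar"].nunique()
    expected = arrangements["exemplar"].nunique()
    short = n_exemplars[n_exemplars != expected]
    if not short.empty:
        raise ArrangementError(
            f"categories with missing exemplars: {sorted(short.index)}"
        )
    entries = []
    for category, grp in arrangements.groupby("category"):
        validate_arrangement(grp)
        d = distances_from_arrangement(grp)
        d.insert(0, "category", category)
        entries.append(d)
    rdm = make_rdm_frame(pd.concat(entries, ignore_index=True))
    rdm.insert(0, "observer", observers[0])
    return rdm


def stratify_levels(rdm: pd.DataFrame, min_gap: float = 0.1) -> pd.DataFrame:
    """Assign each within-category pair to a perceived-similarity level.

    Per category the six percentiles are rank-ordered and split 2-2-2: the
    two smallest dissimilarities are the *high*-similarity pairs, the middle
    two *medium*, the two largest *low*. Any boundary between successive
    levels narrower than ``min_gap`` (in percentile units) marks BOTH
    straddling entries as excluded, keeping the levels non-overlapping.
    Ties in the sort are broken by canonical pair order.
    """
    out = rdm.copy()
    out["level"] = ""
    for category, grp in out.groupby("category"):
        if len(grp) != 6:
            raise RDMError(
                f"category {category}: need exactly 6 pairs to stratify, "
                f"got {len(grp)}"
            )
        order = grp.sort_values(
            ["percentile", "exemplar_i", "exemplar_j"], kind="stable"
        ).index
        labels = np.array(
            ["high", "high", "medium", "medium", "low", "low"], dtype=object
        )
        pct = out.loc[order, "percentile"].to_numpy()
        # boundaries after sorted positions 1 (high|medium) and 3 (medium|low)
        for b in (1, 3):
            if pct[b + 1] - pct[b] < min_gap:
                labels[b] = EXCLUDED
                labels[b + 1] = EXCLUDED
        out.loc[order, "level"] = labels
    return out


def level_counts(partition: pd.DataFrame) -> pd.Series:
    """Retained entries per level (diagnostic)."""
    return partition.loc[partition["level"] != EXCLUDED, "level"].value_counts()


def intersubject_correlation(
    rdms: dict[int, pd.DataFrame], subset: str = "whole"
) -> IntersubjectStats:
    """Leave-one-out intersubject agreement of behaviour RDMs.

    For every observer, Pearson r between their percentile entries and the
    element-wise mean of all other observers' entries. ``subset`` is either
    "whole" or a similarity level, in which case each observer's own level
    partition defines their entry support (the other observers' values are
    taken on those same pairs). The group test is a one-sample t-test of
    Fisher-z transformed correlations against 0 (one-sided, r > 0).
    """
    if len(rdms) < 3:
        raise RDMError("need at least 3 observers")
    ids = sorted(rdms)
    wide = pd.concat(
        [
            rdms[o].set_index(PAIR_KEY)["percentile"].rename(o)
            for o in ids
        ],
        axis=1,
    )
    if wide.isna().any().any():
        raise RDMError("observers' RDMs do not share a common support")
    rs = {}
    for o in ids:
        own_rdm = rdms[o]
        if subset == "whole":
            support = own_rdm[PAIR_KEY]
        else:
            if "level" not in own_rdm.columns:
                raise RDMError("level subset requested but RDMs are unstratified")
            support = restrict_to_level(own_rdm, own_rdm, subset)[PAIR_KEY]
        sel = wide.loc[pd.MultiIndex.from_frame(support)]
        if len(sel) < 3:
            raise RDMError(f"observer {o}: fewer than 3 entries in subset {subset}")
        others = [c for c in ids if c != o]
        rs[o] = float(stats.pearsonr(sel[o], sel[others].mean(axis=1))[0])
    per_obs = pd.Series(rs).sort_index()
    z = np.arctanh(np.clip(per_obs.to_numpy(), -1 + 1e-12, 1 - 1e-12))
    t, p_two = stats.ttest_1samp(z, 0.0)
    p = p_two / 2 if t > 0 else 1 - p_two / 2
    return IntersubjectStats(
        per_observer_r=per_obs,
        mean_r=float(per_obs.mean()),
        min_r=float(per_obs.min()),
        max_r=float(per_obs.max()),
        t=float(t),
        p=float(p),
    )
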