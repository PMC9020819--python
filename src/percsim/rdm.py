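"""Shared RDM conventions: long-form frames, percentile conversion, alignment.

All representational dissimilarity matrices (behavioural, neural, model) are
stored in a common tidy long form restricted to within-category exemplar
pairs: one row per (category, exemplar_i, exemplar_j) with the raw
dissimilarity and its rank-based dissimilarity percentile. With 10
categories of 4 exemplars this gives 6 x 10 = 60 entries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

PAIR_KEY = ["category", "exemplar_i", "exemplar_j"]

LEVELS = ("high", "medium", "low")
EXCLUDED = "excluded"


class RDMError(ValueError):
    """Malformed or incompatible RDM input."""


def to_percentiles(values: np.ndarray) -> np.ndarray:
    """Convert raw dissimilarities to dissimilarity percentiles in [0, 1].

    percentile = (average rank - 1) / (n - 1); ties get averaged ranks, so
    the conversion is monotone in the input and invariant to any strictly
    increasing transform. An all-equal input maps to 0.5 everywhere (with a
    warning) because ranks carry no information there.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise RDMError("need a 1-D vector of at least 2 dissimilarities")
    if np.ptp(values) == 0:
        warnings.warn(
            "all dissimilarities equal; percentiles are uninformative (0.5)",
            stacklevel=2,
        )
    ranks = stats.rankdata(values, method="average")
    return (ranks - 1.0) / (values.size - 1.0)


def make_rdm_frame(
    entries: pd.DataFrame, raw_column: str = "raw", pool: bool = True
) -> pd.DataFrame:
    """Sort entries canonically and attach percentiles pooled over all rows."""
    missing = [c for c in PAIR_KEY + [raw_column] if c not in entries.columns]
    if missing:
        raise RDMError(f"RDM entries missing columns {missing}")
    out = entries.sort_values(PAIR_KEY).reset_index(drop=True)
    if pool:
        out["percentile"] = to_percentiles(out[raw_column].to_numpy())
    return out


def align_rdms(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two RDM frames on the canonical pair key.

    Returns a frame with columns percentile_a / percentile_b (and level_a /
    level_b where present).
    """
    keep_a = [c for c in ["percentile", "level"] if c in a.columns]
    keep_b = [c for c in ["percentile", "level"] if c in b.columns]
    merged = pd.merge(
        a[PAIR_KEY + keep_a],
        b[PAIR_KEY + keep_b],
        on=PAIR_KEY,
        suffixes=("_a", "_b"),
    )
    if merged.empty:
        raise RDMError("RDMs share no entries")
    return merged


def restrict_to_level(
    rdm: pd.DataFrame, partition: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Restrict an RDM to the pairs a level partition assigns to ``level``.

    ``partition`` is any frame with the pair key and a ``level`` column
    (typically a stratified behaviour RDM). Excluded pairs never match.
    """
    if level not in LEVELS:
        raise RDMError(f"unknown level {level!r}; expected one of {LEVELS}")
    keys = partition.loc[partition["level"] == level, PAIR_KEY]
    return pd.merge(rdm, keys, on=PAIR_KEY)


def average_rdm(rdms: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of percentile entries across observers.

    The result is itself a valid RDM frame whose ``raw`` entries are the mean
    percentiles, re-converted to percentiles over the common support.
    """
    if not rdms:
        raise RDMError("no RDMs to average")
    merged = rdms[0][PAIR_KEY].copy()
    cols = []
    for k, rdm in enumerate(rdms):
        col = f"_p{k}"
        merged = pd.merge(
            merged,
            rdm[PAIR_KEY + ["percentile"]].rename(columns={"percentile": col}),
            on=PAIR_KEY,
        )
        cols.append(col)
    if merged.empty:
        raise RDMError("RDMs share no common support")
    out = merged[PAIR_KEY].copy()
    out["raw"] = merged[cols].mean(axis=1)
    return make_rdm_frame(out)
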