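"""Brain RDMs from multivoxel patterns.

Exemplar-specific patterns are the mean over no-response trials (catch
trials involve button presses and are excluded); pairwise pattern
dissimilarity is 1 - Pearson's r, percentile-converted over the 60
within-category pairs with the same pooling convention as behaviour RDMs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import design
from .rdm import RDMError, make_rdm_frame, restrict_to_level
from .synthetic import NeuralPatternSet


class PatternDataError(ValueError):
    """Missing or degenerate pattern data."""


def exemplar_mean_patterns(
    pset: NeuralPatternSet, run_subset: list[int] | None = None
) -> pd.DataFrame:
    """Per-exemplar mean voxel vector over no-response trials.

    Returns a frame indexed by (category, exemplar) whose columns are
    voxels. ``run_subset`` restricts to a subset of runs (e.g. odd runs for
    split-half stability).
    """
    trials = pset.trials
    mask = trials["trial_type"] == design.NO_RESPONSE
    if run_subset is not None:
        mask &= trials["run"].isin(run_subset)
    if not mask.any():
        raise PatternDataError("no no-response trials in the requested runs")
    idx = trials.loc[mask, ["category", "exemplar"]]
    frame = pd.DataFrame(pset.data[mask.to_numpy()], index=pd.MultiIndex.from_frame(idx))
    means = frame.groupby(level=[0, 1]).mean()

    expected = pd.MultiIndex.from_product(
        [sorted(trials["category"].unique()), sorted(trials["exemplar"].unique())],
        names=["category", "exemplar"],
    )
    missing = expected.difference(means.index)
    if len(missing):
        raise PatternDataError(
            f"exemplars with no qualifying no-response trials: {list(missing)}"
        )
    return means.reindex(expected)


def build_brain_rdm(
    means: pd.DataFrame, observer: int | None = None, region: str | None = None
) -> pd.DataFrame:
    """Within-category 1 - Pearson r RDM from exemplar mean patterns."""
    if means.shape[1] < 2:
        raise PatternDataError("need at least 2 voxels")
    rows = []
    for category in means.index.get_level_values(0).unique():
        block = means.loc[category]
        exemplars = sorted(block.index)
        for a in range(len(exemplars)):
            for b in range(a + 1, len(exemplars)):
                x = block.loc[exemplars[a]].to_numpy()
                y = block.loc[exemplars[b]].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    raise PatternDataError(
                        f"zero-variance pattern for category {category} pair "
                        f"({exemplars[a]}, {exemplars[b]}); dissimilarity undefined"
                    )
                r = float(np.corrcoef(x, y)[0, 1])
                rows.append((category, exemplars[a], exemplars[b], 1.0 - r))
    rdm = make_rdm_frame(
        pd.DataFrame(rows, columns=["category", "exemplar_i", "exemplar_j", "raw"])
    )
    if observer is not None:
        rdm.insert(0, "observer", observer)
    if region is not None:
        rdm.insert(1 if observer is not None else 0, "region", region)
    return rdm


def brain_rdm_from_patterns(
    pset: NeuralPatternSet, run_subset: list[int] | None = None
) -> pd.DataFrame:
    """Convenience: exemplar means -> brain RDM for one observer x region."""
    means = exemplar_mean_patterns(pset, run_subset)
    return build_brain_rdm(means, observer=pset.observer, region=pset.region)


def split_half_stability(
    pset: NeuralPatternSet,
    subset: str = "whole",
    partition: pd.DataFrame | None = None,
) -> float:
    """Pearson r between brain RDMs computed on odd vs even runs.

    ``subset`` may be a similarity level, in which case ``partition`` (a
    stratified behaviour RDM) supplies the retained pairs.
    """
    runs = sorted(pset.trials["run"].unique())
    if len(runs) < 2:
        raise PatternDataError("split-half stability needs at least 2 runs")
    odd = [r for r in runs if r % 2 == 1]
    even = [r for r in runs if r % 2 == 0]
    rdm_odd = brain_rdm_from_patterns(pset, odd)
    rdm_even = brain_rdm_from_patterns(pset, even)
    if subset != "whole":
        if partition is None:
            raise RDMError("level subset requires a level partition")
        rdm_odd = restrict_to_level(rdm_odd, partition, subset)
        rdm_even = restrict_to_level(rdm_even, partition, subset)
    merged = pd.merge(
        rdm_odd,
        rdm_even,
        on=["category", "exemplar_i", "exemplar_j"],
        suffixes=("_odd", "_even"),
    )
    if len(merged) < 3:
        raise RDMError("fewer than 3 entries for stability correlation")
    return float(
        stats.pearsonr(merged["percentile_odd"], merged["percentile_even"])[0]
    )


def group_stability(
    psets: list[NeuralPatternSet],
    subset: str = "whole",
    partitions: dict[int, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Split-half stability per observer with a group t-test (z > 0)."""
    rows = []
    for pset in psets:
        part = partitions.get(pset.observer) if partitions else None
        rows.append(
            (
                pset.observer,
                pset.region,
                subset,
                split_half_stability(pset, subset, part),
            )
        )
    out = pd.DataFrame(rows, columns=["observer", "region", "subset", "r"])
    return out
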