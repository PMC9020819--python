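"""Brain-behaviour representational similarity statistics.

Within-subject correlations (whole range and per similarity level), group
inference on Fisher-z values with Bonferroni correction, paired region
contrasts, model-RDM correlations, and the observer-specificity i-index
(within-subject minus mean between-subject correlation) with a
subject-label randomization null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rdm import PAIR_KEY, RDMError, restrict_to_level

SUBSETS = ("whole", "low", "medium", "high")

_Z_CLIP = 1.0 - 1e-12


def _fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


@dataclass(frozen=True)
class CorrelationResult:
    observer: int
    region: str
    subset: str
    r: float
    n_entries: int

    @property
    def z(self) -> float:
        return float(_fisher_z(self.r))


@dataclass(frozen=True)
class GroupStats:
    region: str
    subset: str
    mean_r: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    n_tests: int

    @property
    def significant(self) -> bool:
        return self.p_bonferroni < 0.05


@dataclass(frozen=True)
class IIndexResult:
    region: str
    subset: str
    within_r: pd.Series  # per observer
    between_r: pd.Series  # per observer (mean over others)
    i_per_observer: pd.Series
    mean_i: float
    p_perm: float | None = None
    sem_randomization: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def _subset_support(behaviour_rdm: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "whole":
        return behaviour_rdm[PAIR_KEY]
    if "level" not in behaviour_rdm.columns:
        raise RDMError("level subset requested but behaviour RDM is unstratified")
    return restrict_to_level(behaviour_rdm, behaviour_rdm, subset)[PAIR_KEY]


def brain_behaviour_correlation(
    brain: pd.DataFrame,
    behaviour: pd.DataFrame,
    subset: str = "whole",
    region: str | None = None,
    observer: int | None = None,
) -> CorrelationResult:
    """Pearson r between a brain RDM and a behaviour RDM.

    For level subsets the BEHAVIOUR owner's partition defines the retained
    pairs (excluded pairs are dropped from both sides).
    """
    if subset not in SUBSETS:
        raise RDMError(f"unknown subset {subset!r}")
    support = _subset_support(behaviour, subset)
    merged = pd.merge(
        pd.merge(brain, support, on=PAIR_KEY),
        behaviour[PAIR_KEY + ["percentile"]].rename(
            columns={"percentile": "percentile_behaviour"}
        ),
        on=PAIR_KEY,
    )
    if len(merged) < 3:
        raise RDMError(
            f"fewer than 3 aligned entries for subset {subset!r} "
            f"({len(merged)} found)"
        )
    r = float(
        stats.pearsonr(merged["percentile"], merged["percentile_behaviour"])[0]
    )
    return CorrelationResult(
        observer=observer
        if observer is not None
        else int(brain["observer"].iloc[0]) if "observer" in brain else -1,
        region=region
        if region is not None
        else str(brain["region"].iloc[0]) if "region" in brain else "",
        subset=subset,
        r=r,
        n_entries=len(merged),
    )


def model_rdm_correlation(
    model_rdm: pd.DataFrame,
    target_rdm: pd.DataFrame,
    subset: str = "whole",
    partition: pd.DataFrame | None = None,
) -> tuple[float, int]:
    """Generic RDM-to-RDM Pearson correlation on a common support.

    ``partition`` supplies the level assignment for level subsets (e.g. the
    average-observer partition, or an observer's behaviour partition).
    Returns (r, n_entries).
    """
    if subset == "whole":
        merged = pd.merge(
            model_rdm[PAIR_KEY + ["percentile"]],
            target_rdm[PAIR_KEY + ["percentile"]],
            on=PAIR_KEY,
            suffixes=("_model", "_target"),
        )
    else:
        part = partition if partition is not None else target_rdm
        support = _subset_support(part, subset)
        merged = pd.merge(
            pd.merge(model_rdm[PAIR_KEY + ["percentile"]], support, on=PAIR_KEY),
            target_rdm[PAIR_KEY + ["percentile"]],
            on=PAIR_KEY,
            suffixes=("_model", "_target"),
        )
    if len(merged) < 3:
        raise RDMError("fewer than 3 aligned entries")
    r = float(
        stats.pearsonr(merged["percentile_model"], merged["percentile_target"])[0]
    )
    return r, len(merged)


def group_inference(
    results: list[CorrelationResult],
    n_tests: int,
    alternative: str = "greater",
) -> list[GroupStats]:
    """One-sample t-tests of Fisher-z correlations against 0, per region.

    ``n_tests`` is the Bonferroni family size (regions, or regions x levels
    when a level family is tested). ``alternative='greater'`` implements the
    directional hypothesis r > 0.
    """
    frame = pd.DataFrame(
        [(c.region, c.subset, c.r) for c in results],
        columns=["region", "subset", "r"],
    )
    out = []
    for (region, subset), grp in frame.groupby(["region", "subset"], sort=False):
        z = _fisher_z(grp["r"].to_numpy())
        if np.allclose(np.std(z), 0.0):
            # degenerate zero-variance sample: report the machine floor
            sign = np.sign(z.mean())
            t = float(sign * np.inf) if z.mean() != 0 else 0.0
            p = (
                0.5
                if z.mean() == 0
                else (np.finfo(float).tiny if sign > 0 else 1.0)
            )
        else:
            t, p = stats.ttest_1samp(z, 0.0, alternative=alternative)
            t, p = float(t), float(p)
        out.append(
            GroupStats(
                region=region,
                subset=subset,
                mean_r=float(grp["r"].mean()),
                t=t,
                df=len(grp) - 1,
                p_raw=p,
                p_bonferroni=min(1.0, p * n_tests),
                n_tests=n_tests,
            )
        )
    return out


def compare_regions(
    results: list[CorrelationResult],
    region_a: str,
    region_b: str,
    subset: str,
    n_tests: int = 1,
) -> GroupStats:
    """Paired t-test on Fisher-z differences between two regions (two-sided)."""
    frame = pd.DataFrame(
        [(c.observer, c.region, c.subset, c.r) for c in results],
        columns=["observer", "region", "subset", "r"],
    )
    frame = frame[frame["subset"] == subset]
    a = frame[frame["region"] == region_a].set_index("observer")["r"]
    b = frame[frame["region"] == region_b].set_index("observer")["r"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise RDMError(
            f"observer sets differ between {region_a!r} and {region_b!r}"
        )
    b = b.loc[a.index]
    diff = _fisher_z(a.to_numpy()) - _fisher_z(b.to_numpy())
    if np.allclose(np.std(diff), 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(
            _fisher_z(a.to_numpy()), _fisher_z(b.to_numpy())
        )
        t, p = float(t), float(p)
    return GroupStats(
        region=f"{region_a} vs {region_b}",
        subset=subset,
        mean_r=float((a - b).mean()),
        t=t,
        df=len(a) - 1,
        p_raw=p,
        p_bonferroni=min(1.0, p * n_tests),
        n_tests=n_tests,
    )


def correlation_matrix(
    brains: dict[int, pd.DataFrame],
    behaviours: dict[int, pd.DataFrame],
    subset: str = "whole",
) -> pd.DataFrame:
    """All brain x behaviour observer cross-correlations for one region.

    Entry (o, o') is the correlation of observer o's brain RDM with observer
    o''s behaviour RDM, on the BEHAVIOUR owner's subset support. The
    diagonal holds within-subject correlations.
    """
    ids = sorted(brains)
    if sorted(behaviours) != ids:
        raise RDMError("brain and behaviour observer sets differ")
    mat = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for o_behav in ids:
        support = _subset_support(behaviours[o_behav], subset)
        behav = pd.merge(behaviours[o_behav], support, on=PAIR_KEY)
        behav_vals = behav.set_index(PAIR_KEY)["percentile"]
        for o_brain in ids:
            brain_vals = brains[o_brain].set_index(PAIR_KEY)["percentile"]
            common = behav_vals.index.intersection(brain_vals.index)
            if len(common) < 3:
                raise RDMError(
                    f"fewer than 3 aligned entries for pair ({o_brain}, {o_behav})"
                )
            mat.loc[o_brain, o_behav] = stats.pearsonr(
                brain_vals.loc[common], behav_vals.loc[common]
            )[0]
    return mat


def i_index_from_matrix(mat: pd.DataFrame, region: str, subset: str) -> IIndexResult:
    """Observer-specificity index from a brain x behaviour correlation matrix."""
    if len(mat) < 2:
        raise RDMError("i-index needs at least 2 observers")
    vals = mat.to_numpy(dtype=float)
    n = len(mat)
    within = np.diag(vals)
    between = (vals.sum(axis=1) - within) / (n - 1)
    i = within - between
    ids = list(mat.index)
    return IIndexResult(
        region=region,
        subset=subset,
        within_r=pd.Series(within, index=ids),
        between_r=pd.Series(between, index=ids),
        i_per_observer=pd.Series(i, index=ids),
        mean_i=float(i.mean()),
    )


def i_index(
    brains: dict[int, pd.DataFrame],
    behaviours: dict[int, pd.DataFrame],
    subset: str = "whole",
    region: str = "",
) -> IIndexResult:
    """Point estimates of the i-index for one region (no null distribution)."""
    mat = correlation_matrix(brains, behaviours, subset)
    return i_index_from_matrix(mat, region or _region_of(brains), subset)


def _region_of(brains: dict[int, pd.DataFrame]) -> str:
    first = next(iter(brains.values()))
    return str(first["region"].iloc[0]) if "region" in first.columns else ""


def _null_mean_i(vals: np.ndarray, perm: np.ndarray) -> float:
    """Group mean i after relabelling behaviour RDMs by ``perm``."""
    n = vals.shape[0]
    permuted = vals[:, perm]  # column o' now holds behaviour of perm[o']
    within = np.diag(permuted)
    between = (permuted.sum(axis=1) - within) / (n - 1)
    return float((within - between).mean())


def permutation_null_i_index(
    brains: dict[int, pd.DataFrame],
    behaviours: dict[int, pd.DataFrame],
    subset: str = "whole",
    region: str = "",
    n_perm: int = 10_000,
    seed: int = 0,
) -> IIndexResult:
    """i-index with a subject-label randomization null.

    Each permutation randomly relabels which observer each behaviour RDM
    belongs to (labels may map to themselves) and recomputes the group mean
    i. p uses the add-one convention, p = (1 + #{null >= observed}) /
    (1 + n_perm); the SEM is the null distribution's standard deviation.
    """
    if n_perm < 100:
        raise RDMError("n_perm must be >= 100")
    mat = correlation_matrix(brains, behaviours, subset)
    point = i_index_from_matrix(mat, region or _region_of(brains), subset)
    vals = mat.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = vals.shape[0]
    for k in range(n_perm):
        null[k] = _null_mean_i(vals, rng.permutation(n))
    p_perm = (1.0 + np.sum(null >= point.mean_i)) / (1.0 + n_perm)
    return IIndexResult(
        region=point.region,
        subset=subset,
        within_r=point.within_r,
        between_r=point.between_r,
        i_per_observer=point.i_per_observer,
        mean_i=point.mean_i,
        p_perm=float(p_perm),
        sem_randomization=float(null.std(ddof=1)),
        n_perm=n_perm,
        seed=seed,
    )
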