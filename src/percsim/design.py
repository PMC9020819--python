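"""Study design: configuration and 1-back trial-sequence generation.

The experimental design is a category-exemplar 1-back task: a stream of
object images (10 categories x 4 exemplars by default) in which most trials
require no response, and two kinds of catch trials probe discrimination --
an exact repeat of the previous image (same-exemplar catch) or a different
exemplar of the previous image's category (same-category catch).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

NO_RESPONSE = "no_response"
SAME_EXEMPLAR_CATCH = "same_exemplar_catch"
SAME_CATEGORY_CATCH = "same_category_catch"

TRIAL_TYPES = (NO_RESPONSE, SAME_EXEMPLAR_CATCH, SAME_CATEGORY_CATCH)

TRIAL_COLUMNS = ["run", "position", "category", "exemplar", "trial_type"]


class ConfigurationError(ValueError):
    """Invalid study configuration."""


class GenerationError(RuntimeError):
    """Constraint satisfaction failed while generating a trial sequence."""


@dataclass(frozen=True)
class StudyConfig:
    """Design parameters of one simulated study.

    Defaults mirror a 23-observer design with 10 categories of 4 exemplars,
    8 runs, and per run 3 no-response presentations plus 1 catch presentation
    of every exemplar (160 trials per run, 75% no-response).
    """

    n_observers: int = 23
    n_categories: int = 10
    n_exemplars_per_category: int = 4
    n_runs: int = 8
    reps_noresponse_per_run: int = 3
    reps_catch_per_run: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if field.name == "seed":
                continue
            if getattr(self, field.name) < 1:
                raise ConfigurationError(
                    f"{field.name} must be >= 1, got {getattr(self, field.name)}"
                )
        if self.n_categories < 2:
            raise ConfigurationError(
                "at least 2 categories are required so consecutive no-response "
                "trials can differ in category"
            )

    @property
    def n_exemplars_total(self) -> int:
        return self.n_categories * self.n_exemplars_per_category

    @property
    def trials_per_run(self) -> int:
        return self.n_exemplars_total * (
            self.reps_noresponse_per_run + self.reps_catch_per_run
        )

    @property
    def n_pairs_per_category(self) -> int:
        e = self.n_exemplars_per_category
        return e * (e - 1) // 2

    @property
    def noresponse_fraction(self) -> float:
        return self.reps_noresponse_per_run / (
            self.reps_noresponse_per_run + self.reps_catch_per_run
        )


def exemplar_pairs(n_exemplars: int = 4) -> list[tuple[int, int]]:
    """Canonical (i, j) pairs, 1-based, i < j, lexicographic order."""
    return [
        (i, j)
        for i in range(1, n_exemplars + 1)
        for j in range(i + 1, n_exemplars + 1)
    ]


def _sequence_noresponse(
    config: StudyConfig, rng: np.random.Generator, max_restarts: int
) -> list[tuple[int, int]]:
    """Order the no-response presentations with no two consecutive trials
    from the same category (a same-category neighbour would make the trial
    a de-facto catch trial)."""
    items = [
        (c, e)
        for c in range(1, config.n_categories + 1)
        for e in range(1, config.n_exemplars_per_category + 1)
        for _ in range(config.reps_noresponse_per_run)
    ]
    for _ in range(max_restarts):
        pool = list(items)
        rng.shuffle(pool)
        out: list[tuple[int, int]] = []
        ok = True
        while pool:
            # candidates whose category differs from the previous trial
            if out:
                cand = [k for k, it in enumerate(pool) if it[0] != out[-1][0]]
            else:
                cand = list(range(len(pool)))
            if not cand:
                ok = False
                break
            out.append(pool.pop(cand[rng.integers(len(cand))]))
        if ok:
            return out
    raise GenerationError(
        "could not order no-response trials without same-category neighbours"
    )


def _assign_catches(
    config: StudyConfig,
    order: list[tuple[int, int]],
    rng: np.random.Generator,
    catch_type_prob: float,
    max_restarts: int,
) -> list[tuple[int, int, str] | None]:
    """Attach each catch presentation to a host no-response trial.

    A same-exemplar catch of exemplar (c, e) must follow a presentation of
    (c, e); a same-category catch must follow a presentation of (c, e') with
    e' != e. Returns, per host index, the catch trial inserted after it.
    """
    exemplars = [
        (c, e)
        for c in range(1, config.n_categories + 1)
        for e in range(1, config.n_exemplars_per_category + 1)
    ]
    for _ in range(max_restarts):
        catches: list[tuple[int, int, str]] = []
        for c, e in exemplars:
            for _ in range(config.reps_catch_per_run):
                kind = (
                    SAME_EXEMPLAR_CATCH
                    if rng.random() < catch_type_prob
                    else SAME_CATEGORY_CATCH
                )
                catches.append((c, e, kind))
        rng.shuffle(catches)
        slots: list[tuple[int, int, str] | None] = [None] * len(order)
        failed = False
        for c, e, kind in catches:
            if kind == SAME_EXEMPLAR_CATCH:
                hosts = [
                    k
                    for k, (hc, he) in enumerate(order)
                    if hc == c and he == e and slots[k] is None
                ]
            else:
                hosts = [
                    k
                    for k, (hc, he) in enumerate(order)
                    if hc == c and he != e and slots[k] is None
                ]
            if not hosts:
                failed = True
                break
            slots[hosts[rng.integers(len(hosts))]] = (c, e, kind)
        if not failed:
            return slots
    raise GenerationError(
        "could not place all catch trials after a same-category predecessor"
    )


def generate_run(
    config: StudyConfig,
    run: int,
    rng: np.random.Generator,
    catch_type_prob: float = 0.5,
    max_restarts: int = 100,
) -> pd.DataFrame:
    """Generate one run's ordered trial list."""
    order = _sequence_noresponse(config, rng, max_restarts)
    slots = _assign_catches(config, order, rng, catch_type_prob, max_restarts)
    rows = []
    for (c, e), catch in zip(order, slots):
        rows.append((run, 0, c, e, NO_RESPONSE))
        if catch is not None:
            cc, ce, kind = catch
            rows.append((run, 0, cc, ce, kind))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["position"] = np.arange(1, len(df) + 1)
    return df


def generate_trial_sequence(
    config: StudyConfig,
    seed: int | None = None,
    catch_type_prob: float = 0.5,
    max_restarts: int = 100,
) -> pd.DataFrame:
    """Generate the full multi-run trial sequence for one observer.

    Returns a tidy frame with columns (run, position, category, exemplar,
    trial_type). Within each run every exemplar appears exactly
    ``reps_noresponse_per_run`` times as a no-response trial and
    ``reps_catch_per_run`` times as a catch trial; catch trials immediately
    follow a presentation from their own category (the same exemplar for
    same-exemplar catches, a different one for same-category catches) and
    never open a run.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    runs = [
        generate_run(config, run, rng, catch_type_prob, max_restarts)
        for run in range(1, config.n_runs + 1)
    ]
    return pd.concat(runs, ignore_index=True)


def validate_trial_sequence(trials: pd.DataFrame, config: StudyConfig) -> None:
    """Raise GenerationError if any design invariant is violated."""
    for run, grp in trials.groupby("run"):
        grp = grp.sort_values("position").reset_index(drop=True)
        if len(grp) != config.trials_per_run:
            raise GenerationError(
                f"run {run}: {len(grp)} trials, expected {config.trials_per_run}"
            )
        if grp.loc[0, "trial_type"] != NO_RESPONSE:
            raise GenerationError(f"run {run}: catch trial at position 1")
        for t in range(1, len(grp)):
            prev, cur = grp.loc[t - 1], grp.loc[t]
            tt = cur["trial_type"]
            if tt == NO_RESPONSE and cur["category"] == prev["category"]:
                raise GenerationError(
                    f"run {run} position {cur['position']}: no-response trial "
                    "repeats the preceding category"
                )
            if tt == SAME_EXEMPLAR_CATCH and (
                cur["category"] != prev["category"]
                or cur["exemplar"] != prev["exemplar"]
            ):
                raise GenerationError(
                    f"run {run} position {cur['position']}: same-exemplar catch "
                    "does not repeat the preceding exemplar"
                )
            if tt == SAME_CATEGORY_CATCH and (
                cur["category"] != prev["category"]
                or cur["exemplar"] == prev["exemplar"]
            ):
                raise GenerationError(
                    f"run {run} position {cur['position']}: same-category catch "
                    "must repeat the category with a different exemplar"
                )
        counts = grp.groupby(["category", "exemplar", "trial_type"]).size()
        for c in range(1, config.n_categories + 1):
            for e in range(1, config.n_exemplars_per_category + 1):
                n_nr = counts.get((c, e, NO_RESPONSE), 0)
                n_catch = counts.get((c, e, SAME_EXEMPLAR_CATCH), 0) + counts.get(
                    (c, e, SAME_CATEGORY_CATCH), 0
                )
                if n_nr != config.reps_noresponse_per_run:
                    raise GenerationError(
                        f"run {run}: exemplar ({c},{e}) has {n_nr} no-response "
                        f"presentations, expected {config.reps_noresponse_per_run}"
                    )
                if n_catch != config.reps_catch_per_run:
                    raise GenerationError(
                        f"run {run}: exemplar ({c},{e}) has {n_catch} catch "
                        f"presentations, expected {config.reps_catch_per_run}"
                    )
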