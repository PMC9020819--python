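"""End-to-end pipeline: simulate -> RDMs -> statistics -> summary.

Stages run in dependency order and write tidy CSVs plus a JSON summary
holding one group statistic per region x subset, the behavioural slope
analyses, the i-index permutation results, and (optionally) level-wise
decoding. Every random draw derives from the study seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import arrangements as arr
from . import behaviour as beh
from . import decoding as dec
from . import io as pio
from . import neural, rsa, synthetic

log = logging.getLogger("percsim")


def behaviour_rdms_from_arrangements(
    all_arrangements: pd.DataFrame, min_gap: float = 0.1
) -> dict[int, pd.DataFrame]:
    """Stratified behaviour RDM per observer from stacked arrangements."""
    out = {}
    for observer, grp in all_arrangements.groupby("observer"):
        rdm = arr.build_behaviour_rdm(grp)
        out[int(observer)] = arr.stratify_levels(rdm, min_gap)
    return out


def brain_rdms_from_patterns(
    patterns: dict[tuple[int, str], synthetic.NeuralPatternSet],
) -> dict[str, dict[int, pd.DataFrame]]:
    """Brain RDM per region per observer."""
    out: dict[str, dict[int, pd.DataFrame]] = {}
    for (observer, region), pset in patterns.items():
        out.setdefault(region, {})[observer] = neural.brain_rdm_from_patterns(pset)
    return out


def run_pipeline(
    config: pio.PipelineConfig | None = None, out_dir: Path | str | None = None
) -> dict:
    """Run the full synthetic study and analysis; return the summary dict."""
    config = config or pio.PipelineConfig()
    regions = list(config.regions) or synthetic.default_regions()
    ana = config.analysis

    log.info("simulating study (seed=%d)", config.study.seed)
    study = synthetic.simulate_study(
        config.study, regions, config.structure, config.perf
    )

    log.info("building behaviour RDMs (min_gap=%.3g)", ana.min_gap)
    behaviour_rdms = behaviour_rdms_from_arrangements(
        study.arrangements, ana.min_gap
    )
    isc = arr.intersubject_correlation(behaviour_rdms, "whole")

    log.info("building brain RDMs for %d regions", len(regions))
    brain_rdms = brain_rdms_from_patterns(study.patterns)

    subsets = ["whole", "low", "medium", "high"]
    group_stats = []
    for region in brain_rdms:
        for subset in subsets:
            results = [
                rsa.brain_behaviour_correlation(
                    brain_rdms[region][o], behaviour_rdms[o], subset,
                    region=region, observer=o,
                )
                for o in study.observers
            ]
            family = len(brain_rdms) if subset == "whole" else len(brain_rdms) * 3
            group_stats.extend(rsa.group_inference(results, n_tests=family))

    log.info("i-index permutation tests (n_perm=%d)", ana.n_perm)
    i_results = [
        rsa.permutation_null_i_index(
            brain_rdms[region], behaviour_rdms, "whole", region,
            n_perm=ana.n_perm, seed=config.study.seed + 1,
        )
        for region in brain_rdms
    ]

    log.info("scoring 1-back behaviour")
    scored = {
        o: beh.score_oneback(study.behaviour[o], study.trials[o])
        for o in study.observers
    }
    err_slopes = beh.group_slopes(scored, behaviour_rdms, "error_rate")
    rt_slopes = beh.group_slopes(scored, behaviour_rdms, "rt")
    own_other_err = beh.own_vs_other(scored, behaviour_rdms, "error_rate")

    decoding_stats = []
    if ana.run_decoding:
        log.info("level-wise decoding")
        accs = pd.concat(
            [
                dec.observer_level_accuracies(
                    study.patterns[(o, region)], behaviour_rdms[o], ana.svm_c
                )
                for region in brain_rdms
                for o in study.observers
            ],
            ignore_index=True,
        )
        decoding_stats = dec.level_decoding(accs, n_tests=len(brain_rdms) * 3)

    summary = {
        "config_seed": config.study.seed,
        "n_observers": config.study.n_observers,
        "intersubject": {
            "mean_r": isc.mean_r, "min_r": isc.min_r, "max_r": isc.max_r,
            "t": isc.t, "p": isc.p,
        },
        "group_stats": [
            {
                "region": g.region, "subset": g.subset, "mean_r": g.mean_r,
                "t": g.t, "df": g.df, "p_raw": g.p_raw,
                "p_bonferroni": g.p_bonferroni,
                "significant": bool(g.p_bonferroni <= ana.alpha),
            }
            for g in group_stats
        ],
        "i_index": [
            {
                "region": r.region, "mean_i": r.mean_i, "p_perm": r.p_perm,
                "sem_randomization": r.sem_randomization, "n_perm": r.n_perm,
                "significant": bool(r.p_perm <= ana.alpha),
            }
            for r in i_results
        ],
        "behaviour": {
            "error_slope_mean": err_slopes.mean_slope,
            "error_slope_p": err_slopes.p,
            "rt_slope_mean": rt_slopes.mean_slope,
            "rt_slope_p": rt_slopes.p,
            "own_minus_other_error_slope": float(
                (own_other_err.own - own_other_err.other_mean).mean()
            ),
            "own_vs_other_p": own_other_err.p,
            "n_other_iterations": own_other_err.n_iterations,
        },
        "decoding": [
            {
                "region": d.region, "level": d.level,
                "mean_accuracy": d.mean_accuracy, "p_bonferroni": d.p_bonferroni,
                "significant": bool(d.p_bonferroni <= ana.alpha),
            }
            for d in decoding_stats
        ],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_arrangements_csv(study.arrangements, out_dir / "arrangements.csv")
        pio.write_trials_csv(study.trials, out_dir / "trials.csv")
        pio.write_behaviour_csv(study.behaviour, out_dir / "behaviour.csv")
        pio.write_rdm_csv(
            [behaviour_rdms[o] for o in study.observers],
            out_dir / "behaviour_rdms.csv",
        )
        for region, rdms in brain_rdms.items():
            pio.write_rdm_csv(
                [rdms[o] for o in study.observers],
                out_dir / f"brain_rdms_{region}.csv",
            )
        pio.write_patterns(study.patterns, out_dir / "patterns")
        pio.dump_config(config, out_dir / "config.yaml")
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        pio.write_manifest(out_dir, "pipeline", config)
    return summary
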