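"""Score the category-exemplar 1-back task and fit similarity slopes.

Confusion errors (pressing "same exemplar" when the repeat was a different
exemplar of the same category) should become more frequent - and correct
responses slower - the more similar the two exemplars are perceived to be.
Re-binning each observer's trials by other observers' similarity ratings
tests whether performance tracks the observer's OWN perceived structure.
"""

import percsim as ps
from percsim import behaviour as beh
from percsim import pipeline

study = ps.simulate_study(ps.StudyConfig(n_observers=10, seed=42), with_patterns=False)
partitions = pipeline.behaviour_rdms_from_arrangements(study.arrangements)
scored = {
    o: beh.score_oneback(study.behaviour[o], study.trials[o])
    for o in study.observers
}

perf1 = beh.performance_table(scored[1], partitions[1])
print("observer 1, same-category catch trials by similarity level:")
print(perf1.to_string(index=False))

for measure, unit in [("error_rate", "errors/level step"), ("rt", "s/level step")]:
    slopes = beh.group_slopes(scored, partitions, measure)
    print(
        f"\n{measure}: group slope = {slopes.mean_slope:+.4f} {unit}, "
        f"t({slopes.df}) = {slopes.t:.2f}, p = {slopes.p:.2g}"
    )

oo = beh.own_vs_other(scored, partitions, "error_rate")
print(
    f"\nown vs other ratings ({oo.n_iterations} iterations per observer): "
    f"slope difference = {(oo.own - oo.other_mean).mean():+.4f}, "
    f"t({oo.df}) = {oo.t:.2f}, p = {oo.p:.2g}"
)
print(
    "-> errors rise with perceived similarity, and the rise is steeper under"
    "\n   each observer's own ratings than under other observers' ratings."
)
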