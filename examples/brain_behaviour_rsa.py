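"""Correlate region-of-interest pattern RDMs with perceived similarity.

Builds brain RDMs (1 - Pearson r over exemplar mean patterns, percentile
converted) for three simulated region archetypes and tests, per region and
similarity level, whether they predict each observer's own behaviour RDM.
"""

import percsim as ps
from percsim import pipeline, rsa

study = ps.simulate_study(ps.StudyConfig(n_observers=10, seed=42))
behaviour = pipeline.behaviour_rdms_from_arrangements(study.arrangements)
brains = pipeline.brain_rdms_from_patterns(study.patterns)

for subset, family in [("whole", 3), ("low", 9), ("high", 9)]:
    print(f"\n--- subset: {subset} (Bonferroni family = {family}) ---")
    for region in ("noise", "LOC-like", "PrC-like"):
        results = [
            rsa.brain_behaviour_correlation(
                brains[region][o], behaviour[o], subset, region=region, observer=o
            )
            for o in study.observers
        ]
        g = rsa.group_inference(results, n_tests=family)[0]
        flag = "*" if g.p_bonferroni < 0.05 else " "
        print(
            f"{region:>9}: mean r = {g.mean_r:+.3f}, t({g.df}) = {g.t:6.2f}, "
            f"p_bonf = {g.p_bonferroni:.2g} {flag}"
        )

print(
    "\n-> the observer-specific 'PrC-like' region predicts perceived"
    "\n   similarity at every level; the shared-only 'LOC-like' region only"
    "\n   where exemplars are coarsely different; the noise region never does."
)
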