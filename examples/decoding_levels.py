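"""Leave-one-run-out decoding of exemplar pairs per similarity level.

For each within-category pair retained at a similarity level, a linear SVC
is trained on run-wise mean patterns from 7 runs and tested on the held-out
run. Above-chance accuracy at the HIGH similarity level means a region
resolves even the subtlest perceived differences.
"""

import pandas as pd

import percsim as ps
from percsim import decoding as dec
from percsim import pipeline

study = ps.simulate_study(ps.StudyConfig(n_observers=8, seed=42))
partitions = pipeline.behaviour_rdms_from_arrangements(study.arrangements)

accs = pd.concat(
    [
        dec.observer_level_accuracies(study.patterns[(o, region)], partitions[o])
        for region in ("noise", "LOC-like", "PrC-like")
        for o in study.observers
    ],
    ignore_index=True,
)
for g in dec.level_decoding(accs, n_tests=9):
    flag = "*" if g.p_bonferroni < 0.05 else " "
    print(
        f"{g.region:>9} {g.level:>6}: accuracy = {g.mean_accuracy:.3f} "
        f"(chance 0.5), p_bonf = {g.p_bonferroni:.2g} {flag}"
    )

print(
    "\n-> PrC-like separates exemplars at every level, including pairs the"
    "\n   observer rates as highly similar; LOC-like only at coarser levels."
)
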