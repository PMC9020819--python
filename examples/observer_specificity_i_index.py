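"""The observer-specificity i-index with a subject-label randomization null.

i = within-subject brain-behaviour correlation minus the mean correlation
with every OTHER observer's behaviour RDM. Positive i means a region's
patterns predict the observer's own perceived structure better than anyone
else's. Significance comes from shuffling which observer each behaviour RDM
belongs to.
"""

import percsim as ps
from percsim import pipeline, rsa

study = ps.simulate_study(ps.StudyConfig(n_observers=10, seed=42))
behaviour = pipeline.behaviour_rdms_from_arrangements(study.arrangements)
brains = pipeline.brain_rdms_from_patterns(study.patterns)

for region in ("noise", "LOC-like", "PrC-like"):
    res = rsa.permutation_null_i_index(
        brains[region], behaviour, "whole", region, n_perm=2000, seed=7
    )
    print(
        f"{region:>9}: within r = {res.within_r.mean():+.3f}, "
        f"between r = {res.between_r.mean():+.3f}, "
        f"i = {res.mean_i:+.3f}, p_perm = {res.p_perm:.4g}, "
        f"SEM(rand) = {res.sem_randomization:.4f}"
    )

print(
    "\n-> only the region that encodes each observer's own structure"
    "\n   (PrC-like) shows i > 0: its patterns are observer-specific, not"
    "\n   just stimulus-specific. LOC-like correlates with behaviour (within"
    "\n   r > 0) yet predicts everyone equally well, so i stays at zero."
)
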