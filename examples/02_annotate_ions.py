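"""Exact-mass annotation and ceramide LCB/FA decomposition.

Simulates a few observed ions by jittering theoretical m/z values by ±2 ppm,
matches them back against the candidate space at 5 ppm, then decomposes a
ceramide C:D total into the long-chain base / fatty acyl combinations
consistent with the observed base registry.
"""

import numpy as np

from gangliomics.annotation import (ObservedIon, decompose_ceramide,
                                    enumerate_candidates, match_ion)
from gangliomics.core import SRM_CLASS_PANEL, DEFAULT_CERAMIDE_PANEL

candidates = enumerate_candidates(SRM_CLASS_PANEL, DEFAULT_CERAMIDE_PANEL)
rng = np.random.default_rng(0)

for idx in rng.choice(len(candidates), size=3, replace=False):
    cand = candidates[idx]
    obs = ObservedIon(mz=cand.mz * (1 + rng.uniform(-2e-6, 2e-6)),
                      charge=cand.charge)
    top = match_ion(obs, candidates, tol_ppm=5.0)[0]
    sp = top.candidate.parent
    print(f"observed m/z {obs.mz:9.4f} (z={obs.charge}) -> "
          f"{sp.gclass.name} {sp.ceramide.label}  "
          f"({top.mass_error_ppm:+.2f} ppm)")

# A ceramide total of 34 carbons / 1 double bond admits two structures given
# the d16:1/d18:1 bases: the fatty acyl is deduced by difference.  d18:1
# (sphingosine) combinations are flagged as the major structure.
result = decompose_ceramide("34:1", ["d16:1", "d18:1"])
print(f"\n34:1 decompositions: {[s.label for s in result.structures]}")
print(f"major structure (sphingosine-based): {result.major.label}")
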