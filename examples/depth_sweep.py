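"""Depth-visibility experiment: how source depth limits scalp detection.

Runs full synthetic sessions with the seizure generator at increasing
eccentricities (deep to superficial) and shows that the coherence between
the selected scalp component and the true seizure-onset-zone pair grows
as the generator approaches the scalp, while the dipole localisation
error shrinks. Two seeds per depth keep this example quick; the test
suite runs the five-seed version.
"""

import numpy as np
from scipy.stats import spearmanr

from ictalcoh.pipeline import depth_sweep

results = depth_sweep(seeds=(0, 1), n_surrogates=100)

print(f"{'ecc':>5} {'SNA(SOZ)':>9} {'max-pair SNA':>13} {'d_SOZ mm':>9}")
for ecc in (0.45, 0.55, 0.65, 0.75, 0.85):
    rows = [r for r in results if r.eccentricity == ecc]
    print(f"{ecc:5.2f} {np.median([r.sna_soz for r in rows]):9.3f} "
          f"{np.median([r.max_pair_sna for r in rows]):13.3f} "
          f"{np.median([r.d_soz_mm for r in rows]):9.1f}")

rho = spearmanr([r.max_pair_sna for r in results],
                [r.max_pair_distance_mm for r in results])
print(f"\nSpearman rho (max-pair SNA vs dipole distance): "
      f"{rho.statistic:.2f} (p = {rho.pvalue:.3f})")
# Deep generators stay near the chance coherence floor; superficial ones are
# captured by a scalp component, and high coherence goes with small
# localisation error (negative rho).
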