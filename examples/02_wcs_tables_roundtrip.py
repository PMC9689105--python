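"""Read and write naming data in the WCS table dialects.

Generates a synthetic elicitation table (per-speaker chip namings), estimates
the naming distribution q(w|c) back from it, and shows the estimate
converging to the generating system as speakers are added.
"""

import numpy as np

from colornaming import NamingSystem, make_adult_language, make_elicitation_table, make_grid_universe
from colornaming.universe import load_wcs_naming

universe = make_grid_universe(8, 8, spacing=10.0)
rng = np.random.default_rng(0)
base = make_adult_language(universe, "convex", n_terms=4, rng=rng)
# soften the partition so speakers genuinely disagree at category boundaries
adult = NamingSystem(0.8 * base.q + 0.2 / base.n_terms, base.terms)

print("speakers   max total-variation distance to the generating q(w|c)")
for n_speakers in (5, 50, 500):
    table = make_elicitation_table(adult, n_speakers, np.random.default_rng(1), universe)
    estimate = load_wcs_naming(table, universe, language_id=1)
    tv = 0.5 * np.abs(estimate.q - adult.q).sum(axis=1).max()
    print(f"{n_speakers:8d}   {tv:.4f}")

print("\nEach speaker names every chip with a term drawn from q(.|c); the")
print("frequency estimator recovers the adult distribution as 1/sqrt(n).")
print("Real WCS files (chip.txt, cnum-vhcm-lab-new.txt, term.txt) are read")
print("with load_wcs_palette / load_wcs_naming in exactly the same way.")
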