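"""Train a self-organising-map learner on a toy colour-naming system.

The learner sees word-chip pairs sampled from the adult joint distribution
P(W,C) and gradually organises a 7x7 grid of joint colour+term prototypes.
Accuracy is the fraction of chips whose read-out mode matches the adult mode
map.
"""

import numpy as np

from colornaming import (
    accuracy,
    make_adult_language,
    make_grid_universe,
    mode_map,
    toy_som_config,
    train,
)

universe = make_grid_universe(8, 8, spacing=10.0)
adult = make_adult_language(universe, "convex", n_terms=4, rng=np.random.default_rng(1))
adult_mode = mode_map(adult)

config = toy_som_config(n_iterations=20_000, k=7, seed=0)
state, checkpoints = train(adult, universe, config)

print("samples seen   accuracy vs adult mode map")
for n_seen, system in checkpoints:
    if n_seen in (50, 200, 1000, 5000, 10000, 20000):
        acc = np.mean(np.argmax(system.q, axis=1) == adult_mode)
        print(f"{n_seen:12d}   {acc:.3f}")
print(f"\nfinal accuracy: {accuracy(state, universe, adult_mode):.3f}")
print("Early on the wide neighbourhood radius keeps the map near-uniform")
print("(low accuracy); as sigma decays, cells specialise to category regions")
print("and the adult system is recovered.")
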