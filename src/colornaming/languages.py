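"""Comparison languages: degenerate, hue-permuted, and random convex systems.

The permuted variants probe whether acquisition dynamics depend on the
communicative efficiency of the input: rotating each lightness row's
chromatic chips along the hue axis preserves category sizes and (approximate)
convexity while pushing the system away from the IB frontier.  Random convex
languages are nearest-seed (Voronoi) partitions of CIELAB space -- convex, so
learnable by the map, but communicatively inefficient.
"""

from __future__ import annotations

import numpy as np

from .ib import Frontier, MeaningModel, NamingSystem, distance_to_frontier, score_system
from .universe import Universe

__all__ = [
    "degenerate_language",
    "random_convex_language",
    "permuted_variant",
    "apply_hue_shift",
    "shuffled_language",
]


def degenerate_language(universe: Universe) -> NamingSystem:
    """The one-term language: complexity 0, maximum information loss."""
    return NamingSystem(np.ones((universe.n_chips, 1)), ["w0"])


def random_convex_language(
    universe: Universe, n_terms: int, rng: np.random.Generator
) -> NamingSystem:
    """A Voronoi partition of the chips around ``n_terms`` random seed chips.

    Every chip is assigned deterministically to the term of its nearest seed
    in CIELAB (ties to the lowest seed index), so each category is convex in
    the nearest-seed sense and no category is empty.
    """
    n = universe.n_chips
    if not (1 <= n_terms <= n):
        raise ValueError(f"n_terms must be in [1, {n}]")
    for _ in range(100):
        seeds = np.sort(rng.choice(n, size=n_terms, replace=False))
        assign = np.argmin(universe.sqdist[:, seeds], axis=1)
        if len(np.unique(assign)) == n_terms:
            break
    else:  # pragma: no cover - seeds always claim themselves
        raise RuntimeError("could not generate a partition with no empty terms")
    q = np.zeros((n, n_terms))
    q[np.arange(n), assign] = 1.0
    return NamingSystem(q, [f"t{j}" for j in range(n_terms)])


def _hue_rows(universe: Universe) -> dict[str, list[int]]:
    """Chromatic chip indices per lightness row, ordered by hue column."""
    rows: dict[str, list[tuple[int, int]]] = {}
    for i, c in enumerate(universe.chips):
        if c.grid_col >= 1:
            rows.setdefault(c.grid_row, []).append((c.grid_col, i))
    return {r: [i for _, i in sorted(v)] for r, v in rows.items()}


def apply_hue_shift(naming: NamingSystem, universe: Universe, shift: int) -> NamingSystem:
    """Cyclically rotate naming rows of chromatic chips by ``shift`` hue columns.

    Achromatic chips (column 0) keep their original naming.  Rotation is
    performed independently within each lightness row, matching a horizontal
    shift of the mode map.
    """
    rows = _hue_rows(universe)
    if not rows:
        raise ValueError("universe has no chromatic chips (grid structure required)")
    q = naming.q.copy()
    for idx in rows.values():
        d = shift % len(idx)
        q[idx] = np.roll(naming.q[idx], d, axis=0)
    return NamingSystem(q, list(naming.terms))


def permuted_variant(
    naming: NamingSystem,
    universe: Universe,
    frontier: Frontier,
    meanings: MeaningModel,
) -> tuple[NamingSystem, int]:
    """The hue permutation of ``naming`` farthest from the IB frontier.

    Scores every cyclic shift d in 1..(n_hue_columns - 1) and returns the
    variant maximising the distance to the frontier, with its shift.
    """
    rows = _hue_rows(universe)
    if not rows:
        raise ValueError("universe has no chromatic chips (grid structure required)")
    n_cols = max(len(v) for v in rows.values())
    if n_cols < 2:
        raise ValueError("need at least 2 hue columns to permute")
    best = None
    for d in range(1, n_cols):
        variant = apply_hue_shift(naming, universe, d)
        dist = distance_to_frontier(score_system(meanings, variant), frontier)
        if best is None or dist > best[0]:
            best = (dist, variant, d)
    return best[1], best[2]


def shuffled_language(
    naming: NamingSystem, rng: np.random.Generator
) -> NamingSystem:
    """Non-convex control: the same naming rows randomly reassigned to chips.

    Destroys the spatial coherence of the categories while conserving term
    counts; provided as a fixture for the negative result that non-convex
    languages are not acquired by the map.
    """
    perm = rng.permutation(naming.n_chips)
    return NamingSystem(naming.q[perm], list(naming.terms))
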