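"""Synthetic fixtures: toy universes, adult languages, and elicitation tables.

Everything downstream of the WCS loaders can run on generated data with the
same statistical structure: a grid of stimuli in CIELAB, convex (optionally
noisy) adult naming distributions, and per-speaker elicitation records drawn
from q(w|c).  Fixtures are fully determined by their seed.

The default toy scale -- an 8×8 universe, 4-8 terms, a k=7 map trained for
20,000 samples -- is sized so the full pipeline runs in minutes on one CPU
while preserving the qualitative dynamics of the full palette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ib import (
    MeaningModel,
    NamingSystem,
    annealed_solution,
    capacity_prior,
    gaussian_meanings,
)
from .languages import degenerate_language, random_convex_language
from .universe import Universe, make_grid_universe

__all__ = [
    "make_toy_meanings",
    "make_adult_language",
    "make_elicitation_table",
    "FixtureBundle",
    "make_fixture_bundle",
]

TOY_GRID = (8, 8)
TOY_SPACING = 10.0
TOY_SIGMA_SQ = 64.0

LANGUAGE_STYLES = ("degenerate", "convex", "ib_optimal", "noisy_convex")


def make_toy_meanings(universe: Universe, sigma_sq: float = TOY_SIGMA_SQ) -> MeaningModel:
    """Gaussian perceptual meanings on a synthetic grid (uniform prior)."""
    return gaussian_meanings(universe, sigma_sq)


def make_adult_language(
    universe: Universe,
    style: str,
    n_terms: int | None = None,
    beta: float | None = None,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    meanings: MeaningModel | None = None,
) -> NamingSystem:
    """Generate an adult target language of a given style.

    degenerate : the single-term language.
    convex : random nearest-seed partition with ``n_terms`` categories.
    ib_optimal : communicatively optimal system at trade-off ``beta``
        (solved by annealing on ``meanings``, defaulting to toy Gaussians).
    noisy_convex : convex partition where each chip's term is flipped to a
        uniformly random other term with probability ``noise``, emulating
        speaker disagreement in elicitation.
    """
    if style not in LANGUAGE_STYLES:
        raise ValueError(f"unknown style {style!r}; expected one of {LANGUAGE_STYLES}")
    if rng is None:
        rng = np.random.default_rng(0)
    if style == "degenerate":
        return degenerate_language(universe)
    if style == "ib_optimal":
        if beta is None:
            raise ValueError("ib_optimal requires beta")
        if meanings is None:
            meanings = make_toy_meanings(universe)
        sol = annealed_solution(meanings, beta)
        # drop terms with negligible need probability for a compact lexicon
        p_w = meanings.prior @ sol.system.q
        keep = p_w > 1e-6
        q = sol.system.q[:, keep]
        q /= q.sum(axis=1, keepdims=True)
        return NamingSystem(q, [t for t, k in zip(sol.system.terms, keep) if k])
    if n_terms is None:
        raise ValueError(f"{style} requires n_terms")
    base = random_convex_language(universe, n_terms, rng)
    if style == "convex" or noise == 0.0:
        return base
    if not (0.0 <= noise < 1.0):
        raise ValueError("noise must be in [0, 1)")
    q = base.q.copy()
    assign = np.argmax(q, axis=1)
    flip = rng.random(universe.n_chips) < noise
    for i in np.flatnonzero(flip):
        others = [j for j in range(n_terms) if j != assign[i]]
        q[i] = 0.0
        q[i, rng.choice(others)] = 1.0
    return NamingSystem(q, list(base.terms))


def make_elicitation_table(
    naming: NamingSystem,
    n_speakers: int,
    rng: np.random.Generator,
    universe: Universe | None = None,
    language_id: int = 1,
) -> str:
    """Synthetic per-speaker term table in the WCS ``term.txt`` dialect.

    Each speaker names every chip with a term drawn from q(·|c); the
    estimator in :func:`~colornaming.universe.load_wcs_naming` recovers q as
    the speaker count grows.
    """
    if n_speakers < 1:
        raise ValueError("need at least one speaker")
    ids = universe.ids if universe is not None else np.arange(1, naming.n_chips + 1)
    cdf = np.cumsum(naming.q, axis=1)
    lines = []
    for s in range(1, n_speakers + 1):
        u = rng.random(naming.n_chips)
        picks = (u[:, None] > cdf).sum(axis=1)  # inverse-CDF per chip
        for i, cid in enumerate(ids):
            lines.append(f"{language_id}\t{s}\t{cid}\t{naming.terms[picks[i]]}")
    return "\n".join(lines) + "\n"


@dataclass
class FixtureBundle:
    """A self-contained synthetic data set for the full pipeline."""

    universe: Universe
    meanings: MeaningModel
    adult_systems: dict[str, NamingSystem]
    elicitation: str
    meta: dict = field(default_factory=dict)


def make_fixture_bundle(
    seed: int = 0,
    grid: tuple[int, int] = TOY_GRID,
    spacing: float = TOY_SPACING,
    sigma_sq: float = TOY_SIGMA_SQ,
    n_terms: int = 4,
    beta: float = 1.3,
    noise: float = 0.1,
    n_speakers: int = 20,
) -> FixtureBundle:
    """Build the standard toy bundle; bit-identical for a given seed."""
    rng = np.random.default_rng(seed)
    universe = make_grid_universe(*grid, spacing)
    # the bundle's meanings carry the capacity-achieving prior so that its
    # ib_optimal system is optimal under the same model that scores it
    meanings = capacity_prior(make_toy_meanings(universe, sigma_sq))
    systems = {
        "degenerate": make_adult_language(universe, "degenerate"),
        "convex": make_adult_language(universe, "convex", n_terms=n_terms, rng=rng),
        "ib_optimal": make_adult_language(
            universe, "ib_optimal", beta=beta, meanings=meanings
        ),
        "noisy_convex": make_adult_language(
            universe, "noisy_convex", n_terms=n_terms, noise=noise, rng=rng
        ),
    }
    elicitation = make_elicitation_table(systems["convex"], n_speakers, rng, universe)
    meta = {
        "seed": seed,
        "grid": list(grid),
        "spacing": spacing,
        "sigma_sq": sigma_sq,
        "n_terms": n_terms,
        "beta": beta,
        "noise": noise,
        "n_speakers": n_speakers,
    }
    return FixtureBundle(universe, meanings, systems, elicitation, meta)
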