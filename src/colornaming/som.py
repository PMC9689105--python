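"""Self-organising-map model of colour-term acquisition.

The learner is a k×k grid of cells, each holding a vector that concatenates a
CIELAB colour prototype with a (scaled) colour-term feature block.  Training
presents word-chip pairs sampled from the adult joint distribution
P(W,C) = P(C|W)·P(W): the best-matching unit (BMU) and its grid neighbourhood
move toward the input, with the neighbourhood radius σ shrinking by a small
constant per sample down to a floor.  The learner's current colour-naming
hypothesis is read out by finding, for each chip, the BMU under the colour
features alone and normalising that cell's term block.

Default hyperparameters are calibrated so that a 50,000-sample run shows the
characteristic phases: an early high-σ warm-up in which single samples repaint
large regions of the map, then a tracking phase of rising complexity and
falling information loss, then convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ib import NamingSystem
from .universe import Universe

__all__ = [
    "SOMConfig",
    "SOMState",
    "TrainingSample",
    "JointSampler",
    "init_som",
    "draw_sample",
    "update",
    "train",
    "naming_distribution",
    "accuracy",
    "default_checkpoints",
    "toy_som_config",
]

INIT_SCHEMES = ("small_uniform", "bernoulli100", "uniform_50_100")

# Fraction of the naming mass scale below which a cell's term block is treated
# as uninformative and read out as the uniform distribution.
READOUT_MASS_FLOOR = 1e-3


def default_checkpoints(n_iterations: int) -> tuple[int, ...]:
    """Dense early (every 50 samples to 1,000), then every 500, plus the end."""
    early = list(range(50, min(1000, n_iterations) + 1, 50))
    late = list(range(1500, n_iterations + 1, 500))
    pts = sorted(set(early + late + [n_iterations]))
    return tuple(p for p in pts if p >= 1)


@dataclass(frozen=True)
class SOMConfig:
    """Hyperparameters of the acquisition model.

    k : grid side length (k² cells); 13 by default, which caps the number of
        learnable categories well below the 330-chip identity language.
    lambda0 : constant learning rate in (0, 1].
    sigma0, sigma_decrement, sigma_floor : neighbourhood radius schedule in
        grid units -- linear decay by ``sigma_decrement`` per sample from
        ``sigma0`` down to ``sigma_floor``.
    term_scale : weight of the term one-hot features relative to CIELAB
        features in the joint input vector.
    """

    k: int = 13
    lambda0: float = 0.25
    sigma0: float = 5.0
    sigma_decrement: float = 1e-4
    sigma_floor: float = 0.8
    term_scale: float = 100.0
    n_iterations: int = 50_000
    checkpoints: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.lambda0 <= 1.0):
            raise ValueError("lambda0 must be in (0, 1]")
        if self.sigma_floor > self.sigma0:
            raise ValueError("sigma_floor must not exceed sigma0")
        if self.sigma_floor < 0 or self.sigma_decrement < 0:
            raise ValueError("sigma parameters must be non-negative")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        cps = tuple(self.checkpoints) or default_checkpoints(self.n_iterations)
        if list(cps) != sorted(cps):
            raise ValueError("checkpoints must be sorted ascending")
        object.__setattr__(self, "checkpoints", cps)


def toy_som_config(n_iterations: int = 20_000, k: int = 7, seed: int = 0, **kw) -> SOMConfig:
    """Toy-scale config preserving the default σ-decay profile.

    The default decrement retires σ to its floor at 84% of a 50,000-sample
    run; shorter runs rescale the decrement to keep that fraction of training
    in the shrinking-neighbourhood phase.
    """
    base = SOMConfig(seed=seed)
    sigma0 = kw.pop("sigma0", base.sigma0)
    sigma_floor = kw.pop("sigma_floor", base.sigma_floor)
    dec = kw.pop("sigma_decrement", (sigma0 - sigma_floor) / (0.84 * n_iterations))
    return SOMConfig(
        k=k, n_iterations=n_iterations, sigma0=sigma0, sigma_floor=sigma_floor,
        sigma_decrement=dec, seed=seed, **kw,
    )


@dataclass(frozen=True)
class TrainingSample:
    """One elicitation-style observation: a term index and a chip index."""

    term: int
    chip: int


@dataclass
class SOMState:
    """Mutable learner state: the cell grid, sample count, and current σ."""

    grid: np.ndarray  # (k*k, 3 + n_terms)
    k: int
    n_terms: int
    samples_seen: int = 0
    current_sigma: float = 0.0
    coords: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.grid.shape != (self.k * self.k, 3 + self.n_terms):
            raise ValueError("grid shape must be (k², 3 + n_terms)")
        rows, cols = np.divmod(np.arange(self.k * self.k), self.k)
        self.coords = np.stack([rows, cols], axis=1).astype(float)

    def copy(self) -> "SOMState":
        return SOMState(
            self.grid.copy(), self.k, self.n_terms, self.samples_seen, self.current_sigma
        )


def init_som(
    config: SOMConfig,
    n_terms: int,
    scheme: str = "small_uniform",
    rng: np.random.Generator | None = None,
    eps: float = 1e-6,
) -> SOMState:
    """Initialise the grid under one of the studied schemes.

    small_uniform : entries uniform in [0, eps]; the naming read-out is
        (near-)uniform, matching a learner with no commitments.
    bernoulli100 : each entry 100 with probability 0.5, else 0 -- a random,
        communicatively inefficient starting language.
    uniform_50_100 : each entry uniform in [50, 100]; an alternative random
        initialisation reported to behave very similarly.
    """
    if scheme not in INIT_SCHEMES:
        raise ValueError(f"unknown init scheme {scheme!r}; expected one of {INIT_SCHEMES}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = (config.k * config.k, 3 + n_terms)
    if scheme == "small_uniform":
        grid = rng.uniform(0.0, eps, size=shape)
    elif scheme == "bernoulli100":
        grid = 100.0 * (rng.random(size=shape) < 0.5)
    else:
        grid = rng.uniform(50.0, 100.0, size=shape)
    return SOMState(grid, config.k, n_terms, 0, config.sigma0)


class JointSampler:
    """Draws (term, chip) pairs from P(W,C) = P(C|W)·P(W).

    P(W) is the term marginal of the adult system under a chip prior
    (uniform by default, matching elicitation-style sampling), and
    P(C|W=w) ∝ p(c)·q(w|c).
    """

    def __init__(self, naming: NamingSystem, chip_prior: np.ndarray | None = None):
        n = naming.n_chips
        p_c = np.full(n, 1.0 / n) if chip_prior is None else np.asarray(chip_prior, float)
        joint = p_c[:, None] * naming.q  # p(c, w)
        self.p_w = joint.sum(axis=0)
        cond = np.where(self.p_w[None, :] > 0, joint / np.where(self.p_w[None, :] > 0, self.p_w[None, :], 1.0), 0.0)
        self.w_cdf = np.cumsum(self.p_w)
        self.c_cdf = np.cumsum(cond.T, axis=1)  # (W, C)

    def draw(self, rng: np.random.Generator) -> TrainingSample:
        w = int(np.searchsorted(self.w_cdf, rng.random() * self.w_cdf[-1], side="right"))
        w = min(w, len(self.p_w) - 1)
        row = self.c_cdf[w]
        c = int(np.searchsorted(row, rng.random() * row[-1], side="right"))
        c = min(c, row.shape[0] - 1)
        return TrainingSample(term=w, chip=c)


def draw_sample(naming: NamingSystem, rng: np.random.Generator) -> TrainingSample:
    """One observation from the adult joint distribution P(W,C)."""
    return JointSampler(naming).draw(rng)


def _input_vector(sample: TrainingSample, universe: Universe, n_terms: int, term_scale: float):
    x = np.zeros(3 + n_terms)
    x[:3] = universe.chips[sample.chip].lab
    x[3 + sample.term] = term_scale
    return x


def update(
    state: SOMState, sample: TrainingSample, universe: Universe, config: SOMConfig
) -> SOMState:
    """One SOM step: move the BMU and its neighbourhood toward the input.

    The input is the concatenation of the chip's CIELAB coordinates and the
    scaled term one-hot.  Every cell i moves by
    λ₀·exp(-g(i, BMU)²/(2σ²))·(x - vᵢ) where g is Euclidean distance on the
    grid; σ then decays by ``sigma_decrement`` down to ``sigma_floor``.
    Mutates and returns ``state``.
    """
    x = _input_vector(sample, universe, state.n_terms, config.term_scale)
    diffs = x[None, :] - state.grid
    bmu = int(np.argmin(np.einsum("ij,ij->i", diffs, diffs)))  # ties: lowest row-major
    g2 = np.sum((state.coords - state.coords[bmu]) ** 2, axis=1)
    sigma = state.current_sigma
    if sigma > 0:
        h = config.lambda0 * np.exp(-g2 / (2.0 * sigma * sigma))
    else:  # σ = 0 limit: only the BMU moves
        h = np.where(g2 == 0, config.lambda0, 0.0)
    state.grid += h[:, None] * diffs
    state.current_sigma = max(config.sigma_floor, sigma - config.sigma_decrement)
    state.samples_seen += 1
    return state


def naming_distribution(
    state: SOMState, universe: Universe, terms: list[str] | None = None
) -> NamingSystem:
    """Read out the learner's current naming hypothesis q(w|c).

    For each chip the BMU is found using the colour sub-vector only (so the
    read-out works for unlabelled chips); the BMU's term block, clipped at 0,
    is normalised to a distribution.  Blocks with negligible total mass
    (relative to the naming scale, including the all-non-positive case) read
    out as uniform.
    """
    lab = universe.lab  # (C, 3)
    colour = state.grid[:, :3]  # (k², 3)
    d2 = ((lab[:, None, :] - colour[None, :, :]) ** 2).sum(axis=2)
    bmu = np.argmin(d2, axis=1)
    blocks = np.clip(state.grid[bmu, 3:], 0.0, None)
    mass = blocks.sum(axis=1)
    floor = READOUT_MASS_FLOOR  # absolute; the scale of trained blocks is term_scale
    q = np.where(
        (mass > floor)[:, None],
        blocks / np.where(mass > 0, mass, 1.0)[:, None],
        1.0 / state.n_terms,
    )
    if terms is None:
        terms = [f"w{j}" for j in range(state.n_terms)]
    return NamingSystem(q, terms)


def accuracy(state: SOMState, universe: Universe, adult_mode: np.ndarray) -> float:
    """Fraction of chips whose read-out mode matches the adult mode map."""
    adult_mode = np.asarray(adult_mode)
    if adult_mode.shape[0] != universe.n_chips:
        raise ValueError("adult_mode length must equal chip count")
    pred = np.argmax(naming_distribution(state, universe).q, axis=1)
    return float(np.mean(pred == adult_mode))


def train(
    naming: NamingSystem,
    universe: Universe,
    config: SOMConfig,
    init_scheme: str = "small_uniform",
) -> tuple[SOMState, list[tuple[int, NamingSystem]]]:
    """Train one learner on samples from the adult system.

    Runs ``config.n_iterations`` sequential sample-and-update steps with the
    configured seed and records the naming read-out at each checkpoint.
    Fully deterministic given (naming, universe, config, init_scheme).
    """
    if naming.n_chips != universe.n_chips:
        raise ValueError("naming and universe disagree on chip count")
    rng = np.random.default_rng(config.seed)
    state = init_som(config, naming.n_terms, scheme=init_scheme, rng=rng)
    sampler = JointSampler(naming)
    cps = set(config.checkpoints)
    out: list[tuple[int, NamingSystem]] = []
    for i in range(1, config.n_iterations + 1):
        update(state, sampler.draw(rng), universe, config)
        if i in cps:
            out.append((i, naming_distribution(state, universe, list(naming.terms))))
    return state, out
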