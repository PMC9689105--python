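"""Information Bottleneck model of colour-naming efficiency.

A speaker holds a meaning m_c for each chip c: a Gaussian distribution over
the perceptual universe centred on the chip, with variance ``sigma_sq`` in
CIELAB units squared.  A naming system is an encoder q(w|c) from chips to
words.  Its *complexity* is the mutual information I(M;W) between meanings and
words; its *informativity* is I(W;U), how much the words reveal about the
universe; and its *information loss* is I(M;U) - I(W;U), equivalently the
prior-weighted expected KL divergence between the speaker's meaning and the
listener's reconstruction m̂_w = Σ_c p(c|w) m_c.

The optimal trade-off between complexity and information loss, as the
trade-off weight β varies, is the IB frontier.  It is computed here by reverse
deterministic annealing of the standard self-consistent IB updates:

    q(w|c) ∝ p(w) · exp(-β · KL(m_c ‖ m̂_w))
    p(w)   = Σ_c p(c) q(w|c)
    m̂_w    = Σ_c p(c|w) m_c

The prior over meanings defaults to the capacity-achieving prior of the
channel c → m_c (a neutral proxy for communicative need), obtained with the
Blahut-Arimoto iteration.

All information quantities are in bits (log base 2); 0·log 0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

from .universe import Universe

__all__ = [
    "MeaningModel",
    "NamingSystem",
    "EfficiencyScore",
    "IBSolution",
    "Frontier",
    "ConvergenceError",
    "gaussian_meanings",
    "capacity_prior",
    "score_system",
    "solve_ib",
    "annealed_solution",
    "compute_frontier",
    "distance_to_frontier",
    "frontier_samples",
    "mode_map",
    "mutual_information",
    "default_beta_schedule",
]

_LN2 = np.log(2.0)
DEFAULT_SIGMA_SQ = 64.0  # CIELAB units^2
TERM_PRUNE_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance within max_iter."""

    def __init__(self, msg, last_value=None):
        super().__init__(msg)
        self.last_value = last_value


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information in bits of a joint distribution (rows × columns)."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        raise ValueError("joint distribution has zero mass")
    joint = joint / total
    # entries this small cannot contribute measurable information but can
    # underflow the product of marginals to 0, sending rel_entr to +inf
    joint = np.where(joint > 1e-250, joint, 0.0)
    outer = joint.sum(axis=1, keepdims=True) * joint.sum(axis=0, keepdims=True)
    mi = rel_entr(joint, outer).sum() / _LN2
    return max(float(mi), 0.0)


def _entropy_rows_nats(p: np.ndarray) -> np.ndarray:
    """Row-wise Σ p ln p (negative entropy in nats), with 0·ln0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return t.sum(axis=1)


def _kl_rows_to_cols_bits(m: np.ndarray, mhat: np.ndarray) -> np.ndarray:
    """Matrix D[c, w] = KL(m_c ‖ m̂_w) in bits."""
    neg_h = _entropy_rows_nats(m)  # (C,)
    log_mhat = np.log(np.clip(mhat, 1e-300, None))  # (W, U)
    cross = m @ log_mhat.T  # (C, W)
    return (neg_h[:, None] - cross) / _LN2


@dataclass
class MeaningModel:
    """Speaker meanings m_c(u) with a communicative-need prior p(c)."""

    m: np.ndarray
    prior: np.ndarray
    sigma_sq: float = DEFAULT_SIGMA_SQ

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.m.ndim != 2:
            raise ValueError("m must be 2-D (meanings × universe states)")
        if self.prior.shape != (self.m.shape[0],):
            raise ValueError("prior length must match number of meanings")
        if np.any(self.m < 0) or np.any(self.prior < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.m.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of m must sum to 1")
        if not np.isclose(self.prior.sum(), 1.0, atol=1e-8):
            raise ValueError("prior must sum to 1")

    @property
    def n_meanings(self) -> int:
        return self.m.shape[0]

    def joint_mu(self) -> np.ndarray:
        """Joint p(c, u) = p(c) m_c(u)."""
        return self.prior[:, None] * self.m

    def i_mu(self) -> float:
        """I(M;U): the ceiling on informativity for any naming system."""
        return mutual_information(self.joint_mu())


@dataclass
class NamingSystem:
    """Row-stochastic encoder q(w|c) with term labels."""

    q: np.ndarray
    terms: list[str]

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.terms = [str(t) for t in self.terms]
        if self.q.ndim != 2:
            raise ValueError("q must be 2-D (chips × terms)")
        if self.q.shape[1] != len(self.terms):
            raise ValueError("number of term labels must match q columns")
        if np.any(self.q < 0):
            raise ValueError("q entries must be non-negative")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of q must sum to 1")
        if not np.any(self.q.sum(axis=0) > 0):
            raise ValueError("at least one term must have positive marginal")

    @property
    def n_chips(self) -> int:
        return self.q.shape[0]

    @property
    def n_terms(self) -> int:
        return self.q.shape[1]

    def term_marginal(self, prior: np.ndarray | None = None) -> np.ndarray:
        """P(W) under a chip prior (uniform if not given)."""
        p = np.full(self.n_chips, 1.0 / self.n_chips) if prior is None else prior
        return p @ self.q

    def to_frame(self, universe: Universe | None = None):
        import pandas as pd

        idx = universe.ids if universe is not None else np.arange(1, self.n_chips + 1)
        return pd.DataFrame(self.q, index=pd.Index(idx, name="chip"), columns=self.terms)


@dataclass(frozen=True)
class EfficiencyScore:
    """A naming system's coordinates in the efficiency plane, in bits."""

    complexity: float
    informativity: float
    information_loss: float


@dataclass
class IBSolution:
    beta: float
    system: NamingSystem
    score: EfficiencyScore


@dataclass
class Frontier:
    """IB-optimal solutions ordered by complexity.

    ``interp_loss`` evaluates the piecewise-linear frontier information loss
    at arbitrary complexity (clamped to the solved range at the ends).
    """

    solutions: list[IBSolution]

    complexity: np.ndarray = field(init=False, repr=False)
    informativity: np.ndarray = field(init=False, repr=False)
    information_loss: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not self.solutions:
            raise ValueError("frontier must contain at least one solution")
        self.solutions = sorted(self.solutions, key=lambda s: s.score.complexity)
        self.complexity = np.array([s.score.complexity for s in self.solutions])
        self.informativity = np.array([s.score.informativity for s in self.solutions])
        self.information_loss = np.array([s.score.information_loss for s in self.solutions])

    def interp_loss(self, complexity) -> np.ndarray:
        return np.interp(complexity, self.complexity, self.information_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "beta": [s.beta for s in self.solutions],
                "complexity_bits": self.complexity,
                "informativity_bits": self.informativity,
                "information_loss_bits": self.information_loss,
            }
        )


def gaussian_meanings(universe: Universe, sigma_sq: float = DEFAULT_SIGMA_SQ) -> MeaningModel:
    """Meanings m_c(u) ∝ exp(-d²(c,u)/(2σ²)), rows normalised; uniform prior."""
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    logits = -universe.sqdist / (2.0 * sigma_sq)
    logits -= logits.max(axis=1, keepdims=True)
    m = np.exp(logits)
    m /= m.sum(axis=1, keepdims=True)
    n = universe.n_chips
    return MeaningModel(m, np.full(n, 1.0 / n), sigma_sq)


def capacity_prior(
    meanings: MeaningModel, tol: float = 1e-9, max_iter: int = 20000
) -> MeaningModel:
    """Replace the prior with the capacity-achieving input distribution.

    Runs the Blahut-Arimoto iteration on the channel c → m_c(u), starting from
    the uniform prior, until the gap between the capacity lower and upper
    bounds falls below ``tol`` bits.  For a zero-capacity channel (identical
    rows) the uniform start is already optimal and is returned unchanged.
    """
    m = meanings.m
    p = np.full(m.shape[0], 1.0 / m.shape[0])
    gap = np.inf
    for _ in range(max_iter):
        q_u = p @ m
        d_nats = rel_entr(m, q_u[None, :]).sum(axis=1)
        i_lower = float(p @ d_nats) / _LN2
        i_upper = float(d_nats.max()) / _LN2
        gap = i_upper - i_lower
        if gap < tol:
            return MeaningModel(m.copy(), p, meanings.sigma_sq)
        logits = np.log(np.clip(p, 1e-300, None)) + d_nats
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
    raise ConvergenceError(
        f"capacity iteration did not reach tol={tol} in {max_iter} steps (gap={gap:.3e})",
        last_value=gap,
    )


def score_system(meanings: MeaningModel, naming: NamingSystem) -> EfficiencyScore:
    """Score a naming system: complexity I(M;W), informativity I(W;U), loss."""
    if naming.n_chips != meanings.n_meanings:
        raise ValueError(
            f"naming has {naming.n_chips} chips but meanings has {meanings.n_meanings}"
        )
    p_c = meanings.prior
    joint_cw = p_c[:, None] * naming.q
    complexity = mutual_information(joint_cw)
    joint_wu = naming.q.T @ meanings.joint_mu()  # p(w, u)
    informativity = mutual_information(joint_wu)
    loss = max(meanings.i_mu() - informativity, 0.0)
    return EfficiencyScore(complexity, informativity, loss)


def expected_kl_loss(meanings: MeaningModel, naming: NamingSystem) -> float:
    """Information loss via its decoder form Σ_w p(w) Σ_c p(c|w) KL(m_c ‖ m̂_w).

    Numerically identical to I(M;U) - I(W;U); exposed as a cross-check and for
    reconstruction-error analyses against an explicit decoder.
    """
    p_c = meanings.prior
    p_w = p_c @ naming.q
    keep = p_w > 0
    p_cw = (naming.q[:, keep] * p_c[:, None]) / p_w[keep][None, :]  # p(c|w), C×W
    mhat = p_cw.T @ meanings.m  # W×U
    d = _kl_rows_to_cols_bits(meanings.m, mhat)  # C×W bits
    return float(np.sum(p_c[:, None] * naming.q[:, keep] * d))


def solve_ib(
    meanings: MeaningModel,
    beta: float,
    init: NamingSystem | np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> IBSolution:
    """Fixed point of the self-consistent IB updates at one β.

    Minimises I(M;W) - β·I(W;U) by alternating the encoder, marginal and
    decoder updates until the objective changes by less than ``tol`` bits.
    Terms whose marginal falls below a floor are pruned.  ``init`` defaults to
    a lightly smoothed identity encoder (one term per meaning).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    m, p_c = meanings.m, meanings.prior
    n = meanings.n_meanings
    if init is None:
        q = (1.0 - 1e-3) * np.eye(n) + 1e-3 / n
    elif isinstance(init, NamingSystem):
        q = init.q.copy()
    else:
        q = np.asarray(init, dtype=float).copy()

    prev_obj = np.inf
    for _ in range(max_iter):
        p_w = p_c @ q
        keep = p_w > TERM_PRUNE_FLOOR
        if not keep.all():
            q = q[:, keep]
            q /= q.sum(axis=1, keepdims=True)
            p_w = p_c @ q
        p_cw = (q * p_c[:, None]) / p_w[None, :]
        mhat = p_cw.T @ m  # W×U decoder
        d = _kl_rows_to_cols_bits(m, mhat)  # bits
        logits = np.log(p_w[None, :]) / _LN2 - beta * d  # base-2 logits
        logits -= logits.max(axis=1, keepdims=True)
        q = np.exp(logits * _LN2)
        q /= q.sum(axis=1, keepdims=True)

        complexity = mutual_information(p_c[:, None] * q)
        informativity = mutual_information(q.T @ meanings.joint_mu())
        obj = complexity - beta * informativity
        if abs(prev_obj - obj) < tol:
            system = _as_system(q)
            loss = max(meanings.i_mu() - informativity, 0.0)
            return IBSolution(beta, system, EfficiencyScore(complexity, informativity, loss))
        prev_obj = obj
    raise ConvergenceError(
        f"IB solver did not converge at beta={beta} (last objective {prev_obj:.6g})",
        last_value=prev_obj,
    )


def _as_system(q: np.ndarray) -> NamingSystem:
    return NamingSystem(q, [f"w{j}" for j in range(q.shape[1])])


def annealed_solution(
    meanings: MeaningModel,
    beta: float,
    n_terms: int | None = None,
    n_ladder: int = 12,
    n_restarts: int = 4,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> IBSolution:
    """Solve at one β via a short reverse-annealing ladder with multi-start.

    Starts from a high β (8×) and warm-starts down a geometric ladder to the
    target, which sidesteps poor local fixed points of the plain alternating
    updates.  With ``n_terms`` set, inits are smoothed nearest-seed partitions
    into that many terms (restarts vary the seed chips); the best objective
    over restarts is returned.
    """
    rng = np.random.default_rng(seed)
    ladder = np.geomspace(max(beta, 1e-6) * 8.0, max(beta, 1e-6), n_ladder)
    n = meanings.n_meanings

    def run(q0):
        q = q0
        sol = None
        for b in ladder:
            sol = solve_ib(meanings, b, init=q, tol=tol, max_iter=max_iter)
            q = sol.system.q
        return sol

    if n_terms is None:
        return run(None)

    best = None
    for r in range(n_restarts):
        if r == 0:
            seeds = np.linspace(0, n - 1, n_terms).round().astype(int)
        else:
            seeds = rng.choice(n, size=n_terms, replace=False)
        # nearest-seed partition under the meanings' own overlap geometry
        assign = np.argmax(meanings.m[:, seeds], axis=1)
        q0 = np.full((n, n_terms), 1e-3 / n_terms)
        q0[np.arange(n), assign] += 1.0 - 1e-3
        sol = run(q0)
        obj = sol.score.complexity - beta * sol.score.informativity
        if best is None or obj < best[0] - 1e-15:
            best = (obj, sol)
    return best[1]


def default_beta_schedule(beta_max: float = 2.0**10, beta_min: float = 1.0, n: int = 500):
    """Geometric β grid, descending, for reverse deterministic annealing."""
    return np.geomspace(beta_max, beta_min, n)


def _upper_concave_envelope(points: list[IBSolution]) -> list[IBSolution]:
    """Keep the solutions forming the upper concave hull of informativity vs complexity."""
    pts = sorted(points, key=lambda s: (s.score.complexity, -s.score.informativity))
    # drop points dominated in informativity
    filtered: list[IBSolution] = []
    best_inf = -np.inf
    for s in pts:
        if s.score.informativity > best_inf + 1e-12:
            filtered.append(s)
            best_inf = s.score.informativity
        elif not filtered:
            filtered.append(s)
            best_inf = s.score.informativity
    # Andrew-monotone-chain upper hull in (complexity, informativity)
    hull: list[IBSolution] = []
    for s in filtered:
        while len(hull) >= 2:
            x1, y1 = hull[-2].score.complexity, hull[-2].score.informativity
            x2, y2 = hull[-1].score.complexity, hull[-1].score.informativity
            x3, y3 = s.score.complexity, s.score.informativity
            # middle point below the chord => not concave => drop it
            if (x2 - x1) * (y3 - y1) - (y2 - y1) * (x3 - x1) >= -1e-12:
                hull.pop()
            else:
                break
        hull.append(s)
    return hull


def compute_frontier(
    meanings: MeaningModel,
    beta_schedule=None,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> Frontier:
    """Trace the IB frontier by reverse deterministic annealing.

    Solves at the largest β from a near-identity initialisation, then
    warm-starts each subsequent (smaller) β from the previous encoder.  The
    degenerate one-term point (complexity 0, loss I(M;U)) anchors the left
    end.  Raw solutions are reduced to their upper concave envelope so the
    returned frontier is non-decreasing and concave in complexity.
    """
    if beta_schedule is None:
        beta_schedule = default_beta_schedule()
    betas = np.asarray(beta_schedule, dtype=float)
    diffs = np.diff(betas)
    if len(betas) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("beta_schedule must be strictly monotone")
    betas = np.sort(betas)[::-1]  # anneal from large beta down

    solutions = []
    q = None
    for b in betas:
        try:
            sol = solve_ib(meanings, float(b), init=q, tol=tol, max_iter=max_iter)
        except ConvergenceError as e:
            raise ConvergenceError(f"frontier solve failed at beta={b}: {e}", e.last_value)
        solutions.append(sol)
        q = sol.system.q

    # degenerate anchor: one term, complexity 0, maximum information loss
    n = meanings.n_meanings
    degenerate = NamingSystem(np.ones((n, 1)), ["w0"])
    solutions.append(IBSolution(0.0, degenerate, score_system(meanings, degenerate)))

    return Frontier(_upper_concave_envelope(solutions))


def distance_to_frontier(score: EfficiencyScore, frontier: Frontier) -> float:
    """Signed Euclidean distance in the (complexity, information-loss) plane.

    Magnitude is the minimum distance from the point to the piecewise-linear
    frontier; the sign is positive for points above the interpolated frontier
    loss (achievable region), negative below it (which only numerical error
    can produce).  Points on the frontier score 0.
    """
    x = np.array([score.complexity, score.information_loss])
    cx, cy = frontier.complexity, frontier.information_loss
    if len(cx) == 1:
        dist = float(np.hypot(*(x - np.array([cx[0], cy[0]]))))
    else:
        a = np.stack([cx[:-1], cy[:-1]], axis=1)
        b = np.stack([cx[1:], cy[1:]], axis=1)
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom = np.where(denom == 0, 1.0, denom)
        t = np.clip(np.einsum("ij,ij->i", x[None, :] - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        dist = float(np.sqrt(np.min(np.einsum("ij,ij->i", x[None] - proj, x[None] - proj))))
    sign = 1.0 if score.information_loss >= frontier.interp_loss(score.complexity) else -1.0
    return sign * dist


def frontier_samples(frontier: Frontier, n: int) -> list[NamingSystem]:
    """Pick n frontier systems at (approximately) uniformly spaced complexities."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    cx = frontier.complexity
    if np.ptp(cx) <= 0:
        raise ValueError("frontier has fewer than 2 distinct complexities")
    targets = np.linspace(cx.min(), cx.max(), n)
    picks = [frontier.solutions[int(np.argmin(np.abs(cx - t)))] for t in targets]
    return [p.system for p in picks]


def mode_map(naming: NamingSystem) -> np.ndarray:
    """Most frequent term per chip; ties broken by lowest term index."""
    return np.argmax(naming.q, axis=1)
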