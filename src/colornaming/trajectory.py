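"""Scoring acquisition trajectories in the efficiency plane and group statistics.

Each learner's checkpoints are scored with the communication model
(complexity, information loss), their distance to the IB frontier, and their
accuracy against the adult mode map.  Aggregation over independent learners
and the group comparisons (Welch t-tests, Cohen's d, OLS R²) reproduce the
analyses relating a language's communicative efficiency to its acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ib import (
    EfficiencyScore,
    Frontier,
    MeaningModel,
    NamingSystem,
    distance_to_frontier,
    frontier_samples,
    mode_map,
    score_system,
)
from .languages import permuted_variant, random_convex_language
from .som import SOMConfig, train
from .universe import Universe

__all__ = [
    "TrajectoryPoint",
    "Trajectory",
    "GroupComparison",
    "ExperimentConfig",
    "ExperimentResult",
    "score_trajectory",
    "convergence_time",
    "compare_groups",
    "linear_r2",
    "run_experiment",
]

log = logging.getLogger(__name__)

CONDITIONS = ("attested", "permuted", "random_convex", "frontier_simple", "frontier_complex")
COMPLEXITY_SPLIT = 2.5  # bits; boundary between simple and complex frontier languages
FRONTIER_SIMPLE_MIN = 0.5  # bits; lower complexity cut for frontier languages


@dataclass(frozen=True)
class TrajectoryPoint:
    samples_seen: int
    score: EfficiencyScore
    accuracy: float
    distance: float


@dataclass
class Trajectory:
    """Ordered checkpoints of one learner in the efficiency plane."""

    points: list[TrajectoryPoint]

    def __post_init__(self):
        seen = [p.samples_seen for p in self.points]
        if any(b <= a for a, b in zip(seen, seen[1:])):
            raise ValueError("samples_seen must be strictly increasing")

    @property
    def final(self) -> TrajectoryPoint:
        return self.points[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "samples": [p.samples_seen for p in self.points],
                "complexity": [p.score.complexity for p in self.points],
                "info_loss": [p.score.information_loss for p in self.points],
                "accuracy": [p.accuracy for p in self.points],
                "distance": [p.distance for p in self.points],
            }
        )


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample t-test with Cohen's d (pooled-SD convention)."""

    t: float
    p: float
    d: float
    n_a: int
    n_b: int


def score_trajectory(
    checkpoints: list[tuple[int, NamingSystem]],
    meanings: MeaningModel,
    frontier: Frontier,
    adult_mode: np.ndarray,
) -> Trajectory:
    """Score one learner's checkpoint read-outs in the efficiency plane."""
    adult_mode = np.asarray(adult_mode)
    pts = []
    for n_seen, system in checkpoints:
        if system.n_chips != meanings.n_meanings:
            raise ValueError("checkpoint chip count does not match meanings")
        sc = score_system(meanings, system)
        dist = distance_to_frontier(sc, frontier)
        acc = float(np.mean(np.argmax(system.q, axis=1) == adult_mode))
        pts.append(TrajectoryPoint(n_seen, sc, acc, dist))
    return Trajectory(pts)


def convergence_time(trajectory: Trajectory, epsilon: float = 0.01) -> int:
    """Samples seen at the first checkpoint after which accuracy stays put.

    Returns the sample count of the earliest checkpoint t such that accuracy
    at every checkpoint >= t remains within ``epsilon`` of the final accuracy;
    an oscillating tail falls back to the final checkpoint.
    """
    acc = np.array([p.accuracy for p in trajectory.points])
    final = acc[-1]
    ok = np.abs(acc - final) <= epsilon
    # last index where accuracy left the band, +1
    bad = np.flatnonzero(~ok)
    idx = 0 if bad.size == 0 else int(bad[-1]) + 1
    idx = min(idx, len(acc) - 1)
    return trajectory.points[idx].samples_seen


def compare_groups(a, b) -> GroupComparison:
    """Welch t-test (two-sided) and Cohen's d between two samples.

    Cohen's d uses the pooled standard deviation with (n-1) weights; its sign
    follows mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    res = stats.ttest_ind(a, b, equal_var=False)
    d = (a.mean() - b.mean()) / pooled
    return GroupComparison(float(res.statistic), float(res.pvalue), float(d), len(a), len(b))


def linear_r2(x, y) -> float:
    """Coefficient of determination of the OLS regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; R² undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


# ---------------------------------------------------------------------------
# experiment driver


@dataclass
class ExperimentConfig:
    """A full acquisition-efficiency experiment over languages × conditions.

    ``languages`` maps a name to its adult NamingSystem (the attested
    targets); each requested condition derives its own targets from them or
    from the frontier.  Learner l of any cell uses seed ``seed + l`` so
    learners are mutually independent but the whole run is reproducible.
    """

    languages: dict[str, NamingSystem]
    conditions: tuple[str, ...] = ("attested", "permuted")
    n_learners: int = 50
    seed: int = 0
    som: SOMConfig = field(default_factory=SOMConfig)
    init_scheme: str = "small_uniform"
    n_frontier_languages: int = 42
    convergence_epsilon: float = 0.01
    learner_seeds: tuple[int, ...] | None = None  # default: seed + 0..n_learners-1

    def __post_init__(self):
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}; expected one of {CONDITIONS}")
        if self.n_learners < 1:
            raise ValueError("need at least one learner")


@dataclass
class ExperimentResult:
    """Tidy per-checkpoint trajectories, per-learner summaries, and statistics.

    trajectories : one row per (language, condition, learner, checkpoint).
    summary : one row per (language, condition, learner) with the final
        accuracy, convergence time, and input/final frontier distances.
    comparisons : named group statistics (e.g. input distance attested vs
        permuted, final hypothesis vs input distance).
    r2 : complexity vs acquisition association across frontier languages,
        when frontier conditions were run (else None).
    """

    trajectories: pd.DataFrame
    summary: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    r2: float | None = None

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation over learners per checkpoint."""
        g = self.trajectories.groupby(["language", "condition", "samples"])
        agg = g[["complexity", "info_loss", "accuracy", "distance"]].agg(["mean", "std"])
        agg.columns = ["_".join(c) for c in agg.columns]
        return agg.reset_index()


def _build_targets(
    cfg: ExperimentConfig,
    universe: Universe,
    meanings: MeaningModel,
    frontier: Frontier,
) -> dict[tuple[str, str], NamingSystem]:
    """Resolve (language, condition) cells to concrete target systems."""
    targets: dict[tuple[str, str], NamingSystem] = {}
    rng = np.random.default_rng(cfg.seed)
    for name, system in cfg.languages.items():
        if "attested" in cfg.conditions:
            targets[(name, "attested")] = system
        if "permuted" in cfg.conditions:
            variant, shift = permuted_variant(system, universe, frontier, meanings)
            log.info("permuted variant of %s uses hue shift %d", name, shift)
            targets[(name, "permuted")] = variant
        if "random_convex" in cfg.conditions:
            targets[(name, "random_convex")] = random_convex_language(
                universe, system.n_terms, rng
            )
    wanted = {c for c in cfg.conditions if c.startswith("frontier")}
    if wanted:
        systems = frontier_samples(frontier, cfg.n_frontier_languages)
        for j, sys_j in enumerate(systems):
            cx = score_system(meanings, sys_j).complexity
            if cx < FRONTIER_SIMPLE_MIN:
                continue
            cond = "frontier_simple" if cx < COMPLEXITY_SPLIT else "frontier_complex"
            if cond in wanted:
                targets[(f"frontier_{j:02d}", cond)] = sys_j
    return targets


def run_experiment(
    cfg: ExperimentConfig,
    universe: Universe,
    meanings: MeaningModel,
    frontier: Frontier,
) -> ExperimentResult:
    """Train independent learners for every (language, condition) cell.

    Each cell trains ``cfg.n_learners`` SOMs with distinct seeds, scores their
    trajectories, and aggregates.  A failing cell is logged and skipped;
    remaining cells proceed.
    """
    targets = _build_targets(cfg, universe, meanings, frontier)
    if cfg.learner_seeds is not None:
        seeds = list(cfg.learner_seeds)[: cfg.n_learners]
    else:
        seeds = [cfg.seed + l for l in range(cfg.n_learners)]
    if len(set(seeds)) < len(seeds):
        log.warning("duplicate learner seeds detected; trajectories will repeat")

    traj_rows, summary_rows = [], []
    for (name, cond), target in targets.items():
        adult_mode = mode_map(target)
        input_dist = distance_to_frontier(score_system(meanings, target), frontier)
        try:
            for l, s in enumerate(seeds):
                som_cfg = SOMConfig(
                    **{**cfg.som.__dict__, "seed": s, "checkpoints": cfg.som.checkpoints}
                )
                _, checkpoints = train(target, universe, som_cfg, init_scheme=cfg.init_scheme)
                traj = score_trajectory(checkpoints, meanings, frontier, adult_mode)
                for p in traj.points:
                    traj_rows.append(
                        (name, cond, l, p.samples_seen, p.score.complexity,
                         p.score.information_loss, p.accuracy, p.distance)
                    )
                summary_rows.append(
                    (name, cond, l, traj.final.accuracy,
                     convergence_time(traj, cfg.convergence_epsilon),
                     input_dist, traj.final.distance,
                     score_system(meanings, target).complexity)
                )
        except Exception:  # noqa: BLE001 - cell isolation is the contract
            log.exception("cell (%s, %s) failed; skipping", name, cond)

    trajectories = pd.DataFrame(
        traj_rows,
        columns=["language", "condition", "learner", "samples", "complexity",
                 "info_loss", "accuracy", "distance"],
    )
    summary = pd.DataFrame(
        summary_rows,
        columns=["language", "condition", "learner", "final_accuracy",
                 "convergence_time", "input_distance", "final_distance",
                 "target_complexity"],
    )

    comparisons: dict[str, GroupComparison] = {}

    def _vals(cond, col):
        return summary.loc[summary["condition"] == cond, col].to_numpy()

    def _try(name, a, b):
        try:
            comparisons[name] = compare_groups(a, b)
        except ValueError as e:
            log.info("comparison %s skipped: %s", name, e)

    have = set(summary["condition"].unique())
    if {"attested", "permuted"} <= have:
        # input-language distances: one per (language, condition), not per learner
        per_lang = summary.drop_duplicates(["language", "condition"])
        _try(
            "input_distance_permuted_vs_attested",
            per_lang.loc[per_lang["condition"] == "permuted", "input_distance"],
            per_lang.loc[per_lang["condition"] == "attested", "input_distance"],
        )
        _try("accuracy_attested_vs_permuted",
             _vals("attested", "final_accuracy"), _vals("permuted", "final_accuracy"))
        _try("convergence_permuted_vs_attested",
             _vals("permuted", "convergence_time"), _vals("attested", "convergence_time"))
    for cond in have:
        _try(f"final_vs_input_distance_{cond}",
             _vals(cond, "final_distance"), _vals(cond, "input_distance"))
    if {"frontier_simple", "frontier_complex"} <= have:
        _try("accuracy_frontier_simple_vs_complex",
             _vals("frontier_simple", "final_accuracy"),
             _vals("frontier_complex", "final_accuracy"))

    r2 = None
    frontier_mask = summary["condition"].str.startswith("frontier")
    if frontier_mask.any():
        by_lang = (
            summary[frontier_mask]
            .groupby("language")[["target_complexity", "final_accuracy"]]
            .mean()
        )
        if len(by_lang) >= 3 and np.ptp(by_lang["target_complexity"].to_numpy()) > 0:
            r2 = linear_r2(by_lang["target_complexity"], by_lang["final_accuracy"])

    return ExperimentResult(trajectories, summary, comparisons, r2)
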