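# colornaming

Communicative efficiency and acquisition of colour-naming systems: an
Information Bottleneck (IB) model that scores any colour-naming system on
complexity versus information loss and computes the optimal frontier, a
self-organising-map (SOM) acquisition model trained from elicitation-style
samples, and a trajectory analysis that scores learners' intermediate
hypotheses in the efficiency plane — comparing attested, hue-permuted,
random-convex, and frontier-optimal languages.

## Who this is for

Researchers in computational cognitive science, semantic typology, and
language evolution who want to ask: *do the inductive biases of a category
learner — simplicity and iconicity — act like a pressure for communicative
informativity?* The package runs on the World Colour Survey (WCS) tables for
full-palette analyses, and on self-contained synthetic fixtures with the same
statistical structure for fast, reproducible experiments.

## The model

**Efficiency.** Each chip *c* of the stimulus palette carries a speaker
meaning m_c(u) ∝ exp(−‖c−u‖²/(2σ²)), a Gaussian over CIELAB perceptual
space. A naming system is an encoder q(w|c). Its

- **complexity** is I(M;W), the mutual information between meanings and
  words (bits);
- **informativity** is I(W;U), what the words reveal about the universe;
- **information loss** is I(M;U) − I(W;U), equivalently the prior-weighted
  expected KL divergence D[m_c ‖ m̂_w] between the speaker's meaning and the
  listener's reconstruction m̂_w = Σ_c p(c|w) m_c.

The optimal trade-off for each weight β — minimising I(M;W) − β·I(W;U) — is
found by the self-consistent IB updates, annealed in reverse from high β, and
the resulting frontier separates achievable systems from impossible ones.
The prior p(c) is the capacity-achieving input distribution of the meaning
channel (Blahut–Arimoto), a neutral proxy for communicative need.

**Acquisition.** The learner is a k×k grid of cells, each a concatenated
colour + term-feature vector. Each training step presents a (word, chip)
pair drawn from P(W,C) = P(C|W)·P(W) estimated from elicitation data; the
best-matching unit and its grid neighbourhood (radius σ, decaying to a
floor) move toward the input. The learner's current naming hypothesis is
read out chip-by-chip from the best-matching cell's term features, and every
checkpoint is scored in the (complexity, information-loss) plane.

**Analysis.** Group comparisons use Welch's t-test and pooled-SD Cohen's d;
the association between a frontier language's complexity and its
acquirability is summarised by OLS R².

## Worked example

`examples/01_score_and_frontier.py` builds a toy 8×8 universe and scores a
few systems against the computed frontier:

```
I(M;U) = 3.166 bits  (ceiling on informativity)
frontier: 196 solutions, complexity 0 .. 4.851 bits

system                       complexity  info loss  distance
degenerate (1 term)               0.000      3.166     0.000
random convex, 4 terms            1.944      1.630     0.139
random convex, 8 terms            2.846      0.980     0.150
```

The degenerate one-term language sits exactly at the frontier's left anchor:
zero complexity, maximum information loss (all of I(M;U) is lost). Random
convex partitions are achievable but inefficient — they sit 0.14–0.15 bits
above the frontier. `examples/04_trajectories_in_efficiency_plane.py` then
trains a learner on the toy IB-optimal language:

```
samples   complexity   info loss   dist-to-frontier   accuracy
     50        0.162       3.027              0.009   0.250
   2000        0.219       2.975              0.011   0.375
  10000        0.914       2.393              0.053   0.344
  20000        2.821       1.027              0.174   0.812
```

The trajectory starts near the degenerate anchor and moves right and down
while staying close to the frontier — the learner's simplicity and iconicity
biases function as a pressure for informativity.

The other examples cover the WCS table dialects (`02`), SOM acquisition
dynamics (`03`), and the languages × conditions experiment driver with its
statistics (`05`). A thin CLI wraps the same calls:

```sh
colornaming synth --seed 0 -o bundle/        # fixture tables in WCS dialects
colornaming frontier --fixture-seed 0 -o fr/ # frontier + per-system scores
colornaming experiment exp.yaml -o out/      # full trajectory experiment
```

For a real-data run, point `--chips/--lab/--terms` at the WCS `chip.txt`,
`cnum-vhcm-lab-new.txt`, and `term.txt` files (tab-separated dialects are
documented in `colornaming/universe.py`).

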