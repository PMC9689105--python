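# Methods

This note documents the models, the numerical choices behind them, the
synthetic data they are exercised on, and the limits of what the toy-scale
tests show.

## The efficiency model

A universe is a finite set of colour stimuli ("chips") with CIELAB
coordinates; perceptual dissimilarity is squared Euclidean distance in that
space. Speaker meanings are Gaussian: m_c(u) ∝ exp(−d²(c,u)/(2σ²)), rows
normalised over the universe. The perceptual variance σ² defaults to 64
CIELAB units² and is configurable; the Gaussian form is the modelling
commitment, the particular width a convention inherited from prior IB colour
models.

All information quantities are in bits, with 0·log 0 = 0 (via
`scipy.special.rel_entr`). A naming system q(w|c) is scored by

- complexity I(M;W) under the joint p(c)·q(w|c),
- informativity I(W;U) under p(w,u) = Σ_c p(c) q(w|c) m_c(u),
- information loss I(M;U) − I(W;U).

The loss is identically the prior-weighted expected KL divergence to the
listener's reconstruction m̂_w = Σ_c p(c|w) m_c; both routes are implemented
(`score_system` and `expected_kl_loss`) and the test suite asserts their
agreement to 1e−9 bits, so the decoder-based "reconstruction error" reading
and the information-loss axis coincide by construction.

**Prior.** The meaning prior p(c) is the capacity-achieving input
distribution of the channel c → m_c, computed by the Blahut–Arimoto
iteration from a uniform start until the gap between the capacity lower and
upper bounds falls below 1e−9 bits. For a zero-capacity (identical-rows)
channel the uniform start is already optimal and is returned — the
deterministic tie rule. Note the capacity-achieving prior concentrates mass
on a sparse subset of chips; entries can fall to ~1e−20, which is why the
mutual-information kernel zeroes joint entries below 1e−250 before forming
the product of marginals (they cannot contribute measurable information but
can underflow the denominator).

**Solver.** At each β the standard self-consistent updates are iterated —
encoder q(w|c) ∝ p(w)·exp(−β·KL(m_c ‖ m̂_w)), marginal, decoder — until the
objective I(M;W) − β·I(W;U) changes by less than 1e−9 bits (max 20,000
iterations; convergence slows near phase transitions, hence the generous
cap). Terms whose marginal drops below 1e−12 are pruned and the encoder
renormalised. The default encoder initialisation is a lightly smoothed
identity (0.999·I + 0.001/n): smoothing avoids zero-locked entries during
annealing.

**Frontier.** Reverse deterministic annealing over a geometric β grid from
2¹⁰ down to 1 (500 points by default): the largest β is solved from the
near-identity initialisation and each subsequent β warm-starts from the
previous encoder. The degenerate one-term point (complexity 0, loss
I(M;U)) always anchors the left end. Raw solutions are reduced to their
upper concave envelope in the (complexity, informativity) plane — the
standard Pareto-envelope construction — so the returned frontier is exactly
non-decreasing and concave; points removed by the envelope are transient
solver states, not optimal trade-offs. `annealed_solution` exposes a
single-β version with a short 8×-to-1× ladder and nearest-seed-partition
multi-starts for term-constrained problems; on problems small enough to
enumerate, it reaches the optimum over all deterministic encoders (asserted
to 1e−6 bits in the tests).

**Distance.** Distance to the frontier is the minimum Euclidean distance in
the (complexity, information-loss) plane to the piecewise-linear
interpolation, signed: positive above the interpolated loss (achievable
side), negative below. A genuine frontier point evaluated between knots can
sit a few 1e−5 bits below the chords (the interpolation overestimates the
convex loss curve between knots); the sign makes such cases visible instead
of folding them into a positive distance. A β-weighted objective-deficit
alternative was considered and rejected: the plain geometric distance is
what "distance from the frontier" means in the efficiency plane, and it
needs no choice of β for off-frontier points.

## The acquisition model

The learner is a k×k grid (default k = 13) of cells holding concatenated
[CIELAB, term-scale · one-hot] vectors. Training samples are drawn from
P(W,C) = P(C|W)·P(W) with P(C) uniform over chips (configurable); the
best-matching unit under the full joint vector moves toward the input along
with its grid neighbourhood, weighted λ₀·exp(−g²/(2σ²)) with g the Euclidean
grid distance. σ decays linearly by a fixed decrement per sample from σ₀ to
a floor; λ₀ is constant — only the neighbourhood shrinks.

Defaults: λ₀ = 0.25, σ₀ = 5.0 grid units, decrement 1e−4 per sample, floor
0.8, term scale 100, 50,000 samples. With these values σ reaches its floor
at 84% of a 50,000-sample run; `toy_som_config` preserves that profile for
shorter runs by rescaling the decrement. These hyperparameters were chosen
to reproduce the characteristic acquisition phases — a high-σ warm-up in
which single samples repaint large regions and hypotheses stay near-uniform,
a tracking phase of rising complexity and falling information loss, then
convergence — and all are config-exposed, none hard-coded. The wide, slowly
shrinking neighbourhood is not a nuisance parameter: it is the model's
simplicity/iconicity bias, and sharpening it (lower floor, faster decay)
trades frontier-tracking fidelity for higher final read-out accuracy.

Prediction masks the term features: the read-out finds each chip's
best-matching cell by colour alone and normalises that cell's clipped term
block, so unlabelled chips can be classified. Term blocks whose total mass
is below 1e−3 (including the all-non-positive case) read out as the uniform
distribution — a fresh `small_uniform` grid (entries in [0, ε], ε = 1e−6)
therefore reads out exactly uniform, matching a learner with no commitments,
while trained blocks (scale ≈ 100) are far above the floor. The other two
initialisation schemes, `bernoulli100` (each entry 100 with probability ½)
and `uniform_50_100`, start the learner at a random, communicatively
inefficient system.

Accuracy is the fraction of chips whose read-out mode equals the target
language's mode map, ties broken toward the lowest term index everywhere.
With k = 7 on an 8×8 universe the 49 cells quantise 64 chips, which caps
attainable accuracy at roughly 0.9–0.95 depending on how category
boundaries fall — a representational ceiling, not a training failure.

## Comparison languages

- *Degenerate*: one term for everything; complexity exactly 0.
- *Random convex*: Voronoi partition of chips around uniformly drawn seed
  chips (without replacement), ties to the lowest seed index. Convex in the
  nearest-seed sense, hence learnable, but communicatively inefficient.
- *Hue-permuted*: naming rows of chromatic chips (columns ≥ 1) are
  cyclically rotated along the hue axis within each lightness row;
  achromatic chips stay fixed. All candidate shifts are scored and the one
  farthest from the frontier returned. Rotation conserves term counts and
  approximate convexity while degrading efficiency.
- *Frontier samples*: n solutions nearest to an arithmetic grid of
  complexities spanning the solved frontier; the experiment driver splits
  them at 2.5 bits into simple (0.5 ≤ complexity < 2.5) and complex
  (≥ 2.5) groups.
- *Shuffled* (fixture only): naming rows randomly reassigned to chips — a
  non-convex control the learner is expected to fail on.

## Statistics

`compare_groups` is Welch's two-sample t-test (unequal variances, two-sided
p) with Cohen's d computed from the pooled SD with (n−1) weights; the sign
of d follows mean(a) − mean(b). No multiple-comparison correction is
applied; p-values are reported raw. `linear_r2` is the OLS coefficient of
determination. The experiment driver's default R² regressor pairs a frontier
language's complexity with its mean final accuracy; convergence time is the
natural alternative dependent variable and the summary table carries both.
Convergence time is the first checkpoint after which accuracy stays within
ε = 0.01 of its final value (oscillating tails fall back to the final
checkpoint).

## Synthetic data

The generator emulates the three ingredients the pipeline needs: a stimulus
grid embedded in CIELAB (default 8×8, 10 units spacing, L* fixed at 50),
adult naming systems (degenerate / random convex / IB-optimal / noisy
convex), and per-speaker elicitation tables in the same tab-separated
dialect as the real survey files, so the synthetic and real paths share one
code path. Elicitation noise is uniform-error (a chip's term flips to a
uniformly random other term with probability ε), which suffices for
round-trip testing but does not imitate the perceptual-neighbour structure
of real speaker disagreement. The bundle's meaning model carries the
capacity-achieving prior so that its IB-optimal system is optimal under the
same model that later scores it. The default IB-optimal language is solved
at β = 1.3, which places it mid-way through the attested-like complexity
range of the toy frontier (≈ 2.1 bits), mirroring the 2.5-bit split used at
full scale. Every bundle is bit-identical given its seed.

What toy-scale passes do and do not show: they verify the machinery — exact
degenerate scoring, solver optimality against enumeration, frontier
geometry, recovery and tracking dynamics, statistics — under conditions
whose qualitative structure matches the full palette. They do not establish
the full-palette effect sizes; those require the real survey tables (about
110 languages, 330 chips, 50 learners × 50,000 samples per cell), for which
the same pipeline is invoked through the loaders and the experiment driver.

## Problem sizes used by the default test run

Frontier and scoring checks use the 8×8 universe (500-β frontier, ≈ 200
surviving envelope points); solver-vs-enumeration uses 5 chips × 2 terms;
recovery trains 4 convex languages × 10 learners at k = 7 for 20,000
samples; tracking trains 16 learners on the IB-optimal language and 3
permuted variants × 4 learners; the experiment smoke tests run 2–3 learners
at 500–3,000 samples.

## Known limitations

- The IB solver returns soft encoders; mode maps of near-frontier systems
  can use more terms than the effective lexicon size, and term counts are
  only meaningful after pruning by marginal probability.
- The capacity-achieving prior is a modelling convention; environmental or
  corpus-based need distributions are not implemented (the prior field
  accepts any distribution).
- CIELAB coordinates are taken as given; no colour-space conversion is
  performed.
- The cross-linguistic semantic-feature input encoding for the learner and
  batch/growing map variants are out of scope.
- Mode-map and trajectory plotting is intentionally minimal (CSV exports are
  the primary output surface).
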