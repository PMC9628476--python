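# Methods

This note documents the models and procedures implemented in `mhgs`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and the limits of what the synthetic experiments show.

## The hunger games search engine

HGS is a population metaheuristic for bound-constrained minimization. Each
agent *i* carries a position `X_i ∈ [LB, UB]`, a fitness `F_i`, and a
*hunger* level that accumulates while the agent lags behind the best
solution found so far (`Xb`, `BF`).

Per generation (synchronous update; the budget is counted in function
evaluations, FE):

1. **Evaluation.** All positions are evaluated in one batch; FE increases by
   the population size. The incumbent `(Xb, BF)` and the generation's worst
   fitness `WF` are updated afterwards.
2. **Hunger bookkeeping.** The agent holding the incumbent fitness resets
   its hunger to 0. Every other agent accumulates
   `H = TH` if `TH ≥ LH` else `LH·(1 + r)`, where
   `TH = (F_i − BF)/(WF − BF) · r6 · 2 · (UB − LB)` and `r, r6 ~ U[0,1)`.
   `LH` (default 100) is the lower bound of a hunger increment. For a flat
   generation (`WF = BF`) we define `TH = 0`, which routes every non-best
   agent through the maximal-pressure branch; when bounds differ per
   dimension, `UB − LB` is taken as the mean range (the base algorithm
   treats it as a scalar).
3. **Hunger weights.** `W1 = hungry_i · N / SHungry · r4` with probability
   `l` (default 0.03), else `W1 = 1`; `W2 = (1 − e^{−|hungry_i − SHungry|})
   · r5 · 2 ∈ [0, 2)`. `SHungry = 0` (no hunger information) defaults
   `W1 = 1`. The draws `r4, r5` are fresh per *coordinate*: the weights are
   weight vectors, which is what gives the update directional diversity —
   a per-agent scalar variant was measured to stall all shifted/rotated
   benchmarks and was rejected.
4. **Position update.** With probability `l` an agent self-scales,
   `X ← X·(1 + randn)` with a single normal scalar for the whole position.
   Otherwise each coordinate independently approaches or departs the
   incumbent, gated by the variation control `E = sech(|F_i − BF|)`:
   `X_j ← W1_j·Xb_j ± R·W2_j·|Xb_j − X_j|`, where `R ~ U[−a, a]` is drawn
   once per agent and `a = 2·(1 − FE/MAX_FE)` shrinks linearly over the
   budget. Positions are clamped to the bounds (no reflection).

The best-fitness trace is recorded once per generation and is monotone
non-increasing by construction.

## Centroid-based fuzzy mutation

The mHGS modification combines two fuzzy membership degrees into a per-agent
mutation probability:

- **Crowding.** `P_d = 1/(1 + dist)`, with `dist` the Euclidean distance
  from the agent to the population centroid (mean position), normalized by
  the box diagonal `‖UB − LB‖` so the degree is comparable across search
  spaces (flag `normalize_dist` disables this). Agents at the centroid get
  `P_d = 1`; the +1 keeps the degree finite there.
- **Stagnation.** `P_c = a + b·tanh(unchanged/α − β)` with `a = b = 0.5`,
  `α = 4`, `β = 5`; `unchanged` counts consecutive generations without
  strict improvement of the incumbent (reset to 0 on any strict
  improvement). The degree is ~0 for a freshly improving search, 0.5 after
  `α·β = 20` stagnant generations, and saturates toward 1.

The combined probability is `P_l = ρ·P_d + φ·P_c` with `ρ = 0.6`,
`φ = 0.4` — history deliberately gets the lower weight. One uniform draw
per agent gates firing (`P_l > u`). A fired agent's candidate perturbs
*every* coordinate by `±min(Δq_j, |X_ij|)` with an independent random sign,
where `Δq_j = 0.5·range_j·(1 − FE/MAX_FE)²` decays quadratically over the
budget. (A one-coordinate and a random-subset variant were measured and
performed no better; the all-coordinates choice is the default.)

**Greedy acceptance.** The candidate is evaluated (charged against MAX_FE)
and kept only if it improves on the agent's current fitness; the better of
the new and previous solutions is retained, and the incumbent is updated
when a candidate beats it. Without this selection step the mutation fires
on more than half of all agents per generation and measurably degrades
every benchmark; with it, the mutation acts as an annealed local search
that never accepts a worse solution. It does consume evaluations: measured
at the benchmark protocol it clearly helps composition functions, is
neutral on hybrids, and can slow pure refinement on unimodal functions
where the diverted budget would otherwise feed the contraction dynamics.
The mutation consumes randomness from its own named
stream, so disabling it (or forcing `P_l = 0`) leaves the main search
trajectory bit-identical.

## Linear population reduction

`NP(FE) = round((NP_min − NP_max)/MAX_FE · FE + NP_max)` shrinks the agent
count linearly from `NP_max` (default 100) to `NP_min` (default 30) across
the budget. Shrinking removes the worst-fitness agents first (ties: the
hungrier agent goes first, then the lower index); the incumbent-best agent
always survives. With `NP_max = NP_min` the schedule is a verified no-op.
The benchmark-table protocol below fixes the population at 30 agents, which
makes reduction inactive there by construction.

## Benchmark suite

Ten CEC'20-style functions on `[−100, 100]^D`: shifted/rotated bent cigar
(f1, bias 100), modified Schwefel (f2, 1100), Lunacek bi-Rastrigin (f3,
700), expanded Rosenbrock-plus-Griewank (f4, 1900); three hybrids (f5–f7,
biases 1700/1600/2100) that rotate, permute and split the coordinates into
chunks handled by different base functions; and three compositions (f8–f10,
biases 2200/2400/2500) that blend rotated components with
distance-dependent weights. Each instance draws its shift uniformly from
the inner 80% of the range (so the optimum never touches the boundary) and
a Haar-orthogonal rotation from a seeded stream, which preserves the
optimum *value* (= the bias) exactly; official whitespace-text data files
can be loaded instead, with identical function contracts. The modified
Schwefel per-dimension constant is computed as `w*·sin(√w*)` at
`w* = 420.9687462275036` so shifted instances attain their bias to machine
precision. Hybrid chunk sizes use largest-remainder rounding of the
published proportions. No claim of bit-exactness with the official
reference instances is made.

## Wrapper feature selection

The FS front-end searches `[0, 1]^d`; a position binarizes to a mask by
thresholding at 0.5, with an argmax fallback so the classifier always
receives at least one feature. Fitness of a mask (minimized):

    fobj = α·R + (1 − α)·|selected|/d,       α = 0.99

with `R` the hold-out error of an RBF-kernel SVM (`C = 1`,
`γ = 1/d_selected`) trained on the selected columns, z-scored on the
training fold only. Each run draws one seeded stratified 90/10 split
(test size = round-half-up of 0.1·n) and uses it for every evaluation of
that run. A "literal" variant of the printed objective
(`α + β·|R|/|C| − G` with `β = α`, flagged against a threshold `T`) is kept
for fidelity experiments; `G` and `T` are free parameters with no usable
definition and default to 0.

## Synthetic descriptor tables

The generator emulates QSAR-style descriptor matrices with known ground
truth: informative features are class-conditional Gaussians with unit
variance and class means `class_sep` apart (the per-feature separation
convention of scikit-learn's `make_classification`; random sign per
feature); redundant features are unit-norm linear mixtures of the
informative block plus Gaussian noise of standard deviation 0.05; noise
features are standard normal and independent of the labels; labels are
balanced and flipped with probability `flip_y`. Defaults (300 samples,
50 features, 5 informative, `class_sep` 3, `flip_y` 0.05) define the
recovery experiment's conditions. What the generator does *not* emulate:
the heavy inter-descriptor correlation, mixed scales and discreteness of
real molecular-descriptor tables — passing the synthetic experiments shows
the search and scoring machinery work, not that the selector ranks real
chemistry well.

## Statistics

Run summaries report mean, sample standard deviation (denominator M−1) and
direction-aware best/worst (minimum is best for benchmark fitness, maximum
for accuracy). Friedman mean ranks are computed per (problem, run) cell
with mid-ranks on ties and averaged per algorithm; ranking per cell rather
than per problem mean is deliberate — it is the only convention consistent
with non-integral published mean ranks. A single run's std is reported as 0
with a warning.

## Study protocols and problem sizes

The canonical experiment sizes used by the validation suite and
`scripts/acceptance.py`, chosen to mirror the published protocol:

- Benchmark attainment: 30 independent runs × 45 000 evaluations ×
  30 agents, 10-D, functions f1/f6/f8.
- Convergence: 2-D sphere, 5 000 evaluations, 20 seeds; paired-seed
  comparison against pure uniform random sampling on the 10-D sphere at
  10 000 evaluations, 20 pairs.
- FS recovery: the generator defaults above, 10 runs at 5 000 evaluations.

## Known limitations

- On ill-conditioned rotated functions (bent cigar) the search reliably
  localizes the optimum's narrow valley but refines along it slowly: the
  mutation's isotropic equal-magnitude steps are accepted only below a
  size proportional to the remaining valley error, so final precision is
  schedule-limited rather than machine-limited. Runs typically end 1e2–1e4
  above the optimum value in 10-D at 45 000 evaluations.
- On functions with modified-Schwefel components (f6, f8) a fraction of
  runs terminates in the well-known deceptive local minima roughly +100
  above the best-reachable level.
- The wrapper-FS protocol scores masks against a single small hold-out set
  (30 samples at the default shape); with thousands of adaptive
  evaluations this both saturates (several distinct subsets tie at the
  label-noise floor, and the size penalty then prefers the smallest) and
  invites selection overfitting. Recovered subsets are therefore minimal
  sufficient subsets of the informative features rather than the complete
  informative set; reported hold-out accuracies of selected subsets are
  optimistically biased. This is a property of the protocol, not a defect
  of the search.
- Parallelism is out of scope; all protocols are single-process and
  deterministic given a seed.
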