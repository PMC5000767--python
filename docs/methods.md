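# Methods

## Model and assumptions

`confconv` treats a QM/MM conformational study as a sequence of activation
barriers ΔE₁ … ΔEₙ (kcal·mol⁻¹), one per MD snapshot, in sampling
(chronological) order. Snapshots are treated as independent draws from the
enzyme's conformational ensemble; no autocorrelation between successive
frames is modelled, matching the common practice of extracting snapshots at
wide intervals (the default design is 20 snapshots at 0.5 ns over 10 ns).

The ensemble-level barrier is the Boltzmann-weighted (exponential) average

    dE = -RT * ln[(1/n) * sum_i exp(-dE_i / RT)],

which weights each conformation by its Boltzmann factor and therefore tracks
the low-barrier conformations that dominate the observable rate. Its
companion diagnostic, the disproportionate effect

    DE = 100 * (dE_without_lowest - dE_all) / dE_all,

measures how much the average rests on the single lowest-barrier
conformation (ties on the minimum drop exactly one record, the earliest in
sampling order, for determinism). DE is nonnegative by construction and
zero for an ensemble of identical barriers; a large DE indicates that the
current sample is still hostage to one outlier.

## Convergence rule

Both statistics are recomputed over growing prefixes of the series (the
Boltzmann average from n = 1, DE from n = 2, its first defined prefix). The
change at step n is |v_n − v_{n−1}| / max(|v_{n−1}|, floor) × 100 for the
default relative metric, or the plain absolute difference; the floor
(10⁻⁸ in statistic units) protects the ratio when DE passes near zero, and
the absolute metric is retained as an option for exactly that regime.

A series is converged when `window` consecutive changes all fall strictly
below `threshold` (defaults 5 iterations, 5%). Requiring a full window of
subsequent stability prevents declaring convergence on a value that is
merely pausing on its way somewhere else. Two counting semantics are
exposed:

- `window_end` (default): the reported count is the conformation that
  *completes* the quiet window — i.e. the number of conformations that must
  actually be sampled before convergence can be declared. This is the
  package's default because it is the count a practitioner budgets for, it
  makes the protocol's cost accounting self-consistent (the count equals the
  number of expensive evaluations performed), and it allows the DE criterion
  to be satisfiable near the end of a finite series.
- `window_start`: the index of the estimate the window then confirms
  (always `window` smaller). Useful when quoting "the estimate was already
  correct at n".

A trace too short to host a full window reports no convergence, never a
guess. The combined criterion takes the larger of the two statistics'
counts and is undecided if either never settles.

`ordering_sensitivity` re-runs the combined criterion over seeded random
permutations of the series, quantifying how much a declared count owes to
the arbitrary MD ordering.

## Screening protocol and cost model

Big-QM-region barriers are accurate but expensive; small-QM barriers for the
same conformations are cheap and roughly rank-correlated with them. The
protocol pre-screens every conformation at the small region, sorts
conformations by small-QM barrier ascending (stable on sampling order), and
evaluates big-QM barriers in that order, re-checking the combined criterion
from scratch after each addition (cheap at these sizes; the first success
equals what the full sequence would report). Convergence inside the
protocol is judged on the sequence of big barriers in ranked evaluation
order — the only sequence that exists as evaluations accrue. Feeding the
likely-lowest barriers in first settles the Boltzmann average and DE sooner;
a weaker small/big correlation degrades only the efficiency, not the
correctness, of the result.

Cost is expressed in big-evaluation equivalents: `n_small × relative_cost +
n_big_evaluated`, with `relative_cost` defaulting to 0.1 (a small-region
evaluation costing a tenth of a big one). Savings are quoted against a
baseline of big-QM-evaluating every conformation (configurable), and may be
negative when pre-screening buys nothing. Worked example: 20 screens at 0.1
plus 8 big evaluations cost 10 equivalents against a 20-evaluation baseline
— a 50% saving.

Correlation between the two region sizes is reported as Spearman's rank
coefficient (average ranks on ties), since the protocol relies only on
ordering being roughly preserved; Pearson is available as an option.

## Thermal parameters

The temperature of the Boltzmann weights defaults to 298.15 K with
R = 1.987204 × 10⁻³ kcal·mol⁻¹·K⁻¹, the standard laboratory condition; both
are overridable everywhere (CLI `--temperature`). Lower temperatures pull
the average toward the minimum barrier, higher toward the arithmetic mean;
conclusions about convergence counts can shift with T, so reports always
record the temperature used. Units are fixed to kcal·mol⁻¹ throughout — no
conversion layer.

## Numerical choices

- The Boltzmann average is evaluated by log-sum-exp, which shifts by the
  minimum barrier before exponentiation; barriers of several hundred
  kcal·mol⁻¹ cannot underflow. The shifted path agrees with naive direct
  summation to better than 10⁻¹⁰ relative over the chemically relevant range
  (tested for barriers in [1, 50] kcal·mol⁻¹, n ≤ 100).
- Jensen sandwich: min ΔEᵢ ≤ Boltzmann average ≤ arithmetic mean, strict
  when barriers differ; verified property-wise and at the T → 0 / T → ∞
  limits (within 10⁻³ kcal·mol⁻¹ of the minimum and the mean respectively).
- Barriers must be finite and strictly positive: DE divides by the average,
  and a non-positive barrier has no physical reading here.
- All tie-breaks (minimum barrier, ranking) are stable on sampling order, so
  every pipeline output is deterministic given its inputs.

## Synthetic data generator

The generator emulates the statistical structure the method exploits and
nothing more: *n* independent snapshots on a fixed time grid, small/big
barrier pairs drawn from a bivariate normal with prescribed means, standard
deviations and correlation, and non-positive draws rejected row-wise (which
cannot bias the correlation's sign). A log-normal family, moment-matched on
the natural scale with correlation applied on the log scale, is available
for skewed-barrier scenarios. One integer seed determines the full stream;
no global state.

Defaults — 20 conformations at 0.5 ns; mean 22 (small) and 16 (big)
kcal·mol⁻¹, sd 2.5, correlation 0.6 — were chosen once to echo the barrier
magnitudes and "roughly positive" small/big correlation typical of enzymatic
dehalogenation studies, where small-QM minima near 19 kcal·mol⁻¹ pair with
big-QM barriers in the 11–15 kcal·mol⁻¹ range. For a bivariate normal the
population Spearman correlation is (6/π)·arcsin(ρ/2); the generator's
recovery of that value is part of the test suite.

What the generator does **not** emulate: MD autocorrelation between
frames, multimodal conformational basins, heavy-tailed barrier outliers, or
any systematic small-vs-big offset structure beyond a mean shift. Passing
tests therefore demonstrate the statistics, the stopping rule and the
protocol mechanics — not that any particular real enzyme converges at a
particular count.

## Known limitations

- Convergence counts depend on the arbitrary MD ordering of snapshots;
  `ordering_sensitivity` quantifies this but the headline count is still the
  as-sampled one.
- The windowed rule is a heuristic, not a stationarity test; a series can
  pass it and later drift if the MD itself was unequilibrated.
- The cost model ignores per-conformation variation in QM/MM optimisation
  effort (failed transition-state searches, restarts); `relative_cost` is a
  single study-wide ratio.
- With fewer than `window` + 2 conformations the combined criterion can
  never fire; the protocol then reports the exhaustion path honestly.
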