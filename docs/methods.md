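# Methods

## Model structure

The model is a Takagi–Sugeno–Kang fuzzy system whose rule consequents are
"jump" wavelet networks. For inputs u ∈ ℝᵐ:

* **Mother wavelet.** The multi-dimensional Mexican hat
  φ(z) = (m − ‖z‖²)·exp(−‖z‖²/2); it is zero-mean in each coordinate and
  decays below 1e−12 beyond ‖z‖ ≈ 10.
* **Candidate dictionary.** Scaled/shifted variants
  2^(−am/2)·φ(2ᵃu − B) for integer scales a ∈ [−4, 4]. The amplitude factor
  is the standard dyadic frame normalisation; any constant per-wavelet
  factor is absorbed by the learned least-squares weights, so this choice
  affects conditioning, not expressiveness. Shifts are data-centred,
  B = 2ᵃ·c for a subsample of at most 100 distinct training rows c per
  scale (uniform subsample under the experiment seed): a tensor shift grid
  is exponentially large in m, while data-centred candidates cover exactly
  the support the model must fit.
* **Normalisation.** Inputs are min–max normalised to [0, 1] (constants
  stored in the model) *for wavelet and membership evaluation only*. The
  linear consequent terms use the raw regressors. This split matters: the
  consequent has no intercept, and a no-intercept linear form in min–max
  shifted coordinates cannot represent even a pure linear law in the
  original inputs (the shift introduces an unabsorbable constant). With raw
  linear regressors, linear dynamics are represented exactly and
  extrapolate exactly; the wavelets, which vanish off the training support,
  only ever add local corrections.
* **Rules.** Selected wavelets are grouped by scale; each group is one
  rule's consequent together with all m linear regressors. The number of
  rules n_a therefore equals the number of distinct selected scales. Rule l
  fires at the geometric mean of its participating inputs' Gaussian
  memberships exp(−½((u_i − mu)/su)²); integer antecedent codes
  ca_il ∈ {0..n_a} pick, per input, one of the n_a pool members (code 0
  excludes the input; a rule with no participating inputs fires at 1
  everywhere, i.e. acts globally — the geometric mean is otherwise
  undefined there). The prediction is ŷ = Σ v_l μ̄_l η_l with firings
  normalised over the surviving rules.

## Selection stage

Forward OLS (modified Gram–Schmidt) ranks dictionary candidates by
error-reduction ratio on the residual after the forced linear regressors;
ties break to the lower candidate index, all-zero columns are skipped with a
warning, and ranking stops early if the forced columns already explain the
target to machine precision (ranking against rounding noise would select
junk terms). The wavelet count n ≤ N_max (default 40, consistent with the
parameter counts this model family typically reports) minimises the
validation RMSE of nested least-squares fits; the validation split is the
chronological tail (default 20 %) because the data are time series; ties —
including floating-point-level ties on noiseless targets — resolve to the
smallest n. A genetic algorithm then refines the subset: integer chromosome
of n distinct lattice indices, fitness = validation RMSE, tournament
selection (size 3), uniform crossover (rate 0.9), per-gene random-reset
mutation (rate 1/n), duplicate repair by resampling, elitism, stop after the
generation budget or five consecutive generations without an improvement
above the tolerance. The population is seeded with the OLS subset, so the
refined subset can never be worse.

## Hybrid training

Unknowns split by estimation method: membership means and std-devs, rule
weights v, and antecedent codes live in a flat real genome optimised by the
imperialist competitive algorithm; all consequent weights are solved in
closed form inside every cost evaluation. Because ŷ is linear in all
consequent weights once firings and v are fixed, one joint least squares
over the stacked, firing-scaled columns of all rules is exact — per-rule
solves would ignore the inter-rule coupling. The ICA cost is the training
RMSE of this nested fit (a validation-cost switch exists; training cost is
the default because the validation tail is already consumed by the
selection stage and the genome is low-dimensional relative to the sample
sizes used here).

Genome boxes: mu ∈ [−0.5, 1.5] (normalised units, so means may sit just
outside the data range), su ∈ [1e−3, 2] (the lower clamp prevents singular
memberships), v ∈ [0, 1], code gene ∈ [0, n_a+1) decoded by floor and
clamped. Initialisation: means uniform on [0, 1], su = 0.2, v = 0.7, all
codes 1 (every input participates through its first pool member). ICA
defaults follow the reference metaheuristic settings (population 500, 60
iterations, 5 imperialists, selection pressure 1, assimilation coefficient
1.5, revolution probability 0.5 / rate 0.3, colonies-mean-cost coefficient
0.2); non-finite costs are treated as +∞.

After ICA, rules with v < 0.05 are pruned, and so are *dead* rules — rules
whose maximum normalised firing on the training data is below 1e−3. A dead
rule's consequent columns are numerically zero, its weights are
unidentifiable, and its behaviour wherever it later fires is undefined;
removing it is the model-validity counterpart of the weight threshold. The
consequents are re-solved on the survivors.

## Numerical choices

* The inner-loop least squares uses normal equations with a relative ridge
  of 1e−10 (Cholesky, LAPACK fallback) for speed; the final solve
  equilibrates columns, drops columns below 1e−6 of the largest, and
  truncates at condition 1e−8, giving a minimum-norm solution for
  rank-deficient systems (a warning is emitted).
* **Cancellation guard.** A solution whose per-rule contribution
  v_l·μ̄_l·η_l exceeds 5× the target's maximum magnitude on the *training*
  data relies on near-cancellation between rules; the cancellation is exact
  only on the training set and can explode off-support. The final solve
  escalates a ridge (1e−8 … 1e−2, relative) until every rule's contribution
  is data-scaled. In the replication runs this guard engages on a small
  minority of seeds and converts occasional order-of-magnitude prediction
  blow-ups into ordinary-quality fits.
* Firing normalisation guards a total below 1e−12 by equal blending.
* Model serialisation is JSON; Python float repr round-trips exactly, so a
  saved and reloaded model predicts bit-identically.

## Benchmarks

All simulated benchmarks are regenerated from their governing equations:

* **Piecewise function** — 200 pairs x ~ U[−10, 10] through the three-branch
  map (two linear branches continuous at x = −2, a jump of height 10 at
  x = 0, a smooth damped-oscillation branch on [0, 10]). The source defines
  only this one sample; the package evaluates on an independent 200-pair
  draw from the same distribution, the standard distributional meaning of
  test data. Note the jump makes the test error acutely sensitive to
  whether a test point lands inside the fuzzy switching window at x = 0.
* **Plants 2-1 … 2-5** — exact difference-equation recursions from zero
  initial conditions with divergence detection. Training inputs: 900 steps
  (first 450 iid U[−2, 2], then 1.05·sin(πk/45)) for 2-1; 1000 iid U[−1, 1]
  steps otherwise. Test inputs are the deterministic piecewise-sinusoidal
  signals of the benchmark suite. Regressors follow each plant's own
  difference-equation arguments (series–parallel, i.e. measured past
  outputs; the regressor lists for 2-2…2-5 are not fixed by the benchmark
  definitions, and the equation arguments are the canonical choice). The
  2-5 recursion is the Narendra-type plant whose numerator carries an
  additive input drive; without that term the zero-state response is
  identically zero and no identification task exists.
* **Mackey–Glass** — dx/dt = 0.2x(t−τ)/(1+x(t−τ)¹⁰) − 0.1x(t), x(0) = 1.2,
  x(t<0) = 0, fixed-step RK4 at dt = 0.1 with linear interpolation of the
  delayed state, sampled at unit times; 1200 points, identification window
  t = 124…1123, regressors x(t−6), x(t−12), x(t−18), x(t−24) → x(t), first
  500 retained points train. Halving dt reproduces the series to <1e−3
  before chaotic trajectory divergence amplifies integrator differences
  (sup-norm agreement over the full window is meaningless for a chaotic
  orbit). Optional uniform additive noise is scaled to an exact empirical
  SNR; the evaluation target for noisy variants can be either the noisy or
  the clean series (both conventions are exposed; noisy is the default
  since it is the observable).
* **Gas furnace** — loader for the external two-column (gas rate, CO₂)
  record: 296 rows validated (warning otherwise), regressors y(k−1..3),
  u(k..k−2), chronological halves for train/test. No data is bundled.
* **Synthetic EMG trials** — 796-sample isometric flexion/extension ramp
  trials: triangular torque demand to ±n % MVC over four ramps, two flexor
  (BB, BR) and two extensor (TBL, TBM) envelopes following the rectified
  demand, multiplicative smoothed-noise envelope fluctuation (1 Hz
  4th-order low-pass on rectified noise — the shape of real sEMG
  envelopes), optional inter-muscle crosstalk and monotone power
  nonlinearity, additive torque noise. With noise, crosstalk and
  nonlinearity switched off the torque is an exact linear combination of
  the envelopes (used as a construction check). The generator emulates the
  envelope-level statistics of ramp trials, not raw EMG: no motor-unit
  interference structure, electrode geometry, fatigue or trial-to-trial
  gain drift — results on it bound data-plumbing correctness, not clinical
  performance.

## Replication protocols and budgets

`fjwnn/protocols.py` fixes one protocol per headline benchmark (metric,
data generation, model configuration). Replication uses ten independently
seeded fits per benchmark and reports the mean test error. The GA/ICA
search budgets are reduced from the reference settings (GA 150×12; ICA
population 120–250, 40–60 iterations, scaled to each task's per-evaluation
cost) so that the full seven-benchmark replication runs in roughly fifteen
minutes on one CPU; everything else — sample sizes, excitation signals,
scale range, initialisation, pruning — is the full-scale configuration.
Reduced search budgets raise the variance and the mean of the achieved
error relative to full-budget metaheuristic runs, most visibly on tasks
that need a precisely placed sharp membership boundary (the piecewise
jump).

## Known limitations

* Test inputs for plants 2-2/2-4 drive the outputs outside the training
  envelope (the linear AR dynamics resonate under the slow test sinusoid,
  e.g. plant 2-2 test outputs reach ±5.3 versus ±2.4 in training). The raw
  linear part extrapolates exactly, but the wavelet-modelled nonlinearity
  vanishes off-support, which floors the attainable test error there.
* One-step (series–parallel) prediction only; no closed-loop free-run
  simulation of the identified model.
* The rule weight v and the consequent scale are jointly unidentifiable
  (v·η invariant); v is kept in [0, 1] and pruning acts on v alone.
* The ICA is a serial reference implementation; replicate runs are
  independent and could be parallelised at the process level.
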