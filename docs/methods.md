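# Methods

## Deterministic delay model

Four species — repressor LacI (`r`), activator AraC (`a`), immature GFP
(`g`), mature GFP (`G`) — obey delay differential equations in which each
protein is produced at rate `α_x h(r_τ, a_τ)` with the promoter activity
evaluated `τ_x` minutes in the past, degraded through a shared
Michaelis–Menten proteolysis pathway `γ_x x / (R_0 + r + a + g + G)`,
and diluted at the growth rate `β`; immature GFP matures at rate `λ`
(only `G` is fluorescent).  The composite promoter activity

    h(r, a) = (1/f + a/C_a) / ((1 + a/C_a) (1 + r/C_r)^2)

has basal level `1/f`, saturates at 1 under full activation, and is
repressed quadratically (LacI tetramers occupy two operators).  The three
maximal production rates are tied to one per-plasmid rate `α` by the
plasmid copy numbers and multimer stoichiometries: `α_g = 60α` (monomer
reporter), `α_a = 30α` (dimer), `α_r = 6.25α` (tetramer).  The default
parameter set (the package's reference set) yields a stable limit cycle
with a 41.2-min period; `λ = ln2/10 min⁻¹` and the delays
(5, 5.5, 6 min) are fixed, not fitted.

**Integrator.**  Fixed-step classical RK4 with linear interpolation into
the stored solution for the delayed arguments; constant pre-history,
default `(r, a, g, G) = (0, 10, 0, 0)` (a nonzero activator seed to leave
the trivial fixed point; the attractor is insensitive to the choice).
Default `dt = 0.01` min.  A caveat: when the *total* concentration
approaches zero the shared-proteolysis term approaches its maximal
per-capita rate `γ_x / R_0 ≈ 10^3 min⁻¹` and the equations become stiff;
on the limit cycle the total stays above ~0.06 so `dt = 0.01` is
accurate (period and amplitude change by < 0.2 % under two further step
halvings), but `dt = 0.02` is visibly corrupted and degenerate
near-empty states are handled by clamping at zero.  The zero-production,
zero-history state is exactly invariant.

**Molecule-number scaling family.**  Multiplying
`(α_x, γ_x, R_0, C_a, C_r)` by `Ω` while leaving `f`, delays, `λ`, `β`
unchanged maps any solution `x(t)` to `Ω x(t)`: the wave form is
invariant, absolute numbers scale.  This is exact in exact arithmetic;
in floats, rounding differences are amplified through the sharp
relaxation spikes, so equivalence is asserted to ~1 % of the amplitude
over two periods.

**Fitting.**  Oscillation segments are peak-centred on a ±33-min window
(covering the neighbouring troughs), min–max normalised, averaged, and
re-normalised; the fit error is the relative squared shape mismatch on
the 3-min grid plus the relative squared period mismatch.  Grid points
where the normalised reference is below 0.02 are excluded — the relative
error is undefined at the normalised minimum and numerically explosive
just above it.  The optimiser is gradient descent with finite differences
in log-parameter space (enforcing positivity) and a backtracking line
search; the normalisation removes overall amplitude scale, so only
shape/period-determining parameters (e.g. `C_r`, `f`) are individually
identifiable, which the tests reflect.

## Delayed stochastic simulation

The stochastic model has eight reaction channels: three *delayed*
productions (rate `V α_x h` on concentrations; on firing, a completion
time `t + τ_x` is pushed onto a per-species queue and the count is
incremented only when it pops), four losses (dilution `β` plus shared
proteolysis, evaluated on concentrations), and maturation `g → G`.
Whenever the earliest queued completion precedes the next reaction time
it fires first.  Volume enters as `x → V·R(y/V)` so that production
scales with cell size (replicated plasmids/enzymes) while per-capita
loss rates depend on concentrations.  The production kernel is compiled
with numba; a generic pure-Python event-queue engine over arbitrary
reaction lists serves as an independent cross-check (distributional
agreement is tested against it, and against a Poisson birth–death
oracle, and against the law of large numbers: the ensemble mean at
`Ω = 20` tracks the delay-equation solution).

Single-cell mode fixes `V = 1` with explicit dilution `β` in the loss
propensities — the regime that isolates intrinsic noise.  Ensembles are
initialised at random limit-cycle phases with Poisson counts and with
the delayed-production queue pre-filled as if production had been
running at the phase state (an empty queue would silence production for
the first `τ` minutes and lag the phase).

## Lineage simulation

Each cell grows as `V' = βV` and divides on reaching its own division
size `V_max`; daughters inherit half the volume, a Binomial(n, 1/2)
share of every molecule count, and each queued delayed event with
probability 1/2 (completion times preserved).  Per cell,
`β = β_0(1 + Γ_β η)` (normal, truncated positive) and
`V_max = V_base + Gamma(k, θ)` are redrawn; defaults
`β_0 = 0.0295 min⁻¹`, `Γ_β = 0.099`, `V_base = 4.5 µm`, `k = 2.5`,
`θ = 1`.  A daughter born larger than its drawn `V_max` would have a
negative growth time, so the `V_max` draw is truncated from below at the
birth volume (cells must grow before dividing).  Sister size ratio is
exactly 1/2.

**Volume units.**  Division sizes are in micrometres of cell length, but
the volume multiplying the propensities is dimensionless: cell size
divided by the *mean newborn size* `(V_base + kθ)/2 = 3.5 µm`.  A
typical newborn then has propensity volume 1 (matching the fixed-volume
single-cell mode, and the natural reading of "start at volume 1") and a
typical divider 2.  This convention was chosen because it makes the
single-cell and lineage noise scales commensurate — with raw micrometre
volumes the effective molecule numbers (and hence the meaning of `Ω`)
would silently differ by ~3.5× between the two modes; any fixed
rescaling of the propensity volume is equivalent to rescaling `Ω`.

**Heritable production rates.**  `α_r, α_a, α_g` follow, independently,
the division-time recursion `p' = (q p + (1 − q)⟨p⟩)(1 + Γ η)` with one
deviate per parameter per division and antithetic daughters
`p_{1,2} = m(1 ± Γη)`, which satisfies the sister mean constraint
exactly while each daughter is marginally distributed with CV `Γ`
about `m`.  The stationary law has mean `⟨p⟩` and
`CV² = Γ² / (1 − q²(1 + Γ²))` (for `Γ = 0.12`,
`q = e^{−ln2/5} ≈ 0.87`: stationary CV ≈ 0.25); this closed form is the
Monte-Carlo oracle in the tests.  Progenitors draw their parameters from
the stationary law (50-step burn-in) and their molecule numbers from a
Poisson at a random limit-cycle phase.  `β` and `V_max` are memoryless;
only the production rates are heritable.

## Statistics of branched trajectories

Fluorescence is the mature-reporter concentration `G/V` on the global
3-min frame grid.  Peaks are detected per root-to-leaf branch on a
3-frame moving average with prominence ≥ 20 % of the branch range;
amplitudes are the raw heights at the detected times; peaks and
intervals are de-duplicated across branches sharing their early history
so each oscillation counts once, and peaks before 30 min are discarded
as transient.  Period statistics censor intervals longer than 1.6× the
median: such intervals arise when the detector misses a low peak and
would otherwise count a double period.  CVs use the n−1 sample SD,
pooled across lineages (per-lineage variants agree within 0.1 on
homogeneous data).  The sister correlation `ρ(t)` is the Pearson
coefficient over all pairs `(X_1, X_2)` sampled `t` minutes after their
common division — the first frame after division is lag 3 — with a pair
contributing only until either sister divides again; lineages are
correlated separately and averaged.  Distances for inference:
`|CV_sim − CV_ref|` for amplitude, the `L2` norm of `ρ_sim − ρ_ref`
over the shared 3–30-min lags for correlation.  Distribution comparisons
use the two-sample Kolmogorov–Smirnov test on mean-rescaled amplitudes.

## Noise inference

`scan_grid` fills both distance maps over an `(Ω, Γ)` grid (default
`Ω ∈ {1, 1.5, 2, 2.5, 3}`, `Γ ∈ {0, 0.06, 0.12, 0.18, 0.24}` for the
full model) with deterministic per-cell seeds; failed cells (too few
peaks) carry an infinite sentinel.  `min_contours` takes, per `Ω`
column, the `Γ` minimising each map, with quadratic sub-grid refinement
through the argmin and its neighbours (ties break toward smaller `Γ`).
`intersect_contours` linearly interpolates the contour difference in `Ω`
and returns the sign-change crossing.  Two robustness rules, both
diagnosed on toy-model self-recovery: `Ω` values where *both* contours
sit exactly on a `Γ`-grid boundary are ignored (a saturated argmin
carries no crossing information), and among multiple noisy crossings the
one where both distance maps are smallest wins.  Without a sign change,
a closest approach within half a `Γ`-grid step counts as an
intersection; otherwise the result reports "no intersection" — the
expected, meaningful outcome when the heritable-parameter memory is
removed (`q = 0`): amplitude variability then saturates below the
reference even at the largest `Γ` on the grid while the correlation
contour stays low, and the curves never meet.

## Toy oscillator

The amplitude/phase SDE (`dr = ρ(r_0 − r)dt + Ω^{-1/2}dW_1`,
`dθ = (2π/T)(r_0/r)dt + (r√Ω)^{-1}dW_2`; `ρ = 0.1 min⁻¹`, `T = 41` min,
`r_0 = 1` AU — the unit is arbitrary and cancels in every CV) is
integrated by Euler–Maruyama at `dt = 0.05` min (≤ 0.15 % of the
period; halving `dt` preserves the stationary amplitude variance) with
a reflecting floor at `0.05 r_0` to keep the `1/r` phase drift finite.
With `Γ = 0` the amplitude is Ornstein–Uhlenbeck with stationary
variance `1/(2ρΩ)` — an exact oracle.  Toy lineages divide every
`ln2/β_0 ≈ 23.5` min; daughters copy `(r, θ)` exactly and `r_0` follows
the same homeostatic recursion as the full model's production rates, so
all sister divergence comes from `r_0` resampling plus subsequent
intrinsic noise.  The observable `x = r cos θ` runs through the same
peak/correlation pipeline as the full model, which is what lets the toy
recovery (truth `(200, 0.15)`, grid `Ω ∈ {50…400}`, `Γ ∈ {0.05…0.25}`)
validate the whole inference stack with zero external data.

## Synthetic data

Three generators emit the shared tidy schema.  `full_model` and
`toy_model` wrap the simulators above with a movie-length cutoff;
`parametric_sine` builds branched raised-cosine oscillations with
per-cycle lognormal amplitude jitter, per-cycle normal period jitter,
and a heritable per-cell amplitude factor following the homeostatic
recursion, its memory set from the requested sister-decorrelation
half-life.  Because amplitude targets are defined in terms of the
*measurement pipeline* — the peak detector censors the smallest peaks
and the frame grid clips maxima, biasing a naive generator a few percent
low — the ensemble generator measures itself with the default statistics
and rescales its internal jitter once.  Division rounds are capped at 8
per lineage, emulating a trap's finite capacity (~a few hundred sister
pairs per movie).  Ground truth goes in a sidecar JSON, never in the
table.  What the generators do *not* emulate: segmentation/tracking
errors, photobleaching and background trends, uneven frame intervals,
cell death or filamentation — so passing tests demonstrate correctness
of the analysis pipeline on clean branched data, not robustness to
imaging artefacts.  An Excel reader with an explicit column map ingests
spreadsheet-style tables into the same structures.

## Problem sizes and seeds

Desk-scale defaults, chosen to keep every Monte-Carlo standard error
well inside the tolerances asserted on it: single-cell sweeps use 100
cells × 500 min per `Ω`; lineage statistics 30–50 lineages × 6
generations (≈ 2–3·10³ pooled peaks); inference scans 10 lineages × 5
generations per grid cell; toy recovery 80 reference and 40 simulation
lineages per cell.  Every stochastic entry point takes an explicit seed
and derives per-lineage/per-cell streams from it via `SeedSequence`, so
identical calls are bitwise reproducible.

## Known limitations

- In the fixed-volume single-cell regime the model's period variability
  at `Ω ≈ 0.9` is CV ≈ 0.25–0.30 (amplitude CV ≈ 0.39–0.45), i.e. the
  amplitude-CV and period-CV levels quoted for that regime in the
  literature on this circuit are reached here only at `Ω ≈ 0.2–0.3`;
  the lineage-mode statistics, by contrast, agree closely at the quoted
  `Ω`.  The simulator itself checks out against the master equation
  (law-of-large-numbers, birth–death and standard-SSA cross-checks), so
  this reflects the printed model specification, not the implementation.
- Under strong repression (low `C_r`) the deterministic attractor loses
  simple periodicity (irregular large-amplitude bursting); the window
  period declines only to ≈ 33 min.  The low-IPTG operating point is
  therefore calibrated on the *stochastic* mean period — the observable
  — and the predicted amplitude CV there (≈ 0.6–0.69) carries a heavy
  tail from the bursting backbone and lands somewhat above the
  historical prediction for this condition; the predicted period CV and
  mean period are reproduced.
- At the fitted noise point the simulated period CV is ≈ 0.12–0.13,
  marginally above the ≈ 0.10–0.11 reference level; the statistic grows
  slightly with ensemble size (heavier amplitude tails enter the pool),
  so small-budget runs fluctuate lower.
- Proteolysis competition counts only free proteins; molecules inside
  the delayed-production queue are invisible both to degradation and to
  fluorescence.
- No asymmetric division, cell death, trap geometry or washout.
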