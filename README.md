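# osclineage

Stochastic lineage modeling and noise inference for a synthetic
dual-feedback gene oscillator.

## The problem

Synthetic gene oscillators fluctuate: in time-lapse microscopy of the
AraC/LacI dual-feedback circuit, the oscillation *period* of the GFP
reporter is tight (CV ≈ 0.1) while the *amplitude* varies wildly
(CV ≈ 0.5), and sister cells remain strongly correlated for tens of
minutes after division.  No single noise source explains all three
observations.  This package implements the full modeling chain needed to
dissect them:

- a **deterministic delay model** of the circuit, with LacI (`r`), AraC
  (`a`), immature GFP (`g`) and mature GFP (`G`) produced from a shared
  hybrid promoter with activity

  `h(r, a) = (1/f + a/C_a) / ((1 + a/C_a)(1 + r/C_r)^2)`,

  transcriptional delays `τ_x`, shared Michaelis–Menten proteolysis
  `γ_x x / (R_0 + r + a + g + G)`, GFP maturation `λ` and dilution `β`;
- a **delayed stochastic simulation algorithm** (Gillespie with an event
  queue for delayed productions) whose molecule-number scale is set by
  `Ω`: rates and affinities are multiplied by `Ω` so the deterministic
  wave form is unchanged while absolute copy numbers — and hence the
  intrinsic noise — scale with `Ω`;
- a **lineage simulator** with exponential volume growth, division at a
  sampled size, binomial partitioning of all molecules *and* of the
  queue of in-flight delayed productions, and heritable production rates
  resampled at each division by the homeostatic recursion
  `p' = (q p + (1 − q) ⟨p⟩)(1 + Γ η)` with sister mean constraint
  `(p_1 + p_2)/2 = q p + (1 − q) ⟨p⟩`;
- **summary statistics** of branched trajectories (pooled amplitude and
  period CVs, sister-cell Pearson correlation `ρ(t)` after division);
- a **two-statistic inference** of the intrinsic scale `Ω` and the
  extrinsic parameter-variability CV `Γ`: scan simulations over an
  `(Ω, Γ)` grid, take the per-`Ω` curve of `Γ` minimising
  `|CV_sim − CV_ref|` and the curve minimising the `L2` distance of
  `ρ(t)`, and intersect the two curves;
- an **amplitude/phase toy oscillator**
  `dr = ρ(r_0 − r)dt + Ω^{-1/2} dW_1`,
  `dθ = (2π/T)(r_0/r)dt + (r√Ω)^{-1} dW_2`
  used to validate the inference end to end against known ground truth.

It is aimed at quantitative/systems biologists who want to simulate
dividing-cell gene circuits, compute lineage statistics from tabular
fluorescence data, or estimate noise levels by summary-statistic
matching.

## Worked example

`examples/03_lineage_simulation.py` simulates 20 lineages of 6
generations at the fitted noise point (`Ω = 2.1`, `Γ = 0.12`,
`q = 2^{-1/5}`, a five-generation parameter memory):

```
amplitude CV          : 0.50
period CV             : 0.13
mean period           : 39.2 min
sister corr at 3 min  : 0.99
sister corr at 24 min : 0.78

wrote lineages_fitted.csv (tidy schema, one row per cell frame)
```

Amplitude variability is large while the period stays tight, and sisters
are nearly identical right after division, decorrelating over tens of
minutes — the combination that requires *both* intrinsic molecule-number
noise and heritable parameter variability.  The CSV uses the shared tidy
schema (`lineage_id, cell_id, parent_id, birth_time_min,
division_time_min, frame_time_min, fluorescence`), identical for
simulated and experimental-style tables, so
`osclineage.read_lineage_table` + `osclineage.summarize` treat both the
same way.  The other examples cover the deterministic limit cycle
(41-min period), the single-cell intrinsic-noise sweep (amplitude
CV ≈ 0.44/Ω), toy-model noise recovery, and synthetic table generation.

A thin CLI wraps the same workflows:

```bash
osclineage run toy-recovery --seed 1 --out results/toy
osclineage synth --generator parametric_sine --out results/synth
osclineage stats results/synth/lineages.csv
```

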