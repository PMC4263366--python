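# Methods note

This note records what the package computes, the model behind the toy
generators, the parameter and numerical choices, and the known limitations.
It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute at runtime.

## Scope

Two layers:

1. **Downstream arithmetic on packaged tables.** Per-sugar free energies in
   vacuum, water and two bound poses (with error bars), experimental anomer
   ratios and Michaelis constants are shipped as CSV data. Everything
   derived from them — relative solvation, anomer differences, deviation
   statistics, ranges, enantiomer reports, Km and ratio conversions,
   anomer-averaged binding — is recomputed, never stored.
2. **Estimator machinery validated on a toy system.** Zwanzig one-step
   perturbation, reference transfer and multi-reference combination,
   correlated-error estimation, umbrella reweighting of observables,
   reactive-pose fractions, frame classification, occurrence statistics,
   ring-conformation classification, hydrogen placement and
   unbound-trajectory filtering.

## Stereodescriptor model

Each of the five stereocenters carries an improper dihedral with minimum at
ξ₀ = ±35.264° and force constant k_ξ = 0.102 kJ mol⁻¹ deg⁻². Digit 2 of
the chirality code means ξ₀ = +35.264°, digit 4 means −35.264°. The state
index is `1 + 4b₁ + b₂ + 8b₃ + 2b₄ + 16b₅` with `b_k = 1` where digit k is
4; enantiomers are digit swaps, hence index pairs `(i, 33−i)`. Frame
classification assigns digit 2 when ξ ≥ 0 (the tie at exactly zero is a
measure-zero event, resolved deterministically).

Reference levels soften the real topology stepwise:

- `a`: all five improper terms removed (5 modified terms);
- `ab`: additionally six torsional barriers lowered
  (2×2.09→0.418, 2×5.92→1.05, 2×3.77→1.05 kJ/mol; 11 terms);
- `abc`: additionally six bond-angle terms softened
  (380→285 and 5×320→285 kJ/mol; 17 terms).

## Toy Hamiltonian and sampler

Per center, the environment adds a quartic double well
`B·((ξ/ξ₀)² − 1)²` with default barrier B = 5 kJ/mol ≈ 2 kBT, so both
wells are visited frequently; `chiral_site` environments add per-center
step biases `b_k·1[ξ_k > 0]`, and an optional coupling term (default 0)
breaks separability. With zero coupling the Boltzmann distribution
factorizes, so per-coordinate 1-D quadrature (6001-point grids; error
≤ 0.01 kJ/mol) yields exact state free energies and well populations.
These quadrature oracles — plus a discrete finite-state system with exact
partition functions — back the estimator tests.

The sampler is plain Metropolis with per-coordinate Gaussian proposals,
widths auto-tuned to ~40 % acceptance during a 5 % burn-in (discarded),
parallel coordinate updates when the Hamiltonian is separable, and a
deterministic stream per seed. One sweep is one stored frame, dt = 0.5 ps
nominal.

The probe-distance surrogate `d_x = baseline_x + offset_x·1[ξ_x>0] + ε`,
ε ~ N(0, σ²), truncated below at 0.05 nm, ties each site to one
stereocenter so reactive fractions (strict `d < 0.3` nm) have closed-form
ground truth under any indicator perturbation.

## Estimators and error model

- Zwanzig averages are computed via log-sum-exp; `+inf` perturbation
  energies are treated as zero-weight (unsampled) frames. An estimate is
  flagged *unsampled* when no frame carries weight, and *unreliable* when
  a single frame carries more than half the total weight.
- Error bars use the statistical-inefficiency model `g = 1 + 2τ`, with τ
  from the FFT autocorrelation function truncated at its first non-positive
  value, `stderr = sqrt(g·var/n)`, propagated through the logarithm by the
  delta method. Reweighted observable averages use the delta method on
  `w(Q − ⟨Q⟩)/w̄`.
- Reference transfer (free energies estimated against one softened
  reference carried onto another) is frame-algebraic, so cycle closure is
  exact; transfers whose importance weights have effective sample size
  below 10 are flagged.
- Multi-reference combination exponentially averages m estimates with a
  1/m normalization; unsampled members contribute zero weight (an all-but-
  one-unsampled combination therefore shifts by +kBT ln m).

## Temperatures and conversions

Simulation-derived quantities use 300 K. Conversions of experimental data
use 303.15 K: anomer ratios via ΔG_(β−α) = −kBT ln(β/α) and Michaelis
constants via ΔΔG_bind = kBT ln(Km/Km_ref). Anomer averaging uses
ΔG = −kBT ln(½(e^(−ΔG_α/kBT) + e^(−ΔG_β/kBT))) at 300 K.

## Ring conformations

Cremer–Pople puckering coordinates are computed over the ring ordering
O5, C1…C5 with the plane normal oriented so that the canonical ⁴C₁ chair
maps to θ < 45° and ¹C₄ to θ > 135°; 90° ± 45° is partitioned into the six
boat and six twist-boat sectors on 30° phase boundaries. The label mapping
was anchored by constructing ideal geometries for each conformer and
verifying the classifier recovers all 14 labels.

## Generator realism and limitations

- The toy system reproduces the *structure* of the analysis (soft chiral
  reference, reweighting to 32 states, distance-gated reactivity), not the
  physics of a solvated sugar or an enzyme site. Absolute toy free
  energies are meaningless; only estimator-versus-oracle agreement is.
- Overlap between one softened reference and a stiff real target is
  genuinely poor in this regime: the reference spreads each center across
  both wells (per-well width ≈ 11°) while a real topology pins all five
  (width ≈ 4.9°), so importance-weight effective sample sizes are of order
  tens at 10⁵ frames. Free-energy estimates still agree with quadrature
  within their error bars at the tested seed, but in this heavy-tailed
  regime the exponential average carries a small positive bias and the
  error bar is itself noisy; re-seeded runs can show worst-of-32 deviations
  of several claimed standard errors (demonstrated in
  `examples/02_toy_osp_validation.py`, which prints per-state effective
  sample sizes). This is the known OSP pathology that motivates sampling
  several reference levels and combining them.
- Property averages (as opposed to free energies) are validated under
  indicator perturbations with adequate overlap; reweighting a property
  from the soft reference onto a full stiff target is outside the
  estimator's reliable regime at these sample sizes and is flagged by the
  ESS/weight diagnostics rather than silently reported.
- The published table values carry one-decimal rounding; derived
  identities are therefore only reproducible to the propagated rounding
  (e.g. differences of two one-decimal numbers match within 0.1).
- The distance surrogate is an indicator plus Gaussian noise; it has no
  spatial correlation structure and no pose geometry. Hydrogen placement
  operates on explicit coordinates and is tested on constructed geometries
  only.
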