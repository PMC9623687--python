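# Methods

## Models

All four reliability paths fit the same single-record animal model with an
unknown overall mean μ and heterogeneous residual variances
R_ii = σe²/w_i (w_i the record weight):

1. **GBLUP (exact).** Animal effects u ~ N(0, G_w σu²) with
   G_w = (1−w)·Zc·Zc′ + w·A₂₂. The MME coefficient matrix is
   [[1′R⁻¹1, 1′R⁻¹], [R⁻¹1, R⁻¹ + G_w⁻¹λ]]; PEV_j is the j-th diagonal of
   the animal block of its inverse, σ_j² = (G_w)_jj, and
   r²_j = 1 − λ·PEV_j/σ_j² with λ = σe²/σu². This path is the oracle the
   approximations are judged against.
2. **SNP-BLUP with RPG (exact).** Regression on Z = [√(1−w)·Zc, √w·L]
   with i.i.d. effects g_R ~ N(0, I σu²), L the lower Cholesky factor of
   A₂₂. Then Var(Z g_R) = G_w σu², so this model is equivalent to GBLUP and
   serves as an independent algebraic cross-check: the test suite verifies
   equality of reliabilities to 1e-8.
3. **MC-SNP-BLUP (comparator).** Marker effects stay exact (m equations);
   only the n RPG equations are replaced by n_mc Monte Carlo regression
   columns √w·L·z_i/√n_mc. MME order 1 + m + n_mc.
4. **Full MC-SNP-BLUP (the approximation of interest).** Both genetic
   components are sampled: column i of U is (Zc·g_i + a_i)/√n_mc with
   g_i ~ N(0, (1−w)·I_m) and a_i = √w·L·z_i, a draw from N(0, G_w/n_mc).
   MME order 1 + n_mc, independent of m and n. PEV_j = t_j·C_uss·t_j′ with
   t_j row j of U.

### Conventions that required a decision

- **Square-root blend.** The SNP-BLUP design matrix uses √(1−w) and √w on
  the two blocks. Linear (un-rooted) coefficients would give
  Var(Z g_R) = ((1−w)²·ZcZc′ + w²·A₂₂)σu² ≠ G_w σu², breaking the
  equivalence with GBLUP; the square-root form is the only internally
  consistent choice and the equivalence test enforces it.
- **1/√n_mc column scaling of U.** With s ~ N(0, I σu²) the model needs
  E[UU′] = G_w; unscaled columns would make UU′ grow linearly in n_mc and
  leave both PEV and σ_j² on the wrong scale. Columns therefore always
  carry the 1/√n_mc factor (`column_scaled` on `MCSampleMatrix`).
- **Exact σ_j² sign.** The exact animal variance is
  (1−w)(ZcZc′)_jj + w·(1 + F_j), because the A₂₂ diagonal of an animal
  with inbreeding coefficient F_j is 1 + F_j; a `paper-literal` convention
  switch provides the 1 − F_j variant for comparison with sources that
  print it that way. The default is verified against diag(G_w) exactly.
- **σ_j² default is the MC diagonal** (row norms of U), not the exact
  value: the Monte Carlo errors in the PEV numerator and the σ_j²
  denominator are positively correlated and partially cancel, so the MC
  diagonal gives smaller maximum differences and MSE. The exact mode is
  retained behind `sigma_mode="exact"`.

## Solvers

- The exact paths use dense symmetric (Cholesky) factorisations
  throughout; no iterative solvers. G_w inversion tries a jitter ladder
  0, 1e-10, 1e-8, 1e-6 — a pedigree A₂₂ is positive definite in exact
  arithmetic, so jitter only absorbs float noise, and the jitter used is
  logged. Note that at w = 0 with observed allele frequencies G_w is
  exactly singular (centering makes every row of Zc·Zc′ sum to zero);
  pure-marker models should use the SNP-BLUP path, which needs no G
  inverse.
- **Direct full-MC route:** materialise the order-(1 + n_mc) coefficient
  matrix, form C_uss as the inverse of the Schur complement of the mean
  equation, and evaluate the PEV quadratic forms t_j·C_uss·t_j′ in two
  steps from left to right, never forming U·C_uss·U′.
- **Reduced full-MC route:** when n_mc ≫ n the same quadratic forms are
  computed through an exact rank reduction. Absorbing the mean gives
  C_uss = (λI + U′MU)⁻¹ with M = R⁻¹ − R⁻¹1·1′R⁻¹/(1′R⁻¹1); writing
  M = KK′ (K = R⁻¹ᐟ²(I − uu′), u the normalised R⁻¹ᐟ²1) and applying the
  push-through identity yields

      U C_uss U′ = [P − P·K(λI + K′PK)⁻¹K′·P]/λ,   P = UU′,

  so only n × n systems are factorised. The two routes agree to 1e-9 in
  the tests (machine precision in practice); `engine="auto"` switches to
  the reduced route above n_mc = 3000. This keeps a 20,000-sample sweep at
  desk scale in seconds instead of minutes.

## Random numbers

Every sampler draws from `numpy` PCG64 generators seeded through
`SeedSequence(seed, spawn_key=...)` with one substream per MC column, so a
column's values depend only on its index — results are independent of
generation order and a prefix of columns is reproducible across different
n_mc (up to the global 1/√n_mc factor). Distinct spawn keys separate the
full-MC sampler, the RPG-only sampler, and the three simulator stages.

## Synthetic data

The generator emulates the world the models assume, nothing more:

- discrete non-overlapping generations with random mating (uniform sire/dam
  from the previous generation, sire ≠ dam), founders unrelated and
  non-inbred;
- unlinked biallelic markers transmitted by Mendelian gene dropping, with
  founder frequencies uniform on [0.05, 0.5]. Linkage is deliberately
  absent: nothing in the reliability machinery uses LD, and unlinked loci
  make the marker-relationship/pedigree consistency exact in expectation;
- phenotypes y = μ + u + e with unit phenotypic variance (σu² = h²,
  σe² = 1 − h²) and the true genetic value built from the same
  √(1−w)/√w blend the models assume; record weights default to 1.

Defaults (300-animal pedigree, last 150 genotyped, 400 markers, h² = 0.3)
are a desk-scale stand-in for a dairy evaluation; at this size every model
path runs in seconds, so exact and approximate reliabilities can be
compared directly.

**What a green test does not establish:** real populations have LD,
selection, overlapping generations and multi-breed structure, all of which
the generator omits and all of which the source analyses on real data show
can raise the MC sample count needed for a given accuracy. Conclusions here
are about the correctness of the machinery and the qualitative behaviour of
the approximation, not about how many samples a national evaluation needs.

### A note on the inflation slope

On real evaluations the regression of exact on approximate reliability has
a slope slightly above 1: the approximation overestimates most for
low-reliability animals, compressing the approximate scale from below. That
behaviour needs a wide spread of exact reliabilities. With the generator's
homogeneous information (every animal one unit-weight record, exact r²
spanning only ≈ 0.33–0.53), the per-animal MC noise instead acts as
classical errors-in-variables on the regressor and attenuates the slope
below 1, even though the approximation is still inflated on average (mean
approx − exact ≈ +0.005 at n_mc = 2000, shrinking with n_mc). Giving
animals heterogeneous record weights (0.2–50, exact r² 0.25–0.93) restores
the slope-above-1 behaviour and its monotone decline toward 1 with n_mc;
that check is part of the test suite. The homogeneous-world acceptance
check of the slope direction is therefore expected to fail and is kept as
an honest record of this property.

## Numerical and interface choices

- IDs are strings matched exactly across pedigree, genotype and phenotype
  files; the genotype-file row order is the canonical genotyped-animal
  ordering everywhere, preventing silent misalignment.
- Unknown parents are base animals; an animal with any unknown parent has
  F = 0. Parents never listed as animals are added as founders with a
  warning. Inbreeding is computed both from the tabular A diagonal and by
  the Meuwissen–Luo ancestor trace; the two agree to 1e-12 on random
  pedigrees.
- Missing genotypes (codes `5`/`NA`) are imputed to the column mean rounded
  half-up — the simplest deterministic rule; counts are logged. Monomorphic
  markers are dropped under VanRaden method 2 (whose per-marker scale would
  divide by zero) and retained (centering to zero) under method 1, keeping
  each method's m consistent with its own scale.
- Approximate reliabilities are stored raw and may leave [0, 1]; clamping
  is left to reporting layers so that the comparison statistics see the
  approximation as it is.
- Exact reliabilities are returned from models whose MME are positive
  definite by construction; tests assert r² ∈ [0, 1] for the exact paths.

## Known limitations

- Dense algebra only: pedigrees and marker sets are desk-scale; no sparse
  A⁻¹ (Henderson) construction, no iterative/PCG solvers, no out-of-core U.
- Single trait, one record per animal, overall mean as the only fixed
  effect; no genetic groups; non-genotyped animals are out of scope.
- The RPG-only MC comparator is implemented for equal-MME-size comparisons,
  not optimised for large m.
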