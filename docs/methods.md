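# Methods

This note documents the models implemented in `hairpinxb`, the assumptions
behind them, the synthetic stated world used for validation, and the
numerical choices a maintainer would want to know about.  No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
compute.

## The system being modelled

A ten-residue peptide folds cooperatively into an antiparallel β-hairpin
around a central type II′ turn (a D-Pro–Gly mimic at residues 5–6).  An
aryl iodide side chain on residue 3 (halogen-bond donor) and an ether
oxygen on residue 8 (acceptor) can form a cross-strand I···O halogen bond
only in the folded state.  A reference compound in which the acceptor
oxygen is replaced by a methylene folds by the same cooperative forces
minus the halogen bond, so differences in folding thermodynamics between
the two compounds report on that single weak interaction.

## Two-state melting analysis

**Model.** Fast exchange between one folded and one unfolded state gives

    δ_obs(T) = δ_U + (δ_F − δ_U) / (1 + exp(−ΔH_m/R · (1/T − 1/T_m)))

with terminal shifts δ_U, δ_F, melting temperature `T_m` (folded fraction
0.5) and `ΔH_m` the unfolding enthalpy at `T_m`, assumed
temperature-independent (no ΔCp term, no pre/post-transition baselines —
both are out of scope by design).  `δ → δ_U` as `T → ∞`.

**Fitting.** Nonlinear least squares (`scipy.optimize.least_squares`) with
three starts: `T_m` at the 1/6, 1/2 and 5/6 points of the temperature
range, `ΔH_m = 25 kJ/mol`, terminals from the coldest/hottest 10% of the
data; the best SSE wins.  `T_m` is bounded to the observed range ± 50 K.
Series with less than 0.01 ppm total shift change raise a "no transition"
error.  The global fit first fits every proton individually, rescales each
series to folded fraction with its own terminals (normalisation to each
proton's maximum shift change), then fits one shared `(T_m, ΔH_m)` to the
pooled normalised points with terminals pinned at 0/1.  Protons whose
individual fit fails are excluded with a warning.

**Derived quantities.** Folded fraction `f(T) = 1/(1 + exp(−ΔH_m/R(1/T −
1/T_m)))`; folding constant `k_F = f/(1−f) = (δ_U − δ)/(δ − δ_F)`;
`ΔG°(T) = −RT ln k_F` (route a) or `ΔH_m − TΔS_m` from tabulated values
(route b) — both routes are exposed and neither is silently preferred,
because entropies from the two routes need not agree on real data.  The
van 't Hoff regression of `ln k_F` on `1/T` (points with `f` strictly in
0.02–0.98) returns both the intercept entropy and the slope enthalpy as a
cross-check; for exact two-state data they reproduce `ΔH_m/T_m` and
`ΔH_m` identically.

**Relative stability.** For two compounds observed at matched temperatures
the bilinear products

    y_t = (δ̄_U1 − δ_1)(δ_2 − δ̄_F2),   x_t = (δ_1 − δ̄_F1)(δ̄_U2 − δ_2)

satisfy `y = K x` exactly when `k_F1 = K · k_F2`; `K` is the slope of the
zero-intercept least-squares line (the identity forces y = 0 at x = 0).
`ΔΔG = −R·T_m2·ln K` with `T_m2` the reference compound's melting point.
This form was chosen as the unique bilinear rearrangement whose slope is
`k_F1/k_F2`; it is verified in the tests by the equal-enthalpy closed form
`K = exp(ΔH/R (1/T_m2 − 1/T_m1))`, for which the points are exactly
collinear.

**Temperature coefficients.** `|dδ/dT|` in ppb/K from an ordinary linear
fit; bands < 3 (intramolecular H-bond), 3–5 inclusive (dynamic
equilibrium), > 5 (solvent exposed).  Exact 3 and 5 are assigned to the
middle band.

## NOE build-ups and restraints

The cross-relaxation rate σ is the initial slope of the build-up,
estimated by zero-intercept regression of intensity on mixing time
(intensity is zero at τ_m = 0 by construction).  When no window is given,
the largest prefix of mixing times whose regression keeps every pointwise
relative residual below 10% is used (at least three points; otherwise a
"no linear regime" error).  With strictly curved data this rule still
carries the curvature bias of the retained prefix — for
`I = στ(1 − 0.4τ)` over 0.1–0.7 s the closed-form bias is ≈ 10% — so the
tests freeze the algebraically correct value rather than an optimistic
one.  Standard errors use the HC3 leverage-adjusted (heteroskedasticity
robust) form: build-up noise is typically multiplicative, and the
homoskedastic formula was measured to undershoot the true slope spread by
~25% on such data.  Calibration `r_ij = r_ref (σ_ref/σ_ij)^{1/6}` against
a geminal methylene pair at 1.78 Å (configurable); tolerances
`max(0.1 r, 0.2 Å)`.  The Karplus curve defaults to the Vuister–Bax
`³J(H^N,H^α)` parametrisation `(A, B, C) = (6.51, −1.76, 1.60)` Hz with
phase `φ − 60°`; both the reference pair and coefficients are
configuration, not inference.

## NAMFIS deconvolution

Populations over a rigid pool minimise

    SSE(p) = Σ_k ((obs_k − pred_k)/tol_k)²,  p ≥ 0, Σp = 1,

with `⟨r⟩ = (Σ p_i r_i⁻⁶)^{−1/6}` (isolated spin pair, slow tumbling;
exponent configurable to −3) and `⟨J⟩ = Σ p_i J(φ_i)`.  Tolerance
weighting makes distances (Å) and couplings (Hz) commensurable.  The
solver is SLSQP from a uniform start plus 10 seeded Dirichlet restarts;
ties within 1e−10 of the best SSE break towards fewer non-zero conformers,
then the lexicographically smallest support, so output is deterministic.
One prune-and-refit pass zeroes populations below 1% and refits the
survivors.  A jackknife over random restraint subsets reports the median
and IQR of each population.  Correctness is anchored by a brute-force
oracle: on small instances the optimiser must match or beat an exhaustive
0.02-resolution simplex grid over every 3-conformer sub-pool.

## RDC analysis

`¹D = (¹T − ¹J)/n_H` with uncertainty `√(σ_T² + σ_J²)/n_H`; the
multiplicity scaling reproduces the printed methyl value of the measured
coupling table, and CH₂ groups are treated as the mean of their two bond
couplings (RDCs are linear in the design row, so group averaging averages
rows).  For a unit bond vector the design row is the Losonczi
parametrisation `(c_y²−c_x², c_z²−c_x², 2c_xc_y, 2c_xc_z, 2c_yc_z)` with
Saupe 5-vector `(S_yy, S_zz, S_xy, S_xz, S_yz)`; `D_max = −22 700 Hz` for
a 1.09 Å C–H (the tensor absorbs scale, so only its physical
interpretation depends on this constant).  The tensor is solved by
(weighted) SVD; rank below 5 raises an error naming the null direction.
Quality metrics: Cornilescu `Q = rms(D_obs − D_calc)/rms(D_obs)` and the
condition number `σ_max/σ_min` of the weighted design.  Eigenvalues are
ordered `|A_xx| ≤ |A_yy| ≤ |A_zz|`; `D_a = D_max A_zz/2`, rhombicity
`R = (2/3)(A_xx − A_yy)/A_zz` (bounded by 2/3).

**Ensemble fit.** One shared tensor for all conformers (a single
weak-alignment medium; per-conformer tensors are not modelled) with
populations on the simplex, solved by alternating linear solves — tensor
by least squares on population-averaged rows, populations by anchored
non-negative least squares — iterated to a χ² change below 1e−8 from 10
seeded starts, populations floored at 1e−6 during iteration to avoid
degenerate averaging.

**Model selection.** For sizes m = 1…max, the best m-conformer sub-ensemble
(exhaustive up to 15-conformer pools and m ≤ 4, greedy forward selection
beyond) is scored as `χ² + λ(5 + m − 1)`.  The default penalty is the risk
inflation criterion `λ = 2 ln(pool size)`: each added conformer is the
best of combinatorially many candidate subsets, so the spurious χ² gain
per step scales with the log of the number of candidates and the AIC value
λ = 2 was measured to overfit (it selected oversized ensembles in ~40% of
noisy replicates where RIC stays consistent).  AIC and BIC remain
available by configuration.

## Synthetic stated world

All validation data are generated with known truth:

* **Chains** are built by natural-extension-of-reference-frame placement
  with ideal geometry (N–Cα 1.458, Cα–C′ 1.525, C′–N 1.329, C–H 1.09 Å;
  backbone angles 111°/117°/121°), one pseudo side-chain CB with a geminal
  HB₁/HB₂ pair per residue, iodine on residue 3 and ether oxygen on
  residue 8.  Requested dihedrals are realised exactly.  The folded
  template's dihedrals (β strands around a type II′ turn) were tuned once
  against the fold criteria and frozen.
* **Pools**: folded conformers are the template plus Gaussian dihedral
  jitter (default 8°), *rejection-sampled* against the fold criteria —
  independent per-dihedral jitter otherwise frays the hairpin through the
  strand lever arms, whereas force-field pools relax perturbed structures
  back into their basin.  Unfolded conformers draw φ/ψ from broad β and α
  basins (60/40 mixture) and are rejected in the rare case they fold.  A
  configured fraction of folded conformers (default 0.55) is built
  halogen-bonded with I···O in 2.9–3.4 Å and C–I···O in 145–175°.
* **Observables** come from the same forward models the analysis inverts:
  Eq.-type melt curves on a 218–348 K grid in 10 K steps, build-ups
  `I = στ(1 − κτ)` at seven mixing times 0.1–0.7 s with σ ∝ ⟨r⟩⁻⁶,
  RDC tables `¹T = ¹J + n_H D` from a fixed Saupe 5-vector chosen to give
  couplings within the −68…+58 Hz envelope of a weak lyotropic medium.

A green closed-loop test therefore establishes that the estimators invert
their own forward models correctly and consistently (melt, NAMFIS and RDC
folded fractions all within 0.1 of a 0.5 truth on noise-free data); it
does **not** establish robustness to model misspecification — real data
have baseline drifts, spin diffusion, internal dynamics (S² < 1), and
conformer pools that do not contain the true structures.

## Degenerate inputs and tie-breaks

Monotone-flat melt series, build-ups with no linear prefix, rank-deficient
RDC vector geometries, empty pools and off-simplex populations all raise
typed errors naming the offending quantity.  Distances are symmetric by
construction; dihedrals follow the IUPAC sign convention in (−180°, 180°];
classification is pure and deterministic.

## Known limitations

* No ΔCp or three-state folding models; the two-state form is assumed.
* No relaxation-matrix treatment of spin diffusion; initial-rate only.
* Rigid-pool assumption in NAMFIS; restraint tolerances are the only
  uncertainty model.
* Shared-tensor assumption in the RDC ensemble fit.
* The identifiability of sub-ensemble folded shares depends on the number
  and diversity of measured vectors; the default synthetic set (10 Cα–Hα
  plus 10 CB methylenes) was chosen because sparser sets leave the joint
  population/tensor problem underdetermined.
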