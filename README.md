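# hairpinxb

Quantifying a single, very weak non-covalent interaction in solution — here
an intramolecular I···O halogen bond worth well under a kilojoule per mole —
is beyond the reach of any one NMR observable.  `hairpinxb` implements the
combined strategy for doing it anyway: embed the putative halogen-bond donor
and acceptor into a short peptide that folds cooperatively into a β-hairpin,
then characterise the folding equilibrium three independent ways and let the
difference to a non-bonding reference compound isolate the one interaction
of interest.

The package is aimed at NMR spectroscopists and molecular modellers working
on weak interactions and conformational ensembles.  It provides:

* **Two-state melting analysis** (`hairpinxb.melting`).  Observed chemical
  shifts follow
  `δ(T) = δ_U + (δ_F − δ_U) / (1 + exp(−ΔH_m/R · (1/T − 1/T_m)))`;
  per-proton and pooled-normalised global fits yield `T_m`, `ΔH_m`, folded
  fractions, `ΔG° = −RT ln k_F` with `k_F = (δ_U − δ)/(δ − δ_F)`, van 't
  Hoff entropies, amide temperature-coefficient classes, and the
  terminal-free relative stability `K = k_F¹/k_F²` from the slope of the
  bilinear shift products (`ΔΔG = −R·T_m²·ln K`).
* **NOE/J restraints** (`hairpinxb.restraints`).  Initial-rate analysis of
  NOESY build-ups (zero-intercept regression with automatic linear-window
  selection), distance calibration `r = r_ref (σ_ref/σ)^{1/6}`, and the
  Karplus curve `³J(φ) = A cos²(φ−60°) + B cos(φ−60°) + C`.
* **NAMFIS deconvolution** (`hairpinxb.namfis`).  Populations `p ≥ 0`,
  `Σp = 1` over a rigid conformer pool minimising the tolerance-weighted
  SSE between observed and population-averaged observables, with `⟨r⟩ =
  (Σ p_i r_i⁻⁶)^{−1/6}` for NOE distances and linear averaging for
  couplings; multi-start SLSQP with a prune-and-refit pass.
* **RDC analysis** (`hairpinxb.rdc`).  `¹D = (¹T − ¹J)/n_H` extraction,
  Saupe-tensor fits by SVD of the direction-cosine design matrix with the
  Cornilescu Q factor and condition number, joint population/tensor
  ensemble fits by alternating linear solves, and χ²-penalty sub-ensemble
  model selection.
* **Conformer geometry** (`hairpinxb.conformers`).  Multi-model PDB / XYZ
  pools, distances/dihedrals/C–H vectors, β-hairpin fold classification
  (type II′ turn windows, interstrand Cα distances, H-bond proxies) and
  halogen-bond classification (I···O below the Bondi vdW sum of 3.50 Å and
  C–I···O ≥ 140°).
* **Synthetic ground truth** (`hairpinxb.synthetic`).  A NeRF
  internal-coordinate chain builder and generators for every input table,
  so the whole pipeline is testable end to end with known answers.

The fit-shaped operations are scikit-learn-style estimators
(`TwoStateMelt`, `GlobalMelt`, `NamfisDeconvolution`, `SaupeTensorFit`,
`RdcEnsembleFit`, `RdcModelSelector`, `InitialRateFit`) with
`fit`/`predict`, `get_params`/`set_params` and trailing-underscore fitted
attributes; thin module-level functions wrap them.

## Worked example

```python
import numpy as np
from hairpinxb.melting import (ShiftMeltSeries, fit_two_state, delta_g,
                               folded_fraction, two_state_shift)

T = np.arange(218.0, 349.0, 10.0)                  # 218-348 K in 10 K steps
rng = np.random.default_rng(7)
shifts = two_state_shift(T, 8.02, 8.47, 274.0, 23_900.0) \
    + rng.normal(0, 0.005, T.size)                 # synthetic amide proton

fit = fit_two_state(ShiftMeltSeries("Lys7-NH", T, shifts))
dg, kf = delta_g(fit, 298.0)
print(f"T_m  = {fit.tm_:.1f} K")
print(f"dH_m = {fit.dhm_/1000:.1f} kJ/mol")
print(f"folded fraction at 298 K = {folded_fraction(fit, 298.0):.2f}")
print(f"dG(298 K) = {dg/1000:.1f} kJ/mol  (k_F = {kf:.2f})")
```

prints

```
T_m  = 274.1 K
dH_m = 22.1 kJ/mol
folded fraction at 298 K = 0.31
dG(298 K) = 1.9 kJ/mol  (k_F = 0.46)
```

i.e. from 14 noisy shift observations the fit recovers the melting point of
the underlying equilibrium to 0.1 K; the positive `ΔG°` says the compound
is mostly unfolded at room temperature (folded fraction 0.31), 24 K above
its melting point.

## Pipeline CLI

The same analysis is scriptable end to end:

```bash
hairpinxb --seed 7 simulate --out run/ --n-active 3
hairpinxb --seed 7 melt   --table run/vt_shifts.csv --ref-table run/vt_shifts_ref.csv \
                          --temperature 274 --out run/melt.json
hairpinxb --seed 7 noe    --table run/noe_buildups.csv --out run/noe.json
hairpinxb --seed 7 namfis --pool run/pool.pdb --distances run/noe.distances.csv \
                          --jcouplings run/jcouplings.csv --out run/namfis.json
hairpinxb --seed 7 rdc    --pool run/pool.pdb --table run/rdc_table.csv --out run/rdc.json
hairpinxb --seed 7 report --melt run/melt.json --namfis run/namfis.json \
                          --rdc run/rdc.json --out run/report.json
```

`report.json` places the three independent folded-fraction estimates (melt
curve, NAMFIS, RDC sub-ensemble) side by side, together with the
halogen-bonded population and the I···O geometry of the selected
conformers.

## Acceptance script

`scripts/acceptance.py` regenerates a synthetic dataset with known ground
truth and runs the full pipeline (all six stages) from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It logs the recovered folded-fraction estimates and halogen-bond population
to stderr and writes the results object to `--out`.

## Documentation

`docs/methods.md` describes the models, their assumptions, the synthetic
stated world and its limits, numerical choices and known limitations.
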