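# ire1link

A quantitative model of cofactor-controlled activation of **Ire1**, the
endoplasmic-reticulum stress sensor whose kinase/RNase module
(Ire1KR32) assembles into RNase-active oligomers.  The package is aimed at
enzymologists and modelers who want to analyze — or generate realistic
synthetic versions of — the assays used to characterize this system:
single-turnover RNA-hairpin cleavage kinetics, OD500 turbidity
titrations, cofactor dose-responses and competitive-inhibition series.

## The model

Ire1 activation is treated as conformational selection coupled to
cooperative homo-oligomerization:

1. **Conformation.** A free monomer interconverts between an inactive O
   state (αC-helix "out") and an active I state (αC-helix "in"), with apo
   equilibrium constant `L = [I]/[O]`.  ATP-pocket ligands bind either
   conformation of the single pocket competitively: ligand *j* binds the O
   state with dissociation constant `K_O,j` and the I state `c_j`-fold
   more tightly (`c` is the *latch factor*, the model's encoding of the
   β-phosphate latch).  With `x_j = [C_j]/K_O,j`,

   `f_I = L(1 + Σ c_j x_j) / (1 + Σ x_j + L(1 + Σ c_j x_j))`.

2. **Assembly.** Only I-state monomers (apo or ligand-bound) assemble,
   all-or-none, into an oligomer of `m` protomers:
   `A = K_half (I/K_half)^m` with `I = f_I·M`, closed by the mass balance
   `M + A = E_tot`.  `m` is phenomenological and interpolated in `f_I`
   between an apo value and a cofactor-saturated value, reproducing the
   observed Hill coefficients (≈8 apo, ≈3 with ADP·Mg).

3. **Readouts.** RNase: `k_obs = k_bg + k2·A/(K_M + A)` (single-turnover,
   saturating in oligomer).  Turbidity: `OD500 = α·A` with a detection
   floor — which is why RNase detects oligomers at far lower enzyme
   concentrations than turbidity.

Two macroscopic descriptors summarize a cofactor: the potency
`P_cof = k_obs(saturating cofactor)/k_obs(apo)` at the 3 µM standard
condition (a pure measure of conformational responsiveness — it is exactly
1 for a latch-1 binder regardless of affinity), and the apparent binding
constant `K_cof` from the titration midpoint.  The calibrated registry
reproduces the measured panel: ADP·Mg ≈ 200-fold, ATP/AMP/ATPγS ≈ 10,
sunitinib ≈ 30, APY29 ≈ 250; ADPβS·Mg ≈ 1 (binds but does not latch) with
thiophilic-metal rescue ADPβS·Mn ≈ 100 and ADPβS·Cd ≈ 30; phosphorylation
primes the enzyme 40-fold.

## Worked example

```python
from ire1link import (AssayCondition, calibrated_defaults, gen_timecourse,
                      fit_single_exponential, pcof)

cal = calibrated_defaults()           # deterministic calibration (~2 s)
wt, kin = cal.wild_type, cal.kinetics
adp = cal.registry.get("ADP", "Mg")

print(pcof(wt, kin, adp, 3.0))        # 200.00000000000546

cond = AssayCondition(E_tot_uM=3.0, ligands=((adp, 2.0),))
tc = gen_timecourse(cond, wt, kin)    # noiseless cleavage time course
print(fit_single_exponential(tc).summary())
```

```
200.00000000000546
Model: single_exponential
Converged: True   residual norm: 1.34722e-15
parameter           estimate       std err  unit
k_obs              0.0568753      1.47e-16  min^-1
amplitude                0.8      9.75e-16  fraction
```

The potency of ADP·Mg at the standard 3 µM condition is 200-fold, and the
single-turnover time course generated under 2 mM ADP·Mg is fit back
exactly by the exponential estimator: `k_obs = 0.057 min⁻¹` is the rate of
the partially oligomerized 3 µM enzyme, well below the `k2 = 1 min⁻¹`
plateau.

The same workflows are available from the shell:

```bash
ire1link calibrate -o calibration        # parameter + registry YAML, report CSV
ire1link simulate --design cofactor --ligand ADP --seed 7 -o adp.csv
ire1link fit adp.csv --model isotherm
ire1link panel -o panel                  # full cofactor/metal panel report
```

## Layout

- `src/ire1link/linkage.py` — forward equilibrium model and macroscopic
  descriptors (`conformational_partition`, `solve_species`, `pcof`, ...)
- `src/ire1link/estimators.py` — curve-fit models (single exponential,
  binding isotherm, Hill, competitive inhibition) returning `FitResult`
- `src/ire1link/assays.py` — seeded synthetic-assay generators and
  lossless tabular I/O
- `src/ire1link/panel.py` — cofactor/metal registry, deterministic
  calibration, end-to-end panel analysis
- `src/ire1link/cli.py` — `ire1link` command group
- `docs/methods.md` — model assumptions, parameter meanings, calibration
  procedure and known limitations
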