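# Methods

## Model

The package models allosteric activation of the Ire1 kinase/RNase module
as conformational selection coupled to cooperative homo-oligomerization,
at thermodynamic equilibrium throughout (turbidity of these samples is
stable on re-scanning, so no assembly kinetics are modeled).

**Conformational partition.** A free monomer exchanges between an
inactive O conformation and an active I conformation with apo equilibrium
constant `L_apo = [I]/[O]`.  All ATP-pocket ligands compete for the single
pocket; ligand *j* binds the O state with dissociation constant `K_O,j`
(mM) and the I state `latch_j = K_O,j/K_I,j`-fold more tightly.  The
four-state partition function (O, I, O·C, I·C per ligand, statistical
weights 1, L, x, L·c·x) gives the I-state fraction

    f_I = L(1 + Σ c_j x_j) / (1 + Σ x_j + L(1 + Σ c_j x_j)),   x_j = [C_j]/K_O,j.

`f_I` is a monomer property, independent of enzyme concentration.  Ligand
depletion is ignored (free = total): ligands are mM against µM protein,
and a warning is raised when the excess is below 100-fold.

**Assembly.** Only I-state monomers assemble — apo-I and ligand-bound-I
protomers are pooled as equally competent, consistent with the apo
oligomer adopting the same active conformation as the cofactor-bound one.
A single all-or-none m-mer represents the oligomer:

    A = K_half · (I / K_half)^m,     I = f_I · M,

where `A` is the protomer concentration residing in oligomers and
`K_half` (µM) is the I-pool concentration at which A equals the I pool
itself.  The mass balance `M + A(f_I·M) = E_tot` is strictly monotone in
M and solved by bracketed root finding (`scipy.optimize.brentq`, machine
tolerance) on [0, E_tot]; conservation holds to better than 1e-9
relative.

**Condition-dependent assembly order.** The measured cooperativity of
activation differs between apo (Hill ≈ 8) and cofactor-saturated
(Hill ≈ 3) titrations, and no single m reproduces both.  The effective
order is therefore interpolated linearly in `f_I` between `(f_apo,
m_apo)` and `(f_star, m_sat)` and clamped outside; `f_star` marks
conformational saturation of the assembly machinery.  This is a
phenomenological stand-in, not a mechanistic claim.

**Readouts.**

- RNase: `k_obs = k_bg + k2·A/(K_M + A)` — the single-turnover cleavage
  rate saturates (`k2`) once the oligomer exceeds the Michaelis constant
  for RNA binding.  `K_M` is expressed on the oligomerized-protomer
  basis (an oligomer basis would differ by the factor m, absorbed into
  the value).
- Turbidity: `OD500 = α·A`, linear in oligomerized protein, with readings
  below `od_floor` flagged below-detection.

**Macroscopic descriptors.** `P_cof` is the ratio of k_obs at cofactor
saturation to the apo k_obs at the 3 µM standard enzyme concentration;
saturation is evaluated through the analytic limit `f_sat = L·c/(1+L·c)`
rather than a large finite concentration, avoiding grid artifacts.
`P_cof = 1` exactly at latch 1: binding and conformational activation are
uncoupled in the model exactly as they are experimentally.  A closed-form
approximation `P_cof ≈ (ratio of A values at f_sat and f_apo)/(…)`,
valid when `A ≪ K_M` and the oligomer fraction is small, is provided with
an explicit regime flag.  The apparent `K_cof` is the titration midpoint
located by inverse interpolation in log concentration.

## Default parameters and calibration

The tunable parameters, units and defaults:

| parameter | meaning | default |
|---|---|---|
| `L_apo` | apo conformational equilibrium [I]/[O] | 0.258 (calibrated) |
| `K_half_uM` | assembly half point of the I pool | 3.09 µM (calibrated) |
| `m_apo`, `m_sat` | assembly order, apo / saturated | 12 / 5 |
| `f_star` | conformational-saturation knot | 0.28 |
| `k2` | plateau cleavage rate | 1 min⁻¹ (scale convention) |
| `K_M_uM` | half-saturating oligomerized protomer | 0.1 µM |
| `k_bg` | residual rate floor | 3.02e-4 min⁻¹ (calibrated) |
| `α`, `od_floor` | OD per µM oligomer; detection floor | 0.05 OD/µM; 0.01 OD |

`calibrate_defaults` fixes the free parameters deterministically against
the measured anchor table: (i) a three-unknown least-squares stage solves
`(L_apo, K_half, k_bg)` so that the *fitted* Hill coefficients of the
noiseless apo and ADP-saturated OD500 profiles on the standard
0.03–30 µM grid equal 8 and 3 and `P_cof(ADP·Mg) = 200`, with ADP's
conformational saturation pinned at `f_I = 0.30`; (ii) each registry
latch is solved by bracketed root finding for its P_cof anchor (ADPβS·Mg
is set to exactly 1 as the conformationally silent reference); (iii) the
microscopic `K_O` of ATP and ADPβS are solved so that the *simulated*
competition experiment against 0.2 mM ADP returns the measured apparent
K_i values (0.10 and 0.20 mM), and the remaining binding constants follow
the measured relative-affinity statements (AMP tenfold weaker than ATP,
ATPγS twofold, 2'-d-ADP threefold weaker than ADP; synthetic ligands
nominal).  Variant parameter sets encode phosphorylation state and point
mutations purely through `L_apo` (unphosphorylated solved for
P_cof(ADP) = 5; E715K set qualitatively lower) or per-variant latches
(D828A: ADP latch 1, APY29 latch solved for P_cof = 10).

Two design points deserve emphasis:

- **m values are chosen to reproduce fitted Hill coefficients.**  Because
  `OD = α·A` grows without bound (A → E_tot), an unweighted 4-parameter
  Hill fit of a full 0.03–30 µM profile is biased below the generating
  order by the post-transition tail.  The printed cooperativities are
  themselves fitted values, so the calibration targets the fit output,
  which lands at `m_apo = 12`/`m_sat = 5` with the transitions in the
  upper part of the grid.  Consequently the profile's maximum log–log
  slope (≈ m in the low tail) exceeds the fitted n_H.
- **Registry K_O values are microscopic, anchored through simulated
  measurements.**  In the full competitive model the fitted apparent K_i
  is not equal to the O-state constant (the steep response and the
  activator background both displace the midpoint), so K_O is the value
  that makes the simulated experiment reproduce the measurement.  One
  consequence: the apparent affinities of ADP and ATP agree to ~2.5-fold
  rather than 2-fold; the model treats this as "similar".

## Synthetic assays and noise

Generators emulate the laboratory assay designs: protein titrations (15 log points,
0.03–30 µM) with paired RNase/OD500 readouts, cofactor titrations
(1 µM–10 mM, 12 points; the panel pipeline extends to 300 mM to pin
saturation), competition series (0.01–10 mM, 10 points, fixed 0.2 mM
ADP), metal-rescue panels (one titration per (cofactor, metal) registry
entry — metal concentration itself is not modeled thermodynamically),
and single-turnover time courses (8 points to 3 half-lives, amplitude
0.8).

Noise structure: additive Gaussian noise on fraction cleaved (σ = 0.02)
and OD (σ = 0.005), and a lognormal day factor on each series' rates with
σ = ln(2)/2, matching day-to-day variability typically within twofold
(≥95% of draws fall within a 2.6-fold band).  Every stochastic output
requires a seed, records it with the generating parameters, and
regenerates bit-identically; replicate count defaults to 2 where
replicates are requested.  What the generators do **not** emulate:
gel-quantification artifacts, counting statistics, pipetting covariance
between points, and instrument saturation at high OD — so passing
recovery tests demonstrates estimator/pipeline correctness under the
stated noise model, not robustness to every failure mode of real data.

## Estimators

All fits are unweighted least squares (Levenberg–Marquardt via lmfit)
with analytic initial guesses and standard errors from the local
curvature; nonconvergence and data pathologies are flagged, never
silently dropped.  Models: `F_max(1 − e^{−kt})` for time courses; a
hyperbolic isotherm with the baseline fixed to the supplied background;
the 4-parameter Hill equation (a model-free maximum log–log slope
estimator is provided alongside); and a background-floored inhibition
hyperbola for competition series, reported as apparent K_i (a
Cheng–Prusoff-style correction is available but off by default, since
measured K_i values are compared raw).

## Numerical choices and degenerate inputs

Root finding is bracketed Brent with machine tolerances (the bracket
[0, E_tot] always holds for valid inputs).  E_tot = 0 returns an empty
distribution.  Oligomer amounts below double-precision resolution of the
mass balance keep their model value so monotonicity survives underflow.
Titration features are located in log concentration; flat titrations
raise no-response errors; half points outside a grid raise grid errors.
Fit tolerances are 1e-13 so noiseless self-generated data are recovered
to the 1e-6 relative level the tests assert.

## Limitations

- The all-or-none m-mer with interpolated order is phenomenology; it
  reproduces the observed cooperativities but carries no filament-size
  information.
- Latch factors come out modest (≈1.3–2) because the high assembly order
  amplifies small conformational shifts; they should not be read as
  microscopic free-energy differences.
- At the calibrated operating point the RNase readout at 3 µM is not in
  its saturating plateau for strong activators (that is what lets the
  panel resolve 200- vs 250-fold potencies under a shared k2).
- Metal rescue is encoded per (cofactor, metal) pair; titrating the metal
  itself is outside the model.
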