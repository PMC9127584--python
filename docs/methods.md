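# Models and methods

This note records the models implemented in `aahub`, the defaults and why,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Two-state unfolding models

All unfolding analysis assumes a two-state equilibrium N ⇌ D.  The unfolded
population is the Boltzmann fraction

    fU = exp(−ΔG/RT) / (1 + exp(−ΔG/RT)),

so ΔG_DN > 0 describes a predominantly folded protein, fU = 1/2 at the
midpoint, and the observable is the population-weighted average of the two
state baselines.  (Some published forms of these equations place the
opposite sign in the exponent; with that literal sign the denatured baseline
would dominate under native conditions, so the package uses the convention
above, which reproduces every numerical consequence of the printed
parameter tables.)  R is fixed at 8.314 × 10⁻³ kJ mol⁻¹ K⁻¹; temperatures
are kelvin internally and °C at every file/CLI boundary.

Three parameterizations of ΔG are provided:

* **Chemical (linear extrapolation):** ΔG(c) = ΔG − m·c at fixed T, with
  baselines linear in denaturant.  m ≤ 0 is rejected as non-cooperative.
  Cm = ΔG/m.
* **Thermal (van't Hoff):** ΔG(T) = ΔH_vH·(1 − T/Tm), baselines polynomial
  in T (linear default, quadratic optional).
* **Stability surface:** Gibbs–Helmholtz in T plus linear extrapolation in
  denaturant with a polynomial m-value,

      ΔG(T, x) = ΔHm(1 − T/Tm) + ΔCp(T − Tm − T ln(T/Tm)) − x(m₀ + m₁T + m₂T²).

  The m-polynomial argument is absolute kelvin.  m₁ and m₂ default to zero
  and are freed only on request (`fit_m12`): a three-term m(T) is weakly
  identifiable on the grid sizes typical of these experiments, and the
  nested-model residual inequality is tested rather than assumed.
  Surface baselines are quadratic in T and denaturant-independent.

With ΔCp > 0 the stability curve has a maximum; below it the model
predicts cold denaturation.  `equal_unfolding_window` therefore brackets
its bisection on the heat branch only (from the temperature of maximum
stability to Tm + 50 K) and fails explicitly when a target fraction lies
below the branch minimum — for marginally stable domains, fractions below
≈8 % may simply never occur on the heat branch.

Diagnostics: `vant_hoff_ratio` compares an independently fitted ΔH_vH with
the global ΔHm; a ratio well below 1 (default flag threshold 0.8) indicates
the thermal transition does not reach the fully unfolded state.  The
m-value correlations ΔASA = −907 + 93·n_res and m/cal mol⁻¹ M⁻¹ =
374 + 0.11·ΔASA (cal→kJ via 4.184) are provided in both directions; note
the two directions are not numerically consistent inverses for every
published m value, so neither is privileged.  Helicity from the mean
residue ellipticity at 222 nm uses fH = (MRE − coil)/(helix_max − coil)
with helix_max = −39 500·(1 − 2.57/n) and coil = +640 deg cm² dmol⁻¹;
published reference constants vary, so both are arguments.

## Fitting

All fits use trust-region least squares (`scipy.optimize.least_squares`)
with convergence at 1e−10 relative cost change, parameter bounds
(Tm ∈ [274, 400] K, ΔHm ∈ (0, 1000] kJ mol⁻¹, ΔCp ∈ [−10, 20] kJ mol⁻¹ K⁻¹,
m₀ ∈ [0, 50] kJ mol⁻¹ M⁻¹ by default) and 10 multistarts jittered ±20 %
around data-driven initial guesses: Tm from the steepest smoothed signal
gradient, baselines from the terminal 10 % of each axis, ΔH_vH from the
transition width via dfU/dT|Tm = ΔH_vH/(4RTm²).  Standard errors come from
the SVD-based Jacobian covariance at the optimum (NaN when the fit is
rank-deficient); when a dataset carries ≥ 2 replicate labels each replicate
is also fitted separately and the across-replicate mean ± sample SD is the
headline uncertainty, matching how replicated experiments are usually
reported.  Baselines are always included in the fit even where they would
be omitted from presentation plots.

Identifiability is a real constraint, not a fitting defect: a melt with
ΔH_vH ≈ 46 kJ mol⁻¹ has a transition wider than a 20–90 °C scan, so free
baselines and enthalpy trade off and single-fit tolerances of a few percent
are unattainable at 1 % noise.  The recovery tests therefore assert
per-seed tolerances only where the Fisher information supports them
(sharp transitions, surfaces) and assert unbiasedness of the mean across
seeded replicates otherwise.

CD preprocessing: points whose photomultiplier high-tension voltage exceeds
600 V (instrument ceiling, configurable) are discarded before fitting;
points without a recorded voltage are kept.

## ITC

The one-set-of-sites isotherm treats the syringe species X binding N
independent sites on the cell species M with dissociation constant Kd.
After each injection both species are diluted by the displacement factor
(1 − v/V0), the bound concentration follows from the stable conjugate form
of the binding quadratic, and the injection heat is

    q_i = ΔH·V0·(MX_i − MX_{i−1}·(1 − v_i/V0)) / (moles injected) + q_dil.

Displaced complex leaves the cell athermally; heat is credited to net
complex formed.  Consequences, both tested: in the stoichiometric limit
(Kd → 0) every pre-saturation injection releases exactly ΔH per mole of
injectant, and the total heat converges to N·ΔH·(initial cell moles) as the
per-injection volume shrinks (the deficit is the sites displaced before
binding, ∝ v/V0).  Kd is optimized in log₁₀ space with a delta-method
standard error; the first injection is included by default with a
`discard_first` flag; heats are accepted as kJ per mol of injectant or as
raw µJ converted through the syringe moles per injection.  A Wiseman
c-value N·[cell]/Kd outside [1, 1000] is reported as a diagnostic.
Injection order is physically meaningful, so shuffled injection tables are
rejected.

The decomposition ΔG = RT ln(Kd/M), −TΔS = ΔG − ΔH uses the 1 M reference
state; the identity ΔG = ΔH + (−TΔS) holds by construction.

## NMR

CSPs use the weighted Euclidean distance with ¹⁵N weight 0.154
(configurable).  The reference condition defaults to the lowest temperature
measured.  Missing peaks are missing data — never zeros — because peak
disappearance is itself the signal behind highest-visible-temperature maps.
The CSP table retains the component ¹H/¹⁵N differences so CSPs between two
non-reference conditions remain exact rather than being approximated from
reference-relative magnitudes.  Upper-quartile thresholds use linear
interpolation between closest ranks.  Initial-unfolding analysis divides
the CSP across an equal-unfolding temperature window by the window width in
kelvin and flags residues strictly exceeding mean + 1 SD (so a uniform
table with SD = 0 flags nothing).  Secondary shifts are δ_obs − δ_coil with
helical segments called as runs of ≥ 4 residues above +0.5 ppm (both
configurable); random-coil references are supplied by the user.
Relaxation decays are fitted as I(t) = I₀e^(−Rt) with a log-linear start;
duplicate delays enter as independent points.  Exchange-regime
classification and automated peak tracking are out of scope — peaks are
matched by assignment label.

## Synthetic data

Generators are deterministic functions of (ground truth, seed) and emulate
the study conditions: 20–90 °C melts at 1 °C pitch, 0–8 M urea titrations
(25 points), 6 urea series × 30 temperatures fluorescence surfaces in
triplicate, 20 × 2 µl injections into a 200 µl cell at 27 µM with a 277 µM
syringe, and peak lists at 25–55 °C in 5 °C steps whose shifts drift with
Δ(fraction unfolded) scaled by per-residue sensitivities and whose
intensities decay exponentially with dropout below a detection floor.
Noise is homoscedastic Gaussian (signal-proportional optional); the default
1 % full-scale level in tests corresponds to a clean spectroscopic trace.

What passing the synthetic suite shows: the estimators are consistent and
unbiased under the declared noise model, and the analysis chain is
internally coherent (generation → analysis round-trips).  What it does not
show: robustness to real-data pathologies — correlated baseline drift,
aggregation above the melt, heteroscedastic fluorescence noise, peak
overlap and misassignment — none of which the generators emulate.

## Problem sizes

The recovery studies use 100 seeded triplicate surfaces (3 multistarts per
fit, since the data-driven initializer converges from a single start on
clean surfaces), 40 seeded thermograms, 1000 random isotherm draws for the
oracle comparison, and 200 seeded relaxation decays; together they complete
in about a minute on one core.
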