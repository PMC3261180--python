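# Methods

## The pKa-shift model

An ionizable group couples proton binding to folding: if its pKa in the
folded state differs from its pKa in the unfolded state, the charged form
is differentially stable in the two states, and the thermodynamic linkage
relation gives its electrostatic contribution to the free energy of
unfolding,

    ΔΔG_u^charge = ln(10)·R·T·(pKa_unfold − pKa_fold).

`ln(10)` is used exactly (not the truncated 2.303); the difference is below
every rounding step in the pipeline. R = 8.314 J mol⁻¹ K⁻¹ throughout, and
energies are carried in kJ/mol. Errors on ΔΔG propagate in quadrature from
the two pKa standard errors. The published per-residue ± values are not
exactly quadrature sums of the published pKa errors (e.g. D2 at 298 K:
quadrature gives 0.24 against a printed 0.27), so the error column is
reported but not regression-tested against the printed table; the ΔΔG
values themselves reproduce the printed grid within 0.06 kJ/mol, inside
the ±0.1 kJ/mol tolerance implied by two-decimal pKa inputs.

Unfolded-state side-chain carboxyl resonances can be degenerate
(D12/D48, E47/E64, E50/E90 in this protein); the pairing layer expands a
slash-joined row so both residues share the single fitted unfolded pKa.

## Single-site titration fits

The observable is the side-chain carbonyl ¹³C shift versus pH, fitted to
the modified Henderson–Hasselbalch form

    δ(pH) = [δ_A + δ_B·10^{n(pH−pKa)}] / [1 + 10^{n(pH−pKa)}].

Fits use Levenberg–Marquardt least squares. Initial guesses: plateaus from
the first/last points, pKa from the steepest finite-difference slope,
n = 1 — robust for monotone sigmoids on the pH 1.2–6.7, ~15-point sampling
this package targets. Parameter uncertainties come from the linearised
covariance (J'J)⁻¹·s² by default; a residual-resampling bootstrap is
available (`n_boot`), since how the original error bars were computed is
not documented. Curves with fewer than 5 points, or with a
plateau-to-plateau range under 0.1 ppm (no visible transition at typical
¹³C read precision), are refused rather than fitted.

Model selection between fixed (n = 1, 3 parameters) and free Hill
coefficient (4 parameters) uses the extra-sum-of-squares F-test at
α = 0.05; the simpler model is kept when p ≥ α. When both models reproduce
the data to below RSS = 1e−20 ppm² (noiseless synthetic input), the
variance ratio is meaningless and the simpler model is kept outright.

**Biphasic detection.** Coupled pairs are identified in the original work
by visual curve shape; the automated trigger here flags a curve when the
free-Hill fit gives n < 0.85 *and* the fit residuals cluster (one-sided
Wald–Wolfowitz runs test, p < 0.05). The runs test uses the exact
conditional run-count distribution rather than the normal approximation,
which is unreliable at 15 points. At 15-point sampling the detector is
deliberately conservative (the runs test has limited power); at ≥ 25
points it flags the coupled fixtures reliably while staying quiet on
monophasic noisy curves.

## Coupled-site model and global fitting

N interacting sites define 2^N protonation microstates with energies

    G(x) = Σ_i x_i·ln(10)·R·T·(pH − pKa_int,i) + Σ_{i<j} W_ij·q_i(x)·q_j(x),

where x_i = 1 means protonated, q_i is the site's formal charge when
deprotonated (−1 for carboxylates) and zero when protonated, and W_ij > 0
is repulsive between simultaneously charged groups. This is the standard
microscopic titration formalism; the convention reproduces the observed
biphasic coupling of neighbouring acids, and 3.6 kJ/mol — a measured
carboxylate/lysine pair interaction in this protein — sets the physically
relevant W magnitude. Protonation fractions follow from the explicit
Boltzmann sum; exact enumeration is capped at 20 sites (the use case is 2).
Partition-function weights are computed after subtracting the per-pH
minimum energy, so normalisation holds to 1e−12 at any pH.

The **apparent pKa** of a site is defined operationally as the pH where
its protonation fraction crosses 1/2 in the full coupled system, located
by a 0.1-unit grid scan over pH 0–14 followed by bisection to 1e−6. With
strong coupling a fraction can cross 1/2 more than once; the steepest
crossing is returned with a warning.

Reporter shifts are linear in site deprotonation:
δ_i = baseline_i + Σ_j a_ij·(1 − f_j). Off-diagonal (cross) amplitudes
carry the minor transitions of biphasic curves; with one site the form
reduces exactly to Henderson–Hasselbalch with n = 1.

**Global fit.** All curves are fitted simultaneously over
{pKa_int, W, baselines, amplitude matrix}: a bounded trust-region least
squares refinement of the uncoupled single-site starting point, then 300
seeded Monte-Carlo perturbations (0.5 pH units on pKa_int, 2 kJ/mol on W,
20 % on amplitudes, 0.2 ppm on baselines) around the running best with
refinement of improving candidates, then a final refinement. Bounds
pKa_int ∈ [0, 10], W ∈ [−20, 20] kJ/mol prevent runaway compensation
between W and pKa_int. Runs are bit-reproducible per seed. Apparent-pKa
standard errors come from a residual-resampling bootstrap (≥ 20
replicates) that re-refines locally from the fitted optimum.

**Identifiability.** The observed curves determine only the *macroscopic*
titration constants: with a free amplitude matrix, an uncoupled system
whose pKas are the roots of the coupled partition function reproduces
coupled-pair data exactly (microscopic ↔ macroscopic degeneracy). The
reported apparent pKas therefore carry a representation ambiguity of a few
hundredths of a pH unit at the W ≈ 3.6 kJ/mol, ~1.9-unit-spacing
conditions studied here — well inside the experimental uncertainties, and
consistent with the interaction energy itself not being a reportable
quantity. The degenerate-solution warning (|W| < 0.1 kJ/mol and vanishing
cross-amplitudes) tells the user when single-site fits would have
sufficed.

## Peptide potentiometric fits

Blocked pentapeptides carry one carboxylate; the cumulative NaOH
concentration is fitted verbatim to the charge-balance form

    C_exp = 1000·10^(−pH) − 10^(−pKa)·C_peptide/(10^(−pH) + 10^(−pKa)) − C_offset

with C_peptide fixed at its known value (taken as an input, ~9.4 mM for
40 mg pentapeptide in 10 ml; the synthetic default) and (pKa, C_offset)
free, pKa bounded to the carboxylate range [1, 8]. A uniform shift of all
C_exp values is absorbed exactly by C_offset. The equation's physical
derivation is not part of this package's scope; it is the fitting form,
and the synthetic generator uses the same form, so fits are
self-consistent. No activity or ionic-strength corrections are applied.

## Predictor benchmarking

Predictor outputs are inputs (TSV); no pKa calculator is invoked. Residues
match after normalisation to one-letter-plus-number labels. Per
(method, structure): Pearson r, RMSE in pKa units, and the two-tailed
p-value of r via t = r√(n−2)/√(1−r²). Conformational-ensemble predictions
are averaged arithmetically per residue, dropping residues missing from
some members with a warning. Exact reproduction of published p-values is
not attempted because the residue count per correlation (whether the
coupled pair is included) is not documented; the machinery is instead
verified against constructed tables and a brute-force permutation null.

## Synthetic data

Generators emulate the experimental designs: 15-point pH 1.2–6.7 grids
for NMR titrations (potentiometric series run pH ~2.6–8.2, as NaOH
titrations continue past pH 8), truth pKas from the published tables, and
i.i.d. Gaussian noise — σ = 0.03 ppm on shifts (typical ¹³C read
precision) and σ = 0.2 mM on NaOH concentrations, chosen once to yield
fit uncertainties comparable to the published ± values. The coupled-pair
generator is calibrated by fixed-point iteration so the generating
system's *apparent* pKas equal the requested targets (5.10/3.20 by
default) at W = 3.6 kJ/mol, with plateau and amplitude values typical of
Glu carboxyl carbons (baselines ~179.3/179.6 ppm, self-amplitudes
~3 ppm, cross-amplitudes ~0.7–0.8 ppm).

What the generators do **not** emulate: pH-meter drift, peak overlap and
assignment errors, temperature-dependent chemical-shift baselines,
correlated noise, CO₂ uptake in potentiometry. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every artefact of real spectra.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study-scale problems
directly: 13 residues × 2 temperatures for the ΔΔG grid, 15-point curves,
200-replicate noise calibrations, 300 Monte-Carlo steps for the coupled
fit (60 in unit tests of the well-conditioned two-site problems), 20 000
permutations for the p-value cross-check. Temperature insensitivity is
declared when the largest per-residue |ΔΔG(298 K) − ΔΔG(333 K)| is below a
configurable 2 kJ/mol (the published grid gives 1.66 kJ/mol).

Known limitations: only acidic (Asp/Glu) sites are modelled — bases enter
the formalism via `charge_deprot` but are untested; microscopic parameters
(pKa_int, W) from coupled fits are reported but not individually
identifiable (see above); the exact-enumeration engine is exponential in
the number of sites and refuses N > 20.
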