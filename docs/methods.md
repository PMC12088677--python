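# Methods and design notes

## CPMG relaxation dispersion

Constant-time CPMG intensities are converted with
R2eff = −ln(I/I0)/T_relax, T_relax = 20 ms by default. The νCPMG = 0 plane
is the intensity reference I0 (averaged over replicates), never an R2eff
point. The conversion formula is the standard constant-time convention;
nothing else is consistent with a single fixed relaxation period.

Per-point uncertainties come from replicate spectra at duplicated νCPMG
values: squared deviations from each duplicate group's mean are pooled,
σ² = ΣSS/Σ(m−1), applied to every point of the series, and floored at 1%
of the median R2eff so that a coincidentally identical pair cannot give a
point infinite weight. Without duplicates a configurable default
(0.3 s⁻¹) is used with a warning.

Three models are fit per residue, always jointly across static fields with
per-field R20 and shared exchange parameters:

- no exchange: R2eff = R20;
- Meiboom (two-state fast exchange):
  R2eff = R20 + (φ/kex)[1 − (4νCPMG/kex)·tanh(kex/4νCPMG)], with
  φ = pA·pB·Δω² parameterised at 600 MHz and scaled by (B0/600 MHz)²
  at other fields because Δω is proportional to B0 — this coupling is what
  makes dual-field joint fits well-posed;
- Carver–Richards (CR72) with equal intrinsic rates in the two states:
  R2eff = R20 + kex/2 − νCPMG·cosh⁻¹(D₊cosh η₊ − D₋cos η₋), with
  Ψ = kex² − Δω², ζ = −2Δω·kex(pA−pB), D± = ½[±1 + (Ψ+2Δω²)/√(Ψ²+ζ²)],
  η± = (2√2 νCPMG)⁻¹·√(±Ψ+√(Ψ²+ζ²)), and Δω converted from ¹⁵N ppm to
  rad/s at the ¹⁵N Larmor frequency of the stated ¹H field. For η₊ > 30
  the cosh⁻¹ is evaluated through a log-sum-exp branch so the model never
  returns a non-finite value.

Fitting is trust-region weighted least squares with five starts over
log-spaced kex ∈ [10, 10⁴] s⁻¹ (exchange-rate landscapes are multimodal).
Model selection uses AIC = χ² + 2k with known per-point σ and no
small-sample correction; fits within ΔAIC < 2 of the minimum are ties
resolved toward fewer parameters, so exchange is claimed only when the
data demand it. A model that fails to converge is dropped with a
diagnostic and selection proceeds over the rest.

The global fit shares one kex over all member residues — membership is
residues whose individual selection chose an exchange model — while each
member keeps per-field R20 and its own amplitude parameters. The global
problem is solved with an explicit Jacobian sparsity pattern (each row
touches only the shared kex and its residue's block). Parameter
uncertainties come from seeded Monte-Carlo resampling of the data within
its σ (200 refits by default; 0 falls back to the covariance estimate),
and a >10% refit non-convergence rate is surfaced as a warning. The
global AIC can be compared against the sum of individual AICs; a
constructed two-process dataset (kex 150 and 1500 s⁻¹) correctly prefers
split fits.

Against a numerical two-site Bloch–McConnell propagator the CR72 form is
exact (equal-R20 case): the propagator oracle must extract the dominant
eigenvalue of the linear one-cycle map E(τ)·conj(E(2τ))·E(τ) — the
quantity the closed form parameterises — rather than the endpoint signal
of a 20 ms period, which contains initial-condition transients of several
percent at low νCPMG.

T1/T2 decays are two-parameter exponentials I(t) = I0·e^(−Rt); the
intensity noise is estimated from the residual scatter about the fitted
decay (n−2 degrees of freedom; the duplicate-delay scatter is a subset of
it) and propagated to the rate by Monte-Carlo refitting. With ~9 degrees
of freedom the quoted σ behaves like a t(9) interval, i.e. a nominal 3σ
bound covers ≈98.5% of repeats, not 99.7%. The steady-state NOE is
I_sat/I_ref with first-order error propagation; negative saturated
intensities pass through as negative NOEs (flexible-terminus signature).

## Model-free analysis

J(ω) = (2/5)[S²τm/(1+(ωτm)²) + (1−S²)τ′/(1+(ωτ′)²)], 1/τ′ = 1/τm + 1/τe,
with the two-timescale extension for m5. R1, R2 and NOE use the standard
¹⁵N dipolar + CSA combinations of J at {0, ωN, ωH−ωN, ωH, ωH+ωN} with
r_NH = 1.02 Å and Δσ = −160 ppm (both overridable); Rex terms scale with
(B0/600 MHz)². Frequencies enter as magnitudes and the sign of γN is
carried by the γH/γN ratio in the NOE. One consequence worth noting: in
the extreme-narrowing limit R2/R1 → 1 exactly only for pure dipolar
relaxation; the CSA term raises the limit to
(2.5d² + (7/6)c²)/(2.5d² + c²) ≈ 1.015 at 600 MHz.

The overall tumbling time is estimated from rigid residues (NOE ≥ 0.65 at
600 MHz, no exchange flag — a standard filter; at least five residues
required) by numerically inverting the rigid-limit R2/R1(τm) relation per
residue and taking a 10% trimmed mean; extreme-narrowing ratios are
rejected as uninformative. Models m1 (S²), m2 (S², τe), m3 (S², Rex),
m4 (S², τe, Rex) and m5 (S²f, S²s, τs) are fit by bound-constrained
weighted least squares (S² can never leave [0,1]) and selected by the same
AIC rule as the dispersion module. With shared isotropic diffusion, τm is
re-optimised against the selected models and iterated until it moves by
<0.5% (max 10 rounds); a local-τm mode fits each residue's tumbling
separately. Anisotropic diffusion tensors (spheroids/ellipsoid) are
accepted in the data model but not fit — they require structures, and the
package's validation is parameter recovery on synthetic data generated
under isotropic tumbling.

## Chemical-shift perturbations and hotspots

Δδ = √((ΔδHN² + ΔδN²/25)/2). The combined CSP is implemented with the
square root so Δδ carries ppm units; the literal quadratic-mean form
(ppm²) is available behind `sqrt_form=False` for comparison with sources
that print it without the root. Significance is Δδ strictly above the 10%
trimmed mean (10% of values removed at each tail, rounding down) plus
1.5 times the standard deviation of the untrimmed finite values — the
trim robustifies the centre while σ keeps the scale of the full
distribution. Residues whose bound-state peak vanishes, or whose
I_bound/I_free falls below 0.2 (configurable), are flagged broadened,
carry no Δδ, and never enter thresholds.

Residual CSP analysis compares saturating-ligand profiles:
residual = Δδ(WT) − Δδ(variant). Hotspots are positive residuals above a
cutoff (default: one standard deviation of the residual distribution —
plotted-residual analyses rarely fix a cutoff, so the default is the
package's choice and is configurable); anti-hotspots are
the mirror set; residues broadened in either profile are excluded and
listed.

Titrations are fit globally in the fast-exchange limit:
Δδ_obs = Δδmax·f_bound with the exact 1:1 quadratic
f = ((P+L+Kd) − √((P+L+Kd)² − 4PL))/(2P), one shared Kd (log-parameterised)
and per-residue Δδmax. When the fitted curve never reaches ~80% bound
fraction within the ligand range the response is effectively linear in L,
Kd and Δδmax are degenerate along a ridge, and Kd is reported as a lower
bound (the top ligand concentration) with a flag.

## Binding isotherms

signal = baseline + amplitude·f_bound(titrant; target, Kd) with the same
quadratic bound fraction and the labelled-target concentration fixed
(20 nM default). The quadratic is used rather than a Hill/logistic form:
with target ≪ Kd both are valid, but the quadratic is exact and costs
nothing. Binding is detected through the fitted signal span
|amplitude|·Δf_bound across the series — the amplitude parameter alone is
degenerate with Kd on flat data — and a span within 2σ of zero yields a
"no binding" result with Kd undefined. A fitted Kd below the lowest
(above the highest) titrant concentration is flagged as an upper (lower)
bound. Replicates are compared with Welch's unequal-variance two-sided
t-test; zero-variance degenerate groups short-circuit to p = 1 (equal
means) or p = 0.

## Thermal unfolding

θ(T) = [(m_f·T + b_f) + (m_u·T + b_u)·K(T)]/(1 + K(T)),
K(T) = exp[(−ΔH_vH/R)(1/T − 1/Tm)] with T in kelvin inside K
(R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹) and baselines linear in °C. Only the
unfolded baseline is weighted by K — the transcription of this equation
that multiplies both baselines by the exponential cannot produce a sigmoid
between baselines and is treated as a typographical slip. At T = Tm the
signal is exactly the baseline midpoint, and θ is bounded by the baselines
everywhere. Two-transition curves share baselines and combine as
θ_f + (θ_u − θ_f)·Σaᵢ·Kᵢ/(1+Kᵢ) with Σaᵢ = 1; midpoints fitted closer
than 5 °C trigger an identifiability warning. Initial guesses come from
edge-window baseline fits and the smoothed-derivative inflection; a fit
whose midpoint pins to the grid edge, or whose baseline separation at Tm
is below three times the residual scatter, raises "transition not
bracketed". Model comparison (1 vs 2 transitions) uses χ² + 2k when the
per-point noise is known and the Gaussian profile-likelihood AIC
n·ln(RSS/n) + 2k otherwise.

## Synthetic data: what it emulates and what it does not

Generators reproduce the acquisition designs of the GeoRec2 relaxation,
binding and unfolding experiments: νCPMG ∈ {25,
50, 75, 100, 150, 250, 500, 750, 800, 900, 1000} Hz (plus the reference
plane) at 600 and 850 MHz; T1 delays 0–1200 ms and T2 delays 0–101.8 ms
with the printed duplicate points; 16-point two-fold dilutions from
200 µM with a 20 nM target; 20–90 °C melts in 1 °C steps. Default
ground-truth values are the measured parameters for WT, K267E and R332A
GeoRec2 (kex = 147/376/142 s⁻¹ over 17/33/18 residues, Kd = 3.3/7.2/7.2
µM, Tm = 34/61.5 °C);
per-residue R20 is drawn uniformly from [8, 15] s⁻¹ and φ from
[5×10³, 5×10⁴] s⁻² at 600 MHz — mid-range values typical of backbone
amides in a 25 kDa domain with µs–ms exchange. The R2eff noise default
σ = 0.3 s⁻¹ is the package's choice (no reference R2eff uncertainties are
available for this system) and is configurable everywhere.

Noise is additive Gaussian on the generated quantity (R2eff, shift,
signal, ellipticity) with no intensity dependence, matching the
duplicate-based error model of the fits. Titration broadening is a
simple bound-fraction intensity decay, not an exchange-regime lineshape
model. No spin physics is simulated at the FID level. Passing recovery
tests therefore demonstrates that the estimators are unbiased and
correctly weighted under the stated error model — not that they are
robust to artefacts real spectra can contain (baseline distortions,
peak overlap, temperature drift).

Determinism: every generator takes an explicit seed and identical
configuration yields byte-identical tables.

## Numerical choices

- kex multi-start grid [10, 10⁴] s⁻¹, 5 log-spaced starts; bounds
  [1, 10⁶] s⁻¹. pA constrained to (0.5, 1), Δω to (0, 50) ppm.
- Kd fits are log-parameterised (positivity without an active bound) with
  delta-method errors; titration/isotherm starts span the concentration
  range geometrically.
- AIC ties (ΔAIC < 2) always resolve to the simpler model.
- Weighted fits require σ > 0 for every point; noiseless synthetic data
  carry a 10⁻⁶ placeholder σ so weights stay finite.
- The CR72 cosh⁻¹ argument is clamped at 1 from below (roundoff) and
  evaluated via log-sum-exp above η₊ = 30 (overflow).

## Problem sizes

The recovery studies run at the reference experimental designs:
17/33/18 residues ×
2 fields × 12 νCPMG points for the global dispersion fits, 16-point
isotherms in triplicate, 71-point melts, and 15–20-residue model-free
sets; Monte-Carlo studies use 100 seeds. These sizes keep every suite
deterministic and reproducible on a single CPU.

## Known limitations

- Two-state exchange only; no ≥3-state models, off-resonance R1ρ, or
  temperature-dependent exchange analysis.
- CR72 is implemented for equal intrinsic R20 in the two states.
- Isotropic (or local) tumbling only in model-free fitting.
- Titration lineshapes in slow/intermediate exchange are flagged
  (broadening), not fit.
- The MST signal is fit as given; instrument-side normalisation is out of
  scope.
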