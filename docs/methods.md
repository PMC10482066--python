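# Methods

## The model

A dynamic PET study delivers tracer with a known injection wave-form
C_I(t) (square wave of duration d, an idealised instantaneous bolus, or a
measured profile).  The arterial input function (AIF) is represented
through the whole-body impulse response R:

    C_p(t) = (R * C_I)(t) = ∫₀ᵗ R(t − s) C_I(s) ds.

R is expanded in K piecewise-linear basis elements on a fixed knot ladder
{0 = t₀ < t₁ < … < t_K}: B_k is 1 on [0, t_{k−1}), declines linearly to 0
at t_k.  With non-negative coefficients θ the response is automatically
non-negative and non-increasing — the physically required shape.  All
convolutions of B_k with square or bolus injections are closed-form
(piecewise quadratic), so design matrices are exact.

A blood-pool ROI time-course z_i measured at frame mid-times t_i is
modelled as a positive mixture of the AIF, a dispersed copy of it, and a
background (spillover) pattern S:

    z_i = (1 − π)(R * C_I)(t_i − Δ) + π(E_φ * R * C_I)(t_i − Δ)
          + α₃ S(t_i) + ε_i,

where E_φ is the mono-exponential dispersion kernel with time constant φ,
Δ aligns AIF time to scanner time, and Var(ε_i) ∝ 1/w_i with frame weights
w_i = Δᵢ e^{−τ tᵢ} (duration × decay correction; τ is the isotope decay
constant).  The α₁ coefficient of the undispersed term is fixed at 1 and θ
left unnormalised; π is the dispersion mixing fraction.

Because dispersion and spillover make the normalised response
non-identifiable from ROI data alone, two linear identifiability
constraints are imposed, with targets taken from a population analysis of
directly sampled arterial curves:

* mean residence time: ∫ t R dt / ∫ R dt = μ₁;
* contrast ratio: R(T_b)/R(T_a) = μ₂.

Both are homogeneous linear constraints A'θ = 0 on the coefficients and
are enforced exactly.

## Estimation

For fixed (π, φ, Δ) the coefficient problem

    min_θ Σ w_i (z_i − x_i'θ)²  s.t.  θ ≥ 0, A'θ = 0

is a convex quadratic programme, solved by a primal active-set method
written for this structure: it starts from the feasible point θ = 0,
maintains the equality constraints to linear-solve precision at every
iterate, and handles degeneracy by rank-revealing QR on the restricted
constraint block plus a least-squares (smallest-norm) fall-back for
singular KKT systems.  KKT conditions are verified in the test suite
against closed-form and brute-force oracles.

The nuisance parameters (π, φ, Δ) minimise the reduced objective
WRSS(π, φ, Δ).  This surface is much more sharply curved in Δ
(frame-scale features) than in (π, φ), and nearly flat along curves of
constant total dispersion π·φ.  The search therefore proceeds in stages:

1. dense Δ profile at π = 0 and at the (π, φ) mid-point (the two profiles
   bracket the dispersion-biased apparent shift);
2. a coarse (π, φ) grid at the best Δ candidates;
3. Nelder–Mead simplex plus Powell line-search polish of the best starts;
4. ridge-aware restarts that jump along π·φ = const and re-polish.

Every stage funnels through one tracked objective, so the reported optimum
is the best point ever evaluated regardless of any single optimiser's
behaviour.  Defaults: π ∈ [0, 1], φ ∈ [0.5, 120] s, Δ ∈ [−30, 120] s.
Directly sampled arterial curves are fitted in "arterial" mode — π = 0,
α₃ = 0, Δ-only optimisation, no identifiability constraints — since
arterial samples carry no dispersion or spillover.

## Population prior and regularisation

Fitted, normalised impulse responses from a collection of arterial curves
give the coefficient mean μ_θ and covariance Σ_θ, the constraint targets
(μ₁ from the mean response, μ₂ as the across-curve mean contrast ratio),
circulation-time percentiles (the 50th percentile past a 5 s reference is
the circulatory half-life), and an effective-dimension count (principal
components covering 90% of the coefficient correlation trace).

ROI extraction augments the weighted least squares with a Mahalanobis
penalty λ(θ − μ_θ)'Σ_θ⁻¹(θ − μ_θ) over the θ block only (no population
information exists about spillover).  Σ_θ is stabilised with a ridge of
1e−6 × mean diagonal before inversion, since the number of prior curves
may be below K.  λ = 0 reduces exactly to the unpenalised fit; λ → ∞
returns μ_θ whenever μ_θ is feasible.

Because the prior is built from normalised responses while ROI data are in
activity units, the prior is first put on the data scale.  The "auto"
scale runs an unpenalised pilot fit and matches the integral of its
impulse response to the prior mean's integral; the pilot already separates
the AIF component from dispersion and spillover, so this amplitude is
robust to contamination (a naive projection of the prior-mean AIF onto the
raw data is biased high by spillover and makes strong-λ fits misfit).

λ is selected by generalised cross-validation,
GCV(λ) = (WRSS(λ)/n) / (1 − tr H_λ/n)², with the hat-matrix trace computed
on the converged active set of the equality-constrained smoother and
(π, φ, Δ) re-optimised per λ (warm-started along the increasing-λ path).
The default λ grid spans eight decades around
λ₀ = (tr(X'WX)/K) · (tr Σ_θ/K) — typical data curvature times typical
prior variance — so it brackets the point where the penalty starts to
bind the prior's *sloppiest* directions; centring on the precision trace
instead would collapse the grid onto the stiff (near-zero-variance)
directions and leave useful amounts of shrinkage unreachable.
On typical ROI schedules (n of a few dozen frames) the GCV curve is flat
to a few percent over decades of λ, so a strict arg-min is decided by
noise; values within 10% of the minimum (plus a machine-precision floor)
are treated as tied and the tie breaks toward the larger λ — the smoother,
more prior-consistent estimate.  Genuine oversmoothing (a prior shape
inconsistent with the data) raises GCV by far more than the tie band and
is never selected.

## Pooling and scaling

Several ROI extractions are combined by a precision-weighted average of
coefficient vectors, with per-fit weights 1/σ̂² where σ̂² is the fraction
of the spillover-corrected time-course variance left unexplained by the
fit.  The pooled AIF is known only up to scale; three scaling rules are
provided: (i) force the curve through a direct blood sample (t_B, d_B);
(ii) deconvolve a pure vascular ROI against the unscaled AIF and use the
integrated residue (which must be one for a correctly scaled AIF) as the
factor — integrals outside [0.2, 1.2] are flagged as suspect (tracer
retention or partial-volume loss); (iii) match the late value to the
injected dose per unit Nadler blood volume, with the proportionality
estimated from historical records by no-intercept weighted least squares.

## Synthetic data and the contamination experiment

The generator emulates two study designs:

* **H2O-like** — 5 s square injection, 8.25 min schedule (3–20 s frames),
  ¹⁵O decay; generator impulse response a three-term exponential mixture
  a = (0.90, 0.09, 0.01), b = (5, 35, 120) s, giving a circulation
  half-life of 9.6 s and a 95th percentile of 63 s past the 5 s reference.
* **FDG-like** — 60 s pump infusion, 89 min schedule (15–300 s frames),
  ¹⁸F decay; a = (0.45, 0.35, 0.20), b = (35, 170, 2000) s, half-life
  77 s, 95th percentile 49 min.

The mixtures were calibrated once against the reported tracer percentile
characteristics; they are deliberately outside the span of the
piecewise-linear fitting basis, so recovery experiments measure
approximation rather than self-reproduction.  Subject-to-subject variation
is multiplicative log-normal jitter (cv 20%) on all mixture parameters.

Contaminated ROI concentrations follow
C_T = (1 − p_d) C_p + p_d (E_{φ_d} * C_p) + p_b S̄, with φ_d matched to
the tracer's circulation half-life and S̄ the running integral of the AIF
normalised to one at the end of the study.  Frame measurements add
Gaussian noise with variance ∝ C_T(t_i) e^{τ t_i}/Δ_i; the noise constant
is calibrated so the coefficient of variation at the AIF peak is 2%
(deliberately low — favourable to the uncorrected direct method).
Negative draws are kept: the error model is Gaussian and the weights
down-weight noisy frames.

The experiment compares, against the known truth, (a) direct use of the
noisy ROI curve and (b) the constrained, GCV-regularised extraction with a
prior built from 20 arterial-mode fits of the same generator (noise-free
samples on a standard arterial draw schedule; the prior supplies T_b at
the archetype's scaling sample time, anchoring the contrast-ratio
constraint where the single-sample scale is applied).  Both estimates are
scaled through a single sample of the true AIF (2 min for the H2O-like
design, 10 min for the FDG-like), and accuracy is the root integrated
squared error (RMISE) over the study.  Six contamination levels
(p_d, p_b) from (0.1, 0.125) to (0.6, 2.0) are used, 50 replicates each.

Problem sizes inside the experiment are chosen for throughput: a coarser
evaluation grid (≥ 0.15 s step), a ±20 s shift window (the simulation
introduces no shift), a 3×3×3 multi-start with single refinement, and a
5-point λ grid; the stand-alone fitting functions default to the more
thorough search described above.

### What the experiment does and does not show

The generator reproduces the frame schedules, injection protocols, decay
constants, noise law and contamination model of real studies, and its
impulse-response scales match reported tracer characteristics.  It does
not emulate scanner resolution effects, reconstruction artefacts,
metabolite corrections, or segmentation errors in ROI definition; passing
results demonstrate the statistical behaviour of the extraction under the
stated measurement model, not end-to-end performance on scanner data.

A structural feature of the H2O-like design is worth noting: at the 2 min
scaling time the H2O AIF has decayed to about 1% of its peak, while the
normalised spillover pattern is already near its plateau.  Even the
lightest spillover level therefore destroys the direct method's
single-sample scale, and the direct error saturates near the norm of the
true curve at *every* contamination level.  The regularised extraction's
advantage over it is consequently large at all levels but not monotone in
the contamination level for this design; the FDG-like design, whose AIF
retains ~20% of its peak at the 10 min sample, shows the expected
monotone growth of the advantage.

## Numerical choices

* Time is seconds everywhere internally; CSV headers may declare minutes.
* Frames are half-open [start, end); abutting frames are valid.
* Uniform evaluation grids, step ≈ max(0.05 s, study/20000) capped at
  0.5 s, padded past the study end to cover negative shifts.
* Dispersion uses the exact one-step recursion for the exponential kernel
  on piecewise-linear input (causal, stable for any φ > 0), not FFT.
* Equality constraints are enforced by the QP to ~1e−12; no soft
  penalties.
* Weight vectors are rescaled to mean 1 for conditioning only.
* An all-zero ROI returns a zero fit with a warning rather than an error.
* Degenerate prior covariances (fewer curves than K) are handled by the
  diagonal ridge; identical prior curves give a zero covariance and an
  effective dimension of 0.

## Known limitations

* The percentile semantics (survival-style decline past a reference time,
  default 5 s) is one of several possible readings; it is the one under
  which the 50th percentile is a circulatory half-life.
* GCV under-penalises when the identifiable signal is weak relative to
  the constraint-satisfying degenerate modes; the tie rule mitigates but
  does not remove this, and occasional replicates select a weak penalty
  and produce poor tails.
* Covariance-weighted pooling (the statistically optimal combination) is
  not implemented; the precision-weighted average is used, with the
  covariance version left as an extension hook in `pool`.
* Physiologic scaling applies no recovery-coefficient (partial-volume)
  correction; factors outside [0.2, 1.2] are flagged instead.
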