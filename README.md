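# aifx — arterial input function extraction for dynamic PET

Kinetic analysis of dynamic PET data needs the arterial input function
(AIF): the tracer concentration in arterial blood over the course of the
scan.  When arterial sampling is impractical, the AIF must be recovered
from an image-derived blood-pool region of interest (ROI) — but ROI
time-courses are contaminated by **dispersion** (smearing of the blood
signal) and **spillover** from surrounding tissue, and naive use of the
ROI curve as the AIF can be badly wrong.

`aifx` implements an impulse-response based extraction method for this
problem, aimed at PET methodologists and kinetic modellers.  The AIF is
written as a convolution of the known injection profile C_I with a
whole-body impulse response R,

    C_p(t) = (R * C_I)(t),      R(t|θ) = Σ_k θ_k B_k(t),  θ ≥ 0,

with piecewise-linear basis elements B_k on a fixed knot ladder.  The ROI
measurement model adds a dispersed copy (mono-exponential kernel E_φ,
mixing fraction π), a background spillover term α₃S(t), and a time shift
Δ.  For fixed (π, φ, Δ) the coefficients solve a non-negative,
equality-constrained weighted least-squares problem

    min_θ Σ_i w_i [z_i − x_i'θ]²   s.t.  θ ≥ 0,  A'θ = 0,

where the equality constraints pin the mean residence time
∫tR dt / ∫R dt = μ₁ and a contrast ratio R(T_b)/R(T_a) = μ₂ of the
normalised response — the supplementary information that makes the AIF
identifiable under contamination.  (μ₁, μ₂) and a Mahalanobis penalty
λ(θ−μ_θ)'Σ_θ⁻¹(θ−μ_θ) come from a population analysis of directly
sampled arterial curves; λ is chosen by generalised cross-validation.
Per-ROI extractions can be pooled by precision weighting, and the final
curve is scaled to activity units by a blood sample, a physiologic
(vascular-residue) rule, or injected dose per Nadler blood volume.

See `docs/methods.md` for the full model, the active-set quadratic
programme, numerical choices and known limitations.

## Worked example

Simulate a contaminated blood-pool ROI for an H2O-like bolus study,
build a population prior, and extract the AIF:

```python
import numpy as np
from aifx import gcv_select, scale_blood_sample
from aifx.synthetic_data import (
    builtin_archetypes, build_archetype_prior, calibrate_noise_scale,
    contaminate, make_true_aif, simulate_roi, ContaminationSpec, rmise,
)

arch = next(a for a in builtin_archetypes() if a.name == "h2o")
prior = build_archetype_prior(arch, n_curves=20, seed=7,
                              Tb=arch.sample_time)

c_p, _ = make_true_aif(arch, seed=42)          # ground-truth AIF
c_t = contaminate(c_p, ContaminationSpec(0.6, 2.0, arch.phi_d),
                  arch.schedule)               # heavy contamination
roi = simulate_roi(c_t, arch.schedule, calibrate_noise_scale(arch),
                   seed=42)

lam, table, fit = gcv_select(
    roi, arch.injection, prior.knots, prior.constraint_spec(), prior,
    data_scale="auto", background_mode="prior_aif")
print(f"lambda = {lam:.3g}, pi = {fit.pi:.2f}, phi = {fit.phi:.1f} s, "
      f"alpha3 = {fit.alpha3:.2f}")

aif = fit.aif(arch.injection, c_p.grid)        # unscaled shape
d_B = float(c_p(np.array([arch.sample_time]))[0])
scaled, _ = scale_blood_sample(aif, arch.sample_time, d_B)
print(f"RMISE vs truth: {rmise(scaled, c_p, arch.schedule.end_time):.3f} "
      f"(true peak {c_p.values.max():.3f})")
```

Output:

```
lambda = 711, pi = 0.82, phi = 29.7 s, alpha3 = 2.01
RMISE vs truth: 0.935 (true peak 0.708)
```

The fit attributes the late signal to spillover (α₃ ≈ 2.0 — exactly the
simulated amplitude) plus a large dispersed fraction, and the scaled AIF
error of 0.94 is well below the 1.64 obtained by using the raw ROI curve
directly (scaled through the same blood sample): a 43% reduction on data
whose peak is flattened and whose tail is dominated by background.

The same operations are available from the shell:

```sh
aifx simulate --archetype h2o --level 6 --seed 42 --out roi.csv
aifx extract --tac roi.csv --injection square:5 --prior prior.json \
     --lambda auto --out fit.json --aif-out aif.csv
aifx experiment --levels 1-6 --reps 50 --seed 1 --out results.csv
```

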