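"""Pooling of per-ROI extractions and scaling of the estimated AIF.

Pooling uses the simplified precision-weighted average: each ROI fit gets
a quality measure sigma2 — the proportion of the spillover-corrected
time-course variance left unexplained by the fitted AIF component — and
the pooled coefficients are theta_bar = sum_j theta_j / sigma2_j divided
by sum_j 1 / sigma2_j.

The pooled AIF is known only up to scale (the blood ROI model cannot fix
the absolute activity level in the presence of dispersion or spillover),
so one of three scaling rules is applied: a direct blood sample at a known
time, a physiologic rule (the integrated residue of a pure vascular ROI
must be one), or the injected dose per unit Nadler blood volume.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constrained_fit import FitResult, fit_roi
from .ir_model import (
    ImpulseResponse,
    KnotVector,
    SampledCurve,
    basis_integrals,
)
from .tac_io import InjectionProfile, ROITimeCourse

__all__ = [
    "sigma2_ratio",
    "pool",
    "scale_blood_sample",
    "scale_physiologic",
    "nadler_bv",
    "scale_dose_bv",
    "estimate_beta",
]


def sigma2_ratio(fit: FitResult, roi: ROITimeCourse,
                 background: np.ndarray | None = None) -> float:
    """Residual variance ratio used as the pooling weight denominator.

        sigma2 = sum_i w_i (z_i - x_i' theta_hat)^2
               / sum_i w_i (z_i - alpha3_hat S_i)^2.

    ``background`` (S at the frame mid-times) defaults to the last design
    column stored on the fit.  The value is stored on the fit in place.
    """
    z, w = roi.z, roi.w
    if background is None:
        if fit.X is None:
            raise ValueError("fit carries no design matrix; pass background=")
        background = fit.X[:, -1]
    if fit.X is not None:
        num_res = z - fit.X @ np.concatenate([fit.theta, [fit.alpha3]])
    else:
        raise ValueError("fit carries no design matrix; refit before pooling")
    den_res = z - fit.alpha3 * background
    denom = float(w @ (den_res * den_res))
    if denom <= 0:
        raise ValueError(
            "spillover-corrected variance is zero; the ROI is pure background"
        )
    fit.sigma2 = float(w @ (num_res * num_res)) / denom
    return fit.sigma2


def pool(fits: list[FitResult]) -> tuple[np.ndarray, np.ndarray]:
    """Precision-weighted average of coefficient vectors across ROI fits.

    Returns (theta_bar, weights); weights are sigma2_j^{-1} normalised to
    sum to one.  All fits must share knots and carry a positive sigma2.
    """
    if not fits:
        raise ValueError("need at least one fit to pool")
    knots = fits[0].knots
    for f in fits[1:]:
        if not np.allclose(f.knots.knots, knots.knots):
            raise ValueError("pooled fits must share the same knots")
    s2 = np.array([f.sigma2 for f in fits], dtype=float)
    if np.any(~np.isfinite(s2)) or np.any(s2 <= 0):
        raise ValueError("every fit needs a positive sigma2 (run sigma2_ratio)")
    inv = 1.0 / s2
    weights = inv / inv.sum()
    thetas = np.array([f.theta for f in fits])
    return weights @ thetas, weights


def scale_blood_sample(
    aif: SampledCurve, t_B: float, d_B: float
) -> tuple[SampledCurve, float]:
    """Scale so the curve passes exactly through the blood sample (t_B, d_B)."""
    cur = float(aif(np.array([t_B]))[0])
    if cur <= 0:
        raise ValueError(
            f"unscaled AIF is non-positive at t_B={t_B}; use a later sample time"
        )
    factor = d_B / cur
    return SampledCurve(aif.grid, aif.values * factor), factor


def scale_physiologic(
    aif: SampledCurve,
    vascular_roi: ROITimeCourse,
    knots: KnotVector,
    delta_bounds: tuple[float, float] = (-30.0, 60.0),
    **fit_kwargs,
) -> tuple[SampledCurve, float]:
    """Scale using a pure vascular ROI whose integrated residue must be one.

    The vascular TAC is deconvolved against the unscaled AIF (non-negative
    monotone residue, time-shift optimised); if the AIF were correctly
    scaled the residue integral over the study would be unity, so the
    integral itself is the multiplicative correction.
    """
    inj = InjectionProfile(
        "measured", samples=np.column_stack([aif.grid, aif.values])
    )
    fit = fit_roi(
        vascular_roi, inj, knots, spec=None, mode="arterial",
        delta_bounds=delta_bounds, **fit_kwargs,
    )
    residue_integral = float(fit.theta @ basis_integrals(knots))
    if residue_integral <= 0:
        raise ValueError(
            "vascular deconvolution produced a zero residue; "
            f"fit diagnostics: wrss={fit.wrss:.4g}, delta={fit.delta:.3g}"
        )
    if not 0.2 <= residue_integral <= 1.2:
        warnings.warn(
            f"integrated residue {residue_integral:.3g} outside [0.2, 1.2]; "
            "physiologic scaling is suspect (retention or partial volume)"
        )
    factor = residue_integral
    return SampledCurve(aif.grid, aif.values * factor), factor


def nadler_bv(height: float, weight: float, sex: str) -> float:
    """Total blood volume (litres) by Nadler's anthropometric formula.

    height in metres, weight in kg, sex 'M' or 'F'.
    """
    if not 0.5 <= height <= 2.5:
        raise ValueError("height outside plausible range 0.5-2.5 m")
    if not 2.0 <= weight <= 300.0:
        raise ValueError("weight outside plausible range 2-300 kg")
    if sex == "M":
        return 0.3669 * height**3 + 0.03219 * weight + 0.6041
    if sex == "F":
        return 0.3561 * height**3 + 0.03308 * weight + 0.1833
    raise ValueError("sex must be 'M' or 'F'")


def scale_dose_bv(
    aif: SampledCurve,
    V_I: float,
    tau_act: float,
    bv: float,
    beta_hat: float,
    T_E: float,
) -> tuple[SampledCurve, float]:
    """Scale so the late value C_p(T_E) equals beta_hat * tau_act * V_I / BV.

    ``tau_act`` is the injected activity per ml of injectate (distinct from
    the isotope decay constant), ``V_I`` the injected volume and ``bv`` the
    subject's blood volume (Nadler).  beta_hat must come from historical
    records expressed in the same units (see :func:`estimate_beta`), which
    makes the predicted late activity unit-consistent by construction.
    """
    cur = float(aif(np.array([T_E]))[0])
    if cur <= 0:
        raise ValueError(
            f"unscaled AIF is non-positive at T_E={T_E}; use an earlier T_E"
        )
    target = beta_hat * tau_act * V_I / bv
    factor = target / cur
    return SampledCurve(aif.grid, aif.values * factor), factor


def estimate_beta(history: np.ndarray, weights: np.ndarray | None = None) -> float:
    """No-intercept weighted least-squares slope from historical records.

    ``history`` is an (n, 2) array of (late blood activity, tau_act*V_I/BV)
    pairs; the slope of activity on dose-per-blood-volume is beta_hat.
    """
    history = np.asarray(history, dtype=float)
    if history.ndim != 2 or history.shape[1] != 2 or history.shape[0] < 2:
        raise ValueError("need at least two (activity, dose-per-BV) records")
    y, x = history[:, 0], history[:, 1]
    if weights is None:
        weights = np.ones_like(x)
    sxx = float(weights @ (x * x))
    if sxx <= 0:
        raise ValueError("degenerate predictors: all dose-per-BV values are zero")
    return float(weights @ (x * y)) / sxx
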