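"""Population analysis of directly sampled arterial curves.

Direct arterial samples carry no dispersion or spillover, so each curve is
fitted in "arterial" mode (pi = 0, alpha3 = 0, time-shift only, no
identifiability constraints).  The normalised fitted impulse responses are
then summarised into a prior (coefficient mean and covariance plus the
constraint targets mu1 and mu2), percentile/half-life summaries, and an
effective-dimension count from the principal components of the coefficient
correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constrained_fit import FitResult, default_contrast_times, fit_roi
from .ir_model import ImpulseResponse, KnotVector, ir_eval, normalize_ir
from .regularization import Prior
from .tac_io import FrameSchedule, ROITimeCourse

__all__ = [
    "fit_arterial_curve",
    "build_prior",
    "ir_percentiles",
    "effective_dimension",
    "summarize_population",
]


def _samples_to_roi(times: np.ndarray, values: np.ndarray) -> ROITimeCourse:
    """Wrap instantaneous samples as narrow unit-weight pseudo-frames."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    gaps = np.diff(times)
    half = min(gaps.min() / 2.0, 1.0) * 0.9
    sched = FrameSchedule(times - half, times + half, 0.0)
    return ROITimeCourse(sched, values, np.ones_like(values))


def fit_arterial_curve(
    samples: np.ndarray,
    injection,
    knots: KnotVector,
    delta_bounds: tuple[float, float] = (-30.0, 60.0),
    **fit_kwargs,
) -> tuple[ImpulseResponse, FitResult]:
    """Fit a directly sampled arterial curve; returns (normalised IR, fit).

    No identifiability constraints are applied: with pi = 0 and alpha3 = 0
    the impulse response is identifiable from the data alone.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of (time, activity)")
    if samples.shape[0] < knots.K + 2:
        raise ValueError(
            f"need at least K+2={knots.K + 2} samples for K={knots.K} "
            "coefficients; use fewer knots"
        )
    values = samples[:, 1]
    if not np.any(values != 0.0):
        warnings.warn("all-zero arterial samples; returning a zero fit")
        fit = FitResult(knots, np.zeros(knots.K), 0.0, 0.0, 0.5, 0.0, 0.0)
        return ImpulseResponse(knots, np.zeros(knots.K)), fit
    roi = _samples_to_roi(samples[:, 0], values)
    fit = fit_roi(
        roi, injection, knots, spec=None, mode="arterial",
        delta_bounds=delta_bounds, **fit_kwargs,
    )
    ir = normalize_ir(fit.ir)
    return ir, fit


def build_prior(
    irs: list[ImpulseResponse],
    ref_time: float = 5.0,
    Ta: float | None = None,
    Tb: float | None = None,
) -> Prior:
    """Summarise a collection of (normalised) impulse responses into a Prior.

    mu_theta / Sigma_theta are the coordinate-wise mean and sample
    covariance of the coefficient vectors; mu1 is the mean residence time of
    the mean impulse response (scale invariant); mu2 is the across-curve
    mean of the contrast ratios R(Tb)/R(Ta), clipped into (0, 1].
    """
    if len(irs) < 2:
        raise ValueError("need at least two impulse responses to build a prior")
    knots = irs[0].knots
    for ir in irs[1:]:
        if not np.allclose(ir.knots.knots, knots.knots):
            raise ValueError("all impulse responses must share the same knots")
    if Ta is None or Tb is None:
        dTa, dTb = default_contrast_times(knots)
        Ta = dTa if Ta is None else Ta
        Tb = dTb if Tb is None else Tb

    thetas = np.array([ir.theta for ir in irs])
    mu_theta = thetas.mean(axis=0)
    sigma_theta = np.cov(thetas, rowvar=False, ddof=1)
    sigma_theta = np.atleast_2d(sigma_theta)

    mean_ir = ImpulseResponse(knots, mu_theta)
    mu1 = mean_ir.mean_residence_time

    ratios = []
    for ir in irs:
        ra = float(ir_eval(ir, np.array([Ta]))[0])
        rb = float(ir_eval(ir, np.array([Tb]))[0])
        if ra > 0:
            ratios.append(rb / ra)
    if not ratios:
        raise ValueError(f"no curve is positive at Ta={Ta}; choose an earlier Ta")
    mu2 = float(np.clip(np.mean(ratios), 1e-6, 1.0))
    return Prior(knots, mu_theta, sigma_theta, mu1, mu2, float(Ta), float(Tb))


def ir_percentiles(
    ir: ImpulseResponse, probs, ref_time: float = 5.0
) -> np.ndarray:
    """Circulation-time percentiles of the normalised impulse response.

    q_p is the earliest time t >= ref_time at which R(t)/R(ref_time)
    has declined to 1 - p; the 50th percentile is the circulatory
    half-life of tracer molecules still present at the reference time.
    Solved exactly on the piecewise-linear form.  If the decline target is
    never reached inside the knot span, t_K is returned (flagged by being
    exactly the last knot).
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("percentile probabilities must lie in (0, 1)")
    r_ref = float(ir_eval(ir, np.array([ref_time]))[0])
    if r_ref <= 0:
        raise ValueError(f"impulse response is zero at ref_time={ref_time}")
    # evaluate R on the knot grid past ref_time; R is linear between knots
    ts = np.concatenate([[ref_time], ir.knots.knots[ir.knots.knots > ref_time]])
    rel = ir_eval(ir, ts) / r_ref
    out = np.empty(probs.size)
    for j, p in enumerate(probs):
        target = 1.0 - p
        below = np.where(rel <= target + 1e-15)[0]
        if below.size == 0:
            out[j] = ir.knots.t_end
            continue
        i = below[0]
        if i == 0:
            out[j] = ts[0]
            continue
        t0, t1 = ts[i - 1], ts[i]
        r0, r1 = rel[i - 1], rel[i]
        out[j] = t0 if r0 == r1 else t0 + (r0 - target) / (r0 - r1) * (t1 - t0)
    return out


def effective_dimension(irs: list[ImpulseResponse], threshold: float = 0.9) -> int:
    """Principal components needed to reach ``threshold`` of the correlation trace.

    Zero-variance coefficient coordinates (knots never activated across the
    collection) are dropped before the eigen-analysis.  A degenerate
    collection (no variation at all) returns 0.
    """
    if len(irs) < 2:
        raise ValueError("need at least two impulse responses")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    thetas = np.array([ir.theta for ir in irs])
    sd = thetas.std(axis=0, ddof=1)
    # cutoff relative to the coefficient scale: roundoff-level spread in a
    # coordinate is no variation
    keep = sd > 1e-10 * max(np.abs(thetas).max(), 1e-300)
    if not keep.any():
        warnings.warn("no coefficient variation across the collection")
        return 0
    sub = thetas[:, keep]
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eig = np.clip(eig, 0.0, None)
    cum = np.cumsum(eig)
    total = np.trace(corr)
    if threshold == 1.0:
        return int(np.sum(eig > 1e-10 * total))
    return int(np.searchsorted(cum, threshold * total - 1e-12) + 1)


def summarize_population(
    irs: list[ImpulseResponse],
    probs=(0.25, 0.5, 0.95),
    ref_time: float = 5.0,
    name: str = "tracer",
) -> pd.DataFrame:
    """Percentile summary table: mean +/- SE across curves for each percentile."""
    qs = np.array([ir_percentiles(ir, probs, ref_time) for ir in irs])
    n = len(irs)
    rows = {"tracer": name, "N": n}
    for j, p in enumerate(probs):
        rows[f"q{int(100 * p)}_mean"] = qs[:, j].mean()
        rows[f"q{int(100 * p)}_se"] = qs[:, j].std(ddof=1) / np.sqrt(n)
    return pd.DataFrame([rows])
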