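"""Constrained weighted least-squares extraction of the impulse response.

The blood-pool ROI measurement model is

    z_i = (1 - pi) (R * C_I)(t_i - Delta)
        + pi  (E_phi * R * C_I)(t_i - Delta)
        + alpha3 * S(t_i) + eps_i,

with R = sum_k theta_k B_k, E_phi the mono-exponential dispersion kernel,
S the background (spillover) pattern, and Var(eps_i) ~ 1/w_i.  For fixed
nuisance parameters (pi, phi, Delta) the coefficient fit is a quadratic
programme: minimise the weighted residual sum of squares subject to
theta >= 0 (shape constraints) and A'theta = 0 (identifiability constraints
fixing the mean residence time mu1 and a contrast ratio mu2 of the
normalised impulse response).  The nuisance parameters are then optimised
over the reduced objective WRSS(pi, phi, Delta) by multi-start + simplex
refinement, with the QP solved exactly at every evaluation.

The QP solver is a primal active-set method specialised to the structure
"non-negativity bounds + a few homogeneous equality rows": it starts from
the feasible point theta = 0 and maintains equality feasibility exactly, so
the identifiability constraints hold to linear-solve precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .ir_model import (
    ImpulseResponse,
    KnotVector,
    SampledCurve,
    basis_eval,
    basis_first_moments,
    basis_injection_matrix,
    basis_integrals,
    disperse_values,
    make_grid,
)
from .tac_io import FrameSchedule, InjectionProfile, ROITimeCourse

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintSpec",
    "FitResult",
    "default_contrast_times",
    "build_constraints",
    "build_background",
    "build_design",
    "wrss",
    "qp_solve",
    "fit_roi",
]


@dataclass(frozen=True)
class ConstraintSpec:
    """Identifiability constraints on the normalised impulse response.

    mu1 — target mean residence time int t R dt / int R dt (seconds).
    mu2 — target contrast ratio R(Tb)/R(Ta), in (0, 1].
    Either constraint can be disabled individually.
    """

    mu1: float
    mu2: float
    Ta: float
    Tb: float
    use_mu1: bool = True
    use_mu2: bool = True

    def __post_init__(self) -> None:
        if self.use_mu1 and self.mu1 <= 0:
            raise ValueError("mu1 must be positive")
        if self.use_mu2:
            if not 0 < self.mu2 <= 1:
                raise ValueError("mu2 must lie in (0, 1]")
            if not self.Ta < self.Tb:
                raise ValueError("need Ta < Tb")


def default_contrast_times(knots: KnotVector) -> tuple[float, float]:
    """Default (Ta, Tb) when a prior does not supply them.

    Ta at the knot a quarter of the way up the ladder (early, where R is
    still appreciably positive), Tb at three quarters of the last knot.
    """
    K = knots.K
    Ta = float(knots.knots[max(1, round(0.25 * K))])
    Tb = 0.75 * knots.t_end
    return Ta, Tb


def build_constraints(knots: KnotVector, spec: ConstraintSpec | None) -> np.ndarray:
    """Linear equality matrix A of shape (K+1, m) with A' theta_aug = 0.

    Column 1 (mean residence time): A_k1 = int (mu1 - t) B_k(t) dt.
    Column 2 (contrast ratio):      A_k2 = mu2 B_k(Ta) - B_k(Tb).
    The final row (the spillover coefficient alpha3) is zero: alpha3 is
    unconstrained by the identifiability conditions.
    """
    K = knots.K
    if spec is None:
        return np.zeros((K + 1, 0))
    cols = []
    if spec.use_mu1:
        m0 = basis_integrals(knots)
        m1 = basis_first_moments(knots)
        cols.append(spec.mu1 * m0 - m1)
    if spec.use_mu2:
        if spec.Ta >= knots.t_end or spec.Tb >= knots.t_end:
            raise ValueError(
                "contrast-ratio times must lie inside the knot span "
                f"(Ta={spec.Ta}, Tb={spec.Tb}, t_K={knots.t_end})"
            )
        ba = np.array([basis_eval(knots, k, spec.Ta) for k in range(1, K + 1)])
        bb = np.array([basis_eval(knots, k, spec.Tb) for k in range(1, K + 1)])
        cols.append(spec.mu2 * ba - bb)
    if not cols:
        return np.zeros((K + 1, 0))
    A = np.column_stack(cols)
    return np.vstack([A, np.zeros((1, A.shape[1]))])


def build_background(
    injection: InjectionProfile,
    delta: float,
    mode: str,
    grid: np.ndarray,
    prior=None,
    background_tac: ROITimeCourse | None = None,
) -> SampledCurve:
    """Background (spillover) pattern S on the fine grid.

    ``patlak``    — cumulative integral of the injection profile shifted by
                    Delta (Patlak-style tissue accumulation pattern).
    ``prior_aif`` — cumulative integral of the prior-mean AIF (R(mu_theta)
                    * C_I), shifted by Delta and normalised to 1 at the grid
                    end; requires a prior.
    ``measured``  — a supplied background TAC interpolated to the grid
                    (no Delta shift: it is already on scanner time).
    """
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    if mode == "patlak":
        if injection.kind == "bolus":
            vals = np.where(grid - delta >= 0, injection.mass, 0.0)
        else:
            # midpoint rule: exact for the square wave, second order otherwise
            mid = (grid[:-1] + grid[1:]) / 2.0
            ci = injection.eval_on(mid - delta)
            vals = np.concatenate([[0.0], np.cumsum(ci) * dt])
        return SampledCurve(grid, vals)
    if mode == "prior_aif":
        if prior is None:
            raise ValueError("background mode 'prior_aif' requires a prior")
        ir = ImpulseResponse(prior.knots, np.clip(prior.mu_theta, 0.0, None))
        aif = basis_injection_matrix(prior.knots, injection, grid) @ ir.theta
        cum = np.concatenate([[0.0], np.cumsum((aif[1:] + aif[:-1]) / 2.0) * dt])
        if cum[-1] > 0:
            cum = cum / cum[-1]
        t = grid - delta
        vals = np.interp(t, grid, cum, right=float(cum[-1]))
        vals = np.where(t < 0, 0.0, vals)
        return SampledCurve(grid, vals)
    if mode == "measured":
        if background_tac is None:
            raise ValueError("background mode 'measured' requires a background TAC")
        tm = background_tac.schedule.mid_times
        vals = np.interp(grid, tm, background_tac.z, left=0.0,
                         right=float(background_tac.z[-1]))
        return SampledCurve(grid, vals)
    raise ValueError(f"unknown background mode {mode!r}")


def _interp_columns(grid: np.ndarray, mat: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear interpolation of every column of ``mat`` at times ``t``.

    Zero before the grid start (causality), flat after the end.
    """
    dt = grid[1] - grid[0]
    idx = np.clip(np.searchsorted(grid, t), 1, grid.size - 1)
    frac = (t - grid[idx - 1]) / dt
    frac = np.clip(frac, 0.0, 1.0)
    out = mat[idx - 1] * (1.0 - frac)[:, None] + mat[idx] * frac[:, None]
    out[t < grid[0]] = 0.0
    return out


def build_design(
    bi_plain: np.ndarray,
    bi_dispersed: np.ndarray,
    background: SampledCurve,
    pi: float,
    delta: float,
    schedule: FrameSchedule,
    grid: np.ndarray,
) -> np.ndarray:
    """Design matrix X (n x (K+1)) at the given nuisance parameters.

    Columns 1..K: (1-pi) BI_k(t_i - Delta) + pi (E_phi*BI_k)(t_i - Delta);
    column K+1: the background pattern at the frame mid-times.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    t = schedule.mid_times - delta
    plain = _interp_columns(grid, bi_plain, t)
    if pi == 0.0:
        mix = plain
    else:
        disp = _interp_columns(grid, bi_dispersed, t)
        mix = (1.0 - pi) * plain + pi * disp
    s = background(schedule.mid_times)
    return np.column_stack([mix, s])


def wrss(theta_aug: np.ndarray, X: np.ndarray, z: np.ndarray, w: np.ndarray) -> float:
    """Weighted residual sum of squares sum_i w_i (z_i - x_i' theta)^2."""
    r = z - X @ theta_aug
    return float(w @ (r * r))


# ---------------------------------------------------------------------------
# Quadratic programme: min 0.5 x'Qx - c'x  s.t.  x >= 0 (masked), E x = 0
# ---------------------------------------------------------------------------


class QPInfeasibleError(RuntimeError):
    pass


def _kkt_solve(Q, c, E, free, ridge):
    """Solve the equality-constrained subproblem on the free coordinates.

    Returns (x_free, nu).  Falls back to least squares (smallest-norm
    convention) when the KKT matrix is singular.
    """
    nf = free.size
    Ef = E[free] if E.size else np.zeros((nf, 0))
    # restricted to the free set, equality columns can become vacuous or
    # linearly dependent (the dropped ones are then implied); keep an
    # independent subset via rank-revealing QR
    keep = np.zeros(Ef.shape[1], dtype=bool)
    if Ef.size:
        from scipy.linalg import qr as _qr

        _, r, piv = _qr(Ef, mode="economic", pivoting=True)
        diag = np.abs(np.diag(np.atleast_2d(r)))
        if diag.size and diag[0] > 0:
            rank = int(np.sum(diag > 1e-10 * diag[0]))
            keep[piv[:rank]] = True
    Ef = Ef[:, keep]
    m = Ef.shape[1]
    M = np.zeros((nf + m, nf + m))
    M[:nf, :nf] = Q[np.ix_(free, free)] + ridge * np.eye(nf)
    M[:nf, nf:] = Ef
    M[nf:, :nf] = Ef.T
    rhs = np.concatenate([c[free], np.zeros(m)])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        logger.warning("singular KKT system; using smallest-norm solution")
        sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
    nu_full = np.zeros(E.shape[1] if E.size else 0)
    if m:
        nu_full[keep] = sol[nf:]
    return sol[:nf], nu_full


def _active_set_qp(Q, c, E, nonneg, max_iter=None):
    """Primal active-set QP.  Start x = 0 (feasible: E 0 = 0, 0 >= 0).

    ``nonneg`` is a boolean mask of coordinates bound below by 0;
    unmasked coordinates are free.  Homogeneous equalities E'x... E has
    shape (p, m), constraints are E.T x = 0 -- stored column-wise to match
    the constraint-matrix convention A.
    """
    p = Q.shape[0]
    scale = max(np.abs(c).max(), np.abs(Q).max(), 1.0)
    ridge = 1e-12 * max(np.trace(Q) / p, 1.0)
    tol_feas = 1e-11
    tol_mult = 1e-9 * scale
    if max_iter is None:
        max_iter = 20 * (p + 1)

    x = np.zeros(p)
    working = nonneg.copy()  # True = clamped at zero
    nu = np.zeros(E.shape[1] if E.size else 0)
    for _ in range(max_iter):
        free = np.where(~working)[0]
        if free.size == 0:
            cand = np.zeros(p)
        else:
            xf, nu = _kkt_solve(Q, c, E, free, ridge)
            cand = np.zeros(p)
            cand[free] = xf
        viol = free[cand[free] < -tol_feas] if free.size else np.array([], int)
        if viol.size == 0:
            x = np.clip(cand, 0.0, None) if free.size else cand
            x[~nonneg] = cand[~nonneg]
            g = Q @ x - c
            # KKT solve uses Q x + E nu = c, so stationarity multipliers for
            # the clamped bounds are mu = g + E nu (zero on free coordinates)
            mult = g + (E @ nu if E.size else 0.0)
            clamped = np.where(working)[0]
            if clamped.size == 0:
                return x, working, nu
            j = clamped[np.argmin(mult[clamped])]
            if mult[j] >= -tol_mult:
                return x, working, nu
            working[j] = False
        else:
            d = cand - x
            neg = free[(cand[free] < -tol_feas) & (d[free] < 0)]
            alphas = x[neg] / (x[neg] - cand[neg])
            k = np.argmin(alphas)
            alpha = max(alphas[k], 0.0)
            x = x + alpha * d
            x[neg[k]] = 0.0
            working[neg[k]] = True
    warnings.warn("active-set QP did not converge; returning last iterate")
    return x, working, nu


def qp_solve(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    A: np.ndarray | None = None,
    penalty: tuple[float, np.ndarray, np.ndarray] | None = None,
    nonneg: np.ndarray | None = None,
    return_info: bool = False,
):
    """Non-negative, equality-constrained weighted least squares.

    Minimises sum_i w_i (z_i - x_i' theta)^2 [+ lambda (theta - mu)' P (theta
    - mu) over the first K coordinates] subject to theta >= 0 and A' theta = 0.

    ``penalty`` is (lambda, mu, P) with P the prior precision (inverse
    covariance) on the theta block; the augmented spillover coordinate is
    never penalised (no population information about spillover).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xw = X * w[:, None]
    Q = X.T @ Xw
    c = Xw.T @ z
    if penalty is not None:
        lam, mu, P = penalty
        if lam < 0:
            raise ValueError("penalty weight lambda must be >= 0")
        kdim = P.shape[0]
        Q[:kdim, :kdim] += lam * P
        c[:kdim] += lam * (P @ mu)
    if A is None:
        A = np.zeros((p, 0))
    if A.shape[0] != p:
        raise ValueError("constraint matrix row count must match parameter count")
    if nonneg is None:
        nonneg = np.ones(p, dtype=bool)
    x, working, nu = _active_set_qp(Q, c, A, nonneg)
    if A.shape[1]:
        resid = np.abs(A.T @ x)
        lim = 1e-8 * max(np.linalg.norm(x), 1e-30) * max(np.abs(A).max(), 1.0)
        if np.any(resid > max(lim, 1e-10)):
            raise QPInfeasibleError(
                f"equality constraints violated (max residual {resid.max():.3g}); "
                "constraint set may be infeasible with theta >= 0"
            )
    if return_info:
        return x, {"active_set": np.where(working)[0], "nu": nu, "Q": Q, "c": c}
    return x


# ---------------------------------------------------------------------------
# Full ROI fit: nested optimisation over the nuisance parameters
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a constrained (optionally penalised) ROI fit."""

    knots: KnotVector
    theta: np.ndarray
    alpha3: float
    pi: float
    phi: float
    delta: float
    wrss: float
    sigma2: float | None = None
    lam: float = 0.0
    objective: float = 0.0
    active_set: np.ndarray | None = None
    # fitting context retained for pooling / GCV (not serialised)
    X: np.ndarray | None = field(default=None, repr=False)
    z: np.ndarray | None = field(default=None, repr=False)
    w: np.ndarray | None = field(default=None, repr=False)
    A: np.ndarray | None = field(default=None, repr=False)

    @property
    def ir(self) -> ImpulseResponse:
        return ImpulseResponse(self.knots, np.clip(self.theta, 0.0, None))

    def aif(self, injection: InjectionProfile, grid: np.ndarray) -> SampledCurve:
        """Unscaled AIF estimate R_hat * C_I on the given grid."""
        vals = basis_injection_matrix(self.knots, injection, grid) @ self.ir.theta
        return SampledCurve(grid, vals)


class _FitWorkspace:
    """Precomputed quantities reused across nuisance-parameter evaluations."""

    def __init__(self, roi, injection, knots, background_mode, prior, background_tac,
                 grid_step=None):
        self.roi = roi
        self.injection = injection
        self.knots = knots
        horizon = roi.schedule.end_time
        # pad covers the largest negative time-shift probed by the optimiser
        self.grid = make_grid(horizon, step=grid_step, pad=90.0)
        self.bi = basis_injection_matrix(knots, injection, self.grid)
        self.dt = self.grid[1] - self.grid[0]
        self.background_mode = background_mode
        self.prior = prior
        self.background_tac = background_tac
        self._disp_cache: dict[float, np.ndarray] = {}
        # unshifted background base curve; the Delta shift is applied by
        # interpolation at the frame mid-times (cheap per evaluation)
        self.bg_base = build_background(
            injection, 0.0, background_mode, self.grid,
            prior=prior, background_tac=background_tac,
        )

    def dispersed(self, phi: float) -> np.ndarray:
        key = round(float(phi), 9)
        out = self._disp_cache.get(key)
        if out is None:
            out = disperse_values(self.bi, self.dt, phi)
            if len(self._disp_cache) > 64:
                self._disp_cache.clear()
            self._disp_cache[key] = out
        return out

    def background_at_midtimes(self, delta: float) -> np.ndarray:
        t = self.roi.schedule.mid_times
        if self.background_mode == "measured":
            return self.bg_base(t)
        return self.bg_base(t - delta)

    def design(self, pi: float, phi: float, delta: float) -> np.ndarray:
        if not 0.0 <= pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        t = self.roi.schedule.mid_times - delta
        plain = _interp_columns(self.grid, self.bi, t)
        if pi == 0.0:
            mix = plain
        else:
            disp = _interp_columns(self.grid, self.dispersed(phi), t)
            mix = (1.0 - pi) * plain + pi * disp
        return np.column_stack([mix, self.background_at_midtimes(delta)])


def fit_roi(
    roi: ROITimeCourse,
    injection: InjectionProfile,
    knots: KnotVector,
    spec: ConstraintSpec | None = None,
    background_mode: str = "patlak",
    prior=None,
    background_tac: ROITimeCourse | None = None,
    mode: str = "full",
    penalty: tuple[float, np.ndarray, np.ndarray] | None = None,
    pi_bounds: tuple[float, float] = (0.0, 1.0),
    phi_bounds: tuple[float, float] = (0.5, 120.0),
    delta_bounds: tuple[float, float] = (-30.0, 120.0),
    starts: tuple[int, int, int] = (4, 4, 5),
    refine: bool = True,
    ridge_polish: bool = True,
    n_refine: int = 3,
    maxfev: int = 120,
    warm_start: tuple[float, float, float] | None = None,
    grid_step: float | None = None,
) -> FitResult:
    """Fit the ROI measurement model, optimising (pi, phi, Delta) jointly.

    ``mode='arterial'`` fixes pi = 0 and alpha3 = 0 and optimises the
    time-shift Delta only — the configuration used for directly sampled
    arterial blood curves, which carry no dispersion or spillover.

    The reduced objective WRSS(pi, phi, Delta) (penalised when a prior
    penalty is supplied) is scanned on a coarse multi-start grid and the best
    start is refined with a bounded Nelder–Mead simplex; the inner
    coefficient problem is solved exactly by the active-set QP at every
    evaluation, so the result is deterministic for a fixed grid.
    """
    z, w = roi.z, roi.w
    if not np.any(z != 0.0):
        warnings.warn("all-zero ROI time-course; returning a zero fit")
        K = knots.K
        return FitResult(knots, np.zeros(K), 0.0, 0.0, phi_bounds[0], 0.0, 0.0)

    ws = _FitWorkspace(roi, injection, knots, background_mode, prior,
                       background_tac, grid_step=grid_step)
    A = build_constraints(knots, spec)
    K = knots.K
    arterial = mode == "arterial"
    if arterial:
        cols = np.arange(K)  # drop the spillover column
        nonneg = np.ones(K, dtype=bool)
        A_use = A[:K]
    else:
        cols = np.arange(K + 1)
        nonneg = np.ones(K + 1, dtype=bool)
        A_use = A

    def solve_at(pi, phi, delta):
        X = ws.design(pi, phi, delta)[:, cols]
        x, info = qp_solve(X, z, w, A_use, penalty=penalty, nonneg=nonneg,
                           return_info=True)
        fit_wrss = wrss(x, X, z, w)
        obj = fit_wrss
        if penalty is not None:
            lam, mu, P = penalty
            d = x[: P.shape[0]] - mu
            obj = fit_wrss + lam * float(d @ (P @ d))
        return x, X, fit_wrss, obj, info

    best_seen = {"x": None, "f": np.inf}

    def objective(params):
        if arterial:
            pi, phi, delta = 0.0, phi_bounds[0], params[0]
        else:
            pi, phi, delta = params
        pi = float(np.clip(pi, *pi_bounds))
        phi = float(np.clip(phi, *phi_bounds))
        delta = float(np.clip(delta, *delta_bounds))
        try:
            _, _, _, obj, _ = solve_at(pi, phi, delta)
        except QPInfeasibleError:
            return np.inf
        # every optimiser stage funnels through here; remember the best
        # point ever evaluated so no stage can lose progress
        if obj < best_seen["f"]:
            best_seen["f"] = obj
            best_seen["x"] = (pi, phi, delta)
        return obj

    # --- staged multi-start search ------------------------------------------
    # The reduced objective is far more sharply curved in the time-shift
    # Delta (frame-scale features) than in (pi, phi), so Delta is profiled
    # densely first, then the (pi, phi) grid is scanned at the best Delta
    # candidates, and finally the top starts are polished by a bounded
    # Nelder-Mead simplex.
    span = delta_bounds[1] - delta_bounds[0]
    if warm_start is not None:
        # local refinement from a previous solution (e.g. along the lambda
        # path, where the nuisance optimum moves slowly): a short Powell
        # run, no global scan
        if arterial:
            w_de = float(np.clip(warm_start[2], *delta_bounds))
            objective([w_de])
            if refine:
                optimize.minimize_scalar(
                    lambda d: objective([d]),
                    bounds=(max(delta_bounds[0], w_de - 5.0),
                            min(delta_bounds[1], w_de + 5.0)),
                    method="bounded", options={"xatol": 1e-3},
                )
        else:
            wpt = np.array([
                float(np.clip(warm_start[0], *pi_bounds)),
                float(np.clip(warm_start[1], *phi_bounds)),
                float(np.clip(warm_start[2], *delta_bounds)),
            ])
            objective(wpt)
            if refine:
                optimize.minimize(
                    objective, wpt, method="Powell",
                    bounds=[pi_bounds, phi_bounds, delta_bounds],
                    options={"maxfev": max(maxfev // 2, 30),
                             "xtol": 1e-5, "ftol": 1e-12},
                )
        if best_seen["x"] is None:
            raise RuntimeError("no feasible nuisance-parameter point found")
        pi_hat, phi_hat, delta_hat = best_seen["x"]
        x, X, fit_wrss, obj, info = solve_at(pi_hat, phi_hat, delta_hat)
        lam = penalty[0] if penalty is not None else 0.0
        return FitResult(
            knots=knots, theta=x[:K],
            alpha3=0.0 if arterial else float(x[K]),
            pi=pi_hat, phi=phi_hat, delta=delta_hat, wrss=fit_wrss, lam=lam,
            objective=obj, active_set=info["active_set"],
            X=X, z=z, w=w, A=A_use,
        )

    n_dense = int(np.clip(np.ceil(span / 2.0), max(starts[2], 5), 91))
    dgrid = np.linspace(delta_bounds[0], delta_bounds[1], n_dense)
    pi0 = 0.5 * (pi_bounds[0] + pi_bounds[1])
    phi0 = float(np.sqrt(max(phi_bounds[0], 1e-3) * phi_bounds[1]))

    if arterial:
        dvals = np.array([objective([d]) for d in dgrid])
        best = int(np.argmin(dvals))
        if not np.isfinite(dvals[best]):
            raise RuntimeError("no feasible time-shift found")
        x0, f0 = np.array([dgrid[best]]), dvals[best]
        if refine:
            lo = dgrid[max(best - 1, 0)]
            hi = dgrid[min(best + 1, dgrid.size - 1)]
            res = optimize.minimize_scalar(
                lambda d: objective([d]), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4},
            )
            if res.fun <= f0:
                x0 = np.array([res.x])
    else:
        # profile Delta both without dispersion (pi = 0, the shift of the
        # plain response) and at the mixed mid-point: the apparent shift is
        # biased by dispersion, so the two profiles bracket the truth
        dvals = np.array([objective([pi0, phi0, d]) for d in dgrid])
        order = np.argsort(dvals)
        if not np.isfinite(dvals[order[0]]):
            raise RuntimeError("no feasible nuisance-parameter start found")
        d_cands = [dgrid[order[0]]]
        for i in order[1:]:
            if abs(dgrid[i] - d_cands[0]) > max(4.0, span / 10.0):
                d_cands.append(dgrid[i])
                break
        if pi_bounds[0] == 0.0:
            dvals0 = np.array([objective([0.0, phi0, d]) for d in dgrid])
            d0 = dgrid[int(np.argmin(dvals0))]
            if all(abs(d0 - d) > 1.0 for d in d_cands):
                d_cands.append(d0)
        pis = np.linspace(pi_bounds[0], pi_bounds[1], starts[0])
        phis = np.geomspace(max(phi_bounds[0], 1e-3), phi_bounds[1], starts[1])
        cand = [(p, f, d) for d in d_cands for p in pis for f in phis]
        vals = np.array([objective(np.array(c)) for c in cand])
        x0, f0 = np.array(cand[int(np.argmin(vals))]), float(vals.min())
        if refine:
            bounds = [pi_bounds, phi_bounds, delta_bounds]
            powell_opts = {"maxfev": max(maxfev * 2, 100),
                           "xtol": 1e-7, "ftol": 1e-14}
            seen = []
            endpoints = []
            for idx in np.argsort(vals):
                if len(seen) >= n_refine or not np.isfinite(vals[idx]):
                    break
                start = np.array(cand[idx], dtype=float)
                # skip starts in an already-refined neighbourhood
                if any(
                    abs(start[0] - s[0]) < 0.2
                    and abs(np.log(max(start[1], 1e-3) / max(s[1], 1e-3))) < 0.7
                    and abs(start[2] - s[2]) < max(2.0, span / 30.0)
                    for s in seen
                ):
                    continue
                seen.append(start)
                res = optimize.minimize(
                    objective, start, method="Nelder-Mead", bounds=bounds,
                    options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-12},
                )
                # Powell polish: sequential line searches track the narrow
                # curved valley of the reduced objective better than the
                # collapsed simplex
                res = optimize.minimize(
                    objective, res.x, method="Powell", bounds=bounds,
                    options=powell_opts,
                )
                endpoints.append(np.array(res.x, dtype=float))
            if ridge_polish:
                # near the optimum the objective is almost flat along
                # pi * phi = const (the total-dispersion ridge): distinct
                # local minima on the ridge are reachable by jumps that
                # preserve the product, so re-polish from each endpoint
                for ep in endpoints:
                    if ep[0] <= 0:
                        continue
                    for c in (0.5, 2.0):
                        pj = float(np.clip(ep[0] * c, *pi_bounds))
                        fj = float(np.clip(ep[1] / c, *phi_bounds))
                        if pj <= 0:
                            continue
                        optimize.minimize(
                            objective, np.array([pj, fj, ep[2]]),
                            method="Powell", bounds=bounds,
                            options=powell_opts,
                        )

    # the best point ever evaluated across all stages is the answer
    pi_hat, phi_hat, delta_hat = best_seen["x"]
    x, X, fit_wrss, obj, info = solve_at(pi_hat, phi_hat, delta_hat)

    theta = x[:K]
    alpha3 = 0.0 if arterial else float(x[K])
    lam = penalty[0] if penalty is not None else 0.0
    return FitResult(
        knots=knots, theta=theta, alpha3=alpha3, pi=pi_hat, phi=phi_hat,
        delta=delta_hat, wrss=fit_wrss, lam=lam, objective=obj,
        active_set=info["active_set"], X=X, z=z, w=w, A=A_use,
    )
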