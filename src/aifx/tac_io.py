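"""Readers/writers for TACs, injection profiles, priors and fit results.

File formats (all plain text):

* TAC CSV — columns ``frame_start, frame_end, activity`` and optional
  ``weight``; header comment lines ``# time_unit: s|min`` and
  ``# decay_constant: <1/s>`` set units and the isotope decay constant.
* Arterial-sample CSV — columns ``time, activity`` (same unit comments).
* Prior JSON — ``{knots, mu_theta, sigma_theta, mu1, mu2, Ta, Tb}``.
* Fit JSON — ``{knots, theta, alpha3, pi, phi, delta, wrss, sigma2, lambda}``.

All times are seconds internally.  Frames are half-open intervals
[start, end), so abutting frames (end[i] == start[i+1]) are valid.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "ROITimeCourse",
    "InjectionProfile",
    "default_weights",
    "read_tac",
    "write_tac",
    "read_arterial",
    "write_fit",
    "read_fit",
    "write_prior",
    "read_prior",
]


@dataclass(frozen=True)
class FrameSchedule:
    """PET acquisition frames plus the isotope decay constant (1/s).

    The decay constant enters the frame-weight model: decay-corrected frame
    activities have variance inflated by exp(+tau * t_i) and deflated by the
    frame duration, so the precision weights are w_i ~ Delta_i exp(-tau t_i).
    """

    frame_start: np.ndarray
    frame_end: np.ndarray
    decay_constant: float = 0.0

    def __post_init__(self) -> None:
        fs = np.asarray(self.frame_start, dtype=float)
        fe = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", fs)
        object.__setattr__(self, "frame_end", fe)
        if fs.ndim != 1 or fs.shape != fe.shape or fs.size == 0:
            raise ValueError("frame_start and frame_end must be equal-length 1-d arrays")
        if np.any(fe <= fs):
            raise ValueError("every frame must have frame_end > frame_start")
        if np.any(fs[1:] < fe[:-1] - 1e-12):
            raise ValueError("frames must be ordered and non-overlapping")
        if self.decay_constant < 0:
            raise ValueError("decay_constant must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def mid_times(self) -> np.ndarray:
        return (self.frame_start + self.frame_end) / 2.0

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def end_time(self) -> float:
        return float(self.frame_end[-1])


def default_weights(schedule: FrameSchedule) -> np.ndarray:
    """Precision weights w_i = Delta_i * exp(-tau * t_i), rescaled to mean 1.

    The rescale is purely for numerical conditioning: the weighted
    least-squares minimiser is invariant to a global weight scale.
    """
    w = schedule.durations * np.exp(-schedule.decay_constant * schedule.mid_times)
    return w / w.mean()


@dataclass(frozen=True)
class ROITimeCourse:
    """Decay-corrected ROI activities on a frame schedule with weights."""

    schedule: FrameSchedule
    z: np.ndarray
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.shape != (self.schedule.n_frames,):
            raise ValueError("activity vector length must match the number of frames")
        w = self.w
        if w is None:
            w = default_weights(self.schedule)
        w = np.asarray(w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != z.shape:
            raise ValueError("weight vector length must match the number of frames")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")


@dataclass(frozen=True)
class InjectionProfile:
    """Tracer delivery wave-form C_I(t).

    kind ``square``: constant-rate infusion over [0, duration); default
    height 1/duration so the total injected mass integrates to 1.
    kind ``bolus``: instantaneous delivery of ``mass`` (delta function).
    kind ``measured``: (time, value) samples, linearly interpolated, zero
    outside the sampled support.
    """

    kind: str
    duration: float = 0.0
    height: float | None = None
    mass: float = 1.0
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("square", "bolus", "measured"):
            raise ValueError(f"unknown injection kind {self.kind!r}")
        if self.kind == "square":
            if self.duration <= 0:
                raise ValueError("square injection needs duration > 0")
            if self.height is not None and self.height < 0:
                raise ValueError("injection height must be non-negative")
        if self.kind == "bolus" and self.mass <= 0:
            raise ValueError("bolus mass must be positive")
        if self.kind == "measured":
            s = np.asarray(self.samples, dtype=float)
            if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
                raise ValueError("measured injection needs (time, value) sample pairs")
            if np.any(np.diff(s[:, 0]) <= 0):
                raise ValueError("measured injection times must be strictly increasing")
            if np.any(s[:, 1] < 0):
                raise ValueError("injection profile must be non-negative")
            object.__setattr__(self, "samples", s)

    @property
    def height_value(self) -> float:
        if self.kind != "square":
            raise ValueError("height only defined for square injections")
        return 1.0 / self.duration if self.height is None else self.height

    @property
    def total_integral(self) -> float:
        if self.kind == "square":
            return self.height_value * self.duration
        if self.kind == "bolus":
            return self.mass
        s = self.samples
        return float(np.trapezoid(s[:, 1], s[:, 0]))

    @property
    def support_end(self) -> float:
        if self.kind == "square":
            return self.duration
        if self.kind == "bolus":
            return 0.0
        return float(self.samples[-1, 0])

    def eval_on(self, t) -> np.ndarray:
        """C_I at times t.  A bolus has no finite pointwise representation."""
        t = np.asarray(t, dtype=float)
        if self.kind == "square":
            return np.where((t >= 0) & (t < self.duration), self.height_value, 0.0)
        if self.kind == "measured":
            s = self.samples
            out = np.interp(t, s[:, 0], s[:, 1], left=0.0, right=0.0)
            return np.where(t < 0, 0.0, out)
        raise ValueError("a bolus (delta) profile cannot be evaluated pointwise")

    @staticmethod
    def parse(text: str) -> "InjectionProfile":
        """Parse CLI shorthand ``square:<d>``, ``bolus[:<d>]`` or ``file:<path>``.

        ``bolus:<d>`` with d > 0 denotes a short square wave of that duration
        (the common usage of 'bolus' in injection protocols); ``bolus`` or
        ``bolus:0`` is an instantaneous unit-mass delivery.
        """
        head, _, arg = text.partition(":")
        if head == "square":
            return InjectionProfile("square", duration=float(arg))
        if head == "bolus":
            d = float(arg) if arg else 0.0
            if d > 0:
                return InjectionProfile("square", duration=d)
            return InjectionProfile("bolus")
        if head == "file":
            samples = read_arterial(arg)
            return InjectionProfile("measured", samples=samples)
        raise ValueError(f"cannot parse injection specification {text!r}")


# ---------------------------------------------------------------------------
# CSV / JSON plumbing
# ---------------------------------------------------------------------------


def _read_csv_with_comments(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV whose ``# key: value`` comment lines carry metadata."""
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                key, _, val = stripped.lstrip("#").partition(":")
                if val:
                    meta[key.strip()] = val.strip()
            elif stripped:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    df.columns = [c.strip() for c in df.columns]
    return df, meta


def _time_factor(meta: dict) -> float:
    unit = meta.get("time_unit", "s")
    if unit == "s":
        return 1.0
    if unit == "min":
        return 60.0
    raise ValueError(f"unsupported time unit {unit!r} (use 's' or 'min')")


def read_tac(path) -> ROITimeCourse:
    """Read a ROI time-activity curve CSV into an :class:`ROITimeCourse`.

    Missing weight column => weights from :func:`default_weights` using the
    decay constant declared in the header (default 0).
    """
    df, meta = _read_csv_with_comments(path)
    for col in ("frame_start", "frame_end", "activity"):
        if col not in df.columns:
            raise ValueError(f"TAC file {path} is missing column {col!r}")
    f = _time_factor(meta)
    tau = float(meta.get("decay_constant", 0.0)) / f
    schedule = FrameSchedule(
        df["frame_start"].to_numpy() * f, df["frame_end"].to_numpy() * f, tau
    )
    w = df["weight"].to_numpy() if "weight" in df.columns else None
    return ROITimeCourse(schedule, df["activity"].to_numpy(), w)


def write_tac(path, roi: ROITimeCourse) -> None:
    with open(path, "w") as fh:
        fh.write("# time_unit: s\n")
        fh.write(f"# decay_constant: {float(roi.schedule.decay_constant)!r}\n")
        fh.write("frame_start,frame_end,activity,weight\n")
        for s, e, z, w in zip(
            roi.schedule.frame_start, roi.schedule.frame_end, roi.z, roi.w
        ):
            fh.write(f"{float(s)!r},{float(e)!r},{float(z)!r},{float(w)!r}\n")


def read_arterial(path) -> np.ndarray:
    """Read a (time, activity) sample CSV; returns an (n, 2) array in seconds."""
    df, meta = _read_csv_with_comments(path)
    if "time" not in df.columns or "activity" not in df.columns:
        raise ValueError(f"arterial sample file {path} needs 'time' and 'activity'")
    f = _time_factor(meta)
    out = np.column_stack([df["time"].to_numpy() * f, df["activity"].to_numpy()])
    if np.any(np.diff(out[:, 0]) <= 0):
        raise ValueError("sample times must be strictly increasing")
    return out


def write_fit(path, fit) -> None:
    """Serialise a FitResult to JSON (lossless for all float fields)."""
    payload = {
        "knots": fit.knots.knots.tolist(),
        "theta": fit.theta.tolist(),
        "alpha3": fit.alpha3,
        "pi": fit.pi,
        "phi": fit.phi,
        "delta": fit.delta,
        "wrss": fit.wrss,
        "sigma2": fit.sigma2,
        "lambda": fit.lam,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit(path):
    from .constrained_fit import FitResult
    from .ir_model import KnotVector

    payload = json.loads(Path(path).read_text())
    return FitResult(
        knots=KnotVector(np.array(payload["knots"])),
        theta=np.array(payload["theta"]),
        alpha3=payload["alpha3"],
        pi=payload["pi"],
        phi=payload["phi"],
        delta=payload["delta"],
        wrss=payload["wrss"],
        sigma2=payload["sigma2"],
        lam=payload["lambda"],
    )


def write_prior(path, prior) -> None:
    payload = {
        "knots": prior.knots.knots.tolist(),
        "mu_theta": prior.mu_theta.tolist(),
        "sigma_theta": prior.sigma_theta.tolist(),
        "mu1": prior.mu1,
        "mu2": prior.mu2,
        "Ta": prior.Ta,
        "Tb": prior.Tb,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_prior(path):
    from .ir_model import KnotVector
    from .regularization import Prior

    payload = json.loads(Path(path).read_text())
    return Prior(
        knots=KnotVector(np.array(payload["knots"])),
        mu_theta=np.array(payload["mu_theta"]),
        sigma_theta=np.array(payload["sigma_theta"]),
        mu1=payload["mu1"],
        mu2=payload["mu2"],
        Ta=payload["Ta"],
        Tb=payload["Tb"],
    )
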