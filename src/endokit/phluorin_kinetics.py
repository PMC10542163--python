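"""pHluorin trace processing: background subtraction, photobleach
correction, baseline/peak normalization, single-exponential decay fits and
field-of-view recovery metrics.

The reporter is quenched inside acidic vesicles and bright after exocytosis;
the post-stimulus fluorescence decay therefore reports endocytosis plus
vesicle re-acidification.  Traces are modelled as

    y(t) = p + (1 - p) * exp(-(t - t_peak) / tau)      for t >= t_peak,

on the baseline/peak-normalized scale, where ``tau`` is the endocytic time
constant and ``p`` the plateau fraction (the fraction of the peak that never
recovers, nonzero when endocytosis is impaired).  Photobleaching is undone
multiplicatively, ``F_corr(t) = F(t) * exp(t / K)``, with K fitted on a
no-stimulation control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Trace",
    "BleachModel",
    "NormalizedTrace",
    "DecayFit",
    "FieldSummary",
    "subtract_background",
    "estimate_bleach_constant",
    "correct_and_normalize",
    "fit_decay",
    "recovery_metrics",
    "traces_from_csv",
    "traces_to_csv",
]


@dataclass
class Trace:
    """A fluorescence time series from one ROI (default 2 um^2, 2 Hz)."""

    times_s: np.ndarray
    intensities: np.ndarray
    stim_onset_s: float = 5.0
    stim_end_s: float = 5.5
    roi_area_um2: float = 2.0
    roi_id: str = "roi0"
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float).ravel()
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.times_s.size != self.intensities.size:
            raise ValueError("times and intensities differ in length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.count_nonzero(self.times_s < self.stim_onset_s) < 2:
            raise ValueError("need >= 2 samples before stimulus onset")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass(frozen=True)
class BleachModel:
    """Mono-exponential bleaching, F(t) ~ exp(-t / K).  K = inf means no
    measurable bleaching and the correction is the identity."""

    k_s: float
    f0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k_s > 0):
            raise ValueError("bleach constant K must be positive (or inf)")

    def correction(self, times_s: np.ndarray) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        if math.isinf(self.k_s):
            return np.ones_like(t)
        return np.exp(t / self.k_s)


@dataclass
class NormalizedTrace:
    """Bleach-corrected trace on the 0 (baseline) .. 1 (peak) scale."""

    times_s: np.ndarray
    y: np.ndarray
    baseline_index: int
    peak_index: int
    stim_onset_s: float
    stim_end_s: float


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential decay fit of a normalized trace.

    ``amplitude`` is the fitted peak level on the normalized scale; it is
    close to 1 and absorbs the noise in the single-frame peak used for
    normalization.  ``plateau`` is the plateau fraction of that amplitude.
    """

    tau_s: float
    plateau: float
    residual_rms: float
    converged: bool
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_s > 0):
            raise ValueError("tau must be positive")
        if not (-0.1 - 1e-9 <= self.plateau <= 1.1 + 1e-9):
            raise ValueError("plateau outside soft bounds [-0.1, 1.1]")


@dataclass
class FieldSummary:
    """Field-of-view average trace with its decay fit and percent of the
    peak remaining at the report time (default 60 s from imaging start)."""

    times_s: np.ndarray
    mean_y: np.ndarray
    fit: DecayFit
    percent_remaining: float
    measured_at_s: float
    truncated: bool = False


def subtract_background(
    data: Union[np.ndarray, Trace],
    radius_px: int = 50,
    background: Optional[float] = None,
):
    """Remove background: rolling-ball per frame for images, a constant
    offset (the mean of a user-designated background ROI) for traces.

    ``data`` may be a 2-D frame, a (t, y, x) stack, or a :class:`Trace`.
    Output intensities are clipped at a small negative epsilon.
    """
    if isinstance(data, Trace):
        if background is None:
            raise ValueError("trace mode requires a background level")
        out = Trace(
            data.times_s,
            np.maximum(data.intensities - float(background), -1e-9),
            data.stim_onset_s,
            data.stim_end_s,
            data.roi_area_um2,
            data.roi_id,
            data.field_id,
        )
        return out

    from skimage.restoration import rolling_ball

    arr = np.asarray(data, dtype=float)
    if np.any(arr < 0):
        raise ValueError("image input must be nonnegative")
    if arr.ndim == 2:
        frames = arr[None]
    elif arr.ndim == 3:
        frames = arr
    else:
        raise ValueError("expected a 2-D frame or 3-D stack")
    if radius_px >= min(frames.shape[1:]):
        raise ValueError("rolling-ball radius must be smaller than the frame")
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        out[i] = frame - rolling_ball(frame, radius=radius_px)
    out = np.maximum(out, 0.0)
    return out[0] if arr.ndim == 2 else out


def estimate_bleach_constant(control: Trace) -> BleachModel:
    """Fit F(t) = F0 * exp(-t / K) to a no-stimulation control trace.

    A log-linear regression provides the starting point; the constant is
    refined by nonlinear least squares.  A non-decaying control returns the
    K = inf sentinel (identity correction).
    """
    t = control.times_s
    f = control.intensities
    if np.any(f <= 0):
        f = np.clip(f, 1e-12, None)
    logf = np.log(f)
    slope, intercept = np.polyfit(t, logf, 1)
    if slope >= 0:
        return BleachModel(math.inf, float(np.mean(f)))
    k0 = -1.0 / slope
    f00 = math.exp(intercept)

    def resid(theta):
        return theta[0] * np.exp(-t / theta[1]) - f

    res = least_squares(resid, x0=[f00, k0], bounds=([1e-12, 1e-9], [np.inf, np.inf]))
    f0_hat, k_hat = res.x
    if k_hat > 100.0 * max(control.duration_s, 1e-9):
        return BleachModel(math.inf, float(f0_hat))
    return BleachModel(float(k_hat), float(f0_hat))


def correct_and_normalize(
    trace: Trace,
    bleach: BleachModel,
    peak_window_s: float = 10.0,
) -> NormalizedTrace:
    """Undo bleaching and normalize to the pre-stimulus frame and the
    post-stimulus peak.

    F_corr(t) = F(t) * exp(t / K); the baseline is the single frame
    immediately before stimulus onset and the peak is the maximum of F_corr
    in (onset, onset + peak_window_s].  The normalized trace is exactly 0 at
    the baseline frame and exactly 1 at the peak frame.
    """
    t = trace.times_s
    corr = trace.intensities * bleach.correction(t)
    pre = np.nonzero(t < trace.stim_onset_s)[0]
    ib = int(pre[-1])
    window = (t > trace.stim_onset_s) & (t <= trace.stim_onset_s + peak_window_s)
    if not np.any(window):
        raise ValueError("no samples in the peak search window")
    iw = np.nonzero(window)[0]
    ip = int(iw[np.argmax(corr[iw])])
    denom = corr[ip] - corr[ib]
    if denom == 0:
        raise ValueError("no response: peak equals baseline")
    y = (corr - corr[ib]) / denom
    return NormalizedTrace(t, y, ib, ip, trace.stim_onset_s, trace.stim_end_s)


def _decay_residuals(theta, s, y, with_plateau):
    if with_plateau:
        a, p, tau = theta
    else:
        (a, tau), p = theta, 0.0
    return a * (p + (1.0 - p) * np.exp(-s / tau)) - y


def _decay_jac(theta, s, y, with_plateau):
    if with_plateau:
        a, p, tau = theta
        e = np.exp(-s / tau)
        return np.column_stack(
            [p + (1.0 - p) * e, a * (1.0 - e), a * (1.0 - p) * e * s / tau**2]
        )
    a, tau = theta
    e = np.exp(-s / tau)
    return np.column_stack([e, a * e * s / tau**2])


def fit_decay(
    trace: NormalizedTrace,
    with_plateau: bool = True,
    tau_starts: Sequence[float] = (2.0, 10.0, 50.0),
) -> DecayFit:
    """Fit y(t) = a [p + (1 - p) exp(-(t - t_peak)/tau)] to the post-peak
    decay.

    The free amplitude ``a`` (close to 1) makes the fit robust to the noise
    of the single peak frame the trace was normalized to: anchoring the
    model at exactly 1 would propagate that one frame's noise into tau and
    the plateau.  For noise-free traces a = 1 and the fit is exact.

    Trust-region least squares with analytic Jacobian; a fixed multi-start
    grid over tau keeps the fit deterministic.  Bounds: tau in (0, 10x trace
    duration], p in [-0.1, 1.1], a in [0.2, 2].
    """
    s = trace.times_s[trace.peak_index :] - trace.times_s[trace.peak_index]
    ydata = trace.y[trace.peak_index :]
    if s.size < 5:
        raise ValueError("need >= 5 post-peak samples to fit the decay")
    duration = float(trace.times_s[-1] - trace.times_s[0])
    tau_hi = 10.0 * max(duration, 1.0)
    p0 = float(np.clip(ydata[-1], -0.05, 1.05))

    best = None
    for tau0 in tau_starts:
        tau0 = min(max(tau0, 1e-3), tau_hi * 0.99)
        if with_plateau:
            x0 = [1.0, p0, tau0]
            bounds = ([0.2, -0.1, 1e-6], [2.0, 1.1, tau_hi])
        else:
            x0 = [1.0, tau0]
            bounds = ([0.2, 1e-6], [2.0, tau_hi])
        res = least_squares(
            _decay_residuals,
            x0=x0,
            jac=_decay_jac,
            bounds=bounds,
            args=(s, ydata, with_plateau),
            method="trf",
        )
        if best is None or res.cost < best.cost:
            best = res
    if with_plateau:
        a_hat, p_hat, tau_hat = best.x
    else:
        (a_hat, tau_hat), p_hat = best.x, 0.0
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return DecayFit(
        float(tau_hat), float(p_hat), rms, bool(best.status > 0), float(a_hat)
    )


def recovery_metrics(
    traces: Sequence[NormalizedTrace],
    at_s: float = 60.0,
    with_plateau: bool = True,
) -> FieldSummary:
    """Field-of-view summary: mean normalized trace, decay fit of the mean,
    and percent of peak fluorescence remaining at ``at_s`` (nearest sample,
    measured from imaging start).

    Averaging is of the normalized y values, never of fitted parameters.
    Traces shorter than ``at_s`` report the last sample with a flag.
    """
    if not traces:
        raise ValueError("need >= 1 normalized trace")
    t0 = traces[0].times_s
    for tr in traces[1:]:
        if tr.times_s.size != t0.size or not np.allclose(tr.times_s, t0):
            raise ValueError("traces in a field must share one time base")
    mean_y = np.mean([tr.y for tr in traces], axis=0)

    truncated = bool(t0[-1] < at_s)
    idx = int(np.argmin(np.abs(t0 - at_s))) if not truncated else t0.size - 1
    percent = 100.0 * float(mean_y[idx])

    # peak of the mean trace, searched after stimulus onset
    window = t0 > traces[0].stim_onset_s
    iw = np.nonzero(window)[0]
    peak_index = int(iw[np.argmax(mean_y[iw])])
    mean_trace = NormalizedTrace(
        t0, mean_y, traces[0].baseline_index, peak_index,
        traces[0].stim_onset_s, traces[0].stim_end_s,
    )
    fit = fit_decay(mean_trace, with_plateau=with_plateau)
    return FieldSummary(t0, mean_y, fit, percent, float(t0[idx]), truncated)


def traces_from_csv(path, stim_onset_s: float = 5.0, stim_end_s: float = 5.5):
    """Load ROI traces from a tidy CSV with columns time_s, roi_id, F and
    optional field_id / background columns."""
    df = pd.read_csv(path)
    required = {"time_s", "roi_id", "F"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must contain columns {sorted(required)}")
    traces = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("time_s")
        field = str(sub["field_id"].iloc[0]) if "field_id" in sub else "field0"
        traces.append(
            Trace(
                sub["time_s"].to_numpy(),
                sub["F"].to_numpy(),
                stim_onset_s,
                stim_end_s,
                roi_id=str(roi_id),
                field_id=field,
            )
        )
    return traces


def traces_to_csv(traces: Sequence[Trace], path) -> pd.DataFrame:
    """Write traces as tidy CSV (time_s, roi_id, field_id, F)."""
    rows = [
        pd.DataFrame(
            {
                "time_s": tr.times_s,
                "roi_id": tr.roi_id,
                "field_id": tr.field_id,
                "F": tr.intensities,
            }
        )
        for tr in traces
    ]
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False)
    return df
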