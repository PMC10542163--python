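"""Binding-assay analytics: one-site saturation Kd fits and NMR chemical
shift perturbations.

The ELISA binding model is simple one-site saturation,
``B(c) = Bmax * c / (Kd + c)`` — no ligand depletion or cooperativity.
Chemical shift perturbations combine amide 1H and 15N shifts as the weighted
Euclidean norm ``sqrt(ddH^2 + (ddN / s)^2)`` with the conventional nitrogen
scale s = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "KdFit",
    "ShiftPair",
    "one_site",
    "fit_one_site_kd",
    "chemical_shift_perturbation",
    "csp_table",
]

NITROGEN_SCALE = 5.0


@dataclass
class BindingCurve:
    """Concentration-signal pairs from a saturation binding assay.

    Concentrations in nM, signals in arbitrary units; ``replicate`` labels
    repeated measurements at the same concentration.
    """

    concentrations: np.ndarray
    signals: np.ndarray
    replicate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float).ravel()
        self.signals = np.asarray(self.signals, dtype=float).ravel()
        if self.concentrations.size != self.signals.size:
            raise ValueError("concentrations and signals differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.replicate is None:
            self.replicate = np.zeros(self.concentrations.size, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate).ravel()

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_nM": self.concentrations,
                "signal": self.signals,
                "replicate": self.replicate,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingCurve":
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        return cls(df["concentration_nM"].to_numpy(), df["signal"].to_numpy(), rep)


@dataclass(frozen=True)
class KdFit:
    """One-site saturation fit result; standard errors from the Jacobian."""

    kd_nM: float
    bmax: float
    kd_se: float
    bmax_se: float
    residual_rms: float
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.kd_nM <= 0 or self.bmax <= 0:
            raise ValueError("Kd and Bmax must be positive")


@dataclass(frozen=True)
class ShiftPair:
    """Per-residue amide shift changes (ppm) between free and bound spectra."""

    residue: int
    delta_h_ppm: float
    delta_n_ppm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_h_ppm) and np.isfinite(self.delta_n_ppm)):
            raise ValueError("shift changes must be finite")


def one_site(c: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Fraction-bound signal of the one-site saturation model."""
    c = np.asarray(c, dtype=float)
    return bmax * c / (kd + c)


def fit_one_site_kd(curve: BindingCurve) -> KdFit:
    """Nonlinear least-squares fit of the one-site saturation model.

    Requires >= 4 distinct concentrations.  The fit is flagged unreliable
    when the titration does not reach saturation (max concentration below
    Kd/10), since Bmax and Kd are then nearly unidentifiable.
    """
    if curve.n_distinct < 4:
        raise ValueError("need >= 4 distinct concentrations to fit Kd")
    c, y = curve.concentrations, curve.signals
    bmax0 = max(float(y.max()), 1e-12)
    pos = c[c > 0]
    # start Kd at the concentration whose signal is nearest half-saturation
    kd0 = float(c[np.argmin(np.abs(y - bmax0 / 2.0))])
    if kd0 <= 0:
        kd0 = float(np.median(pos)) if pos.size else 1.0

    popt, pcov = curve_fit(
        one_site,
        c,
        y,
        p0=[bmax0, kd0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=10000,
    )
    bmax, kd = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = y - one_site(c, bmax, kd)
    rms = float(np.sqrt(np.mean(resid**2)))
    reliable = bool(c.max() >= kd / 10.0)
    return KdFit(kd, bmax, float(perr[1]), float(perr[0]), rms, reliable)


def chemical_shift_perturbation(
    delta_h_ppm,
    delta_n_ppm=None,
    nitrogen_scale: float = NITROGEN_SCALE,
):
    """Weighted-Euclidean CSP, ``sqrt(ddH^2 + (ddN/s)^2)`` in ppm.

    Accepts scalars, arrays, or a :class:`ShiftPair` as first argument.
    Symmetric in the sign of each input and homogeneous of degree 1.
    """
    if isinstance(delta_h_ppm, ShiftPair):
        pair = delta_h_ppm
        delta_h_ppm, delta_n_ppm = pair.delta_h_ppm, pair.delta_n_ppm
    dh = np.asarray(delta_h_ppm, dtype=float)
    dn = np.asarray(delta_n_ppm, dtype=float)
    out = np.sqrt(dh**2 + (dn / nitrogen_scale) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_table(df: pd.DataFrame, nitrogen_scale: float = NITROGEN_SCALE) -> pd.DataFrame:
    """Append a ``csp_ppm`` column to a (residue, delta_h_ppm, delta_n_ppm) table."""
    out = df.copy()
    out["csp_ppm"] = chemical_shift_perturbation(
        df["delta_h_ppm"].to_numpy(), df["delta_n_ppm"].to_numpy(), nitrogen_scale
    )
    return out
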