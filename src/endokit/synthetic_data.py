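"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Each generator returns its ground truth alongside the data so recovery can
be tested without any external dataset:

* STED-like two-channel fields — Gaussian blobs convolved with a Gaussian
  PSF plus optional Poisson or Gaussian noise.  Convolution of a Gaussian
  blob with a Gaussian PSF is evaluated in closed form (variances add, flux
  is conserved), so noise-free fields match direct evaluation of the stated
  formula at every pixel.
* EM synapse profiles — a membrane polyline carrying parametric
  semicircular or omega-shaped (bulb + neck) pits, vesicle circles and
  endosome polygons, emitted in the annotation JSON schema.
* pHluorin traces — baseline, linear rise during the stimulus train, then
  exponential decay to a plateau, all multiplied by mono-exponential
  bleaching; sampled at 2 Hz with the stimulus train at 5-5.5 s (10 pulses
  at 20 Hz) by default.
* One-site saturation binding curves.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .binding_metrics import BindingCurve
from .phluorin_kinetics import Trace
from .sted_distance import DEFAULT_PIXEL_PITCH_NM, Image2D

__all__ = [
    "GaussianBlob",
    "PointSource",
    "GroundTruthField",
    "PitSpec",
    "EndosomeSpec",
    "GroundTruthProfile",
    "GroundTruthTrace",
    "make_sted_field",
    "make_em_profile",
    "make_phluorin_trace",
    "make_binding_curve",
    "demo_colocalization_field",
]


# ---------------------------------------------------------------------------
# STED fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianBlob:
    """Reference-channel structure: isotropic Gaussian of peak ``amplitude``
    and width ``sigma_nm`` centered at (x, y) in nm."""

    x_nm: float
    y_nm: float
    amplitude: float
    sigma_nm: float


@dataclass(frozen=True)
class PointSource:
    """Target-channel punctum; ``amplitude`` is the observed peak after PSF
    convolution."""

    x_nm: float
    y_nm: float
    amplitude: float


@dataclass
class GroundTruthField:
    """Specification + ground truth of one synthetic two-channel field."""

    reference_blobs: list[GaussianBlob]
    target_puncta: list[PointSource]
    shape: tuple[int, int] = (64, 64)
    pixel_pitch_nm: float = DEFAULT_PIXEL_PITCH_NM
    psf_sigma_nm: float = 60.0
    noise: Union[str, tuple] = "none"  # "none" | "poisson" | ("gaussian", sigma)
    photons_per_unit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_pitch_nm > 0):
            raise ValueError("pixel pitch must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("PSF sigma must be >= 0")
        h_nm = self.shape[0] * self.pixel_pitch_nm
        w_nm = self.shape[1] * self.pixel_pitch_nm
        for b in list(self.reference_blobs) + list(self.target_puncta):
            if b.amplitude <= 0:
                raise ValueError("amplitudes must be positive")
            if not (0 <= b.x_nm <= w_nm and 0 <= b.y_nm <= h_nm):
                raise ValueError(
                    f"source at ({b.x_nm}, {b.y_nm}) nm is outside the "
                    f"{w_nm} x {h_nm} nm image bounds"
                )
        mode = self.noise[0] if isinstance(self.noise, tuple) else self.noise
        if mode not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def _pixel_centers(shape: tuple[int, int], pitch: float):
    ys = (np.arange(shape[0]) + 0.5) * pitch
    xs = (np.arange(shape[1]) + 0.5) * pitch
    return np.meshgrid(xs, ys)


def _render_gaussian(xx, yy, x0, y0, peak, sigma):
    return peak * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


def _apply_noise(img: np.ndarray, spec: GroundTruthField, rng) -> np.ndarray:
    mode = spec.noise[0] if isinstance(spec.noise, tuple) else spec.noise
    if mode == "none":
        return img
    if mode == "poisson":
        counts = rng.poisson(np.clip(img, 0, None) * spec.photons_per_unit)
        return counts / spec.photons_per_unit
    sigma = float(spec.noise[1])
    return np.clip(img + rng.normal(0.0, sigma, img.shape), 0.0, None)


def make_sted_field(spec: GroundTruthField) -> tuple[dict[str, Image2D], GroundTruthField]:
    """Render the two channels of a synthetic STED field.

    Reference blobs are convolved with the PSF analytically: a blob of peak
    A and width sigma becomes a Gaussian of width sqrt(sigma^2 + psf^2) and
    peak A * sigma^2 / (sigma^2 + psf^2) (flux conserved).  Target puncta
    are point sources whose PSF image is a Gaussian of width psf_sigma and
    the stated peak; with psf_sigma = 0 the full amplitude lands in the
    pixel containing the source.  Ground truth is returned unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    pitch = spec.pixel_pitch_nm
    xx, yy = _pixel_centers(spec.shape, pitch)

    ref = np.zeros(spec.shape)
    for b in spec.reference_blobs:
        var = b.sigma_nm**2 + spec.psf_sigma_nm**2
        if var == 0:
            row = min(int(b.y_nm / pitch), spec.shape[0] - 1)
            col = min(int(b.x_nm / pitch), spec.shape[1] - 1)
            ref[row, col] += b.amplitude
        else:
            peak = b.amplitude * (b.sigma_nm**2 / var) if b.sigma_nm > 0 else b.amplitude
            ref += _render_gaussian(xx, yy, b.x_nm, b.y_nm, peak, math.sqrt(var))

    tgt = np.zeros(spec.shape)
    for p in spec.target_puncta:
        if spec.psf_sigma_nm == 0:
            row = min(int(p.y_nm / pitch), spec.shape[0] - 1)
            col = min(int(p.x_nm / pitch), spec.shape[1] - 1)
            tgt[row, col] += p.amplitude
        else:
            tgt += _render_gaussian(xx, yy, p.x_nm, p.y_nm, p.amplitude, spec.psf_sigma_nm)

    images = {
        "reference": Image2D(_apply_noise(ref, spec, rng), pitch, "reference"),
        "target": Image2D(_apply_noise(tgt, spec, rng), pitch, "target"),
    }
    return images, spec


def demo_colocalization_field(
    n_hosts: int = 10,
    n_guests: int = 10,
    n_inside: int = 7,
    pixel_pitch_nm: float = DEFAULT_PIXEL_PITCH_NM,
    seed: int = 0,
) -> tuple[dict[str, Image2D], dict]:
    """A noise-free field with ``n_hosts`` host blobs on a grid and
    ``n_guests`` guest puncta of which exactly ``n_inside`` sit inside the
    hosts' half-maximum boundaries.

    The host half-max radius is known analytically (sigma_eff sqrt(2 ln 2)),
    so inside guests are placed well within it and outside guests in empty
    grid cells far from every host.
    """
    if n_inside > min(n_hosts, n_guests):
        raise ValueError("cannot place more inside-guests than hosts or guests")
    pitch = pixel_pitch_nm
    blob_sigma = 3.0 * pitch
    psf_sigma = 2.0 * pitch
    sigma_eff = math.hypot(blob_sigma, psf_sigma)
    halfmax_r = sigma_eff * math.sqrt(2.0 * math.log(2.0))

    n_cells = n_hosts + (n_guests - n_inside)
    cols = int(math.ceil(math.sqrt(n_cells)))
    rows_n = int(math.ceil(n_cells / cols))
    cell = 20.0 * pitch  # grid spacing, well above the half-max diameter
    margin = 12.0 * pitch
    shape_px = (
        int(round((rows_n * cell + 2 * margin) / pitch)),
        int(round((cols * cell + 2 * margin) / pitch)),
    )
    centers = [
        (margin + (c + 0.5) * cell, margin + (r + 0.5) * cell)
        for r in range(rows_n)
        for c in range(cols)
    ][:n_cells]

    hosts = [GaussianBlob(x, y, 1000.0, blob_sigma) for x, y in centers[:n_hosts]]
    rng = np.random.default_rng(seed)
    guests = []
    for i in range(n_inside):  # well inside: offset < half of the half-max radius
        hx, hy = centers[i]
        ang = rng.uniform(0, 2 * math.pi)
        rad = 0.3 * halfmax_r
        guests.append(PointSource(hx + rad * math.cos(ang), hy + rad * math.sin(ang), 800.0))
    for i in range(n_guests - n_inside):  # empty grid cells, far from all hosts
        gx, gy = centers[n_hosts + i]
        guests.append(PointSource(gx, gy, 800.0))

    spec = GroundTruthField(
        reference_blobs=hosts,
        target_puncta=guests,
        shape=shape_px,
        pixel_pitch_nm=pitch,
        psf_sigma_nm=psf_sigma,
        noise="none",
        seed=seed,
    )
    images, _ = make_sted_field(spec)
    truth = {
        "spec": spec,
        "halfmax_radius_nm": halfmax_r,
        "n_hosts": n_hosts,
        "n_guests": n_guests,
        "n_inside": n_inside,
        "fraction_inside": n_inside / n_guests,
    }
    return images, truth


# ---------------------------------------------------------------------------
# EM profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PitSpec:
    """Parametric endocytic pit attached to the membrane.

    ``position`` is the arc-length fraction of the membrane at the base
    midpoint.  ``shape`` is "semicircle" (depth = base/2 by geometry) or
    "omega" (circular bulb + straight neck of width ``neck_nm``).
    """

    position: float
    base_nm: float
    shape: str = "semicircle"
    depth_nm: Optional[float] = None
    neck_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.position < 1.0):
            raise ValueError("pit position must be a fraction in (0, 1)")
        if self.base_nm <= 0:
            raise ValueError("pit base width must be positive")
        if self.shape not in ("semicircle", "omega"):
            raise ValueError(f"unknown pit shape {self.shape!r}")
        if self.shape == "omega":
            if self.depth_nm is None or self.neck_nm is None:
                raise ValueError("omega pits need depth_nm and neck_nm")
            if not (0 < self.neck_nm < self.base_nm):
                raise ValueError("neck must be narrower than the base")
            if self.depth_nm <= self.neck_nm / 2:
                raise ValueError("omega depth too shallow for the bulb")


@dataclass(frozen=True)
class EndosomeSpec:
    cx_nm: float
    cy_nm: float
    diameter_nm: float
    circular: bool = True
    ferritin: bool = False


@dataclass
class GroundTruthProfile:
    """Specification + ground truth of one synthetic EM synaptic profile."""

    membrane_nm: np.ndarray
    psd_intervals: list[tuple[int, int]] = field(default_factory=list)
    vesicle_diameters_nm: list[float] = field(default_factory=list)
    vesicle_ferritin: Optional[list[bool]] = None
    pits: list[PitSpec] = field(default_factory=list)
    endosomes: list[EndosomeSpec] = field(default_factory=list)
    scale_nm_per_px: float = 2.0
    time_point: Union[str, float] = "no-stim"
    condition: str = "synthetic"
    micrograph_id: str = "synthetic-0"

    def __post_init__(self) -> None:
        self.membrane_nm = np.asarray(self.membrane_nm, dtype=float)
        if self.membrane_nm.ndim != 2 or self.membrane_nm.shape[0] < 2:
            raise ValueError("membrane needs >= 2 points")
        if any(d <= 0 for d in self.vesicle_diameters_nm):
            raise ValueError("vesicle diameters must be positive")
        if self.vesicle_ferritin is None:
            self.vesicle_ferritin = [False] * len(self.vesicle_diameters_nm)


def _arc_point(membrane: np.ndarray, s: float) -> np.ndarray:
    arcs = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(membrane, axis=0), axis=1))]
    )
    s = float(np.clip(s, 0.0, arcs[-1]))
    i = int(np.searchsorted(arcs, s, side="right") - 1)
    i = min(i, membrane.shape[0] - 2)
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg == 0 else (s - arcs[i]) / seg
    return membrane[i] + t * (membrane[i + 1] - membrane[i])


def _pit_base_endpoints(
    membrane: np.ndarray, s_mid: float, base: float
) -> tuple[np.ndarray, np.ndarray]:
    """Points on the membrane straddling s_mid whose chord length equals the
    pit base width (exact on straight membrane, bisection otherwise)."""
    arcs = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(membrane, axis=0), axis=1))]
    )
    total = arcs[-1]
    if base >= total:
        raise ValueError("pit base wider than the membrane span")

    def chord(h: float) -> float:
        return float(
            np.linalg.norm(_arc_point(membrane, s_mid + h) - _arc_point(membrane, s_mid - h))
        )

    h = base / 2.0
    if abs(chord(h) - base) < 1e-12 * base:
        pass  # straight membrane: arc offset == chord
    else:
        lo, hi = base / 2.0, min(s_mid, total - s_mid)
        if chord(hi) < base:
            raise ValueError("membrane too curved/short to fit the pit base")
        from scipy.optimize import brentq

        h = brentq(lambda x: chord(x) - base, lo, hi, xtol=1e-12)
    return _arc_point(membrane, s_mid - h), _arc_point(membrane, s_mid + h)


def _semicircle_local(base: float, n: int = 65) -> np.ndarray:
    """Semicircular pit in chord coordinates (u along chord, v outward)."""
    r = base / 2.0
    theta = np.linspace(math.pi, 0.0, n)  # odd n includes the apex exactly
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _omega_local(base: float, depth: float, neck: float, n_arc: int = 65) -> np.ndarray:
    """Omega pit: straight neck from the base endpoints to a circular bulb
    whose apex sits exactly ``depth`` above the chord."""
    w = neck / 2.0
    r_max = (depth**2 + w**2) / (2.0 * depth)
    r = max(0.9 * r_max, 1.001 * w)
    if r >= r_max:
        r = 0.5 * (w + r_max)  # very shallow bulb: fall back between bounds
    c = depth - r
    y_n = c - math.sqrt(r**2 - w**2)
    if y_n < 0:
        raise ValueError("omega pit parameters give a neck below the membrane")
    phi_r = math.atan2(y_n - c, w)
    phi_l = math.atan2(y_n - c, -w) + 2.0 * math.pi
    phis = np.linspace(phi_l, phi_r, n_arc)  # symmetric about pi/2: apex hit
    arc = np.column_stack([r * np.cos(phis), c + r * np.sin(phis)])
    pts = [(-base / 2.0, 0.0), (-w, y_n)]
    pts.extend(map(tuple, arc))
    pts.extend([(w, y_n), (base / 2.0, 0.0)])
    return np.asarray(pts)


def make_em_profile(spec: GroundTruthProfile) -> tuple[dict, GroundTruthProfile]:
    """Emit the annotation record (JSON schema, pixel coords) for a
    parametric synapse profile; the spec is the ground truth.

    Semicircular pits of radius r produce polylines whose base chord is
    exactly 2r long and whose apex is exactly r above the chord; omega pits
    honor the stated base, neck and depth.
    """
    membrane = spec.membrane_nm
    arcs = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(membrane, axis=0), axis=1))]
    )
    total = arcs[-1]
    pit_polylines = []
    for pit in spec.pits:
        p0, p1 = _pit_base_endpoints(membrane, pit.position * total, pit.base_nm)
        chord = p1 - p0
        chord_len = float(np.linalg.norm(chord))
        t_hat = chord / chord_len
        n_hat = np.array([t_hat[1], -t_hat[0]])  # left normal: into the cell
        if pit.shape == "semicircle":
            local = _semicircle_local(chord_len)
        else:
            local = _omega_local(chord_len, pit.depth_nm, pit.neck_nm)
        mid = (p0 + p1) / 2.0
        world = mid + local[:, :1] * t_hat + local[:, 1:] * n_hat
        world[0] = p0  # base endpoints exactly on the membrane
        world[-1] = p1
        pit_polylines.append(world)

    theta = np.linspace(0.0, 2.0 * math.pi, 33)[:-1]
    endo_polys = []
    for e in spec.endosomes:
        r = e.diameter_nm / 2.0
        endo_polys.append(
            np.column_stack(
                [e.cx_nm + r * np.cos(theta), e.cy_nm + r * np.sin(theta)]
            )
        )

    # vesicles are placed on a jitter-free grid above the membrane bbox
    x0, y0 = membrane[:, 0].min(), membrane[:, 1].min()
    vesicles = []
    for i, (d, fer) in enumerate(zip(spec.vesicle_diameters_nm, spec.vesicle_ferritin)):
        vesicles.append(
            {
                "cx": (x0 + 100.0 + 90.0 * i) / spec.scale_nm_per_px,
                "cy": (y0 - 150.0 - 60.0 * (i % 3)) / spec.scale_nm_per_px,
                "d_nm": float(d),
                "ferritin": bool(fer),
            }
        )

    s = spec.scale_nm_per_px
    record = {
        "micrograph_id": spec.micrograph_id,
        "condition": spec.condition,
        "time_point": spec.time_point,
        "scale_nm_per_px": s,
        "membrane": (membrane / s).tolist(),
        "psd": [list(iv) for iv in spec.psd_intervals],
        "vesicles": vesicles,
        "endosomes": [
            {"polygon": (poly / s).tolist(), "circular": e.circular, "ferritin": e.ferritin}
            for poly, e in zip(endo_polys, spec.endosomes)
        ],
        "pits": [(p / s).tolist() for p in pit_polylines],
        "section_thickness_nm": 40.0,
    }
    return record, spec


# ---------------------------------------------------------------------------
# pHluorin traces
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthTrace:
    """Specification + ground truth of one synthetic pHluorin trace.

    Defaults encode the standard protocol: 2 Hz sampling, 5 s baseline,
    10 stimuli at 20 Hz (stimulus window 5-5.5 s), mono-exponential decay
    with plateau, multiplied by mono-exponential bleaching.
    """

    sampling_rate_hz: float = 2.0
    duration_s: float = 120.0
    baseline_f0: float = 100.0
    amplitude: float = 100.0
    onset_s: float = 5.0
    stim_count: int = 10
    stim_rate_hz: float = 20.0
    tau_s: float = 10.7
    plateau: float = 0.0
    bleach_k_s: float = 300.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not (self.tau_s > 0):
            raise ValueError("tau must be positive")
        if not (self.bleach_k_s > 0):
            raise ValueError("bleach constant must be positive (or inf)")
        if not (0.0 <= self.plateau <= 1.0):
            raise ValueError("plateau fraction must be in [0, 1]")

    @property
    def stim_end_s(self) -> float:
        return self.onset_s + self.stim_count / self.stim_rate_hz


def ideal_trace(spec: GroundTruthTrace, times_s: np.ndarray) -> np.ndarray:
    """Noise- and bleach-free trace: baseline, linear rise across the
    stimulus window, then exponential decay to the plateau."""
    t = np.asarray(times_s, dtype=float)
    rise_end = spec.stim_end_s
    out = np.full(t.shape, spec.baseline_f0)
    rising = (t >= spec.onset_s) & (t < rise_end)
    out[rising] = spec.baseline_f0 + spec.amplitude * (
        (t[rising] - spec.onset_s) / (rise_end - spec.onset_s)
    )
    after = t >= rise_end
    out[after] = spec.baseline_f0 + spec.amplitude * (
        spec.plateau + (1.0 - spec.plateau) * np.exp(-(t[after] - rise_end) / spec.tau_s)
    )
    return out


def make_phluorin_trace(spec: GroundTruthTrace) -> tuple[Trace, GroundTruthTrace]:
    """Sample the observed trace: ideal(t) * exp(-t / K) + Gaussian noise."""
    n = int(round(spec.duration_s * spec.sampling_rate_hz)) + 1
    t = np.arange(n) / spec.sampling_rate_hz
    ideal = ideal_trace(spec, t)
    bleach = (
        np.ones_like(t) if math.isinf(spec.bleach_k_s) else np.exp(-t / spec.bleach_k_s)
    )
    observed = ideal * bleach
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        observed = observed + rng.normal(0.0, spec.noise_sigma, observed.shape)
    trace = Trace(
        t,
        observed,
        stim_onset_s=spec.onset_s,
        stim_end_s=spec.stim_end_s,
    )
    return trace, spec


# ---------------------------------------------------------------------------
# binding curves
# ---------------------------------------------------------------------------


def make_binding_curve(
    kd_nM: float,
    bmax: float,
    concentrations_nM: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> tuple[BindingCurve, dict]:
    """One-site saturation curve: signal = Bmax c / (Kd + c) + noise."""
    if kd_nM <= 0:
        raise ValueError("Kd must be positive")
    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    all_c = np.tile(conc, replicates)
    rep = np.repeat(np.arange(replicates), conc.size)
    signal = bmax * all_c / (kd_nM + all_c)
    if noise_sigma > 0:
        signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
    curve = BindingCurve(all_c, signal, rep)
    return curve, {"kd_nM": kd_nM, "bmax": bmax, "noise_sigma": noise_sigma}
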