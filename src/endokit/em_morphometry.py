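"""Electron-micrograph morphometry from annotation coordinates.

Consumes per-micrograph annotations of one synaptic profile — plasma
membrane polyline, postsynaptic density (PSD) interval(s), vesicle circles,
endosome polygons and endocytic-pit polylines — and produces the standard
flash-and-freeze readouts: per-profile structure counts over the time
course, and pit width/depth geometry.

Classification rules: vesicles below 60 nm diameter are synaptic vesicles,
60-100 nm (inclusive) are large endocytic vesicles (LEVs), circular
structures above 100 nm count as endosomes alongside annotated endosome
polygons.  Pit width is the Euclidean length of the base chord (the segment
joining the two base endpoints, which are the polyline's first and last
vertices); depth is the maximum perpendicular distance from the base chord
to any pit vertex.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .stats_report import MedianCI, median_with_ci

__all__ = [
    "Vesicle",
    "Endosome",
    "SynapticProfile",
    "StructureCounts",
    "PitMeasurement",
    "AnnotationError",
    "parse_annotations",
    "write_annotations",
    "classify_structures",
    "pit_geometry",
    "per_profile_counts",
    "timecourse_summary",
    "SV_LV_BOUND_NM",
    "LV_UPPER_BOUND_NM",
]

#: large-vesicle diameter window, bounds inclusive
SV_LV_BOUND_NM = 60.0
LV_UPPER_BOUND_NM = 100.0

#: pit base endpoints must lie within this distance of the membrane
PIT_BASE_TOL_NM = 5.0

NO_STIM = "no-stim"


class AnnotationError(ValueError):
    """Raised when annotation records fail validation; carries a per-record
    report in ``errors``."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid annotations:\n" + "\n".join(errors))


@dataclass(frozen=True)
class Vesicle:
    cx_nm: float
    cy_nm: float
    diameter_nm: float
    ferritin: bool = False

    def __post_init__(self) -> None:
        if not (self.diameter_nm > 0):
            raise ValueError(f"vesicle diameter must be positive, got {self.diameter_nm}")


@dataclass
class Endosome:
    polygon_nm: np.ndarray
    circular: bool = False
    ferritin: bool = False

    def __post_init__(self) -> None:
        self.polygon_nm = np.asarray(self.polygon_nm, dtype=float)
        if self.polygon_nm.ndim != 2 or self.polygon_nm.shape[0] < 3:
            raise ValueError("endosome polygon needs >= 3 vertices")


@dataclass
class SynapticProfile:
    """One annotated EM section of a synapse, coordinates in nm."""

    micrograph_id: str
    condition: str
    time_point: Union[str, float]  # NO_STIM or seconds after stimulation
    scale_nm_per_px: float
    membrane_nm: np.ndarray
    psd_intervals: list[tuple[int, int]] = field(default_factory=list)
    vesicles: list[Vesicle] = field(default_factory=list)
    endosomes: list[Endosome] = field(default_factory=list)
    pits_nm: list[np.ndarray] = field(default_factory=list)
    section_thickness_nm: float = 40.0

    def __post_init__(self) -> None:
        self.membrane_nm = np.asarray(self.membrane_nm, dtype=float)
        if self.membrane_nm.ndim != 2 or self.membrane_nm.shape[0] < 2:
            raise ValueError("membrane needs >= 2 points")
        if not (self.scale_nm_per_px > 0):
            raise ValueError("scale must be positive")
        self.pits_nm = [np.asarray(p, dtype=float) for p in self.pits_nm]
        for i, (a, b) in enumerate(self.psd_intervals):
            n = self.membrane_nm.shape[0]
            if not (0 <= a <= b < n):
                raise ValueError(f"psd interval {i} out of membrane index range")


@dataclass(frozen=True)
class StructureCounts:
    """Per-profile endocytic structure counts, split by ferritin flag."""

    n_pits: int
    n_synaptic_vesicles: int
    n_large_vesicles: int
    n_endosomes: int
    n_synaptic_vesicles_ferritin: int = 0
    n_large_vesicles_ferritin: int = 0
    n_endosomes_ferritin: int = 0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0 or int(value) != value:
                raise ValueError(f"{name} must be a nonnegative integer")


@dataclass(frozen=True)
class PitMeasurement:
    """Width, depth and position of one endocytic pit."""

    width_nm: float
    depth_nm: float
    base_to_psd_edge_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.width_nm > 0):
            raise ValueError("pit width must be positive")
        if self.depth_nm < 0:
            raise ValueError("pit depth must be >= 0")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _polyline_arclengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_to_polyline_distance(point: np.ndarray, poly: np.ndarray) -> float:
    """Min distance from a point to an open polyline (exact per segment)."""
    p = np.asarray(point, dtype=float)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def _nearest_arc_position(point: np.ndarray, poly: np.ndarray) -> float:
    """Arc-length coordinate of the nearest point on the polyline."""
    p = np.asarray(point, dtype=float)
    arcs = _polyline_arclengths(poly)
    best_d, best_s = math.inf, 0.0
    for i in range(poly.shape[0] - 1):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        proj = a + t * ab
        d = float(np.linalg.norm(proj - p))
        if d < best_d:
            best_d = d
            best_s = arcs[i] + t * (arcs[i + 1] - arcs[i])
    return best_s


# ---------------------------------------------------------------------------
# parsing / serialization (JSON schema)
# ---------------------------------------------------------------------------


def _profile_from_record(rec: dict) -> SynapticProfile:
    scale = float(rec["scale_nm_per_px"])
    if scale <= 0:
        raise ValueError("bad scale")
    if "membrane" not in rec or len(rec["membrane"]) < 2:
        raise ValueError("missing or degenerate membrane")
    membrane = np.asarray(rec["membrane"], dtype=float) * scale
    vesicles = [
        Vesicle(
            float(v["cx"]) * scale,
            float(v["cy"]) * scale,
            float(v["d_nm"]),
            bool(v.get("ferritin", False)),
        )
        for v in rec.get("vesicles", [])
    ]
    endosomes = [
        Endosome(
            np.asarray(e["polygon"], dtype=float) * scale,
            bool(e.get("circular", False)),
            bool(e.get("ferritin", False)),
        )
        for e in rec.get("endosomes", [])
    ]
    pits = [np.asarray(p, dtype=float) * scale for p in rec.get("pits", [])]
    profile = SynapticProfile(
        micrograph_id=str(rec.get("micrograph_id", "")),
        condition=str(rec.get("condition", "")),
        time_point=rec.get("time_point", NO_STIM),
        scale_nm_per_px=scale,
        membrane_nm=membrane,
        psd_intervals=[tuple(iv) for iv in rec.get("psd", [])],
        vesicles=vesicles,
        endosomes=endosomes,
        pits_nm=pits,
        section_thickness_nm=float(rec.get("section_thickness_nm", 40.0)),
    )
    for i, pit in enumerate(profile.pits_nm):
        if pit.ndim != 2 or pit.shape[0] < 2:
            raise ValueError(f"pit {i} needs >= 2 points")
        for end in (pit[0], pit[-1]):
            if _point_to_polyline_distance(end, membrane) > PIT_BASE_TOL_NM:
                raise ValueError(f"pit {i} base endpoint off membrane (> {PIT_BASE_TOL_NM} nm)")
    return profile


def parse_annotations(source) -> list[SynapticProfile]:
    """Load and validate annotation records (JSON file, path, or list of
    dicts); coordinates are converted to nm via each record's scale.

    All records are validated; if any fail, an :class:`AnnotationError`
    carrying the per-record report is raised.
    """
    if isinstance(source, (str, Path)):
        records = json.loads(Path(source).read_text())
    else:
        records = source
    if isinstance(records, dict):
        records = [records]
    profiles, errors = [], []
    for i, rec in enumerate(records):
        try:
            profiles.append(_profile_from_record(rec))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"record {i} ({rec.get('micrograph_id', '?')}): {exc}")
    if errors:
        raise AnnotationError(errors)
    return profiles


def profile_to_record(profile: SynapticProfile) -> dict:
    """Serialize a profile back to the JSON annotation schema (px coords)."""
    s = profile.scale_nm_per_px
    return {
        "micrograph_id": profile.micrograph_id,
        "condition": profile.condition,
        "time_point": profile.time_point,
        "scale_nm_per_px": s,
        "membrane": (profile.membrane_nm / s).tolist(),
        "psd": [list(iv) for iv in profile.psd_intervals],
        "vesicles": [
            {"cx": v.cx_nm / s, "cy": v.cy_nm / s, "d_nm": v.diameter_nm,
             "ferritin": v.ferritin}
            for v in profile.vesicles
        ],
        "endosomes": [
            {"polygon": (e.polygon_nm / s).tolist(), "circular": e.circular,
             "ferritin": e.ferritin}
            for e in profile.endosomes
        ],
        "pits": [(p / s).tolist() for p in profile.pits_nm],
        "section_thickness_nm": profile.section_thickness_nm,
    }


def write_annotations(profiles: Sequence[SynapticProfile], path) -> None:
    Path(path).write_text(
        json.dumps([profile_to_record(p) for p in profiles], indent=2)
    )


# ---------------------------------------------------------------------------
# classification and geometry
# ---------------------------------------------------------------------------


def classify_structures(profile: SynapticProfile) -> StructureCounts:
    """Partition annotated structures into the standard classes.

    Every vesicle is counted exactly once: diameter < 60 nm -> synaptic
    vesicle; 60-100 nm inclusive -> large vesicle; > 100 nm (a circular
    structure larger than LEVs) -> endosome.  Annotated endosome polygons
    are endosomes regardless of shape.  Ferritin flags are carried through.
    """
    n_sv = n_lv = n_endo = 0
    n_sv_f = n_lv_f = n_endo_f = 0
    for v in profile.vesicles:
        if v.diameter_nm < SV_LV_BOUND_NM:
            n_sv += 1
            n_sv_f += v.ferritin
        elif v.diameter_nm <= LV_UPPER_BOUND_NM:
            n_lv += 1
            n_lv_f += v.ferritin
        else:
            n_endo += 1
            n_endo_f += v.ferritin
    for e in profile.endosomes:
        n_endo += 1
        n_endo_f += e.ferritin
    return StructureCounts(
        n_pits=len(profile.pits_nm),
        n_synaptic_vesicles=n_sv,
        n_large_vesicles=n_lv,
        n_endosomes=n_endo,
        n_synaptic_vesicles_ferritin=int(n_sv_f),
        n_large_vesicles_ferritin=int(n_lv_f),
        n_endosomes_ferritin=int(n_endo_f),
    )


def pit_geometry(
    pit_nm: np.ndarray,
    membrane_nm: np.ndarray,
    psd_intervals: Sequence[tuple[int, int]] = (),
) -> PitMeasurement:
    """Width, depth and along-membrane PSD distance of one pit.

    Width is the Euclidean base-chord length; depth the maximum
    perpendicular distance from the chord to any vertex (measured to the
    chord, not a local membrane tangent, which keeps the semicircle case
    exact and is robust to curved flanking membrane).  The base midpoint's
    along-membrane arc distance to the nearest PSD interval edge is reported
    when a PSD is annotated.
    """
    pit = np.asarray(pit_nm, dtype=float)
    if pit.ndim != 2 or pit.shape[0] < 2:
        raise ValueError("pit polyline needs >= 2 points")
    if pit.shape[0] == 2:
        warnings.warn("degenerate pit with 2 points; depth is 0")
    p0, p1 = pit[0], pit[-1]
    chord = p1 - p0
    width = float(np.linalg.norm(chord))
    if width == 0:
        raise ValueError("pit base endpoints coincide")
    # perpendicular distance of each vertex from the infinite chord line
    rel = pit - p0
    depth = float(np.max(np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])) / width)

    base_to_psd = None
    if psd_intervals:
        membrane = np.asarray(membrane_nm, dtype=float)
        arcs = _polyline_arclengths(membrane)
        s_mid = _nearest_arc_position((p0 + p1) / 2.0, membrane)
        edges = [arcs[i] for iv in psd_intervals for i in iv]
        base_to_psd = float(min(abs(s_mid - e) for e in edges))
    return PitMeasurement(width, depth, base_to_psd)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

_COUNT_COLS = [
    "n_pits",
    "n_synaptic_vesicles",
    "n_large_vesicles",
    "n_endosomes",
    "n_synaptic_vesicles_ferritin",
    "n_large_vesicles_ferritin",
    "n_endosomes_ferritin",
]


def per_profile_counts(
    profiles: Sequence[SynapticProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate structure counts per profile and summarize per group.

    Returns ``(per_profile, summary)``.  The summary holds mean and SEM
    (SD/sqrt(n), ddof=1) per (condition, time point) and structure class,
    plus the stimulation-induced increase: mean at time t minus the mean of
    the same condition's no-stim control (missing when there is no control).
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    rows = []
    for p in profiles:
        counts = classify_structures(p)
        row = {
            "micrograph_id": p.micrograph_id,
            "condition": p.condition,
            "time_point": p.time_point,
        }
        row.update(counts.__dict__)
        rows.append(row)
    per_profile = pd.DataFrame(rows)

    summaries = []
    for (cond, tp), sub in per_profile.groupby(["condition", "time_point"], sort=False):
        entry = {"condition": cond, "time_point": tp, "n_profiles": len(sub)}
        for col in _COUNT_COLS:
            vals = sub[col].to_numpy(dtype=float)
            entry[f"{col}_mean"] = vals.mean()
            entry[f"{col}_sem"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        summaries.append(entry)
    summary = pd.DataFrame(summaries)

    # stimulation-induced increase over the no-stim control
    for col in _COUNT_COLS:
        increases = []
        for _, row in summary.iterrows():
            ctrl = summary[
                (summary["condition"] == row["condition"])
                & (summary["time_point"] == NO_STIM)
            ]
            if ctrl.empty or row["time_point"] == NO_STIM:
                increases.append(np.nan)
            else:
                increases.append(row[f"{col}_mean"] - ctrl[f"{col}_mean"].iloc[0])
        summary[f"{col}_increase"] = increases
    return per_profile, summary


def timecourse_summary(
    profiles: Sequence[SynapticProfile],
    level: float = 0.95,
) -> dict:
    """Flash-and-freeze time-course report.

    Produces the per-group count summary, the summed LEV+endosome means, and
    per-group pit width/depth medians with distribution-free CIs.
    """
    per_profile, summary = per_profile_counts(profiles)
    summary = summary.copy()
    summary["lev_plus_endosome_mean"] = (
        summary["n_large_vesicles_mean"] + summary["n_endosomes_mean"]
    )

    pit_rows = []
    for p in profiles:
        for pit in p.pits_nm:
            m = pit_geometry(pit, p.membrane_nm, p.psd_intervals)
            pit_rows.append(
                {
                    "condition": p.condition,
                    "time_point": p.time_point,
                    "width_nm": m.width_nm,
                    "depth_nm": m.depth_nm,
                    "base_to_psd_edge_nm": m.base_to_psd_edge_nm,
                }
            )
    pit_table = pd.DataFrame(
        pit_rows,
        columns=["condition", "time_point", "width_nm", "depth_nm", "base_to_psd_edge_nm"],
    )

    pit_summaries = []
    if not pit_table.empty:
        for (cond, tp), sub in pit_table.groupby(["condition", "time_point"], sort=False):
            entry = {"condition": cond, "time_point": tp, "n_pits": len(sub)}
            for col in ("width_nm", "depth_nm"):
                ci: MedianCI = median_with_ci(sub[col].to_numpy(), level)
                entry[f"{col}_median"] = ci.median
                entry[f"{col}_ci_low"] = ci.lower
                entry[f"{col}_ci_high"] = ci.upper
            pit_summaries.append(entry)
    return {
        "per_profile": per_profile,
        "count_summary": summary,
        "pit_table": pit_table,
        "pit_summary": pd.DataFrame(pit_summaries),
    }
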