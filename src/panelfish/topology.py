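"""Nuclear topology quantification for 3D-FISH probe signals.

A segmented nucleus is represented by a closed surface — an ellipsoid
(center + semi-axes, μm) or a watertight triangulated mesh — and each
hybridization signal by its gravity center and reconstructed volume.  The
module answers three questions about a two-probe experiment:

* how deep inside the nucleus does each probe sit?  Measured two ways: the
  minimum Euclidean distance to the nuclear envelope, and the index of the
  equal-volume concentric shell containing the probe.  Shells are defined by
  scaled copies of the envelope about the center of the bounding cuboid: the
  smallest scale factor s whose copy contains the probe maps to zone
  ceil(n_zones * s^3), because a copy scaled by s encloses volume s^3 * V.
* are the two probes colocalized?  Either by overlap of the reconstructed
  signals (center distance <= sum of equivalent-sphere radii) or by a fixed
  distance threshold (default 0.5 μm).
* do conditions differ?  Chi-square / Fisher tests on colocalization
  contingency tables, rank tests (Mann-Whitney, Kruskal-Wallis) or one-way
  ANOVA on distances, and chi-square comparison of radial zone occupancy.

Mesh containment is decided by ray-crossing parity (vectorized
Möller–Trumbore over all faces) and mesh surface distance by the exact
minimum over all triangles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import optimize, stats
from trimesh.proximity import closest_point_naive

from .panel_io import PanelValidationError, _delimiter_for

DEFAULT_N_ZONES = 10
DEFAULT_COLOC_THRESHOLD_UM = 0.5
CLUSTER_CHANNEL = "cluster_probe"
SUBTEL_CHANNEL = "subtelomeric_probe"

_BISECT_TOL = 1e-6
# fixed, irrationally oriented ray for crossing-parity tests
_RAY_DIR = np.array([0.57735026, 0.52573111, 0.62480505])
_RAY_DIR /= np.linalg.norm(_RAY_DIR)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _ray_crossings_inside(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Odd/even ray-crossing containment test, no spatial index required."""
    tri = mesh.triangles  # (F, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    d = _RAY_DIR
    h = np.cross(d, e2)  # (F, 3)
    a = np.einsum("fj,fj->f", e1, h)
    valid = np.abs(a) > 1e-14
    inv_a = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)
    inside = np.zeros(len(points), dtype=bool)
    block = max(1, int(4_000_000 // max(len(tri), 1)))
    for start in range(0, len(points), block):
        p = points[start:start + block]  # (P, 3)
        s = p[:, None, :] - v0[None, :, :]  # (P, F, 3)
        u = np.einsum("pfj,fj->pf", s, h) * inv_a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pfj,j->pf", q, d) * inv_a
        t = np.einsum("pfj,fj->pf", q, e2) * inv_a
        eps = 1e-10
        hit = (
            valid[None, :]
            & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
            & (t > eps)
        )
        inside[start:start + block] = (hit.sum(axis=1) % 2) == 1
    return inside


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def ellipsoid_surface_point(axes: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Intersection of a ray from the center with the ellipsoid surface."""
    direction = np.asarray(direction, float)
    scale = np.sqrt(np.sum((direction / axes) ** 2, axis=-1, keepdims=True))
    return direction / scale


def _ellipsoid_envelope_distance(axes: np.ndarray, rel: np.ndarray) -> float:
    """Minimum distance from a point (ellipsoid frame) to the surface.

    Multi-start local minimization over the spherical parametrization; for
    spheres the answer is analytic.
    """
    a, b, c = axes
    if math.isclose(a, b, rel_tol=1e-12) and math.isclose(a, c, rel_tol=1e-12):
        return abs(a - float(np.linalg.norm(rel)))

    def surf(tp: np.ndarray) -> np.ndarray:
        th, ph = tp
        st = math.sin(th)
        return np.array([a * st * math.cos(ph), b * st * math.sin(ph), c * math.cos(th)])

    def f(tp: np.ndarray) -> float:
        return float(np.sum((surf(tp) - rel) ** 2))

    dirs = _fibonacci_directions(512)
    pts = ellipsoid_surface_point(axes, dirs)
    d2 = np.sum((pts - rel) ** 2, axis=1)
    best = float("inf")
    for idx in np.argsort(d2)[:6]:
        x, y, z = pts[idx]
        th0 = math.acos(np.clip(z / c, -1.0, 1.0))
        ph0 = math.atan2(y / b, x / a)
        res = optimize.minimize(
            f, np.array([th0, ph0]), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 400},
        )
        best = min(best, math.sqrt(res.fun))
    return best


# ---------------------------------------------------------------------------
# nucleus geometry
# ---------------------------------------------------------------------------

@dataclass
class NucleusGeometry:
    """Closed nuclear surface with the reference frame for all spatial ops.

    The scaling/reference center is the center of the axis-aligned bounding
    cuboid in which the nucleus is inscribed (for an ellipsoid this is its
    geometric center).
    """

    nucleus_id: str
    ellipsoid: tuple[np.ndarray, np.ndarray] | None = None  # (center, semi-axes)
    mesh: trimesh.Trimesh | None = None

    @classmethod
    def from_ellipsoid(cls, nucleus_id: str, center, axes) -> "NucleusGeometry":
        center = np.asarray(center, float)
        axes = np.asarray(axes, float)
        if axes.shape != (3,) or (axes <= 0).any():
            raise PanelValidationError(f"semi-axes must be 3 positive numbers, got {axes}")
        return cls(nucleus_id, ellipsoid=(center, axes))

    @classmethod
    def from_mesh(cls, nucleus_id: str, mesh: trimesh.Trimesh) -> "NucleusGeometry":
        if not mesh.is_watertight:
            raise PanelValidationError(f"nucleus {nucleus_id!r}: mesh is not watertight")
        if mesh.volume <= 0:
            raise PanelValidationError(f"nucleus {nucleus_id!r}: non-positive volume")
        return cls(nucleus_id, mesh=mesh)

    # -- frame ----------------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        """Center of the axis-aligned bounding cuboid."""
        if self.ellipsoid is not None:
            return self.ellipsoid[0].copy()
        return self.mesh.bounds.mean(axis=0)

    @property
    def centroid(self) -> np.ndarray:
        """Volumetric centroid (alternative scaling center)."""
        if self.ellipsoid is not None:
            return self.ellipsoid[0].copy()
        return np.asarray(self.mesh.center_mass, float)

    @property
    def volume(self) -> float:
        if self.ellipsoid is not None:
            a, b, c = self.ellipsoid[1]
            return 4.0 / 3.0 * math.pi * a * b * c
        return float(self.mesh.volume)

    # -- queries ---------------------------------------------------------
    def contains(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        if self.ellipsoid is not None:
            center, axes = self.ellipsoid
            return np.sum(((points - center) / axes) ** 2, axis=1) < 1.0
        return _ray_crossings_inside(self.mesh, points)

    def envelope_distance(self, point) -> tuple[float, bool]:
        """Minimum distance from a point to the envelope.

        Returns ``(distance, outside)``; for points outside the surface the
        distance is reported negative with the outside flag set.
        """
        point = np.asarray(point, float)
        inside = bool(self.contains(point[None, :])[0])
        if self.ellipsoid is not None:
            center, axes = self.ellipsoid
            d = _ellipsoid_envelope_distance(axes, point - center)
        else:
            _, dist, _ = closest_point_naive(self.mesh, point[None, :])
            d = float(dist[0])
        return (d, False) if inside else (-d, True)

    def scale_factor(self, point) -> float:
        """Smallest s such that the envelope scaled by s about the cuboid
        center contains the point (bisection to 1e-6 for meshes; exact for
        ellipsoids).  Raises for points outside the surface."""
        return float(self.scale_factors(np.asarray(point, float)[None, :])[0])

    def scale_factors(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        center = self.center
        if self.ellipsoid is not None:
            _, axes = self.ellipsoid
            s = np.sqrt(np.sum(((points - center) / axes) ** 2, axis=1))
            # boundary inclusive: a point on the envelope has s = 1
            if (s > 1.0 + 1e-9).any():
                bad = points[s > 1.0 + 1e-9][0]
                raise PointOutsideNucleus(self.nucleus_id, bad)
            return np.minimum(s, 1.0)
        inside = self.contains(points)
        if not inside.all():
            # tolerate points exactly on the surface (s = 1)
            rel_out = points[~inside] - center
            shrunk = center + rel_out / (1.0 + 10 * _BISECT_TOL)
            if not self.contains(shrunk).all():
                raise PointOutsideNucleus(self.nucleus_id, points[~inside][0])
        rel = points - center
        lo = np.zeros(len(points))
        hi = np.ones(len(points))
        at_center = np.linalg.norm(rel, axis=1) < 1e-12
        # containment in the copy scaled by s <=> center + rel/s inside the mesh
        for _ in range(int(math.ceil(math.log2(1.0 / _BISECT_TOL)))):
            mid = 0.5 * (lo + hi)
            q = center + rel / np.where(at_center, 1.0, mid)[:, None]
            inside = _ray_crossings_inside(self.mesh, q)
            hi = np.where(inside, mid, hi)
            lo = np.where(inside, lo, mid)
        s = 0.5 * (lo + hi)
        s[at_center] = 0.0
        return s


class PointOutsideNucleus(PanelValidationError):
    def __init__(self, nucleus_id: str, point) -> None:
        self.nucleus_id = nucleus_id
        self.point = np.asarray(point, float)
        super().__init__(f"point {self.point.tolist()} outside nucleus {nucleus_id!r}")


def envelope_distance(nucleus: NucleusGeometry, point) -> tuple[float, bool]:
    """Minimum distance from a probe center to the nuclear envelope.

    Functional form of :meth:`NucleusGeometry.envelope_distance`; returns
    ``(distance, outside_flag)`` with a negative distance for points
    outside the surface.
    """
    return nucleus.envelope_distance(point)


def shell_zone(nucleus: NucleusGeometry, point, n_zones: int = DEFAULT_N_ZONES):
    """Equal-volume shell assignment for a point inside a nucleus.

    Returns ``(s, zone)`` where s is the envelope scale factor and
    zone = ceil(n_zones * s^3) clipped to [1, n_zones]; s = 0 (the center)
    maps to zone 1, s = 1 (the envelope) to zone ``n_zones``.  The
    equivalent-sphere radius fraction of the reduced copy equals s for
    affine scaling, so s is also that quantity.
    """
    s = nucleus.scale_factor(point)
    return s, zone_of_scale(s, n_zones)


def zone_of_scale(s: float | np.ndarray, n_zones: int = DEFAULT_N_ZONES):
    """Zone index for a scale factor: intervals ((k-1)/n, k/n] in s^3."""
    z = np.ceil(n_zones * np.asarray(s, float) ** 3)
    z = np.clip(z, 1, n_zones).astype(int)
    return z if z.ndim else int(z)


# ---------------------------------------------------------------------------
# probes and pair calls
# ---------------------------------------------------------------------------

@dataclass
class ProbeSignal:
    """One reconstructed hybridization signal (gravity center + volume)."""

    nucleus_id: str
    channel: str
    gravity_center: np.ndarray
    volume: float

    def __post_init__(self) -> None:
        self.gravity_center = np.asarray(self.gravity_center, float)
        if self.volume <= 0:
            raise PanelValidationError(
                f"probe volume must be positive, got {self.volume}"
            )

    @property
    def equivalent_radius(self) -> float:
        """Radius of the sphere with the same volume, (3V / 4π)^(1/3)."""
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class ProbePairCall:
    """Full spatial record for one two-probe nucleus."""

    nucleus_id: str
    center_distance: float
    status: str  # "colocalized" | "separated"
    mode: str
    zone_cluster: int | None
    zone_subtel: int | None
    s_cluster: float | None
    s_subtel: float | None
    envelope_distance_cluster: float
    envelope_distance_subtel: float
    outside_cluster: bool
    outside_subtel: bool

    @property
    def colocalized(self) -> bool:
        return self.status == "colocalized"


def colocalization_call(
    p1: ProbeSignal,
    p2: ProbeSignal,
    nucleus: NucleusGeometry,
    mode: str = "overlap",
    threshold: float = DEFAULT_COLOC_THRESHOLD_UM,
    n_zones: int = DEFAULT_N_ZONES,
) -> ProbePairCall:
    """Rank a two-channel probe pair as colocalized or separated.

    ``overlap`` mode (default): colocalized iff the center distance does not
    exceed the sum of the probes' equivalent-sphere radii.  ``threshold``
    mode: colocalized iff the distance is at most ``threshold`` μm (boundary
    inclusive in both modes).  Probes with gravity centers outside the
    nucleus are flagged and excluded from shell assignment but kept in the
    call.
    """
    if p1.nucleus_id != p2.nucleus_id or p1.nucleus_id != nucleus.nucleus_id:
        raise PanelValidationError(
            f"probes/nucleus mismatch: {p1.nucleus_id!r}, {p2.nucleus_id!r}, "
            f"{nucleus.nucleus_id!r}"
        )
    if p1.channel == p2.channel:
        raise PanelValidationError(f"probes share channel {p1.channel!r}")
    if mode not in ("overlap", "threshold"):
        raise ValueError(f"mode must be 'overlap' or 'threshold', got {mode!r}")
    by_channel = {p.channel: p for p in (p1, p2)}
    cluster = by_channel.get(CLUSTER_CHANNEL, p1)
    subtel = by_channel.get(SUBTEL_CHANNEL, p2 if cluster is p1 else p1)

    d = float(np.linalg.norm(p1.gravity_center - p2.gravity_center))
    if mode == "overlap":
        coloc = d <= p1.equivalent_radius + p2.equivalent_radius
    else:
        coloc = d <= threshold

    def _probe_position(p: ProbeSignal):
        dist, outside = nucleus.envelope_distance(p.gravity_center)
        if outside:
            return None, None, dist, True
        s = nucleus.scale_factor(p.gravity_center)
        return s, zone_of_scale(s, n_zones), dist, False

    s_c, z_c, e_c, out_c = _probe_position(cluster)
    s_s, z_s, e_s, out_s = _probe_position(subtel)
    return ProbePairCall(
        nucleus_id=nucleus.nucleus_id,
        center_distance=d,
        status="colocalized" if coloc else "separated",
        mode=mode,
        zone_cluster=z_c,
        zone_subtel=z_s,
        s_cluster=s_c,
        s_subtel=s_s,
        envelope_distance_cluster=e_c,
        envelope_distance_subtel=e_s,
        outside_cluster=out_c,
        outside_subtel=out_s,
    )


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------

@dataclass
class ColocalizationTable:
    counts: pd.DataFrame       # conditions x (colocalized, separated)
    percent: pd.DataFrame      # same shape, row percentages
    chi2_stat: float
    chi2_p: float
    fisher_p: float | None     # two-sided, 2x2 only


def colocalization_table(
    calls_by_condition: Mapping[str, Sequence[ProbePairCall]],
) -> ColocalizationTable:
    """Contingency table and tests for colocalization across conditions.

    Chi-square without continuity correction; for exactly two conditions
    Fisher's exact test (two-sided) is reported alongside.
    """
    if len(calls_by_condition) < 2:
        raise PanelValidationError("need at least 2 conditions")
    rows = {}
    for cond, calls in calls_by_condition.items():
        if not calls:
            raise PanelValidationError(f"condition {cond!r} has zero calls")
        n_coloc = sum(c.colocalized for c in calls)
        rows[cond] = {"colocalized": n_coloc, "separated": len(calls) - n_coloc}
    counts = pd.DataFrame.from_dict(rows, orient="index")[["colocalized", "separated"]]
    percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
    if (counts.sum(axis=0) == 0).any():
        # one outcome never observed: distributions are trivially identical
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(
            counts.to_numpy(), correction=False
        )
    fisher_p = None
    if counts.shape[0] == 2:
        _, fisher_p = stats.fisher_exact(counts.to_numpy(), alternative="two-sided")
        fisher_p = float(fisher_p)
    return ColocalizationTable(counts, percent, float(chi2_stat), float(chi2_p), fisher_p)


@dataclass
class DistanceStats:
    design: str
    statistic: float
    p_value: float
    descriptives: pd.DataFrame  # mean, sem, n per condition


def distance_stats(
    values_by_condition: Mapping[str, Sequence[float]],
    design: str = "two_group_rank",
) -> DistanceStats:
    """Compare distance distributions across conditions.

    ``two_group_rank``: Mann-Whitney U, two-sided; exact when the combined
    sample is at most 20 with no ties, otherwise the normal approximation
    with tie correction.  ``multi_group_rank``: Kruskal-Wallis.
    ``multi_group_anova``: one-way ANOVA.  Descriptives report mean ± SEM
    per condition.
    """
    groups = {k: np.asarray(list(v), float) for k, v in values_by_condition.items()}
    if len(groups) < 2 or any(len(v) == 0 for v in groups.values()):
        raise PanelValidationError("need >= 2 non-empty conditions")
    desc = pd.DataFrame(
        {
            "n": {k: len(v) for k, v in groups.items()},
            "mean": {k: float(v.mean()) for k, v in groups.items()},
            "sem": {
                k: float(stats.sem(v)) if len(v) > 1 else math.nan
                for k, v in groups.items()
            },
        }
    )
    vals = list(groups.values())
    pooled = np.concatenate(vals)
    all_equal = bool(np.all(pooled == pooled[0]))
    if design == "two_group_rank":
        if len(groups) != 2:
            raise PanelValidationError("two_group_rank needs exactly 2 conditions")
        x, y = vals
        if all_equal:
            return DistanceStats(design, len(x) * len(y) / 2.0, 1.0, desc)
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return DistanceStats(design, float(res.statistic), float(res.pvalue), desc)
    if design == "multi_group_rank":
        if all_equal:
            return DistanceStats(design, 0.0, 1.0, desc)
        res = stats.kruskal(*vals)
        return DistanceStats(design, float(res.statistic), float(res.pvalue), desc)
    if design == "multi_group_anova":
        if all_equal:
            return DistanceStats(design, 0.0, 1.0, desc)
        res = stats.f_oneway(*vals)
        stat = float(res.statistic)
        p = float(res.pvalue)
        if math.isnan(stat):
            stat, p = 0.0, 1.0
        return DistanceStats(design, stat, p, desc)
    raise ValueError(f"unknown design {design!r}")


@dataclass
class RadialProfile:
    occupancy: pd.DataFrame          # (condition, channel) x zone fractions
    counts: pd.DataFrame             # same shape, raw counts
    chi2_by_channel: dict[str, tuple[float, float]]


def radial_profile(
    calls_by_condition: Mapping[str, Sequence[ProbePairCall]],
    n_zones: int = DEFAULT_N_ZONES,
) -> RadialProfile:
    """Zone-occupancy distribution of probes per condition and channel.

    Fractions sum to 1 per (condition, channel); a chi-square test compares
    the zone count distributions between conditions, per channel.  Probes
    flagged outside the nucleus carry no zone and are excluded.
    """
    if not calls_by_condition:
        raise PanelValidationError("no conditions supplied")
    zones = list(range(1, n_zones + 1))
    rows = {}
    for cond, calls in calls_by_condition.items():
        if not calls:
            raise PanelValidationError(f"condition {cond!r} has zero calls")
        for channel, attr in ((CLUSTER_CHANNEL, "zone_cluster"),
                              (SUBTEL_CHANNEL, "zone_subtel")):
            zs = [getattr(c, attr) for c in calls if getattr(c, attr) is not None]
            counts = pd.Series(zs, dtype=int).value_counts().reindex(zones, fill_value=0)
            rows[(cond, channel)] = counts
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index = pd.MultiIndex.from_tuples(counts.index, names=["condition", "channel"])
    occupancy = counts.div(counts.sum(axis=1), axis=0)
    chi2 = {}
    for channel in counts.index.get_level_values("channel").unique():
        sub = counts.xs(channel, level="channel")
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if sub.shape[0] < 2 or sub.shape[1] < 2:
            chi2[channel] = (0.0, 1.0)
        else:
            s, p, _, _ = stats.chi2_contingency(sub.to_numpy(), correction=False)
            chi2[channel] = (float(s), float(p))
    return RadialProfile(occupancy, counts, chi2)


def calls_to_frame(calls: Iterable[ProbePairCall]) -> pd.DataFrame:
    """Flatten pair calls into a report-ready table."""
    recs = []
    for c in calls:
        recs.append({
            "nucleus_id": c.nucleus_id,
            "center_distance_um": c.center_distance,
            "status": c.status,
            "mode": c.mode,
            "zone_cluster": c.zone_cluster,
            "zone_subtel": c.zone_subtel,
            "s_cluster": c.s_cluster,
            "s_subtel": c.s_subtel,
            "envelope_distance_cluster_um": c.envelope_distance_cluster,
            "envelope_distance_subtel_um": c.envelope_distance_subtel,
            "outside_cluster": c.outside_cluster,
            "outside_subtel": c.outside_subtel,
        })
    return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# external formats
# ---------------------------------------------------------------------------

def read_nuclei_table(path: str | Path) -> dict[str, NucleusGeometry]:
    """Ellipsoid parameter table: nucleus_id, cx, cy, cz, a, b, c (μm)."""
    path = Path(path)
    t = pd.read_csv(path, sep=_delimiter_for(path))
    need = {"nucleus_id", "cx", "cy", "cz", "a", "b", "c"}
    if not need <= set(t.columns):
        raise PanelValidationError(f"nuclei table needs columns {sorted(need)}")
    out = {}
    for _, r in t.iterrows():
        nid = str(r["nucleus_id"])
        if nid in out:
            raise PanelValidationError(f"duplicate nucleus_id {nid!r}")
        out[nid] = NucleusGeometry.from_ellipsoid(
            nid, [r["cx"], r["cy"], r["cz"]], [r["a"], r["b"], r["c"]]
        )
    return out


def read_nucleus_mesh(path: str | Path, nucleus_id: str | None = None) -> NucleusGeometry:
    """Load a nucleus surface from a PLY mesh (must be watertight)."""
    path = Path(path)
    mesh = trimesh.load(path, process=False, force="mesh")
    return NucleusGeometry.from_mesh(nucleus_id or path.stem, mesh)


def write_nuclei_table(nuclei: Mapping[str, NucleusGeometry], path: str | Path) -> None:
    recs = []
    for nid, nuc in nuclei.items():
        if nuc.ellipsoid is None:
            raise PanelValidationError(
                f"nucleus {nid!r} is a mesh; export it as PLY instead"
            )
        c, ax = nuc.ellipsoid
        recs.append({"nucleus_id": nid, "cx": c[0], "cy": c[1], "cz": c[2],
                     "a": ax[0], "b": ax[1], "c": ax[2]})
    path = Path(path)
    pd.DataFrame.from_records(recs).to_csv(
        path, sep=_delimiter_for(path), index=False, float_format="%.10g"
    )


def read_probes_table(path: str | Path) -> list[ProbeSignal]:
    """Probe table: nucleus_id, channel, x, y, z (μm), volume (μm^3)."""
    path = Path(path)
    t = pd.read_csv(path, sep=_delimiter_for(path))
    need = {"nucleus_id", "channel", "x", "y", "z", "volume"}
    if not need <= set(t.columns):
        raise PanelValidationError(f"probes table needs columns {sorted(need)}")
    return [
        ProbeSignal(str(r["nucleus_id"]), str(r["channel"]),
                    [r["x"], r["y"], r["z"]], float(r["volume"]))
        for _, r in t.iterrows()
    ]


def write_probes_table(probes: Sequence[ProbeSignal], path: str | Path) -> None:
    recs = [
        {"nucleus_id": p.nucleus_id, "channel": p.channel,
         "x": p.gravity_center[0], "y": p.gravity_center[1],
         "z": p.gravity_center[2], "volume": p.volume}
        for p in probes
    ]
    path = Path(path)
    pd.DataFrame.from_records(recs).to_csv(
        path, sep=_delimiter_for(path), index=False, float_format="%.10g"
    )


def read_conditions_table(path: str | Path) -> dict[str, str]:
    """Condition map: nucleus_id, condition."""
    path = Path(path)
    t = pd.read_csv(path, sep=_delimiter_for(path))
    if not {"nucleus_id", "condition"} <= set(t.columns):
        raise PanelValidationError("conditions table needs nucleus_id, condition")
    return dict(zip(t["nucleus_id"].astype(str), t["condition"].astype(str)))


def call_all_pairs(
    nuclei: Mapping[str, NucleusGeometry],
    probes: Sequence[ProbeSignal],
    mode: str = "overlap",
    threshold: float = DEFAULT_COLOC_THRESHOLD_UM,
    n_zones: int = DEFAULT_N_ZONES,
) -> list[ProbePairCall]:
    """Group probes by nucleus and produce one pair call per nucleus."""
    by_nucleus: dict[str, list[ProbeSignal]] = {}
    for p in probes:
        by_nucleus.setdefault(p.nucleus_id, []).append(p)
    calls = []
    for nid, plist in by_nucleus.items():
        if nid not in nuclei:
            raise PanelValidationError(f"probes reference unknown nucleus {nid!r}")
        if len(plist) != 2:
            raise PanelValidationError(
                f"nucleus {nid!r} has {len(plist)} probes; expected a two-channel pair"
            )
        calls.append(colocalization_call(
            plist[0], plist[1], nuclei[nid], mode=mode,
            threshold=threshold, n_zones=n_zones,
        ))
    return calls
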