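"""Injury placement and Garway-Heath zone summaries.

The initial insult is a uniform superoxide bolus over a small disk at a
named anatomical location.  Presets live on the temporal–nasal and
superior–inferior axes at radius-fractions 0.2 / 0.5 / 0.8 of the nerve
radius, plus a 20-site validation lattice (spokes on the four anatomical
axes x 5 radial positions).

Damage is summarized over an angular sectorization of the nerve into the
seven Garway-Heath zones.  Zone ids run nasal → temporal, zones 2–3
along the inferior route and 4–5 along the superior one: 1 nasal,
2 inferonasal, 3 inferotemporal, 4 superotemporal, 5 superonasal, and
the ~90°-wide temporal sector split at its bisector into 6.1 (superior
half) and 6.2 (inferior half).  Sector angles follow the published
Garway-Heath disc sectors, converted to the model convention (nasal =
0°, superior = 90°, temporal = 180°); the whole map, including which
sectors carry which ids, is config-overridable.  The same zones carry
the 76-point Humphrey 30-2 visual-field assignment used to average
threshold sensitivities per zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nerve_geometry import OpticNerveModel

# (zone_id, start_deg, end_deg) in model angle convention, half-open [start, end)
# numbering runs nasal → temporal: 1 nasal, 2 inferonasal, 3 inferotemporal,
# 4 superotemporal, 5 superonasal, 6.1/6.2 the split temporal sector
DEFAULT_ZONE_SECTORS: tuple[tuple[str, float, float], ...] = (
    ("1", 309.0, 360.0),
    ("1", 0.0, 59.0),
    ("5", 59.0, 99.0),
    ("4", 99.0, 139.0),
    ("6.1", 139.0, 184.0),
    ("6.2", 184.0, 229.0),
    ("3", 229.0, 269.0),
    ("2", 269.0, 309.0),
)

ZONE_IDS = ("1", "2", "3", "4", "5", "6.1", "6.2")

_AXIS_PRESETS = {
    # (radius fraction rho, angle degrees); temporal = 180°, nasal = 0°
    "far_temporal": (0.8, 180.0),
    "mid_temporal": (0.5, 180.0),
    "temporal": (0.2, 180.0),
    "nasal": (0.2, 0.0),
    "mid_nasal": (0.5, 0.0),
    "far_nasal": (0.8, 0.0),
    "superior": (0.2, 90.0),
    "mid_superior": (0.5, 90.0),
    "mid_inferior": (0.5, 270.0),
    "inferior": (0.2, 270.0),
}

#: 20 validation sites: spokes on the four anatomical axes x 5 radial
#: positions (sites 1-5 nasal, 6-10 superior, 11-15 temporal, 16-20 inferior)
GRID_SPOKE_ANGLES = (0.0, 90.0, 180.0, 270.0)
GRID_RADII = (0.15, 0.3, 0.5, 0.7, 0.85)


def _grid_site(k: int) -> tuple[float, float]:
    if not 1 <= k <= 20:
        raise ValueError(f"grid site must be 1..20, got {k}")
    spoke, ring = divmod(k - 1, 5)
    return GRID_RADII[ring], GRID_SPOKE_ANGLES[spoke]


class GeometryError(ValueError):
    pass


class IncompleteFieldError(ValueError):
    pass


@dataclass(frozen=True)
class InjurySpec:
    """Initial-insult location and size.

    Either ``preset`` (named location or ``grid_k``) or explicit
    ``(rho, angle)`` polar coordinates; ``footprint_radius`` is a fraction
    of the nerve radius and ``amount`` the total bolus in µmol (``None``
    defers to ``SimulationParams.injury_amount``).
    """

    preset: str | None = "mid_temporal"
    rho: float | None = None
    angle: float | None = None
    footprint_radius: float | None = None
    amount: float | None = None

    def resolve(self) -> tuple[float, float]:
        if self.rho is not None and self.angle is not None:
            return float(self.rho), float(self.angle) % 360.0
        if self.preset is None:
            raise ValueError("either preset or explicit (rho, angle) required")
        if self.preset in _AXIS_PRESETS:
            return _AXIS_PRESETS[self.preset]
        if self.preset.startswith("grid_"):
            return _grid_site(int(self.preset.split("_", 1)[1]))
        raise ValueError(f"unknown injury preset {self.preset!r}")


def place_injury(
    model: OpticNerveModel, spec: InjurySpec, params=None
) -> np.ndarray:
    """The t=0 concentration field: ``amount`` spread uniformly over the
    footprint disk (in-nerve pixels only)."""
    rho, angle = spec.resolve()
    foot = spec.footprint_radius
    if foot is None:
        foot = params.injury_footprint if params is not None else 0.05
    amount = spec.amount
    if amount is None:
        amount = params.injury_amount if params is not None else 0.0
    if rho + foot > 1.0 + 1e-12:
        raise GeometryError(
            f"footprint (rho={rho}, radius={foot}) extends outside the nerve"
        )
    R = model.nerve_radius
    cx = rho * R * np.cos(np.radians(angle))
    cy = rho * R * np.sin(np.radians(angle))
    n = model.label_grid.shape[0]
    coords = (np.arange(n) + 0.5) / model.resolution - R
    yy = coords[:, None]
    xx = coords[None, :]
    mask = ((xx - cx) ** 2 + (yy - cy) ** 2 <= (foot * R) ** 2) & model.inside_mask()
    field0 = np.zeros((n, n))
    npx = int(mask.sum())
    if npx == 0:
        raise GeometryError("injury footprint covers no in-nerve pixels")
    if amount > 0:
        field0[mask] = amount / npx
    return field0


@dataclass(frozen=True)
class ZoneMap:
    """Angular sectorization into Garway-Heath zones (half-open sectors)."""

    sectors: tuple[tuple[str, float, float], ...] = DEFAULT_ZONE_SECTORS

    def __post_init__(self):
        # verify exact partition of [0, 360)
        edges = sorted((s, e, z) for z, s, e in self.sectors)
        pos = 0.0
        for s, e, _ in edges:
            if abs(s - pos) > 1e-9 or e <= s:
                raise ValueError("sectors must partition [0, 360) without gaps")
            pos = e
        if abs(pos - 360.0) > 1e-9:
            raise ValueError("sectors must cover the full circle")

    @property
    def zone_ids(self) -> tuple[str, ...]:
        seen = []
        for z, _, _ in self.sectors:
            if z not in seen:
                seen.append(z)
        return tuple(sorted(seen))

    def zone_of_angle(self, theta: float) -> str:
        t = theta % 360.0
        for z, s, e in self.sectors:
            if s <= t < e:
                return z
        raise RuntimeError("unreachable: sectors partition the circle")

    def zones_of_angles(self, theta: np.ndarray) -> np.ndarray:
        t = np.asarray(theta, dtype=float) % 360.0
        out = np.empty(t.shape, dtype=object)
        for z, s, e in self.sectors:
            out[(t >= s) & (t < e)] = z
        return out


def zone_of(x: float, y: float, zone_map: ZoneMap, nerve_radius: float | None = None) -> str:
    """Zone of a point (µm, nerve-centered).  Points outside the nerve error."""
    if nerve_radius is not None and x * x + y * y > nerve_radius**2:
        raise GeometryError(f"point ({x}, {y}) lies outside the nerve")
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return zone_map.zone_of_angle(theta)


def zone_summary(result, zone_map: ZoneMap | None = None):
    """Per-zone degenerated fraction at steady state (axon membership by
    center coordinates).  Returns a DataFrame (zone_id, n_axons,
    fraction_degenerated)."""
    import pandas as pd

    if zone_map is None:
        zone_map = ZoneMap()
    model = result.model
    zones = zone_map.zones_of_angles(model.angles())
    dead = ~model.alive
    rows = []
    for z in zone_map.zone_ids:
        sel = zones == z
        n = int(sel.sum())
        frac = float(dead[sel].sum() / n) if n else 0.0
        rows.append((z, n, frac))
    return pd.DataFrame(rows, columns=["zone_id", "n_axons", "fraction_degenerated"])


# --- Humphrey 30-2 visual-field machinery ------------------------------------

def humphrey_30_2_coordinates() -> np.ndarray:
    """The 76 Humphrey 30-2 test locations (x, y in degrees of visual field)."""
    pts = []
    xs_by_halfwidth = {
        27: (3, 9),
        21: (3, 9, 15),
        15: (3, 9, 15, 21),
        9: (3, 9, 15, 21, 27),
        3: (3, 9, 15, 21, 27),
    }
    for y in (27, 21, 15, 9, 3, -3, -9, -15, -21, -27):
        for ax in xs_by_halfwidth[abs(y)]:
            pts.append((-ax, y))
            pts.append((ax, y))
    pts.sort(key=lambda p: (-p[1], p[0]))
    return np.array(pts, dtype=float)


def default_vf_zone_assignment(zone_map: ZoneMap | None = None) -> np.ndarray:
    """Approximate point → Garway-Heath-zone table for the 30-2 grid.

    Each field point is mapped to the disc sector its nerve-fiber bundle
    enters: the field location is inverted to a retinal location, the
    entry angle at the disc (nasal to the fovea, at (-15.5, 1.5) retinal
    degrees for a right eye) is taken, and the zone of that angle is
    looked up in the (nasal = 0°) sector map.  Shipped as an editable
    table; it reproduces the topology of the published map, not its
    patient-derived boundaries.
    """
    if zone_map is None:
        zone_map = ZoneMap()
    pts = humphrey_30_2_coordinates()
    retinal = -pts  # field inversion through the nodal point
    disc = np.array([-15.5, 1.5])
    v = retinal - disc
    theta = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360.0
    # angle measured from the disc toward the retinal periphery: points
    # temporal to the disc (the papillomacular side, v_x > 0) enter on the
    # temporal disc margin (model 180°), so flip by 180°.
    theta = (180.0 - theta) % 360.0
    return zone_map.zones_of_angles(theta)


@dataclass
class VisualFieldGrid:
    """76 threshold sensitivities (dB) on the Humphrey 30-2 layout."""

    thresholds: np.ndarray
    coordinates: np.ndarray = field(default_factory=humphrey_30_2_coordinates)
    zone_assignment: np.ndarray = None

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.size != 76:
            raise ValueError(f"expected 76 thresholds, got {self.thresholds.size}")
        if self.zone_assignment is None:
            self.zone_assignment = default_vf_zone_assignment()
        if len(self.zone_assignment) != 76:
            raise ValueError("zone assignment must cover all 76 points")

    def to_text(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "point_index": np.arange(76),
                "x_deg": self.coordinates[:, 0],
                "y_deg": self.coordinates[:, 1],
                "threshold_dB": self.thresholds,
                "zone_id": self.zone_assignment,
            }
        ).to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_text(path) -> "VisualFieldGrid":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"zone_id": str})
        return VisualFieldGrid(
            thresholds=df["threshold_dB"].to_numpy(),
            coordinates=df[["x_deg", "y_deg"]].to_numpy(),
            zone_assignment=df["zone_id"].astype(str).to_numpy(),
        )


def vf_zone_means(vf: VisualFieldGrid):
    """Mean threshold (dB) of the points assigned to each zone."""
    import pandas as pd

    if not np.all(np.isfinite(vf.thresholds)):
        raise IncompleteFieldError("visual field contains missing values")
    rows = []
    for z in ZONE_IDS:
        sel = vf.zone_assignment == z
        rows.append((z, float(vf.thresholds[sel].mean()) if sel.any() else np.nan))
    return pd.DataFrame(rows, columns=["zone_id", "mean_threshold_dB"])
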