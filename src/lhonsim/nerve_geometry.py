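"""Synthetic optic-nerve cross-sections as packed circular axons on a pixel grid.

A nerve at radius-scale ``s`` is a disk of radius ``s * 750`` µm (the human
optic nerve is ~1.5 mm across) holding ``round(s^2 * 1.2e6)`` axons — the
human count of ~1.2 million scaled by cross-sectional area.  Axons are
non-overlapping disks separated by a minimum edge-to-edge clearance that
stands in for myelin and glia, placed by random sequential adsorption:
draw a uniform position inside the nerve, draw a radius from the local
(angle-interpolated) size profile, accept iff the clearance constraint
holds against all previously placed axons.

The cross-section is rasterized onto a label grid at fixed resolution
(default 10 px/µm, i.e. a 1500x1500 matrix for the 10%-scale nerve):
each pixel-center is classified as outside the nerve, extra-axonal, or
belonging to a specific axon.

Coordinate convention (right eye): x increases nasally, so temporal is
the -x half and nasal the +x half; superior is +y.  Grid row i / col j
map to y = (i + 0.5)/res - R and x = (j + 0.5)/res - R with R the nerve
radius in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .axon_population import (
    MixtureParams,
    QUADRANT_CENTER_ANGLES,
    RADIUS_SUPPORT,
    default_quadrant_params,
    tertile_bounds,
)

HUMAN_NERVE_RADIUS_UM = 750.0
HUMAN_AXON_COUNT = 1_200_000

LABEL_OUTSIDE = -2
LABEL_EXTRA_AXONAL = -1

SIZE_CLASS_NAMES = ("small", "medium", "large")


class PackingError(RuntimeError):
    """Random sequential insertion stalled before reaching the axon target."""

    def __init__(self, message: str, achieved: int, target: int):
        super().__init__(message)
        self.achieved = achieved
        self.target = target


@dataclass
class AxonRecord:
    id: int
    center: tuple[float, float]  # µm, nerve-centered
    radius: float  # µm
    size_class: Literal["small", "medium", "large"]
    status: Literal["alive", "degenerated"] = "alive"
    death_iteration: int | None = None


@dataclass
class OpticNerveModel:
    """Packed axon population plus its rasterization.

    Array attributes are the authoritative state; :attr:`axons` builds
    per-axon records on demand.  ``pix_idx``/``pix_off`` and
    ``perim_idx``/``perim_off`` are CSR-style flat-pixel-index lists per
    axon (offsets of length n_axons + 1).
    """

    scale: float
    resolution: float  # px per µm
    nerve_radius: float  # µm
    clearance: float  # µm
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray
    size_class: np.ndarray  # int8: 0 small, 1 medium, 2 large
    label_grid: np.ndarray  # int32
    pix_idx: np.ndarray
    pix_off: np.ndarray
    perim_idx: np.ndarray
    perim_off: np.ndarray
    alive: np.ndarray = field(default=None)
    death_iteration: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.radius.size
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        if self.death_iteration is None:
            self.death_iteration = np.full(n, -1, dtype=np.int32)

    @property
    def n_axons(self) -> int:
        return int(self.radius.size)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def axon(self, i: int) -> AxonRecord:
        if not 0 <= i < self.n_axons:
            raise KeyError(f"no axon with id {i}")
        return AxonRecord(
            id=i,
            center=(float(self.x[i]), float(self.y[i])),
            radius=float(self.radius[i]),
            size_class=SIZE_CLASS_NAMES[self.size_class[i]],
            status="alive" if self.alive[i] else "degenerated",
            death_iteration=None
            if self.death_iteration[i] < 0
            else int(self.death_iteration[i]),
        )

    @property
    def axons(self) -> list[AxonRecord]:
        return [self.axon(i) for i in range(self.n_axons)]

    def axon_pixels(self, i: int) -> np.ndarray:
        """Flat indices into the raveled label grid for axon ``i``."""
        return self.pix_idx[self.pix_off[i] : self.pix_off[i + 1]]

    def pixel_counts(self) -> np.ndarray:
        return np.diff(self.pix_off).astype(np.int64)

    def inside_mask(self) -> np.ndarray:
        return self.label_grid != LABEL_OUTSIDE

    def angles(self) -> np.ndarray:
        """Polar angle of each axon center, degrees in [0, 360)."""
        return np.degrees(np.arctan2(self.y, self.x)) % 360.0

    def to_axon_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n_axons),
                "x_um": self.x,
                "y_um": self.y,
                "radius_um": self.radius,
                "size_class": np.array(SIZE_CLASS_NAMES)[self.size_class],
                "status": np.where(self.alive, "alive", "degenerated"),
                "death_iteration": self.death_iteration,
            }
        )


@njit(cache=False)
def _rsa_pack(cand_x, cand_y, cand_r, clearance, nerve_r, n_target, retry_cap):
    """Sequential insertion with a cell-list neighbor structure.

    Consumes candidates in order; for each axon slot, up to ``retry_cap``
    candidates are tried before declaring a stall.  Returns accepted
    candidate indices (prefix of length ``n_acc``) and attempts used.
    """
    cell = 1.0  # µm; >= 2*(r_typical + clearance) neighborhoods via window
    ncell = int(np.ceil(2.0 * nerve_r / cell)) + 2
    head = np.full((ncell, ncell), -1, dtype=np.int32)
    nxt = np.full(n_target, -1, dtype=np.int32)
    ax = np.empty(n_target)
    ay = np.empty(n_target)
    ar = np.empty(n_target)
    accepted = np.empty(n_target, dtype=np.int64)
    n_acc = 0
    r_max_seen = 0.0
    retries = 0
    attempts = 0
    n_cand = cand_x.size

    for idx in range(n_cand):
        if n_acc >= n_target:
            break
        attempts += 1
        x = cand_x[idx]
        y = cand_y[idx]
        r = cand_r[idx]
        ok = True
        # inside the nerve circle entirely
        if x * x + y * y > (nerve_r - r) ** 2:
            ok = False
        if ok:
            reach = r + clearance + r_max_seen
            ci = int((x + nerve_r) / cell)
            cj = int((y + nerve_r) / cell)
            w = int(reach / cell) + 1
            i0 = max(ci - w, 0)
            i1 = min(ci + w, ncell - 1)
            j0 = max(cj - w, 0)
            j1 = min(cj + w, ncell - 1)
            for ii in range(i0, i1 + 1):
                if not ok:
                    break
                for jj in range(j0, j1 + 1):
                    k = head[ii, jj]
                    while k >= 0:
                        dx = ax[k] - x
                        dy = ay[k] - y
                        lim = ar[k] + r + clearance
                        if dx * dx + dy * dy < lim * lim:
                            ok = False
                            break
                        k = nxt[k]
                    if not ok:
                        break
        if ok:
            ax[n_acc] = x
            ay[n_acc] = y
            ar[n_acc] = r
            ci = int((x + nerve_r) / cell)
            cj = int((y + nerve_r) / cell)
            nxt[n_acc] = head[ci, cj]
            head[ci, cj] = n_acc
            accepted[n_acc] = idx
            n_acc += 1
            if r > r_max_seen:
                r_max_seen = r
            retries = 0
        else:
            retries += 1
            if retries >= retry_cap:
                break
    return accepted, n_acc, attempts


def _sample_candidates(
    rng: np.random.Generator,
    n: int,
    nerve_r: float,
    quadrant_params: dict[str, MixtureParams],
    blockwise: bool,
    support=RADIUS_SUPPORT,
):
    """Vectorized candidate positions + locally-sampled radii."""
    u = rng.random(n)
    rho = nerve_r * np.sqrt(rng.random(n))
    theta = rng.random(n) * 360.0
    x = rho * np.cos(np.radians(theta))
    y = rho * np.sin(np.radians(theta))

    order = ["nasal", "superior", "temporal", "inferior"]
    flats = np.stack([quadrant_params[t].as_flat() for t in order])  # (4, 9)
    seg = (theta // 90.0).astype(np.intp) % 4
    t = (theta - seg * 90.0) / 90.0
    if blockwise:
        nearest = (seg + (t >= 0.5)) % 4
        flat = flats[nearest]
    else:
        flat = (1.0 - t)[:, None] * flats[seg] + t[:, None] * flats[(seg + 1) % 4]

    a = flat[:, 0::3]
    mu = flat[:, 1::3]
    sd = flat[:, 2::3] / np.sqrt(2.0)
    w = a * flat[:, 2::3]
    w /= w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1)
    pick = (rng.random(n)[:, None] > cw).sum(axis=1)
    rows = np.arange(n)
    radii = rng.normal(mu[rows, pick], sd[rows, pick])
    lo, hi = support
    bad = (radii < lo) | (radii > hi)
    while bad.any():
        radii[bad] = rng.normal(mu[rows[bad], pick[bad]], sd[rows[bad], pick[bad]])
        bad = (radii < lo) | (radii > hi)
    return x, y, radii


def build_nerve(
    scale: float = 0.1,
    resolution: float = 10.0,
    clearance: float = 0.05,
    quadrant_params: dict[str, MixtureParams] | None = None,
    rng_seed: int = 0,
    blockwise: bool = False,
    retry_cap: int = 200,
    attempt_factor: int = 50,
) -> OpticNerveModel:
    """Build a packed, rasterized optic-nerve model.

    Targets ``round(scale^2 * 1.2e6)`` axons; raises :class:`PackingError`
    if insertion stalls below 95% of that target.  Size classes are
    tertiles of the generated population, so the initial small/medium/
    large proportions are equal by construction.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    if quadrant_params is None:
        quadrant_params = default_quadrant_params()

    nerve_r = scale * HUMAN_NERVE_RADIUS_UM
    n_target = int(round(scale**2 * HUMAN_AXON_COUNT))
    rng = np.random.default_rng(rng_seed)

    budget = attempt_factor * n_target
    placed_idx = []
    xs = np.empty(0)
    n_acc_total = 0
    # generate candidates in chunks until target reached or budget spent
    all_x = np.empty(0)
    all_y = np.empty(0)
    all_r = np.empty(0)
    cx, cy, cr = _sample_candidates(rng, budget, nerve_r, quadrant_params, blockwise)
    accepted, n_acc, attempts = _rsa_pack(
        cx, cy, cr, clearance, nerve_r, n_target, retry_cap
    )
    if n_acc < 0.95 * n_target:
        raise PackingError(
            f"packing stalled at {n_acc} of {n_target} axons "
            f"after {attempts} attempts",
            achieved=n_acc,
            target=n_target,
        )
    sel = accepted[:n_acc]
    x, y, r = cx[sel], cy[sel], cr[sel]

    bounds = tertile_bounds(r)
    size_class = bounds.classify(r)

    label = _rasterize_disks(x, y, r, nerve_r, resolution)
    pix_idx, pix_off = _pixel_csr(label, x.size)
    perim_idx, perim_off = _perimeter_csr(label, pix_idx, pix_off)

    return OpticNerveModel(
        scale=scale,
        resolution=resolution,
        nerve_radius=nerve_r,
        clearance=clearance,
        x=x,
        y=y,
        radius=r,
        size_class=size_class,
        label_grid=label,
        pix_idx=pix_idx,
        pix_off=pix_off,
        perim_idx=perim_idx,
        perim_off=perim_off,
    )


def _rasterize_disks(x, y, r, nerve_r, resolution) -> np.ndarray:
    """Label grid by pixel-center containment: axon id, extra-axonal, outside."""
    n_px = int(np.ceil(2.0 * nerve_r * resolution))
    label = np.full((n_px, n_px), LABEL_OUTSIDE, dtype=np.int32)

    coords = (np.arange(n_px) + 0.5) / resolution - nerve_r
    yy = coords[:, None]
    xx = coords[None, :]
    inside = yy * yy + xx * xx <= nerve_r * nerve_r
    label[inside] = LABEL_EXTRA_AXONAL

    for i in range(x.size):
        _fill_disk(label, x[i], y[i], r[i], nerve_r, resolution, np.int32(i))
    return label


@njit(cache=False)
def _fill_disk(label, cx, cy, r, nerve_r, resolution, idx):
    n_px = label.shape[0]
    i0 = max(int((cy - r + nerve_r) * resolution) - 1, 0)
    i1 = min(int((cy + r + nerve_r) * resolution) + 2, n_px)
    j0 = max(int((cx - r + nerve_r) * resolution) - 1, 0)
    j1 = min(int((cx + r + nerve_r) * resolution) + 2, n_px)
    r2 = r * r
    for i in range(i0, i1):
        py = (i + 0.5) / resolution - nerve_r
        for j in range(j0, j1):
            px = (j + 0.5) / resolution - nerve_r
            dx = px - cx
            dy = py - cy
            if dx * dx + dy * dy <= r2:
                label[i, j] = idx


def _pixel_csr(label: np.ndarray, n_axons: int):
    flat = label.ravel()
    ax_mask = flat >= 0
    idx = np.nonzero(ax_mask)[0]
    labs = flat[idx]
    order = np.argsort(labs, kind="stable")
    idx = idx[order]
    labs = labs[order]
    off = np.searchsorted(labs, np.arange(n_axons + 1))
    return idx.astype(np.int64), off.astype(np.int64)


def _perimeter_mask(label: np.ndarray) -> np.ndarray:
    """Axon pixels with at least one von Neumann neighbor of a different label."""
    ax = label >= 0
    diff = np.zeros(label.shape, dtype=bool)
    # treat the grid edge as "different"
    diff[0, :] = diff[-1, :] = diff[:, 0] = diff[:, -1] = True
    diff[1:, :] |= label[1:, :] != label[:-1, :]
    diff[:-1, :] |= label[:-1, :] != label[1:, :]
    diff[:, 1:] |= label[:, 1:] != label[:, :-1]
    diff[:, :-1] |= label[:, :-1] != label[:, 1:]
    return ax & diff


def _perimeter_csr(label: np.ndarray, pix_idx, pix_off):
    pmask_flat = _perimeter_mask(label).ravel()
    keep = pmask_flat[pix_idx]
    perim_idx = pix_idx[keep]
    # offsets: cumulative count of kept pixels per axon
    counts = np.add.reduceat(keep.astype(np.int64), pix_off[:-1]) if pix_idx.size else np.zeros(pix_off.size - 1, dtype=np.int64)
    counts = np.where(np.diff(pix_off) == 0, 0, counts)
    off = np.concatenate([[0], np.cumsum(counts)])
    return perim_idx.astype(np.int64), off.astype(np.int64)


def rasterize(model: OpticNerveModel) -> np.ndarray:
    """Recompute the label grid from the axon records (deterministic)."""
    return _rasterize_disks(
        model.x, model.y, model.radius, model.nerve_radius, model.resolution
    )


def perimeter_pixels(model: OpticNerveModel, axon_id: int) -> set[tuple[int, int]]:
    """Pixels of ``axon_id`` having a von Neumann neighbor with another label."""
    if not 0 <= axon_id < model.n_axons:
        raise KeyError(f"no axon with id {axon_id}")
    n_cols = model.label_grid.shape[1]
    flat = model.perim_idx[model.perim_off[axon_id] : model.perim_off[axon_id + 1]]
    return {(int(f // n_cols), int(f % n_cols)) for f in flat}
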