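"""Deterministic synthetic fixtures.

Stand-ins for the external data the model draws on: per-quadrant
axon-radius histograms with the published regional skew (small calibers
temporal, large nasal), a synthetic Humphrey 30-2 visual field with the
temporal-zone depression characteristic of LHON, and tiny hand-checkable
stencil cases for the diffusion update.  Everything is generated from a
seed, never shipped as data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axon_population import MixtureParams, RadiusHistogram, default_quadrant_params, sample_radii
from .injury_zones import VisualFieldGrid, default_vf_zone_assignment


@dataclass
class ToyStencilCase:
    """A small grid plus the expected field after ``n_steps`` updates.

    ``expected`` is evaluated by direct summation of the update rule in
    plain Python loops, independent of the simulation kernels.
    """

    field0: np.ndarray
    codes: np.ndarray  # full-grid compartment codes (0 outside, 1.. see engine)
    D: float
    S: float
    P: float
    n_steps: int
    expected: np.ndarray


@dataclass
class Fixtures:
    histograms: dict[str, RadiusHistogram]
    visual_field: VisualFieldGrid
    stencil_cases: list[ToyStencilCase] = field(default_factory=list)


def pan_like_histograms(
    seed: int = 0, n_per_quadrant: int = 50_000, n_bins: int = 40
) -> dict[str, RadiusHistogram]:
    """Radius histograms per quadrant drawn from the default profiles.

    Emulates digitized caliber histograms from normal human nerves: the
    temporal histogram is dominated by small calibers, the nasal one
    carries a heavy large-caliber shoulder.
    """
    rng = np.random.default_rng(seed)
    out = {}
    edges = np.linspace(0.1, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for tag, mp in default_quadrant_params().items():
        radii = sample_radii(mp, n_per_quadrant, rng_seed=rng)
        counts, _ = np.histogram(radii, bins=edges)
        out[tag] = RadiusHistogram(centers, counts.astype(float), region_tag=tag)
    return out


def lhon_like_visual_field(seed: int = 0, baseline_db: float = 30.0) -> VisualFieldGrid:
    """A synthetic 30-2 field with radially-graded temporal depression.

    Zone-wise depression depths follow the clinical pattern: deepest in
    the temporal zones (papillomacular damage), shallowest nasally.
    """
    rng = np.random.default_rng(seed)
    depression = {
        "1": 3.0,
        "2": 6.0,
        "3": 12.0,
        "4": 13.0,
        "5": 8.0,
        "6.1": 22.0,
        "6.2": 21.0,
    }
    zones = default_vf_zone_assignment()
    thr = np.array(
        [baseline_db - depression[z] for z in zones]
    ) + rng.normal(0.0, 0.7, size=76)
    return VisualFieldGrid(thresholds=np.clip(thr, 0.0, None))


def toy_stencil_cases(seed: int = 0) -> list[ToyStencilCase]:
    """5x5 grids with expected fields computed by direct loop evaluation."""
    rng = np.random.default_rng(seed)
    cases = []
    for D, S, P, n_steps in [(0.1, 0.0, 0.0, 2), (0.25, 0.01, 0.0, 2), (0.2, 0.005, 0.05, 3)]:
        codes = np.ones((5, 5), dtype=np.uint8)  # all extra-axonal
        codes[0, 0] = 0  # one outside corner exercises the no-flux boundary
        if P > 0:
            codes[2, 2] = 3  # one producing perimeter pixel
        f0 = rng.random((5, 5)) * np.where(codes > 0, 1.0, 0.0)
        expected = _evolve_by_hand(f0, codes, D, S, P, n_steps)
        cases.append(
            ToyStencilCase(
                field0=f0, codes=codes, D=D, S=S, P=P, n_steps=n_steps, expected=expected
            )
        )
    return cases


def _evolve_by_hand(f0, codes, D, S, P, n_steps):
    """Direct summation of the update rule; the independent oracle."""
    f = f0.astype(float).copy()
    n, m = f.shape
    # production quantized as in the engine (single-precision constant)
    Pq = float(np.float32(P))
    for _ in range(n_steps):
        g = np.zeros_like(f)
        for i in range(n):
            for j in range(m):
                if codes[i, j] == 0:
                    continue
                c = f[i, j]
                acc = c + (Pq if codes[i, j] == 3 else 0.0)
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m and codes[ii, jj] != 0:
                        acc += D * (f[ii, jj] - c)
                acc *= 1.0 - S
                g[i, j] = max(acc, 0.0)
        f = g
    return f


def generate_fixtures(seed: int = 0) -> Fixtures:
    """The full deterministic fixture bundle for one seed."""
    return Fixtures(
        histograms=pan_like_histograms(seed),
        visual_field=lhon_like_visual_field(seed),
        stencil_cases=toy_stencil_cases(seed),
    )
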