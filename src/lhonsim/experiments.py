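"""Study drivers: parameter sweeps, repetition, injury-axis and scale studies.

Each driver runs full steady-state simulations over a set of seeds and
condenses the outcomes into tidy tables.  The one inferential statistic
is a one-way ANOVA across runs, implemented directly from between- and
within-group sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .diffusion_engine import SimulationParams, SimulationResult, clone_model, run_to_steady_state
from .injury_zones import InjurySpec
from .nerve_geometry import build_nerve

SWEEPABLE = ("S_intra", "S_extra", "release_R", "D_intra", "D_extra", "threshold_T")

SIZE_NAMES = ("small", "medium", "large")


@dataclass
class StudyConfig:
    """Shared study settings: nerve geometry + simulation constants + injury."""

    scale: float = 0.1
    resolution: float = 10.0
    clearance: float = 0.05
    params: SimulationParams = None
    injury: InjurySpec = None
    quadrant_params: dict = None

    def __post_init__(self):
        if self.params is None:
            self.params = SimulationParams()
        if self.injury is None:
            self.injury = InjurySpec(preset="mid_temporal")

    def build(self, seed: int):
        return build_nerve(
            scale=self.scale,
            resolution=self.resolution,
            clearance=self.clearance,
            quadrant_params=self.quadrant_params,
            rng_seed=seed,
        )


def _run_one(config: StudyConfig, seed: int, params: SimulationParams | None = None,
             injury: InjurySpec | None = None, model=None) -> SimulationResult:
    if model is None:
        model = config.build(seed)
    else:
        model = clone_model(model)
    return run_to_steady_state(
        model,
        injury if injury is not None else config.injury,
        params if params is not None else config.params,
        rng_seed=seed,
    )


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from sums of squares.

    Returns (F, p).  Written out from the between/within decomposition so
    it can be validated against an independent implementation.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = k - 1
    df_w = n_total - k
    if df_w <= 0 or ss_within == 0:
        return np.inf if ss_between > 0 else 0.0, np.nan if ss_within == 0 else 1.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(_scipy_stats.f.sf(F, df_b, df_w))
    return float(F), p


@dataclass
class SweepResult:
    parameter: str
    table: pd.DataFrame  # value, frac_dead_all, per-class, steady_iteration, converged


def sweep(
    param_name: str,
    values: Sequence[float],
    base_config: StudyConfig,
    seeds: Sequence[int] = (0, 1, 2),
) -> SweepResult:
    """Steady-state outcome as one constant is varied, others held fixed.

    Runs one simulation per (value, seed) with matched seeds across
    values (the same synthetic nerves are reused for every value, so rows
    differ only through the swept constant); fractions are means over
    seeds.  Non-converged runs are flagged per row, not fatal.
    """
    if param_name not in SWEEPABLE:
        raise ValueError(f"{param_name!r} not sweepable; choose from {SWEEPABLE}")
    models = {s: base_config.build(s) for s in seeds}
    rows = []
    for v in values:
        p = replace(base_config.params, **{param_name: v})
        fracs, classes, iters, conv = [], [], [], True
        for s in seeds:
            res = _run_one(base_config, s, params=p, model=models[s])
            fracs.append(res.overall_dead_fraction)
            classes.append(res.class_dead_fractions("class"))
            iters.append(res.steady_iteration)
            conv &= res.converged
        cm = np.mean(classes, axis=0)
        rows.append(
            (
                v,
                float(np.mean(fracs)),
                *cm,
                float(np.mean(iters)),
                conv,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "value",
            "frac_dead_all",
            "frac_dead_small",
            "frac_dead_medium",
            "frac_dead_large",
            "steady_iteration",
            "converged",
        ],
    )
    return SweepResult(parameter=param_name, table=table)


@dataclass
class RepetitionSummary:
    n_runs: int
    table: pd.DataFrame  # one row per run
    mean_of_class: np.ndarray  # within-class dead fractions (small, medium, large)
    sd_of_class: np.ndarray
    mean_of_all: np.ndarray  # fraction-of-all-axons dead per class
    sd_of_all: np.ndarray
    overall_mean: float
    overall_sd: float
    anova_F: float
    anova_p: float


def repeat_study(
    config: StudyConfig, n_runs: int = 10, seeds: Sequence[int] | None = None
) -> RepetitionSummary:
    """Repeat the simulation on freshly generated nerves.

    One fresh nerve per seed, identical injury preset and constants.
    Summaries report degenerated fractions both within each size class
    and as fractions of all axons, plus a one-way ANOVA comparing the
    per-class degeneration profiles across runs (a small F / large p
    indicates run-to-run consistency).
    """
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) < 2:
        raise ValueError("need >= 2 seeds")
    rows = []
    for s in seeds:
        res = _run_one(config, s)
        wc = res.class_dead_fractions("class")
        fa = res.class_dead_fractions("all")
        rows.append(
            (
                s,
                res.model.n_axons,
                res.overall_dead_fraction,
                *wc,
                *fa,
                res.steady_iteration,
                res.converged,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "seed",
            "n_axons",
            "frac_dead_all",
            "within_small",
            "within_medium",
            "within_large",
            "of_all_small",
            "of_all_medium",
            "of_all_large",
            "steady_iteration",
            "converged",
        ],
    )
    wc = table[["within_small", "within_medium", "within_large"]].to_numpy()
    fa = table[["of_all_small", "of_all_medium", "of_all_large"]].to_numpy()
    # one group per run, the three class proportions as its observations:
    # a significant F would indicate run-to-run inconsistency
    F, p = anova_oneway(list(wc))
    return RepetitionSummary(
        n_runs=len(seeds),
        table=table,
        mean_of_class=wc.mean(axis=0),
        sd_of_class=wc.std(axis=0, ddof=1),
        mean_of_all=fa.mean(axis=0),
        sd_of_all=fa.std(axis=0, ddof=1),
        overall_mean=float(table.frac_dead_all.mean()),
        overall_sd=float(table.frac_dead_all.std(ddof=1)),
        anova_F=F,
        anova_p=p,
    )


AXIS_PRESETS = {
    "temporal_nasal": (
        "far_temporal",
        "mid_temporal",
        "temporal",
        "nasal",
        "mid_nasal",
        "far_nasal",
    ),
    "superior_inferior": ("superior", "mid_superior", "mid_inferior", "inferior"),
}


def axis_study(
    axis: str, config: StudyConfig, seeds: Sequence[int] = (0, 1, 2)
) -> pd.DataFrame:
    """Steady-state outcome per injury preset along one anatomical axis."""
    if axis not in AXIS_PRESETS:
        raise ValueError(f"axis must be one of {tuple(AXIS_PRESETS)}")
    models = {s: config.build(s) for s in seeds}
    rows = []
    for preset in AXIS_PRESETS[axis]:
        injury = InjurySpec(preset=preset)
        fr, wc, fa, iters = [], [], [], []
        for s in seeds:
            res = _run_one(config, s, injury=injury, model=models[s])
            fr.append(res.overall_dead_fraction)
            wc.append(res.class_dead_fractions("class"))
            fa.append(res.class_dead_fractions("all"))
            iters.append(res.steady_iteration)
        rows.append(
            (
                preset,
                float(np.mean(fr)),
                *np.mean(wc, axis=0),
                *np.mean(fa, axis=0),
                float(np.mean(iters)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "preset",
            "frac_dead_all",
            "within_small",
            "within_medium",
            "within_large",
            "of_all_small",
            "of_all_medium",
            "of_all_large",
            "steady_iteration",
        ],
    )


def scale_study(
    scales: Sequence[float],
    config: StudyConfig,
    seeds: Sequence[int] = (0, 1, 2),
    memory_budget_bytes: int = 6 * 1024**3,
) -> pd.DataFrame:
    """Axon counts and steady-state outcomes per nerve scale.

    Refuses scales whose grids would exceed ``memory_budget_bytes``
    (about ten double-precision grids are live during a run).
    """
    rows = []
    for sc in scales:
        n_px = int(np.ceil(2 * sc * 750.0 * config.resolution))
        need = 10 * 8 * n_px * n_px
        if need > memory_budget_bytes:
            raise MemoryError(
                f"scale {sc} needs ~{need/1e9:.1f} GB (budget "
                f"{memory_budget_bytes/1e9:.1f} GB)"
            )
        cfg = replace(config, scale=sc)
        fr, wc, fa, counts = [], [], [], []
        for s in seeds:
            res = _run_one(cfg, s)
            fr.append(res.overall_dead_fraction)
            wc.append(res.class_dead_fractions("class"))
            fa.append(res.class_dead_fractions("all"))
            counts.append(res.model.n_axons)
        rows.append(
            (
                sc,
                float(np.mean(counts)),
                float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
                float(np.mean(fr)),
                *np.mean(wc, axis=0),
                *np.mean(fa, axis=0),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scale",
            "n_axons_mean",
            "n_axons_sd",
            "frac_dead_all",
            "within_small",
            "within_medium",
            "within_large",
            "of_all_small",
            "of_all_medium",
            "of_all_large",
        ],
    )
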