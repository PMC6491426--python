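"""Superoxide reaction–diffusion on the rasterized nerve, with threshold death.

Each iteration updates every in-nerve grid element synchronously
(Jacobi-style, from the previous field only):

    C'[i,j] = ( C[i,j] + P[i,j]
                + sum over the 4 von Neumann neighbors n of
                  D_pair(i,j;n) * (C[n] - C[i,j]) ) * (1 - S[i,j])

* ``P`` is the basal superoxide production, applied at perimeter pixels
  of alive axons only — total production per axon is therefore
  proportional to its circumference in the slice.
* ``D_pair`` is the mean of the two elements' location constants
  (intra- vs extra-axonal); pairs crossing the nerve boundary
  contribute nothing (no-flux boundary).
* ``S`` is first-order scavenging: each element retains a fraction
  ``1 - S_loc`` of its post-diffusion content per iteration
  (``S_intra`` inside alive axons, ``S_extra`` elsewhere in the nerve).
  A zeroth-order subtractive variant (``C' = max(0, C' - S_loc)``) is
  available via ``scavenging="subtractive"``.

After the field update, every alive axon whose mean intra-pixel
concentration has reached the toxic threshold degenerates: a fixed
amount of superoxide (the release constant) is added uniformly over its
pixels and the pixels become extra-axonal for all subsequent production,
scavenging and diffusion.

The run terminates at steady state: no element's concentration changes
by more than ``ss_epsilon`` per iteration (or, with
``ss_metric="total"``, the summed superoxide changes by less than
``ss_epsilon``), with no new deaths, for ``ss_quiet_window``
consecutive iterations.

Implementation note: the per-pixel compartment is a byte code
(0 outside, 1 extra-axonal or degenerated, 2 alive-axon interior,
3 alive-axon perimeter) and all location-dependent constants are 4-entry
table lookups, so degeneration updates are single byte writes and the
stencil kernel streams one byte plus two doubles per element.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numba import njit

from .nerve_geometry import OpticNerveModel

CODE_OUTSIDE = 0
CODE_EXTRA = 1
CODE_INTRA = 2
CODE_PERIM = 3


class NumericalFailure(RuntimeError):
    def __init__(self, iteration: int):
        super().__init__(f"non-finite concentration at iteration {iteration}")
        self.iteration = iteration


class CalibrationError(RuntimeError):
    def __init__(self, message: str, achieved_range: tuple[float, float]):
        super().__init__(message)
        self.achieved_range = achieved_range


@dataclass(frozen=True)
class SimulationParams:
    """Rate constants of the superoxide model.

    Diffusion constants are unitless per-pair transfer fractions and must
    respect the explicit-stencil stability bound (sum of the four pair
    constants at any element <= 1, i.e. each <= 0.25).  Production is
    µmol per iteration per perimeter pixel.  With the default first-order
    scavenging, ``S_intra``/``S_extra`` are the fraction of an element's
    content removed per iteration; with the subtractive variant they are
    µmol removed per element per iteration.  ``threshold_T`` (µmol, mean
    over an axon's pixels) triggers degeneration; ``release_R`` (µmol) is
    dumped over a degenerating axon's pixels.  ``threshold_T`` is fixed
    by bisection to the 35–40% steady-state survival benchmark for a
    mid-temporal injury on the 10%-scale nerve (see :func:`calibrate`).
    """

    D_intra: float = 0.25
    D_extra: float = 0.25
    P_coeff: float = 0.06
    S_intra: float = 0.005
    S_extra: float = 0.005
    threshold_T: float = 16.74
    release_R: float = 20_000.0
    injury_amount: float = 500_000.0
    injury_footprint: float = 0.05  # fraction of nerve radius
    ss_epsilon: float = 0.01
    ss_quiet_window: int = 10
    ss_metric: Literal["element", "total"] = "element"
    max_iterations: int = 20_000
    scavenging: Literal["first_order", "subtractive"] = "first_order"
    death_aggregator: Literal["mean", "max"] = "mean"

    def __post_init__(self):
        for name in ("D_intra", "D_extra"):
            v = getattr(self, name)
            if not 0 <= v <= 0.25:
                raise ValueError(f"{name}={v} violates stability bound [0, 0.25]")
        for name in ("P_coeff", "S_intra", "S_extra", "release_R", "injury_amount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ss_epsilon <= 0:
            raise ValueError("ss_epsilon must be > 0")
        if self.scavenging == "first_order" and not (
            0 <= self.S_intra <= 1 and 0 <= self.S_extra <= 1
        ):
            raise ValueError("first-order scavenging fractions must be in [0, 1]")

    def tables(self):
        """Per-code lookup tables (D, P, retention, subtractive S)."""
        D = np.array([0.0, self.D_extra, self.D_intra, self.D_intra])
        wtab = 0.5 * (D[:, None] + D[None, :])
        wtab[0, :] = 0.0
        wtab[:, 0] = 0.0
        # production is carried in a single-precision grid on the fast path;
        # quantize it identically everywhere so all kernels agree bitwise
        ptab = np.array([0.0, 0.0, 0.0, float(np.float32(self.P_coeff))])
        S = np.array([0.0, self.S_extra, self.S_intra, self.S_intra])
        rtab = 1.0 - S
        return wtab, ptab, rtab, S


@dataclass
class SimulationState:
    """One time step: padded concentration field plus live/dead bookkeeping."""

    field_padded: np.ndarray  # float64, 1-px halo of zeros
    model: OpticNerveModel
    code_padded: np.ndarray = None  # uint8 compartment codes, same halo
    iteration: int = 0
    newly_dead: list = field(default_factory=list)
    jmin: np.ndarray = None
    jmax: np.ndarray = None
    nbdef: np.ndarray = None  # per-pixel count of outside von Neumann neighbors
    P32: np.ndarray = None  # dense float32 production grid (alive perimeters)
    ins32: np.ndarray = None  # 1.0 inside the nerve, 0.0 outside (float32)
    axon_order: np.ndarray = None  # axon ids sorted by first pixel (scan order)
    pix_pad: np.ndarray = None  # per-axon flat indices into the padded field
    perim_pad: np.ndarray = None
    axon_sums: np.ndarray = None
    total: float = 0.0
    max_element_change: float = np.inf
    _buf: np.ndarray = None

    @property
    def field(self) -> np.ndarray:
        return self.field_padded[1:-1, 1:-1]

    @property
    def code(self) -> np.ndarray:
        return self.code_padded[1:-1, 1:-1]

    @property
    def inside(self) -> np.ndarray:
        return self.code != CODE_OUTSIDE


def _pad_flat(idx: np.ndarray, n_cols: int) -> np.ndarray:
    """Unpadded flat grid indices → flat indices into the 1-px-padded grid."""
    return idx + 2 * (idx // n_cols) + (n_cols + 2) + 1


def _scan_order(model: OpticNerveModel) -> np.ndarray:
    """Axon ids sorted by their first pixel's flat index (raster scan order)."""
    n = model.n_axons
    starts = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    nonempty = model.pix_off[:-1] < model.pix_off[1:]
    starts[nonempty] = model.pix_idx[model.pix_off[:-1][nonempty]]
    return np.argsort(starts, kind="stable").astype(np.int64)


def init_state(
    model: OpticNerveModel, params: SimulationParams, field0: np.ndarray | None = None
) -> SimulationState:
    n, m = model.grid_shape
    label = model.label_grid
    code = np.zeros((n + 2, m + 2), dtype=np.uint8)
    inner = code[1:-1, 1:-1]
    inner[label >= -1] = CODE_EXTRA
    pix_pad = _pad_flat(model.pix_idx, m)
    perim_pad = _pad_flat(model.perim_idx, m)
    cf = code.ravel()
    for a in range(model.n_axons):
        if model.alive[a]:
            cf[pix_pad[model.pix_off[a] : model.pix_off[a + 1]]] = CODE_INTRA
            cf[perim_pad[model.perim_off[a] : model.perim_off[a + 1]]] = CODE_PERIM

    inside = inner != CODE_OUTSIDE
    jmin = np.zeros(n, dtype=np.int64)
    jmax = np.full(n, -1, dtype=np.int64)
    for r in np.nonzero(inside.any(axis=1))[0]:
        cols = np.nonzero(inside[r])[0]
        jmin[r], jmax[r] = cols[0], cols[-1]

    # count of outside-or-off-grid neighbors per pixel (no-flux boundary)
    padded_ins = np.zeros((n + 2, m + 2), dtype=np.uint8)
    padded_ins[1:-1, 1:-1] = inside
    nbdef = (
        4
        - padded_ins[:-2, 1:-1].astype(np.int16)
        - padded_ins[2:, 1:-1]
        - padded_ins[1:-1, :-2]
        - padded_ins[1:-1, 2:]
    ).astype(np.uint8)

    P32 = np.zeros((n, m), dtype=np.float32)
    pf = P32.ravel()
    for a in range(model.n_axons):
        if model.alive[a]:
            pf[model.perim_idx[model.perim_off[a] : model.perim_off[a + 1]]] = 1.0
    P32 *= np.float32(params.P_coeff)

    Cp = np.zeros((n + 2, m + 2), dtype=np.float64)
    if field0 is not None:
        Cp[1:-1, 1:-1] = field0
    st = SimulationState(
        field_padded=Cp,
        model=model,
        code_padded=code,
        jmin=jmin,
        jmax=jmax,
        nbdef=nbdef,
        P32=P32,
        ins32=inside.astype(np.float32),
        axon_order=_scan_order(model),
        pix_pad=pix_pad,
        perim_pad=perim_pad,
        axon_sums=np.zeros(model.n_axons),
        _buf=np.zeros_like(Cp),
    )
    st.total = float(st.field[inside].sum())
    return st


@njit(cache=False)
def _step_kernel(Cp, Cnewp, codep, wtab, ptab, rtab, stab, jmin, jmax, subtractive):
    n = jmin.shape[0]
    total = 0.0
    maxdiff = 0.0
    for i in range(n):
        for j in range(jmin[i], jmax[i] + 1):
            a = codep[i + 1, j + 1]
            wn = wtab[a, codep[i, j + 1]]
            ws = wtab[a, codep[i + 2, j + 1]]
            ww = wtab[a, codep[i + 1, j]]
            we = wtab[a, codep[i + 1, j + 2]]
            acc = (
                (1.0 - (wn + ws + ww + we)) * Cp[i + 1, j + 1]
                + wn * Cp[i, j + 1]
                + ws * Cp[i + 2, j + 1]
                + ww * Cp[i + 1, j]
                + we * Cp[i + 1, j + 2]
                + ptab[a]
            )
            if subtractive:
                acc -= stab[a]
                if acc < 0.0:
                    acc = 0.0
            else:
                acc *= rtab[a]
            Cnewp[i + 1, j + 1] = acc
            total += acc
            d = acc - Cp[i + 1, j + 1]
            if d < 0.0:
                d = -d
            if d > maxdiff:
                maxdiff = d
    return total, maxdiff


@njit(cache=False)
def _step_kernel_uniform(Cp, Cnewp, codep, nbdef, D, ptab, rtab, stab, jmin, jmax,
                         subtractive):
    """Specialized stencil for D_intra == D_extra == D.

    Every interior pair weight is D, so the update reduces to
    ``D * (4-neighbor sum) + D * (outside-neighbor count) * C + (1-4D) * C``
    with the outside-neighbor count precomputed per pixel (no-flux
    boundary).  Produces results identical to the general kernel.
    """
    n = jmin.shape[0]
    wc = 1.0 - 4.0 * D
    total = 0.0
    maxdiff = 0.0
    for i in range(n):
        for j in range(jmin[i], jmax[i] + 1):
            a = codep[i + 1, j + 1]
            c = Cp[i + 1, j + 1]
            acc = (
                D * (Cp[i, j + 1] + Cp[i + 2, j + 1] + Cp[i + 1, j] + Cp[i + 1, j + 2])
                + (wc + D * nbdef[i, j]) * c
                + ptab[a]
            )
            if subtractive:
                acc -= stab[a]
                if acc < 0.0:
                    acc = 0.0
            else:
                acc *= rtab[a]
            Cnewp[i + 1, j + 1] = acc
            total += acc
            d = acc - c
            if d < 0.0:
                d = -d
            if d > maxdiff:
                maxdiff = d
    return total, maxdiff


@njit(cache=False, fastmath=True)
def _step_kernel_fast(Cp, Cnewp, nbdef, P32, ins32, D, ret, jmin, jmax):
    """Fully uniform case: one D everywhere, one first-order S everywhere.

    Branch-free inner loop (production is a dense float32 array, zero off
    the alive perimeter) so the compiler can vectorize; numerically
    identical to the general kernel under these parameter conditions up
    to floating-point reassociation.
    """
    n = jmin.shape[0]
    wc = 1.0 - 4.0 * D
    total = 0.0
    maxdiff = 0.0
    for i in range(n):
        rowt = 0.0
        rowm = 0.0
        for j in range(jmin[i], jmax[i] + 1):
            c = Cp[i + 1, j + 1]
            acc = (
                D * (Cp[i, j + 1] + Cp[i + 2, j + 1] + Cp[i + 1, j] + Cp[i + 1, j + 2])
                + (wc + D * nbdef[i, j]) * c
                + P32[i, j]
            ) * (ret * ins32[i, j])
            Cnewp[i + 1, j + 1] = acc
            rowt += acc
            rowm = max(rowm, abs(acc - c))
        total += rowt
        maxdiff = max(maxdiff, rowm)
    return total, maxdiff


@njit(cache=False)
def _axon_sums_kernel(Cp_flat, pix_pad, pix_off, alive, order, sums):
    # axons visited in spatial (first-pixel) order so the gathers walk the
    # field nearly sequentially
    for t in range(order.size):
        a = order[t]
        if not alive[a]:
            sums[a] = 0.0
            continue
        s = 0.0
        for k in range(pix_off[a], pix_off[a + 1]):
            s += Cp_flat[pix_pad[k]]
        sums[a] = s


def step(state: SimulationState, params: SimulationParams) -> SimulationState:
    """Advance the field one iteration (synchronous update, in place)."""
    wtab, ptab, rtab, stab = params.tables()
    subtractive = params.scavenging == "subtractive"
    if (
        params.D_intra == params.D_extra
        and params.S_intra == params.S_extra
        and not subtractive
    ):
        total, maxdiff = _step_kernel_fast(
            state.field_padded,
            state._buf,
            state.nbdef,
            state.P32,
            state.ins32,
            params.D_intra,
            1.0 - params.S_intra,
            state.jmin,
            state.jmax,
        )
    elif params.D_intra == params.D_extra:
        total, maxdiff = _step_kernel_uniform(
            state.field_padded,
            state._buf,
            state.code_padded,
            state.nbdef,
            params.D_intra,
            ptab,
            rtab,
            stab,
            state.jmin,
            state.jmax,
            subtractive,
        )
    else:
        total, maxdiff = _step_kernel(
            state.field_padded,
            state._buf,
            state.code_padded,
            wtab,
            ptab,
            rtab,
            stab,
            state.jmin,
            state.jmax,
            subtractive,
        )
    if not np.isfinite(total):
        raise NumericalFailure(state.iteration)
    state.max_element_change = float(maxdiff)
    state.field_padded, state._buf = state._buf, state.field_padded
    _axon_sums_kernel(
        state.field_padded.ravel(),
        state.pix_pad,
        state.model.pix_off,
        state.model.alive,
        state.axon_order,
        state.axon_sums,
    )
    state.total = float(total)
    state.iteration += 1
    state.newly_dead = []
    return state


def step_reference(state: SimulationState, params: SimulationParams) -> np.ndarray:
    """Pure-numpy synchronous update, independent of the compiled kernel.

    Returns the next (unpadded) concentration field; serves as the oracle
    the fast kernel is checked against.
    """
    wtab, ptab, rtab, stab = params.tables()
    codep = state.code_padded
    Cp = state.field_padded
    a = codep[1:-1, 1:-1]
    acc = Cp[1:-1, 1:-1].copy() + ptab[a]
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = codep[1 + di : codep.shape[0] - 1 + di, 1 + dj : codep.shape[1] - 1 + dj]
        Cn = Cp[1 + di : Cp.shape[0] - 1 + di, 1 + dj : Cp.shape[1] - 1 + dj]
        w = wtab[a, nb]
        acc += w * (Cn - Cp[1:-1, 1:-1])
    if params.scavenging == "subtractive":
        acc = np.maximum(acc - stab[a], 0.0)
    else:
        acc = acc * rtab[a]
    acc[a == CODE_OUTSIDE] = 0.0
    return acc


def apply_degeneration(state: SimulationState, params: SimulationParams) -> SimulationState:
    """Kill alive axons at/above threshold; release superoxide over their pixels."""
    model = state.model
    counts = model.pixel_counts()
    if params.death_aggregator == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            agg = np.where(counts > 0, state.axon_sums / np.maximum(counts, 1), 0.0)
    else:
        flat = state.field_padded.ravel()
        agg = np.array(
            [
                flat[state.pix_pad[model.pix_off[i] : model.pix_off[i + 1]]].max()
                if counts[i]
                else 0.0
                for i in range(model.n_axons)
            ]
        )
    dying = np.nonzero(model.alive & (agg >= params.threshold_T) & (counts > 0))[0]
    if dying.size:
        Cf = state.field_padded.ravel()
        cf = state.code_padded.ravel()
        for i in dying:
            px = state.pix_pad[model.pix_off[i] : model.pix_off[i + 1]]
            Cf[px] += params.release_R / px.size
            state.total += params.release_R
            cf[px] = CODE_EXTRA
            state.P32.ravel()[
                model.perim_idx[model.perim_off[i] : model.perim_off[i + 1]]
            ] = 0.0
            model.alive[i] = False
            model.death_iteration[i] = state.iteration
    state.newly_dead = list(map(int, dying))
    return state


@dataclass
class SimulationResult:
    steady_iteration: int
    converged: bool
    model: OpticNerveModel
    field: np.ndarray
    history: "object"  # pandas.DataFrame: iteration, total, dead fractions
    frames: list = field(default_factory=list)

    @property
    def overall_dead_fraction(self) -> float:
        return float((~self.model.alive).mean())

    def class_dead_fractions(self, of: Literal["class", "all"] = "class") -> np.ndarray:
        """Degenerated fraction per size class (small, medium, large), as a
        fraction of that class (``of="class"``) or of all axons (``of="all"``)."""
        dead = ~self.model.alive
        out = np.empty(3)
        n_all = self.model.n_axons
        for k in range(3):
            in_k = self.model.size_class == k
            denom = in_k.sum() if of == "class" else n_all
            out[k] = dead[in_k].sum() / max(denom, 1)
        return out


def run_to_steady_state(
    model: OpticNerveModel,
    injury,
    params: SimulationParams,
    rng_seed: int = 0,
    frame_cadence: int = 0,
) -> SimulationResult:
    """Iterate field update + degeneration until steady state.

    ``injury`` may be an :class:`~lhonsim.injury_zones.InjurySpec` or a
    prebuilt t=0 concentration field.  ``frame_cadence > 0`` retains a
    (iteration, field, alive) snapshot every that many iterations.  A run
    that hits ``max_iterations`` without meeting the steady-state test is
    returned flagged ``converged=False`` rather than raising.
    """
    import pandas as pd

    from .injury_zones import InjurySpec, place_injury

    if isinstance(injury, InjurySpec):
        field0 = place_injury(model, injury, params)
    else:
        field0 = injury
    state = init_state(model, params, field0)

    class_n = np.array([(model.size_class == k).sum() for k in range(3)], dtype=float)
    dead_k = np.array(
        [(~model.alive)[model.size_class == k].sum() for k in range(3)], dtype=float
    )
    rows = []
    frames = []
    quiet = 0
    prev_total = state.total
    steady_iter = params.max_iterations
    converged = False
    while state.iteration < params.max_iterations:
        step(state, params)
        apply_degeneration(state, params)
        for a in state.newly_dead:
            dead_k[model.size_class[a]] += 1
        rows.append(
            (
                state.iteration,
                state.total,
                *(dead_k / np.maximum(class_n, 1)),
                dead_k.sum() / max(model.n_axons, 1),
            )
        )
        if frame_cadence and state.iteration % frame_cadence == 0:
            frames.append((state.iteration, state.field.copy(), model.alive.copy()))
        if params.ss_metric == "element":
            quiescent = state.max_element_change < params.ss_epsilon
        else:
            quiescent = abs(state.total - prev_total) < params.ss_epsilon
        if quiescent and not state.newly_dead:
            quiet += 1
            if quiet >= params.ss_quiet_window:
                steady_iter = state.iteration
                converged = True
                break
        else:
            quiet = 0
        prev_total = state.total

    history = pd.DataFrame(
        rows,
        columns=[
            "iteration",
            "total_umol",
            "frac_dead_small",
            "frac_dead_medium",
            "frac_dead_large",
            "frac_dead_all",
        ],
    )
    return SimulationResult(
        steady_iteration=steady_iter,
        converged=converged,
        model=model,
        field=state.field.copy(),
        history=history,
        frames=frames,
    )


def calibrate(
    params: SimulationParams,
    model: OpticNerveModel,
    target_survival: tuple[float, float] = (0.35, 0.40),
    free_parameter: str = "threshold_T",
    bracket: tuple[float, float] | None = None,
    max_evals: int = 12,
) -> SimulationParams:
    """Bisect one free parameter to the steady-state survival benchmark.

    Survival (1 − overall degenerated fraction) for a mid-temporal injury
    must be non-decreasing in the free parameter over the bracket (it is
    for the toxic threshold: raising it can only spare axons); this is
    asserted at the bracket endpoints.  Returns the input parameters
    unchanged if they already land inside the target interval.
    """
    from .injury_zones import InjurySpec

    injury = InjurySpec(preset="mid_temporal")
    lo_t, hi_t = target_survival
    if bracket is None:
        v0 = getattr(params, free_parameter)
        bracket = (v0 * 0.88, v0 * 1.12)

    def survival(value: float) -> float:
        p = replace(params, **{free_parameter: value})
        m = clone_model(model)
        res = run_to_steady_state(m, injury, p)
        return 1.0 - res.overall_dead_fraction

    current = survival(getattr(params, free_parameter))
    if lo_t <= current <= hi_t:
        return params

    a, b = bracket
    sa, sb = survival(a), survival(b)
    if not sa <= sb:
        raise CalibrationError(
            "survival not non-decreasing over bracket", achieved_range=(sa, sb)
        )
    if not (sa <= (lo_t + hi_t) / 2.0 <= sb):
        raise CalibrationError(
            f"target {target_survival} not bracketed by survival "
            f"({sa:.3f}, {sb:.3f})",
            achieved_range=(sa, sb),
        )
    val = None
    for _ in range(max_evals):
        mid = 0.5 * (a + b)
        sm = survival(mid)
        if lo_t <= sm <= hi_t:
            val = mid
            break
        if sm < lo_t:
            a = mid
        else:
            b = mid
    if val is None:
        raise CalibrationError(
            f"no value inside {target_survival} after {max_evals} bisections",
            achieved_range=(survival(a), survival(b)),
        )
    return replace(params, **{free_parameter: val})


def clone_model(model: OpticNerveModel) -> OpticNerveModel:
    """Fresh-status copy sharing the immutable geometry arrays."""
    return OpticNerveModel(
        scale=model.scale,
        resolution=model.resolution,
        nerve_radius=model.nerve_radius,
        clearance=model.clearance,
        x=model.x,
        y=model.y,
        radius=model.radius,
        size_class=model.size_class,
        label_grid=model.label_grid,
        pix_idx=model.pix_idx,
        pix_off=model.pix_off,
        perim_idx=model.perim_idx,
        perim_off=model.perim_off,
    )
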