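"""PNG snapshot export of simulation frames.

The rendering follows the simulator's display convention: superoxide in
shades of pink (intensity-scaled), alive axons green, degenerated axons
blue, extra-axonal space dark, outside-nerve background black.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

# RGB class colors
_BACKGROUND = np.array([0, 0, 0], dtype=np.uint8)
_EXTRA = np.array([30, 30, 30], dtype=np.uint8)
_ALIVE = np.array([0, 170, 0], dtype=np.uint8)
_DEAD = np.array([40, 70, 220], dtype=np.uint8)
_PINK = np.array([255, 105, 180], dtype=np.float64)


def render_frame(
    model,
    field: np.ndarray,
    alive: np.ndarray,
    pink_scale: float | None = None,
) -> np.ndarray:
    """RGB image (H, W, 3) of one simulation state.

    Superoxide is overlaid as pink with per-pixel opacity
    ``min(1, C / pink_scale)``; ``pink_scale`` defaults to the 99th
    percentile of the nonzero field.
    """
    label = model.label_grid
    img = np.empty((*label.shape, 3), dtype=np.uint8)
    img[:] = _BACKGROUND
    img[label == -1] = _EXTRA
    ax = label >= 0
    alive_px = np.zeros(label.shape, dtype=bool)
    flat = alive_px.ravel()
    for i in range(model.n_axons):
        if alive[i]:
            flat[model.axon_pixels(i)] = True
    img[ax & alive_px] = _ALIVE
    img[ax & ~alive_px] = _DEAD

    if field is not None and np.any(field > 0):
        if pink_scale is None:
            nz = field[field > 0]
            pink_scale = float(np.percentile(nz, 99)) or 1.0
        alpha = np.clip(field / pink_scale, 0.0, 1.0)[..., None]
        img = (img * (1.0 - alpha) + _PINK * alpha).astype(np.uint8)
    return img


def export_snapshots(result, out_dir, cadence: int = 1) -> list[Path]:
    """Write retained frames of a run as PNGs; returns written paths.

    ``cadence`` further thins the retained frames (every n-th); 0 writes
    nothing.  Frames must have been retained by the run
    (``frame_cadence > 0`` in :func:`run_to_steady_state`).
    """
    from PIL import Image

    if cadence <= 0:
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for k, (iteration, field, alive) in enumerate(result.frames):
        if k % cadence:
            continue
        img = render_frame(result.model, field, alive)
        path = out / f"frame_{iteration:06d}.png"
        Image.fromarray(img).save(path)
        written.append(path)
    return written


def class_pixel_counts(model, alive: np.ndarray) -> dict:
    """Pixel tallies per display class, for cross-checks against a frame."""
    label = model.label_grid
    ax_counts = model.pixel_counts()
    alive_px = int(ax_counts[alive].sum())
    dead_px = int(ax_counts[~alive].sum())
    extra = int((label == -1).sum())
    outside = int((label == -2).sum())
    return {
        "alive": alive_px,
        "dead": dead_px,
        "extra_axonal": extra,
        "outside": outside,
    }
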