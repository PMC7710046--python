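"""Frame-by-frame simulated scanning of trajectories and movie export.

All frames of a trajectory are oriented with the same rotation, placed with a
single common stage offset (from the first frame, so vertical motion between
frames stays visible), and scanned on one shared grid built from the union of
the frames' bounding boxes.  Per-frame restaging is available behind a flag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .geometry import Orientation, ScanGrid, build_grid, orient, stage
from .structure_io import Structure, Trajectory
from .tip_scan import HeightMap, TipModel, scan

__all__ = ["MovieResult", "scan_trajectory", "export_movie"]


@dataclass
class MovieResult:
    """Ordered height maps on a single shared grid."""

    frames: List[HeightMap]
    shared_grid: ScanGrid
    labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("MovieResult needs at least one frame")
        for hm in self.frames:
            if hm.grid != self.shared_grid:
                raise ValidationError("all movie frames must share one grid")
        if not self.labels:
            self.labels = [f"frame {k}" for k in range(len(self.frames))]

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def global_max(self) -> float:
        return max(float(hm.heights.max()) for hm in self.frames)


def scan_trajectory(
    traj: Trajectory,
    tip: TipModel,
    step: float,
    orientation: Optional[Orientation] = None,
    margin: float = 2.0,
    restage_per_frame: bool = False,
) -> MovieResult:
    """Scan every trajectory frame on a shared grid.

    The stage offset is computed once from the first oriented frame and
    applied to all frames (``restage_per_frame=True`` re-drops each frame
    onto z = 0 instead).  The shared grid spans the union of all oriented
    frames' lateral VdW bounding boxes plus the margin, registered to the
    first frame's centroid.
    """
    orientation = Orientation.identity() if orientation is None else orientation
    oriented = [orient(f, orientation) for f in traj.frames]

    first_staged = stage(oriented[0])
    dz = first_staged.coords[0, 2] - oriented[0].coords[0, 2]

    placed: List[Structure] = []
    for frame in oriented:
        if restage_per_frame:
            placed.append(stage(frame))
        else:
            coords = frame.coords
            coords[:, 2] += dz
            placed.append(frame.with_coords(coords))

    x_lo = y_lo = np.inf
    x_hi = y_hi = -np.inf
    for frame in placed:
        coords, radii = frame.coords, frame.radii
        x_lo = min(x_lo, float(np.min(coords[:, 0] - radii)))
        x_hi = max(x_hi, float(np.max(coords[:, 0] + radii)))
        y_lo = min(y_lo, float(np.min(coords[:, 1] - radii)))
        y_hi = max(y_hi, float(np.max(coords[:, 1] + radii)))
    grid = build_grid(
        placed[0],
        step,
        margin,
        bounds=(x_lo - margin, x_hi + margin, y_lo - margin, y_hi + margin),
    )

    maps = [scan(frame, tip, grid) for frame in placed]
    labels = [frame.label or f"frame {k}" for k, frame in enumerate(traj.frames)]
    return MovieResult(frames=maps, shared_grid=grid, labels=labels)


def export_movie(
    result: MovieResult,
    outdir: os.PathLike,
    fps: float = 5.0,
    colormap: str = "afmhot",
    prefix: str = "frame",
    write_gif: bool = True,
    zrange: Optional[Sequence[float]] = None,
) -> dict:
    """Write per-frame PNGs plus an animated GIF with a global z-color scale.

    The color scale is fixed across frames (0 to the movie-wide maximum
    unless ``zrange`` is given), so the tallest frame saturates the palette
    and relative heights are comparable between frames.  Frame indices are
    zero-padded in filenames.  Returns a dict with the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps
    from matplotlib.colors import Normalize

    os.makedirs(outdir, exist_ok=True)
    if zrange is None:
        vmin, vmax = 0.0, result.global_max
        if vmax <= vmin:
            vmax = vmin + 1.0
    else:
        vmin, vmax = float(zrange[0]), float(zrange[1])

    norm = Normalize(vmin=vmin, vmax=vmax, clip=True)
    mapper = colormaps[colormap]

    width = max(3, len(str(len(result) - 1)))
    png_paths = []
    rgb_frames = []
    for k, hmap in enumerate(result.frames):
        rgba = (mapper(norm(hmap.heights[::-1])) * 255).astype(np.uint8)  # +y up
        rgb_frames.append(rgba[..., :3])
        path = os.path.join(os.fspath(outdir), f"{prefix}_{k:0{width}d}.png")
        import imageio.v3 as iio

        iio.imwrite(path, rgba)
        png_paths.append(path)

    gif_path = None
    if write_gif:
        import imageio.v3 as iio

        gif_path = os.path.join(os.fspath(outdir), f"{prefix}.gif")
        iio.imwrite(gif_path, rgb_frames, duration=1000.0 / fps, loop=0)

    return {"pngs": png_paths, "gif": gif_path, "zrange": (vmin, vmax)}
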