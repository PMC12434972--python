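"""Synthetic stand layout and 5-band reflectance scenes.

Stands in for the UAV orthomosaic: crown polygons are painted onto a
5-band raster (band order B, G, R, RE, NIR; float32 reflectance) over a
soil/ground background.  Three spatial damage patterns are supported:

``aggregated``
    severity decays outward from an aggregation centre — the outbreak
    geometry of a defoliator spreading from its point of origin
    (severe core, then moderate, mild, healthy rings);
``saltatory``
    aggregated plus a few isolated severe trees planted inside the
    healthy margin (wind-carried larvae ahead of the front);
``random``
    levels shuffled independently of position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import shapely
from pydantic import BaseModel, Field, model_validator
from shapely.geometry import Point

from pestspec.cohort import BAND_NAMES


class SceneConfig(BaseModel):
    """Geometry and noise of the synthetic scene."""

    extent: tuple[float, float] = (600.0, 300.0)  # width, height in metres
    resolution: float = Field(default=0.5, gt=0.0)  # m / pixel
    crown_radius_range: tuple[float, float] = (1.5, 3.0)
    pattern: Literal["aggregated", "random", "saltatory"] = "aggregated"
    aggregation_center: tuple[float, float] | None = None
    decay_scale: float = Field(default=80.0, gt=0.0)
    #: sd of the positional jitter applied to severity ranks, as a
    #: fraction of decay_scale; 0 gives perfectly concentric rings
    rank_jitter: float = Field(default=0.15, ge=0.0)
    n_outliers: int = Field(default=5, ge=0)  # saltatory planted severe trees
    background_spectrum: tuple[float, float, float, float, float] = (
        0.08,
        0.12,
        0.15,
        0.20,
        0.25,
    )
    pixel_noise_sd: float = Field(default=0.005, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.crown_radius_range[0] <= 0 or (
            self.crown_radius_range[1] < self.crown_radius_range[0]
        ):
            raise ValueError("invalid crown_radius_range")
        if any(not (0 <= v <= 1) for v in self.background_spectrum):
            raise ValueError("background_spectrum must lie in [0, 1]")
        return self

    @property
    def center(self) -> tuple[float, float]:
        if self.aggregation_center is not None:
            return self.aggregation_center
        return (self.extent[0] / 2.0, self.extent[1] / 2.0)


@dataclass
class Scene:
    """A rendered scene: raster, georeferencing, crown ROIs and truth table."""

    raster: np.ndarray  # (5, H, W) float32 reflectance
    resolution: float
    origin: tuple[float, float]  # (x, y) of the raster's top-left corner
    rois: list  # shapely Polygons, one per tree, cohort order
    trees: pd.DataFrame  # cohort with x, y, core/planted_outlier flags
    config: SceneConfig = field(repr=False, default=None)

    @property
    def band_names(self):
        return BAND_NAMES

    def pixel_centers(self):
        """(xs, ys) of pixel-centre coordinates; row 0 is the top row."""
        _, h, w = self.raster.shape
        x0, ytop = self.origin
        xs = x0 + (np.arange(w) + 0.5) * self.resolution
        ys = ytop - (np.arange(h) + 0.5) * self.resolution
        return xs, ys


def _layout_positions(n: int, config: SceneConfig, rng: np.random.Generator):
    """Jittered-grid crown centres: dense, non-overlapping, aperiodic."""
    w, h = config.extent
    rmax = config.crown_radius_range[1]
    ncols = int(np.ceil(np.sqrt(n * w / h)))
    nrows = int(np.ceil(n / ncols))
    while ncols * nrows < n:
        nrows += 1
    cw, ch = w / ncols, h / nrows
    if min(cw, ch) < 2 * rmax:
        raise ValueError("extent too small for the cohort's crowns")
    cells = [(i, j) for i in range(nrows) for j in range(ncols)]
    idx = rng.permutation(len(cells))[:n]
    xs = np.empty(n)
    ys = np.empty(n)
    for k, ci in enumerate(idx):
        i, j = cells[ci]
        mx = max(cw / 2 - rmax, 0.0)
        my = max(ch / 2 - rmax, 0.0)
        xs[k] = (j + 0.5) * cw + rng.uniform(-mx, mx)
        ys[k] = (i + 0.5) * ch + rng.uniform(-my, my)
    return xs, ys


def _assign_positions(levels: np.ndarray, xs, ys, config: SceneConfig, rng):
    """Map damage levels onto positions according to the spatial pattern.

    Returns (perm, core, outlier): ``perm[t]`` is the position index of
    cohort tree ``t``; ``core`` flags severe trees in the inner half of
    the severe ring; ``outlier`` flags planted saltatory severe trees.
    """
    n = len(levels)
    core = np.zeros(n, dtype=bool)
    outlier = np.zeros(n, dtype=bool)
    if config.pattern == "random":
        perm = rng.permutation(n)
        return perm, core, outlier
    cx, cy = config.center
    d = np.hypot(xs - cx, ys - cy)
    score = d + rng.normal(0.0, config.rank_jitter * config.decay_scale, size=n)
    pos_order = np.argsort(score, kind="stable")  # innermost first
    tree_order = np.argsort(-levels, kind="stable")  # severe first
    perm = np.empty(n, dtype=int)
    perm[tree_order] = pos_order
    severe = np.flatnonzero(levels == 4)
    if severe.size:
        dsev = d[perm[severe]]
        core[severe[dsev <= np.median(dsev)]] = True
    if config.pattern == "saltatory" and config.n_outliers > 0 and severe.size:
        healthy = np.flatnonzero(levels == 1)
        dh = d[perm[healthy]]
        margin = healthy[dh >= np.quantile(dh, 0.75)]
        k = min(config.n_outliers, margin.size, severe.size)
        # keep the planted trees mutually isolated
        chosen: list[int] = []
        cand = rng.permutation(margin)
        for t in cand:
            if len(chosen) == k:
                break
            p = perm[t]
            if all(
                np.hypot(xs[p] - xs[perm[c]], ys[p] - ys[perm[c]]) > 4 * config.decay_scale / 10
                for c in chosen
            ):
                chosen.append(t)
        dsev_all = d[perm[severe]]
        donors = severe[np.argsort(-dsev_all)][: len(chosen)]  # outermost severe
        for t, s in zip(chosen, donors):
            # severe tree s takes the margin position of healthy tree t
            perm[t], perm[s] = perm[s], perm[t]
            core[s] = False
            outlier[s] = True
    return perm, core, outlier


def generate_scene(
    cohort: pd.DataFrame,
    config: SceneConfig | None = None,
    seed: int | None = None,
    render_raster: bool = True,
) -> Scene:
    """Lay a cohort out in space and render the 5-band reflectance raster.

    Pixels whose centre falls inside a crown polygon carry that tree's
    spectrum plus truncated-normal pixel noise; all other pixels carry
    the background spectrum.  Overlapping-crown pixels go to the nearest
    crown centre.  ``render_raster=False`` skips rasterisation (layout
    and ROIs only), which is enough for purely spatial analyses.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(cohort)
    levels = cohort["damage_level"].to_numpy()
    xs, ys = _layout_positions(n, config, rng)
    perm, core, outlier = _assign_positions(levels, xs, ys, config, rng)
    tx, ty = xs[perm], ys[perm]
    radii = rng.uniform(*config.crown_radius_range, size=n)

    trees = cohort.copy().reset_index(drop=True)
    trees["x"] = tx
    trees["y"] = ty
    trees["crown_radius"] = radii
    trees["core"] = core
    trees["planted_outlier"] = outlier

    rois = [Point(x, y).buffer(r, quad_segs=16) for x, y, r in zip(tx, ty, radii)]

    w, h = config.extent
    res = config.resolution
    W = int(round(w / res))
    H = int(round(h / res))
    origin = (0.0, h)
    raster = None
    if render_raster:
        spectra = trees[list(BAND_NAMES)].to_numpy()
        raster = np.empty((5, H, W), dtype=np.float32)
        raster[:] = np.asarray(config.background_spectrum, dtype=np.float32)[
            :, None, None
        ]
        owner_dist = np.full((H, W), np.inf)
        pcx = (np.arange(W) + 0.5) * res
        pcy = h - (np.arange(H) + 0.5) * res
        for t, poly in enumerate(rois):
            minx, miny, maxx, maxy = poly.bounds
            j0 = max(int(np.floor(minx / res)) - 1, 0)
            j1 = min(int(np.ceil(maxx / res)) + 1, W)
            i0 = max(int(np.floor((h - maxy) / res)) - 1, 0)
            i1 = min(int(np.ceil((h - miny) / res)) + 1, H)
            if j0 >= j1 or i0 >= i1:
                continue
            gx, gy = np.meshgrid(pcx[j0:j1], pcy[i0:i1])
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(
                gx.shape
            )
            dist = np.hypot(gx - tx[t], gy - ty[t])
            sub = owner_dist[i0:i1, j0:j1]
            win = inside & (dist < sub)
            if not win.any():
                continue
            sub[win] = dist[win]
            vals = rng.normal(
                spectra[t][:, None], config.pixel_noise_sd, size=(5, int(win.sum()))
            )
            block = raster[:, i0:i1, j0:j1]
            block[:, win] = np.clip(vals, 0.0, 1.0).astype(np.float32)
    return Scene(
        raster=raster,
        resolution=res,
        origin=origin,
        rois=rois,
        trees=trees,
        config=config,
    )
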