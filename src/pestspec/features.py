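"""ROI-mean extraction and labeled feature tables.

A tree's spectral signature is the per-band arithmetic mean over the
pixels whose centres fall inside its crown polygon (pixel-centre
containment; simple and deterministic).  The feature table holds one
row per tree, one column per vegetation index, a CONV/RE family tag per
column, and the ordinal damage label per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from pestspec.cohort import BAND_NAMES
from pestspec.indices import CONV, RE, default_registry

log = logging.getLogger(__name__)


def extract_roi_means(raster, rois, resolution=1.0, origin=None, tree_ids=None):
    """Per-ROI 5-band mean reflectance over pixel-centre-contained pixels.

    Parameters mirror the scene convention: raster is (bands, H, W) with
    row 0 at the top, ``origin`` is the (x, y) of the top-left corner
    (default ``(0, H * resolution)``).  Empty ROIs (no pixel centre
    inside) produce a NaN row and a logged error record rather than
    aborting the run.

    Returns a DataFrame indexed by tree id with columns B, G, R, RE, NIR.
    """
    raster = np.asarray(raster)
    nb, H, W = raster.shape
    if origin is None:
        origin = (0.0, H * resolution)
    x0, ytop = origin
    if tree_ids is None:
        tree_ids = [str(i) for i in range(len(rois))]
    pcx = x0 + (np.arange(W) + 0.5) * resolution
    pcy = ytop - (np.arange(H) + 0.5) * resolution
    out = np.full((len(rois), nb), np.nan)
    errors = []
    for t, poly in enumerate(rois):
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(int(np.floor((minx - x0) / resolution)) - 1, 0)
        j1 = min(int(np.ceil((maxx - x0) / resolution)) + 1, W)
        i0 = max(int(np.floor((ytop - maxy) / resolution)) - 1, 0)
        i1 = min(int(np.ceil((ytop - miny) / resolution)) + 1, H)
        if j0 >= j1 or i0 >= i1:
            errors.append(tree_ids[t])
            continue
        gx, gy = np.meshgrid(pcx[j0:j1], pcy[i0:i1])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        if not inside.any():
            errors.append(tree_ids[t])
            continue
        block = raster[:, i0:i1, j0:j1].reshape(nb, -1)
        out[t] = block[:, inside].mean(axis=1)
    if errors:
        log.error("%d ROI(s) contained no pixel centre: %s", len(errors), errors)
    return pd.DataFrame(out, index=pd.Index(tree_ids, name="tree_id"), columns=BAND_NAMES)


@dataclass
class FeatureTable:
    """Trees x spectral features, with damage labels and family tags."""

    values: pd.DataFrame  # index: tree_id, columns: feature names
    labels: pd.Series  # damage level (1..4) aligned to values.index
    families: dict[str, str] = field(default_factory=dict)  # name -> CONV|RE

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"labels missing for trees: {missing[:5]}")
        if self.values.isna().any().any():
            raise ValueError("feature table must not contain missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, family: str | None = None, features=None) -> "FeatureTable":
        """Restrict to one family (``"CONV"``/``"RE"``) and/or named features."""
        cols = self.feature_names
        if family is not None and family.lower() != "all":
            fam = family.upper()
            if fam not in (CONV, RE):
                raise ValueError(f"unknown family {family!r}")
            cols = [c for c in cols if self.families.get(c) == fam]
        if features is not None:
            keep = set(features)
            cols = [c for c in cols if c in keep]
        return FeatureTable(
            self.values[cols].copy(),
            self.labels.copy(),
            {c: self.families.get(c, "") for c in cols},
        )

    def select_rows(self, ids) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[ids].copy(), self.labels.loc[ids].copy(), dict(self.families)
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "damage_level", self.labels)
        out.index.name = out.index.name or "tree_id"
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, families=None) -> "FeatureTable":
        labels = df["damage_level"].astype(int)
        values = df.drop(columns=["damage_level"])
        if families is None:
            reg = default_registry()
            families = {c: reg[c].family for c in values.columns if c in reg}
        return cls(values, labels, dict(families))

    @classmethod
    def from_csv(cls, path, families=None) -> "FeatureTable":
        df = pd.read_csv(path, index_col=0)
        df.index.name = "tree_id"
        return cls.from_frame(df, families)


def build_feature_table(
    spectra: pd.DataFrame,
    labels: pd.Series,
    registry=None,
    family: str = "all",
    na_policy: str = "drop",
) -> FeatureTable:
    """Evaluate the index bank on per-tree band means.

    ``spectra`` must have columns B, G, R, RE, NIR indexed by tree id.
    Not-computable cells (domain-guard violations) are handled per
    ``na_policy``: ``"drop"`` removes the affected rows (logged),
    ``"impute"`` fills with the column median.
    """
    registry = registry if registry is not None else default_registry()
    fam = family.upper()
    defs = [
        d
        for d in registry.values()
        if fam in ("ALL",) or d.family == fam
    ]
    labels = labels.reindex(spectra.index)
    if labels.isna().any():
        raise ValueError("labels must cover every tree in `spectra`")
    bands = [spectra[b].to_numpy(dtype=float) for b in BAND_NAMES]
    cols = {d.name: np.atleast_1d(d(*bands)) for d in defs}
    values = pd.DataFrame(cols, index=spectra.index)
    n_bad = int(values.isna().any(axis=1).sum())
    if n_bad:
        if na_policy == "drop":
            log.warning("dropping %d row(s) with not-computable index values", n_bad)
            keep = ~values.isna().any(axis=1)
            values = values.loc[keep]
            labels = labels.loc[keep]
        elif na_policy == "impute":
            log.warning("imputing %d row(s) with column medians", n_bad)
            values = values.fillna(values.median())
        else:
            raise ValueError(f"unknown na_policy {na_policy!r}")
    return FeatureTable(values, labels.astype(int), {d.name: d.family for d in defs})


def class_mean_differences(table: FeatureTable) -> pd.DataFrame:
    """Successive differences of class means, ordered healthy -> severe.

    For each feature returns the three signed differences
    (healthy - mild, mild - moderate, moderate - severe) and a
    ``consistent`` flag that is True iff all non-zero differences share
    one sign (an all-zero feature is consistent by convention).  A
    feature whose differences change sign responds weakly/ambiguously to
    damage progression.
    """
    levels = sorted(table.labels.unique())
    expected = [1, 2, 3, 4]
    missing = [l for l in expected if l not in levels]
    if missing:
        raise ValueError(f"class(es) missing from the table: {missing}")
    means = table.values.groupby(table.labels).mean().loc[expected]
    diffs = -means.diff().iloc[1:]  # row l holds mean(l-1) - mean(l)
    diffs.index = ["healthy-mild", "mild-moderate", "moderate-severe"]
    out = diffs.T
    signs = np.sign(out.to_numpy())
    consistent = []
    for row in signs:
        nz = row[row != 0]
        consistent.append(bool(len(nz) == 0 or np.all(nz == nz[0])))
    out["consistent"] = consistent
    return out
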