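"""Shared fixtures: one default-scale synthetic scene and feature table,
generated once per session, plus small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pestspec as ps


@pytest.fixture(scope="session")
def default_cohort():
    return ps.generate_cohort(ps.CohortConfig(), seed=101)


@pytest.fixture(scope="session")
def default_scene(default_cohort):
    return ps.generate_scene(default_cohort, ps.SceneConfig(), seed=202)


@pytest.fixture(scope="session")
def default_table(default_scene):
    scene = default_scene
    spectra = ps.extract_roi_means(
        scene.raster,
        scene.rois,
        resolution=scene.resolution,
        origin=scene.origin,
        tree_ids=scene.trees["tree_id"].tolist(),
    )
    labels = pd.Series(
        scene.trees["damage_level"].to_numpy(), index=spectra.index
    )
    return ps.build_feature_table(spectra, labels)


def make_table(values: np.ndarray, labels, names=None) -> ps.FeatureTable:
    """Small helper to wrap raw arrays in a FeatureTable."""
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    idx = [f"t{i}" for i in range(values.shape[0])]
    return ps.FeatureTable(
        pd.DataFrame(values, index=idx, columns=names),
        pd.Series(np.asarray(labels), index=idx),
        {},
    )


@pytest.fixture
def toy_separable():
    """Perfectly separable 2-feature, 4-class toy (disjoint boxes)."""
    rng = np.random.default_rng(0)
    n = 40
    X = []
    y = []
    centers = [(0, 0), (10, 0), (0, 10), (10, 10)]
    for level, (cx, cy) in enumerate(centers, start=1):
        X.append(np.column_stack([
            rng.uniform(cx - 1, cx + 1, n), rng.uniform(cy - 1, cy + 1, n)
        ]))
        y += [level] * n
    return make_table(np.vstack(X), y)
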