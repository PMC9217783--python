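"""Shared fixtures: a tiny hand-built annotation set and fast synthetic
parameter presets."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon

from stereopath.annotations import (
    AnnotationSet,
    LayerRegion,
    MarkerPoint,
    SectionTransform,
    SulcusAnnotation,
    Vessel,
)
from stereopath.stereology import SamplingDesign
from stereopath.synthetic import SyntheticParams

LAYER_ORDER = ("I", "II", "III", "IV-VI", "WM")


def rect(x0, y0, x1, y1) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def make_tiny_set(n_markers: int = 10) -> AnnotationSet:
    """Two sections of flat stacked layer bands, a slot sulcus, markers.

    Each section is a 4000 × 2500 µm stack: layer I on top (y in
    [-200, 0]), II [-450, -200], III [-900, -450], IV-VI [-2000, -900],
    WM [-2500, -2000].  The sulcus fundus sits mid-ribbon with mouths
    450 µm away (depth 450, sulcal radius 150 at the default third).
    """
    sections = ["sec1", "sec2"]
    bounds = [0.0, -200.0, -450.0, -900.0, -2000.0, -2500.0]
    layer_regions = []
    for sid in sections:
        for layer, top, bottom in zip(LAYER_ORDER, bounds[:-1], bounds[1:]):
            layer_regions.append(LayerRegion(sid, layer,
                                             rect(0, bottom, 4000, top)))
    markers = []
    rng = np.random.default_rng(1234)
    structures = ("neuropil_thread", "neuritic_thread_cluster", "neuron")
    for i in range(n_markers):
        markers.append(
            MarkerPoint(
                float(rng.uniform(10, 3990)),
                float(rng.uniform(-1990, -10)),
                sections[i % 2],
                structures[i % 3],
            )
        )
    vessels = [
        Vessel(1000.0, -500.0, "sec1", 60.0),
        Vessel(3000.0, -1500.0, "sec1", 25.0),
        Vessel(2000.0, -800.0, "sec2", 45.0),
    ]
    sulci = [
        SulcusAnnotation(sid, fundus=(2000.0, -100.0),
                         mouth_a=(1550.0, -100.0), mouth_b=(2450.0, -100.0))
        for sid in sections
    ]
    return AnnotationSet(
        subject_id="tiny",
        region="prefrontal",
        sections=sections,
        layer_regions=layer_regions,
        markers=markers,
        vessels=vessels,
        sulci=sulci,
        transforms={sid: SectionTransform.identity(sid) for sid in sections},
        design=SamplingDesign(),
    )


@pytest.fixture
def tiny_set() -> AnnotationSet:
    return make_tiny_set()


@pytest.fixture
def fast_params() -> SyntheticParams:
    """Scaled-down generator settings for quick tests."""
    return SyntheticParams(
        lambda0=60.0,
        n_sections=3,
        ribbon_length=4000.0,
        seed=2024,
    )


def pip_even_odd(poly: Polygon, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Brute-force even–odd (crossing number) point-in-polygon oracle.

    Counts boundary-crossing parity of a horizontal ray for the exterior
    ring and subtracts hole parities.  Independent of shapely's
    predicates; agrees with boundary-inclusive containment except on the
    measure-zero boundary itself.
    """
    def ring_parity(coords, xs, ys):
        inside = np.zeros(len(xs), dtype=bool)
        pts = np.asarray(coords)
        n = len(pts) - 1  # closed ring
        for i in range(n):
            x1, y1 = pts[i]
            x2, y2 = pts[i + 1]
            cond = (y1 > ys) != (y2 > ys)
            with np.errstate(divide="ignore", invalid="ignore"):
                xin = (x2 - x1) * (ys - y1) / (y2 - y1) + x1
            inside ^= cond & (xs < xin)
        return inside

    res = ring_parity(poly.exterior.coords, xs, ys)
    for hole in poly.interiors:
        res ^= ring_parity(hole.coords, xs, ys)
    return res
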