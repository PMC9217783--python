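"""Synthetic annotation-set generator with known ground truth.

Emulates the statistical structure of tau-pathology annotation exports
from serially sectioned gyrencephalic cortex: a layered cortical ribbon
folded into a single deep sulcus, marker intensity decaying
geometrically with laminar depth, enrichment in the sulcal depth (the
bottom third of the sulcus), near-absence in white matter, and a
fraction of markers clustered around blood vessels.  Every generated
set passes :func:`~stereopath.annotations.validate_annotation_set` and
carries a :class:`GroundTruth` record for parameter-recovery tests.

The marker process is an inhomogeneous Poisson process with intensity

    λ(layer, position) = λ0 · α^(layer index) · (1 + β · 1[sulcal depth])

(white matter uses wm_factor · λ0), realised as superposition of a
per-layer homogeneous process and an independent "extra" process at
rate β·λ restricted to the fundus-centred sulcal disc — identical in
law to (1+β)-thinning.  A ``perivascular_fraction`` of markers is then
relocated to Gaussian offsets around uniformly chosen vessels, which
preserves the total intensity exactly.

Geometry note: the default sulcus is deep and narrow relative to the
cortical thickness, so the sulcal-depth disc crosses the full layer
stack on the sulcal walls and samples the layers in close to their
global area proportions.  Under that geometry the realised sulcal/gyral
density ratio is (1+β) to within ~1% and the per-layer decay stays
within ~5% of α even with enrichment switched on; a shallow wide sulcus
would confound the two (the disc would oversample superficial layers).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .annotations import (
    CORTICAL_LAYERS,
    LAYERS,
    STRUCTURES,
    AnnotationSet,
    LayerRegion,
    MarkerPoint,
    SectionTransform,
    SulcusAnnotation,
    Vessel,
    write_annotation_set,
)
from .stereology import SamplingDesign

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "SectionGeometry",
    "CortexGeometry",
    "make_cortex_geometry",
    "sample_vessels",
    "sample_markers",
    "generate_annotation_set",
    "generate_bundle",
]

MM2_PER_UM2 = 1.0e-6


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth intensity model and geometry of a synthetic subject.

    Rates are per mm² of section area.  ``lambda0`` is the base marker
    intensity in layer I; each deeper cortical layer is multiplied by
    ``depth_decay`` (α), white matter uses ``wm_factor`` × λ0, and the
    sulcal depth region is enriched by the factor (1 + sulcal_enrichment).
    Vessel diameters are log-normal with log-scale parameters
    (vessel_diameter_mu, vessel_diameter_sigma), in log-µm, chosen so a
    sizeable share of vessels falls below the 30 µm eligibility cut.
    """

    lambda0: float = 200.0
    depth_decay: float = 0.6
    wm_factor: float = 0.02
    sulcal_enrichment: float = 2.0
    vessel_density: float = 8.0
    vessel_diameter_mu: float = 3.5
    vessel_diameter_sigma: float = 0.45
    perivascular_fraction: float = 0.2
    cluster_sd: float = 30.0
    n_sections: int = 10
    seed: int = 0
    # geometry (µm)
    ribbon_length: float = 8000.0
    layer_thicknesses: tuple[float, float, float, float] = (150.0, 200.0,
                                                           350.0, 700.0)
    wm_thickness: float = 600.0
    sulcus_amplitude: float = 2400.0
    sulcus_width: float = 500.0
    section_wobble: float = 0.05
    structure_probs: tuple[float, float, float] = (0.85, 0.12, 0.03)
    subject_id: str = "synthetic"
    region: str = "prefrontal"

    def validate(self) -> None:
        if self.lambda0 < 0 or self.vessel_density < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 < self.depth_decay <= 1.0):
            raise ValueError("depth_decay must be in (0, 1]")
        if self.wm_factor < 0 or self.wm_factor > min(
            self.depth_decay ** i for i in range(4)
        ):
            raise ValueError(
                "wm_factor must be non-negative and below the cortical "
                "depth-profile minimum"
            )
        if self.sulcal_enrichment < 0:
            raise ValueError("sulcal_enrichment must be non-negative")
        if not (0.0 <= self.perivascular_fraction <= 1.0):
            raise ValueError("perivascular_fraction must be in [0, 1]")
        if self.n_sections < 1:
            raise ValueError("n_sections must be at least 1")
        if any(t <= 0 for t in self.layer_thicknesses) or \
                self.wm_thickness <= 0:
            raise ValueError("band thicknesses must be positive")
        if abs(sum(self.structure_probs) - 1.0) > 1e-9:
            raise ValueError("structure_probs must sum to 1")

    @property
    def cortex_thickness(self) -> float:
        return float(sum(self.layer_thicknesses))

    def layer_intensity(self, layer: str) -> float:
        """Base (gyral) intensity of a layer, markers per mm²."""
        if layer == "WM":
            return self.wm_factor * self.lambda0
        idx = CORTICAL_LAYERS.index(layer)
        return self.lambda0 * self.depth_decay ** idx


@dataclass
class GroundTruth:
    """Realised and expected quantities of one synthetic annotation set.

    Counts are the generator's own (curve-based) assignments, computed
    independently of the polygon-based analysis path, so they can serve
    as an oracle for it.
    """

    seed: int
    layer_counts: dict[str, int]
    layer_section_counts: dict[str, list[int]]
    layer_areas_um2: dict[str, float]
    expected_layer_intensity: dict[str, float]
    sulcal_count: int
    gyral_count: int
    sulcal_area_um2: float
    gyral_area_um2: float
    expected_sulcal_gyral_ratio: float
    n_vessels_eligible: int
    n_vessels_associated: int
    vessel_association_rate: float | None
    n_markers: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# Geometry

_CURVE_STEP = 10.0  # µm polygonisation step along the ribbon


@dataclass
class SectionGeometry:
    """Analytic description of one section's folded cortical ribbon."""

    section_id: str
    length: float
    amplitude: float
    width: float
    cum_depths: tuple[float, ...]  # layer boundaries, 0 .. cortex+wm
    wm_thickness: float

    @property
    def centre(self) -> float:
        return self.length / 2.0

    def pial(self, x):
        """Pial surface height at x (0 at the flat gyral crown)."""
        if self.amplitude == 0.0:
            return np.zeros_like(np.asarray(x, dtype=float)) \
                if np.ndim(x) else 0.0
        return -self.amplitude * np.exp(
            -((np.asarray(x, dtype=float) - self.centre) ** 2)
            / (2.0 * self.width ** 2)
        )

    def band_polygon(self, top_depth: float, bottom_depth: float) -> Polygon:
        xs = np.arange(0.0, self.length + _CURVE_STEP / 2, _CURVE_STEP)
        xs[-1] = self.length
        p = self.pial(xs)
        top = np.column_stack([xs, p - top_depth])
        bottom = np.column_stack([xs[::-1], p[::-1] - bottom_depth])
        return Polygon(np.vstack([top, bottom]))

    def layer_of(self, x: float, y: float) -> str | None:
        """Band label of a point from the analytic curve (oracle path)."""
        depth = float(self.pial(x)) - y
        if depth < 0:
            return None
        for i in range(4):
            if depth < self.cum_depths[i + 1]:
                return LAYERS[i]
        if depth < self.cum_depths[4] + self.wm_thickness:
            return "WM"
        return None

    def sulcus(self) -> SulcusAnnotation | None:
        if self.amplitude == 0.0:
            return None
        mx = 2.0 * self.width
        fundus = (self.centre, float(self.pial(self.centre)))
        mouth_a = (self.centre - mx, float(self.pial(self.centre - mx)))
        mouth_b = (self.centre + mx, float(self.pial(self.centre + mx)))
        return SulcusAnnotation(self.section_id, fundus, mouth_a, mouth_b)


@dataclass
class CortexGeometry:
    sections: list[SectionGeometry]
    layer_regions: list[LayerRegion]
    sulci: list[SulcusAnnotation]

    def section(self, section_id: str) -> SectionGeometry:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def layer_area_um2(self, layer: str) -> float:
        """Exact band area summed over sections (thickness × length)."""
        idx = LAYERS.index(layer)
        total = 0.0
        for s in self.sections:
            if layer == "WM":
                t = s.wm_thickness
            else:
                t = s.cum_depths[idx + 1] - s.cum_depths[idx]
            total += t * s.length
        return total


def make_cortex_geometry(params: SyntheticParams) -> CortexGeometry:
    """Build the per-section layer polygons and sulcus landmarks.

    The ribbon is a Gaussian-valley fold; layer bands are vertical
    offsets of the pial curve, so band areas are exactly thickness ×
    ribbon length and the bands tile the ribbon without overlap.  Shape
    varies smoothly across the serial series via a small sinusoidal
    modulation of the fold amplitude and width.  A flat ribbon
    (sulcus_amplitude = 0) carries no sulcus annotation.
    """
    params.validate()
    cortex_t = params.cortex_thickness
    if params.sulcus_amplitude > 0 and \
            params.sulcus_amplitude < cortex_t / 4:
        raise ValueError(
            "sulcus_amplitude too small relative to the cortical thickness "
            "to form a resolvable fold; use 0 for a flat ribbon"
        )
    cum = (0.0,) + tuple(np.cumsum(params.layer_thicknesses))
    sections: list[SectionGeometry] = []
    layer_regions: list[LayerRegion] = []
    sulci: list[SulcusAnnotation] = []
    n = params.n_sections
    for k in range(n):
        phase = 2.0 * math.pi * k / max(n, 2)
        amp = params.sulcus_amplitude * (
            1.0 + params.section_wobble * math.sin(phase)
        )
        width = params.sulcus_width * (
            1.0 + params.section_wobble * math.cos(phase)
        )
        sid = f"s{k:02d}"
        geom = SectionGeometry(
            section_id=sid,
            length=params.ribbon_length,
            amplitude=amp if params.sulcus_amplitude > 0 else 0.0,
            width=width,
            cum_depths=cum,
            wm_thickness=params.wm_thickness,
        )
        sections.append(geom)
        for i, layer in enumerate(CORTICAL_LAYERS):
            layer_regions.append(
                LayerRegion(sid, layer, geom.band_polygon(cum[i], cum[i + 1]))
            )
        layer_regions.append(
            LayerRegion(sid, "WM",
                        geom.band_polygon(cum[4],
                                          cum[4] + params.wm_thickness))
        )
        s = geom.sulcus()
        if s is not None:
            sulci.append(s)
    return CortexGeometry(sections, layer_regions, sulci)


# ---------------------------------------------------------------------------
# Sampling


def _substreams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def _sample_in_band(
    geom: SectionGeometry,
    top_depth: float,
    bottom_depth: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform points in a vertical-offset band (exact, no rejection)."""
    x = rng.uniform(0.0, geom.length, n)
    depth = rng.uniform(top_depth, bottom_depth, n)
    y = geom.pial(x) - depth
    return np.column_stack([x, y])


def sample_vessels(
    geometry: CortexGeometry,
    params: SyntheticParams,
    rng: np.random.Generator | None = None,
) -> list[Vessel]:
    """Homogeneous Poisson vessel centres in the cortical ribbon.

    Diameters are log-normal; with the default parameters a sizeable
    share falls below the 30 µm analysis cut, so eligibility filtering
    is exercised downstream.
    """
    params.validate()
    if rng is None:
        rng = _substreams(params.seed)[1]
    cortex_t = params.cortex_thickness
    vessels: list[Vessel] = []
    for geom in geometry.sections:
        area_mm2 = geom.length * cortex_t * MM2_PER_UM2
        n = rng.poisson(params.vessel_density * area_mm2)
        pts = _sample_in_band(geom, 0.0, cortex_t, n, rng)
        diams = np.exp(rng.normal(params.vessel_diameter_mu,
                                  params.vessel_diameter_sigma, n))
        for (x, y), d in zip(pts, diams):
            vessels.append(Vessel(float(x), float(y), geom.section_id,
                                  float(d)))
    return vessels


def _sulcal_radius(geom: SectionGeometry,
                   depth_fraction: float) -> tuple[float, tuple[float, float]]:
    s = geom.sulcus()
    if s is None:
        return 0.0, (geom.centre, 0.0)
    return depth_fraction * s.depth(), s.fundus


def sample_markers(
    geometry: CortexGeometry,
    params: SyntheticParams,
    vessels: Sequence[Vessel] | None = None,
    rng: np.random.Generator | None = None,
    depth_fraction: float = 1.0 / 3.0,
) -> tuple[list[MarkerPoint], GroundTruth]:
    """Draw markers from the layered, sulcus-enriched Poisson model.

    Returns the markers plus the ground truth (realised per-layer and
    sulcal/gyral counts via the generator's analytic band test, expected
    intensities, and the realised vessel-association rate).
    """
    params.validate()
    if rng is None:
        rng = _substreams(params.seed)[2]
    if params.perivascular_fraction > 0 and not vessels:
        raise ValueError(
            "perivascular_fraction > 0 requires a vessel field; "
            "sample vessels first"
        )
    beta = params.sulcal_enrichment

    xs_all: list[np.ndarray] = []
    sids_all: list[str] = []
    for geom in geometry.sections:
        radius, fundus = _sulcal_radius(geom, depth_fraction)
        bands = [(layer,
                  geom.cum_depths[i], geom.cum_depths[i + 1])
                 for i, layer in enumerate(CORTICAL_LAYERS)]
        bands.append(("WM", geom.cum_depths[4],
                      geom.cum_depths[4] + geom.wm_thickness))
        for layer, top, bottom in bands:
            lam = params.layer_intensity(layer)
            area_mm2 = (bottom - top) * geom.length * MM2_PER_UM2
            n_base = rng.poisson(lam * area_mm2)
            pts = _sample_in_band(geom, top, bottom, n_base, rng)
            if beta > 0 and radius > 0:
                n_cand = rng.poisson(beta * lam * area_mm2)
                cand = _sample_in_band(geom, top, bottom, n_cand, rng)
                d = np.hypot(cand[:, 0] - fundus[0], cand[:, 1] - fundus[1])
                pts = np.vstack([pts, cand[d <= radius]])
            if len(pts):
                xs_all.append(pts)
                sids_all.append(geom.section_id)
                # parallel arrays by chunk; flatten below

    chunks = xs_all
    chunk_sids = sids_all
    all_xy = np.vstack(chunks) if chunks else np.empty((0, 2))
    all_sid = np.concatenate(
        [np.full(len(c), sid) for c, sid in zip(chunks, chunk_sids)]
    ) if chunks else np.empty(0, dtype=str)
    n_total = len(all_xy)

    # perivascular relocation: Bernoulli(p) subset moved to Gaussian
    # offsets around a uniformly chosen vessel on the same section
    if params.perivascular_fraction > 0 and n_total:
        vessels_by_sid: dict[str, list[Vessel]] = {}
        for v in vessels or []:
            vessels_by_sid.setdefault(v.section_id, []).append(v)
        relocate = rng.random(n_total) < params.perivascular_fraction
        for i in np.flatnonzero(relocate):
            vs = vessels_by_sid.get(str(all_sid[i]))
            if not vs:
                continue
            v = vs[rng.integers(0, len(vs))]
            all_xy[i, 0] = v.x + rng.normal(0.0, params.cluster_sd)
            all_xy[i, 1] = v.y + rng.normal(0.0, params.cluster_sd)

    structures = np.array(STRUCTURES)[
        rng.choice(3, size=n_total, p=params.structure_probs)
    ] if n_total else np.empty(0, dtype=str)

    markers = [
        MarkerPoint(float(x), float(y), str(sid), str(st))
        for (x, y), sid, st in zip(all_xy, all_sid, structures)
    ]

    truth = _ground_truth(geometry, params, markers, vessels or [],
                          depth_fraction)
    return markers, truth


def _ground_truth(
    geometry: CortexGeometry,
    params: SyntheticParams,
    markers: Sequence[MarkerPoint],
    vessels: Sequence[Vessel],
    depth_fraction: float,
) -> GroundTruth:
    layer_section_counts = {layer: [0] * len(geometry.sections)
                            for layer in LAYERS}
    sulcal = gyral = 0
    sulcal_area = 0.0
    cortex_area = 0.0
    sec_index = {g.section_id: i for i, g in enumerate(geometry.sections)}
    radii = {}
    for geom in geometry.sections:
        radius, fundus = _sulcal_radius(geom, depth_fraction)
        radii[geom.section_id] = (radius, fundus)
        cortex_area += geom.length * params.cortex_thickness
        if radius > 0:
            cortex = geom.band_polygon(0.0, params.cortex_thickness)
            disc = Point(*fundus).buffer(radius, quad_segs=128)
            sulcal_area += cortex.intersection(disc).area

    for m in markers:
        geom = geometry.section(m.section_id)
        layer = geom.layer_of(m.x, m.y)
        if layer is not None:
            layer_section_counts[layer][sec_index[m.section_id]] += 1
        if layer in CORTICAL_LAYERS:
            radius, fundus = radii[m.section_id]
            d = math.hypot(m.x - fundus[0], m.y - fundus[1])
            if radius > 0 and d <= radius:
                sulcal += 1
            else:
                gyral += 1

    # sulcal-disc intersection area per layer band, summed over sections
    beta = params.sulcal_enrichment
    p = params.perivascular_fraction
    inter_area = {layer: 0.0 for layer in LAYERS}
    if any(r > 0 for r, _ in radii.values()):
        for i, layer in enumerate(LAYERS):
            for geom in geometry.sections:
                radius, fundus = radii[geom.section_id]
                if radius <= 0:
                    continue
                if layer == "WM":
                    top, bottom = (geom.cum_depths[4],
                                   geom.cum_depths[4] + geom.wm_thickness)
                else:
                    top, bottom = geom.cum_depths[i], geom.cum_depths[i + 1]
                band = geom.band_polygon(top, bottom)
                disc = Point(*fundus).buffer(radius, quad_segs=128)
                inter_area[layer] += band.intersection(disc).area

    # total expected marker intensity (for the relocation component);
    # relocated markers land around uniformly chosen vessels, i.e.
    # approximately uniformly over the cortex at rate p * total / area
    lam_total = sum(
        params.layer_intensity(layer)
        * (geometry.layer_area_um2(layer) + beta * inter_area[layer])
        for layer in LAYERS
    )
    rho = p * lam_total / cortex_area if cortex_area > 0 else 0.0

    # expected intensity per layer: the layered-and-enriched process thinned
    # by (1-p), plus the flat relocation component (cortical layers only;
    # clusters sit around vessels, which are confined to the cortex)
    expected_intensity = {}
    for layer in LAYERS:
        band_area = geometry.layer_area_um2(layer)
        frac = inter_area[layer] / band_area if band_area > 0 else 0.0
        lam_eff = (1.0 - p) * params.layer_intensity(layer) * (
            1.0 + beta * frac
        )
        if layer != "WM":
            lam_eff += rho
        expected_intensity[layer] = lam_eff

    # expected sulcal/gyral density ratio under the realised geometry:
    # (1+beta) distorted by the disc's layer mix and the relocation flat
    mean_sulc = 0.0
    if sulcal_area > 0:
        mean_sulc = sum(
            params.layer_intensity(layer) * inter_area[layer]
            for layer in CORTICAL_LAYERS
        ) / sulcal_area
    gyral_area = cortex_area - sulcal_area
    num_gyr = sum(
        params.layer_intensity(layer) * geometry.layer_area_um2(layer)
        for layer in CORTICAL_LAYERS
    ) - mean_sulc * sulcal_area
    mean_gyr = num_gyr / gyral_area if gyral_area > 0 else 0.0
    if mean_gyr > 0 and sulcal_area > 0:
        expected_ratio = (
            ((1.0 - p) * (1.0 + beta) * mean_sulc + rho)
            / ((1.0 - p) * mean_gyr + rho)
        )
    else:
        expected_ratio = float("nan")

    # realised vessel association (brute force, generator side)
    elig = [v for v in vessels if v.diameter > 30.0]
    n_assoc = 0
    mk_by_sid: dict[str, list[MarkerPoint]] = {}
    for m in markers:
        mk_by_sid.setdefault(m.section_id, []).append(m)
    for v in elig:
        best = math.inf
        for m in mk_by_sid.get(v.section_id, []):
            d = math.hypot(m.x - v.x, m.y - v.y) - v.diameter / 2.0
            best = min(best, max(0.0, d))
        if best <= 100.0:
            n_assoc += 1

    return GroundTruth(
        seed=params.seed,
        layer_counts={l: sum(c) for l, c in layer_section_counts.items()},
        layer_section_counts=layer_section_counts,
        layer_areas_um2={l: geometry.layer_area_um2(l) for l in LAYERS},
        expected_layer_intensity=expected_intensity,
        sulcal_count=sulcal,
        gyral_count=gyral,
        sulcal_area_um2=sulcal_area,
        gyral_area_um2=gyral_area,
        expected_sulcal_gyral_ratio=expected_ratio,
        n_vessels_eligible=len(elig),
        n_vessels_associated=n_assoc,
        vessel_association_rate=(100.0 * n_assoc / len(elig)
                                 if elig else None),
        n_markers=len(markers),
    )


# ---------------------------------------------------------------------------
# Bundles


def generate_annotation_set(
    params: SyntheticParams,
    design: SamplingDesign | None = None,
) -> tuple[AnnotationSet, GroundTruth]:
    """Generate a complete synthetic annotation set with ground truth.

    Uses a single master seed with deterministic substreams for
    geometry, vessels and markers; identity alignment transforms.
    """
    params.validate()
    _, rng_vessels, rng_markers = _substreams(params.seed)
    geometry = make_cortex_geometry(params)
    vessels = sample_vessels(geometry, params, rng_vessels)
    markers, truth = sample_markers(geometry, params, vessels, rng_markers)
    sections = [g.section_id for g in geometry.sections]
    aset = AnnotationSet(
        subject_id=params.subject_id,
        region=params.region,
        sections=sections,
        layer_regions=geometry.layer_regions,
        markers=markers,
        vessels=vessels,
        sulci=geometry.sulci,
        transforms={sid: SectionTransform.identity(sid) for sid in sections},
        design=design or SamplingDesign(),
    )
    return aset, truth


def generate_bundle(
    params: SyntheticParams,
    out_dir: str | Path,
    design: SamplingDesign | None = None,
) -> tuple[AnnotationSet, GroundTruth]:
    """Write a synthetic bundle (GeoJSON + CSVs + config + ground truth)."""
    aset, truth = generate_annotation_set(params, design)
    out = write_annotation_set(aset, out_dir)
    truth.to_json(Path(out) / "ground_truth.json")
    return aset, truth
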