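"""Data model and I/O for microscope-style annotation exports.

An :class:`AnnotationSet` bundles, for one subject and brain region, the
per-section annotations a stereology workstation exports after manual
marking: layer contour polygons (cortical layers I, II, III, IV–VI and
white matter), typed marker points (tau-immunoreactive neuropil threads,
neuritic thread clusters, neurons), blood vessels (centre + diameter),
sulcus landmarks (fundus and the two sulcal mouths), per-section affine
alignment transforms, and the fractionator sampling design.

On disk a set is a plain-text bundle: a GeoJSON FeatureCollection for
geometry, CSV tables for markers / vessels / transforms, and a YAML
config naming the subject, region, serial section order and design
constants.  All coordinates and lengths are micrometres.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.geometry.polygon import orient

from .stereology import SamplingDesign

__all__ = [
    "STRUCTURES",
    "LAYERS",
    "CORTICAL_LAYERS",
    "REGIONS",
    "AnnotationError",
    "MarkerPoint",
    "LayerRegion",
    "Vessel",
    "SulcusAnnotation",
    "SectionTransform",
    "AnnotationSet",
    "Finding",
    "ValidationReport",
    "load_annotation_set",
    "write_annotation_set",
    "validate_annotation_set",
    "apply_alignment",
]

STRUCTURES = ("neuropil_thread", "neuritic_thread_cluster", "neuron")
LAYERS = ("I", "II", "III", "IV-VI", "WM")
CORTICAL_LAYERS = ("I", "II", "III", "IV-VI")
REGIONS = ("prefrontal", "parietal")

DEFAULT_SULCAL_DEPTH_FRACTION = 1.0 / 3.0


class AnnotationError(ValueError):
    """Raised for structurally unusable annotation input."""


@dataclass(frozen=True)
class MarkerPoint:
    """A typed pathology marker placed on one section, coordinates in µm."""

    x: float
    y: float
    section_id: str
    structure: str

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise AnnotationError(
                f"unknown marker structure {self.structure!r}; "
                f"expected one of {STRUCTURES}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise AnnotationError(
                f"non-finite marker coordinates ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class LayerRegion:
    """A contoured layer polygon on one section.

    The polygon is stored as a shapely ring (holes allowed, e.g. for
    structures enclosed by white matter); winding order is normalised to
    counter-clockwise exteriors on load.
    """

    section_id: str
    layer: str
    polygon: Polygon

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise AnnotationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )


@dataclass(frozen=True)
class Vessel:
    """A blood-vessel profile: centre coordinates and diameter, in µm."""

    x: float
    y: float
    section_id: str
    diameter: float


@dataclass(frozen=True)
class SulcusAnnotation:
    """Landmarks of one sulcus: fundus (deepest point) and the two mouths.

    ``depth_fraction`` delimits the sulcal depth region as that fraction
    of the fundus-to-mouth distance; the conventional choice is the
    bottom third of the sulcus (1/3).
    """

    section_id: str
    fundus: tuple[float, float]
    mouth_a: tuple[float, float]
    mouth_b: tuple[float, float]
    depth_fraction: float = DEFAULT_SULCAL_DEPTH_FRACTION

    def depth(self) -> float:
        """Mean Euclidean fundus-to-mouth distance, µm."""
        da = math.dist(self.fundus, self.mouth_a)
        db = math.dist(self.fundus, self.mouth_b)
        return 0.5 * (da + db)


@dataclass(frozen=True)
class SectionTransform:
    """Planar affine alignment for one section.

    ``affine`` holds six coefficients (a, b, c, d, tx, ty) mapping
    (x, y) -> (a·x + b·y + tx, c·x + d·y + ty), µm to µm.
    """

    section_id: str
    affine: tuple[float, float, float, float, float, float]

    @classmethod
    def identity(cls, section_id: str) -> "SectionTransform":
        return cls(section_id, (1.0, 0.0, 0.0, 1.0, 0.0, 0.0))

    @property
    def det(self) -> float:
        a, b, c, d, _, _ = self.affine
        return a * d - b * c

    @property
    def is_identity(self) -> bool:
        return self.affine == (1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    def apply_xy(self, x, y):
        a, b, c, d, tx, ty = self.affine
        return a * x + b * y + tx, c * x + d * y + ty

    def apply_polygon(self, poly: Polygon) -> Polygon:
        from shapely import affinity

        a, b, c, d, tx, ty = self.affine
        return affinity.affine_transform(poly, [a, b, c, d, tx, ty])

    def length_scale(self) -> float:
        """Isotropic length rescaling factor, sqrt(|det|)."""
        return math.sqrt(abs(self.det))


@dataclass
class AnnotationSet:
    """All annotations for one subject and brain region."""

    subject_id: str
    region: str
    sections: list[str]
    layer_regions: list[LayerRegion] = field(default_factory=list)
    markers: list[MarkerPoint] = field(default_factory=list)
    vessels: list[Vessel] = field(default_factory=list)
    sulci: list[SulcusAnnotation] = field(default_factory=list)
    transforms: dict[str, SectionTransform] = field(default_factory=dict)
    design: SamplingDesign = field(default_factory=SamplingDesign)

    def markers_on(self, section_id: str) -> list[MarkerPoint]:
        return [m for m in self.markers if m.section_id == section_id]

    def vessels_on(self, section_id: str) -> list[Vessel]:
        return [v for v in self.vessels if v.section_id == section_id]

    def layers_on(self, section_id: str) -> list[LayerRegion]:
        return [r for r in self.layer_regions if r.section_id == section_id]

    def sulcus_on(self, section_id: str) -> SulcusAnnotation | None:
        for s in self.sulci:
            if s.section_id == section_id:
                return s
        return None


@dataclass(frozen=True)
class Finding:
    code: str
    message: str
    offending_id: str


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def sort(self) -> "ValidationReport":
        key = lambda f: (f.code, f.offending_id, f.message)
        self.errors.sort(key=key)
        self.warnings.sort(key=key)
        return self


# ---------------------------------------------------------------------------
# I/O

_GEOMETRY_FILE = "geometry.geojson"
_MARKERS_FILE = "markers.csv"
_VESSELS_FILE = "vessels.csv"
_TRANSFORMS_FILE = "transforms.csv"
_CONFIG_FILE = "config.yaml"


def _normalise_polygon(poly: Polygon) -> Polygon:
    # CCW exterior, CW holes; drops duplicate closing ambiguity
    return orient(poly, sign=1.0)


def load_annotation_set(
    bundle_dir: str | Path,
    *,
    geometry_path: str | Path | None = None,
    markers_path: str | Path | None = None,
    vessels_path: str | Path | None = None,
    transforms_path: str | Path | None = None,
    config_path: str | Path | None = None,
) -> AnnotationSet:
    """Load an annotation bundle from disk.

    ``bundle_dir`` is a directory holding the standard file names
    (geometry.geojson, markers.csv, vessels.csv, transforms.csv,
    config.yaml); any of them can be overridden by keyword.  Rows whose
    structure label or section reference cannot be interpreted raise
    :class:`AnnotationError` naming the offending row.
    """
    bundle = Path(bundle_dir)
    geometry_path = Path(geometry_path or bundle / _GEOMETRY_FILE)
    markers_path = Path(markers_path or bundle / _MARKERS_FILE)
    vessels_path = Path(vessels_path or bundle / _VESSELS_FILE)
    transforms_path = Path(transforms_path or bundle / _TRANSFORMS_FILE)
    config_path = Path(config_path or bundle / _CONFIG_FILE)

    for p in (geometry_path, config_path):
        if not p.exists():
            raise FileNotFoundError(p)

    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    subject_id = str(cfg.get("subject_id", "unknown"))
    region = str(cfg.get("region", "prefrontal"))
    sections = [str(s) for s in cfg.get("sections", [])]
    design = SamplingDesign(**(cfg.get("design") or {}))
    known = set(sections)

    with open(geometry_path) as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise AnnotationError(
            f"{geometry_path}: expected a GeoJSON FeatureCollection"
        )

    layer_regions: list[LayerRegion] = []
    sulci: list[SulcusAnnotation] = []
    for i, feat in enumerate(collection.get("features", [])):
        props = feat.get("properties") or {}
        role = props.get("role")
        sid = str(props.get("section_id"))
        if sid not in known:
            raise AnnotationError(
                f"geometry feature {i} references unknown section {sid!r}"
            )
        if role == "layer":
            geom = shape(feat["geometry"])
            if geom.geom_type != "Polygon":
                raise AnnotationError(
                    f"geometry feature {i}: layer geometry must be a "
                    f"Polygon, got {geom.geom_type}"
                )
            layer_regions.append(
                LayerRegion(sid, str(props.get("layer")),
                            _normalise_polygon(geom))
            )
        elif role == "sulcus":
            geom = shape(feat["geometry"])
            coords = [tuple(map(float, p.coords[0])) for p in geom.geoms] \
                if geom.geom_type == "MultiPoint" else None
            if not coords or len(coords) != 3:
                raise AnnotationError(
                    f"geometry feature {i}: sulcus must be a MultiPoint of "
                    "(fundus, mouth_a, mouth_b)"
                )
            sulci.append(
                SulcusAnnotation(
                    sid, coords[0], coords[1], coords[2],
                    float(props.get("depth_fraction",
                                    DEFAULT_SULCAL_DEPTH_FRACTION)),
                )
            )
        else:
            raise AnnotationError(
                f"geometry feature {i}: unknown role {role!r}"
            )

    markers: list[MarkerPoint] = []
    if markers_path.exists():
        with open(markers_path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                sid = str(row["section_id"])
                if sid not in known:
                    raise AnnotationError(
                        f"{markers_path.name} row {i + 1}: unknown section "
                        f"{sid!r}"
                    )
                try:
                    markers.append(
                        MarkerPoint(float(row["x"]), float(row["y"]), sid,
                                    row["structure"].strip())
                    )
                except AnnotationError as exc:
                    raise AnnotationError(
                        f"{markers_path.name} row {i + 1}: {exc}"
                    ) from exc

    vessels: list[Vessel] = []
    if vessels_path.exists():
        with open(vessels_path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                sid = str(row["section_id"])
                if sid not in known:
                    raise AnnotationError(
                        f"{vessels_path.name} row {i + 1}: unknown section "
                        f"{sid!r}"
                    )
                vessels.append(
                    Vessel(float(row["x"]), float(row["y"]), sid,
                           float(row["diameter"]))
                )

    transforms: dict[str, SectionTransform] = {
        sid: SectionTransform.identity(sid) for sid in sections
    }
    if transforms_path.exists():
        with open(transforms_path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                sid = str(row["section_id"])
                if sid not in known:
                    raise AnnotationError(
                        f"{transforms_path.name} row {i + 1}: unknown "
                        f"section {sid!r}"
                    )
                coeffs = tuple(
                    float(row[k]) for k in ("a", "b", "c", "d", "tx", "ty")
                )
                transforms[sid] = SectionTransform(sid, coeffs)

    return AnnotationSet(
        subject_id=subject_id,
        region=region,
        sections=sections,
        layer_regions=layer_regions,
        markers=markers,
        vessels=vessels,
        sulci=sulci,
        transforms=transforms,
        design=design,
    )


def write_annotation_set(aset: AnnotationSet, out_dir: str | Path) -> Path:
    """Write a bundle (GeoJSON + CSVs + YAML config) and return its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features = []
    for lr in aset.layer_regions:
        features.append({
            "type": "Feature",
            "geometry": mapping(_normalise_polygon(lr.polygon)),
            "properties": {"role": "layer", "section_id": lr.section_id,
                           "layer": lr.layer},
        })
    for s in aset.sulci:
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "MultiPoint",
                "coordinates": [list(s.fundus), list(s.mouth_a),
                                list(s.mouth_b)],
            },
            "properties": {"role": "sulcus", "section_id": s.section_id,
                           "depth_fraction": s.depth_fraction},
        })
    with open(out / _GEOMETRY_FILE, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    with open(out / _MARKERS_FILE, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section_id", "x", "y", "structure"])
        for m in aset.markers:
            w.writerow([m.section_id, repr(m.x), repr(m.y), m.structure])

    with open(out / _VESSELS_FILE, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section_id", "x", "y", "diameter"])
        for v in aset.vessels:
            w.writerow([v.section_id, repr(v.x), repr(v.y), repr(v.diameter)])

    with open(out / _TRANSFORMS_FILE, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section_id", "a", "b", "c", "d", "tx", "ty"])
        for sid in aset.sections:
            t = aset.transforms.get(sid, SectionTransform.identity(sid))
            w.writerow([sid] + [repr(c) for c in t.affine])

    design = aset.design
    cfg = {
        "subject_id": aset.subject_id,
        "region": aset.region,
        "sections": list(aset.sections),
        "design": {
            "frame_w": design.frame_w,
            "frame_h": design.frame_h,
            "grid_fraction": design.grid_fraction,
            "dissector_height": design.dissector_height,
            "guard_top": design.guard_top,
            "guard_bottom": design.guard_bottom,
            "cut_thickness": design.cut_thickness,
            "section_period": design.section_period,
            "mounted_thickness": design.mounted_thickness,
        },
    }
    with open(out / _CONFIG_FILE, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out


# ---------------------------------------------------------------------------
# Validation

_OVERLAP_TOL = 1e-6


def validate_annotation_set(aset: AnnotationSet) -> ValidationReport:
    """Check every type invariant; violations are findings, not exceptions.

    Error codes: BAD_REGION, BAD_DESIGN, UNKNOWN_SECTION, BAD_POLYGON,
    LAYER_OVERLAP, BAD_DIAMETER, BAD_SULCUS, BAD_DEPTH_FRACTION,
    BAD_TRANSFORM, MISSING_TRANSFORM.  Findings are deterministically
    ordered by (code, offending id, message).
    """
    report = ValidationReport()
    err = report.errors.append
    known = set(aset.sections)

    if aset.region not in REGIONS:
        err(Finding("BAD_REGION",
                    f"region {aset.region!r} not in {REGIONS}", aset.region))
    try:
        aset.design.validate()
    except Exception as exc:
        err(Finding("BAD_DESIGN", str(exc), "design"))

    for i, m in enumerate(aset.markers):
        if m.section_id not in known:
            err(Finding("UNKNOWN_SECTION",
                        f"marker {i} references section {m.section_id!r}",
                        f"marker:{i}"))

    for i, v in enumerate(aset.vessels):
        if v.section_id not in known:
            err(Finding("UNKNOWN_SECTION",
                        f"vessel {i} references section {v.section_id!r}",
                        f"vessel:{i}"))
        if not (v.diameter > 0):
            err(Finding("BAD_DIAMETER",
                        f"vessel {i} diameter {v.diameter} µm is not "
                        "positive", f"vessel:{i}"))

    for i, lr in enumerate(aset.layer_regions):
        lid = f"layer:{lr.section_id}:{lr.layer}"
        if lr.section_id not in known:
            err(Finding("UNKNOWN_SECTION",
                        f"layer region {i} references section "
                        f"{lr.section_id!r}", lid))
        if (not lr.polygon.is_valid) or lr.polygon.is_empty:
            err(Finding("BAD_POLYGON",
                        f"layer polygon {lr.layer} on section "
                        f"{lr.section_id} is invalid or empty", lid))
        elif lr.polygon.area <= 0:
            err(Finding("BAD_POLYGON",
                        f"layer polygon {lr.layer} on section "
                        f"{lr.section_id} has zero area", lid))

    # pairwise interior overlap within each section
    by_section: dict[str, list[LayerRegion]] = {}
    for lr in aset.layer_regions:
        by_section.setdefault(lr.section_id, []).append(lr)
    for sid, regions in by_section.items():
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                if not (a.polygon.is_valid and b.polygon.is_valid):
                    continue
                inter = a.polygon.intersection(b.polygon).area
                min_area = min(a.polygon.area, b.polygon.area)
                if min_area > 0 and inter / min_area > _OVERLAP_TOL:
                    err(Finding(
                        "LAYER_OVERLAP",
                        f"layers {a.layer} and {b.layer} on section {sid} "
                        f"overlap ({inter:.1f} µm², "
                        f"{100 * inter / min_area:.2f}% of smaller)",
                        f"layer:{sid}:{a.layer}+{b.layer}"))

    for i, s in enumerate(aset.sulci):
        sid = f"sulcus:{s.section_id}"
        if s.section_id not in known:
            err(Finding("UNKNOWN_SECTION",
                        f"sulcus {i} references section {s.section_id!r}",
                        sid))
        if not (0.0 < s.depth_fraction <= 1.0):
            err(Finding("BAD_DEPTH_FRACTION",
                        f"depth_fraction {s.depth_fraction} outside (0, 1]",
                        sid))
        if s.fundus == s.mouth_a or s.fundus == s.mouth_b or s.depth() <= 0:
            err(Finding("BAD_SULCUS",
                        "fundus coincides with a mouth point "
                        f"on section {s.section_id}", sid))

    for sid in aset.sections:
        t = aset.transforms.get(sid)
        if t is None:
            err(Finding("MISSING_TRANSFORM",
                        f"section {sid} has no alignment transform", sid))
        elif abs(t.det) <= 1e-9:
            err(Finding("BAD_TRANSFORM",
                        f"transform for section {sid} is singular "
                        f"(det = {t.det:g})", sid))
    for sid in aset.transforms:
        if sid not in known:
            err(Finding("UNKNOWN_SECTION",
                        f"transform references section {sid!r}",
                        f"transform:{sid}"))

    return report.sort()


# ---------------------------------------------------------------------------
# Alignment


def apply_alignment(aset: AnnotationSet) -> AnnotationSet:
    """Map every coordinate by its section's affine; returns a new set.

    Vessel diameters (lengths) rescale by the isotropic factor
    sqrt(|det|) of the linear part.  Transforms in the returned set are
    reset to the identity (the coordinates are now in the aligned frame).
    The input set is left unchanged.
    """
    missing = [sid for sid in aset.sections if sid not in aset.transforms]
    if missing:
        raise AnnotationError(
            f"sections without alignment transform: {missing}"
        )

    def tf(sid: str) -> SectionTransform:
        return aset.transforms[sid]

    markers = [
        replace(m, **dict(zip(("x", "y"), tf(m.section_id).apply_xy(m.x, m.y))))
        for m in aset.markers
    ]
    vessels = []
    for v in aset.vessels:
        t = tf(v.section_id)
        nx, ny = t.apply_xy(v.x, v.y)
        vessels.append(replace(v, x=nx, y=ny,
                               diameter=v.diameter * t.length_scale()))
    layer_regions = [
        replace(lr, polygon=tf(lr.section_id).apply_polygon(lr.polygon))
        for lr in aset.layer_regions
    ]
    sulci = [
        replace(
            s,
            fundus=tf(s.section_id).apply_xy(*s.fundus),
            mouth_a=tf(s.section_id).apply_xy(*s.mouth_a),
            mouth_b=tf(s.section_id).apply_xy(*s.mouth_b),
        )
        for s in aset.sulci
    ]
    return AnnotationSet(
        subject_id=aset.subject_id,
        region=aset.region,
        sections=list(aset.sections),
        layer_regions=layer_regions,
        markers=markers,
        vessels=vessels,
        sulci=sulci,
        transforms={sid: SectionTransform.identity(sid)
                    for sid in aset.sections},
        design=aset.design,
    )
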