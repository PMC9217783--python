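"""Design-based stereological estimators.

Implements the optical-fractionator population estimate, the
Gundersen–Jensen coefficient of error (CE) for systematic section series,
Cavalieri volume estimation from serial profile areas, and per-volume
density records.

The fractionator estimates the number of objects in a region from counts
made in a known fraction of the tissue:

    N_hat = sum(Q-) / (ssf * asf * tsf)

where ssf is the section sampling fraction (section thickness / section
period), asf the area sampling fraction of the counting-frame grid, and
tsf the thickness sampling fraction (optical dissector height / mounted
section thickness).  With exhaustive counting (grid covering 100% of the
region of interest) asf = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DesignError",
    "SamplingDesign",
    "SamplingFractions",
    "PopulationEstimate",
    "VolumeEstimate",
    "DensityRecord",
    "UM3_PER_MM3",
    "UM3_PER_CM3",
    "sampling_fractions",
    "fractionator_estimate",
    "gundersen_ce",
    "cavalieri_volume",
    "layer_density",
    "frame_grid_counts",
    "sample_slab_population",
]

UM3_PER_MM3 = 1.0e9
UM3_PER_CM3 = 1.0e12

UNIT_SCALES = ("per_mm3", "per_cm3")


class DesignError(ValueError):
    """Raised when a sampling design violates its own constraints."""


@dataclass(frozen=True)
class SamplingDesign:
    """Constants of an optical-fractionator sampling design.

    Defaults follow a common exhaustive design for 50 µm vibratome series:
    700 × 700 µm counting frame, systematic-random grid covering 100% of
    the region of interest, 11 µm optical dissector with 2 µm guard zones
    top and bottom, sections cut at 50 µm every 500 µm.

    ``mounted_thickness`` is the post-processing (shrunken) thickness of
    the mounted section within which the dissector is focused.  It is
    rarely reported alongside the cut thickness; the default of 15 µm is
    the minimum admissible value (dissector height plus both guards) and
    rescales every population estimate by a constant — see the methods
    note before comparing absolute densities across studies.
    """

    frame_w: float = 700.0
    frame_h: float = 700.0
    grid_fraction: float = 1.0
    dissector_height: float = 11.0
    guard_top: float = 2.0
    guard_bottom: float = 2.0
    cut_thickness: float = 50.0
    section_period: float = 500.0
    mounted_thickness: float = 15.0

    def validate(self) -> None:
        if not (0.0 < self.grid_fraction <= 1.0):
            raise DesignError(
                f"grid_fraction must be in (0, 1], got {self.grid_fraction}"
            )
        if self.frame_w <= 0 or self.frame_h <= 0:
            raise DesignError("counting frame dimensions must be positive")
        if self.dissector_height <= 0:
            raise DesignError("dissector_height must be positive")
        if self.guard_top < 0 or self.guard_bottom < 0:
            raise DesignError("guard zones cannot be negative")
        window = self.dissector_height + self.guard_top + self.guard_bottom
        if window > self.mounted_thickness + 1e-9:
            raise DesignError(
                "dissector plus guard zones "
                f"({window} µm) exceed mounted thickness "
                f"({self.mounted_thickness} µm)"
            )
        if self.mounted_thickness > self.cut_thickness + 1e-9:
            raise DesignError(
                "mounted thickness cannot exceed cut thickness "
                "(sections shrink, they do not swell)"
            )
        if self.section_period < self.cut_thickness:
            raise DesignError("section_period must be >= cut_thickness")

    def replace(self, **kwargs) -> "SamplingDesign":
        return replace(self, **kwargs)


class SamplingFractions(NamedTuple):
    ssf: float
    asf: float
    tsf: float


def sampling_fractions(design: SamplingDesign) -> SamplingFractions:
    """Section, area and thickness sampling fractions of a design.

    ssf = cut_thickness / section_period, asf = grid_fraction (1 for an
    exhaustive grid), tsf = dissector_height / mounted_thickness.
    """
    design.validate()
    return SamplingFractions(
        ssf=design.cut_thickness / design.section_period,
        asf=design.grid_fraction,
        tsf=design.dissector_height / design.mounted_thickness,
    )


@dataclass(frozen=True)
class PopulationEstimate:
    """Fractionator population estimate for one structure in one region.

    ``ce`` is the Gundersen–Jensen coefficient of error, or None when it
    is undefined (fewer than three sections, or no objects counted).
    """

    raw_count: int
    ssf: float
    asf: float
    tsf: float
    estimate: float
    ce: float | None
    section_counts: tuple[int, ...] = field(default=(), repr=False)

    @property
    def ce_defined(self) -> bool:
        return self.ce is not None


def gundersen_ce(section_counts: Sequence[int], m: int = 1) -> float | None:
    """Gundersen–Jensen coefficient of error for a systematic count series.

    With per-section counts Q_i, A = ΣQ_i², B = ΣQ_iQ_{i+1}, C = ΣQ_iQ_{i+2}
    and the Poisson "nugget" noise = ΣQ_i, the smoothness-class variance is

        Var_SRS = (3(A − noise) − 4B + C) / 240      (m = 1)
        Var_SRS = (3(A − noise) − 4B + C) / 12       (m = 0)

    clamped at zero, and CE = sqrt(noise + Var_SRS) / ΣQ_i.  m = 1 is the
    conventional smoothness class for biological section series.

    Returns None (undefined) for fewer than 3 sections or an all-zero
    series; an undefined CE is a signal, never silently zero.
    """
    if m not in (0, 1):
        raise ValueError(f"smoothness class m must be 0 or 1, got {m}")
    q = np.asarray(list(section_counts), dtype=float)
    if q.size < 3:
        return None
    if np.any(q < 0):
        raise ValueError("section counts must be non-negative")
    total = float(q.sum())
    if total == 0.0:
        return None
    a = float(np.dot(q, q))
    b = float(np.dot(q[:-1], q[1:]))
    c = float(np.dot(q[:-2], q[2:]))
    denom = 240.0 if m == 1 else 12.0
    var_srs = (3.0 * (a - total) - 4.0 * b + c) / denom
    var_srs = max(var_srs, 0.0)
    return math.sqrt(total + var_srs) / total


def fractionator_estimate(
    section_counts: Sequence[int],
    design: SamplingDesign,
    m: int = 1,
) -> PopulationEstimate:
    """Optical-fractionator population estimate from per-section counts.

    ``section_counts`` are the dissector counts Q- per section, in serial
    order.  The estimate is ΣQ- scaled by the reciprocal sampling
    fractions; the CE is attached when the series supports it (≥ 3
    sections with a nonzero total).
    """
    counts = [int(c) for c in section_counts]
    if len(counts) == 0:
        raise ValueError("at least one section count is required")
    if any(c < 0 for c in counts):
        raise ValueError("section counts must be non-negative")
    ssf, asf, tsf = sampling_fractions(design)
    raw = sum(counts)
    estimate = raw / (ssf * asf * tsf)
    ce = gundersen_ce(counts, m=m)
    return PopulationEstimate(
        raw_count=raw,
        ssf=ssf,
        asf=asf,
        tsf=tsf,
        estimate=estimate,
        ce=ce,
        section_counts=tuple(counts),
    )


@dataclass(frozen=True)
class VolumeEstimate:
    """Cavalieri volume from serial profile areas.

    volume = Σ area_i × spacing, areas in µm², spacing in µm, volume in µm³.
    """

    per_section_areas: tuple[tuple[str, float], ...]
    spacing: float
    volume: float


def cavalieri_volume(
    areas: Sequence[tuple[str, float]], spacing: float
) -> VolumeEstimate:
    """Cavalieri estimator: summed profile areas times section spacing."""
    areas = [(str(sid), float(a)) for sid, a in areas]
    if not areas:
        raise ValueError("at least one section area is required")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if any(a < 0 for _, a in areas):
        raise ValueError("areas must be non-negative")
    volume = sum(a for _, a in areas) * spacing
    return VolumeEstimate(
        per_section_areas=tuple(areas), spacing=float(spacing), volume=volume
    )


@dataclass(frozen=True)
class DensityRecord:
    """Per-volume density of one structure in one partition of one region."""

    subject_id: str
    region: str
    partition_label: str
    structure: str
    density_value: float
    unit_scale: str

    def converted(self, unit_scale: str) -> "DensityRecord":
        if unit_scale not in UNIT_SCALES:
            raise ValueError(f"unknown unit scale {unit_scale!r}")
        if unit_scale == self.unit_scale:
            return self
        factor = 1000.0 if unit_scale == "per_cm3" else 1.0 / 1000.0
        return replace(self, density_value=self.density_value * factor,
                       unit_scale=unit_scale)


def layer_density(
    estimate: PopulationEstimate,
    volume: VolumeEstimate,
    unit_scale: str = "per_cm3",
    *,
    subject_id: str = "",
    region: str = "",
    partition_label: str = "",
    structure: str = "",
) -> DensityRecord:
    """Population estimate divided by Cavalieri volume, on a stated scale.

    1 mm³ = 1e9 µm³ and 1 cm³ = 1e12 µm³; the per-cm³ value is therefore
    always 1000 × the per-mm³ value.
    """
    if unit_scale not in UNIT_SCALES:
        raise ValueError(f"unknown unit scale {unit_scale!r}")
    if volume.volume <= 0:
        raise ValueError("volume must be positive to form a density")
    per_um3 = estimate.estimate / volume.volume
    scale = UM3_PER_CM3 if unit_scale == "per_cm3" else UM3_PER_MM3
    return DensityRecord(
        subject_id=subject_id,
        region=region,
        partition_label=partition_label,
        structure=structure,
        density_value=per_um3 * scale,
        unit_scale=unit_scale,
    )


def frame_grid_counts(
    points_xy: np.ndarray,
    design: SamplingDesign,
    offset: tuple[float, float] = (0.0, 0.0),
) -> int:
    """Count points falling inside a systematic counting-frame grid.

    The grid tiles the plane with cells of step frame / sqrt(grid_fraction)
    so that the frame covers exactly ``grid_fraction`` of each cell; the
    grid phase is set by ``offset``.  The two-forbidden-edges convention is
    applied: a point is counted iff it falls in the half-open frame
    [x0, x0 + frame_w) × [y0, y0 + frame_h), i.e. points on the inclusion
    (lower-left) edges count and points on the exclusion edges do not.
    With grid_fraction = 1 every point is counted.
    """
    design.validate()
    pts = np.asarray(points_xy, dtype=float)
    if pts.size == 0:
        return 0
    pts = pts.reshape(-1, 2)
    if design.grid_fraction >= 1.0:
        return int(pts.shape[0])
    step_x = design.frame_w / math.sqrt(design.grid_fraction)
    step_y = design.frame_h / math.sqrt(design.grid_fraction)
    ox, oy = offset
    lx = np.mod(pts[:, 0] - ox, step_x)
    ly = np.mod(pts[:, 1] - oy, step_y)
    inside = (lx < design.frame_w) & (ly < design.frame_h)
    return int(np.count_nonzero(inside))


def sample_slab_population(
    points_xyz: np.ndarray,
    design: SamplingDesign,
    rng: np.random.Generator,
    n_sections: int | None = None,
) -> list[int]:
    """Simulate fractionator sampling of a known 3D point population.

    ``points_xyz`` is an (n, 3) array of object coordinates in µm, z being
    depth through the tissue slab.  A random section phase is drawn, the
    slab is cut into sections of ``cut_thickness`` every ``section_period``,
    each cut section shrinks linearly onto ``mounted_thickness``, and an
    object is counted iff its shrunken depth lies in the dissector window
    [guard_top, guard_top + dissector_height).  For grid_fraction < 1 a
    random-phase counting-frame grid is applied in the section plane.

    Returns per-section dissector counts (serial order), suitable for
    :func:`fractionator_estimate`.  Over random phases the resulting
    estimate is unbiased for the true number of points.
    """
    design.validate()
    pts = np.asarray(points_xyz, dtype=float).reshape(-1, 3)
    period = design.section_period
    phase = rng.uniform(0.0, period)
    # section index of each point: section k spans
    # [phase + k*period, phase + k*period + cut_thickness)
    k = np.floor((pts[:, 2] - phase) / period).astype(int)
    local = pts[:, 2] - (phase + k * period)
    in_section = local < design.cut_thickness
    shrink = design.mounted_thickness / design.cut_thickness
    mounted_depth = local * shrink
    in_dissector = in_section & (
        (mounted_depth >= design.guard_top)
        & (mounted_depth < design.guard_top + design.dissector_height)
    )
    if pts.size == 0:
        return [0] * (n_sections or 0)
    k_min = int(np.floor((pts[:, 2].min() - phase) / period))
    k_max = int(np.floor((pts[:, 2].max() - phase) / period))
    counts: list[int] = []
    for sec in range(k_min, k_max + 1):
        sel = in_dissector & (k == sec)
        if design.grid_fraction < 1.0:
            step_x = design.frame_w / math.sqrt(design.grid_fraction)
            step_y = design.frame_h / math.sqrt(design.grid_fraction)
            off = (rng.uniform(0, step_x), rng.uniform(0, step_y))
            counts.append(frame_grid_counts(pts[sel, :2], design, off))
        else:
            counts.append(int(np.count_nonzero(sel)))
    if n_sections is not None:
        if len(counts) < n_sections:
            counts += [0] * (n_sections - len(counts))
    return counts
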