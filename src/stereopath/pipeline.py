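"""Config-driven orchestration: from annotation bundles to report tables.

Reproduces the standard output surfaces of a stereological tau survey:

* a layer-density table (population estimate / Cavalieri layer volume,
  per layer and structure, on an explicit unit scale),
* a sulcal-versus-gyral partition density table,
* a perivascular vessel-association summary,
* a coefficient-of-error table with the conventional < 15% acceptability
  flagging,
* pooled marker-density heatmaps, and
* a pairwise density-comparisons table (e.g. "subject A's layer I
  neuropil density is k times subject B's").

Multiple subjects/regions are treated as independent analysis units
concatenated into long-format tables.  Given identical inputs and
config the pipeline is deterministic, down to byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely import intersects_xy
from shapely.ops import unary_union

from . import __version__
from .annotations import (
    CORTICAL_LAYERS,
    LAYERS,
    STRUCTURES,
    AnnotationSet,
    Finding,
    apply_alignment,
    load_annotation_set,
    validate_annotation_set,
)
from .spatial import (
    HeatmapGrid,
    assign_markers_to_layers,
    density_heatmap,
    partition_sulcal_gyral,
    regional_density,
    vessel_association,
)
from .stereology import (
    UM3_PER_CM3,
    UM3_PER_MM3,
    cavalieri_volume,
    fractionator_estimate,
    layer_density,
)

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "ReportBundle",
    "analyze_annotation_set",
    "run_pipeline",
    "density_ratio_table",
    "flag_high_ce",
    "CE_LIMIT",
]

logger = logging.getLogger(__name__)

CE_LIMIT = 0.15


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and batched findings."""

    def __init__(self, stage: str, message: str,
                 findings: Sequence[Finding] = ()):
        self.stage = stage
        self.findings = list(findings)
        detail = "; ".join(
            f"[{f.code}] {f.message}" for f in self.findings[:20]
        )
        super().__init__(f"stage {stage!r}: {message}"
                         + (f" — {detail}" if detail else ""))


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    bundles: list[str]
    out_dir: str | None = None
    design_overrides: dict = field(default_factory=dict)
    layer_unit_scale: str = "per_cm3"
    partition_unit_scale: str = "per_mm3"
    heatmap_cell: float = 250.0
    heatmap_bandwidth: float | None = 250.0
    heatmap_structures: list[str] = field(
        default_factory=lambda: ["neuropil_thread"])
    vessel_threshold: float = 100.0
    vessel_min_diameter: float = 30.0
    ce_limit: float = CE_LIMIT
    make_plots: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if not self.bundles:
            raise PipelineError("config", "no input bundles configured")
        if self.vessel_threshold <= 0 or self.vessel_min_diameter <= 0:
            raise PipelineError("config", "thresholds must be positive")
        for scale in (self.layer_unit_scale, self.partition_unit_scale):
            if scale not in ("per_mm3", "per_cm3"):
                raise PipelineError("config",
                                    f"unknown unit scale {scale!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        bundles = [
            str((base / b).resolve()) if not Path(b).is_absolute() else b
            for b in raw.pop("bundles", [])
        ]
        out_dir = raw.pop("out_dir", None)
        if out_dir is not None and not Path(out_dir).is_absolute():
            out_dir = str((base / out_dir).resolve())
        cfg = cls(bundles=bundles, out_dir=out_dir, **raw)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables and artifacts of one pipeline run."""

    layer_density_table: pd.DataFrame
    partition_density_table: pd.DataFrame
    vessel_table: pd.DataFrame
    ce_table: pd.DataFrame
    comparisons_table: pd.DataFrame
    heatmaps: dict[tuple[str, str, str], HeatmapGrid]
    provenance: dict

    def write(self, out_dir: str | Path, make_plots: bool = True) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.layer_density_table.to_csv(out / "layer_densities.csv",
                                        index=False)
        self.partition_density_table.to_csv(
            out / "partition_densities.csv", index=False)
        self.vessel_table.to_csv(out / "vessel_association.csv", index=False)
        self.ce_table.to_csv(out / "coefficient_of_error.csv", index=False)
        self.comparisons_table.to_csv(out / "density_comparisons.csv",
                                      index=False)
        for (subject, region, structure), grid in self.heatmaps.items():
            stem = f"heatmap_{subject}_{region}_{structure}"
            np.savetxt(out / f"{stem}.csv", grid.counts, fmt="%d",
                       delimiter=",")
            if make_plots:
                _plot_heatmap(grid, out / f"{stem}.png",
                              title=f"{subject} {region} {structure}")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)
        return out


def _plot_heatmap(grid: HeatmapGrid, path: Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = grid.smoothed if grid.smoothed is not None else grid.counts
    nx, ny = data.shape
    x0, y0 = grid.origin
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(
        data.T, origin="lower", cmap="inferno",
        extent=(x0, x0 + nx * grid.cell, y0, y0 + ny * grid.cell),
        aspect="equal",
    )
    fig.colorbar(im, ax=ax, label="markers per bin")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Per-subject analysis


def analyze_annotation_set(
    aset: AnnotationSet,
    config: PipelineConfig | None = None,
) -> ReportBundle:
    """Run the full analysis chain on one annotation set.

    Stages: validate → align → layer assignment → fractionator + CE →
    Cavalieri volumes → layer densities → sulcal/gyral partition
    densities → vessel association → heatmaps.  Validation errors abort
    in batch before any computation.
    """
    config = config or PipelineConfig(bundles=["<in-memory>"])
    report = validate_annotation_set(aset)
    if not report.ok:
        raise PipelineError("validate",
                            f"{len(report.errors)} validation error(s) in "
                            f"{aset.subject_id}/{aset.region}",
                            report.errors)
    aligned = apply_alignment(aset)
    if config.design_overrides:
        aligned.design = aligned.design.replace(**config.design_overrides)
        aligned.design.validate()
    design = aligned.design
    subject, region = aligned.subject_id, aligned.region
    logger.info("analyzing %s/%s: %d markers, %d vessels, %d sections",
                subject, region, len(aligned.markers),
                len(aligned.vessels), len(aligned.sections))

    # --- layer counts and densities
    labels = assign_markers_to_layers(aligned.markers, aligned.layer_regions)
    sec_index = {sid: i for i, sid in enumerate(aligned.sections)}
    n_sections = len(aligned.sections)
    counts: dict[tuple[str, str], list[int]] = {
        (layer, st): [0] * n_sections
        for layer in LAYERS for st in STRUCTURES
    }
    for lab, m in zip(labels, aligned.markers):
        if lab.label in LAYERS:
            counts[(lab.label, m.structure)][sec_index[m.section_id]] += 1

    layer_scale = (UM3_PER_CM3 if config.layer_unit_scale == "per_cm3"
                   else UM3_PER_MM3)
    layer_rows = []
    ce_rows = []
    for layer in LAYERS:
        areas = [
            (sid, sum(lr.polygon.area
                      for lr in aligned.layers_on(sid)
                      if lr.layer == layer))
            for sid in aligned.sections
        ]
        vol = cavalieri_volume(areas, design.section_period)
        for st in STRUCTURES:
            est = fractionator_estimate(counts[(layer, st)], design)
            rec = layer_density(
                est, vol, config.layer_unit_scale,
                subject_id=subject, region=region,
                partition_label=layer, structure=st,
            )
            layer_rows.append({
                "subject_id": subject, "region": region, "layer": layer,
                "structure": st, "raw_count": est.raw_count,
                "estimate": est.estimate,
                "volume_mm3": vol.volume / UM3_PER_MM3,
                "density_value": rec.density_value,
                "unit_scale": rec.unit_scale,
            })
            ce_rows.append({
                "subject_id": subject, "region": region, "layer": layer,
                "structure": st, "raw_count": est.raw_count,
                "ce": est.ce if est.ce is not None else np.nan,
            })

    # --- sulcal / gyral partition
    part_counts = {"sulcal": {st: [0] * n_sections for st in STRUCTURES},
                   "gyral": {st: [0] * n_sections for st in STRUCTURES}}
    part_areas = {"sulcal": [0.0] * n_sections,
                  "gyral": [0.0] * n_sections}
    any_sulcus = False
    for sid in aligned.sections:
        ribbon_polys = [lr.polygon for lr in aligned.layers_on(sid)
                        if lr.layer in CORTICAL_LAYERS]
        if not ribbon_polys:
            continue
        ribbon = unary_union(ribbon_polys)
        sulcus = aligned.sulcus_on(sid)
        section_markers = aligned.markers_on(sid)
        i = sec_index[sid]
        if sulcus is None:
            part_areas["gyral"][i] = ribbon.area
            for m in section_markers:
                if intersects_xy(ribbon, m.x, m.y):
                    part_counts["gyral"][m.structure][i] += 1
            continue
        any_sulcus = True
        plabels, areas = partition_sulcal_gyral(section_markers, ribbon,
                                                sulcus)
        part_areas["sulcal"][i] = areas["sulcal"]
        part_areas["gyral"][i] = areas["gyral"]
        for pl, m in zip(plabels, section_markers):
            if pl.label in ("sulcal", "gyral"):
                part_counts[pl.label][m.structure][i] += 1

    part_rows = []
    for st in STRUCTURES:
        sc = {label: part_counts[label][st]
              for label in ("sulcal", "gyral")
              if sum(part_areas[label]) > 0}
        ar = {label: part_areas[label] for label in sc}
        if not sc:
            continue
        for rec in regional_density(
            sc, ar, design, st, subject_id=subject, region=region,
            unit_scale=config.partition_unit_scale,
        ):
            part_rows.append({
                "subject_id": subject, "region": region,
                "partition": rec.partition_label, "structure": st,
                "raw_count": sum(sc[rec.partition_label]),
                "area_mm2": sum(ar[rec.partition_label]) / 1e6,
                "density_value": rec.density_value,
                "unit_scale": rec.unit_scale,
            })
    if not any_sulcus:
        logger.info("%s/%s: no sulcus annotations; partition table is "
                    "gyral-only", subject, region)

    # --- perivascular association
    summary = vessel_association(
        aligned.markers, aligned.vessels,
        threshold=config.vessel_threshold,
        min_diameter=config.vessel_min_diameter,
    )
    vessel_rows = [{
        "subject_id": subject, "region": region,
        "n_vessels": summary.n_vessels,
        "n_associated": summary.n_associated,
        "pct_associated": (summary.pct_associated
                           if summary.pct_associated is not None
                           else np.nan),
        "mean_distance_um": (summary.mean_distance
                             if summary.mean_distance is not None
                             else np.nan),
        "threshold_um": summary.threshold,
        "min_diameter_um": summary.min_diameter,
    }]

    # --- heatmaps (raw pooled distribution, no fractionator correction)
    heatmaps: dict[tuple[str, str, str], HeatmapGrid] = {}
    for st in config.heatmap_structures:
        heatmaps[(subject, region, st)] = density_heatmap(
            aligned.markers, grid_cell=config.heatmap_cell,
            bandwidth=config.heatmap_bandwidth, structure=st,
        )

    layer_df = pd.DataFrame(layer_rows)
    provenance = {
        "stereopath_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "subjects": [f"{subject}/{region}"],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    return ReportBundle(
        layer_density_table=layer_df,
        partition_density_table=pd.DataFrame(part_rows),
        vessel_table=pd.DataFrame(vessel_rows),
        ce_table=pd.DataFrame(ce_rows),
        comparisons_table=density_ratio_table(layer_df),
        heatmaps=heatmaps,
        provenance=provenance,
    )


def _concat(bundles: list[ReportBundle], config: PipelineConfig
            ) -> ReportBundle:
    heatmaps: dict = {}
    subjects: list[str] = []
    for b in bundles:
        heatmaps.update(b.heatmaps)
        subjects.extend(b.provenance.get("subjects", []))
    layer_df = pd.concat([b.layer_density_table for b in bundles],
                         ignore_index=True)
    prov = dict(bundles[0].provenance)
    prov["subjects"] = subjects
    prov["config_hash"] = config.content_hash()
    return ReportBundle(
        layer_density_table=layer_df,
        partition_density_table=pd.concat(
            [b.partition_density_table for b in bundles],
            ignore_index=True),
        vessel_table=pd.concat([b.vessel_table for b in bundles],
                               ignore_index=True),
        ce_table=pd.concat([b.ce_table for b in bundles],
                           ignore_index=True),
        comparisons_table=density_ratio_table(layer_df),
        heatmaps=heatmaps,
        provenance=prov,
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Load, validate, analyse and report every configured bundle."""
    config.validate()
    results = []
    for bundle_path in config.bundles:
        try:
            aset = load_annotation_set(bundle_path)
        except Exception as exc:
            raise PipelineError("load", f"{bundle_path}: {exc}") from exc
        results.append(analyze_annotation_set(aset, config))
    report = _concat(results, config)
    if config.out_dir:
        report.write(config.out_dir, make_plots=config.make_plots)
        logger.info("report written to %s", config.out_dir)
    return report


# ---------------------------------------------------------------------------
# Derived tables


def density_ratio_table(layer_density_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise subject density ratios per (region, layer, structure).

    For every ordered pair of subjects sharing a region, layer and
    structure, reports density_a / density_b (NaN when the denominator
    is zero).  This is the quantitative form of statements like
    "subject A's layer I density is k times subject B's".
    """
    df = layer_density_table
    cols = ["subject_id", "region", "layer", "structure", "density_value"]
    if df.empty or any(c not in df.columns for c in cols):
        return pd.DataFrame(columns=["region", "layer", "structure",
                                     "subject_a", "subject_b", "ratio"])
    rows = []
    for (region, layer, st), grp in df.groupby(
            ["region", "layer", "structure"], sort=True):
        vals = dict(zip(grp["subject_id"], grp["density_value"]))
        for a, b in itertools.permutations(sorted(vals), 2):
            denom = vals[b]
            rows.append({
                "region": region, "layer": layer, "structure": st,
                "subject_a": a, "subject_b": b,
                "ratio": (vals[a] / denom) if denom else np.nan,
            })
    return pd.DataFrame(rows)


def flag_high_ce(ce_table: pd.DataFrame,
                 limit: float = CE_LIMIT) -> pd.DataFrame:
    """Rows whose coefficient of error is ≥ limit or undefined.

    Mirrors the conventional acceptability rule for stereological
    estimates (CE below 15%); undefined CEs (too few sections or no
    objects counted) are flagged with reason "insufficient counts".
    """
    df = ce_table.copy()
    undefined = df["ce"].isna()
    high = df["ce"] >= limit
    flagged = df[undefined | high].copy()
    flagged["reason"] = np.where(
        undefined[undefined | high], "insufficient counts",
        f"CE >= {limit:g}",
    )
    return flagged.reset_index(drop=True)
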