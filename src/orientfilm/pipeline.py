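"""End-to-end orchestration of the three analysis pathways.

Pathway (a): channel selection -> Niblack binarization -> connected
components -> shape summary (count, area, relative coverage).
Pathway (b): pathway-(a) mask -> object centroids -> Voronoi tessellation
-> regularity index.
Pathway (c): gradient -> structure tensor -> orientation/coherency fields
and renders -> ROI tiling -> directional summaries -> angle series.

``run_study`` applies all three to a set of sample images, assembles a
Table-style summary (count, A, relative coverage vs the reference sample,
VRI), the cross-sample correlation/chi-square matrix and the PCA separation
report, and writes everything (plus a manifest with the resolved config)
to the output directory.  Every stage logs its parameters; all randomness
flows from the single config seed, so identical configs give bit-identical
CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anglestats, binarize, roiorient, shapestats, tensorfield, vortess
from .io import (read_image, write_field_tiff, write_mask_png, write_rgb_png)

__all__ = ["RunConfig", "SampleReport", "run_pathway_a", "run_pathway_b",
           "run_pathway_c", "run_study"]

log = logging.getLogger("orientfilm")


@dataclass
class RunConfig:
    """Serializable configuration of a full run."""

    inputs: list = field(default_factory=list)  # paths or sample ids
    channel: str = "auto"  # auto | r | g | b
    niblack_radius: int = 40
    niblack_k: float = -0.2
    polarity: str = "dark_foreground"
    connectivity: int = 8
    px_per_mm: float | None = 125.0
    voronoi_include_unbounded: bool = False
    voronoi_cell_center: str = "centroid"
    tensor_operator: str = "riesz"
    window_sigma: float = 8.0
    n_rois: int = 20
    roi_size: int = 250
    peaks_per_roi: int = 3
    chi2_mode: str = "paired"
    reference_sample: str | None = None  # default: first input
    rng_seed: int = 0
    output_dir: str = "orientfilm_out"
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class SampleReport:
    sample_id: str
    shape_summary: shapestats.ShapeSummary | None = None
    coverage: float | None = None
    vri_result: vortess.VriResult | None = None
    angle_series: roiorient.AngleSeries | None = None
    roi_summaries: list = field(default_factory=list)
    field_paths: dict = field(default_factory=dict)


def _gray(image, config: RunConfig) -> binarize.GrayImage:
    arr = np.asarray(image)
    if arr.ndim == 3:
        override = None if config.channel == "auto" else config.channel
        gray, scores = binarize.select_channel(arr, override=override)
        log.info("channel scores %s", scores)
        return gray
    return binarize.GrayImage(arr.astype(float), px_per_mm=config.px_per_mm)


def run_pathway_a(image, config: RunConfig,
                  out_dir: Path | None = None, sample_id: str = "sample",
                  ) -> tuple[shapestats.ShapeSummary, binarize.BinaryMask,
                             list]:
    """Binarize and quantify the coverage of one image."""
    gray = _gray(image, config)
    log.info("[%s] niblack radius=%d k=%.3g polarity=%s", sample_id,
             config.niblack_radius, config.niblack_k, config.polarity)
    mask = binarize.niblack_mask(gray, radius=config.niblack_radius,
                                 k=config.niblack_k, polarity=config.polarity)
    objects = shapestats.label_objects(mask, connectivity=config.connectivity)
    summary = shapestats.summarize(objects, px_per_mm=config.px_per_mm)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mask_png(out_dir / f"{sample_id}_mask.png", mask.pixels)
        shapestats.objects_to_table(objects, config.px_per_mm).to_csv(
            out_dir / f"{sample_id}_objects.csv", index=False)
    return summary, mask, objects


def run_pathway_b(image, config: RunConfig, objects=None,
                  sample_id: str = "sample") -> vortess.VriResult:
    """Voronoi regularity of the segmented-object centroids."""
    if objects is None:
        _, _, objects = run_pathway_a(image, config, sample_id=sample_id)
    if len(objects) < 3:
        raise ValueError(
            f"[{sample_id}] only {len(objects)} segmented objects; the Voronoi "
            "pathway needs at least 3 (check radius/k or image contrast)")
    seeds = vortess.seeds_from_objects(objects)
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    diagram = vortess.tessellate(seeds, window=(0.0, float(w), 0.0, float(h)))
    return vortess.vri(diagram,
                       include_unbounded=config.voronoi_include_unbounded,
                       cell_center=config.voronoi_cell_center)


def run_pathway_c(image, config: RunConfig,
                  out_dir: Path | None = None, sample_id: str = "sample",
                  ) -> tuple[dict, list, roiorient.AngleSeries]:
    """Orientation/coherency fields, ROI summaries and the angle series."""
    gray = _gray(image, config)
    orient, tensor = tensorfield.orientation_field(
        gray.pixels, operator=config.tensor_operator,
        window_sigma=config.window_sigma)
    h, w = gray.pixels.shape
    roi_size = min(config.roi_size, h, w)
    rois = roiorient.tile_rois((h, w), n_rois=config.n_rois, roi_size=roi_size)
    summaries = [roiorient.summarize_roi(orient, tensor, roi,
                                         peaks_per_roi=config.peaks_per_roi)
                 for roi in rois]
    series = roiorient.collect_angle_series(
        gray.pixels, rois, peaks_per_roi=config.peaks_per_roi,
        sample_id=sample_id, operator=config.tensor_operator,
        window_sigma=config.window_sigma)
    paths: dict = {}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "theta": out_dir / f"{sample_id}_theta.tif",
            "coherency": out_dir / f"{sample_id}_coherency.tif",
            "energy": out_dir / f"{sample_id}_energy.tif",
            "hsb": out_dir / f"{sample_id}_hsb.png",
        }
        write_field_tiff(paths["theta"], orient.theta)
        write_field_tiff(paths["coherency"], orient.coherency)
        write_field_tiff(paths["energy"], orient.energy)
        write_rgb_png(paths["hsb"], tensorfield.render_hsb(orient, gray.pixels))
        rows = [{
            "sample_id": sample_id, "roi_id": s.roi.id,
            "dominant_theta": s.dominant_theta,
            "mean_coherency": s.mean_coherency,
            "elongation": s.elongation, "isotropic": s.isotropic,
        } for s in summaries]
        pd.DataFrame(rows).to_csv(out_dir / f"{sample_id}_rois.csv", index=False)
        pd.DataFrame({
            "sample_id": sample_id,
            "roi_id": [p[0] for p in series.provenance],
            "rank": [p[1] for p in series.provenance],
            "angle_deg": series.angles,
        }).to_csv(out_dir / f"{sample_id}_angles.csv", index=False)
        paths = {k: str(v) for k, v in paths.items()}
    return paths, summaries, series


def run_study(images: dict, config: RunConfig) -> dict:
    """Run all pathways over named sample images plus cross-sample stats.

    ``images`` maps sample id -> 2-D/3-D array (or path).  Returns a dict of
    SampleReport per sample plus the cross-sample statistics; writes the
    Table-style summary CSV, the stats matrices and a run manifest under
    ``config.output_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    if not images:
        raise ValueError("need at least one image")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    reports: dict[str, SampleReport] = {}
    for sid, img in images.items():
        if isinstance(img, (str, Path)):
            img = read_image(img)
        rep = SampleReport(sample_id=sid)
        summary, mask, objects = run_pathway_a(img, config, out_dir=out,
                                               sample_id=sid)
        rep.shape_summary = summary
        rep.coverage = mask.coverage
        try:
            rep.vri_result = run_pathway_b(img, config, objects=objects,
                                           sample_id=sid)
        except ValueError as exc:
            log.warning("voronoi pathway skipped: %s", exc)
        rep.field_paths, rep.roi_summaries, rep.angle_series = run_pathway_c(
            img, config, out_dir=out, sample_id=sid)
        reports[sid] = rep

    ids = list(reports)
    ref = config.reference_sample or ids[0]
    if ref not in reports:
        raise ValueError(f"reference sample {ref!r} not among inputs")
    ref_area = reports[ref].shape_summary.total_area
    table = pd.DataFrame([{
        "sample": sid,
        "count": r.shape_summary.count,
        "area": r.shape_summary.total_area,
        "area_unit": r.shape_summary.area_unit,
        "coverage": r.coverage,
        "relative_cvg_pct": binarize.relative_coverage(
            r.shape_summary.total_area, ref_area) if ref_area > 0 else np.nan,
        "vri": (r.vri_result.vri if r.vri_result is not None else np.nan),
    } for sid, r in reports.items()])
    table.to_csv(out / "summary_table.csv", index=False)

    cross: dict = {}
    if len(ids) >= 2:
        ns = {len(reports[s].angle_series) for s in ids}
        if len(ns) != 1:
            raise ValueError(
                f"angle-series lengths differ across samples ({sorted(ns)}); "
                "cross-sample statistics need equal N")
        rows = []
        for i, s1 in enumerate(ids):
            for s2 in ids[i + 1:]:
                ps = anglestats.pairwise_stats(reports[s1].angle_series,
                                               reports[s2].angle_series,
                                               chi2_mode=config.chi2_mode)
                rows.append({"a": s1, "b": s2, "pearson_r": ps.pearson_r,
                             "pearson_p": ps.pearson_p,
                             "spearman_rho": ps.spearman_rho,
                             "spearman_p": ps.spearman_p,
                             "chi2": ps.chi2_stat, "chi2_p": ps.chi2_p})
        pd.DataFrame(rows).to_csv(out / "pairwise_stats.csv", index=False)
        sep = anglestats.separation_report(
            {s: reports[s].angle_series for s in ids})
        cross = {"pairwise": rows, "separation": {
            "min_between_distance": sep["min_between_distance"],
            "mean_within_sample_distance": sep["mean_within_sample_distance"],
            "silhouette": sep["silhouette"],
            "explained_first2": sep["explained_first2"],
        }}
        (out / "cross_sample.json").write_text(
            json.dumps(cross, indent=2, sort_keys=True))
    else:
        log.info("single image: cross-sample statistics skipped")

    import platform
    manifest = {
        "config_hash": config.config_hash(),
        "samples": ids,
        "reference": ref,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {"reports": reports, "table": table, "cross": cross}
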