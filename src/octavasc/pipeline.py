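"""End-to-end pipeline driver and configuration.

``run_pipeline`` chains angiography reconstruction, Hessian enhancement,
lumen segmentation, centerline extraction, per-segment measurement, the
resolution filter and the image-level summary, writing every artifact
(with the fully resolved configuration echoed for provenance) when an
output directory is given. Identical input and configuration reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ovio
from .morphometry import (
    MorphometrySummary,
    VesselSegmentMetrics,
    apply_resolution_filter,
    measure_segments,
    summarize,
)
from .reconstruction import OCTAVolume, OCTVolume4D, compute_decorrelation, estimate_noise_floor
from .segmentation import CenterlineGraph, LumenMask, extract_centerlines, segment_lumens
from .vesselness import DEFAULT_SCALES_UM, VesselnessVolume, multiscale_vesselness

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults.

    Unknown keys are rejected by :meth:`from_dict`; the resolved
    configuration is echoed verbatim into every output for provenance.
    """

    # angiography
    noise_floor_percentile: float = 0.5
    # vessel enhancement
    scales_um: tuple[float, ...] = DEFAULT_SCALES_UM
    alpha: float = 0.5
    beta: float = 0.5
    c: float | str = "auto"
    # segmentation
    threshold_window_um: float = 120.0
    threshold_offset: float = 0.05
    min_decorrelation: float = 0.05
    vesselness_gate: float = 0.01
    gate_dilation_um: float = 8.0
    closing_radius_um: float = 8.0
    min_component_volume_um3: float = 1e4
    min_branch_length_um: float = 40.0
    # morphometry
    sample_spacing_um: float = 10.0
    min_diameter_um: float = 15.0
    density_convention: str = "enface"
    half_length_scale_factor: float = 3.0
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        self.scales_um = tuple(float(s) for s in self.scales_um)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.noise_floor_percentile < 1:
            raise ValueError("noise_floor_percentile must be in (0, 1)")
        if len(self.scales_um) == 0:
            raise ValueError("scales_um must be non-empty")
        if self.density_convention not in ("enface", "volumetric"):
            raise ValueError("density_convention must be 'enface' or 'volumetric'")
        if self.min_diameter_um < 0 or self.sample_spacing_um <= 0:
            raise ValueError("invalid morphometry settings")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales_um"] = list(self.scales_um)
        return d


@dataclass
class PipelineResult:
    """All pipeline artifacts for one input volume."""

    summary: MorphometrySummary
    segments: pd.DataFrame
    octa: OCTAVolume
    vesselness: VesselnessVolume
    mask: LumenMask
    centerlines: CenterlineGraph
    all_metrics: list[VesselSegmentMetrics]
    retained_metrics: list[VesselSegmentMetrics]
    config: PipelineConfig

    def summary_json(self) -> str:
        payload = {"summary": self.summary.as_dict(), "config": self.config.to_dict()}
        return json.dumps(payload, indent=2, sort_keys=True)


def _segments_frame(metrics: list[VesselSegmentMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "segment_id": [m.segment_id for m in metrics],
            "length_um": [m.arc_length_um for m in metrics],
            "diameter_um": [m.diameter_um for m in metrics],
            "area_um2": [m.area_um2 for m in metrics],
            "n_samples": [m.n_samples for m in metrics],
        }
    )


def run_pipeline(
    volume: OCTVolume4D,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run angiography -> enhancement -> segmentation -> morphometry.

    Raises with a stage-labelled message on inconsistent inputs; writes
    all artifacts plus the echoed config under ``output_dir`` if given.
    """
    cfg = config or PipelineConfig()
    cfg.validate()

    logger.info("[angiography] %d frames, grid %s", volume.n_frames, volume.grid_shape)
    floor = estimate_noise_floor(volume, cfg.noise_floor_percentile)
    octa = compute_decorrelation(volume, noise_floor=floor)
    logger.info(
        "[angiography] noise floor %.4g; %d low-SNR voxels",
        floor,
        int(octa.low_snr_mask.sum()),
    )

    usable_scales = tuple(s for s in cfg.scales_um if s >= max(volume.voxel_size))
    if not usable_scales:
        raise ValueError(
            "[enhancement] no scale in scales_um is at least the largest voxel "
            f"dimension ({max(volume.voxel_size)} um)"
        )
    if len(usable_scales) < len(cfg.scales_um):
        logger.warning(
            "[enhancement] dropping scales below the largest voxel dimension: %s",
            sorted(set(cfg.scales_um) - set(usable_scales)),
        )
    vess = multiscale_vesselness(
        octa, scales_um=usable_scales, alpha=cfg.alpha, beta=cfg.beta, c=cfg.c
    )
    logger.info("[enhancement] scales %s, peak response %.3f", cfg.scales_um, vess.response.max())

    mask = segment_lumens(
        octa,
        vess,
        window_um=cfg.threshold_window_um,
        offset=cfg.threshold_offset,
        min_decorrelation=cfg.min_decorrelation,
        vesselness_gate=cfg.vesselness_gate,
        gate_dilation_um=cfg.gate_dilation_um,
        min_component_volume_um3=cfg.min_component_volume_um3,
        closing_radius_um=cfg.closing_radius_um,
    )
    logger.info("[segmentation] %d lumen voxels", int(mask.mask.sum()))

    graph = extract_centerlines(mask, min_branch_length_um=cfg.min_branch_length_um)
    logger.info(
        "[centerlines] %d edges, %d nodes, total %.1f um",
        graph.n_edges,
        graph.n_nodes,
        graph.total_length_um,
    )

    metrics = measure_segments(
        graph,
        octa,
        mask,
        sample_spacing_um=cfg.sample_spacing_um,
        vesselness=vess,
        half_length_scale_factor=cfg.half_length_scale_factor,
    )
    retained = apply_resolution_filter(metrics, min_diameter_um=cfg.min_diameter_um)
    logger.info(
        "[morphometry] %d segments measured, %d retained above %.0f um",
        len(metrics),
        len(retained),
        cfg.min_diameter_um,
    )

    summary = summarize(retained, mask, convention=cfg.density_convention)
    result = PipelineResult(
        summary=summary,
        segments=_segments_frame(retained),
        octa=octa,
        vesselness=vess,
        mask=mask,
        centerlines=graph,
        all_metrics=metrics,
        retained_metrics=retained,
        config=cfg,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        ovio.write_volume(out / "decorrelation.tif", octa.decorrelation.astype(np.float32))
        ovio.write_volume(out / "low_snr_mask.tif", octa.low_snr_mask.astype(np.uint8))
        ovio.write_volume(out / "vesselness.tif", vess.response.astype(np.float32))
        ovio.write_volume(out / "best_scale.tif", vess.best_scale.astype(np.float32))
        ovio.write_volume(out / "lumen_mask.tif", mask.mask.astype(np.uint8))
        ovio.write_centerlines_csv(out / "centerlines.csv", graph)
        result.segments.to_csv(out / "segments.csv", index=False)
        (out / "summary.json").write_text(result.summary_json())
    return result
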