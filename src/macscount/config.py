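"""Run configuration, seeding and the end-to-end pipeline.

A run is described by one YAML file with sections ``population``,
``optics``, ``camera``, ``detection``, ``overlap``, ``statistics`` and
``frap`` plus a root ``seed``.  Missing keys take documented defaults;
unknown keys are rejected by name.  Every pipeline run writes its fully
resolved configuration next to the outputs so the run is reproducible
from that file alone.  All randomness flows from the root seed through
independently spawned substreams, so changing the seed changes the
stochastic outputs but never the schemas.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import DetectionConfig, detect_frame, truth_mask
from .frap import FrapExperiment
from .geometry import PopulationSpec
from .overlap import infer_true_lambda, undercount_curve
from .simulate import CameraModel, OpticsModel, generate_dataset
from . import stats as cstats

log = logging.getLogger("macscount")

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline"]


@dataclass
class OverlapSettings:
    resolution_nm: float = 250.0
    reps: int = 2000
    n_max: int = 20


@dataclass
class StatisticsSettings:
    n_bins: int = 5
    trim: float = 0.01
    size_covariate: str = "length_um"
    maturation_time_min: float = 10.0
    doubling_time_min: float = 25.0


@dataclass
class RunConfig:
    population: PopulationSpec = field(default_factory=PopulationSpec)
    optics: OpticsModel = field(default_factory=OpticsModel)
    camera: CameraModel = field(default_factory=CameraModel)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    overlap: OverlapSettings = field(default_factory=OverlapSettings)
    statistics: StatisticsSettings = field(default_factory=StatisticsSettings)
    frap: FrapExperiment = field(default_factory=FrapExperiment)
    seed: int = 0
    n_frames: int = 1
    use_truth_masks: bool = False
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "population": PopulationSpec,
    "optics": OpticsModel,
    "camera": CameraModel,
    "detection": DetectionConfig,
    "overlap": OverlapSettings,
    "statistics": StatisticsSettings,
    "frap": FrapExperiment,
}
_SCALARS = {"seed", "n_frames", "use_truth_masks", "log_level"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, merging defaults.

    An empty (or missing) file yields the full documented defaults;
    unknown sections or keys raise with the offending names.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                data.setdefault(k, {}).update(v)
            else:
                data[k] = v
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, data.get(name, {}) or {}, name)
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=False))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """simulate -> detect -> count -> correct -> analyze, all on disk.

    Writes TIFF frames, ``spots.csv``, ``counts.csv``, ``curve.csv``,
    ``lambda.json``, ``stats.json`` and the resolved config; returns the
    stats dict.  Per-stage QC counts (cells, spots, border-clipped and
    unassigned spots) are logged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    save_config(config, out / "config_resolved.yaml")
    sim_seed, overlap_seed = _spawn_seeds(config.seed, 2)

    truth = generate_dataset(
        config.population, config.optics, config.camera, out,
        n_frames=config.n_frames, seed=sim_seed,
    )
    log.info("simulated %d frames, %d cells", config.n_frames, len(truth))

    import tifffile

    from .simulate import ImageFrame
    from .geometry import sample_population

    all_spots: list[dict] = []
    all_counts: list[pd.DataFrame] = []
    n_border = n_unassigned = 0
    px_um = config.camera.pixel_size_um
    # regenerate geometries deterministically for truth masks
    rng_mask = np.random.default_rng(sim_seed)
    for k in range(config.n_frames):
        cells, _, _ = sample_population(config.population, rng_mask)
        spot_img = tifffile.imread(out / f"frame_{k}_spot.tif")
        seg_img = tifffile.imread(out / f"frame_{k}_seg.tif")
        spot_frame = ImageFrame(spot_img, config.camera.pixel_size, "spot", k)
        seg_frame = ImageFrame(seg_img, config.camera.pixel_size, "segmentation", k)
        mask = (
            truth_mask(cells, spot_img.shape, px_um) if config.use_truth_masks else None
        )
        spots, table = detect_frame(spot_frame, config.detection, mask=mask, seg_frame=seg_frame)
        # re-draw the population's molecule placements so rng_mask stays in
        # step with generate_dataset's stream
        n_border += sum(s.border_clipped for s in spots)
        n_unassigned += sum((not s.border_clipped) and s.cell_id < 0 for s in spots)
        for s in spots:
            all_spots.append(
                {"frame_id": k, "x_px": s.x, "y_px": s.y, "intensity": s.intensity,
                 "cell_id": s.cell_id, "border_clipped": s.border_clipped}
            )
        all_counts.append(table)
    spots_df = pd.DataFrame(
        all_spots, columns=["frame_id", "x_px", "y_px", "intensity", "cell_id", "border_clipped"]
    )
    counts_df = (
        pd.concat(all_counts, ignore_index=True)
        if all_counts
        else pd.DataFrame(columns=["cell_id", "area_um2", "length_um", "count", "frame_id"])
    )
    spots_df.to_csv(out / "spots.csv", index=False)
    counts_df.to_csv(out / "counts.csv", index=False)
    log.info(
        "detected %d spots (%d border-clipped, %d unassigned) in %d cells",
        len(spots_df), n_border, n_unassigned, len(counts_df),
    )

    # overlap curve + correction for a representative (median-length) cell
    from .geometry import CellGeometry

    med_len = float(truth["length_um"].median()) if len(truth) else config.population.length_mean
    rep_geom = CellGeometry(
        length=med_len,
        width=config.population.width,
        pressed=config.population.pressed,
        height_factor=config.population.height_factor if config.population.pressed else 1.0,
        area_factor=config.population.area_factor if config.population.pressed else 1.0,
    )
    rng_overlap = np.random.default_rng(overlap_seed)
    curve = undercount_curve(
        rep_geom,
        n_range=range(0, config.overlap.n_max + 1),
        resolution_nm=config.overlap.resolution_nm,
        reps=config.overlap.reps,
        rng=rng_overlap,
    )
    curve.to_csv(out / "curve.csv")
    result = infer_true_lambda(
        counts_df["count"].to_numpy(dtype=int) if len(counts_df) else np.array([], dtype=int),
        rep_geom,
        resolution_nm=config.overlap.resolution_nm,
        reps=config.overlap.reps,
        rng=rng_overlap,
    )
    (out / "lambda.json").write_text(json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in result.items()}, indent=2))

    stats_out: dict = {"lambda_hat": result["lambda_hat"], "lambda_ci": list(result["ci"])}
    if len(counts_df) >= 2:
        pooled = cstats.summarize(counts_df["count"])
        stats_out["pooled"] = pooled.as_dict()
        _, conc_summary = cstats.concentration(counts_df)
        stats_out["concentration"] = conc_summary
        bins = cstats.condition_on_size(
            counts_df, n_bins=config.statistics.n_bins,
            by=config.statistics.size_covariate, trim=config.statistics.trim,
        )
        stats_out["size_bins"] = [b.as_dict() for b in bins]
        stats_out["corrected_mean"] = cstats.maturation_correction(
            pooled.mean,
            config.statistics.maturation_time_min,
            config.statistics.doubling_time_min,
        )
    (out / "stats.json").write_text(json.dumps(stats_out, indent=2, default=float))
    return stats_out
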