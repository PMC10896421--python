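"""TIFF stack readers/writers, run configuration, and the pipeline driver.

Stacks travel as multi-page TIFF (one page per slice, 16-bit unsigned by
default), calibration frames as single-page TIFF (32-bit float for the
unit-mean flat, which is not representable as integers), cohort layout
as ``manifest.csv`` + per-animal stack files.  A run is described by a
YAML config; every output directory receives a ``run_manifest.json``
carrying the config hash and seed so a run can be reproduced from its
artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationFrames, ImageStack, normalize_flat
from .stats import pool_and_test, two_way_anova
from .volume import build_histogram, process_animal

__all__ = [
    "StackFormatError",
    "read_stack",
    "write_stack",
    "read_frame",
    "write_frame",
    "read_calibration_dir",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class StackFormatError(ValueError):
    """Raised for malformed or unsupported image files."""


def read_stack(
    path: str | Path,
    channel: str,
    pixel_size_um: float = 1.0,
    slice_thickness_um: float = 100.0,
    animal_id: str = "",
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`, pages in z order.

    Accepts single-sample grayscale pages (8/16-bit integer or 32-bit
    float); values are promoted to float counts unchanged.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as e:
        raise StackFormatError(f"cannot read TIFF stack {path}: {e}") from e
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(
            f"{path}: expected grayscale pages, got array of ndim {data.ndim} "
            "(multi-sample/RGB pages are unsupported)"
        )
    if data.shape[0] == 0:
        raise StackFormatError(f"{path}: zero pages")
    if not (np.issubdtype(data.dtype, np.integer)
            or np.issubdtype(data.dtype, np.floating)):
        raise StackFormatError(f"{path}: unsupported pixel dtype {data.dtype}")
    return ImageStack(
        channel=channel, data=data.astype(np.float64),
        pixel_size_um=pixel_size_um, slice_thickness_um=slice_thickness_um,
        animal_id=animal_id,
    )


def write_stack(stack: ImageStack, path: str | Path, dtype: str = "uint16") -> Path:
    """Write a stack as multi-page TIFF.

    ``dtype='uint16'`` rounds and clips to the camera's integer range;
    ``'float32'`` preserves fractional values (used for RR volumes).
    """
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype == "float32":
        data = stack.data.astype(np.float32)
    else:
        raise StackFormatError(f"unsupported output dtype {dtype!r}")
    tifffile.imwrite(path, data)
    return path


def read_frame(path: str | Path) -> np.ndarray:
    """Read a single-page TIFF calibration frame as a float 2D array."""
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim != 2:
        raise StackFormatError(f"{path}: calibration frame must be single-page 2D")
    return arr.astype(np.float64)


def write_frame(frame: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frame, dtype=np.float32))
    return path


def read_calibration_dir(caldir: str | Path) -> CalibrationFrames | None:
    """Load ``calibration_{dark,flat}_{nadh,fad}.tif`` frames if present."""
    caldir = Path(caldir)
    dark, flat = {}, {}
    for c in ("NADH", "FAD"):
        d = caldir / f"calibration_dark_{c.lower()}.tif"
        f = caldir / f"calibration_flat_{c.lower()}.tif"
        if d.exists():
            dark[c] = read_frame(d)
        if f.exists():
            flat[c] = normalize_flat(read_frame(f))
    if not dark and not flat:
        return None
    return CalibrationFrames(dark=dark, flat=flat)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Serialized (with its hash) into every output directory.  Flag-style
    overrides from the CLI are applied before validation.
    """

    manifest: str = ""
    calibration_dir: str | None = None
    output_dir: str = "results"
    # segmentation
    seg_method: str = "otsu"
    seg_channel: str = "nadh"
    fixed_threshold: float | None = None
    # redox ratio
    fad_floor: float | None = None
    histogram_bins: int = 100
    histogram_range: str = "percentile"
    mean_denominator: str = "tissue_voxels"  # or 'full_grid'
    # statistics
    ss_type: int = 2
    sidedness: str = "two"
    direction: str | None = None
    alpha: float = 0.05
    t_variant: str = "student"
    # outputs
    export_histograms: bool = True
    export_volumes: bool = False
    export_plots: bool = False
    # misc
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if self.calibration_dir and not Path(self.calibration_dir).exists():
            raise FileNotFoundError(
                f"calibration dir not found: {self.calibration_dir}")
        if self.mean_denominator not in ("tissue_voxels", "full_grid"):
            raise ValueError("mean_denominator must be 'tissue_voxels' or 'full_grid'")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline driver


def _plot_histogram(hdf: pd.DataFrame, summary, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(hdf["rr_bin_center"], hdf["density"], alpha=0.6)
    ax.axvline(summary.mean_rr, color="k", ls="--",
               label=f"mean RR = {summary.mean_rr:.2f}")
    ax.set_xlabel("redox ratio (NADH/FAD)")
    ax.set_ylabel("density")
    ax.set_title(f"{summary.animal_id} ({summary.genotype} {summary.sex})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    cohort_results: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)
    output_dir: Path | None = None


def _cohort_row(tissue: str, result) -> dict:
    tt = result.ttest
    return dict(
        tissue=tissue,
        F_genotype=result.anova.genotype.F, p_genotype=result.anova.genotype.p,
        F_sex=result.anova.sex.F, p_sex=result.anova.sex.p,
        F_interaction=result.anova.interaction.F,
        p_interaction=result.anova.interaction.p,
        pooled=result.pooled,
        t=tt.t if tt else np.nan,
        df=tt.df if tt else np.nan,
        p=tt.p if tt else np.nan,
        mean_wt=tt.mean_wt if tt else np.nan,
        mean_ko=tt.mean_ko if tt else np.nan,
        percent_change=result.percent_change
        if result.percent_change is not None else np.nan,
        notes="; ".join(result.notes),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Process every animal in the manifest and run the cohort statistics.

    Per-animal failures are collected and reported; the run fails only
    when a tissue ends with fewer than 2 animals per genotype.  Identical
    config + inputs give identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    manifest_path = Path(config.manifest)
    manifest = pd.read_csv(manifest_path)
    required = {"animal_id", "genotype", "sex", "tissue", "nadh_path", "fad_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")

    caldir = config.calibration_dir or manifest_path.parent
    frames = read_calibration_dir(caldir)
    if frames is None:
        logger.warning("no calibration frames found in %s; identity calibration",
                       caldir)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows, failures = [], {}
    for rec in manifest.itertuples(index=False):
        try:
            nadh = read_stack(manifest_path.parent / rec.nadh_path, "NADH",
                              animal_id=rec.animal_id)
            fad = read_stack(manifest_path.parent / rec.fad_path, "FAD",
                             animal_id=rec.animal_id)
            summary, vol = process_animal(
                nadh, fad, frames,
                animal_id=rec.animal_id, genotype=rec.genotype, sex=rec.sex,
                tissue=rec.tissue, seg_method=config.seg_method,
                seg_channel=config.seg_channel,
                fixed_threshold=config.fixed_threshold,
                fad_floor=config.fad_floor,
            )
            rows.append(asdict(summary))
            if config.export_histograms or config.export_plots:
                hist = build_histogram(vol, n_bins=config.histogram_bins,
                                       range_rule=config.histogram_range)
                centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
                hdf = pd.DataFrame({"rr_bin_center": centers,
                                    "density": hist.density})
                if config.export_histograms:
                    hdf.to_csv(outdir / f"{rec.animal_id}_histogram.csv",
                               index=False)
                if config.export_plots:
                    _plot_histogram(hdf, summary,
                                    outdir / f"{rec.animal_id}_histogram.png")
            if config.export_volumes:
                rr_img = np.where(vol.retained, vol.rr, 0.0)
                tifffile.imwrite(outdir / f"{rec.animal_id}_rr.tif",
                                 rr_img.astype(np.float32))
                sidecar = dict(animal_id=rec.animal_id,
                               n_mask_voxels=vol.mask.n_voxels,
                               excluded_voxels=vol.excluded_voxels,
                               config_hash=config.config_hash())
                (outdir / f"{rec.animal_id}_rr.json").write_text(
                    json.dumps(sidecar, indent=2))
        except Exception as e:  # collected, reported at the end
            logger.error("animal %s failed: %s", rec.animal_id, e)
            failures[str(rec.animal_id)] = str(e)

    summaries = pd.DataFrame(rows)
    if summaries.empty:
        raise RuntimeError(f"all animals failed: {failures}")
    summaries.to_csv(outdir / "animal_summaries.csv", index=False)

    cohort_rows = []
    for tissue, sub in summaries.groupby("tissue"):
        counts = sub.groupby("genotype")["animal_id"].count()
        if len(counts) < 2 or (counts < 2).any():
            raise RuntimeError(
                f"tissue {tissue!r} has fewer than 2 animals per genotype "
                f"after failures ({counts.to_dict()}); cohort degenerate"
            )
        anova = two_way_anova(sub, response="mean_rr", alpha=config.alpha,
                              ss_type=config.ss_type)
        result = pool_and_test(sub, anova, response="mean_rr",
                               sidedness=config.sidedness,
                               direction=config.direction, tissue=tissue,
                               t_variant=config.t_variant)
        cohort_rows.append(_cohort_row(tissue, result))
    cohort_results = pd.DataFrame(cohort_rows)
    cohort_results.to_csv(outdir / "cohort_results.csv", index=False)

    run_manifest = dict(
        config=asdict(config), config_hash=config.config_hash(),
        rng_seed=config.rng_seed, n_animals=len(summaries),
        failures=failures,
    )
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2,
                                                         default=str))
    return PipelineResult(summaries=summaries, cohort_results=cohort_results,
                          failures=failures, output_dir=outdir)
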