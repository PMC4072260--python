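"""End-to-end study orchestration at desk scale.

``run_study`` assembles the full comparison: generate (or ingest) a cohort of
trichrome tiles, quantify fibrosis on every slide with the three estimators —
colocalization, the trainable pixel classifier, and the stereology point grid
— add simulated (or supplied) pathologist scores, and emit the comparison
report: per-slide measurements, summary statistics, correlation matrix,
Friedman + Wilcoxon paired comparisons, regression and Bland-Altman plots,
plus run metadata (config hash, seeds, package version) for reproducibility.

One tile stands for one slide.  Outputs are deterministic for a fixed config:
identical seeds give byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement_stats import (
    MethodMeasurements,
    bland_altman,
    fit_regression,
    friedman_test,
    pairs_table,
    pearson_matrix,
    summarize_methods,
    wilcoxon_pairs,
    with_pathologist_mean,
)
from .pattern_classifier import (
    classify_tile,
    load_model,
    regions_from_phantom,
    render_class_markup,
    save_model,
    tissue_fibrosis_pct,
    train_classifier,
)
from .stain_deconvolution import StainMatrix, quantify_tile
from .stereology import point_count_on_phantom
from .synthetic_histology import (
    default_stain_model,
    generate_cohort,
    load_phantom,
    load_tile,
    save_tile,
    simulate_pathologist,
)

logger = logging.getLogger("fibroquant")

DIGITAL_METHODS = ("colocalization", "genie")
DEFAULT_FRIEDMAN_COLUMNS = ["stereology", "colocalization", "genie", "pathologist_mean"]
DEFAULT_PAIRS = [
    ("colocalization", "stereology"),
    ("genie", "stereology"),
    ("pathologist_mean", "stereology"),
    ("colocalization", "genie"),
]
MEASUREMENTS_SCHEMA_VERSION = 1
MEASUREMENTS_COLUMNS = [
    "slide_id",
    "true_fibrosis_pct",
    "stereology",
    "colocalization",
    "genie",
    "pathologist_week0",
    "pathologist_week2",
    "pathologist_mean",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and slide)."""


@dataclass
class StudyConfig:
    """Everything needed to re-run a study bit-for-bit."""

    mode: str = "synthetic"  # "synthetic" | "tiles"
    n_slides: int = 116
    fibrosis_range: tuple[float, float] = (0.0, 90.0)
    tile_shape: tuple[int, int] = (256, 256)
    noise_sd: float = 0.02
    thresholds: tuple[float, float, float] = (0.15, 0.15, 0.15)
    grid_interval: int = 8  # scaled to the desk-scale tile (200 px on WSI scans)
    pattern_size: int = 2
    classifier_window: int = 7
    iteration_budget: int = 1000
    pathologist_noise_sd: float = 4.0
    pathologist_step: float = 5.0
    reference: str = "stereology"
    seed: int = 0
    out_dir: str = "study_out"
    tiles_manifest: str | None = None  # tiles mode: cohort manifest CSV
    model_path: str | None = None  # tiles mode: pre-trained classifier
    write_markups: bool = False
    write_plots: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResult:
    measurements: MethodMeasurements
    summary: pd.DataFrame
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame
    friedman: object
    pairs: pd.DataFrame
    out_dir: Path
    truths: np.ndarray | None = None
    files: dict[str, str] = field(default_factory=dict)


def _load_cohort_from_manifest(manifest_path: str) -> list:
    from .synthetic_histology import CohortTruth

    manifest = Path(manifest_path)
    base = manifest.parent
    df = pd.read_csv(manifest)
    cohort = []
    for _, row in df.iterrows():
        tile_path = base / str(row["tile_path"])
        if not tile_path.exists():
            raise StageError(f"stage ingest: tile file missing for slide {row['slide_id']}")
        label_path = base / str(row["label_path"]) if "label_path" in row else None
        if label_path is None or not label_path.exists():
            raise StageError(f"stage ingest: label map missing for slide {row['slide_id']}")
        phantom = load_phantom(label_path)
        tile = load_tile(tile_path)
        truth = float(row.get("true_fibrosis_pct", np.nan))
        if np.isnan(truth):
            truth = 100.0 * phantom.fibrosis_fraction_of_tissue
        cohort.append(CohortTruth(str(row["slide_id"]), truth, phantom, tile))
    return cohort


def run_study(config: StudyConfig) -> StudyResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stain_model = default_stain_model()
    matrix = StainMatrix(stain_model.od_vectors)

    # --- stage: cohort ----------------------------------------------------
    if config.mode == "synthetic":
        cohort = generate_cohort(
            config.n_slides,
            config.fibrosis_range,
            stain_model,
            noise_sd=config.noise_sd,
            seed=config.seed,
            tile_shape=tuple(config.tile_shape),
        )
    elif config.mode == "tiles":
        if not config.tiles_manifest:
            raise StageError("stage ingest: tiles mode requires tiles_manifest")
        cohort = _load_cohort_from_manifest(config.tiles_manifest)
    else:
        raise StageError(f"stage config: unknown mode {config.mode!r}")
    logger.info("cohort of %d slides ready", len(cohort))

    # --- stage: classifier training ---------------------------------------
    if config.model_path:
        model = load_model(config.model_path)
    else:
        regions = []
        for s in cohort[: min(3, len(cohort))]:
            regions.extend(
                regions_from_phantom(s.phantom, s.tile, seed=config.seed + 3)
            )
        try:
            model, report = train_classifier(
                regions,
                iteration_budget=config.iteration_budget,
                seed=config.seed + 4,
                window=config.classifier_window,
                background_intensity=stain_model.background_intensity,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage train: {exc}") from exc
        logger.info("classifier trained, training accuracy %.4f", report.training_accuracy)
        save_model(model, out_dir / "classifier_model.bin")

    # --- stage: per-slide quantification ----------------------------------
    rows = []
    for i, s in enumerate(cohort):
        try:
            coloc = quantify_tile(
                s.tile, matrix, stain_model.background_intensity, config.thresholds
            )
            class_map = classify_tile(s.tile, model)
            genie_pct = tissue_fibrosis_pct(class_map)
            stereo = point_count_on_phantom(
                s.phantom,
                sampling_interval=config.grid_interval,
                pattern_size=config.pattern_size,
                offset="random",
                seed=config.seed + 100 + i,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage quantify ({s.slide_id}): {exc}") from exc
        rows.append(
            {
                "slide_id": s.slide_id,
                "true_fibrosis_pct": s.true_fibrosis_pct,
                "stereology": stereo.pct,
                "colocalization": coloc.fibrosis_pct,
                "genie": genie_pct,
            }
        )
        if config.write_markups:
            save_tile(coloc.markup, out_dir / f"{s.slide_id}_coloc_markup.png")
            save_tile(render_class_markup(class_map), out_dir / f"{s.slide_id}_genie_markup.png")
        logger.info("slide %s quantified (%d/%d)", s.slide_id, i + 1, len(cohort))
    df = pd.DataFrame(rows).set_index("slide_id")

    # --- stage: pathologist scores ----------------------------------------
    truths = df["true_fibrosis_pct"].to_numpy()
    df["pathologist_week0"] = simulate_pathologist(
        truths, config.pathologist_noise_sd, config.pathologist_step, seed=config.seed + 1
    )
    df["pathologist_week2"] = simulate_pathologist(
        truths, config.pathologist_noise_sd, config.pathologist_step, seed=config.seed + 2
    )
    df = with_pathologist_mean(df)

    # --- stage: comparison report ------------------------------------------
    method_cols = [c for c in df.columns if c != "true_fibrosis_pct"]
    measurements = MethodMeasurements(df[method_cols].clip(0.0, 100.0))
    summary = summarize_methods(measurements)
    corr, corr_p = pearson_matrix(measurements)
    friedman = friedman_test(measurements, DEFAULT_FRIEDMAN_COLUMNS)
    comparisons = wilcoxon_pairs(measurements, DEFAULT_PAIRS)
    pairs = pairs_table(comparisons)

    files = {}
    out = df.reset_index()[MEASUREMENTS_COLUMNS]
    _write_csv(out, out_dir / "measurements.csv", files, "measurements")
    _write_csv(summary.reset_index(names="method"), out_dir / "summary.csv", files, "summary")
    _write_csv(corr.reset_index(names="method"), out_dir / "correlations.csv", files, "correlations")
    _write_csv(
        corr_p.reset_index(names="method"), out_dir / "correlation_pvalues.csv", files, "correlation_pvalues"
    )
    _write_csv(pairs.reset_index(), out_dir / "pairs.csv", files, "pairs")

    if config.write_plots:
        from .plots import bland_altman_plot, regression_plot

        ref = measurements.column(config.reference)
        for method in ("colocalization", "genie", "pathologist_mean"):
            ba = bland_altman(ref, measurements.column(method))
            p = out_dir / f"bland_altman_{method}.png"
            bland_altman_plot(ba, f"{method} vs {config.reference}", p)
            files[f"bland_altman_{method}"] = p.name
            for transform in ("raw", "ln"):
                fit = fit_regression(ref, measurements.column(method), transform)
                p = out_dir / f"regression_{method}_{transform}.png"
                regression_plot(fit, config.reference, method, p)
                files[f"regression_{method}_{transform}"] = p.name

    meta = {
        "package_version": __version__,
        "schema_version": MEASUREMENTS_SCHEMA_VERSION,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "n_slides": len(cohort),
        "friedman": {
            "chi_square": friedman.chi_square,
            "df": friedman.df,
            "p_value": friedman.p_value,
        },
    }
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    files["run_meta"] = "run_meta.json"

    return StudyResult(
        measurements=measurements,
        summary=summary,
        correlations=corr,
        correlation_p=corr_p,
        friedman=friedman,
        pairs=pairs,
        out_dir=out_dir,
        truths=truths,
        files=files,
    )


def _write_csv(df: pd.DataFrame, path: Path, files: dict, key: str) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
    files[key] = path.name
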