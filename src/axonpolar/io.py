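"""Measurement-table CSV schema, run configuration, and the pipeline driver.

The measurement CSV is UTF-8, comma-separated, header mandatory, decimal
point, one row per neurite.  Required columns::

    neurite_id, dish_id, pair_id, paradigm, length_um,
    tau_max, tau_min, map2_max, map2_min,
    soma_diameter_um, open_day, excluded

Optional columns carried when present: ``chamber_length_um``,
``length_at_opening_um``, ``i_diff``, ``is_axon``.  Floats are written as
shortest-round-trip decimal text, so a write/read cycle preserves values
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import competition, quantify
from .model import (
    DEFAULT_LC_GRID,
    DEFAULT_P_DEFINITIVE,
    DEFAULT_SIGMA_GRID,
    FitError,
    definitive_length,
    fit_sigmoid,
    rmse_landscape,
)
from .synthetic import (
    IntensityModel,
    SyntheticConfig,
    generate_pair_dataset,
    generate_single_dataset,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "FormatError",
    "PipelineError",
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "run_pipeline",
]

logger = logging.getLogger("axonpolar")

REQUIRED_COLUMNS = [
    "neurite_id",
    "dish_id",
    "pair_id",
    "paradigm",
    "length_um",
    "tau_max",
    "tau_min",
    "map2_max",
    "map2_min",
    "soma_diameter_um",
    "open_day",
    "excluded",
]
OPTIONAL_COLUMNS = ["chamber_length_um", "length_at_opening_um", "i_diff", "is_axon"]


def write_profile_images(directory, record_id: str, tau_image, map2_image, path_df) -> None:
    """Image-mode output: one 16-bit grayscale TIFF per channel plus a
    path-coordinates CSV (x_px, y_px ordered from the soma)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{record_id}_tau.tif", np.asarray(tau_image, dtype=np.uint16))
    tifffile.imwrite(directory / f"{record_id}_map2.tif", np.asarray(map2_image, dtype=np.uint16))
    path_df.to_csv(directory / f"{record_id}_path.csv", index=False)


def read_profile_images(directory, record_id: str):
    """Load the two channel TIFFs and path CSV written by
    :func:`write_profile_images`; returns (tau_image, map2_image, path_df)."""
    import tifffile

    directory = Path(directory)
    tau = tifffile.imread(directory / f"{record_id}_tau.tif")
    map2 = tifffile.imread(directory / f"{record_id}_map2.tif")
    path_df = pd.read_csv(directory / f"{record_id}_path.csv")
    return tau, map2, path_df


class FormatError(ValueError):
    """Malformed measurement CSV (e.g. a missing required column)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _row_problems(row: pd.Series) -> list[str]:
    problems = []
    if not np.isfinite(row["length_um"]) or row["length_um"] <= 0:
        problems.append(f"length_um must be > 0, got {row['length_um']}")
    for col in ("tau_max", "tau_min", "map2_max", "map2_min"):
        v = row[col]
        if not np.isfinite(v) or v < 0:
            problems.append(f"{col} must be a nonnegative number, got {v}")
    if not problems:
        if row["tau_max"] < row["tau_min"]:
            problems.append("tau_max < tau_min")
        if row["map2_max"] < row["map2_min"]:
            problems.append("map2_max < map2_min")
    return problems


def read_measurements(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate a measurement CSV.

    Returns ``(records, errors)``: valid rows (with ``i_diff``/``is_axon``
    recomputed from the extrema) and a table of rejected rows with a
    ``reason`` column.  A missing required column raises
    :class:`FormatError` naming the column.
    """
    df = pd.read_csv(
        path,
        dtype={"neurite_id": str, "dish_id": str, "pair_id": str, "paradigm": str},
        keep_default_na=True,
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    for col in ("pair_id", "neurite_id", "dish_id", "paradigm"):
        df[col] = df[col].fillna("")

    bad_idx, reasons = [], []
    for idx, row in df.iterrows():
        problems = _row_problems(row)
        if problems:
            bad_idx.append(idx)
            reasons.append("; ".join(problems))
    errors = df.loc[bad_idx].copy()
    errors["reason"] = reasons
    good = df.drop(index=bad_idx).reset_index(drop=True)
    if len(good):
        good = quantify.add_idiff(good)
        good["excluded"] = good["excluded"].astype(bool)
        good["is_axon"] = good["is_axon"].astype(int)
    if len(errors):
        logger.warning("rejected %d of %d rows from %s", len(errors), len(df), path)
    return good, errors


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement table, required columns first, full precision."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, columns=cols, index=False)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run (fully serializable)."""

    outdir: str = "axonpolar_run"
    seed: int = 0
    input_csv: str | None = None  # analyze this CSV instead of simulating
    threshold: float = 1.0
    bin_width: float = 20.0
    p_definitive: float = DEFAULT_P_DEFINITIVE
    Lc_grid: tuple[float, float, float] = DEFAULT_LC_GRID
    sigma_grid: tuple[float, float, float] = DEFAULT_SIGMA_GRID
    map_length_max: float = 200.0
    map_step: float = 2.0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_pairs_simultaneous: int = 18
    n_pairs_stepwise: int = 11
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            intensity = syn.pop("intensity", None)
            if intensity is not None:
                syn["intensity"] = IntensityModel(**intensity)
            for key in ("length_range", "first_length_range"):
                if syn.get(key) is not None:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SyntheticConfig(**syn)
        for key in ("Lc_grid", "sigma_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _setup_logging(outdir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate (optional) → quantify → fit → sweep → landscape → pairs.

    Writes every artifact into ``config.outdir`` together with the echoed
    configuration and a log; identical config + seed reproduce every CSV
    byte for byte.  Returns the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    config.to_json(outdir / "config.json")
    logger.info("run seed = %d", config.seed)
    summary: dict = {"seed": config.seed}

    stage = "simulate"
    try:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        if config.input_csv is not None:
            single, errors = read_measurements(config.input_csv)
            if len(errors):
                errors.to_csv(outdir / "rejected_rows.csv", index=False)
            pairs_sim = pairs_step = None
        else:
            single = generate_single_dataset(syn)
            pairs_sim = generate_pair_dataset(
                dataclasses.replace(syn, n_pairs=config.n_pairs_simultaneous, seed=config.seed + 1),
                "simultaneous",
            )
            pairs_step = generate_pair_dataset(
                dataclasses.replace(syn, n_pairs=config.n_pairs_stepwise, seed=config.seed + 2),
                "stepwise",
            )
        stage = "quantify"
        single = quantify.add_idiff(single, threshold=config.threshold)
        write_measurements(single, outdir / "dataset_single.csv")
        kept = single[~single["excluded"]]
        logger.info(
            "single-neurite dataset: %d records, %d kept after exclusion",
            len(single),
            len(kept),
        )

        stage = "fit"
        fit_single = fit_sigmoid(
            kept["length_um"].to_numpy(float),
            kept["is_axon"].to_numpy(float),
            p_definitive=config.p_definitive,
        )
        fit_single.to_json(outdir / "fit_single.json")
        Lt_ref = definitive_length(fit_single)
        summary["single"] = fit_single.summary()
        logger.info(
            "single fit: Lc=%.1f μm sigma=%.1f μm Lt=%.1f μm",
            fit_single.Lc,
            fit_single.sigma,
            Lt_ref,
        )

        stage = "sweep"
        sweep = quantify.threshold_sweep(single, bin_width=config.bin_width)
        sweep.to_csv(outdir / "sweep.csv")
        summary["sweep_monotone"] = {f"{t:.2f}": m for t, m in sweep.monotone.items()}

        stage = "landscape"
        scape = rmse_landscape(
            kept["length_um"].to_numpy(float),
            kept["is_axon"].to_numpy(float),
            Lc_grid=config.Lc_grid,
            sigma_grid=config.sigma_grid,
        )
        scape.to_csv(outdir / "landscape.csv")
        summary["landscape_argmin"] = {
            "Lc_um": scape.argmin[0],
            "sigma_um": scape.argmin[1],
            "rmse": scape.min_rmse,
        }

        stage = "pairs"
        if pairs_sim is not None:
            for name, pairs in (("simultaneous", pairs_sim), ("stepwise", pairs_step)):
                pairs = quantify.add_idiff(pairs, threshold=config.threshold)
                write_measurements(pairs, outdir / f"pairs_{name}.csv")
                block: dict = {
                    "outcomes": competition.pair_outcome_counts(
                        pairs, config.threshold
                    )
                }
                fit_pooled = competition.fit_pair_pooled(
                    pairs, p_definitive=config.p_definitive
                )
                fit_pooled.to_json(outdir / f"fit_pairs_{name}.json")
                block["pooled"] = fit_pooled.summary()
                delta, se = competition.lc_shift(fit_single, fit_pooled)
                block["lc_shift_vs_single_um"] = {"delta": delta, "se": se}
                try:
                    fit_cond = competition.fit_conditional(
                        pairs, Lt_ref, p_definitive=config.p_definitive
                    )
                    block["conditional"] = fit_cond.summary()
                    d2, se2 = competition.lc_shift(fit_pooled, fit_cond)
                    block["lc_shift_conditional_um"] = {"delta": d2, "se": se2}
                except FitError as err:
                    # a single-class conditional subset is a property of a
                    # small cohort, not a stage failure; record and move on
                    block["conditional"] = {"error": str(err)}
                    logger.warning("conditional fit (%s): %s", name, err)
                if name == "stepwise":
                    block["patterns"] = (
                        competition.stepwise_patterns(pairs)["pattern"]
                        .value_counts()
                        .to_dict()
                    )
                summary[name] = block

            stage = "map"
            grid = np.arange(0.0, config.map_length_max + config.map_step, config.map_step)
            pmap = competition.probability_map(fit_single, grid, grid)
            pmap.grid().to_csv(outdir / "map_simultaneous.csv", index=False)
            pmap.save_png(outdir / "map_simultaneous.png")

        stage = "summary"
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except Exception as err:
        logger.error("stage %r failed: %s", stage, err)
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
    logger.info("run complete: %s", outdir)
    return outdir
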