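"""End-to-end orchestration: simulate -> extract -> stats -> classify -> report.

The pipeline runs the synthetic experiment (or ingests user-supplied raw
tables), derives all fluorescence and morphology traits into the long trait
table, applies the plant-exclusion filter (plants that died or never grew
are removed across all days), runs the temporal statistics and cross-time
correlation analyses, fits the per-treatment genotype classifiers, and
writes every product plus a manifest with file hashes.  A fixed seed makes
the whole run reproducible file-for-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from phenoheat import classify, fluortraits, morphometry, stats, synthdata

log = logging.getLogger("phenoheat")


# ---------------------------------------------------------------------------
# raster I/O (masks as 8-bit PNG, thermal as 32-bit TIFF in deg C)


def write_mask_png(mask: morphometry.RosetteMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_mask_png(path: str | Path, scale: float) -> morphometry.RosetteMask:
    return morphometry.clean_mask(iio.imread(Path(path)), scale=scale)


def write_thermal_tiff(raster: morphometry.ThermalRaster, path: str | Path) -> None:
    tifffile.imwrite(Path(path), raster.grid.astype(np.float32))


def read_thermal_tiff(path: str | Path) -> morphometry.ThermalRaster:
    return morphometry.ThermalRaster(grid=tifffile.imread(Path(path)).astype(np.float64))


# ---------------------------------------------------------------------------
# exclusion filter


def apply_exclusion_filter(
    table: pd.DataFrame, registry: pd.DataFrame
) -> pd.DataFrame:
    """Remove all rows of excluded plants (died or failed to grow).

    Mirrors the screening rule of the original experiment: a flagged plant
    is dropped across *all* imaging days, so the retained table holds a
    complete day series per plant.
    """
    excluded = set(registry.loc[registry["excluded"].astype(bool), "plant_id"])
    kept = table[~table["plant_id"].isin(excluded)].reset_index(drop=True)
    n_before = table["plant_id"].nunique()
    n_after = kept["plant_id"].nunique()
    log.info(
        "exclusion filter: %d of %d plants removed, %d retained",
        len(excluded), n_before, n_after,
    )
    if n_after == 0:
        log.warning("exclusion filter removed every plant")
    return kept


# ---------------------------------------------------------------------------
# simulation -> trait table


def extract_day_traits(
    state: synthdata.PlantDayState,
    raw: fluortraits.RawFluorescence,
    mask: morphometry.RosetteMask,
    thermal: morphometry.ThermalRaster,
) -> dict[str, float]:
    """All trait values of one plant-day from its three measurement modes."""
    traits = fluortraits.fluor_trait_dict(raw)
    traits.update(morphometry.extract_morpho_traits(mask).as_dict())
    traits["temperature"] = morphometry.rosette_temperature(mask, thermal)
    return traits


def simulate_trait_table(
    params: synthdata.SimulationParams,
    n_reps: int = 20,
    grid: tuple[int, int] = (180, 180),
    scale: float = 0.6,
    design: synthdata.ExperimentDesign | None = None,
    raster_out: Path | None = None,
) -> tuple[synthdata.ExperimentDesign, pd.DataFrame, pd.DataFrame]:
    """Run simulation + trait extraction in memory.

    Returns ``(design, states_frame, trait_table)`` with the trait table in
    long format, *before* the exclusion filter.  With ``raster_out`` set,
    masks (PNG) and thermal rasters (TIFF) are also written there.
    """
    if design is None:
        design = synthdata.build_design(n_reps, params.seed)
    states = synthdata.simulate_experiment(design, params)
    if raster_out is not None:
        (raster_out / "masks").mkdir(parents=True, exist_ok=True)
        (raster_out / "thermal").mkdir(parents=True, exist_ok=True)
    records = []
    for j, state in enumerate(states):
        mask = synthdata.render_rosette_mask(
            state, grid=grid, scale=scale, seed=params.seed * 1_000_003 + j
        )
        raw = synthdata.simulate_fluorescence_day(
            state, design.light_protocol, params, seed=params.seed * 1_000_003 + j
        )
        thermal = synthdata.simulate_thermal_day(
            mask, state, params, seed=params.seed * 1_000_003 + j
        )
        if raster_out is not None:
            stem = f"{state.plant_id}_das{state.das:+d}"
            write_mask_png(mask, raster_out / "masks" / f"{stem}.png")
            write_thermal_tiff(thermal, raster_out / "thermal" / f"{stem}.tif")
        records.append(
            {
                "plant_id": state.plant_id,
                "genotype": state.genotype,
                "treatment": state.treatment,
                "das": state.das,
                "traits": extract_day_traits(state, raw, mask, thermal),
            }
        )
    table = fluortraits.assemble_trait_table(records)
    return design, synthdata.states_frame(states), table


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    out_dir: str = "phenoheat_run"
    n_reps: int = 20
    scale_mm_per_px: float = 0.6
    grid: tuple[int, int] = (180, 180)
    params: synthdata.SimulationParams = field(default_factory=synthdata.SimulationParams)
    simulate: bool = True
    raw_fluor_csv: str | None = None  # ingestion path when simulate=False
    trait_csv: str | None = None
    write_rasters: bool = True
    run_stats: bool = True
    run_correlogram: bool = True
    run_classifier: bool = True
    correlogram_trait: str = "Fq_Lss5"
    classifier_k: int = 5
    classifier_lambdas: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("params", {})
        cfg = cls(**data)
        if sim:
            cfg.params = synthdata.SimulationParams(**sim)
        cfg.params.seed = cfg.seed
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["grid"] = list(self.grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate(self) -> None:
        self.params.validate()
        if not self.simulate:
            if self.trait_csv is None:
                raise ValueError("simulate=False requires trait_csv (or raw inputs)")
            if not Path(self.trait_csv).exists():
                raise FileNotFoundError(self.trait_csv)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest.

    Outputs under ``config.out_dir``: ``registry.csv``, ``states.csv``,
    ``traits.csv`` (post-filter), ``masks/``, ``thermal/`` (optional),
    ``stats_treated_vs_control.csv``, ``stats_genotype.csv``,
    ``stats_interactions.csv``, ``correlogram.csv``, ``classifier_report.csv``
    and ``manifest.json``.  Idempotent for a fixed seed.
    """
    t_start = time.perf_counter()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_times: dict[str, float] = {}

    def _stage(name: str):
        log.info("stage %s", name)
        stage_times[name] = time.perf_counter()

    def _done(name: str):
        stage_times[name] = round(time.perf_counter() - stage_times[name], 3)

    # --- stage 1: simulate + extract (or ingest) ---
    if config.simulate:
        _stage("simulate")
        config.params.seed = config.seed
        design, states_df, table = simulate_trait_table(
            config.params,
            n_reps=config.n_reps,
            grid=config.grid,
            scale=config.scale_mm_per_px,
            raster_out=out if config.write_rasters else None,
        )
        registry = synthdata.registry_frame(design)
        registry.to_csv(out / "registry.csv", index=False)
        states_df.to_csv(out / "states.csv", index=False)
        written += [out / "registry.csv", out / "states.csv"]
        _done("simulate")
    else:
        _stage("ingest")
        table = pd.read_csv(config.trait_csv)
        registry = (
            table[["plant_id"]].drop_duplicates().assign(excluded=False)
        )
        _done("ingest")

    # --- stage 2: exclusion filter ---
    _stage("filter")
    table = apply_exclusion_filter(table, registry)
    table.to_csv(out / "traits.csv", index=False)
    written.append(out / "traits.csv")
    _done("filter")

    # --- stage 3: statistics ---
    if config.run_stats:
        _stage("stats")
        tvc = stats.treated_vs_control_tests(table)
        gvt = stats.genotype_tests(table)
        inter_rows = []
        for trait in sorted(table["trait"].unique()):
            for hs in ("HS3h", "HS6h", "HS9h"):
                try:
                    res = stats.fit_interaction_model(table, trait, hs)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                for term, sr in res.items():
                    inter_rows.append(
                        (trait, hs, term, sr.estimate, sr.se, sr.statistic, sr.df, sr.p, sr.stars)
                    )
        inter = pd.DataFrame(
            inter_rows,
            columns=["trait", "treatment", "term", "estimate", "se", "t", "df", "p", "stars"],
        )
        tvc.to_csv(out / "stats_treated_vs_control.csv", index=False)
        gvt.to_csv(out / "stats_genotype.csv", index=False)
        inter.to_csv(out / "stats_interactions.csv", index=False)
        written += [
            out / "stats_treated_vs_control.csv",
            out / "stats_genotype.csv",
            out / "stats_interactions.csv",
        ]
        _done("stats")

    # --- stage 4: cross-time correlogram ---
    if config.run_correlogram:
        _stage("correlogram")
        days = sorted(table["das"].unique())
        grid_df = stats.cross_time_grid(
            table, config.correlogram_trait, "area", days, stratify=("treatment",)
        )
        by_geno = stats.cross_time_grid(
            table,
            config.correlogram_trait,
            "area",
            [d for d in (0, 1, 7) if d in days],
            stratify=("genotype", "treatment"),
        )
        grid_df.to_csv(out / "correlogram.csv", index=False)
        by_geno.to_csv(out / "correlogram_by_genotype.csv", index=False)
        written += [out / "correlogram.csv", out / "correlogram_by_genotype.csv"]
        _done("correlogram")

    # --- stage 5: classification ---
    if config.run_classifier:
        _stage("classify")
        rows = []
        for group in synthdata.TREATMENTS:
            fm = classify.build_features(table, group)
            cv = classify.cv_accuracy(
                fm,
                k=config.classifier_k,
                seed=config.seed,
            )
            top = classify.rank_traits(cv.models[int(np.argmax(cv.fold_accuracies))], top_n=10)
            rows.append(
                {
                    "group": group,
                    "trait_set": "all",
                    "accuracy": cv.accuracy,
                    "n_samples": cv.n_samples,
                    "n_plants": cv.n_plants,
                    "top_traits": ";".join(top),
                }
            )
        report = pd.DataFrame(rows)
        report.to_csv(out / "classifier_report.csv", index=False)
        written.append(out / "classifier_report.csv")
        _done("classify")

    manifest = {
        "seed": config.seed,
        "n_reps": config.n_reps,
        "stages": stage_times,
        "elapsed_s": round(time.perf_counter() - t_start, 3),
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# headline-pattern summaries


def qymax_recovery_day(
    table: pd.DataFrame,
    genotype: str,
    treatment: str = "HS6h",
    alpha: float = 0.05,
    equivalence_margin: float = 0.02,
) -> int | None:
    """First DAS >= 0 at which QY max no longer differs from control.

    "No longer differs" means the treated-vs-control t-test is
    non-significant at ``alpha`` *or* the mean deficit is below the
    practical-equivalence margin (a quarter of the smallest injected dip),
    and the group stays recovered on all later days.
    """
    sub = table[(table["trait"] == "QYmax") & (table["genotype"] == genotype)]
    days = sorted(d for d in sub["das"].unique() if d >= 0)
    recovered: list[bool] = []
    for das in days:
        ctrl = sub[(sub["treatment"] == "control") & (sub["das"] == das)]["value"].to_numpy()
        trt = sub[(sub["treatment"] == treatment) & (sub["das"] == das)]["value"].to_numpy()
        res = stats.students_ttest(trt, ctrl)
        recovered.append(res.p >= alpha or abs(res.estimate) < equivalence_margin)
    for i, das in enumerate(days):
        if all(recovered[i:]):
            return das
    return None
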