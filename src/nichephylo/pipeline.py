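"""End-to-end orchestration: ingest -> SDMs -> null tests -> overlap ->
conservatism, from one declarative configuration.

The stages mirror a presence-only niche-conservatism study: read and
align the rasters and occurrence records, deduplicate localities to one
per species per cell, drop species below the minimum unique-locality
count (default 4), prune correlated variables (default |r| >= 0.7), fit
one maximum-entropy SDM per species (default 500 iterations), test each
against the target-group null model (default 100 replicates), exclude
species whose models are not significant, compute pairwise Hellinger's
I and clade summaries, read patristic distances from the tree, and run
the conservatism correlation.  Every stage logs record counts and all
intermediate artefacts are written to the output directory.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geodata, maxent_sdm, null_model, niche_overlap, conservatism
from .errors import ConfigError, DataError
from .phylo_metrics import patristic_matrix, read_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for a full pipeline run."""

    env_dir: str = ""
    occurrences: str = ""
    pool: str = ""
    tree: str = ""
    out_dir: str = "results"
    clade_partition: str = ""          # optional CSV: species,clade
    layer_kinds: str = ""              # optional CSV: layer,kind
    min_localities: int = 4
    correlation_cutoff: float = 0.7
    reg_multiplier: float = 1.0
    max_iterations: int = 500
    null_replicates: int = 100
    feature_mode: str = "auto"
    exclude_nonsignificant: bool = True
    run_mantel: bool = False
    mantel_permutations: int = 999
    seed: int = 0

    RANGES = {"min_localities": (1, None), "correlation_cutoff": (0.0, 1.0),
              "reg_multiplier": (0.0, None), "max_iterations": (1, None),
              "null_replicates": (1, None), "mantel_permutations": (1, None)}


def validate_config(source: str | Path | dict) -> tuple[PipelineConfig | None,
                                                        list[str]]:
    """Parse and validate a YAML config; returns (config, violations).

    All violations are collected, not just the first: missing required
    paths, out-of-range thresholds and unknown keys are each reported.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            return None, ["config must be a mapping"]
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for key in ("env_dir", "occurrences", "pool", "tree"):
        val = getattr(cfg, key)
        if not val:
            errors.append(f"missing required path: {key}")
        elif not Path(val).exists():
            errors.append(f"path does not exist: {key} = {val}")
    for key, (lo, hi) in PipelineConfig.RANGES.items():
        val = getattr(cfg, key)
        if lo is not None and val < lo:
            errors.append(f"{key} = {val} below minimum {lo}")
        if hi is not None and val > hi:
            errors.append(f"{key} = {val} above maximum {hi}")
    if cfg.feature_mode != "auto":
        classes = [c.strip() for c in cfg.feature_mode.split(",")]
        unknown = set(classes) - set(maxent_sdm.AUTO_THRESHOLDS)
        if unknown:
            errors.append(f"unknown feature classes: {sorted(unknown)}")
    return (None, errors) if errors else (cfg, [])


def _read_env(cfg: PipelineConfig) -> geodata.EnvStack:
    env_dir = Path(cfg.env_dir)
    paths = sorted(env_dir.glob("*.asc"))
    if not paths:
        raise DataError(f"no .asc rasters in {env_dir}")
    kinds_map: dict[str, str] = {}
    if cfg.layer_kinds and Path(cfg.layer_kinds).is_file():
        tbl = pd.read_csv(cfg.layer_kinds)
        kinds_map = dict(zip(tbl["layer"], tbl["kind"]))
    kinds = [kinds_map.get(p.stem, geodata.CONTINUOUS) for p in paths]
    return geodata.read_env_stack(paths, kinds)


@dataclass
class RunReport:
    """All pipeline outputs plus reproducibility metadata."""

    config: PipelineConfig
    species_table: pd.DataFrame
    overlap_matrix: pd.DataFrame
    clade_summary: pd.DataFrame | None
    conservatism_result: conservatism.ConservatismResult | None
    excluded: list[str]
    wall_clock_s: float
    stage_log: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write artefacts under ``config.out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []

    def log(msg: str) -> None:
        stage_log.append(msg)
        logger.info(msg)

    def fail(stage: str, exc: Exception):
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    # ingest
    try:
        env = _read_env(config)
        occ = geodata.read_occurrences(config.occurrences)
        tree = read_tree(Path(config.tree))
    except Exception as exc:
        fail("ingest", exc)
    log(f"ingest: {env.n_layers} layers, {len(occ)} occurrence records, "
        f"{len(tree.tip_labels)} tree tips")

    # dedup / filter
    try:
        occ = geodata.deduplicate(geodata.assign_cells(occ, env.grid, mask=env.mask))
        retained, excluded_few = geodata.filter_min_localities(
            occ, config.min_localities)
        if not retained:
            raise DataError("no species retained after the minimum-locality filter")
    except Exception as exc:
        fail("filter", exc)
    log(f"filter: {len(occ)} unique localities; retained {len(retained)} "
        f"species, excluded {len(excluded_few)} below "
        f"{config.min_localities} localities")

    # variable selection
    try:
        env_sel, removal_log = geodata.select_variables(env, config.correlation_cutoff)
        removal_log.to_csv(out / "variable_removal.csv", index=False)
    except Exception as exc:
        fail("variable_selection", exc)
    log(f"variables: kept {env_sel.n_layers} of {env.n_layers} layers")

    # per-species SDM + null test
    try:
        pool_df = pd.read_csv(config.pool)
        pool_df.columns = [c.strip().lower() for c in pool_df.columns]
        if "species" not in pool_df.columns:
            pool_df["species"] = "pool"
        pool_set = geodata.deduplicate(geodata.assign_cells(
            geodata.OccurrenceSet(pool_df), env.grid, mask=env.mask))
        rng = np.random.default_rng(config.seed)
        results = {}
        n_loc = {}
        smaps = {}
        features_cache: dict[int, maxent_sdm.FeatureMatrix] = {}
        for sp in retained:
            cells = occ.cells_for(sp)
            n = len(cells)
            key = n if config.feature_mode == "auto" else -1
            if key not in features_cache:
                mode = ("auto" if config.feature_mode == "auto"
                        else [c.strip() for c in config.feature_mode.split(",")])
                features_cache[key] = maxent_sdm.build_features(env_sel, n, mode)
            features = features_cache[key]
            pool_rows = null_model.pool_from_occurrences(pool_set, features)
            pres = features.rows_for_cells(cells)
            res = null_model.run_null_test(
                features, pres, pool_rows, R=config.null_replicates,
                reg_multiplier=config.reg_multiplier,
                max_iterations=config.max_iterations,
                seed=int(rng.integers(2 ** 31)))
            model, smap, _ = maxent_sdm.fit_and_score(
                features, pres, reg_multiplier=config.reg_multiplier,
                max_iterations=config.max_iterations)
            maxent_sdm.save_model(model, out / f"model_{sp}.txt")
            geodata.write_ascii_grid(smap.as_raster(env.grid),
                                     out / f"suitability_{sp}.asc")
            results[sp] = res
            n_loc[sp] = n
            smaps[sp] = smap
        table = null_model.null_test_table(results, n_loc)
        table.to_csv(out / "null_tests.csv", index=False)
    except Exception as exc:
        fail("sdm_null_test", exc)
    n_sig = int(table["significant"].sum())
    log(f"sdm: fitted {len(retained)} species; {n_sig} significant under the "
        f"null model ({config.null_replicates} replicates)")

    # exclusions
    excluded = list(excluded_few)
    if config.exclude_nonsignificant:
        failed = sorted(table.loc[~table["significant"], "species"])
        excluded += failed
        smaps = {sp: m for sp, m in smaps.items() if sp not in set(failed)}
        if failed:
            log(f"excluded non-significant species: {', '.join(failed)}")

    # overlap
    try:
        if len(smaps) < 2:
            raise DataError("fewer than two species left for overlap analysis")
        overlap = niche_overlap.pairwise_overlap(smaps)
        overlap.to_csv(out / "overlap_matrix.csv")
        clade_summary = None
        if config.clade_partition and Path(config.clade_partition).is_file():
            part_df = pd.read_csv(config.clade_partition)
            partition = dict(zip(part_df["species"], part_df["clade"]))
            clade_summary = niche_overlap.clade_overlap_summary(overlap, partition)
            clade_summary.to_csv(out / "clade_summary.csv", index=False)
    except Exception as exc:
        fail("overlap", exc)
    log(f"overlap: {len(overlap)}x{len(overlap)} Hellinger's I matrix")

    # patristic + conservatism
    try:
        dist = patristic_matrix(tree)
        dist.to_csv(out / "patristic_matrix.csv")
        cons = conservatism.conservatism_test(
            overlap, dist, run_mantel=config.run_mantel,
            n_perm=config.mantel_permutations, seed=config.seed)
        cons.to_frame().to_csv(out / "conservatism.csv", index=False)
    except Exception as exc:
        fail("conservatism", exc)
    log(f"conservatism: n_pairs={cons.n_pairs} r={cons.r:.4f} "
        f"R^2={cons.r_squared:.4f} p={cons.p_value:.4g}")

    # report + config echo
    wall = time.time() - t0
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    with open(out / "report.txt", "w") as fh:
        fh.write("nichephylo pipeline report\n")
        fh.write(f"seed: {config.seed}\nwall_clock_s: {wall:.2f}\n\n")
        fh.write("assumed settings not fixed by the study design: "
                 f"correlation cutoff {config.correlation_cutoff}, "
                 f"regularization multiplier {config.reg_multiplier}\n\n")
        fh.write("\n".join(stage_log) + "\n")
    return RunReport(config, table, overlap, clade_summary, cons,
                     excluded, wall, stage_log)
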