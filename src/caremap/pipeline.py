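"""End-to-end analysis pipeline.

Stage order mirrors the standard small-area workflow: indirect
standardization (SMR) -> spatially smoothed SMR -> Moran's I of the smoothed
surface -> VIF collinearity screen -> covariate-adjusted Leroux CAR fit ->
posterior summaries.  Covariates the screen drops are excluded from the fit
automatically and recorded, so the screening decision itself is
reproducible.  Every stage's inputs, outputs, warnings and timing land in a
machine-readable manifest; given the manifest (config + seed + package
versions) the run is exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .collinearity import screen
from .data import read_area_table, read_gal, write_results
from .errors import CaremapError, SchemaError
from .leroux import LerouxModelSpec, fit, smoothed_smr, summarize
from .moran import morans_i
from .standardization import standardize

log = logging.getLogger("caremap.pipeline")


class PipelineError(CaremapError):
    """A stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, covariate roles and model settings for one full run."""

    table: str
    gal: str
    out_dir: str
    covariates: tuple[str, ...]
    psychiatrist_col: str | None = None
    vif_covariates: tuple[str, ...] | None = None  # default: socioeconomic set
    vif_threshold: float = 2.5
    moran_permutations: int = 999
    moran_style: str = "row"
    model: LerouxModelSpec = field(default_factory=LerouxModelSpec)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        model = LerouxModelSpec(**raw.pop("model", {}))
        raw["covariates"] = tuple(raw["covariates"])
        if raw.get("vif_covariates") is not None:
            raw["vif_covariates"] = tuple(raw["vif_covariates"])
        return cls(model=model, **raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _screen_set(cfg: PipelineConfig) -> list[str]:
    """Covariates entering the VIF screen.

    By default the screen covers the socioeconomic covariates only — the
    health-workforce variables (physician density and the psychiatrist
    indicator) are the exposures of interest and are kept out of the
    drop rule.
    """
    if cfg.vif_covariates is not None:
        return list(cfg.vif_covariates)
    exclude = {cfg.psychiatrist_col} if cfg.psychiatrist_col else set()
    exclude.add("physicians_per_1000")
    return [c for c in cfg.covariates if c not in exclude]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; return the result bundle.

    Artifacts written to ``cfg.out_dir``: smr.csv, ssmr.csv, moran.json,
    vif.json, fit.json and manifest.json.  Any stage failure aborts with
    the stage name; artifacts produced so far stay on disk and the manifest
    carries a FAILED marker for the offending stage.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.as_dict(),
        "seed": cfg.seed,
        "versions": {
            "caremap": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
        "status": "RUNNING",
    }
    bundle: dict = {}
    stage = "init"

    def _finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
        log.info("stage %s done (%.2fs)", name, manifest["stages"][name]["seconds"])

    def _write_manifest() -> None:
        write_results(manifest, out / "manifest.json")

    try:
        # ------------------------------------------------------------ read
        stage = "read"
        t0 = time.perf_counter()
        table = read_area_table(cfg.table)
        missing = [c for c in cfg.covariates if c not in table.covariates.columns]
        if missing:
            raise SchemaError(f"covariate column(s) not in table: {missing}")
        if cfg.psychiatrist_col and cfg.psychiatrist_col not in table.covariates.columns:
            raise SchemaError(
                f"psychiatrist column {cfg.psychiatrist_col!r} not in table"
            )
        adj = read_gal(cfg.gal, table.area_ids)
        manifest["warnings"].extend(adj.warnings)
        n_isolated = int(adj.isolated.sum())
        if n_isolated:
            manifest["warnings"].append(f"{n_isolated} isolated area(s) (no neighbors)")
        _finish_stage("read", t0, n_areas=table.n_areas, n_edges=adj.n_edges)

        # --------------------------------------------------------- smr
        stage = "smr"
        t0 = time.perf_counter()
        rates, expected, smr_vec = standardize(table)
        smr_df = pd.DataFrame(
            {
                "area_id": table.area_ids,
                "O": table.observed_totals,
                "E": expected.expected,
                "SMR": smr_vec.smr,
                "flag_undefined": ~smr_vec.defined,
            }
        )
        smr_df.to_csv(out / "smr.csv", index=False)
        bundle["smr"] = smr_df
        _finish_stage("smr", t0, total_observed=int(table.observed_totals.sum()))

        # modeled subset: areas with positive expected counts
        keep = expected.expected > 0
        if not keep.all():
            manifest["warnings"].append(
                f"{int((~keep).sum())} area(s) with E=0 excluded from model fitting"
            )
        adj_m = adj.subset(keep) if not keep.all() else adj
        o_m = table.observed_totals[keep]
        e_m = expected.expected[keep]

        # --------------------------------------------------------- ssmr
        stage = "ssmr"
        t0 = time.perf_counter()
        sm = smoothed_smr(
            o_m, e_m, adj_m, dataclasses.replace(cfg.model, seed=cfg.seed)
        )
        ssmr_df = pd.DataFrame({"area_id": sm.area_ids, "sSMR": sm.ssmr})
        ssmr_df.to_csv(out / "ssmr.csv", index=False)
        bundle["ssmr"] = ssmr_df
        _finish_stage(
            "ssmr", t0, mean_ssmr=float(sm.ssmr.mean()), sd_ssmr=float(sm.ssmr.std())
        )

        # --------------------------------------------------------- moran
        stage = "moran"
        t0 = time.perf_counter()
        moran = morans_i(
            sm.ssmr,
            adj_m,
            style=cfg.moran_style,
            n_perm=cfg.moran_permutations,
            seed=cfg.seed,
        )
        write_results(moran.as_dict(), out / "moran.json")
        bundle["moran"] = moran
        _finish_stage("moran", t0, morans_i=moran.i, p_value=moran.p_value)

        # ----------------------------------------------------------- vif
        stage = "vif"
        t0 = time.perf_counter()
        screen_cols = _screen_set(cfg)
        report, _ = screen(
            table.covariates.loc[keep, screen_cols],
            screen_cols,
            threshold=cfg.vif_threshold,
        )
        write_results(report.as_dict(), out / "vif.json")
        bundle["vif"] = report
        dropped = [name for name, _ in report.dropped]
        _finish_stage("vif", t0, dropped=dropped)

        # ----------------------------------------------------------- fit
        stage = "fit"
        t0 = time.perf_counter()
        fit_cols = [c for c in cfg.covariates if c not in dropped]
        x = np.column_stack(
            [np.ones(int(keep.sum())), table.covariates.loc[keep, fit_cols].to_numpy()]
        )
        f = fit(
            o_m,
            e_m,
            x,
            adj_m,
            dataclasses.replace(cfg.model, seed=cfg.seed),
            coef_names=("intercept", *fit_cols),
        )
        summary = summarize(f)
        fit_json = {
            "summary": summary.as_dict(),
            "acceptance": f.acceptance,
            "covariates": fit_cols,
            "dropped_by_vif": dropped,
            "n_areas_modeled": int(keep.sum()),
        }
        write_results(fit_json, out / "fit.json")
        bundle["fit"] = f
        bundle["summary"] = summary
        _finish_stage("fit", t0, converged=summary.converged)

        manifest["status"] = "OK"
        _write_manifest()
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
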