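"""End-to-end orchestration: simulate -> vca -> plan -> agree -> injury -> spatial.

One global seed fans out deterministically to per-stage child seeds so any
stage can be re-run in isolation with identical output. Every stage writes
its tables/JSON into the output directory and registers them in the
returned manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io, sampling_plan, spatial, synthetic, threshold, vca
from ._rand import child_seed
from .injury import fit_injury, predict_retention

log = logging.getLogger("lygusscout")

SWEEP_THRESHOLD = 8.0    # adults+nymphs per 100 sweeps (squaring)
DROP_THRESHOLD = 2.5     # adults+nymphs per 1.5 row-m (bloom)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "lygusscout-run"
    precision_D: float = 0.25
    sweep_threshold: float = SWEEP_THRESHOLD
    drop_threshold: float = DROP_THRESHOLD
    sweep_spec: synthetic.HierarchySpec | None = None
    drop_spec: synthetic.HierarchySpec | None = None
    n_landscape_fields: int = 60
    retention_beta0: float = math.log(23.4)
    retention_beta1: float = -0.012
    retention_re_sd: float = 0.1
    rvsp_n_sim: int = 500
    spatial_kwargs: dict = field(default_factory=dict)
    units_csv: dict = field(default_factory=dict)  # optional user CSVs per method
    spatial_csv: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.precision_D <= 1:
            raise ValueError("precision_D must lie in (0, 1]")
        if min(self.sweep_threshold, self.drop_threshold) <= 0:
            raise ValueError("thresholds must be positive")


def _default_specs(config: PipelineConfig):
    sweep = config.sweep_spec or dataclasses.replace(
        synthetic.HierarchySpec(), seed=child_seed(config.seed, "sweep"))
    drop = config.drop_spec or synthetic.HierarchySpec(
        n_states=5, districts_per_state=2, fields_per_district=7,
        variance_shares={"year": 0.01, "state": 0.10, "district": 0.07,
                         "field": 0.45, "quadrant": 0.37, "error": 0.0},
        grand_mean=0.7, taylor_a=1.08, taylor_b=1.17,
        seed=child_seed(config.seed, "drop"), total_sd=1.3)
    return sweep, drop


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of produced files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}, "timing_s": {}}

    def register(name: str, path: Path):
        manifest["files"][name] = str(path)

    data = {}

    def _simulate():
        sweep_spec, drop_spec = _default_specs(config)
        for method, spec in (("sweep", sweep_spec), ("drop", drop_spec)):
            if method in config.units_csv:
                units = io.read_units_csv(config.units_csv[method])
            else:
                units = synthetic.generate_hierarchical_counts(spec, method)
            data[method] = units
            path = out / f"units_{method}.csv"
            io.write_units_csv(units, path)
            register(f"units_{method}", path)
        retention = synthetic.generate_retention(
            data["sweep"], beta0=config.retention_beta0,
            beta1=config.retention_beta1,
            re_sd_field=config.retention_re_sd,
            re_sd_quadrant=config.retention_re_sd,
            seed=child_seed(config.seed, "retention"))
        data["retention"] = retention
        path = out / "retention.csv"
        io.write_retention_csv(retention, path)
        register("retention", path)
        if config.spatial_csv:
            dataset = io.read_spatial_csv(config.spatial_csv)
            landscape = None
        else:
            landscape, dataset = synthetic.generate_landscape_dataset(
                config.n_landscape_fields,
                seed=child_seed(config.seed, "landscape"))
        data["spatial"] = dataset
        if landscape is not None:
            path = out / "landscape.csv"
            io.write_landscape_csv(landscape, path)
            register("landscape", path)
        path = out / "spatial.csv"
        io.write_spatial_csv(dataset, path)
        register("spatial_dataset", path)

    def _vca():
        for method in ("sweep", "drop"):
            table = vca.fit_nested_vca(data[method])
            path = out / f"vca_{method}.csv"
            table.to_frame().to_csv(path, index=False)
            register(f"vca_{method}", path)
        cv_cmp = vca.cv_asymptotic_test(
            data["sweep"]["total"], data["drop"]["total"])
        path = out / "cv_test.json"
        io.write_json(cv_cmp, path)
        register("cv_test", path)

    def _plan():
        for method in ("sweep", "drop"):
            fit = sampling_plan.fit_taylor(data[method])
            plan = sampling_plan.SamplingPlan.from_fit(fit, config.precision_D)
            pooled_mean = data[method]["total"].mean()
            rvsp = sampling_plan.resample_validation(
                data[method]["total"].to_numpy(), fit.a, fit.b,
                D=config.precision_D, n_sim=config.rvsp_n_sim,
                seed=child_seed(config.seed, f"rvsp-{method}"))
            path = out / f"plan_{method}.json"
            io.write_json({
                "taylor": fit, "precision_D": config.precision_D,
                "green_N_at_pooled_mean": sampling_plan.green_sample_size(
                    fit.a, fit.b, pooled_mean, config.precision_D),
                "rvsp": {"navg": rvsp.navg, "nsd": rvsp.nsd,
                         "nmin": rvsp.nmin, "nmax": rvsp.nmax},
            }, path)
            register(f"plan_{method}", path)
            stop_path = out / f"stop_line_{method}.csv"
            plan.stop_table.to_csv(stop_path, index=False)
            register(f"stop_line_{method}", stop_path)

    def _agree():
        for method, thr in (("sweep", config.sweep_threshold),
                            ("drop", config.drop_threshold)):
            summary = threshold.agreement_analysis(data[method], thr)
            path = out / f"agreement_{method}.json"
            io.write_json(summary, path)
            register(f"agreement_{method}", path)

    def _injury():
        fit = fit_injury(data["retention"])
        path = out / "injury.json"
        io.write_json({
            "fit": fit,
            "retention_at_threshold_pct": predict_retention(
                fit, config.sweep_threshold),
        }, path)
        register("injury", path)

    def _spatial():
        fit = spatial.fit_spatial(data["spatial"], **config.spatial_kwargs)
        path = out / "spatial_fit.json"
        io.write_json({
            "params": fit.params.reset_index(names="covariate"),
            "sigma2_w": fit.sigma2_w, "rho": fit.rho,
            "stage_sd": fit.stage_sd,
        }, path)
        register("spatial_fit", path)
        cv_res = spatial.cross_validate(
            data["spatial"], seed=child_seed(config.seed, "spatial-cv"),
            **config.spatial_kwargs)
        path = out / "spatial_cv.csv"
        io.write_json({
            "slope": cv_res.slope, "intercept": cv_res.intercept,
            "r2": cv_res.r2, "p_value": cv_res.p_value,
            "predicted": cv_res.predicted, "observed": cv_res.observed,
        }, out / "spatial_cv.json")
        register("spatial_cv", out / "spatial_cv.json")

    for name, fn in (("simulate", _simulate), ("vca", _vca), ("plan", _plan),
                     ("agree", _agree), ("injury", _injury), ("spatial", _spatial)):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["timing_s"][name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, manifest["timing_s"][name])

    manifest_path = out / "manifest.json"
    register("manifest", manifest_path)
    io.write_json(manifest, manifest_path)
    return manifest
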